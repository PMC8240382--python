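"""Parity-mode discrimination: grow the Gini tree on the window's climatic
covariates, 10-fold cross-validate, prune with the 1-SE rule, and report
variable importance and the confusion summary, for both windows."""

from _common import OCC_CSV, RESULTS, SEED, WORLD_DIR
from parityniche import (
    MonthlyClimateStack,
    RunConfig,
    read_occurrences,
    run_period,
)

stack = MonthlyClimateStack.load(WORLD_DIR)
occ = read_occurrences(OCC_CSV)

for period in ("reproductive", "annual"):
    cfg = RunConfig(period=period, background_n=1000, seed=SEED,
                    run_overlap_tests=False)
    bundle = run_period(stack, occ, cfg, outdir=RESULTS / period)
    pruned = bundle["pruned_tree"]
    cs = bundle["confusion"]
    print(f"\n== {period} ==")
    print(pruned.to_text())
    print(f"leaves: {pruned.n_leaves()}; overall correct: {cs.percent()}% "
          f"(oviparous {cs.percent('oviparous')}%, "
          f"viviparous {cs.percent('viviparous')}%)")
    print("top importance (global, % of impurity improvement):")
    print(bundle["importance"].head(4).to_string(index=False))
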