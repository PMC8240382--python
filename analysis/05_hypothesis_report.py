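"""Map each window's observed parity-mode climate differences onto the
viviparity hypotheses (cold-climate / maternal-manipulation /
selfish-mother) via the 9-way combination table."""

import json

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
    pattern = bundle["pattern"]
    combo = bundle["combination"]
    print(f"\n== {period} ==")
    print(f"variability difference:        {pattern.variability_diff}")
    print(f"average-temperature difference: {pattern.mean_temp_diff}")
    print(f"-> combination {combo.number}: supported hypotheses "
          f"{list(combo.hypotheses) or 'none'} "
          f"(predictions {list(combo.predictions) or '-'})")
    print(f"full report: {RESULTS / period / 'hypothesis.json'}")
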