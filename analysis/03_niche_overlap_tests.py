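"""Niche ordination and overlap: PCA-env, per-clade occupancy surfaces,
pairwise Schoener's D, and the similarity/equivalency permutation tests,
for both study windows.  Tables land in results/<window>/."""

from _common import BACKGROUND_N, N_REPS, OCC_CSV, RESULTS, SEED, WORLD_DIR
from parityniche import (
    MonthlyClimateStack,
    RunConfig,
    overlap_matrix_frame,
    read_occurrences,
    run_period,
)

stack = MonthlyClimateStack.load(WORLD_DIR)
occ = read_occurrences(OCC_CSV)

for period in ("reproductive", "annual"):
    cfg = RunConfig(
        period=period, background_n=BACKGROUND_N, n_reps=N_REPS, seed=SEED
    )
    bundle = run_period(stack, occ, cfg, outdir=RESULTS / period)
    model = bundle["model"]
    print(f"\n== {period} ==")
    print(
        f"PC1 {100 * model.explained[0]:.1f}% / PC2 {100 * model.explained[1]:.1f}% "
        f"of climatic variation"
    )
    d = bundle["d_obs"]
    lo = min(d, key=d.get)
    hi = max(d, key=d.get)
    print(f"D range: {d[lo]:.3f} ({'-'.join(lo)}) .. {d[hi]:.3f} ({'-'.join(hi)})")
    n_noneq = sum(1 for t in bundle["equivalency"].values() if t.p_value <= 0.05)
    n_sim = sum(1 for t in bundle["similarity"].values() if t.p_value < 0.05)
    print(
        f"equivalency rejected (niches non-equivalent) in {n_noneq}/15 pairs; "
        f"similarity significant in {n_sim}/15 pairs"
    )
    print(overlap_matrix_frame(bundle).to_string())
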