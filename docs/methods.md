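# Methods

This note documents the models, conventions and design choices behind
`parityniche`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Bioclimatic variables over a month window

All derived variables are statistics of the monthly layers restricted to a
window *W* of calendar months (the full year, or May–July for the
reproductive season). With tavgₘ = (tminₘ + tmaxₘ)/2:

| variable | definition | units |
|---|---|---|
| BIO1 | mean over W of tavgₘ | °C |
| BIO2 | mean over W of (tmaxₘ − tminₘ) | °C |
| BIO3 | 100 · BIO2 / (max tmaxₘ − min tminₘ) | % |
| BIO4 | 100 · SD over W of tavgₘ | SD×100, °C·100 |
| BIO6 | min over W of tminₘ | °C |
| BIO15 | 100 · SD over W of precₘ / (1 + mean precₘ) | CV % |
| minTmax | min over W of tmaxₘ | °C |
| meanTmin | mean over W of tminₘ | °C |

Conventions: sample SD (ddof = 1) for BIO4/BIO15, matching the common
bioclim toolchains; the +1 in the BIO15 denominator is the ANUCLIM guard
against arid-pixel division; BIO4 is kept on the SD×100 scale internally
(divide by 100 for a °C reading). Window months are sorted before any
computation so results are exactly invariant to how the window is written.
A single-month window is rejected (the seasonality SDs are undefined);
pixels with zero window temperature range get BIO3 = nodata with a warning;
nodata in any contributing monthly layer propagates to every derived layer.

The reproductive covariate set is {BIO2, BIO3, BIO4, BIO6, BIO15, minTmax,
meanTmin}; the annual set replaces the window-specific minTmax/meanTmin with
BIO1 to give six non-redundant variables. Both lists are configurable. For
the hypothesis mapping the variables are classed as *variability*-type
(BIO2, BIO3, BIO4, BIO15) or *average-temperature*-type (BIO1, BIO6,
minTmax, meanTmin).

Rasters use geographic lon/lat, pixel-is-area, row 0 at the top, and
point→pixel lookup by floor((coord − origin)/pixel_size). On-disk formats
are ESRI ASCII grid (plain text) and single-band TIFF via `tifffile`, with
the grid geometry carried in the ImageDescription tag; an optional
temperature scale factor supports the classic ×10 integer-storage dialect.

## Niche ordination (PCA-env)

The analysis extent is the convex hull of the occurrence records (pixel
centers on the hull boundary count as inside). A background (availability)
sample of 20 000 distinct pixels — 5 000 in the synthetic-world runs, where
a 200×200 landscape has only 40 000 pixels — is drawn uniformly inside the
hull, excluding nodata pixels. The ordination is a correlation-matrix PCA
(variables standardized by the calibration mean and ddof-1 SD) fitted on
background ∪ occurrences; axis signs are fixed so each axis's
largest-magnitude loading is positive, making runs reproducible.

Occupancy surfaces live on a 100×100 grid spanning the pooled background
scores on (PC1, PC2) expanded by a 5 % margin so kernels are not clipped;
all clades of a run share the grid. Densities use a separable Gaussian
product kernel with per-axis Silverman bandwidths (0.9·min(SD, IQR/1.34)·
n^(−1/5)), estimated from the occurrence scores for the occurrence density
*o* and from the background scores for the availability density *e*; a
scalar bandwidth multiplier is exposed. The default occupancy is
availability-corrected, z ∝ o/e on cells with e above ε = 10⁻¹²·max(e)
(z = 0 elsewhere), normalized to Σz = 1; a raw mode (z ∝ o) is retained for
sensitivity analysis. Overlap is Schoener's D = 1 − ½·Σ|z₁ − z₂|, clipped
to [0, 1].

## Permutation tests

Both tests compare the observed D of a clade pair against 1000
(configurable) simulated overlaps, with add-one p-values
(p_lower = (1 + #{D_sim ≤ D_obs})/(n + 1); two-tailed doubles the smaller
tail, capped at 1), so p is never 0. Replicate *r* draws its generator from
seed base + r, making the null distribution independent of scheduling.

*Similarity* (two-tailed): each replicate translates **both** clades'
occupancy surfaces by independent uniform random cell offsets; cells shifted
off the grid or off the background-supported cells are dropped and the
surface renormalized; offsets leaving no mass are redrawn. A one-sided-shift
variant is available by flag.

*Equivalency* (lower-tailed — rejects when the two niches overlap less than
exchangeable occurrences would allow): pooled occurrence scores are randomly
re-partitioned into the original group sizes and the surfaces — including
their Silverman bandwidths — are rebuilt from scratch each replicate,
mirroring exactly the procedure that produced D_obs. The pooled rows are
put in canonical (sorted) order first, so the test is exactly symmetric in
clade order. The availability surface does not depend on the partition and
is computed once. Under the null (both clades drawn from one niche) the
test statistic is exchangeable with its replicates, so p-values are uniform
on {1/(n+1), …, 1}; the acceptance suite verifies the 5 % rejection rate
and KS-uniformity over 500 simulated datasets.

Output tables mirror the paper-style pairwise matrix: D_obs (with an
asterisk when the similarity test is significant) below the diagonal,
equivalency significance codes (** p ≤ 0.01, * p < 0.05, NS) above it.

## Classification trees

The CART implementation is self-contained because surrogate splits, the
relative-error cross-validation profile and primary+surrogate importance
are the quantities of interest and are not exposed together by the usual
Python libraries.

*Growing.* Binary splits minimize Gini impurity; the split search is
exhaustive over midpoints of consecutive distinct values, ties resolved to
the smallest threshold, then the lowest variable index. Defaults follow
classic CART practice: minsplit = 20, minbucket = 7 (= round(minsplit/3)),
complexity parameter 0 (grow until pure or the size limits bind). Splits
searched on a partially missing covariate are down-weighted by the observed
fraction. Each node retains up to (n_covariates − 1) surrogate splits,
ranked by agreement with the primary left/right assignment and kept only if
they beat the blind majority-direction rule; missing values route primary →
surrogates → majority side.

*Pruning.* Weakest-link cost-complexity pruning with misclassification-count
risk; cp is normalized by the root risk (the relative-error scale). Every
step of the sequence is the *smallest* optimal subtree at its cp — in
particular the cp = 0 row already collapses branches whose splits do not
change the training misclassification count. Cross-validation uses
stratified-by-class folds (10 by default, fixed seed; fold construction
retries if a training fold would lose a class), evaluates each fold's tree
at the geometric means of adjacent cp values, and reports
xerror = CV misclassifications / root risk with
xstd = sqrt(err·(1 − err/n)) / root risk. Note xerror is normalized by the
*in-sample* root risk, which underestimates the population trivial error by
O(√n) counts, so under pure noise xerror sits slightly above 1 — the null
simulation in the test suite quantifies this. The 1-SE rule selects the
smallest subtree whose xerror is within one xstd of the minimum.

*Importance.* Each split credits its primary variable with its n-weighted
Gini decrease; each retained surrogate earns the same improvement weighted
by its **adjusted** agreement, (agree − majority)/(n − majority) — the
rpart convention, under which a surrogate that barely beats the trivial
rule earns almost nothing (raw-agreement weighting was considered and
rejected: it lets any landscape-correlated covariate accumulate large
surrogate credit at every split). Credits are normalized to percent, either
globally or per split; a variable is *significant* when its share exceeds
100/n_variables. Direction tags give each variable's association with
viviparity: the primary variable's sign comes from which child leans
viviparous, surrogate variables inherit it through the sign of their
Spearman correlation with the primary variable on the node's cases, and
votes are improvement-weighted across splits.

*Confusion summaries* use resubstitution predictions (the leaf counts of
the pruned tree account for the full sample), reported per parity mode, per
clade and overall, with percentages rounded to one decimal.

## Hypothesis mapping

The pruned global tree's significant variables are reduced to a
(variability difference, average-temperature difference) pattern: within
each variable family the significant variables vote by majority of their
direction tags; an exact tie maps to "no difference" with a warning. The
pattern indexes the fixed 9-row combination table linking it to the
supported hypothesis predictions (CCP₁; MMP₁…₃; SMP₁…₂). Conditional rows
(higher variability + higher temperature; lower variability + lower
temperature) carry their trade-off footnotes verbatim rather than being
resolved — no decision rule for the trade-off magnitudes exists. The
schematic incubation-temperature ranges behind the predictions are
represented only as these enumerated outcomes, not as numeric ranges.

## Synthetic worlds

The generator emulates what the pipeline needs from a real monthly climate
product and georeferenced clade occurrences, not climatic realism (no
orography, lapse rates or dispersal). Per-pixel monthly mean temperature is

    T(m) = base + a1·cos(2π(m−7)/12) + a2·cos(4π(m−7)/12) + noiseₘ,

where base, the harmonic amplitudes a1/a2, the diurnal range (≥ 0.5 °C) and
the precipitation parameters are low-frequency Gaussian random fields
(smoothed white noise re-standardized to the target mean/SD; correlation
length 15 pixels on the default 200×200 grid). tmin/tmax sit half a diurnal
range below/above T(m), so tmax ≥ tmin by construction; precipitation is
log-normal with a seasonally modulated exponent, hence non-negative with
spatially varying BIO15. The second harmonic decouples May–July seasonality
from annual seasonality (their window variances weight a1 and a2
differently), which is what makes a reproductive-vs-annual sign reversal
geographically realizable. With a single harmonic the annual temperature SD
is |a1|·√(6/11) exactly — the generator test checks the realized spatial
mean of BIO4 against this closed form.

Occurrences: 185 records split A:37, B:41, C:19, D:26, E:47, F:15 (the real
sample's clade structure; A–B oviparous, C–F viviparous). Each clade samples
pixels without replacement with probability ∝ a Gaussian suitability kernel
(width 0.5 field-SD) around the clade's niche centroid, specified as offsets
in field-SD units on chosen (window, variable) pairs. Presets:

- `null` — all centroids at the landscape mean;
- `smh_reproductive` — viviparous clades 1.5 field-SD below oviparous in
  reproductive BIO4 and BIO15;
- `cch_cold` — viviparous 1.5 SD below in reproductive meanTmin and BIO6;
- `mmh_variable` — viviparous 1.5 SD above in reproductive BIO4 and BIO15;
- `annual_reversal` — viviparous below oviparous in reproductive BIO4 but
  above in annual BIO4.

Directional presets also *anchor* the opposite variable family at the
landscape mean for every clade (e.g. `smh_reproductive` pins meanTmin,
minTmax and BIO6 at offset 0): the annual cosine does not average to zero
over May–July, so selecting low-seasonality pixels would otherwise also
select different average temperatures and contaminate a scenario defined as
"variability differs, averages do not".

What passing tests on these worlds do and do not show: they demonstrate
that the pipeline recovers known, well-separated niche structure and stays
calibrated under the null; they do not establish anything about the real
Eurasian system, whose effect sizes, spatial sampling biases, collinearity
structure and nodata geometry the generator does not attempt to reproduce.

## Problem sizes and numerical choices

Synthetic-world runs use a 200×200 grid, 5 000 background pixels and (in
the narrative scripts) 199 permutation replicates; the calibration
experiment uses 500 simulated datasets × 99 permutations and the recovery
experiment 100 seeded worlds — sizes chosen so the whole study re-runs on a
laptop-class single core in minutes while keeping Monte-Carlo error well
inside the asserted bounds. Degenerate inputs are defined, not accidental:
constant climates give BIO4 = BIO15 = 0 exactly; a pure or one-class sample
yields a single-leaf tree with a warning; an unreachable synthetic niche
centroid raises with advice. Known limitations: geographic-space overlap,
MaxEnt-style suitability modelling, Hellinger-based overlap (I), random
forests and formal mean-difference tests between parity modes are out of
scope; occurrence records are not deduplicated per pixel by default —
distinct populations are distinct records even when they share a pixel —
but `RunConfig(dedupe=True)` drops same-clade same-pixel duplicates.
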