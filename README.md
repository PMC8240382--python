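# parityniche

Climatic-niche comparison of egg-laying (oviparous) and live-bearing
(viviparous) clades of the Eurasian common lizard *Zootoca vivipara*, and a
test of which hypothesis for the evolution and maintenance of viviparity —
cold-climate (CCH), maternal-manipulation (MMH) or selfish-mother (SMH) —
the observed climate differences support.

The species comprises six genetic clades: A and B are oviparous, C–F are
viviparous. Because all three hypotheses locate the benefit of live birth in
the *reproductive* season, every analysis is run twice: on annual climates
and on the May–July reproductive window.

## What the package computes

1. **Window-specific bioclim variables** from monthly tmin/tmax/precipitation
   rasters: mean diurnal range (BIO2), isothermality (BIO3), temperature
   seasonality (BIO4 = 100·SD of monthly mean temperature), minimum
   temperature of the coldest window month (BIO6), precipitation seasonality
   (BIO15 = 100·SD/(1+mean)), plus minTmax and meanTmin for the reproductive
   window and BIO1 for the annual set.
2. **PCA-env niche ordination**: a correlation-matrix PCA calibrated on
   20 000 background pixels sampled inside the convex hull of the occurrences
   pooled with the occurrence pixels; a 100×100 grid over (PC1, PC2); per-clade
   Gaussian-kernel occurrence densities corrected by background availability
   and normalized into occupancy surfaces *z* (Σz = 1).
3. **Niche overlap and permutation tests**: Schoener's
   *D* = 1 − ½·Σ|z₁ − z₂| for each clade pair; a two-tailed *similarity* test
   (both occupancy surfaces translated by random offsets, 1000 replicates) and
   a lower-tailed *equivalency* test (pooled occurrences randomly re-assigned,
   surfaces rebuilt per replicate), with add-one permutation p-values.
4. **Parity-mode discrimination**: a CART classification tree (Gini impurity,
   complexity parameter 0, up to n−1 surrogate splits per node), 10-fold
   cross-validated, pruned by the 1-SE rule; variable importance as percent of
   primary + surrogate impurity improvement with a 100/n-variables
   significance threshold and per-variable direction tags.
5. **Hypothesis mapping**: the observed (variability difference,
   average-temperature difference) pattern between parity modes is looked up
   in the 9-way combination table; e.g. lower climatic variability for
   viviparous clades with no average-temperature difference is combination 7,
   which supports only the SMH (prediction SMP₁).

Because the original occurrence coordinates and the global climate rasters
are not redistributable, the package ships a first-class synthetic world
generator (`parityniche.synthetic`): smooth Gaussian-random-field monthly
climates with an annual temperature cycle, and 185 clade-structured
occurrences whose niche centroids are set by scenario presets (`null`,
`smh_reproductive`, `cch_cold`, `mmh_variable`, `annual_reversal`).

## Worked example

The numbered scripts under `analysis/` run the whole study on the
selfish-mother synthetic scenario (`python analysis/01_simulate_world.py`,
then 02…05; rasters land in `scratch/`, tables in `results/`). Script 04
prints, for the reproductive window:

```
split 1: BIO4 < 229.7 [78/107] (decrease 0.4055, 6 surrogate(s))
  leaf: predict viviparous [3/102]
  leaf: predict oviparous [75/5]
leaves: 2; overall correct: 95.7% (oviparous 96.2%, viviparous 95.3%)
top importance (global, % of impurity improvement):
variable  importance_pct  significant  direction
    BIO4       33.755274         True         -1
   BIO15       27.426160         True         -1
    BIO3       24.894515         True          1
```

Reading: the pruned tree separates parity modes with a single threshold on
temperature seasonality — occurrences with BIO4 below 229.7 (i.e. monthly
mean temperatures varying by less than ≈2.3 °C SD over May–July) are
classified viviparous (102 of the 107 viviparous records fall there, against
3 oviparous); the significant variables are all seasonality-related, with
lower values (direction −1) associated with viviparity. Script 05 then maps
this pattern (variability ↓ for viviparous, averages unchanged) to
combination 7 — selfish-mother hypothesis, prediction SMP₁.

The same machinery is available as a CLI
(`parityniche simulate|derive|niche|tests|cart|hypotheses|run-all`) and as a
library (`run_period` / `run_all` return the full result bundle).

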