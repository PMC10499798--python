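# suitmap

Ensemble boosted-regression-tree (BRT) suitability mapping and marginal-land
accounting for energy crops, with a fully synthetic virtual-species landscape
so the entire workflow runs and is testable end-to-end without any external
data download.

## The problem

Energy crops such as cassava are promoted for bioenergy, but planting them on
productive farmland competes with food. The question this pipeline answers
is: *how much marginal land — grassland, savanna, shrubland — is
environmentally suitable for the crop, where is it, and how does that change
under future climate scenarios?*

The workflow is the standard ensemble species-distribution-model (SDM)
protocol used in ecological niche modelling:

1. **Occurrences → presence cells.** Georeferenced occurrence records are
   aggregated onto a regular 0.05° lat-lon grid; duplicate records collapse
   to unique presence cells.
2. **Screened background sampling.** Pseudo-absence (background) cells are
   drawn from cells a reference suitability surface scores below 0.5,
   excluding presence cells. Each of B = 25 seeded draws takes exactly as
   many background cells as there are presences (draw *b* is seeded
   `base_seed + b`).
3. **Boosted regression trees.** One sub-model per draw: stagewise additive
   logistic boosting of depth-limited regression trees on the Bernoulli
   deviance gradient — prediction = logistic(intercept + lr·Σ trees) — with
   shrinkage (`learning_rate`), bagging (`bag_fraction`), and the tree count
   selected by stratified ten-fold cross-validation on held-out deviance.
4. **Ensemble.** The 25 sub-model maps are averaged per cell; their
   per-cell standard deviation is the uncertainty layer. Diagnostics:
   ROC-AUC (rank formulation, ties ½), relative contribution (per-split gain
   accumulated per variable, normalized to 100%), and marginal-effect
   (partial-dependence) curves on the suitability scale.
5. **Accounting.** Suitable iff ensemble suitability ≥ 0.5; masked to
   marginal land-cover classes; per-region areas from the exact spherical
   band formula A = R²·Δλ·(sin φ_top − sin φ_bot), reported in Mha; scenario
   changes decomposed into expansion, contraction, and net = exp − con.

The synthetic-landscape module generates test worlds with the statistical
structure this analysis assumes: spatially autocorrelated covariates, a known
logistic truth dominated by one window-shaped temperature-annual-range
response, suitability-biased occurrence sampling, contiguous land-cover and
region partitions, and additive climate-shift scenarios.

## Worked example

The numbered scripts under `analysis/` run the study end-to-end on the
default synthetic world (200×200 cells at 0.05°, 8 climate layers plus
elevation/slope/soil, 1600 occurrence points, B = 25, trees capped at 1000):

```sh
python analysis/01_simulate_world.py
python analysis/02_fit_ensemble.py      # ~5 min on one core
python analysis/03_project_scenarios.py
python analysis/04_account_areas.py
```

`02_fit_ensemble.py` prints:

```
cross-validated AUC: {'across_folds': '0.986 ± 0.006', 'across_submodels': '0.986 ± 0.001'}
top relative contributions (%):
        variable  mean_pct  ci_low  ci_high
      temp_range     91.58   91.41    91.74
  temp_coldest_q      1.85    1.76     1.93
precip_wettest_q      1.43    1.37     1.50
   annual_precip      0.92    0.85     0.99
          bio_07      0.86    0.80     0.91
-> the dominant driver is temp_range at 91.6% [91.4, 91.7]
```

The ensemble discriminates presences from background almost perfectly
(AUC 0.986) and correctly identifies the generative world's dominant driver
(`temp_range`, built with 75% of the true effect weight) far above every
noise variable. `04_account_areas.py` then prints the area accounting:

```
current marginal land suitable for the crop: 16.31 Mha
   region  area_mha  percent
region_06      5.91    36.23
region_04      5.63    34.51
...
scenario net changes vs current (Mha):
  rcp45_2030      -1.19
  ...
  rcp85_2080      -8.97
```

In this virtual world warming shifts the temperature annual range *above*
the suitable window almost everywhere, so every scenario contracts — the
sign and monotone ordering across pathways/horizons is exactly what the
generative truth implies, which is the point of the recovery test.

There is also a CLI over the same pipeline:

```sh
suitmap report -c analysis/config.yaml        # all stages + run manifest
suitmap simulate|fit|project|account -c config.yaml [--seed N] [--outdir DIR]
```

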