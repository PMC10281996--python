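# shaderange

Ensemble species-distribution modelling for cocoa agroforestry: where do
cocoa and its shade-tree species find suitable habitat today, how does that
change under future climate scenarios, and where do enough shade species
overlap to support diverse agroforestry?

The package is a library-first implementation of the full multi-species
SDM pipeline — occurrence cleaning, buffered pseudo-absence sampling,
collinearity-driven predictor selection, a four-algorithm consensus model,
scenario projection with land-cover-constrained area accounting, and
stacked species-richness mapping — validated end to end on *virtual
species* whose true niches are known by construction. It is aimed at
ecologists and agroforestry researchers who want a tested, reproducible
desk-scale version of this workflow, driven from Python or from a single
YAML config.

## The method in brief

Per species, presences (after cleaning and 2.5 arc-min thinning, keeping
species with n > 60) are contrasted with 1000 pseudo-absences drawn
uniformly from land cells within 500 km of the presences. Predictors are
reduced by iterative VIF (drop while any VIF > 8, VIF = 1/(1−R²)) then
pairwise Pearson filtering (|r| ≤ 0.7). Four classifiers — GLM, GAM, GBM,
RF — are assessed by stratified fourfold cross-validation with

- AUC = P(score_presence > score_absence) (Mann–Whitney, ties ½),
- TSS = sensitivity + specificity − 1,

and combined as a weighted average with w_a ∝ max(AUC_a − 0.5, 0).
Continuous suitability is binarized at the threshold maximizing
sensitivity + specificity; suitable areas are geodesic-cell sums
(R²·Δλ·Δsin φ), optionally restricted to land-cover classes usable for
agroforestry (shrubs, grassland, cropland, sparse vegetation). Binary maps
stack into richness surfaces; hotspots are cells with richness strictly
above a threshold (default 25 species). Full details and design rationale:
[docs/methods.md](docs/methods.md).

## Worked example

`examples/` holds one short script per capability. Fitting the consensus
model for a virtual species whose niche uses only BIO1 and BIO12
(`python examples/05_ensemble_model.py`) prints:

```
mean 4-fold CV AUC per algorithm:
  GAM: 0.750  (weight 0.256)
  GBM: 0.724  (weight 0.230)
  GLM: 0.752  (weight 0.258)
  RF: 0.749  (weight 0.256)
binarization threshold (max sens+spec): 0.420, ensemble TSS 0.807
permutation importance (%):
BIO1     59.9
BIO12    39.9
phh2o     0.2
climatic/edaphic split: 100 / 0
```

All four algorithms discriminate presences from background at AUC ≈ 0.75
(the ceiling for a species this widespread — see the methods note), the
ensemble weights are nearly even because the skills are, and permutation
importance recovers the two layers the species actually responds to,
assigning the unused soil layer ~0%. Projecting the same model under a
warming/drying scenario (`python examples/06_projection_area_change.py`):

```
current suitable area: 50,545 km^2 (20.5% of the study area)
future suitable area:  32,623 km^2 (-35.5% vs current)
under the agroforestry land-cover mask: 29,251 -> 26,289 km^2 (-10.1%)
```

The end-to-end workflow runs from one config:

```bash
shaderange demo --out demo --seed 7      # synthetic inputs + config.yml
shaderange run --config demo/config.yml  # qc -> ... -> community products
```

producing per-species suitability/binary rasters, an area-change table per
scenario, richness and hotspot maps, and a manifest with a SHA-256
checksum per artifact (reruns are bit-identical for a fixed seed).

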