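# guildfill

Do non-native seed-eating birds establish in rice fields because those fields
hold resources that native birds under-exploit? `guildfill` is a Python
toolkit for the survey analysis behind that question: point-count surveys of
seed-eating birds across rice-growing landscapes, with

- **detectability-corrected densities** — half-normal point-transect detection
  functions g(r) = exp(−r²/2σ²) with covariates on log σ (emergent
  vegetation, trees/bushes, flock size), AIC selection over all
  simplifications of the global model, and density = count / p with
  p = (2σ²/w²)(1 − e^{−w²/2σ²}) averaged over the 100 m survey disc;
- **resource selection** — Jacobs index J = (u − a)/(u + a − 2ua) per species
  for feeding and shelter resources, with availability a conditioned on the
  point counts a species occupies, and community-weighted mean weight-holding
  capacity of field-margin plants;
- **functional diversity** — Gower distance on mixed trait matrices, an
  average-linkage dendrogram chosen by cophenetic correlation, branch-length
  FD ∈ [0, 1] per point-count community, and standardized effect sizes
  SES = (FD_obs − μ₀)/s₀ against richness-held null models (uniform or
  occurrence-frequency-weighted, 1000 iterations);
- **habitat-association gradients** — species scores (0/+1/+2) projected onto
  ordered wet→dry and open→closed gradients by a max-over-habitats rule, with
  native/non-native group profiles and their point of maximal divergence;
- **inference** — site-random-intercept mixed models fitted by ML with
  likelihood-ratio tests, Moran's I permutation diagnostics for residual
  spatial autocorrelation, and Wilcoxon–Mann–Whitney group comparisons;
- **a synthetic survey generator** with known ground truth (true abundances,
  detection scales, resource-use probabilities), so every estimator in the
  pipeline has a recovery test and the whole pipeline can be exercised
  end-to-end without any field data.

It is aimed at community ecologists analysing point-count data with resource
grids, and at anyone who wants a tested, reusable implementation of
dendrogram FD with null models or Jacobs-index selection.

## Worked example

Simulate a survey under the `paper-like` preset — 51 rice-containing and 10
rice-free sites, non-natives programmed denser in rice and sheltering in
emergent vegetation, most natives the reverse — and run the full analysis:

```python
from guildfill import synthetic, pipeline

config = synthetic.paper_like_config()
dataset, truth = synthetic.generate_survey(config, seed=7)
traits = synthetic.generate_traits(n_native=9, n_nonnative=4, seed=7)
result = pipeline.analyse(dataset, traits, pipeline.RunConfig(n_iter=1000, seed=7))

models = result["habitat_models"].set_index("response")
print(f"point counts: {len(dataset.point_counts)}, observations: {len(dataset.observations)}")
print(f"dendrogram: {result['dendrogram'].linkage_method} linkage, "
      f"cophenetic c = {result['dendrogram'].cophenetic_c:.3f}")
for resp in ("native_density", "nonnative_density", "fd_native"):
    row = models.loc[resp]
    print(f"{resp}: rice effect = {row['estimate']:+.3f}, chi2 = {row['chi2']:.2f}, P = {row['p']:.4f}")
w = result["selection_comparisons"].set_index(["activity", "resource"]).loc[("shelter", "emergent")]
print(f"emergent shelter selection, native vs non-native: W = {w['W']:.0f}, P = {w['p']:.4f}")
```

prints

```
point counts: 480, observations: 1207
dendrogram: average linkage, cophenetic c = 0.626
native_density: rice effect = -10.047, chi2 = 90.27, P = 0.0000
nonnative_density: rice effect = +12.014, chi2 = 94.57, P = 0.0000
fd_native: rice effect = -0.093, chi2 = 66.03, P = 0.0000
emergent shelter selection, native vs non-native: W = 0, P = 0.0028
```

Reading this: the rice coefficients are from site-random-intercept mixed
models compared to their intercept-only nulls by likelihood-ratio test —
native summed density is lower in rice fields and non-native density higher
(birds per point count, after dividing counts by detection probability), and
the functional diversity of the native community drops in rice (on the [0, 1]
FD scale). W = 0 is the native-group Mann–Whitney statistic for the emergent-
vegetation shelter Jacobs index: every native species ranks below every
non-native one, i.e. non-natives select emergent vegetation for shelter far
more strongly. All four recovered effects match the directions programmed
into the simulation truth.

The same stages are available from the shell, communicating via CSV:

```sh
guildfill simulate --preset paper-like --seed 7 --out survey/
guildfill validate --survey survey/
guildfill detect --survey survey/ --out detect/
guildfill select --survey survey/ --activity shelter --out selection.csv
guildfill fd --survey survey/ --traits survey/traits.csv --null frequency --seed 7 --out fd.csv
guildfill run --config run.yaml   # all stages + manifest.json with checksums
```

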