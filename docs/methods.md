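# Methods

`guildfill` implements the quantitative machinery of a point-count study of
seed-eating birds across rice-growing agricultural landscapes: how strongly
each species selects feeding and shelter resources, how detectability-corrected
densities and community functional diversity differ between rice fields and
adjacent open habitats, and whether those contrasts survive the spatial
structure of the survey design. This note records the models, the defaults,
and the design decisions taken where the methodology was genuinely open.

## Survey data model

A survey is sites → point counts → observations. Each point count is a 5-minute
100 m-radius count in one habitat class (`rice`, `agriculture`, `river`,
`wetland`) carrying the local availability of four vegetation resource classes
(forbs, rough grass, emergent vegetation, trees/bushes) measured on a 49-cell
grid, so raw availabilities are multiples of 1/49. Each observation is one
*flock* (group) with a distance (≤ 100 m), a flock size, an activity
(`feeding`, `shelter`, `other`) and the resource class used. Flocks — not
individuals — are the detection and selection unit throughout, because
distance, activity and resource are recorded once per group; flock size enters
separately where it matters (counts, detection covariate).

## Detectability and density

Detections decline with distance following a half-normal curve
g(r) = exp(−r²/2σ²). The distances of one species' detections within the
truncation radius w = 100 m are fitted with the conditional point-transect
likelihood

    f(r | x) = g(r; σ(x)) · r / ∫₀ʷ g(s; σ(x)) · s ds,

with log σ(x) = β₀ + βᵀx. This is the standard estimator under
uniform-in-area animal placement; the truncation radius is fixed, so no
encounter-rate component is needed. Candidate covariates on log σ are the
availability of emergent vegetation and of trees/bushes (raw proportions in
[0, 1]) and log flock size (a skewed count, hence the log — the original
protocol does not state a transform). All 2³ simplifications of the global
model are fitted and the minimum-AIC model kept, ties (ΔAIC < 10⁻⁶) going to
the smaller model. Species need ≥ 20 detections (configurable) to be
modelled; species below that are excluded from density analyses and listed as
unmodelled.

The disc-averaged detection probability has the closed form

    p(σ) = (2σ²/w²) · (1 − exp(−w²/2σ²)),

evaluated with `expm1` so it is accurate for σ ≫ w, and density at a point is
(sum of flock sizes counted) / p(point covariates). When flock size is in a
species' selected model, point-level prediction uses the species' geometric
mean observed flock size as the representative flock. Detection probabilities
below 10⁻³ are capped there and flagged rather than allowed to explode a
density estimate. Densities are point estimates only — downstream models
consume them as responses, so no delta-method variance is propagated.

The detectability-bias check regresses predicted per-species, per-point p on
a non-native indicator, a rice indicator and their interaction, with a site
random intercept (falling back to OLS for singular fits or a single site).
With this coding, a *native* detectability advantage confined to rice fields
appears as a **negative** interaction coefficient; the magnitude is in
probability units.

## Resource selection

Jacobs index J = (u − a)/(u + a − 2ua) per species × resource × activity,
where u is the proportion of that species' flocks of that activity using the
resource, and a is the availability averaged (unweighted) over the point
counts where the species was recorded (`occupied` mode — this removes
occupancy effects from the selection signal; `all` mode averages over every
point count and folds them back in). J is undefined at a ∈ {0, 1} and the
result is clipped into [−1, 1] against 1-ulp floating overshoot at the
corners. u counts flocks; a flag enables flock-size weighting, which the
default avoids because each recorded group is one selection decision. Species
with fewer than 5 activity observations are flagged, not dropped. Group
comparisons are Wilcoxon–Mann–Whitney with natives as group 1.

Community-weighted mean weight-holding capacity per quadrat is
Σ coverₖ·capacityₖ / Σ coverₖ, invariant to cover rescaling and bounded by the
capacities present.

## Functional diversity

Traits are mixed continuous / ordinal / categorical. Gower dissimilarity
averages, over traits measured for both species, |xᵢ−xⱼ|/range for continuous
and ordinal traits (ordinals as equally spaced ranks within their declared
level set) and 0/1 mismatch for categoricals; missing values use
pairwise-available averaging, constant traits contribute zero dissimilarity
(with a warning), and a species pair sharing no measured trait is an error.
Each trait variable carries equal weight; no within-group aggregation of the
trait-group structure is applied.

The pool dendrogram is agglomerative; single, complete and average linkage are
compared by cophenetic correlation with the source distances and the highest-c
tree kept (ties → average linkage, which is also the expected winner on this
kind of data). FD of a community is the total branch length of the subtree
spanning the community's leaves *within the global tree*, divided by the
pool's total branch length — so FD ∈ [0, 1], FD(pool) = 1, and singletons
(which span no branches) score 0. Subtree extraction from the one global tree
is the standard reading of this measure; per-community rebuilding is not done
(the community matrix is presence–absence, as the measure requires).
Internally each non-root edge stores its below-edge leaf set; an edge is in
the spanning subtree iff the community has members both below and outside it,
which turns FD over thousands of communities into one boolean matrix product.

Null models hold richness S fixed and redraw community membership from the
pool without replacement: uniformly, or with inclusion probability
proportional to each species' *point-count occurrence frequency*
(site-level frequency is the plausible alternative; point-count occurrence is
used because the communities being standardized are point counts). Weighted
sampling without replacement is implemented with exponential racing keys,
distribution-identical to successive renormalized draws, and vectorized over
iterations. The default is 1000 iterations; SES = (FD_obs − μ₀)/s₀, undefined
(flagged) when s₀ = 0, e.g. at S = pool size. The null distribution of FD
depends on S only, so draws are shared across communities of equal richness.
Species packing is summarized by the Pearson correlation of SES with richness.

## Habitat gradients

Habitat-association scores are consumed as already-coded integers (0 none, 1
weak, 2 strong) per species × habitat; the literature-coding step that
produces them is upstream of this package. Habitats map onto ordered
gradients — wet→dry with 4 categories, open→closed with 6 — and may span
several positions; a species' score at a position is the maximum over all
habitats mapped there (so habitats scored 0 can never change it). Group
profiles are means ± SE per position (SE undefined for single-species
groups), and the divergence profile |mean_nonnative − mean_native| reports
all tied argmax positions.

## Inference

All habitat contrasts are Gaussian mixed models with a site random intercept
— the survey's spatial clustering is handled entirely through that term —
fitted by maximum likelihood (not REML) so likelihood-ratio tests between
nested fixed structures are valid; the habitat term always has 1 df. Richness
is modelled on the same Gaussian scale for uniformity with the other
responses. Residual spatial autocorrelation is checked with Moran's I
(expected value −1/(n−1)) against a two-sided permutation null; the default
weight scheme is row-standardized symmetrized 8-nearest-neighbour with 999
permutations — a declared default, since the diagnostic's original weight
scheme is unstated. Rank comparisons report the group-1 Mann–Whitney
statistic W = rank-sum − n₁(n₁+1)/2 ∈ [0, n₁n₂], exact p when n₁n₂ ≤ 400
without ties, normal approximation with tie correction otherwise; fully tied
inputs return p = 1 with a note. The one-sample "is mean SES zero" question
uses the mixed-model intercept test, falling back to a one-sample t when the
mixed fit is singular.

## Synthetic surveys and what they do (not) show

The generator mirrors the study design: 51 sites containing rice fields plus
10 without, 1–16 point counts per site (mean ≈ 7.5, sd 3.3), Beta-distributed
availabilities discretized to the 49-cell grid, flocks per point ~
Poisson(λ_habitat · exp(site effect)), site effects lognormal (sd 0.4 on the
log scale), uniform-in-area placement (radial density 2r/w²), half-normal
thinning with covariate-dependent σ, and activity/resource draws from
per-species multinomials restricted to locally available classes. Flock sizes
are 1 + Poisson(mean − 1) — a configurable placeholder, since no flock-size
distribution is documented. The `paper-like` preset programs the study's
qualitative contrasts (non-natives denser in rice, lighter, sheltering in
emergent vegetation and feeding on rough grass; most natives the reverse) so
end-to-end runs have known directional truth. Quadrat generation biases
rice-margin floras toward fewer, flimsier (low weight-holding-capacity)
plants.

What the generator does **not** emulate: observer heterogeneity, double
counting and movement during counts, temporal within-season dynamics,
species' spatial aggregation beyond the site effect, and trait–niche
coupling (trait tables are drawn independently of the density parameters
except for the body-mass contrast). Recovery tests therefore demonstrate
estimator correctness under the stated model, not robustness to field
realities outside it.

## Numerical choices and problem sizes

- Optimizer: L-BFGS-B on the negative conditional log-likelihood with σ
  bounded to [0.5 m, 10⁶ m]; fits pinned at a bound are flagged (e.g. the
  degenerate all-distances-zero case pins at the lower bound).
- CSV round trips use pandas' `round_trip` float parsing so write∘read is the
  identity to the bit.
- Calibration checks run at desk scale: 500 replicates for test type-I error
  (LRT at 12 sites × 5 points; Moran at n = 40, 199 permutations), 500
  communities × 1000 iterations for SES calibration, 10 seeded replicates of
  a 25-site preset for end-to-end direction recovery. These sizes were chosen
  to keep Monte-Carlo error comfortably inside the asserted envelopes.
- All randomness flows through `numpy.random.default_rng` seeds; fixed seeds
  give byte-identical outputs, and the pipeline manifest records seeds and
  output checksums.

## Known limitations

- Only the half-normal detection key is implemented (no hazard-rate or
  uniform keys, no binning, no bootstrap density variance).
- Selection is Jacobs-index only; no RSF/SSF or compositional analysis.
- Abundance-weighted FD metrics (FDis, Rao Q, FRic) are deliberately absent:
  the FD measure here is defined on presence–absence communities.
- The spatial model is the site random intercept; no explicit spatial
  covariance structures are fitted.
- Occupancy-level reproduction of the original survey is built in via its
  published summary table; per-species trait values and masses from that
  survey are not published as printed text, so trait-level statistics can
  only be recomputed when the deposited trait table is supplied externally.
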