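# Methods

This note documents the models implemented in `isotroph`, their
assumptions, the defaults and why, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Trophic position from amino-acid δ¹⁵N

The estimator is the standard glutamic-acid/phenylalanine form,

TP = (δ¹⁵N_Glu − δ¹⁵N_Phe − β) / TDF + 1,

which assumes (i) a single basal producer sets β for the whole chain,
(ii) a constant per-level discrimination TDF, and (iii) no alternative
nitrogen routing. Units are ‰ throughout; TP is dimensionless with
TP = 1 at the producer.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| β (rape) | −7.5 ± 1.6‰ | producer Glu–Phe offset, rape leaves |
| β (legume) | −8.2 ± 1.4‰ | producer offset, legume leaves |
| β (C3) | −8.4 ± 1.6‰ | generic C3-plant offset, fallback where litter amino-acid δ¹⁵N is unmeasurable (straw, manure, field/initial specimens) |
| TDF | 7.6 ± 1.2‰ | per-trophic-level Glu–Phe increase |

How the ±SDs of β and TDF enter a TP confidence interval is a design
choice: this package propagates both (plus optional per-acid analytical
SDs) by Monte Carlo — β and TDF drawn from normals, TP computed per
draw, equal-tail interval reported. A closed-form interval for the
ratio does not exist; the first-order delta method,
sd ≈ √((σ_β/TDF)² + ((Δ−β)·σ_TDF/TDF²)²), serves as an independent
check and agrees with the MC SD to within a few percent. TDF draws are
truncated below at 0.1‰ to keep the ratio finite; at the defaults this
rejects a ~3·10⁻¹⁰ tail, so the distortion is nil (the rejection count
is logged). A minimum of 1000 draws is enforced; the default is
100 000.

Planned contrasts (each litter vs the reference, within species) use a
per-cell pooled-variance two-sample t with unadjusted two-sided
p-values by default — the simplest defensible estimator for a priori
contrasts — with optional Holm adjustment. A global linear model is
deliberately not fitted here.

## Mean-centering and LDA fingerprinting

Centering subtracts each sample's mean over the eAA panel from every
entry of that sample, removing baseline δ¹³C offsets (diet quality,
lipid content, trophic baseline) so that only the pattern remains. The
centering panel defaults to all five measured eAAs (Ile, Leu, Phe,
Thr, Val) even when downstream analyses use the three-tracer subset;
the subset-centering variant is available via the `panel` argument.
Centering is idempotent and makes the pipeline exactly invariant to
per-sample constants — a property the acceptance tests check to 1e-12
through the LDA coordinates and the mixing inputs.

The LDA solves the generalized eigenproblem B v = λ W v (between-class
vs pooled within-class scatter). Centered data lie on the zero-sum
hyperplane, so the problem is solved in an orthonormal basis of the
data's own subspace (the range of W + B) and the axes mapped back;
within that subspace the pooled covariance is non-singular and the
scalings are W-orthonormal. Determinism conventions: axes ordered by
decreasing eigenvalue, the largest-magnitude loading of each axis made
positive, classes ordered by first appearance in the library, and
posterior ties broken to the earliest class. Priors default to *equal*
across classes because endmember library sizes reflect compilation
effort, not prevalence; proportional priors (the convention of some
reference implementations) are available. Classification uses the
shared-covariance Gaussian posterior; confidence ellipses scale the
group covariance by the χ²₂ quantile.

The library validity rule — at least panel_size + 2 specimens per
class — keeps the pooled covariance well-conditioned; leave-one-out
cross-validation additionally requires that bound to survive any
single removal.

## Bayesian source mixing

Per species × litter cell c, consumer tracer values follow

y_ij ~ Normal(Σₖ p_k^c μ_jk, √(Σₖ (p_k^c)² σ_jk² + σ²_res,j)),

with sources k ∈ {plant, bacteria, fungi}, tracers j ∈ {Leu, Phe, Val}
(Ile and Thr carry too little centered dynamic range to be
informative), source moments (μ, σ) computed from the centered
endmember library, a Dirichlet(1,1,1) prior on each p^c, and a
per-tracer residual SD shared across cells (uniform prior on (0, 10‰)).
Trophic fractionation of eAA δ¹³C is fixed at zero — essential amino
acids are routed, not synthesized — with an optional offset for
sensitivity analysis.

Design choices made where the design was genuinely open:

- **Fixed nested cells.** Every species × litter cell gets an
  independent proportion vector (a fully saturated fixed-effects
  layout). Hierarchical pooling across cells is out of scope.
- **Error model.** `source_plus_residual` (source variance propagated
  into the likelihood SD plus a residual term) is the default,
  following mixing-model convention; `residual_only` is available.
- **Source-mean sampling error.** The endmember library is itself a
  finite sample; treating its means as known makes credible intervals
  too narrow once consumers are numerous. By default the standard
  error of each source mean (σ_jk/√n_k) is marginalized analytically
  as a shared per-cell mean offset: the cell covariance is
  σ²I + v·11ᵀ with v = Σₖ pₖ² σ_jk²/n_k, whose likelihood factors into
  a within-cell part and a cell-mean part via sufficient statistics.
  This restored nominal ~95% per-component coverage in calibration
  runs; it can be disabled (`propagate_source_mean_error=False`).

**Sampler.** Random-walk Metropolis on isometric log-ratio (ILR)
coordinates of p (two free parameters per cell; Helmert basis) and on
log σ_res. The Dirichlet prior in ILR coordinates absorbs the Jacobian
into Σₖ αₖ log pₖ. Cells are conditionally independent given σ_res, so
all cell blocks are proposed and accepted in parallel each iteration,
followed by a joint update of the residual scales; chains run in
lockstep on vectorized state. Proposal scales adapt in batches of 100
iterations during burn-in toward ~30% acceptance (the 20–40% band) and
are frozen afterwards, keeping the retained chain Markovian. Chains
are initialized overdispersed from the prior. All randomness flows
from a single integer seed; runs are bit-reproducible.

Default run lengths are 300 000 iterations, 200 000 burn-in, 3 chains,
thinning 100. The `fast` profile (20 000 / 10 000 / 3 / thin 10) is
the package's desk-scale default for tests and examples; with three
tracers and tens of cells it yields R̂ < 1.02 and effective sample
sizes of several hundred per parameter. Convergence is judged by the
split Gelman–Rubin statistic per scalar parameter (accept only if all
R̂ < 1.05, constant-chain degenerate cases flagged rather than
failed); the pipeline withholds posterior summaries and exits nonzero
when the rule fails. Effective sample size uses the multi-chain
autocorrelation estimator with Geyer's initial-positive-pair
truncation.

A brute-force oracle, `least_squares_simplex`, enumerates the simplex
at 0.01 resolution and minimizes the residual sum of squares; in the
limit of vanishing source and residual SDs the posterior mean must
approach it (checked to 0.02 in the acceptance suite).

## PLFA summaries

The strict mole-percent filter (retain only acids *above* 0.2% of the
per-sample total; applied per sample, with a dataset-level alternative
exposed as a flag) runs first; marker group sums are computed on the
filtered table while total abundance is reported from all detected
acids — this matches the convention of filtering "in the analyses"
while quoting absolute abundance over the full acid set. Group sums
use compensated summation; `bacterial = Gram⁺ + Gram⁻` holds exactly
and the fungal:bacterial ratio is flagged undefined (NaN) when the
bacterial sum is zero. Fatty-acid names are normalized (ω ↔ w,
cis/trans suffixes dropped) so lab dialects converge.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with ground truth recorded in a manifest:

- **Design.** Full factorial: 4 litter treatments × 5 earthworm
  species × 5 replicates (all configurable). The litter-quality rank
  wheat_straw < horse_manure < legume < rape mirrors the C:N gradient
  of those materials.
- **Endmembers.** Gaussian clouds (default SD 1.0‰) around fixed
  5-eAA class means whose centered centroids are separated by 5.0–6.9‰
  (≥ 4× the within-class SD) and form a well-conditioned,
  near-equilateral triangle in the Leu/Phe/Val tracer subspace.
  Conditioning is deliberate: proportion identifiability depends on
  the triangle's height, not merely on pairwise distances — a
  near-collinear set of centroids leaves one simplex direction
  ill-determined however far apart the centroids are.
- **Consumers.** Raw eAA δ¹³C = convex mixture of class means under
  the cell's true proportions + N(0, 0.5‰) tracer noise (centering
  commutes with mixing, so centered consumers are the same mixture of
  centered fingerprints). δ¹⁵N Glu/Phe pairs invert the TP equation —
  glu − phe = β + (TP−1)·TDF with β = −8.4‰, TDF = 7.6‰ — plus
  N(0, 0.5‰) analytical noise per acid, so the TP estimator recovers
  the configured truth exactly at zero noise.
- **Directional truth.** Defaults encode plant share rising (0.15 →
  0.60) and TP falling (2.6 → 2.0) along the litter-quality rank, and
  a fungal-PLFA multiplier rising 0.6 → 1.6, giving end-to-end tests
  orderings to recover.
- **PLFA.** 28 acids (9 markers, 17 abundant non-markers, 2 trace
  acids constructed below the 0.2 mol% filter) with unit-mean
  log-normal noise (SD 0.2 on the log scale).
- **Seeding.** One config seed feeds three named substreams
  (endmembers, consumers, plfa), so simulators are independently
  reproducible.

What the generator does **not** emulate: missing values and unequal
cell sizes, instrument drift and derivatization corrections,
covariance between amino acids within a sample beyond what centering
induces, real endmember libraries' between-study heterogeneity,
consumer physiology (gut passage, selective assimilation), and any
temporal dynamics. Passing tests therefore demonstrate that the
estimators recover truth under the model's own assumptions at
realistic noise, not that those assumptions hold in any particular
field system.

## Problem sizes in tests and the acceptance script

Recovery and coverage checks run on 25-consumer cells at the fast MCMC
profile; the end-to-end gradient check uses a 2-species × 4-litter ×
5-replicate design over 20 seeds; the acceptance script uses 10 seeds
for the gradient rate and 5 replicates for interval coverage. These
sizes were chosen so a complete run stays in the minutes range on one
CPU while keeping Monte-Carlo error well below every tolerance tested.

## Known limitations

- The mixing model assumes independent Gaussian tracers; centering
  induces weak negative correlations between tracer errors that the
  likelihood ignores (a shared simplification of this model family).
- Proportions near simplex edges are estimated with inward bias at
  small n (posterior means cannot leave the simplex).
- The TP module covers the single Glu–Phe pair only; multi-amino-acid
  TP estimators and compound-specific TDF variation are out of scope.
- Equal-tail credible intervals are reported; for strongly skewed
  edge posteriors HPD intervals would be narrower.
- The contrasts helper is not a replacement for a full linear-model
  analysis of a factorial design.
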