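# Methods

## Problem and data model

The package analyzes 3D densitometric reconstructions of an immunostained
nucleus: per specimen and protein marker, a volume of stained-pixel counts
inside a binary nucleus mask, with anisotropic voxels (0.014 mm in-plane,
0.3 mm between sections in the emulated study design).  All modeling happens
on *sector grids*: the mask is divided into k×k×k equal-volume sectors
(k = 3 for the across-specimen consistency stage, k = 10 for model fitting)
and each sector carries the summed count of its voxels plus normalized
coordinates in [0, 1] along three anatomical axes.

## Axes and rasterization

The first axis is the rostrocaudal (slice) direction.  The two in-plane
axes are the principal components of the pooled 2D millimetre coordinates
of all mask voxels; components are ordered by variance and signed so their
largest-magnitude loading is positive.  The sign convention is purely for
determinism — the model family is symmetric under axis flips (a flip only
negates a gradient weight), and true anatomical labels would require an
atlas, which is out of scope.

"Equal volume" is implemented as equal voxel *count* via nested conditional
quantile bins: mask voxels are split into k rank-based bins along the first
axis (sizes differing by at most one), each slab is split into k bins along
the second axis, and each resulting column into k along the third.  Nesting
matters: *marginal* quantile bins leave the corner intersections of a
convex lens-shaped mask geometrically empty (a point below the 10% quantile
on all three axes lies outside the body), whereas conditional binning
guarantees all k³ sectors exist with ~n/k³ voxels each — which is what
"k³ sectors of equal volume" requires on a real nucleus.  Equal geometric
spacing would be even worse, leaving edge sectors nearly unsupported.
Sector coordinates are bin centers `(b + 0.5)/k`.  Sector intensity is the
voxel sum, keeping the count scale the NB error model expects; means are a
trivial rescale and deliberately not the default.

## Preprocessing

* **Threshold windows.** Stained pixels are those with 8-bit values inside
  a per-marker window (e.g. CALR (0, 95), GAD6567 (51, 112)); windows are
  taken as given per marker, assuming the darker-stain-lower-value
  convention on the red channel.
* **Masked smoothing.** Gaussian smoothing with FWHM 0.3 mm (σ =
  FWHM/2.35482 per axis, divided by the voxel spacing to get voxel units,
  kernel truncated at 4σ) is applied as normalized convolution:
  `smooth(data·mask)/smooth(mask)` evaluated inside the mask.  This is the
  standard realization of "kernel truncated outside the mask and
  renormalized": per-voxel weights sum to one over mask voxels, constants
  are preserved exactly, and outside intensity cannot leak in.
* **Outlier exclusion.** Before ML fitting, sectors with
  `log(y+1) > median + 5·IQR` (statistics over the grid's included sectors,
  linear-interpolation quantiles) are excluded.  log1p admits zero counts;
  the rule runs once per grid, not iteratively, and its statistics are
  frozen before flagging, making it idempotent.

## Consistency stage

Per specimen and marker, the 27 coarse sectors are standardized to mean 0
and sample SD 1 (ddof = 1).  Per sector, a two-sided one-sample t test
across specimens (df = n−1) is adjusted by Benjamini–Hochberg within the
marker's 27-sector family and thresholded at q < 0.05.  Two-sided tests and
per-marker families are design choices where the procedure was
underspecified; BH is the field default FDR procedure.  A sector identical
across specimens is handled specially: identically zero means a perfect
null (t = 0, p = 1, kept in the family); constant nonzero values have an
undefined t and are flagged and dropped from the family.

## Model family

Sector counts follow a negative binomial parameterized by mean μ and shape
α (a Poisson whose rate is gamma-distributed with parameter α): variance
μ + μ²/α, Poisson limit as α → ∞, consistent with the fitted upper bound of
10²⁰.  The log-pmf is computed in gamma-function form so non-integer
intensities (e.g. after smoothing) remain admissible; for α > 10⁸ the
log-gamma difference switches to its asymptotic expansion
`lgamma(y+α) − lgamma(α) ≈ y·ln α + y(y−1)/(2α)`, which avoids the
catastrophic cancellation that would otherwise corrupt the Poisson limit.

The four mean models are described in the README.  Two points where the
printed equations needed a decision:

* **Projection simplex.** The axis weights are implemented as
  β₂′ = β₂(1−β₁), β₃′ = 1 − β₁ − β₂′, giving a proper two-parameter simplex
  over the three axes.  The literal alternative β₂′ = 1 − β₁ forces β₃′ ≡ 0
  and leaves the second fitted weight inert, contradicting its own [0, 1]
  fitting bound.
* **Boundary scale.** The subdivision boundaries τ₁, τ₂ are fractions of
  the min-max normalized projection `p_norm`, so "each subdivision spans at
  least 20% of the projection axis" is meaningful regardless of where the
  raw projection happens to sit.  The sigmoid model is implemented exactly
  as printed — both logistic terms decrease with the projection — and at
  κ → ∞ it reproduces a reparameterized step model
  (λ₀′ = λ₀ + λ₂, λ₂′ = −λ₂), a documented and tested equivalence.

Parameter counts: 2 (A), 5 (B), 8 (C), 9 (D).  Box bounds: λ₀ and the
step/sigmoid offsets in [−15, 200]; linear gradient weights in [−2, 2];
β₁, β₂ in [0, 1]; τ₁ in [0.2, 0.6]; τ₂ in [0.4, 0.8]; κ and α in [1, 10²⁰].
The τ₂ − τ₁ ≥ 0.2 span constraint is enforced by a large additive penalty
on the NLL (box bounds alone cannot express it), with a gradient toward the
feasible region so the optimizer recovers from unordered proposals.  The
linear predictor is clamped to ±700 before exponentiation; overflow can
therefore never produce silent infinities.

## Fitting and model comparison

Each model is fitted by minimizing the NB negative log-likelihood with
differential evolution (population 20× the parameter count, default up to
5000 generations, seeded), then a bounded L-BFGS-B refinement from the DE
optimum.  Refinement minimizes the same likelihood — BIC needs the
likelihood optimum; a squared-residual refinement of μ is available as an
option but is inconsistent with the NB likelihood and not the default.
α and κ are searched on a log₁₀ scale (bounds [0, 20]): uniform sampling
over [1, 10²⁰] on the natural scale would concentrate essentially all
proposals around 10¹⁹⁻²⁰.  The feasible set is unchanged.

Models are fitted smallest-first, and every fitted nested optimum is
embedded into the initial DE population of the larger models (the
homogeneous optimum with zero effects into B/C/D; the step-model optimum
with κ = 10⁶ into the sigmoid model) and kept as a hard floor on the
reported optimum.  Best-found NLL is therefore monotone under nesting by
construction, not by luck of the stochastic search.

Comparison uses BIC = 2·nll + k·ln(n) — lower is better, complexity is
penalized — and BIC weights computed on ΔBIC to avoid overflow.  The
preferred model per (specimen, marker) is the lowest-BIC model; exact ties
go to the model with fewer parameters, then alphabetically.  Margins
(per specimen, per marker, overall) are the argmax of mean wBIC, with a
lowest-mean-BIC mode available.

## Synthetic studies

The generator emulates the study structure: 7 specimens × 12 markers,
10×10×10 sector grids, NB counts with α = 10 (clear overdispersion) around
a baseline of e³ ≈ 20 counts per sector, per-marker generating models
mirroring the across-specimen preference pattern of the motivating study
(nine linear-gradient markers, three sigmoidal), effect magnitudes
0.5–1.5 on the log scale, and a per-specimen intercept jitter
(SD 0.3 log-units) representing global staining-intensity differences
between individuals.  The intercept SD is an invention for testing — the
study reports no variance component — and a single study seed expands into
per-(specimen, marker) substreams, so any grid is independently
reproducible.

What the generator does *not* emulate: microscopy noise, staining
chemistry, registration error, rater disagreement in mask delineation, or
spatial autocorrelation between sectors (sectors are independent draws, as
in the fitted models).  Passing recovery tests therefore show the
estimator and selection machinery work when the model class is true; they
do not validate the biological adequacy of the model class on real tissue.

## Problem sizes and numerical choices in the test/acceptance runs

Null and power experiments for the consistency stage simulate at the fine
sector scale (9×9×9, chosen divisible by 3) and block-sum to the 27 coarse
sectors, because a coarse sector physically aggregates the counts of the
fine sectors it covers (a sum of k iid NB(μ, α) draws is NB(kμ, kα), so
aggregate counts are large and nearly symmetric).  Simulating coarse
sectors as single low-count NB draws would overstate the skewness of real
sector sums and, with only 7 specimens per t test, inflate the family error
rate above its nominal level.

Recovery experiments run at the study's data scale (1000 sectors, α = 10,
effect magnitudes ≥ 1) with a reduced optimizer budget (DE maxiter 60,
population 20×k, plus refinement), which on grids of this size reliably
reaches the same optima as larger budgets: model recovery is scored over
20 replicates per generating model, gradient-weight recovery (MAE ≤ 0.1)
over 50 replicates in the tests, and the consistency stage's false-positive
rate under a homogeneous null over 200 replicated 7-specimen markers.  An
exhaustive coarse-grid likelihood search on 5×5×5 grids serves as an
independent optimizer oracle.  The sigmoid generating model uses κ = 15:
large enough to be distinguishable from a linear gradient, small enough not
to collapse into the step model.

## Known limitations

* The anatomical orientation of the PCA axes is conventional, not
  anatomically labeled; comparing fitted gradient directions across
  specimens requires consistent physical orientation of the input volumes.
* The likelihood treats sectors as independent; smoothing introduces
  short-range correlation that the NB GLM ignores (as does the modeled
  study), which biases dispersion slightly upward.
* Model C/D boundaries are restricted to τ₁ ∈ [0.2, 0.6], τ₂ ∈ [0.4, 0.8]
  with a ≥20% middle span, so subdivisions hugging the nucleus edge are
  not representable by design.
* The deposited study grids' file format is undocumented; refitting real
  data requires manual conversion to the canonical CSV schema.
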