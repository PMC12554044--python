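# Methods

`precmap` estimates individual-level resting-state network (RSN) maps from
short cortical-surface BOLD fMRI scans and models their development across a
neonatal cohort. This note describes the model, the preprocessing rules, the
synthetic cohort used to validate every stage, the numerical choices, and
the known limitations.

## Subject-level model (template ICA)

At each cortical vertex `v` the retained, normalised BOLD time course
`y_v ∈ R^T` is modelled as

    y_v = A s_v + e_v,
    s_v ~ N(μ_v, diag(σ²_v)),      e_v ~ N(0, ν² I_T),

where `s_v ∈ R^L` holds the subject's true amplitude of each of the `L`
networks at that vertex, `A` (T×L) is a mixing matrix of network time
courses shared across vertices, and `ν²` is an isotropic noise variance.
The empirical prior `(μ, σ²)` — the *template* — carries the population mean
map and the between-subject variance of each network, estimated from a
held-out reference sample.

`A` and `ν²` are estimated by expectation–maximisation. The E-step posterior
of `s_v` is Gaussian with covariance
`C_v = (diag(1/σ²_v) + AᵀA/ν²)⁻¹` and mean
`m_v = μ_v + C_v Aᵀ(y_v − Aμ_v)/ν²`, evaluated in a batched, numerically
symmetric form (`C_v = D^{1/2}(I + D^{1/2}AᵀA D^{1/2}/ν²)⁻¹D^{1/2}`,
`D = diag(σ²_v)`) that remains exact when some `σ² = 0` (point-mass prior:
the posterior is the prior mean and the vertex is excluded from testing).
The M-step updates `A` and `ν²` in closed form; the observed-data
log-likelihood, computed by the matrix-determinant lemma and Woodbury
identity, is non-decreasing across iterations.

**Mixing-scale constraint.** The amplitude of `s` trades off against the
column scale of `A`; the prior pins it only softly, and in unconstrained EM
the per-session map scale drifts (we observed up to 3× across sessions of a
cohort), making amplitudes incomparable. Each column of `A` is therefore
constrained to unit temporal variance in the M-step, via column-wise
constrained ascent (a generalised-EM step: every column update increases the
expected complete-data log-likelihood on the constraint manifold, so the
likelihood stays monotone). This matches the generative convention of
unit-variance network time courses. The cyclic column order leaves a tiny
(≈1e-5 relative) order dependence; plain EM (`constrain_mixing=False`) is
exactly permutation-equivariant.

**Outputs.** Posterior mean `m`, posterior SD, and their ratio — called the
t-statistic map, although under the conjugate Gaussian model it is a
posterior z-score and is referred to the standard normal. Engagement masks
come from the one-sided test H0: `s_v ≤ γ` with multiple-comparison
correction across vertices within each network (Bonferroni by default;
Benjamini–Hochberg and uncorrected are available).

**Engagement threshold γ.** The library default is γ = 0 (any significantly
positive amplitude). The pipeline default is γ = 15% of each network's
template peak amplitude (`gamma_peak_fraction = 0.15`, per network, in map
units). Two constraints pin this choice. γ must be well above zero: with
informative data the posterior resolves arbitrarily small positive
amplitudes, so a γ = 0 mask floods into background cortex wherever a
subject's random deviation happens to be positive, and the mask-averaged
strength is then dominated by vertices unrelated to the network. And γ must
sit below the smallest network amplitude expected in the cohort: a higher
threshold (we measured this at 25%) makes the weakest sessions — the
youngest preterm infants — return empty masks, and the resulting missing
records are informative (missing-not-at-random), biasing the fitted
trajectories exactly where the cohort is most sensitive.

## Preprocessing

* **DVARS**: root-mean-square across vertices of the frame-to-frame signal
  difference; the first frame has no predecessor and is undefined (never
  flagged). Computed on unnormalised data, before any scaling.
* **Outlier flagging**: a frame is motion-corrupted when its DVARS is
  strictly above Q75 + 1.5·(Q75 − Q25) of the session's defined DVARS
  values. Because this rule thresholds the tail of the same distribution it
  is computed from, a light-tailed baseline yields an irreducible ≈0.35%
  false-positive rate; it detects planted artifacts of ≥10× the noise SD
  with 100% sensitivity.
* **Block retention**: the contiguous block of `block_length` frames
  (default 1600 of a 2300-frame session) with the fewest flags is retained;
  ties go to the earliest start. A session is excluded when strictly more
  than 10% of the retained block is flagged (161 of 1600 excludes; 160 does
  not). No scrubbing is performed inside the block.
* **Smoothing**: geodesic Gaussian smoothing as heat diffusion with the
  cotangent Laplacian and lumped vertex-area mass matrix, total diffusion
  time t = FWHM²/(16 ln 2). On meshes with ≤3000 vertices the heat kernel is
  applied exactly through a cached eigendecomposition; larger meshes use
  implicit (backward-Euler) stepping, unconditionally stable, 50 steps by
  default. Constants are fixed points; the area-weighted integral is
  conserved to rounding. On a finely subdivided sphere the diffused impulse
  matches the nominal 3 mm FWHM within a few percent (the graph-geodesic
  distance itself overestimates arc length by up to ~15% on coarse meshes,
  which matters when *fitting* a kernel width, not when applying one).
* **Normalisation**: each vertex time course is centred; one global factor
  scales the session so the mean vertex-wise temporal SD is 1.

## Empirical prior (template)

Group ICA (fixed-point negentropy ICA on temporally concatenated,
PCA-reduced reference data; reduction dimension 4L by default) yields L
spatial components, sign-fixed to positive skewness. Components are matched
to networks by greedy maximal absolute spatial correlation against the
generator's ground-truth maps — the software stand-in for the visual
identification a human would do on real data. Dual regression of each
reference session against the matched group maps gives rough subject maps;
their vertex-wise sample mean and unbiased sample variance form the
template. The between-subject variance is noise-corrected by default:
split-half dual regression gives a per-subject sampling-variance estimate
((m₁−m₂)²/4), whose average is subtracted and the result floored at zero.
At low noise this estimator floors at the finite-sample dual-regression
error, so the correction is conservative.

**Reference-sample composition.** Reference sessions are drawn at uniform
scan-age quantiles across the whole cohort (single-scan subjects only), not
from an age extreme. Because the prior mean acts as the shrinkage target
for every subject, a reference sample skewed to one age or group biases
shrinkage differentially across the cohort and can forge a spurious
prematurity × age interaction; a mid-cohort target avoids this. Reference
sessions never re-enter downstream analyses.

## Session metrics

* **Connectivity strength**: area-weighted mean of the t map within the
  network's engagement mask, `Σ aᵥtᵥ / Σ aᵥ`. Empty masks yield a missing
  value (never zero, which would bias trajectories).
* **Winner-takes-all parcellation**: each vertex is labelled with the
  network of the highest t value (1-based; 0 = unassigned when restricted
  to significant vertices); exact ties go to the lowest network index.
  Operating on t maps rather than posterior means is a configuration choice.
* **Mask overlap**: area-weighted Dice between two sessions' masks plus a
  per-vertex first/second/both/neither label map.

## Cohort statistics

All models are ordinary least squares per network on the tidy records table,
with two-sided t-distribution p-values. Scan age is centred at 40 weeks
postmenstrual age so the preterm coefficient measures the offset at term
age. Sex is one indicator; preterm means birth before 37 weeks; motion is
the session's mean DVARS over the retained block.

* **Trajectory model**: strength ~ scan_age + sex + motion + preterm +
  preterm×scan_age. `p_SA` (scan age) tests maturation, `p_PB` (preterm)
  the offset, and the interaction tests convergence of trajectories.
* **Term-equivalent comparison**: strength ~ preterm + sex + motion +
  scan_age on sessions scanned within 37–44.9 weeks; the preterm
  coefficient's t-test is the adjusted group difference.
* **Longitudinal slope**: for two-scan subjects, one OLS of strength on
  scan age with motion as covariate (default). A two-step variant
  (residualise on motion, then regress on age) is provided; its CI ignores
  the first step's uncertainty and measures ~88% rather than 95% coverage,
  which is why it is not the default.
* **Motion balance**: paired t-test of motion between first and second
  scans; identical motion is the degenerate zero-variance case, reported as
  p = 1.

No correction across networks is applied by default (per-network p-values
are reported side by side); a Holm option exists.

## Synthetic cohort

The generator defines the study conditions and the ground truth all tests
are scored against.

* **Surface**: subdivided-icosahedron sphere (radius 50 mm). Analyses in the
  test-suite run at subdivision 2–3 (162/642 vertices); kernel-width checks
  use subdivision 5 (10242 vertices).
* **Networks**: L flat-top bumps `exp(−ln2·(d/w)⁸)` (half maximum at
  d = w mm) at farthest-point-sampled peaks — parcel-like plateaus with
  steep borders, like cortical RSNs, rather than shallow Gaussian hills
  (whose mask boundary, a truncated mean, would swing strongly with
  amplitude in a way real parcels do not). Between-subject variance is
  `var_scale`·(0.1 + μ) times a smooth positive random field: variability
  concentrates where the network is present, with a small background floor.
* **Subjects**: per-network gain g = 1 + slope·(age − 40) + offset·preterm
  (+ interaction·preterm·(age−40)); the subject map is N(g·μ, σ²)
  vertex-wise. BOLD is C sᵀ + white noise, with C temporally smooth,
  orthogonalised, unit-variance columns (keeps EM identifiable at short T).
  Motion spikes are transient single-frame global shifts of amplitude
  10× the noise SD at Bernoulli(1%) frames.
* **Cohort design**: term singletons (birth 37.1–42.3 w, scan 37.4–44.9 w),
  preterm singletons (birth 25.6–36.9 w, scan from shortly after birth to
  44.9 w), and longitudinal preterm pairs (preterm scan, then 37–44.9 w),
  sexes balanced. Defaults: slope +0.05/week, offset −0.3, zero
  interaction, noise at SNR 1 (signal power = vertex-mean Σ_l μ²_l), 2300
  frames at TR 392 ms with a 1600-frame retained block.

What the generator does **not** emulate: real cortical geometry and folding,
hemodynamic response and autocorrelated noise, distance-dependent noise
correlations, imperfect surface alignment across subjects, global
physiological signals, or any volumetric/subcortical structure. Passing
tests therefore demonstrate correctness of the algorithms under the model's
assumptions, not performance on dHCP data.

## Validation design and problem sizes

Tests and the acceptance script scale the study down so the full suite runs
on one CPU in minutes: cohorts of ~170 sessions at 642 vertices, 4 networks,
290-frame sessions with 200-frame retained blocks for end-to-end checks;
30-vertex instances for closed-form oracles; 10242-vertex spheres for
kernel-width checks. The end-to-end trajectory check verifies the Fig.-4-
style pattern (age p < 0.05, prematurity p < 0.05, interaction p > 0.05)
across seeded replicates of the full pipeline.

**Slope recovery and shrinkage attenuation.** Because the generator's
effects are multiplicative on the template, the truth on the measured
strength scale is `k·slope` with `k` a nuisance baseline; recovery is
therefore tested through the OLS contrast `β_age − slope·β_0` (mean zero
under correct recovery, with its exact coefficient-covariance SE). Through
the full empirical-Bayes pipeline this contrast is *not* centred on zero:
shrinkage toward the population template attenuates individual amplitude
differences, hence also the fitted slope, by design — the same attenuation
applies to any template-ICA analysis. Unbiased ±2·SE recovery is therefore
asserted at the records level (cohort model → records → OLS), where it is a
property of the statistical stage, and the pipeline-level check asserts the
qualitative pattern and sign structure instead.

## Numerical choices

* EM stops on relative log-likelihood change < 1e-6 (max 100 iterations;
  50 in cohort-scale runs). ν² is floored at 1e-12.
* Posterior SD at point-mass vertices is reported as 1e-12 and the vertex
  excluded from tests and masks.
* Quantiles for DVARS flagging use linear interpolation (NumPy default).
* WTA and block-selection ties break to the lowest index / earliest start.
* The spectral smoother clips tiny negative eigenvalues of the
  mass-normalised Laplacian at zero.
* Per-stage seeds derive from the single run seed via
  `SeedSequence(seed).spawn(...)`, one child per stage in fixed order, so
  any stage can be replayed bit-identically.

## Known limitations

* Isotropic noise (single ν²); no vertex-specific or autocorrelated noise.
* No spatial prior on deviations from the template; inference is
  vertex-independent given A and ν².
* The ICA → network matching uses the generator's ground truth as the
  matching target; on real data this step is a human decision.
* Graph-geodesic distances (Dijkstra over mesh edges) overestimate true
  geodesics by up to ~15% on coarse meshes; template bump widths inherit
  this, which is irrelevant for synthetic ground truth but would matter for
  measuring real cortical distances.
* The engagement-mask strength metric is mildly nonlinear in the underlying
  network amplitude (truncated mean over an amplitude-dependent mask plus
  empirical-Bayes shrinkage); at cohort scale this can inflate the
  interaction test's type-I error a few points above nominal. The
  records-level statistics are exactly calibrated.
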