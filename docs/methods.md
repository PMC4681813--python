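# Methods

This note documents the models implemented in `motioncomplexity`, the
parameter choices that matter, and what the synthetic-data experiments do
and do not establish.

## Data model

A *trajectory* is a time-ordered sequence of (x, y) positions in
centimetres inside a rectangular workspace (default 10 × 10 cm, origin at
the lower-left corner, x rightward, y upward). A *motion pattern* is the
set of N repetitions of one self-chosen closed-form movement (default
expectation N = 10). Before any analysis every repetition is resampled to
T = 150 points equidistant in recorded time (linear interpolation,
endpoints preserved exactly). Resampling is deliberately equidistant in
*time*, not arc length, and repetitions are compared index-by-index after
each is resampled over its own duration — no dynamic time warping. Time
normalisation of unequal-duration repetitions is therefore an
interpretation baked into the pipeline; alternatives such as
arc-length parameterisation would change the variance measure for strongly
non-uniform speed profiles.

**Across-repetition variance (VAR).** For each time index and each spatial
dimension, the unbiased sample variance across the N repetitions; summed
over x and y and averaged over time. Units cm². The measure is invariant
under rigid translation and scales as c² under uniform spatial scaling.
It is the confound control: a score that any pure
variability-driven measure must follow.

## Gaussian-process complexity

Each spatial dimension is modelled as an independent zero-mean GP over the
time index with squared-exponential covariance

    k(t, t') = sigma_f^2 exp(-|t - t'|^2 / lambda^2).

The N repetitions are treated by default as independent realisations of
the same GP (block-diagonal covariance over the concatenation, one T × T
solve per evaluation); a `concat="continuous"` switch instead places all
N·T samples on one running time index. Block mode is cheaper and invariant
to repetition order, which is why it is the default.

Observations of each dimension are centred and scaled to unit variance,
which fixes sigma_f² = 1 and makes (lambda, sigma_n²) identifiable. Both
are fitted by maximising the log marginal likelihood: a coarse grid search
(lambda over 30 log-spaced values spanning 0.5–500 time indices; sigma_n²
over 10 log-spaced values 1e-4–1; ties broken toward the smallest lambda)
followed by Nelder–Mead refinement in log space. A fit whose grid optimum
sits on the boundary is flagged.

The marginal likelihood splits into a data-dependent goodness-of-fit term
−½ yᵀ(K+sigma_n²I)⁻¹y and the Gaussian normaliser
−½ log det(K+sigma_n²I) − (M/2) log 2π. The *reported complexity score*
is the differential entropy

    H = 1/2 log det(2 pi e (K_lambda_hat + sigma_ref^2 I)),

summed over x and y, evaluated at the fitted length scale under a *fixed
reference noise* sigma_ref² = 1e-2 rather than the fitted noise. The
reference noise makes the score a function of the length scale alone —
the model property that carries a pattern's spatial complexity — instead
of the pattern's repetition variability: with the fitted noise in the
determinant, near-noiseless patterns would receive arbitrarily large
negative log-determinants through sigma_n² → 0 and the score would rank
patterns by variability, defeating the variance control. The entropy is
strictly decreasing in lambda, so any positive reference level produces
the same ranking.

## Probabilistic-movement-primitive complexity

A trajectory tau = [x_1..x_T, y_1..y_T] is represented as tau ≈ Psi·omega
with normalised Gaussian bases of a linear phase z ∈ [0, 1]:

    b_i(z) = exp(-(z - c_i)^2 / (2 h^2)),  phi_i = b_i / sum_j b_j,

n = 20 bases per dimension (omega ∈ R⁴⁰), centers equally spaced on
[0, 1], width h = 1/(n−1) so adjacent bases overlap at exp(−1/2) — a
standard choice for normalised RBF features; both are configurable.
Per-trajectory weights are ridge least squares (penalty 1e-10, just enough
to guard rank deficiency; the two dimensions decouple).

The weight vectors of one pattern are modelled as draws from
N(mu_omega, Sigma_omega) with a conjugate Normal-inverse-Wishart prior.
The prior location mu_0 and scale Psi_0 are the maximum-likelihood mean
and covariance of the weight vectors pooled over *the whole collection
being analysed* (empirical Bayes; a 1e-8 ridge keeps Psi_0 positive
definite when fewer vectors than dimensions are pooled). The pooling scope
matters: the prior encodes what patterns in this experiment look like, and
a pattern's entropy is then driven by how its own scatter and its offset
from the population mean extend that prior. Strengths are kappa_0 = 0.1
and nu_0 = 10. With d = 40 this nu_0 makes the prior improper as a
distribution; the MAP formulas (mu, Psi/nu) only require nu > 0 and a
positive-definite Psi, so the state validation enforces exactly that.

The complexity score is the differential entropy of the MAP predictive

    p(tau) = N(Psi mu_omega, Psi Sigma_omega Psi^T + Sigma_tau),

with Sigma_tau = 1e-10·I making the 2T × 2T covariance full rank. The
log-determinant is computed with the matrix-determinant lemma so only a
2n × 2n factorisation is formed; at sigma_tau = 1e-10 the lemma route is
numerically *more* accurate than a dense eigendecomposition, whose
null-space eigenvalues carry O(eps·‖ΨΣΨᵀ‖/sigma_tau) relative error.

Ranking robustness to (kappa_0, nu_0) over ±1 order of magnitude is
enforced by test (Spearman > 0.9 on a 40-pattern mixed set).

## Symbolisation and information measures

The workspace is tessellated into half-open 1 × 1 cm cells
([k, k+1) on both axes; top/right edge points belong to the last cell).
A trajectory emits one symbol of {l, r, u, d} per cell-boundary crossing.
Segments crossing several boundaries between samples are subdivided at the
exact line-grid intersections and crossings are emitted in traversal
order; an exact corner hit emits the x-crossing first (deterministic
tie-break). Both the half-open convention and the corner rule are
interpretations; they only matter on a measure-zero set of points.

Because 10 repetitions yield far too few transitions, symbol corpora are
built by sampling trajectories from the fitted PMP model (clipped to the
workspace) until at least 10 000 transitions accumulate; a cap of 10 000
sampled trajectories turns a degenerate single-cell model into an explicit
error rather than an endless loop.

**LZ-76.** The number of blocks in the exhaustive-history parsing: each
block is the shortest continuation not occurring as a substring of the
preceding text (the copy source may overlap the block), and the final
block counts whether or not it is novel. The normalised variant is
c(n)·log_k(n)/n, which approaches 1 for long i.i.d. equiprobable
sequences.

**Block entropies and EMC.** H(L) is the plug-in Shannon entropy (base 2)
of overlapping length-L blocks; h_L = H(L+1) − H(L) with h_0 = H(1); the
entropy rate h is the last reliable h_L and EMC = Σ (h_L − h). The
requested maximum block length (default 8) is truncated to the largest L
whose number of distinct observed blocks stays below sqrt(n) — a plug-in
undersampling guard. Plug-in estimates are biased downward at large L;
no Miller–Madow or NSB correction is applied (the bias largely cancels in
the h_L − h differences that EMC accumulates, and rankings are
insensitive to it). Base-2 logs throughout; a different base rescales all
values without affecting correlations.

## Synthetic pattern classes

The generator emulates the four canonical demonstration classes that
dissociate spatial complexity from repetition variability:

* `random_high_var` — no repeatable base curve: each repetition is an
  independent random walk low-passed with a Gaussian kernel of 8 samples
  and closed by detrending. Erratic but locally smooth, so a GP explains
  it with a moderate length scale (low entropic complexity) while the
  weight distribution over independent curves is very broad (high PMP
  entropy).
* `complex_low_var` — a closed curve of 10 equal-amplitude random
  harmonics, repeated almost exactly. The flat spectrum keeps high
  harmonics visible, giving a genuinely short correlation length.
* `ellipse_high_var` / `ellipse_low_var` — a plain ellipse with random
  aspect ratio (1.2–2) and orientation per pattern (each drawing is a
  different ellipse, as each human pattern is a different drawing), with
  large / small repetition variability.
* `graded` — harmonic curves with K = 1 + round(grade) harmonics, for
  dose-response designs.

Repetition variability is a smooth periodic Gaussian field (correlation
length T/8 samples) of sd 0.4 cm (high) or 0.1 cm (low) added to the base
curve — it displaces whole curve sections coherently, emulating imperfect
motor memory, not sensor jitter. Base curves are scaled into the workspace
with a 1.5 cm margin and all repetitions are clipped to the workspace, so
bounds hold exactly.

What the generator does *not* emulate: realistic speed profiles (e.g. the
two-thirds power law), drawing around a required via-point, pen-up
segments, or any biomechanical constraint. Passing the class-ordering
tests therefore shows that the five measures behave as designed on curves
with controlled frequency content and variability — not that human data
would produce the same effect sizes.

Jury simulation: each juror perceives a pattern's true score plus
Gaussian noise and ranks the m patterns of a trial 1..m (m = most
creative); exact ties break by subject order. Averaging per-juror ranks
gives the rank table consumed by the correlation stage.

## Correlation stage

Spearman correlations use midranks for ties and the t approximation for
p-values (a seeded permutation p is available for small n); no
multiple-testing correction is applied to the per-subject significance
bands (p < 0.001 / 0.01 / 0.05 / ns) — they are descriptive. Positive
rho means "more complex ↔ judged more creative" (rank m = most creative).

One exactness caveat is worth recording: with a *noiseless* jury that
ranks by the measure itself, the pooled trial-wise correlation cannot be
exactly 1, because jury ranks are integers 1..m repeated over K trials
(ties) while the measures are distinct reals; the midrank Pearson ceiling
is sqrt((n²−K²)/(n²−1)) ≈ 0.995 for m = 10, K = 55, and the test suite
asserts that exact ceiling. The identity that *is* exact — and is tested
as such — is at the rank level: ranking patterns by any computed measure
and feeding those ranks through the pipeline reproduces unit rank–rank
correlations and a purely diagonal coincidence histogram.

## Numerical choices

* Cholesky factorisations escalate a diagonal jitter 1e-10 → 1e-6 (scaled
  by the mean diagonal) before raising a diagnostic error; log
  determinants come from Cholesky diagonals.
* Grid-search ties break toward the smallest length scale.
* All sampling is driven by `numpy.random.Generator` seeds; identical
  seeds reproduce corpora, samples and juries bit-for-bit.
* Tabular I/O round-trips at full float64 precision (`%.17g` on write,
  round-trip float parsing on read).

## Problem sizes in the test suite

The ordering suite uses 20 patterns per class at T = 150, N = 10 with
10 000-transition corpora; parameter recovery uses 50 seeded GP
simulations (T = 150) and 20 seeded PMP fits at N ∈ {5, 10, 50}; the
pipeline identities use a 10 × 55 design for the rank arithmetic and a
4 × 5 design where full complexity records are recomputed. These sizes
keep the whole suite around two minutes while leaving every statistical
margin wide (each ordering was verified on independent seed sets during
development).

## Known limitations

* The GP treats the repeated mean shape as covariance structure (zero-mean
  prior), so the fitted length scale conflates base-curve curvature with
  perturbation smoothness; this is intrinsic to the zero-mean formulation.
* PMP entropy depends on the collection through the empirical-Bayes prior:
  a pattern's score is only comparable within the collection it was
  analysed with.
* Plug-in entropies are biased at block lengths near the undersampling
  guard; EMC values at the default corpus length are comparative, not
  absolute.
* Human rank data are discrete and tied; pooled correlations are bounded
  away from ±1 as described above.
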