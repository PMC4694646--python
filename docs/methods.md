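# Methods

## Model and pipeline

Every session is a V × T matrix of vertex time series on a triangulated
surface mesh, tagged with a processing state.  Cleaning (volume discard,
robust despiking, global-mean intensity scaling to 10,000, nuisance
regression) produces the `cleaned` state, from which three branches feed the
metrics exactly as each requires:

| branch | state | metrics |
|---|---|---|
| surface smoothing (6 mm FWHM) | `cleaned+smoothed` | ALFF, fALFF |
| ideal DFT band-pass 0.01–0.1 Hz | `cleaned+bandpassed` | ReHo1/2, DCw, ECw |
| band-pass + per-vertex z-scoring | `…+znormalized` | SFC |
| none (cleaned, *not* normalized) | `cleaned` | DR |

Metrics refuse inputs in the wrong state; this is enforced at run time, not
by convention.

The longitudinal model is a random-intercept LME per target (vertex or
global mean): y = Xβ + Zb + ε with b ~ N(0, σ²b I), ε ~ N(0, σ²w I), i.e.
compound-symmetric within-subject covariance.  The global-mean model uses
age, sex and meanFD as fixed effects; the vertex model additionally uses the
metric's global mean (post-hoc standardization), mcBBR and the subject's
per-vertex surface Jacobian.  Continuous covariates are mean-centered and
sex is coded 0/1.  ICC = σ²b/(σ²b + σ²w); we use this standard orientation
(high between-subject variance ⇒ high reliability) and record it in output
metadata.  The normalized intra/inter strengths are σ²w and σ²b over their
sum; the "significance strength" is the Wald z of the adjusted intercept,
reported unthresholded.  Dual-regression maps get no global-mean model and
no gM covariate: the spatial mean of a stage-2 regression map is fixed by
the regression algebra, so it carries no information and would make the
design singular.  The Fisher-z network interplay values can optionally be
decomposed with the whole-brain design, one fit per unordered network pair
(`fit_interplay=True`).

## ReML estimation

Variance components are estimated by restricted maximum likelihood,
profiling in the variance ratio λ = σ²b/σ²w.  For the random-intercept model
the marginal covariance is block diagonal, V0 = I + λ J per subject, so each
λ evaluation needs only per-subject sums (O(G p²) after precomputing the
sufficient statistics).  The profile criterion

    (n − p)·log σ̂²w(λ) + Σ_j log(1 + λ n_j) + log|XᵀV0⁻¹X|

is minimized over a 49-point log grid on λ ∈ [10⁻⁸, 10⁴] plus the λ = 0
boundary, followed by bounded scalar refinement (Brent, xatol 10⁻¹²) in the
bracketing interval; the refined optimum is compared against λ = 0 so
boundary solutions (σ̂²b = 0) are exact and flagged.  The optimizer is fully
deterministic — no random starts.  On balanced intercept-only data the
interior solution coincides with the closed-form one-way ANOVA estimator
(σ̂²w = MSW, σ̂²b = (MSB − MSW)/k), which the tests verify to 10⁻⁶ relative,
and the general solution is cross-checked against statsmodels' MixedLM.  At
the boundary ReML's σ̂²w is the pooled variance, not MSW, which is why the
oracle comparison conditions on an interior solution.

## Numerical choices

- **Kendall's W** uses within-series midranks and the tie correction
  Σ(t³ − t); a brute-force term-by-term evaluation is the test oracle.  The
  one-ring neighborhood of a regular icosphere vertex has K = 7 members
  (center included), the two-ring K = 19; K is emergent from mesh adjacency
  rather than forced to a fixed count.
- **Spectral decomposition** follows the cos/sin parameterization at Fourier
  frequencies l/(T·Δt), l = 1..T/2 (Nyquist at half weight, no sine term).
  Odd-length series drop their last sample for the decomposition only.
  ALFF divides the summed in-band amplitude by T/2; the fALFF denominator is
  the full range excluding DC.
- **Fisher z** clips |ρ| ≥ 1 − 10⁻⁷ to ±arctanh(1 − 10⁻⁷) ≈ 8.4 so the LME
  always sees finite values; clips are logged.
- **Connectome threshold** keeps the ⌊0.05·V(V−1)/2⌋ *most positive*
  Fisher-z weights (at 5% density on band-passed data the retained tail is
  positive; centrality on mixed-sign weights is ill-defined).  Ties at the
  cutoff break lexicographically for bit-reproducibility.  Eigenvector
  centrality is computed by power iteration (uniform deterministic start,
  tolerance 10⁻¹⁰ on the eigen-residual, 10,000-iteration budget) on the
  largest connected component, with zeros elsewhere.
- **Surface smoothing** iterates the doubly stochastic diffusion step
  W = I − εL (L the combinatorial graph Laplacian).  One step spreads
  variance by ≈ ε·valence·edge², so ε and the step count are calibrated to
  the requested FWHM given the nominal 4 mm edge length; ε ≤ 1/(max valence
  + 1) keeps all weights non-negative.  W preserves constants and the total
  sum exactly.
- **Despiking** flags robust z-scores (|x − median|/(1.4826·MAD)) above 5
  and linearly interpolates across flagged points; an all-flagged series is
  left untouched with a warning.
- **Dual regression** appends an intercept column at both stages so mean
  offsets in the non-normalized input do not leak into the time courses.
- **Nuisance design**: Friston-24 expansion, WM and CSF mean series, linear
  and quadratic trends, intercept, regressed jointly in a single OLS (the
  alternative — sequential regression — is not used); collinear columns are
  dropped with a warning.  FD follows the Power convention with a 50 mm
  rotation radius.
- ICC = 0 is assigned to the "slight" band although the printed intervals
  are open at 0; interval boundaries (0.2, 0.4, 0.6, 0.8) map to the lower
  band.

## The synthetic cohort

The generator emulates a balanced month-long test-retest design.  Each
network (a contiguous atlas patch grown by seeded breadth-first search) gets
a unit-RMS sum of sinusoids with random phases per (network, subject,
session), at Fourier frequencies of the *post-discard analysis window*
(2·⌊(T_raw − 5)/2⌋ samples) inside Ω — so the oscillation passes through
volume discard and the spectral decomposition without leakage and ALFF is
analytically predictable.  A vertex's signal is

    baseline + A_ij(v)·osc_{network(v)}(t) + nuisance + white noise,
    A_ij(v) = a0 + b_j(v) + w_ij(v)

with b_j(v) ~ N(0, σb(v)²) drawn once per subject and w_ij(v) ~ N(0, σw(v)²)
per session.  Putting the within-session dispersion on the *amplitude*
(rather than only as white measurement noise) is deliberate: amplitude-borne
metrics then inherit the stated variance components, making
ICC(v) = σb²/(σb² + σw²) the exact ground truth the pipeline should recover.
White measurement noise is a separate parameter (`noise_sd`, default 0.2
relative to unit signal RMS).  Subject effects are drawn independently per
vertex so that surface smoothing attenuates the between- and within-subject
components by the same factor and the per-vertex truth survives smoothing.

Shared nuisance structure — a motion-coupled drift from a random-walk
six-parameter motion trace (steps 0.02 mm / 4·10⁻⁴ rad), and WM/CSF-like
band-limited series with per-vertex coupling gains (s.d. 0.5) — is added so
the nuisance regression has real work to do; meanFD is computed from the
actual simulated motion.  Covariates follow the study demographics where
stated: age ~ U(20, 30), sex ~ Bernoulli(0.5); mcBBR is log-normal and the
per-vertex Jacobian ~ N(1, 0.05²).  Covariate effect sizes default to zero
and are config-exposed.  A single master seed drives per-subject and
per-session SeedSequence streams, so cohorts are bit-identical across runs.

Defaults: 30 subjects × 10 sessions, T_raw = 300 at Δt = 2 s (295 retained
after the 5-volume discard), Ω = [0.01, 0.1] Hz, a0 = 1, σb = σw = 0.2
(true ICC 0.5), baseline 1000.  The magnitudes of σb and σw per metric are
not empirically established values — they are simulation choices, exposed in
`CohortConfig`.

What the generator does *not* emulate: hemodynamic response shapes, spatial
autocorrelation of the noise field, scanner artifacts, registration error,
non-stationary oscillations.  Passing tests therefore demonstrate that the
pipeline's estimators are correct and calibrated under the stated generative
model, not that real data meet that model.

## Error budget of ICC recovery

The recovery check (ALFF through the full pipeline, truth spanning
[0.1, 0.9] across 162 vertices, 30 × 10 design) is limited by the sampling
variance of the variance-ratio estimator itself:
Var(ICĈ) ≈ 2(1 − ρ)²(1 + (k−1)ρ)²/(k(k−1)(n−1)) gives per-vertex standard
errors of 0.03–0.08 over the gradient at n = 30, k = 10, i.e. an expected
mean absolute error of ≈ 0.05 even for an oracle applied directly to the
generative amplitudes.  The measurement pipeline adds a small downward bias
(≈ 0.01–0.02): smoothing mixes phase-incoherent oscillations at network
boundaries, and regressing 29 nuisance columns from 295 samples removes a
session-varying share of in-band variance; both inflate the apparent
within-subject variance.  Observed performance at the default seed: MAE
0.057, Pearson r 0.958.  Enlarging the subject sample — not the vertex count
— is the only way to tighten the MAE substantially.

## Problem sizes used in tests

Unit tests run on icospheres of 12–162 vertices and cohorts of ≤ 6 subjects;
the recovery and calibration checks use the full 30 × 10 design on the
162-vertex mesh (seconds to minutes on one CPU).  The fsaverage5-scale mesh
(10,242 vertices per hemisphere, `build_icosphere(5)`) is supported by the
same code paths; the connectome stage holds a dense V × V matrix, which at
that scale is ≈ 800 MB per session.
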