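# Methods

## The model

`sgmkit` implements a linear, closed-form spectral graph model (SGM) of
whole-brain electrophysiological spectra. Local neural activity in each brain
region is summarized by gamma-shaped transfer functions of an
excitatory-inhibitory (E-I) circuit; long-range propagation across the
structural connectome is governed by a *complex* graph Laplacian whose phase
factors encode axonal conduction delays.

For a structural weight matrix **C** with column-sum degree vector **deg**
and inter-region delays τ_jk = d_jk / S (distances in mm converted to seconds
at conduction speed S m/s):

    C(ω) = diag(1/deg) · [ c_jk · exp(−iω τ_jk) ]          (complex connectivity)
    L(ω) = I − α C(ω)                                       (complex Laplacian)
    T(ω) = ( iω I + F(ω)/τ_G · L(ω) )⁻¹ H_local(ω)          (network transfer)

with the gamma filter F(ω) = (1/τ²)/(iω + 1/τ)² evaluated at the graph time
constant τ_G. The local transfer H_local(ω) couples two gamma filters
F_e(ω; τ_e), F_i(ω; τ_i) in an E-I feedback loop with loop gain G_EI,
inhibitory self-gain G_II and excitatory self-gain fixed at 1; it is
spatially homogeneous and pluggable behind the `local_transfer` contract, so
an alternative local circuit can be swapped without touching network code.

**The observable.** The driving noise is modelled as *uncorrelated*
unit-variance white noise in every region, so the regional power spectrum is
the diagonal of the output spectral density:

    psd_j(ω) = Σ_k |T_jk(ω)|²

and the modelled EEG observable is the global (region-mean) PSD. This choice
matters: a perfectly *coherent* drive (the same realization entering every
region, i.e. T applied to a ones vector) weights the Laplacian eigenmodes
very differently and reverses some qualitative effects of the coupling α —
in particular, under the incoherent convention the strong-coupling regime
(α ∈ 0.7–0.9) carries more broadband power than the weak regime (α ∈
0.1–0.3) when averaging over the physiological prior, which is the behavior
this package asserts. The coherent response x = T·p to a deterministic drive
vector p is still exposed on `SpectralResponse` because the analytic limit
checks (α → 0 closed form, linearity in the drive) and the direct-vs-eigen
oracle are naturally stated on it. Consequently `psd` is *not* |x|²
elementwise; the two fields answer different questions and are documented as
such.

**Two evaluation routes.** `network_response(method="direct")` inverts the
system per frequency; `method="eigen"` expands over the eigenmodes
L(ω) = U Λ U⁻¹ and sums modal terms u_i ũ_i / (iω + λ_i F(ω)/τ_G). Because
the Laplacian is non-Hermitian (row normalization plus complex phases), the
expansion must use U⁻¹ rather than a conjugate transpose; the direct solve is
the ground truth and the test suite holds both routes to < 1e-8 relative
agreement. Eigendecompositions are recomputed per frequency (C(ω) changes
with ω); batching across the grid is internal.

## Parameters

| parameter | meaning | unit | bounds | notes |
|---|---|---|---|---|
| τ_e | excitatory time constant | s | [0.001, 0.03] | strongest determinant of the summary vector |
| τ_i | inhibitory time constant | s | [0.001, 0.03] | |
| α | long-range coupling | – | [0.01, 1.0] | drives PDR emergence in suitable regimes |
| S | conduction speed | m/s | [0.5, 15] | weakest determinant (highest posterior dispersion) |
| G_EI | E-I loop gain | – | [1, 20] | |
| G_II | inhibitory self-gain | – | [1, 20] | raises relative alpha power and flattens the >10 Hz slope |
| τ_G | graph time constant | s | [0.01, 0.3] | also sets the network-level filter F(ω) |

The default frequency grid is 100 linearly spaced bins over 0.5–50 Hz; the
lower edge avoids the ω = 0 singularity of the network operator.

## Spectral summaries

A global PSD is reduced to a 21-element observation vector: aperiodic offset
and exponent from a no-knee log-log line fit (robust to narrowband peaks by
iterative refitting on the lower residual percentile), the highest-power
Gaussian peak (center frequency, height above the aperiodic fit, bandwidth =
2σ; sentinel zeros when no peak clears 2 residual SDs and 0.05 log₁₀ units),
and mean log power in 16 equal-width bands over 0.5–50 Hz. Peak Gaussians
are fitted by unbounded Levenberg-Marquardt on a local window with an
analytic Jacobian and sanitized afterwards; a moment-based fallback covers
non-convergence. The layout is versioned
(`ap2-peak3-bins16/v1`) and enforced at inference time. For
posterior-dominant-rhythm analyses specifically, the peak search is
restricted to 3–15 Hz (`first_peak_in_band`). The 26-element manifold
embedding features (23 half-Hz bins to 12 Hz plus high-alpha, beta and gamma
band means) truncate the nominal 40–55 Hz gamma band at the grid maximum.

## Inference

Simulation-based inference over the seven-parameter box prior. The
conditional density estimator is a full-covariance Gaussian mixture (default
8 components) fitted to the joint of summary statistics and
*logit-reparameterized* parameters: each parameter is mapped through the
logit of its position in the prior interval, so the box interior maps onto
R⁷ and the box-uniform prior becomes a smooth logistic density. The posterior
at an observation is the exact analytic conditional of the mixture, sampled
and mapped back through the sigmoid. This parameterization was chosen over a
natural-units mixture for two reasons: (1) samples cannot leak outside the
physiological box, by construction; (2) the uninformative-data limit is
honest — a Gaussian fit of a *uniform* truncated to the box loses ~36% of
its variance, which would masquerade as posterior shrinkage, whereas the
logit-space fit keeps spurious shrinkage within ±0.15. The mixture size is
the largest for which that bias bound holds (measured max spurious shrinkage:
0.128 at K=4, 0.124 at K=8, 0.182 at K=10).

Two schemes share this estimator:

* **Amortized (NPE-style)** `train_npe`: one training on prior draws, any
  number of queries. Default desk-scale budget 4000–5000 simulations.
* **Truncated sequential (TSNPE-style)** `tsnpe_fit`: per-observation, 2–3
  rounds; after each round the proposal is truncated to the axis-aligned box
  holding 1−ε of posterior mass (ε = 1e-4, per-parameter empirical quantiles
  of 10⁴ draws) intersected with the prior, the next budget is drawn
  uniformly inside it, and the estimator is retrained on all accumulated
  pairs. Default desk-scale budget 3 × 1000.

Posterior sampling passes draws through a rejection step against the prior
box and reports the in-box acceptance rate as the leakage diagnostic; with
the built-in estimator the rate is 1 by construction. Point estimates are
the posterior mean (default) and a per-parameter KDE mode on a 512-point
grid over the prior interval — both are exposed because either convention is
defensible for downstream regression.

## What the data do and do not identify

Local sensitivity of the summary vector (standardized units per full prior
width, averaged over prior draws on a 16-region synthetic connectome): τ_e ≈
33, τ_i ≈ 12, G_EI ≈ 9, τ_G ≈ 8, G_II ≈ 8, α ≈ 1.6, S ≈ 0.14. The global-mean
spectrum therefore pins down the local time constants sharply, the gains and
graph time constant moderately, and the long-range coupling and conduction
speed only weakly — posterior dispersion is smallest for the time constants
and largest for conduction speed, and a 30k-simulation rejection-ABC
reference posterior confirms near-prior spread for α and S over the full
prior. Population-level trends in α remain recoverable (weak single-subject
information aggregates across a cohort), which is exactly what the cohort
recovery suite demonstrates; single-subject α shrinkage at desk budgets is
small, and the acceptance suite records this as a measured limitation rather
than papering over it.

## Diagnostics

* **Shrinkage** 1 − σ²_post/σ²_prior and **posterior z-score**
  |μ_post − θ̃|/σ_post, elementwise, with uniform prior variance (b−a)²/12.
* **Simulation-based calibration**: ranks of ground-truth parameters within
  L = 100 posterior draws over M = 100–200 prior replicates; uniformity
  tested per parameter by a one-sample KS test on (rank + 0.5)/(L + 1), with
  0.01 as the conservative significance threshold.
* **C2ST**: 5-fold cross-validated accuracy of a one-hidden-layer MLP
  (10 × d units) on standardized features, equal class sizes by subsampling;
  reported with fold SD.
* **PDI** (posterior dispersion index): posterior SD divided by prior
  interval width — a repo-local normalization (the quantity's published form
  is not specified anywhere we could adopt it from); 0 for a point mass,
  1/√12 ≈ 0.289 when the posterior equals the prior. Only orderings across
  parameters are meaningful.

## Cohort statistics

Ages are analysed as log₁₀ years (one day = 1/365.25 y; base 10 chosen and
recorded in outputs). Trends are Pearson correlations of per-subject point
estimates against log-age. Prediction uses degree-2 polynomial regression
with per-feature terms only (no cross-interactions unless requested) under
10-fold cross-validation; out-of-fold predictions are pooled and scored as
adjusted R² = 1 − (1−R²)(n−1)/(n−p−1). Predicted-vs-observed regressions put
predictions on x and observations on y, so an unbiased predictor has slope 1
and intercept 0. Heteroskedasticity is tested with the Breusch-Pagan LM
statistic n·R²_aux (auxiliary regression of squared residuals on the model
design), χ² null with one df per predictor. Spectral contrasts use base-2
Jensen-Shannon divergence between normalized mean spectra (0 = identical,
1 = disjoint); the coupling-vs-connectome contrast simulates the *same*
parameter draws on both connectomes (paired design, so an
identical-connectome contrast is exactly zero) and assesses the statistic
(regime effect − connectome effect) by joint label permutation (default 1000
permutations).

## Synthetic data

The connectome generator scatters regions uniformly in a 140 mm-diameter
sphere, decays weights as exp(−d/60 mm) with symmetric log-normal jitter
(σ = 0.4), keeps the strongest 30% of pairs, and guarantees connectivity by
re-adding edges along a random spanning order. It reproduces the gross
geometry and distance-dependence of a template structural connectome but not
tractography statistics, modular organization or hemispheric structure —
recovery results on it speak to the method, not to any particular brain.

Cohorts are age-structured with log-uniform ages over 1 day–30 years (so
neonates are well represented; the real-world age distribution of any
particular study is deliberately not replicated) and planted linear-in-log-age
parameter trajectories with between-subject jitter: α rises (+0.10/decade
from 0.50 at age 1 y), S rises (+1.5 m/s/decade from 7.0), G_EI falls
(−1.5/decade from 10), G_II rises (+1.5/decade from 10), τ_e and τ_i shorten
(−0.002 s/decade), τ_G flat. Magnitudes keep every trajectory strictly
inside the physiological box over the full age range (2%-of-range clipping
margin). Observation noise is multiplicative log-normal per frequency bin
(σ = 0.1 by default): positive, heavy-tailed, and unbiased in log power,
which is how EEG PSD noise behaves to first order. What passing tests show:
the pipeline recovers planted trend *signs* and supports age prediction with
adjusted R² > 0.3 under these conditions. What they do not show: performance
on real EEG with channel artifacts, subject-specific connectomes, or model
misspecification beyond multiplicative noise.

## Numerical choices and degenerate inputs

Connectome validation rejects non-finite, negative, dimensionally
inconsistent matrices and isolated regions (the Laplacian divides by
degrees); self-connections are zeroed with a logged warning. Degrees are
column sums, identical to row sums for the symmetric matrices used
throughout. The direct route reports the offending frequency on a singular
system; responses are checked finite; zero global power raises rather than
returning −∞ dB. GMM conditionals add a 1e-10 ridge before Cholesky
sampling. Simulation batches exclude and count failures, aborting above a
10% failure rate. All randomness flows through explicit seeds or
`numpy.random.Generator` instances; training is deterministic given (data,
seed, backend versions).

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which every claim is statistically meaningful: 12–16-region
synthetic connectomes, 100-point spectra, amortized budgets of 2000–4000
simulations, TSNPE at 3 × 1000 per observation, cohorts of 100 subjects, 200
draws per coupling regime for the divergence contrast, and 200–500
permutations/replicates for calibration rates. Paper-scale budgets (up to
10⁶ simulations, 10⁴ posterior draws per subject, full cohorts) are plain
configuration changes.

## Known limitations

* The local E-I transfer is one published algebraic form behind a pluggable
  contract; directional claims are asserted against the contract, not the
  algebra.
* α and S are weakly identified from global-mean spectra at desk budgets
  (see above); per-subject estimates of them should be interpreted only in
  aggregate.
* The coupling-ladder monotonicity is a regime-dependent property; it is
  asserted in a fixed, documented nuisance regime that expresses a clear
  ~8 Hz rhythm, not across the whole box.
* No raw-EEG preprocessing: inputs are precomputed PSD tables.
* The 2-D manifold embedding of spectra is delegated to `umap-learn` in an
  example script only; it is stochastic and has no ground truth to test
  against.
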