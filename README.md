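# sgmkit

Spectral graph modelling of whole-brain EEG spectra with simulation-based
Bayesian inference of the model's physiological parameters.

## The problem

The spectral content of the EEG changes dramatically across development — a
posterior dominant rhythm (PDR) emerges and accelerates, and the aperiodic
1/f background flattens and steepens in characteristic ways — but linking
those spectral changes to interpretable circuit-level quantities requires a
generative model that can be inverted against observed spectra. `sgmkit` is
for computational neuroscientists who want to do exactly that: simulate
whole-brain spectra from a structural connectome with a closed-form linear
model, infer the posterior distribution of its seven parameters from a
spectral summary of an observed EEG, check that the inference is calibrated,
and run population-level (e.g. developmental-trajectory) statistics over
per-subject estimates.

## The model

The spectral graph model (SGM) is linear and closed-form in the Fourier
domain. Local excitatory-inhibitory dynamics enter through gamma-shaped
transfer functions F(ω) = (1/τ²)/(iω + 1/τ)²; long-range propagation enters
through a complex graph Laplacian built from the structural connectome
**C** with conduction delays τ_jk = d_jk/S:

    C(ω) = diag(1/deg) · [ c_jk e^{−iω τ_jk} ],   L(ω) = I − α C(ω)
    T(ω) = ( iω I + F(ω)/τ_G · L(ω) )⁻¹ H_local(ω)

The modelled observable is the global-mean power spectrum under uncorrelated
white noise driving every region, psd_j(ω) = Σ_k |T_jk(ω)|². Seven
parameters govern the model: local time constants τ_e, τ_i (s), long-range
coupling α, conduction speed S (m/s), gains G_EI, G_II, and the graph time
constant τ_G (s), each bounded by a physiological box prior.

Inference is likelihood-free: spectra simulated from prior draws are reduced
to summary statistics (aperiodic 1/f fit, strongest periodic peak, binned
band powers) and a conditional density estimator — a Gaussian mixture over a
logit-reparameterized parameter space — is trained on the (parameter,
summary) pairs, either amortized (`train_npe`) or per-observation with
sequential proposal truncation (`tsnpe_fit`). Diagnostics include posterior
shrinkage and z-scores, simulation-based calibration with KS uniformity
tests, a classifier two-sample test, and a posterior dispersion index. See
`docs/methods.md` for the full model account and design choices.

## Worked example

Generate a synthetic connectome and age-structured cohort, infer posteriors,
and summarize developmental trends — all from the shell:

```bash
sgmkit synth --n-subjects 30 --n-regions 16 --seed 1 --out demo
sgmkit infer --psd demo/psd.csv --subjects demo/metadata.csv \
             --weights demo/weights.csv --distances demo/distances.csv \
             --method npe --budget 3000 --seed 1 --out demo/posteriors
sgmkit cohort --posteriors demo/posteriors --metadata demo/metadata.csv \
              --k 5 --out demo/report.json
```

which prints

```
wrote connectome, PSD table and metadata for 30 subjects to demo
wrote posteriors for 30 subjects to demo/posteriors
wrote cohort report to demo/report.json
```

`demo/report.json` then contains the per-parameter age correlations and the
cross-validated age-regression metrics; with seed 1 the run above prints
(abridged):

```json
{
  "n_subjects": 30,
  "correlations": {
    "tau_i": {"r": -0.922, "p": 4.30e-13, "n": 30},
    "alpha": {"r": 0.787,  "p": 2.46e-07, "n": 30},
    "speed": {"r": 0.254,  "p": 0.176,    "n": 30},
    "g_ei":  {"r": -0.688, "p": 2.63e-05, "n": 30},
    "g_ii":  {"r": 0.517,  "p": 0.00345,  "n": 30}
  },
  "age_regression": {"adj_r2": 0.392, "r2": 0.560, "mse": 0.576}
}
```

The correlations are Pearson r of each posterior-mean parameter against
log₁₀ age: the planted developmental trends — shortening time constants,
rising coupling, falling excitatory gain, rising inhibitory gain — are
recovered with the expected signs (conduction speed, the least-identified
parameter, shows the planted sign but does not reach significance at
n = 30), and the degree-2 cross-validated regression of log-age on the four
trend parameters reaches adjusted R² ≈ 0.39. The same workflow applied to
real data replaces
`demo/psd.csv` with a table of observed global-mean PSDs (first column
`frequency_hz`) and the connectome CSVs with a template structural
connectome.

The equivalent library calls are `make_connectome` / `make_cohort` →
`sample_prior` / `simulate_batch` / `train_npe` (or `tsnpe_fit`) →
`sample_posterior` → `CohortTable` / `age_correlation` / `cv_regression`.

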