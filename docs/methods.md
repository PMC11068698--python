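# Methods

## Model

The membrane voltage follows

    dv/dt = f(v) + η(t) + ε s(t)          outside refractory windows
    dv/dt = dv_spike/dt (t − t_i)          for t_i ≤ t < t_i + τ_ref,

with a spike registered at the first time `v ≥ v_T` and the voltage
subsequently following the prescribed waveform `v_spike` from threshold
`v_T` down to reset `v_R` over the absolute refractory period `τ_ref`.
The drift is leaky, `f(v) = μ − v` (voltage in units of the
threshold–reset distance, time in membrane time constants), with a
generic-drift escape hatch for small validation runs.  Neither noise nor
signal influences the voltage during refractoriness (the stimulus is
invisible to the neuron while it spikes); both processes keep evolving.

Spike shapes: `clamp` (voltage held at `v_R`; its derivative carries a
Dirac impulse of weight `v_R − v_T` at the window's left edge, represented
symbolically and never as a float), `alpha`
(`κ(t+t0)e^{−βt} − Δv` with `t0`, `β` solved from the boundary
conditions), and `tabulated` waveforms.

Driving noise: white Gaussian of intensity `D` (per-step increments
`√(2D/dt) g_k`, flat spectrum `2D`), or Ornstein–Uhlenbeck noise with
variance `σ²` and correlation time `τ_c`, generated by the exact
one-step update so its Lorentzian spectrum `2σ²τ_c/(1+(τ_c ω)²)` holds at
any step size (up to sampling distortion near the Nyquist frequency,
which is why spectral checks stop well below it).

## Numerical scheme

Euler–Maruyama with step `dt` (default 1e-3); the spike time is the first
grid point with `v ≥ v_T`, with no sub-step interpolation.  The
refractory window is played back from a precomputed shape table and
integration resumes from exactly `v_R`; `τ_ref` is required to sit on the
grid (snapped with a warning otherwise), since the boxcar-transform
identities are exact only on-grid.  The per-spike threshold overshoot
discarded by this scheme is O(dt) and checked to be negligible against
the statistical errors at the default step.  Burn-in (ten times the
slowest characteristic time, rounded up to whole windows) is discarded.
Randomness follows one master seed via `numpy` `SeedSequence` spawning:
noise, signal and per-chunk streams are derived deterministically, and
all outputs are bit-reproducible.  Long runs are simulated in chunks that
continue the voltage and accumulate window spectra without holding the
full traces (a refractory window straddling a chunk boundary is
truncated; at ≥64 windows per chunk this affects a vanishing fraction of
windows).

## Spectral conventions

Finite-window transform `ã(ω) = dt Σ a_n e^{+iωt_n}` on windows of `N`
samples, frequencies `ω_k = 2πk/T`, `k = 1..N/2−1`; window means are
subtracted (removing the DC delta of the rate and making estimates
covariances); no taper by default (Hann optional).  The stored
orientation is `S_ab(ω) = ⟨b̃ ã*⟩/T`, the transform of
`C_ab(τ) = ⟨a(t) b(t+τ)⟩`; swapping the pair conjugates the estimate
exactly.  Standard errors are window-to-window scatter.

**Convention audit.**  The FRR mixes estimated cross-spectra with
analytic transforms, and their relative complex orientation (conjugation
of `S_xv`, evaluation of `FI` and `B̃` at `±ω`, an overall sign) cannot
be trusted to any single written form — the τ_ref→0 limit of the clamp
transform must reproduce the known non-refractory relation with
`+(v_T−v_R) S_xx`, which fixes the boundary impulse to enter `FI` with
full weight `+(v_T−v_R)`.  The package therefore derives the orientation
numerically: `audit_conventions` evaluates all eight sign/conjugation
combinations against a probe-measured susceptibility on a white-noise run
(deliberately with a long τ_ref so wrong refractory orientations are
maximally penalized).  The winner — positive sign, `S_xv` conjugated,
`FI`/`B̃` evaluated at `−ω` — is frozen in `AUDITED_CONVENTION`, beats the
runner-up by ~3× in band-median error, is stable across seeds (tested),
and agrees with a from-scratch derivation of the Rice-averaged relation
in the package's own estimator convention.  Every report records the
audited orientation.

## Susceptibility measurement

Two independent routes:

* **Broadband probe.**  A Gaussian signal, exactly band-limited white in
  the window's Fourier basis (flat height `level` up to `cutoff`, drawn
  per window), scaled by `ε`; `χ̂ = S_sx/(ε S_ss)` is the least-squares
  regression of the spike train on the signal.  The probe adds effective
  spectral height `ε² level` to the drive and thereby shifts the
  operating point, biasing `χ` by roughly `0.75 ε² level/(2D)`; the
  default `ε = 0.11`, `level = 1` keeps this near 1% of the default noise
  while many short windows (2¹³ steps × 32768) control the variance.  An
  optional equal-size rerun at `ε/2` stores a linearity metric.
* **Furutsu–Novikov.**  For Gaussian drive, `S_ηx(ω) = χ(ω) S_ηη(ω)`
  holds exactly, so `χ` can be read off a spontaneous run by dividing the
  noise–spike-train cross-spectrum by the analytic noise spectrum.  This
  is probe-free (no back-action) and the most precise option at matched
  cost; the two methods agree within combined errors (tested).

## FRR evaluation and smoothing

The white-noise prediction `[ (1+iω) S_xv + FI S_xx ]/(2D)` suffers a
strong cancellation: individual terms are several times larger than the
result, so per-frequency noise is amplified.  Predictions are therefore
formed on a fine grid (long spontaneous windows, 2¹⁷ steps × 256 windows
by default) and Welch-smoothed — a centered boxcar over 16 adjacent,
nearly independent fine bins — onto the coarser grid of the probe
measurement.  Discrepancies are summarized as the median relative error
over the band `[π r0/2, 8π r0]` around the firing rate.

For the colored-noise recovery the refractory noise mean `⟨η⟩_ref` is
computed from the stationary-average formula
`(⟨f(v)⟩/r0 − ∫(f(v_spike) − v̇_spike))/τ_ref` (with `⟨v⟩` over the full
trace including refractory samples; a flag is not provided because the
alternative changes results only at O(r0 τ_ref dt)).  This estimator
amplifies the sample-mean fluctuation of the drive by `1/(r0 τ_ref)` and
is therefore intrinsically noisy at short τ_ref; its standard error
(propagated from window scatter of `⟨f(v)⟩` and `r0`, correlations
neglected) is carried into the recovery's per-frequency error bars, and
the pooled per-spike empirical mean serves as a low-noise cross-check.
Frequencies where `|χ|` is below three of its standard errors are masked
before division.

## Validation experiments (desk scale)

Default sizes (`dt = 1e-3`): spontaneous ensembles of 256 windows × 2¹⁷
steps; probe ensembles of 32768 windows × 2¹³ steps; triple-correlation
runs of 256 windows × 2¹⁴ steps; ISI runs sized for ≥2000 spikes.  Each
experiment completes in seconds to about a minute on one core; a
paper-scale preset (`dt = 1e-5`, window `T ≈ 167`, 1000 windows) exists
behind a runtime warning.  The noise-spectrum recovery experiment uses
the Furutsu–Novikov susceptibility by default: the refractory corrections
separating the three recovery variants are only a few percent of the
noise spectrum when `τ_ref` is a hundredth of the mean ISI, and the probe
estimator's noise would drown them; the probe route remains available via
`chi_method="probe"`.

The white-noise intensity is nowhere pinned by the reference setups, so
`D = 0.1` is the package default and all white-noise checks are
relation-based rather than tied to particular firing rates.  Threshold
and reset default to `v_T = 1`, `v_R = 0`; these values reproduce both
printed alpha-shape parameter pairs exactly and are an inference, not a
quoted statement.

## What the synthetic data does and does not show

The simulator is the data source; it realizes exactly the model the
relations are derived for (additive Gaussian noise, hard threshold,
stereotyped shape, stationary input).  Passing tests therefore
demonstrate the internal consistency and correct implementation of the
relations and estimators — not their applicability to real recordings,
where noise is neither Gaussian nor additive, spike shapes vary,
and stationarity fails.  Known limitations: the colored-noise relation is
an approximation valid for `τ_c` and `τ_ref` short against the mean ISI
(systematic high-frequency deviations appear when `τ_c` reaches a third
of the mean ISI); Euler discretization biases the firing rate at O(dt)
(about 4% at `dt = 1e-3` in the slow colored regime); and the probe
susceptibility carries the operating-point bias described above.
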