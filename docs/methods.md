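# Methods

This package estimates time-resolved, *directional* functional coupling
between scalp EEG band dynamics and heartbeat (RR interval) spectral
dynamics — brain–heart interplay (BHI) — and applies the paired
preictal-vs-postictal group statistics used in focal-epilepsy studies.
This note documents the model, the estimators, the synthetic study
conditions, and the numerical choices, in enough detail to reproduce or
criticize any of them.

## The generative model

Two physiologically motivated observation equations, on a common coarse
time grid (default step 1 s), tie the two systems together.

**Heartbeats (brain → heart branch).** Beats are produced by an integral
pulse frequency modulation (IPFM) model: a beat fires whenever

    ∫ (HR_ref / 60) · (1 + m(t)) dt

crosses an integer.  The autonomic modulation is a two-tone signal

    m(t) = C_LF(t) sin(ω_LF t) + C_HF(t) sin(ω_HF t),

with ω placed at the centers of the heart-rate-variability (HRV)
low-frequency band (LF, 0.04–0.15 Hz, sympathovagal) and high-frequency
band (HF, 0.15–0.40 Hz, vagal/respiratory).  Each tone amplitude follows

    C_i(t) = C_i0 + k_bth(t⁻) · P_brain(t⁻),        i ∈ {LF, HF},

where `P_brain` is the power of one EEG band on the grid and `k_bth` is
the time-resolved brain-to-heart (BtH) coupling coefficient.

**EEG (heart → brain branch).** Each channel is a sum of band-limited
oscillations, one per classic band (δ 1–4, θ 4–8, α 8–12, β 12–30 Hz),
whose amplitudes follow a first-order exogenous autoregression driven by
an HRV band power:

    a_j(t) = η_j a_j(t⁻) + k_htb(t⁻) · P_i(t⁻),      j ∈ {δ, θ, α, β}.

`k_htb` is the heart-to-brain (HtB) coupling coefficient; η_j (|η_j| < 1)
is the band's autoregressive memory.  Carrier phases never enter the
amplitude-domain fit and are treated as irrelevant to coupling estimation.

The lag `t⁻` is fixed at one grid step (1 s) in both directions.

## Signal-to-series reduction

* **EEG band power**: zero-phase FIR band-pass (Hamming windowed-sinc,
  order ≈ 3·fs/f_lo, applied forward–backward, i.e. |H|²) followed by the
  squared Hilbert analytic envelope, averaged within each grid bin.  For a
  tone of amplitude A this yields A²/2; amplitudes are reported as
  √(2·power) so a pure tone's amplitude is recovered exactly.
* **HRV band power**: R peaks from a Pan–Tompkins-style energy detector
  (band-pass 5–15 Hz, derivative, squaring, 150 ms integration, adaptive
  threshold, 220 bpm refractory period, record-level QRS polarity vote);
  RR artifacts corrected by the local-median rule (|RR − 11-beat median| >
  0.25 s → cubic replacement, the "medium" setting of common HRV
  software); cubic interpolation to 4 Hz; then a smoothed pseudo
  Wigner–Ville distribution (SPWVD) of the analytic, mean-removed RR
  series, integrated over LF or HF per grid point.  Lag (frequency)
  smoothing uses a ±32 s Hamming window, time smoothing a 5 s Hamming
  window; normalization again maps a tone of amplitude A to A²/2.  A
  Welch estimate over the whole window is kept as an independent
  cross-check of the SPWVD normalization.
* Grid points closer to a window edge than the filter/kernel support are
  flagged invalid and excluded from all fits.

## Inversion (the coupling estimators)

Both observation equations are linear in their two unknowns, so each is
inverted by ordinary least squares over a sliding window on the grid:

* BtH: regress C_i(k) on [1, P_brain(k−1)] → (C_i0, k_bth);
* HtB: regress a_j(k) on [a_j(k−1), P_i(k−1)] → (η_j, k_htb).

The coefficient is assigned to the window center; the series of window
estimates is the time-resolved coupling.  Windows with invalid points, a
numerically constant driver, or near-collinear regressors (collinearity
judged on unit-RMS-scaled regressors, so microvolt-vs-s² units cannot
masquerade as degeneracy) are flagged and returned as NaN, never
extrapolated.  Negative estimates are retained — the group tests compare
paired values, so sign information matters.

**Estimation window: 120 s, step 1 s.** This was a genuinely open design
point.  Measured HRV band powers can only vary on timescales ≳ 30 s
(amplitude-modulation sidebands must stay inside bands only 0.11–0.25 Hz
wide, and the SPWVD lag window spans ±32 s), so very short windows leave
the exogenous regressor nearly constant within the window and the
two-parameter fit becomes ridge-degenerate: in simulation, planted
four-fold coupling changes were invisible at 15 s windows and cleanly
recovered at 120 s.  The window is configurable; for analysis windows
shorter than 6 min it is capped at a third of the window length.

Noiseless series generated by the observation equations are recovered
exactly (relative error ~1e-13, the package's master oracle); with
additive noise at 10 % of the response level, the median absolute error
of the recovered coupling is below 10 % across 100 seeds.

## Analysis windows and cohort statistics

Per seizure event, a window of length L (default 10 min) ending at the
labeled clinical onset and one starting at the labeled offset are
analyzed (preictal / postictal; the ictal span itself is never used).
Events lacking L seconds on either side are excluded, with the reason
logged.  L ∈ {10, 7, 5, 3, 2, 1} min matches the window-length
sensitivity settings the pipeline supports.

Per event, channel, direction and band pair, the phase summary is the
median of the coefficient series over the window; 1-min sub-window
medians feed the trend analysis.

Group comparison (≥ 6 paired events):

1. Shapiro–Wilk screen of the paired differences per channel; if a
   majority of channels reject normality at 0.05, nonparametric testing
   is recommended (the default path).
2. Two-sided Wilcoxon signed-rank per channel, α = 0.01.  The null
   distribution is exact (dynamic programming over midranks, valid under
   ties, zeros dropped) up to n = 25 events, and a normal approximation
   with tie and continuity corrections beyond.  The exact path is tested
   against a full 2ⁿ enumeration oracle.
3. Spatial cluster permutation correction: channel adjacency from a
   Delaunay triangulation of the 2-D montage with edges > 1.5× the median
   edge length pruned; connected components of raw-significant channels
   with size < 2 are discarded; surviving cluster sizes are compared with
   the permutation null of the maximum cluster size under random
   within-event pre/post swaps (sign flips; default 1000 permutations,
   seeded), keeping clusters whose size exceeds the null's 95 % quantile.
   Cluster *size* (channel count) is the statistic, not cluster mass.
4. Trends: each event's 1-min medians (both phases pooled, 2·L/60 values)
   are z-scored within event — pooling keeps pre/post levels comparable —
   then averaged across events per minute.  Per-phase z-scoring is
   available behind a flag.

Under a simulated global null (38 events × 29 channels) the family-wise
error of the corrected maps is at the nominal 5 % level within binomial
error, and size-1 clusters are never reported.

## The synthetic study conditions

The forward simulator runs the full model and renders signals the real
pipeline must work for: EEG assembled from band-center carriers with the
AR amplitudes (plus white noise), ECG as a Gaussian-derivative QRS pulse
train at the IPFM beat times (plus beat-time jitter), a seizure span
filled with burst noise, and plain-text annotations.  Defaults, chosen
once as plausible resting physiology:

| quantity | default | note |
|---|---|---|
| reference heart rate | 70 bpm | per-event jitter ±4 bpm in cohorts |
| C_LF0 / C_HF0 | 0.04 / 0.03 | gives RR std ≈ 0.05 s |
| HRV baseline fluctuation | 30 %, τ ≈ 30 s | slow sympathovagal wandering |
| η (all bands) | 0.8 | ~5 s amplitude memory |
| band amplitudes δ/θ/α/β | 20/12/10/6 µV | ±15 % per-channel individuality |
| amplitude innovation | 50 % of (1−η)·a₀ | spontaneous waxing/waning |
| heart→brain drive fraction | 0.6 | share of steady-state amplitude |
| brain→heart drive fraction | 0.1 | share of C_i baseline |
| EEG noise | 2 µV | additive white |
| RR jitter | 3 ms | beat-time noise |
| sampling rate | 128 Hz | all bands < 32 Hz; 512 Hz supported |

The planted-effect study (the end-to-end detection benchmark) plants a
marked LF→δ heart-to-brain change in a 10-channel central patch — 3× the
base coupling preictally, 0.25× postictally — with the brain→heart
feedback weakened to 0.05 so the planted change stays in the heart→brain
branch.  16-event cohorts at 10-min windows are analyzed exactly like
real data (ECG → R peaks → RR → SPWVD; EEG → envelopes; sliding OLS;
Wilcoxon + cluster correction), restricted to the planted band pair.

**What the simulator does not emulate** — and therefore what passing
tests do not show about real data: volume conduction and channel
cross-talk, realistic ECG morphology (P/T waves) and ectopy, respiration
and its coupling into HF power, 1/f EEG background and artifacts, and
drug or vigilance effects.  The amplitude-modulation structure of real
EEG is richer than a single band-center carrier; the simulator's bands
are spectrally clean apart from additive noise.

One known internal inconsistency is accepted: the EEG amplitudes are
driven by the *baseline* HRV band powers (before the brain→heart
contribution is added), because the two branches would otherwise form an
algebraic loop on the grid.  At the default drive fractions the neglected
feedback is < 10 % of the driver and is invisible to the estimators.

## Numerical choices and degenerate inputs

* IPFM integration: trapezoidal cumulative integral at 1/512 s, beat
  times by linear interpolation of the threshold crossing (equivalent to
  integrator reset); mean rate converges to HR_ref within 1 % at 600 s.
* FIR margins are excluded from power series rather than tapered.
* RR correction never changes the number of intervals; beat times are
  rebuilt from corrected intervals.  >20 % corrected beats sets a quality
  flag.  Flat ECG yields an empty beat list plus a warning, not an error.
* Constant-driver windows: coefficient NaN + degeneracy flag; the
  companion parameter (intercept or AR gain) is refit alone when it
  remains identifiable.
* All randomness flows from explicit seeds; identical (scenario, seed)
  reproduce sessions bit for bit.

## Known limitations

* The 120 s estimation window trades time resolution for identifiability;
  coupling changes faster than ~2 min are smoothed.  The 1-min trend
  curves therefore understate edge minutes (which hold no window centers
  and are reported as NaN).
* Estimated coefficients carry a model-misspecification offset
  (intrinsic, non-cardiac cortical amplitude is absorbed into the
  exogenous term).  Paired pre/post contrasts cancel the offset; absolute
  coefficient values should not be interpreted as physical gains.
* Cluster-level inference is about clusters, not individual channels:
  a raw-significant neighbor can join a true cluster (spatial spillover).
* The Kubios "medium" artifact rule is proprietary; the local-median rule
  used here is an approximation validated only on synthetic artifacts.
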