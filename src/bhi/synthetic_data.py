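"""Forward simulation of coupled EEG / heartbeat sessions with known coupling.

The generator runs the coupling model forward:

* per channel, EEG band amplitudes follow the exogenous autoregression
  a_j(k) = eta_j a_j(k-1) + (1-eta_j) a_base_j + sum_i k_htb(k-1) P_i(k-1)
  on the 1 s grid, and the EEG is assembled as band-center sinusoids with
  those (interpolated) amplitudes plus additive noise;
* the heartbeat modulation amplitudes follow
  C_i(k) = C_i0 + B_i(k) + sum_ch k_bth(k-1) P_brain,ch(k-1) / n_drivers,
  where B_i is a slow baseline fluctuation, and the RR series comes from
  the IPFM integrator driven by the two-tone modulation;
* the ECG is rendered as a Gaussian-derivative QRS pulse at each beat so
  the R-peak detector has something realistic to chew on;
* a seizure span carries an amplitude burst and is excluded from analysis,
  and coupling coefficients may change level from the preictal to the
  postictal side (the planted effect).

Everything is reproducible from (scenario, seed).  Besides the full-signal
simulator there is a series-level generator (``simulate_coupled_series``)
that runs the same observation equations directly on the grid - the
noiseless forward-inverse round trip through the estimators is exact there,
which makes it the master oracle for the inversion code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import sdg_core
from .sdg_core import IPFMParams
from .types import (
    EEG_BAND_NAMES,
    EEG_BANDS,
    HRV_BAND_NAMES,
    HRV_BANDS,
    PhysioRecording,
    SeizureAnnotation,
    STANDARD_CHANNELS,
    montage_xy,
)

#: contiguous central patch used for planted effects
CENTRAL_PATCH = ("C3", "Cz", "C4", "Fc1", "Fc2", "Cp1", "Cp2", "Fz", "Pz",
                 "Cp5")

DEFAULT_A_BASE = {"delta": 20.0, "theta": 12.0, "alpha": 10.0, "beta": 6.0}
DEFAULT_ETA = {"delta": 0.8, "theta": 0.8, "alpha": 0.8, "beta": 0.8}


@dataclass
class EffectSpec:
    """A planted pre/post change in one coupling coefficient.

    The base coefficient is multiplied by ``pre_mult`` before seizure onset
    and by ``post_mult`` after seizure offset (linear ramp in between).
    ``channels`` limits the change to a patch (HtB: the affected EEG
    channels; BtH: the driving EEG channels).
    """

    direction: str                # "HtB" | "BtH"
    eeg_band: str = "delta"
    hrv_band: str = "LF"
    channels: tuple = CENTRAL_PATCH
    pre_mult: float = 2.0
    post_mult: float = 0.25


@dataclass
class SimScenario:
    """Complete specification of one simulated session."""

    seed: int = 0
    duration_s: float = 1350.0
    n_channels: int = 29
    fs: float = 128.0
    hr_ref_bpm: float = 70.0
    onset_s: float = 630.0
    offset_s: float = 690.0
    eta: dict = field(default_factory=lambda: dict(DEFAULT_ETA))
    a_base: dict = field(default_factory=lambda: dict(DEFAULT_A_BASE))
    c_lf0: float = 0.04
    c_hf0: float = 0.03
    #: relative slow fluctuation of the LF/HF modulation baselines
    hrv_baseline_frac: float = 0.3
    #: fractional strength of the coupling drives (0 = decoupled)
    htb_strength: float = 0.6
    bth_strength: float = 0.1
    effects: tuple = ()
    eeg_noise_uv: float = 2.0
    #: stochastic innovation of the band-amplitude recursion, as a fraction
    #: of (1 - eta) * a_base (spontaneous cortical waxing/waning)
    amp_noise_frac: float = 0.5
    #: slow per-channel multiplicative amplitude individuality
    chan_mod_frac: float = 0.15
    rr_jitter_s: float = 0.003
    baseline_tau_s: float = 30.0
    grid_step_s: float = 1.0
    ipfm_dt: float = 1.0 / 512.0
    subject_id: str = "SIM"

    def __post_init__(self) -> None:
        if any(abs(v) >= 1 for v in self.eta.values()):
            raise ValueError("|eta| < 1 required")
        L = self.onset_s
        if self.duration_s < 2 * 60.0 + (self.offset_s - self.onset_s):
            raise ValueError("duration too short")
        if self.eeg_noise_uv < 0 or self.rr_jitter_s < 0:
            raise ValueError("noise levels must be >= 0")
        if not 0 <= self.onset_s < self.offset_s <= self.duration_s:
            raise ValueError("seizure span must lie inside the record")

    @property
    def channel_labels(self) -> list:
        return list(STANDARD_CHANNELS[: self.n_channels])


@dataclass
class SimOutput:
    recording: PhysioRecording
    annotations: list
    truth: dict                  # (direction, eeg_band, hrv_band, channel) -> series
    grid_t_s: np.ndarray
    scenario: SimScenario


def _smooth_noise(rng, n, tau_pts, scale=1.0):
    """Zero-mean unit-variance smooth series, correlation time ~ tau_pts."""
    x = gaussian_filter1d(rng.standard_normal(n + 4 * int(tau_pts)),
                          sigma=max(tau_pts / 2.0, 1.0), mode="wrap")
    x = x[2 * int(tau_pts): 2 * int(tau_pts) + n]
    s = x.std()
    return scale * (x - x.mean()) / (s if s > 0 else 1.0)


def _phase_profile(t, onset, offset, pre, post):
    """pre level before onset, post level after offset, linear in between."""
    out = np.full(t.shape, pre, dtype=float)
    after = t >= offset
    out[after] = post
    mid = (t >= onset) & (t < offset)
    if mid.any() and offset > onset:
        frac = (t[mid] - onset) / (offset - onset)
        out[mid] = pre + frac * (post - pre)
    return out


def _base_coeff_htb(scenario: SimScenario, band: str, hrv: str) -> float:
    """Base HtB gain scaled so the cardiac drive contributes a
    ``htb_strength`` fraction of the band's steady-state amplitude."""
    c0 = scenario.c_lf0 if hrv == "LF" else scenario.c_hf0
    p_i = c0 ** 2 / 2.0
    if p_i == 0.0 or scenario.htb_strength == 0.0:
        return 0.0
    eta = scenario.eta[band]
    a = scenario.a_base[band]
    return scenario.htb_strength * a * (1.0 - eta) / (2 * p_i)


def _base_coeff_bth(scenario: SimScenario, band: str, hrv: str) -> float:
    """Base BtH gain scaled so the *total* cortical drive (all four bands
    together) moves C_i by a ``bth_strength`` fraction of its baseline.

    The expected band power includes the amplitude inflation caused by the
    heart-to-brain drive (steady state about (1 + htb_strength) a_base)."""
    c0 = scenario.c_lf0 if hrv == "LF" else scenario.c_hf0
    a_eff = scenario.a_base[band] * (1.0 + scenario.htb_strength)
    p_b = a_eff ** 2 / 2.0
    if p_b == 0.0:
        return 0.0
    n_bands = len(EEG_BAND_NAMES)
    return scenario.bth_strength * c0 / (n_bands * p_b)


def simulate_session(scenario: SimScenario) -> SimOutput:
    """Run the coupled generative model forward for one session."""
    rng = np.random.default_rng(scenario.seed)
    sc = scenario
    labels = sc.channel_labels
    n_ch = len(labels)
    step = sc.grid_step_s
    t = np.arange(0.0, sc.duration_s, step)
    n = t.size
    tau = sc.baseline_tau_s / step

    # --- heartbeat modulation baselines (slow fluctuation around c_*0)
    b_lf = sc.c_lf0 * (1.0 + sc.hrv_baseline_frac * _smooth_noise(rng, n, tau))
    b_hf = sc.c_hf0 * (1.0 + sc.hrv_baseline_frac * _smooth_noise(rng, n, tau))
    b_lf = np.clip(b_lf, 0.2 * sc.c_lf0, None)
    b_hf = np.clip(b_hf, 0.2 * sc.c_hf0, None)
    p_true = {"LF": b_lf ** 2 / 2.0, "HF": b_hf ** 2 / 2.0}

    # --- coefficient time courses
    truth = {}
    htb_coeff = {}
    for band in EEG_BAND_NAMES:
        for hrv in HRV_BAND_NAMES:
            base = _base_coeff_htb(sc, band, hrv)
            for ch in labels:
                prof = np.full(n, base)
                for eff in sc.effects:
                    if (eff.direction == "HtB" and eff.eeg_band == band
                            and eff.hrv_band == hrv and ch in eff.channels):
                        prof = base * _phase_profile(
                            t, sc.onset_s, sc.offset_s,
                            eff.pre_mult, eff.post_mult,
                        )
                htb_coeff[(hrv, band, ch)] = prof
                truth[("HtB", band, hrv, ch)] = prof

    bth_coeff = {}
    for band in EEG_BAND_NAMES:
        for hrv in HRV_BAND_NAMES:
            base = _base_coeff_bth(sc, band, hrv)
            for ch in labels:
                prof = np.full(n, base)
                for eff in sc.effects:
                    if (eff.direction == "BtH" and eff.eeg_band == band
                            and eff.hrv_band == hrv and ch in eff.channels):
                        prof = base * _phase_profile(
                            t, sc.onset_s, sc.offset_s,
                            eff.pre_mult, eff.post_mult,
                        )
                bth_coeff[(band, hrv, ch)] = prof
                truth[("BtH", band, hrv, ch)] = prof

    # --- EEG band amplitudes per channel (exogenous AR on the grid)
    amps = np.zeros((n_ch, len(EEG_BAND_NAMES), n))
    for bi, band in enumerate(EEG_BAND_NAMES):
        eta = sc.eta[band]
        a0 = sc.a_base[band]
        # per-channel amplitude individuality (slow, multiplicative)
        chan_mod = np.stack([
            1.0 + sc.chan_mod_frac * _smooth_noise(rng, n, tau)
            for _ in range(n_ch)
        ])
        a = np.full(n_ch, a0, dtype=float)
        sig_a = sc.amp_noise_frac * (1.0 - eta) * a0
        innov = sig_a * rng.standard_normal((n_ch, n))
        drive_all = np.zeros((n_ch, n))
        for hrv in HRV_BAND_NAMES:
            kk = np.stack([htb_coeff[(hrv, band, ch)] for ch in labels])
            drive_all += kk * p_true[hrv][None, :]
        for k in range(n):
            if k > 0:
                a = (eta * a + (1.0 - eta) * a0 * chan_mod[:, k]
                     + drive_all[:, k - 1] + innov[:, k])
                a = np.maximum(a, 0.05 * a0)
            amps[:, bi, k] = a

    # --- modulation amplitudes from EEG band powers
    p_brain = amps ** 2 / 2.0                      # (ch, band, t)
    c = {"LF": b_lf.copy(), "HF": b_hf.copy()}
    for hrv in HRV_BAND_NAMES:
        drive = np.zeros(n)
        for bi, band in enumerate(EEG_BAND_NAMES):
            kk = np.stack([bth_coeff[(band, hrv, ch)] for ch in labels])
            contrib = (kk * p_brain[:, bi, :]).mean(axis=0)
            drive[1:] += contrib[:-1]              # lag one grid step
        c[hrv] = np.clip(c[hrv] + drive, 0.0, 0.45)

    # --- heartbeats via IPFM, RR jitter, ECG rendering
    params = IPFMParams(hr_ref_bpm=sc.hr_ref_bpm, c_lf0=sc.c_lf0,
                        c_hf0=sc.c_hf0)
    m = sdg_core.modulation_from_eq1(c["LF"], c["HF"], t, params)
    beats = sdg_core.ipfm_generate(m, params, sc.duration_s, dt=sc.ipfm_dt)
    if sc.rr_jitter_s > 0:
        beats = np.sort(
            beats + rng.normal(0.0, sc.rr_jitter_s, size=beats.size)
        )
        beats = beats[(beats > 0) & (beats < sc.duration_s)]

    n_samp = int(round(sc.duration_s * sc.fs))
    t_fine = np.arange(n_samp) / sc.fs
    ecg = _render_ecg(beats, sc.fs, n_samp)
    ecg += 0.02 * rng.standard_normal(n_samp)

    # --- EEG assembly: band-center carriers with interpolated amplitudes
    eeg = np.zeros((n_ch, n_samp))
    for bi, band in enumerate(EEG_BAND_NAMES):
        f_c = EEG_BANDS[band].center_hz
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        carrier = np.sin(
            2 * np.pi * f_c * t_fine[None, :] + phases[:, None]
        )
        i0 = np.clip(np.searchsorted(t, t_fine, side="right") - 1, 0,
                     n - 2)
        frac = np.clip((t_fine - t[i0]) / step, 0.0, 1.0)
        a_fine = (amps[:, bi, i0] * (1.0 - frac)
                  + amps[:, bi, i0 + 1] * frac)
        eeg += a_fine * carrier
    if sc.eeg_noise_uv > 0:
        eeg += sc.eeg_noise_uv * rng.standard_normal(eeg.shape)

    # --- ictal burst (analysis never looks inside, but files do contain it)
    ictal = (t_fine >= sc.onset_s) & (t_fine < sc.offset_s)
    if ictal.any():
        burst = 40.0 * rng.standard_normal((n_ch, int(ictal.sum())))
        eeg[:, ictal] += burst
        ecg[ictal] += 0.3 * rng.standard_normal(int(ictal.sum()))

    rec = PhysioRecording(
        eeg=eeg, ecg=ecg, fs=sc.fs, channel_labels=labels,
        montage_xy=montage_xy(labels), subject_id=sc.subject_id,
    )
    ann = [SeizureAnnotation(sc.onset_s, sc.offset_s, "sz1")]
    return SimOutput(recording=rec, annotations=ann, truth=truth,
                     grid_t_s=t, scenario=sc)


def _render_ecg(beats, fs, n_samp):
    """Gaussian-derivative QRS template (about 1 mV peak) at each beat."""
    width = 0.012                                  # s, template sigma
    half = int(round(5 * width * fs))
    tt = (np.arange(-half, half + 1)) / fs
    template = -tt / width * np.exp(0.5 - (tt / width) ** 2 / 2.0)
    ecg = np.zeros(n_samp)
    idx = np.round(beats * fs).astype(int)
    for i in idx:
        lo, hi = i - half, i + half + 1
        slo, shi = max(lo, 0), min(hi, n_samp)
        ecg[slo:shi] += template[slo - lo: shi - lo]
    return ecg


# ---------------------------------------------------------------------------
# Series-level generator (inversion oracle)
# ---------------------------------------------------------------------------

def simulate_coupled_series(direction: str, n: int = 600, *,
                            coeff=0.5, eta: float = 0.8, intercept: float = 2.0,
                            driver_mean: float = 1.0, driver_std: float = 0.5,
                            driver_tau: float = 5.0,
                            noise_std: float = 0.0, seed: int = 0):
    """Run one observation equation forward directly on the grid.

    direction "BtH": y(k) = intercept + coeff(k-1) * P(k-1) + noise;
    direction "HtB": y(k) = eta * y(k-1) + coeff(k-1) * P(k-1) + noise.

    ``coeff`` may be a scalar or a length-n series (time-varying coupling).
    Returns (t_s, y, driver, coeff_series).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n, dtype=float)
    driver = driver_mean + _smooth_noise(rng, n, driver_tau, scale=driver_std)
    driver = np.clip(driver, 0.05 * driver_mean, None)
    kser = np.broadcast_to(np.asarray(coeff, dtype=float), (n,)).copy()
    y = np.zeros(n)
    eps = noise_std * rng.standard_normal(n) if noise_std > 0 else np.zeros(n)
    if direction == "BtH":
        y[0] = intercept + kser[0] * driver_mean
        y[1:] = intercept + kser[:-1] * driver[:-1] + eps[1:]
    elif direction == "HtB":
        y[0] = kser[0] * driver_mean / (1.0 - eta)
        for k in range(1, n):
            y[k] = eta * y[k - 1] + kser[k - 1] * driver[k - 1] + eps[k]
    else:
        raise ValueError("direction must be 'BtH' or 'HtB'")
    return t, y, driver, kser


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(n_events: int, template: SimScenario | None = None,
                    seed: int = 0, null_mode: bool = False) -> list:
    """Independent events from per-event perturbed copies of a template.

    ``null_mode`` strips all planted effects (pre == post coupling), for
    calibration of the statistical pipeline.
    """
    if n_events < 6:
        raise ValueError("need at least 6 events for paired statistics")
    template = template or SimScenario()
    rng = np.random.default_rng(seed)
    out = []
    for e in range(n_events):
        sc = SimScenario(
            seed=int(rng.integers(0, 2**31 - 1)),
            duration_s=template.duration_s,
            n_channels=template.n_channels,
            fs=template.fs,
            hr_ref_bpm=float(
                np.clip(template.hr_ref_bpm + rng.normal(0, 4), 45, 110)
            ),
            onset_s=template.onset_s,
            offset_s=template.offset_s,
            eta=dict(template.eta),
            a_base={k: v * float(rng.uniform(0.85, 1.15))
                    for k, v in template.a_base.items()},
            c_lf0=template.c_lf0 * float(rng.uniform(0.85, 1.15)),
            c_hf0=template.c_hf0 * float(rng.uniform(0.85, 1.15)),
            htb_strength=template.htb_strength,
            bth_strength=template.bth_strength,
            effects=() if null_mode else template.effects,
            eeg_noise_uv=template.eeg_noise_uv,
            rr_jitter_s=template.rr_jitter_s,
            baseline_tau_s=template.baseline_tau_s,
            grid_step_s=template.grid_step_s,
            ipfm_dt=template.ipfm_dt,
            subject_id=f"SIM{e:02d}",
        )
        out.append(simulate_session(sc))
    return out


def simulate_summary_cohort(n_events: int = 38, n_channels: int = 29,
                            effect_channels=(), effect_size: float = 0.0,
                            spatial_corr: float = 0.3, seed: int = 0):
    """Per-event, per-channel phase-median coupling summaries, directly.

    A lightweight generator for calibrating the group statistics: each
    event contributes a preictal and a postictal per-channel summary value
    with spatially correlated noise (common event-level component plus
    channel noise).  ``effect_size`` is added to the *preictal* value of
    ``effect_channels`` (so positive = preictal > postictal).  Returns
    (pre, post) arrays of shape (n_events, n_channels).
    """
    rng = np.random.default_rng(seed)
    labels = list(STANDARD_CHANNELS[:n_channels])
    shared = rng.standard_normal((n_events, 1, 2))
    chan = rng.standard_normal((n_events, n_channels, 2))
    vals = (np.sqrt(spatial_corr) * shared
            + np.sqrt(1 - spatial_corr) * chan)
    pre = vals[:, :, 0].copy()
    post = vals[:, :, 1].copy()
    for ch in effect_channels:
        pre[:, labels.index(ch)] += effect_size
    return pre, post, labels


# ---------------------------------------------------------------------------
# Fixture writer
# ---------------------------------------------------------------------------

def write_session(sim: SimOutput, out_dir, stem: str | None = None):
    """Write a simulated session as EDF + plain-text annotations."""
    import pathlib

    from ._edf import write_edf

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or sim.recording.subject_id or "session"
    edf_path = out_dir / f"{stem}.edf"
    ann_path = out_dir / f"{stem}_annotations.txt"

    rec = sim.recording
    signals = [rec.eeg[i] for i in range(rec.n_channels)] + [rec.ecg]
    labels = [f"EEG {ch}" for ch in rec.channel_labels] + ["ECG"]
    dims = ["uV"] * rec.n_channels + ["mV"]
    write_edf(edf_path, signals, labels, rec.fs, dims,
              patient_id=rec.subject_id)
    with open(ann_path, "w") as f:
        f.write("# event_id onset_s offset_s\n")
        for a in sim.annotations:
            f.write(f"{a.event_id} {a.onset_s:.3f} {a.offset_s:.3f}\n")
    return edf_path, ann_path
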