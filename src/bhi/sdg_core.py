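"""The directional brain-heart coupling model: forward synthesis and inversion.

The generative picture has two halves:

* Brain -> heart.  Heartbeats come from an integral pulse frequency
  modulation (IPFM) model: a beat fires whenever the integral of the
  instantaneous rate (hr_ref/60) * (1 + m(t)) reaches 1.  The modulation

      m(t) = C_LF(t) sin(w_LF t) + C_HF(t) sin(w_HF t)

  carries one tone per HRV band, and each amplitude evolves as

      C_i(t) = C_i0 + k_bth(t-) * P_brain(t-),

  where P_brain is the power of one EEG band and k_bth is the
  time-resolved brain-to-heart coupling coefficient.

* Heart -> brain.  Each EEG band amplitude a_j follows a first-order
  exogenous autoregression driven by an HRV band power P_i:

      a_j(t) = eta_j * a_j(t-) + k_htb(t-) * P_i(t-).

Inversion is sliding-window ordinary least squares of those two linear
observation equations on the common 1 s grid, with the lag t- fixed at one
grid step.  Noiseless data generated by the forward equations are recovered
exactly; that forward-inverse round trip is the module's master oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .types import (
    BHISeries,
    BandPowerSeries,
    EEG_BAND_NAMES,
    HRV_BAND_NAMES,
    HRV_BANDS,
)

DEFAULT_WINDOW_S = 120.0
DEFAULT_STEP_S = 1.0
#: lag "t-" between driver and response, in grid steps
LAG_STEPS = 1


@dataclass
class IPFMParams:
    """Integral pulse frequency modulation parameters.

    hr_ref_bpm sets the mean rate; c_lf0/c_hf0 are baseline (dimensionless)
    modulation amplitudes of the LF and HF tones; omega_* default to the
    band-center angular frequencies.
    """

    hr_ref_bpm: float = 70.0
    c_lf0: float = 0.0
    c_hf0: float = 0.0
    omega_lf: float = HRV_BANDS["LF"].omega_center
    omega_hf: float = HRV_BANDS["HF"].omega_center

    def __post_init__(self) -> None:
        if not 20.0 < self.hr_ref_bpm < 220.0:
            raise ValueError("hr_ref_bpm must lie in (20, 220)")
        if self.c_lf0 < 0 or self.c_hf0 < 0:
            raise ValueError("baseline modulation amplitudes must be >= 0")


@dataclass
class HtBParams:
    """Per-band autoregressive parameters of the EEG amplitude model."""

    eta: dict          # band name -> gain, |eta| < 1
    phi: dict | None = None   # band name -> carrier phase (rad)

    def __post_init__(self) -> None:
        if set(self.eta) != set(EEG_BAND_NAMES):
            raise ValueError(f"eta must cover bands {EEG_BAND_NAMES}")
        if any(abs(v) >= 1.0 for v in self.eta.values()):
            raise ValueError("|eta| < 1 required for stable synthesis")
        if self.phi is None:
            self.phi = {b: 0.0 for b in EEG_BAND_NAMES}


def modulation_from_eq1(c_lf_series, c_hf_series, t_s, params: IPFMParams):
    """Two-tone IPFM modulation with time-varying amplitudes.

    Returns a callable m(t) that linearly interpolates the amplitude series
    onto any evaluation time (held constant outside their support).
    """
    c_lf = np.asarray(c_lf_series, dtype=float)
    c_hf = np.asarray(c_hf_series, dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    if np.any(c_lf < 0) or np.any(c_hf < 0):
        raise ValueError("modulation amplitudes must be nonnegative")

    def m(t):
        t = np.asarray(t, dtype=float)
        alf = np.interp(t, t_s, c_lf)
        ahf = np.interp(t, t_s, c_hf)
        return alf * np.sin(params.omega_lf * t) + ahf * np.sin(
            params.omega_hf * t
        )

    return m


def ipfm_generate(modulation, params: IPFMParams, duration_s: float,
                  dt: float = 1.0 / 512.0) -> np.ndarray:
    """Generate beat times from the IPFM model.

    The integrator accumulates (hr_ref/60)*(1 + m(t)); each unit crossing
    emits a beat, located by linear interpolation of the crossing (this is
    equivalent to resetting the integrator at every beat).
    """
    t = np.arange(0.0, duration_s + dt, dt)
    if callable(modulation):
        m = np.asarray(modulation(t), dtype=float)
    else:
        m = np.asarray(modulation, dtype=float)
        if m.size != t.size:
            raise ValueError("sampled modulation must match the time grid")
    rate = params.hr_ref_bpm / 60.0 * (1.0 + m)
    if np.any(rate <= 0):
        raise ValueError("modulation drives the instantaneous rate <= 0")
    integral = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2.0 * dt)])
    n_beats = int(np.floor(integral[-1]))
    if n_beats < 1:
        return np.empty(0)
    levels = np.arange(1, n_beats + 1, dtype=float)
    return np.interp(levels, integral, t)


# ---------------------------------------------------------------------------
# Sliding-window least squares
# ---------------------------------------------------------------------------

def _sliding_ols(y: np.ndarray, r1: np.ndarray, r2: np.ndarray,
                 valid: np.ndarray, win: int, step: int,
                 cond_max: float = 1e8):
    """Batched 2-regressor OLS over sliding windows.

    Solves y ~ b1*r1 + b2*r2 in every window of ``win`` points advancing by
    ``step``.  Windows containing invalid points, a (numerically) constant
    second regressor, or an ill-conditioned normal matrix are flagged and
    their b2 set to NaN.  Returns (centers_idx, b1, b2, resid_var, flags).
    """
    n = y.size
    if n < win:
        raise ValueError("series shorter than the estimation window")
    Y = sliding_window_view(y, win)[::step]
    R1 = sliding_window_view(r1, win)[::step]
    R2 = sliding_window_view(r2, win)[::step]
    V = sliding_window_view(valid, win)[::step]
    centers = np.arange(0, n - win + 1, step) + win // 2

    s11 = np.einsum("ij,ij->i", R1, R1)
    s12 = np.einsum("ij,ij->i", R1, R2)
    s22 = np.einsum("ij,ij->i", R2, R2)
    t1 = np.einsum("ij,ij->i", R1, Y)
    t2 = np.einsum("ij,ij->i", R2, Y)

    # collinearity is judged on unit-RMS regressors so that wildly
    # different physical units (microvolts vs squared seconds) do not
    # masquerade as degeneracy
    with np.errstate(divide="ignore", invalid="ignore"):
        rho2 = np.where((s11 > 0) & (s22 > 0),
                        s12 * s12 / (s11 * s22), 1.0)
    one_minus = np.maximum(1.0 - rho2, 0.0)
    cond = np.where(one_minus > 0,
                    (1 + np.sqrt(rho2)) / np.maximum(1 - np.sqrt(rho2), 1e-300),
                    np.inf)

    det = s11 * s22 - s12 * s12
    r2_var = R2.var(axis=1)
    r2_scale = np.maximum(np.abs(R2).max(axis=1) ** 2, 1e-300)
    degenerate = (
        ~V.all(axis=1)
        | (r2_var <= 1e-20 * r2_scale)
        | (cond > cond_max)
        | (det <= 0)
    )

    safe_det = np.where(det > 0, det, 1.0)
    b1 = (s22 * t1 - s12 * t2) / safe_det
    b2 = (s11 * t2 - s12 * t1) / safe_det
    resid = Y - b1[:, None] * R1 - b2[:, None] * R2
    resid_var = resid.var(axis=1)
    b2 = np.where(degenerate, np.nan, b2)
    # b1 (intercept / AR gain) stays estimable when only r2 degenerates:
    # refit the 1-regressor model on those windows
    only_r2 = degenerate & V.all(axis=1) & (s11 > 0)
    b1 = np.where(only_r2, t1 / np.where(s11 > 0, s11, 1.0), b1)
    b1 = np.where(degenerate & ~only_r2, np.nan, b1)
    return centers, b1, b2, resid_var, degenerate


def _grid_step(t_s: np.ndarray) -> float:
    d = np.diff(t_s)
    if d.size == 0 or not np.allclose(d, d[0]):
        raise ValueError("time grid must be uniform")
    return float(d[0])


def _check_alignment(t_a: np.ndarray, t_b: np.ndarray) -> None:
    if t_a.shape != t_b.shape or not np.allclose(t_a, t_b):
        raise ValueError("driver and response series must share the grid")


def estimate_coupling(y: np.ndarray, driver_power: np.ndarray,
                      t_s: np.ndarray, valid: np.ndarray,
                      window_s: float, step_s: float,
                      autoregressive: bool) -> dict:
    """Shared inversion core for both directions.

    Regresses y(k) on [1, P(k-1)] (brain->heart) or on
    [y(k-1), P(k-1)] (heart->brain, autoregressive=True).
    """
    step_grid = _grid_step(t_s)
    win = int(round(window_s / step_grid))
    step = max(int(round(step_s / step_grid)), 1)
    if win < 10:
        raise ValueError("estimation window must span >= 10 grid points")
    lag = LAG_STEPS
    yk = y[lag:]
    r2 = driver_power[:-lag]
    r1 = y[:-lag] if autoregressive else np.ones_like(yk)
    v = valid[lag:] & valid[:-lag]
    centers, b1, b2, rv, flags = _sliding_ols(yk, r1, r2, v, win, step)
    return {
        "t_s": t_s[lag:][centers],
        "coeff": b2,
        "extra": b1,
        "resid_var": rv,
        "degenerate": flags,
    }


def estimate_bth(c_i: BandPowerSeries, p_brain: BandPowerSeries,
                 window_s: float = DEFAULT_WINDOW_S,
                 step_s: float = DEFAULT_STEP_S) -> BHISeries:
    """Brain-to-heart coupling: HRV band amplitude C_i regressed on the
    lagged EEG band power, per sliding window.

    ``c_i`` is the HRV band series whose *amplitude* (sqrt(2 power)) is the
    response; ``p_brain`` is the EEG band power series of one channel.
    """
    _check_alignment(c_i.t_s, p_brain.t_s)
    res = estimate_coupling(
        c_i.amplitude, p_brain.power, c_i.t_s,
        c_i.valid & p_brain.valid, window_s, step_s, autoregressive=False,
    )
    return BHISeries(
        direction="BtH", eeg_band=p_brain.band.name, hrv_band=c_i.band.name,
        channel=p_brain.channel, **res,
    )


def estimate_htb(a_j: BandPowerSeries, p_i: BandPowerSeries,
                 window_s: float = DEFAULT_WINDOW_S,
                 step_s: float = DEFAULT_STEP_S) -> BHISeries:
    """Heart-to-brain coupling: EEG band amplitude a_j regressed on its own
    lag and the lagged HRV band power, per sliding window.

    The companion AR gain eta is returned in ``extra``.
    """
    _check_alignment(a_j.t_s, p_i.t_s)
    res = estimate_coupling(
        a_j.amplitude, p_i.power, a_j.t_s,
        a_j.valid & p_i.valid, window_s, step_s, autoregressive=True,
    )
    return BHISeries(
        direction="HtB", eeg_band=a_j.band.name, hrv_band=p_i.band.name,
        channel=a_j.channel, **res,
    )


def n_windows(n_points: int, window_s: float, step_s: float,
              grid_step_s: float = 1.0) -> int:
    """Coefficient series length for a grid of n_points (after the 1-step
    lag): floor((span - window)/step) + 1."""
    win = int(round(window_s / grid_step_s))
    step = max(int(round(step_s / grid_step_s)), 1)
    return (n_points - LAG_STEPS - win) // step + 1


def compute_bhi_window(eeg: np.ndarray, fs: float, rr4hz: np.ndarray,
                       channel_labels, grid_step_s: float = 1.0,
                       window_s: float = DEFAULT_WINDOW_S,
                       step_s: float = DEFAULT_STEP_S,
                       t0: float = 0.0,
                       eeg_bands=EEG_BAND_NAMES,
                       hrv_bands=HRV_BAND_NAMES) -> list:
    """All directional coupling series per channel for one window.

    With the full band sets, per channel: 8 BtH (4 EEG bands x {LF, HF})
    + 8 HtB ({LF, HF} x 4 EEG bands).  ``eeg_bands``/``hrv_bands`` restrict
    the grid (e.g. a single pair for focused studies).  EEG and RR series
    must cover the same span.
    """
    from . import band_power as bp

    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    if eeg.shape[0] != len(channel_labels):
        raise ValueError("channel_labels must match eeg rows")

    hrv_series = {
        b: bp.hrv_band_power(rr4hz, b, grid_step_s=grid_step_s, t0=t0)
        for b in hrv_bands
    }
    n_grid = next(iter(hrv_series.values())).t_s.size

    from .types import get_band

    out = []
    for band in eeg_bands:
        grid, power, valid = bp.eeg_band_power_multi(
            eeg, fs, band, grid_step_s=grid_step_s, t0=t0
        )
        if grid.size != n_grid:
            raise ValueError("EEG and HRV grids must align")
        for ci, ch in enumerate(channel_labels):
            pb = BandPowerSeries(band=get_band(band), t_s=grid,
                                 power=power[ci], valid=valid,
                                 channel=ch)
            for hb in hrv_bands:
                out.append(estimate_bth(hrv_series[hb], pb,
                                        window_s=window_s, step_s=step_s))
                out.append(estimate_htb(pb, hrv_series[hb],
                                        window_s=window_s, step_s=step_s))
    return out


def compute_bhi_event(pre, post, **kw) -> dict:
    """Coupling series for the pre/post window pair of one event.

    ``pre`` and ``post`` are dicts with keys eeg, fs, rr4hz,
    channel_labels (as produced by the preprocessing stage).
    """
    result = {}
    n_pairs = 2 * len(kw.get("eeg_bands", EEG_BAND_NAMES)) * len(
        kw.get("hrv_bands", HRV_BAND_NAMES)
    )
    for phase, w in (("preictal", pre), ("postictal", post)):
        series = compute_bhi_window(
            w["eeg"], w["fs"], w["rr4hz"], w["channel_labels"],
            t0=w.get("t0", 0.0), **kw,
        )
        expected = n_pairs * len(w["channel_labels"])
        if len(series) != expected:
            raise RuntimeError(
                f"{phase}: produced {len(series)} series, expected {expected}"
            )
        result[phase] = series
    return result
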