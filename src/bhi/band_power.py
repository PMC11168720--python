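"""Time-resolved band power estimation for EEG channels and RR dynamics.

Two estimators share a common uniform output grid (default 1 s step):

* EEG bands (delta/theta/alpha/beta): zero-phase FIR band-pass followed by
  the squared Hilbert analytic envelope, moving-average smoothed.  For a
  pure in-band tone of amplitude A this returns A^2/2, matching the
  sinusoidal amplitude convention used by the coupling model.
* HRV bands (LF/HF): a smoothed pseudo-Wigner-Ville distribution (SPWVD) of
  the mean-removed 4 Hz RR series, integrated over the band.  Independent
  time and lag smoothing keeps the estimate stable at the low frequencies
  (0.04-0.4 Hz) where heartbeat autonomic rhythms live.

Both estimators mark grid points too close to the window edges as invalid
(filter / kernel transients); downstream regressions honour that mask.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal

from .types import BandDefinition, BandPowerSeries, get_band

RR_FS = 4.0  # Hz, conventional HRV resampling rate


def fir_bandpass(lo_hz: float, hi_hz: float, fs: float,
                 order_factor: float = 3.0) -> np.ndarray:
    """Windowed-sinc (Hamming) band-pass FIR taps.

    The order scales with fs / lo_hz so the transition band stays narrow
    relative to the lower cutoff; the kernel is odd-length and symmetric
    (linear phase).
    """
    if fs <= 2.0 * hi_hz:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {hi_hz} Hz upper cutoff"
        )
    numtaps = int(math.ceil(order_factor * fs / lo_hz)) + 1
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, [lo_hz, hi_hz], pass_zero=False, fs=fs,
                         window="hamming")


def apply_zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward application of a FIR filter (magnitude |H|^2, zero
    phase), done in one FFT round trip, edge-padded by reflection.
    Length-preserving."""
    from scipy.fft import irfft, next_fast_len, rfft

    x = np.asarray(x, dtype=float)
    pad = len(taps)
    flat = x.reshape(-1, x.shape[-1]) if x.ndim > 1 else x[None, :]
    n = flat.shape[-1]
    padded = np.concatenate(
        [flat[:, pad:0:-1], flat, flat[:, -2:-pad - 2:-1]], axis=-1
    )
    nfft = next_fast_len(padded.shape[-1])
    H = rfft(taps, nfft)
    # |H|^2 is the response of forward-backward filtering and has zero phase
    spec = rfft(padded, nfft, axis=-1) * (H * np.conj(H)).real[None, :]
    out = irfft(spec, nfft, axis=-1)[:, pad:pad + n]
    return out.reshape(x.shape)


def power_grid(duration_s: float, grid_step_s: float = 1.0,
               t0: float = 0.0) -> np.ndarray:
    """The shared coarse time grid: centers of consecutive grid_step bins."""
    n = int(math.floor(duration_s / grid_step_s))
    return t0 + (np.arange(n) + 0.5) * grid_step_s


def eeg_band_power_multi(eeg: np.ndarray, fs: float,
                         band: BandDefinition | str,
                         grid_step_s: float = 1.0,
                         t0: float = 0.0):
    """Band envelope power of many channels at once.

    Returns (grid, power (n_channels, n_grid), valid).  The power at each
    grid point is the mean of the squared analytic envelope (halved, so a
    tone of amplitude A gives A^2/2) over that grid bin.
    """
    if isinstance(band, str):
        band = get_band(band)
    if not band.is_eeg:
        raise ValueError(f"{band.name} is not an EEG band")
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    n = eeg.shape[-1]
    min_len = 10.0 / band.lo_hz
    if n / fs < min_len:
        raise ValueError(
            f"signal shorter than {min_len:.0f} s required for {band.name}"
        )
    taps = fir_bandpass(band.lo_hz, band.hi_hz, fs)
    xb = apply_zero_phase(eeg, taps)
    env2 = np.abs(
        signal.hilbert(xb, N=_fast_len(n), axis=-1)[..., :n]
    ) ** 2
    grid = power_grid(n / fs, grid_step_s, t0=t0)
    win = max(int(round(grid_step_s * fs)), 1)
    usable = grid.size * win
    power = 0.5 * env2[:, :usable].reshape(eeg.shape[0], grid.size, win
                                           ).mean(axis=-1)
    margin_s = len(taps) / fs
    rel = grid - t0
    valid = (rel >= margin_s) & (rel <= n / fs - margin_s)
    return grid, power, valid


def eeg_band_power(channel_signal: np.ndarray, fs: float,
                   band: BandDefinition | str,
                   grid_step_s: float = 1.0,
                   t0: float = 0.0,
                   channel: str = "") -> BandPowerSeries:
    """Band-pass + analytic-envelope power of one EEG channel on the grid."""
    if isinstance(band, str):
        band = get_band(band)
    grid, power, valid = eeg_band_power_multi(
        np.asarray(channel_signal, dtype=float)[None, :], fs, band,
        grid_step_s=grid_step_s, t0=t0,
    )
    return BandPowerSeries(band=band, t_s=grid, power=power[0],
                           valid=valid, channel=channel)


def _fast_len(n: int) -> int:
    from scipy.fft import next_fast_len

    return next_fast_len(n)


def spwvd_band_power(x: np.ndarray, fs: float, bands,
                     grid_step_s: float = 1.0, t0: float = 0.0,
                     lag_halfwidth_s: float = 32.0,
                     time_smooth_s: float = 5.0,
                     nfft: int = 1024):
    """Smoothed pseudo-Wigner-Ville band powers of a real series.

    Returns one power vector per requested band, evaluated on the common
    grid.  The analytic signal removes negative-frequency cross-terms; the
    Hamming lag window (half-width ``lag_halfwidth_s``) smooths in
    frequency and an independent Hamming time window (``time_smooth_s``)
    smooths in time.  Normalized so an in-band tone of amplitude A
    integrates to A^2/2.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    z = signal.hilbert(x - x.mean(), N=_fast_len(n))[:n]
    half = min(int(round(lag_halfwidth_s * fs)), (n - 1) // 2)
    if half < 4:
        raise ValueError("series too short for the requested lag window")
    lag_win = np.hamming(2 * half + 1)
    tw = max(int(round(time_smooth_s * fs)) | 1, 1)
    time_win = np.hamming(tw)
    time_win /= time_win.sum()

    # instantaneous autocorrelation K[tau, t] = z[t+tau] conj(z[t-tau]),
    # time-smoothed along t, for tau = 0..half (hermitian in tau)
    taus = np.arange(half + 1)
    K = np.zeros((half + 1, n), dtype=complex)
    for i, tau in enumerate(taus):
        prod = np.zeros(n, dtype=complex)
        sl = slice(tau, n - tau)
        prod[sl] = z[2 * tau:] * np.conj(z[: n - 2 * tau])
        K[i] = np.convolve(prod, time_win, mode="same")

    grid = power_grid(n / fs, grid_step_s, t0=t0)
    cols = np.clip(((grid - t0) * fs).astype(int), 0, n - 1)
    Kc = K[:, cols] * lag_win[half:, None]

    nfft = max(nfft, 2 * half + 2)
    # build full hermitian lag axis then FFT -> real-valued distribution
    full = np.zeros((nfft, Kc.shape[1]), dtype=complex)
    full[: half + 1] = Kc
    full[-half:] = np.conj(Kc[1:][::-1])
    W = np.real(np.fft.fft(full, axis=0))
    # lag step of 1 sample = tau step 2/fs in signal time -> freq axis:
    freqs = np.fft.fftfreq(nfft, d=2.0 / fs)

    out = {}
    for b in bands:
        bdef = get_band(b) if isinstance(b, str) else b
        sel = (freqs >= bdef.lo_hz) & (freqs < bdef.hi_hz)
        # sum over all bins of W equals nfft * |z|^2 at the grid point;
        # analytic-signal power |z|^2 = A^2 for a tone of amplitude A
        out[bdef.name] = 0.5 * W[sel].sum(axis=0) / nfft
    margin_s = lag_halfwidth_s
    rel = grid - t0
    valid = (rel >= margin_s) & (rel <= n / fs - margin_s)
    return grid, out, valid


def hrv_band_power(rr4hz: np.ndarray, band: BandDefinition | str,
                   grid_step_s: float = 1.0, t0: float = 0.0,
                   fs: float = RR_FS, **spwvd_kw) -> BandPowerSeries:
    """Time-resolved LF or HF power (s^2) of the 4 Hz RR series."""
    if isinstance(band, str):
        band = get_band(band)
    if band.is_eeg:
        raise ValueError(f"{band.name} is not an HRV band")
    rr4hz = np.asarray(rr4hz, dtype=float)
    if rr4hz.size / fs < 2.0 / band.lo_hz:
        raise ValueError(
            f"series shorter than {2.0 / band.lo_hz:.0f} s required for "
            f"{band.name}"
        )
    grid, powers, valid = spwvd_band_power(
        rr4hz, fs, [band], grid_step_s=grid_step_s, t0=t0, **spwvd_kw
    )
    return BandPowerSeries(band=band, t_s=grid, power=powers[band.name],
                           valid=valid)


def welch_band_power(x: np.ndarray, fs: float, band: BandDefinition | str,
                     nperseg_s: float = 120.0) -> float:
    """Window-average band power via Welch - a cross-check for the SPWVD
    path (single number over the whole segment, same tone normalization)."""
    if isinstance(band, str):
        band = get_band(band)
    x = np.asarray(x, dtype=float)
    nper = min(int(nperseg_s * fs), x.size)
    f, pxx = signal.welch(x - x.mean(), fs=fs, nperseg=nper)
    sel = (f >= band.lo_hz) & (f < band.hi_hz)
    return float(np.trapezoid(pxx[sel], f[sel]))
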