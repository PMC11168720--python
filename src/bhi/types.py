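"""Core domain containers for the brain-heart interplay (BHI) pipeline.

The pipeline couples two physiological signal families:

* multichannel scalp EEG, summarized per classic frequency band
  (delta 1-4 Hz, theta 4-8 Hz, alpha 8-12 Hz, beta 12-30 Hz), and
* heartbeat (RR interval) dynamics, summarized in the heart-rate-variability
  low-frequency (LF, 0.04-0.15 Hz) and high-frequency (HF, 0.15-0.4 Hz) bands.

Everything downstream of raw signals lives on a common coarse time grid so
that band-power series from both sides can be regressed against each other.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

EEG_BAND_NAMES = ("delta", "theta", "alpha", "beta")
HRV_BAND_NAMES = ("LF", "HF")

#: 29-channel scalp montage used throughout (10-20 extended labels).
STANDARD_CHANNELS = (
    "Fp1", "F3", "C3", "P3", "O1", "F7", "T3", "T5", "Fc1", "Fc5",
    "Cp1", "Cp5", "F9", "Fz", "Cz", "Pz", "Fp2", "F4", "C4", "P4",
    "O2", "F8", "T4", "T6", "Fc2", "Fc6", "Cp2", "Cp6", "F10",
)

#: Channels absent in reduced 19-channel montages.
REDUCED_MONTAGE_MISSING = (
    "Fc1", "Fc5", "Cp1", "Cp5", "F9", "Fc2", "Fc6", "Cp2", "Cp6", "F10",
)

# Approximate 2-D scalp projection (x: left-right, y: posterior-anterior),
# unit head radius.  Only relative geometry matters (adjacency, topomaps).
MONTAGE_2D = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F9": (-0.98, 0.47), "F7": (-0.81, 0.59), "F3": (-0.43, 0.55),
    "Fz": (0.0, 0.52), "F4": (0.43, 0.55), "F8": (0.81, 0.59),
    "F10": (0.98, 0.47),
    "Fc5": (-0.66, 0.30), "Fc1": (-0.22, 0.27),
    "Fc2": (0.22, 0.27), "Fc6": (0.66, 0.30),
    "T3": (-1.0, 0.0), "C3": (-0.45, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.45, 0.0), "T4": (1.0, 0.0),
    "Cp5": (-0.66, -0.30), "Cp1": (-0.22, -0.27),
    "Cp2": (0.22, -0.27), "Cp6": (0.66, -0.30),
    "T5": (-0.81, -0.59), "P3": (-0.43, -0.55), "Pz": (0.0, -0.52),
    "P4": (0.43, -0.55), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}


def montage_xy(channel_labels) -> np.ndarray:
    """Return the 2-D montage coordinates for a list of channel labels."""
    return np.array([MONTAGE_2D[ch] for ch in channel_labels], dtype=float)


@dataclass
class BandDefinition:
    """A named frequency band with its central angular frequency (rad/s)."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise ValueError(f"band {self.name}: lo_hz must be < hi_hz")

    @property
    def omega_center(self) -> float:
        return 2.0 * math.pi * 0.5 * (self.lo_hz + self.hi_hz)

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.lo_hz + self.hi_hz)

    @property
    def is_eeg(self) -> bool:
        return self.name in EEG_BAND_NAMES


EEG_BANDS = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 12.0, 30.0),
}

HRV_BANDS = {
    "LF": BandDefinition("LF", 0.04, 0.15),
    "HF": BandDefinition("HF", 0.15, 0.40),
}

ALL_BANDS = {**EEG_BANDS, **HRV_BANDS}


def get_band(name: str) -> BandDefinition:
    try:
        return ALL_BANDS[name]
    except KeyError:
        raise KeyError(f"unknown band {name!r}; known: {sorted(ALL_BANDS)}") from None


@dataclass
class PhysioRecording:
    """Synchronized multichannel EEG (uV) + single-lead ECG (mV)."""

    eeg: np.ndarray            # (n_channels, n_samples), microvolts
    ecg: np.ndarray            # (n_samples,), millivolts
    fs: float                  # Hz
    channel_labels: list
    montage_xy: np.ndarray     # (n_channels, 2)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.eeg = np.atleast_2d(np.asarray(self.eeg, dtype=float))
        self.ecg = np.asarray(self.ecg, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.eeg.shape[1] != self.ecg.shape[0]:
            raise ValueError("eeg and ecg must share the sample count")
        if len(self.channel_labels) != self.eeg.shape[0]:
            raise ValueError("channel_labels length must equal eeg row count")

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SeizureAnnotation:
    """One seizure event: clinical onset/offset, seconds from record start."""

    onset_s: float
    offset_s: float
    event_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.onset_s < self.offset_s:
            raise ValueError("require 0 <= onset_s < offset_s")


@dataclass
class RRSeries:
    """Beat times and RR intervals, optionally with the 4 Hz resampling."""

    beat_times_s: np.ndarray    # strictly increasing, seconds
    rr_s: np.ndarray            # successive differences, seconds
    rr4hz: np.ndarray | None = None
    t4hz: np.ndarray | None = None
    n_corrected: int = 0
    quality_warning: bool = False

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.rr_s = np.asarray(self.rr_s, dtype=float)
        if self.beat_times_s.size and np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat_times_s must be strictly increasing")
        if self.rr_s.size and np.any(self.rr_s <= 0):
            raise ValueError("rr intervals must be positive")
        if self.rr_s.size != max(self.beat_times_s.size - 1, 0):
            raise ValueError("rr_s must have len(beat_times_s) - 1 entries")

    @classmethod
    def from_beats(cls, beat_times_s, **kw) -> "RRSeries":
        beat_times_s = np.asarray(beat_times_s, dtype=float)
        return cls(beat_times_s, np.diff(beat_times_s), **kw)


@dataclass
class AnalysisWindowPair:
    """The pre/post-seizure analysis spans for one event."""

    preictal: tuple          # (start_s, end_s)
    postictal: tuple         # (start_s, end_s)
    window_len_s: float
    event_id: str = ""


@dataclass
class BandPowerSeries:
    """Time-resolved power of one signal in one band on a uniform grid.

    ``power`` is in uV^2 for EEG bands and s^2 for HRV bands.  ``amplitude``
    follows the sinusoidal convention amplitude = sqrt(2 * power), so a pure
    tone of amplitude A has band power A^2 / 2 and recovered amplitude A.
    """

    band: BandDefinition
    t_s: np.ndarray
    power: np.ndarray
    valid: np.ndarray | None = None
    channel: str = ""

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.t_s.shape != self.power.shape:
            raise ValueError("t_s and power must have the same shape")
        if self.valid is None:
            self.valid = np.ones(self.t_s.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        # tiny negative values from smoothing are clipped, not propagated
        self.power = np.clip(self.power, 0.0, None)

    @property
    def amplitude(self) -> np.ndarray:
        return np.sqrt(2.0 * self.power)


@dataclass
class BHISeries:
    """Time-resolved directional coupling coefficient for one band pair.

    ``direction`` is "BtH" (EEG band power drives an HRV modulation
    amplitude) or "HtB" (HRV band power drives an EEG band amplitude).
    ``extra`` carries the companion coefficient of the fit: the intercept
    C_i0 for BtH, the autoregressive gain eta for HtB.
    """

    direction: str
    eeg_band: str
    hrv_band: str
    channel: str
    t_s: np.ndarray
    coeff: np.ndarray
    extra: np.ndarray | None = None
    resid_var: np.ndarray | None = None
    degenerate: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("BtH", "HtB"):
            raise ValueError("direction must be 'BtH' or 'HtB'")
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.coeff = np.asarray(self.coeff, dtype=float)
        if self.degenerate is None:
            self.degenerate = ~np.isfinite(self.coeff)

    @property
    def label(self) -> str:
        if self.direction == "BtH":
            return f"{self.eeg_band}->{self.hrv_band}"
        return f"{self.hrv_band}->{self.eeg_band}"


@dataclass
class StatMap:
    """Per-channel paired-test results with cluster-corrected significance."""

    channels: list
    p: np.ndarray
    effect_sign: np.ndarray        # +1: preictal > postictal, -1: opposite
    raw_significant: np.ndarray
    alpha: float
    cluster_id: np.ndarray | None = None
    corrected_significant: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.channels)
        for name in ("p", "effect_sign", "raw_significant"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must match channels")
        if self.corrected_significant is not None:
            bad = np.asarray(self.corrected_significant) & ~np.asarray(
                self.raw_significant
            )
            if bad.any():
                raise ValueError("corrected significance implies raw significance")


def asdict_shallow(obj) -> dict:
    """One-level dataclass -> dict (no recursion into ndarray fields)."""
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
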