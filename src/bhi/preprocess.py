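"""Recording ingestion and conditioning.

Covers everything between raw files and band-power estimation: EDF reading
with channel harmonization, zero-phase 1-32 Hz EEG band-pass, R-peak
detection (Pan-Tompkins-style energy detector), RR artifact correction in
the spirit of Kubios's "medium" rule, cubic 4 Hz RR resampling, and the
extraction of equal-length analysis windows before seizure onset and after
seizure offset.
"""

from __future__ import annotations

import logging
import re
import warnings

import numpy as np
from scipy import interpolate, signal

from .band_power import apply_zero_phase, fir_bandpass
from .types import (
    AnalysisWindowPair,
    PhysioRecording,
    REDUCED_MONTAGE_MISSING,
    RRSeries,
    SeizureAnnotation,
    STANDARD_CHANNELS,
    montage_xy,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 600.0
RR_GRID_STEP_S = 0.25          # 4 Hz resampling
ARTIFACT_THRESHOLD_S = 0.25    # "medium" local-median deviation rule
ARTIFACT_MEDIAN_WINDOW = 11    # beats


# ---------------------------------------------------------------------------
# File reading
# ---------------------------------------------------------------------------

def _normalize_label(raw: str) -> str:
    """Map an EDF channel label onto the montage vocabulary."""
    s = re.sub(r"^(EEG|ECG|EKG)\s*", "", raw.strip(), flags=re.I)
    s = s.split("-")[0].strip()          # drop reference suffix (e.g. Fp1-Ref)
    for ch in STANDARD_CHANNELS:
        if s.lower() == ch.lower():
            return ch
    return s


def _parse_time_s(token: str) -> float:
    token = token.strip()
    if ":" in token:
        parts = [float(p) for p in token.split(":")]
        while len(parts) < 3:
            parts.insert(0, 0.0)
        h, m, s = parts
        return h * 3600.0 + m * 60.0 + s
    return float(token)


def read_annotations(path) -> list:
    """Parse the plain-text annotation dialect: one seizure per line,
    ``event_id  onset  offset`` (seconds or HH:MM:SS), '#' comments."""
    out = []
    with open(path) as f:
        for i, line in enumerate(f):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) == 2:
                ev, (on, off) = f"seizure_{i}", toks
            else:
                ev, on, off = toks[0], toks[1], toks[2]
            out.append(
                SeizureAnnotation(_parse_time_s(on), _parse_time_s(off), ev)
            )
    return out


def read_recording(path, annotation_path=None, subject_id=""):
    """Read an EDF file into a PhysioRecording (+ seizure annotations).

    EEG channels are matched (case-insensitively, reference suffixes
    stripped) against the 29-label montage; labels from that set that are
    absent in the file are logged, not fabricated.  Exactly one ECG
    derivation is required.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - mne raises various types
        raise ValueError(f"unreadable EDF file {path}: {exc}") from exc

    fs = float(raw.info["sfreq"])
    data = raw.get_data()  # volts

    eeg_rows, eeg_labels, ecg_row = [], [], None
    for i, name in enumerate(raw.ch_names):
        if re.search(r"\b(ECG|EKG)", name, flags=re.I):
            if ecg_row is None:
                ecg_row = i
            continue
        lab = _normalize_label(name)
        if lab in STANDARD_CHANNELS:
            eeg_rows.append(i)
            eeg_labels.append(lab)
    if ecg_row is None:
        raise ValueError(f"{path}: no ECG derivation found")
    if not eeg_rows:
        raise ValueError(f"{path}: no recognizable EEG channels")

    missing = [ch for ch in STANDARD_CHANNELS if ch not in eeg_labels]
    if missing:
        logger.warning(
            "%s: %d montage channels absent: %s",
            path, len(missing), ", ".join(missing),
        )

    order = sorted(range(len(eeg_labels)),
                   key=lambda k: STANDARD_CHANNELS.index(eeg_labels[k]))
    eeg_labels = [eeg_labels[k] for k in order]
    eeg = data[[eeg_rows[k] for k in order]] * 1e6   # V -> uV
    ecg = data[ecg_row] * 1e3                        # V -> mV

    rec = PhysioRecording(
        eeg=eeg, ecg=ecg, fs=fs, channel_labels=eeg_labels,
        montage_xy=montage_xy(eeg_labels), subject_id=subject_id,
    )
    anns = read_annotations(annotation_path) if annotation_path else []
    return rec, anns


# ---------------------------------------------------------------------------
# EEG conditioning
# ---------------------------------------------------------------------------

def bandpass_eeg(rec: PhysioRecording, low_hz: float = 1.0,
                 high_hz: float = 32.0) -> PhysioRecording:
    """Zero-phase FIR band-pass of every EEG channel (ECG untouched)."""
    if rec.fs <= 2.0 * high_hz:
        raise ValueError(
            f"fs={rec.fs} Hz too low for a {high_hz} Hz upper cutoff"
        )
    taps = fir_bandpass(low_hz, high_hz, rec.fs)
    filtered = apply_zero_phase(rec.eeg, taps)
    return PhysioRecording(
        eeg=filtered, ecg=rec.ecg, fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        montage_xy=rec.montage_xy, subject_id=rec.subject_id,
    )


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_rpeaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins-style R-peak detection.

    Band-pass (5-15 Hz) -> differentiate -> square -> 150 ms moving-window
    integration -> peak picking with a refractory period at the 220 bpm
    physiological ceiling and an amplitude threshold adaptive to the
    detected peak population.  Returns beat times in seconds.
    """
    ecg = np.asarray(ecg, dtype=float).ravel()
    if ecg.size < 10 * fs:
        raise ValueError("need at least 10 s of ECG")
    sos = signal.butter(2, [5.0, min(15.0, 0.45 * fs)], btype="bandpass",
                        fs=fs, output="sos")
    xf = signal.sosfiltfilt(sos, ecg)
    energy = np.gradient(xf) ** 2
    win = max(int(round(0.150 * fs)), 1)
    integ = np.convolve(energy, np.ones(win) / win, mode="same")

    refractory = int(round(60.0 / 220.0 * fs))
    cand, _ = signal.find_peaks(integ, distance=refractory)
    if cand.size == 0:
        warnings.warn("no QRS-like activity detected", stacklevel=2)
        return np.empty(0)
    heights = integ[cand]
    # adaptive floor: a fraction of the typical QRS peak, but safely above
    # the baseline energy level
    thr = max(0.15 * np.median(heights[heights > np.median(heights)])
              if (heights > np.median(heights)).any()
              else 0.15 * heights.max(),
              3.0 * np.median(integ))
    keep = cand[heights >= thr]
    if keep.size < 2 or keep.size < ecg.size / fs / 3.0:  # < 20 bpm overall
        warnings.warn("no reliable QRS train detected", stacklevel=2)
        return np.empty(0)

    # refine to the R-wave extremum near each energy peak; the QRS polarity
    # is decided once per record so biphasic complexes don't flip between
    # their positive and negative lobes beat to beat
    half = int(round(0.10 * fs))
    probe = np.array([xf[max(c - half, 0): c + half + 1] for c in keep
                      if half <= c < ecg.size - half - 1], dtype=object)
    pol_votes = [np.max(seg) + np.min(seg) for seg in probe]
    polarity = 1.0 if np.median(pol_votes) >= 0 else -1.0
    peaks = []
    for c in keep:
        lo, hi = max(c - half, 0), min(c + half + 1, ecg.size)
        peaks.append(lo + int(np.argmax(polarity * xf[lo:hi])))
    peaks = np.unique(peaks)
    # enforce the refractory again after refinement
    out = [peaks[0]]
    for p in peaks[1:]:
        if p - out[-1] >= refractory:
            out.append(p)
        elif np.abs(xf[p]) > np.abs(xf[out[-1]]):
            out[-1] = p
    return np.asarray(out, dtype=float) / fs


# ---------------------------------------------------------------------------
# RR conditioning
# ---------------------------------------------------------------------------

def correct_rr_artifacts(rr: RRSeries,
                         threshold_s: float = ARTIFACT_THRESHOLD_S,
                         median_window: int = ARTIFACT_MEDIAN_WINDOW,
                         ) -> RRSeries:
    """Replace RR outliers by local cubic interpolation.

    An interval is an artifact when it deviates from the local
    ``median_window``-beat median by more than ``threshold_s`` (the
    "medium" setting).  Beat times are rebuilt from the corrected
    intervals, so the sample count never changes.  If more than 20% of
    intervals needed correction the output carries a quality warning.
    """
    rr_v = rr.rr_s
    n = rr_v.size
    if n < 10:
        raise ValueError("need >= 10 RR intervals")
    med = signal.medfilt(rr_v, kernel_size=min(median_window | 1, n | 1))
    bad = np.abs(rr_v - med) > threshold_s
    corrected = rr_v.copy()
    if bad.any():
        good = ~bad
        idx = np.arange(n)
        if good.sum() >= 4:
            f = interpolate.interp1d(idx[good], rr_v[good], kind="cubic",
                                     fill_value="extrapolate")
        else:
            f = interpolate.interp1d(idx[good], rr_v[good], kind="linear",
                                     fill_value="extrapolate")
        corrected[bad] = f(idx[bad])
        corrected = np.clip(corrected, 0.2, 3.0)
    frac = bad.mean()
    if frac > 0.2:
        logger.warning("%.0f%% of RR intervals corrected", 100 * frac)
    beats = rr.beat_times_s[0] + np.concatenate([[0.0], np.cumsum(corrected)])
    return RRSeries(
        beat_times_s=beats, rr_s=corrected,
        n_corrected=int(bad.sum()), quality_warning=bool(frac > 0.2),
    )


def interpolate_rr(rr: RRSeries, grid_step_s: float = RR_GRID_STEP_S,
                   ) -> RRSeries:
    """Cubic interpolation of (beat time, RR) onto the uniform 4 Hz grid.

    The RR value at a beat is the interval ending at that beat; the grid
    spans the support of those points.
    """
    if rr.beat_times_s.size < 4:
        raise ValueError("need >= 4 beats for cubic interpolation")
    t_beats = rr.beat_times_s[1:]
    k0 = int(np.ceil(t_beats[0] / grid_step_s))
    k1 = int(np.floor(t_beats[-1] / grid_step_s))
    t4 = np.arange(k0, k1 + 1) * grid_step_s
    f = interpolate.interp1d(t_beats, rr.rr_s, kind="cubic")
    return RRSeries(
        beat_times_s=rr.beat_times_s, rr_s=rr.rr_s,
        rr4hz=f(t4), t4hz=t4,
        n_corrected=rr.n_corrected, quality_warning=rr.quality_warning,
    )


def ecg_to_rr(ecg: np.ndarray, fs: float, **correct_kw) -> RRSeries:
    """Full ECG -> corrected, 4 Hz-resampled RR series."""
    beats = detect_rpeaks(ecg, fs)
    if beats.size < 11:
        raise ValueError("too few beats detected for RR analysis")
    rr = RRSeries.from_beats(beats)
    rr = correct_rr_artifacts(rr, **correct_kw)
    return interpolate_rr(rr)


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

class EventExcluded(Exception):
    """Raised when an event lacks the data needed for both windows."""


def extract_windows(rec: PhysioRecording, ann: SeizureAnnotation,
                    window_len_s: float = DEFAULT_WINDOW_S,
                    ) -> AnalysisWindowPair:
    """The pre-onset / post-offset window pair for one seizure.

    preictal = [onset - L, onset), postictal = (offset, offset + L].
    Events without L seconds of data on either side are excluded (with the
    reason), mirroring the handling of subjects with too little
    peri-seizure data.
    """
    L = float(window_len_s)
    if ann.onset_s < L:
        raise EventExcluded(
            f"event {ann.event_id or '?'}: only {ann.onset_s:.0f} s before "
            f"onset, {L:.0f} s required"
        )
    if rec.duration_s - ann.offset_s < L:
        raise EventExcluded(
            f"event {ann.event_id or '?'}: only "
            f"{rec.duration_s - ann.offset_s:.0f} s after offset, "
            f"{L:.0f} s required"
        )
    return AnalysisWindowPair(
        preictal=(ann.onset_s - L, ann.onset_s),
        postictal=(ann.offset_s, ann.offset_s + L),
        window_len_s=L,
        event_id=ann.event_id,
    )


def slice_window(rec: PhysioRecording, span) -> dict:
    """Cut one analysis span out of a recording (EEG rows + ECG)."""
    i0 = int(round(span[0] * rec.fs))
    i1 = int(round(span[1] * rec.fs))
    return {
        "eeg": rec.eeg[:, i0:i1],
        "ecg": rec.ecg[i0:i1],
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "t0": 0.0,
        "span": (float(span[0]), float(span[1])),
    }


def prepare_window(rec: PhysioRecording, span, bandpassed: bool = True,
                   **rr_kw) -> dict:
    """Slice a span and attach the RR pipeline output for that span."""
    w = slice_window(rec, span)
    rr = ecg_to_rr(w["ecg"], rec.fs, **rr_kw)
    w["rr"] = rr
    w["rr4hz"] = rr.rr4hz
    w["t_rr4hz"] = rr.t4hz
    return w
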