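"""End-to-end study orchestration: events -> coupling tables -> group maps.

``analyze_event`` takes one recording + one seizure annotation through
preprocessing, band power and coupling estimation, and reduces the
coefficient series to per-phase medians and per-minute medians.
``run_study`` does that for a cohort, runs the group statistics per
direction/band pair, and writes a results tree (tables as CSV, run
manifest as JSON, optional topomaps as PNG).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import group_stats, preprocess, sdg_core
from .types import EEG_BAND_NAMES, HRV_BAND_NAMES, montage_xy

logger = logging.getLogger(__name__)

ALLOWED_WINDOW_MIN = (10, 7, 5, 3, 2, 1)

#: the 16 direction/band-pair combinations of the coupling grid
BAND_PAIRS = tuple(
    [("BtH", e, h) for h in HRV_BAND_NAMES for e in EEG_BAND_NAMES]
    + [("HtB", e, h) for h in HRV_BAND_NAMES for e in EEG_BAND_NAMES]
)


@dataclass
class RunConfig:
    window_min: int = 10
    alpha: float = 0.01
    min_cluster: int = 2
    n_perm: int = 1000
    seed: int = 7
    cluster_alpha: float = 0.05
    grid_step_s: float = 1.0
    est_window_s: float = 120.0
    est_step_s: float = 1.0
    mode: str = "preictal_vs_postictal"
    render_maps: bool = False
    #: band subsets (full grid by default); a focused study may restrict
    eeg_bands: tuple = EEG_BAND_NAMES
    hrv_bands: tuple = HRV_BAND_NAMES

    def __post_init__(self) -> None:
        if self.window_min not in ALLOWED_WINDOW_MIN:
            raise ValueError(f"window_min must be one of {ALLOWED_WINDOW_MIN}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        known = ("preictal_vs_postictal", "surrogate_interictal",
                 "interictal_vs_preictal", "interictal_vs_postictal")
        if self.mode not in known:
            raise ValueError(f"mode must be one of {known}")

    @property
    def window_len_s(self) -> float:
        return self.window_min * 60.0


@dataclass
class EventSummary:
    """Per-event reduction of all coupling series."""

    event_id: str
    channels: list
    #: (direction, eeg_band, hrv_band) -> {"preictal": (n_ch,), ...}
    phase_medians: dict
    #: (direction, eeg_band, hrv_band) -> (n_ch, 2*n_minutes), pre then post
    minute_medians: dict
    n_minutes: int


def _reduce_series(series_list, channels, window_len_s) -> tuple:
    n_min = int(window_len_s // 60)
    phase_med = {}
    minute_med = {}
    by_key = {}
    for s in series_list:
        by_key.setdefault((s.direction, s.eeg_band, s.hrv_band), {})[
            s.channel
        ] = s
    for key, per_ch in by_key.items():
        med = np.full(len(channels), np.nan)
        mmed = np.full((len(channels), n_min), np.nan)
        for ci, ch in enumerate(channels):
            s = per_ch[ch]
            ok = np.isfinite(s.coeff) & ~np.asarray(s.degenerate, dtype=bool)
            if ok.any():
                med[ci] = np.median(s.coeff[ok])
            mins = (s.t_s // 60.0).astype(int)
            for mi in range(n_min):
                sel = ok & (mins == mi)
                if sel.any():
                    mmed[ci, mi] = np.median(s.coeff[sel])
        phase_med[key] = med
        minute_med[key] = mmed
    return phase_med, minute_med


def analyze_event(rec, ann, config: RunConfig | None = None) -> EventSummary:
    """One seizure event through the full estimation chain."""
    cfg = config or RunConfig()
    wp = preprocess.extract_windows(rec, ann, cfg.window_len_s)
    rec_f = preprocess.bandpass_eeg(rec)
    return _analyze_window_pair(rec_f, wp.preictal, wp.postictal,
                                ann.event_id, cfg)


def analyze_surrogate_event(rec, first_onset_s: float,
                            config: RunConfig | None = None,
                            lead_s: float = 3600.0) -> EventSummary:
    """Two interictal windows around a surrogate (fictitious) event."""
    cfg = config or RunConfig(window_min=5)
    spans = group_stats.surrogate_window_pair(
        first_onset_s, window_len_s=cfg.window_len_s, lead_s=lead_s,
    )
    rec_f = preprocess.bandpass_eeg(rec)
    return _analyze_window_pair(rec_f, spans[0], spans[1],
                                "surrogate", cfg)


def _analyze_window_pair(rec_f, span_pre, span_post, event_id,
                         cfg: RunConfig) -> EventSummary:
    summaries = {}
    minutes = {}
    # short analysis windows cannot host the full estimation window; cap it
    # at a third of the span (>= 10 grid steps enforced downstream)
    eff_window_s = min(cfg.est_window_s, cfg.window_len_s / 3.0)
    for phase, span in (("preictal", span_pre), ("postictal", span_post)):
        w = preprocess.prepare_window(rec_f, span)
        rr4 = _rr_on_window_grid(w, cfg.window_len_s)
        series = sdg_core.compute_bhi_window(
            w["eeg"], w["fs"], rr4, w["channel_labels"],
            grid_step_s=cfg.grid_step_s, window_s=eff_window_s,
            step_s=cfg.est_step_s,
            eeg_bands=cfg.eeg_bands, hrv_bands=cfg.hrv_bands,
        )
        pm, mm = _reduce_series(series, w["channel_labels"],
                                cfg.window_len_s)
        summaries[phase] = pm
        minutes[phase] = mm
    channels = list(rec_f.channel_labels)
    phase_medians = {
        key: {ph: summaries[ph][key] for ph in ("preictal", "postictal")}
        for key in summaries["preictal"]
    }
    minute_medians = {
        key: np.concatenate(
            [minutes["preictal"][key], minutes["postictal"][key]], axis=1
        )
        for key in minutes["preictal"]
    }
    return EventSummary(
        event_id=event_id, channels=channels,
        phase_medians=phase_medians, minute_medians=minute_medians,
        n_minutes=int(cfg.window_len_s // 60),
    )


def _rr_on_window_grid(w, window_len_s) -> np.ndarray:
    """RR values on the full-window 4 Hz grid (edge-held outside the beat
    support; the spectral estimator's edge mask covers the shortfall)."""
    t4 = np.arange(int(window_len_s * 4)) * 0.25
    tt = np.clip(t4, w["t_rr4hz"][0], w["t_rr4hz"][-1])
    return np.interp(tt, w["t_rr4hz"], w["rr4hz"])


# ---------------------------------------------------------------------------
# Cohort-level study
# ---------------------------------------------------------------------------

def collect_phase_matrices(summaries, key) -> tuple:
    """Stack per-event phase medians into (events x channels) matrices,
    restricted to channels present in every event."""
    common = set(summaries[0].channels)
    for s in summaries[1:]:
        common &= set(s.channels)
    channels = [c for c in summaries[0].channels if c in common]
    pre = np.stack([
        s.phase_medians[key]["preictal"][[s.channels.index(c)
                                          for c in channels]]
        for s in summaries
    ])
    post = np.stack([
        s.phase_medians[key]["postictal"][[s.channels.index(c)
                                           for c in channels]]
        for s in summaries
    ])
    return pre, post, channels


def group_maps(summaries, config: RunConfig) -> dict:
    """Cluster-corrected stat map per direction/band pair."""
    maps = {}
    for key in BAND_PAIRS:
        if key[1] not in config.eeg_bands or key[2] not in config.hrv_bands:
            continue
        pre, post, channels = collect_phase_matrices(summaries, key)
        ok = np.isfinite(pre).all(axis=0) & np.isfinite(post).all(axis=0)
        if not ok.all():
            pre, post = pre[:, ok], post[:, ok]
            channels = [c for c, k in zip(channels, ok) if k]
        if len(channels) < 3 or pre.shape[0] < 6:
            continue
        xy = montage_xy(channels)
        adj = group_stats.delaunay_adjacency(xy)
        raw = group_stats.wilcoxon_paired_map(pre, post, channels,
                                              alpha=config.alpha)
        maps[key] = group_stats.cluster_permutation_correct(
            raw, pre - post, adj, min_cluster=config.min_cluster,
            n_perm=config.n_perm, seed=config.seed,
            cluster_alpha=config.cluster_alpha,
        )
    return maps


def group_trends(summaries, key) -> dict:
    """Channel-averaged z-scored minute trend for one band pair."""
    import warnings as _w

    mats = []
    for s in summaries:
        m = s.minute_medians[key]
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            mats.append(np.nanmean(m, axis=0))   # average over channels
    mats = np.stack(mats)
    return group_stats.trend_zscore(mats)


def run_study(config: RunConfig, events, out_dir) -> dict:
    """Full study: per-event estimation, group maps, trends, artifacts.

    ``events`` is a list of (PhysioRecording, SeizureAnnotation) pairs (a
    SimOutput from the simulator works too).  Events without enough data
    around the seizure are excluded and logged, not fatal.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries, exclusions = [], []
    for k, ev in enumerate(events):
        rec, ann = _as_event(ev)
        try:
            if config.mode == "surrogate_interictal":
                s = analyze_surrogate_event(rec, ann.onset_s, config)
            else:
                s = analyze_event(rec, ann, config)
            s = dataclasses.replace(s, event_id=s.event_id or f"ev{k:02d}")
            summaries.append(s)
        except preprocess.EventExcluded as exc:
            exclusions.append({"event": k, "reason": str(exc)})
            logger.warning("event %d excluded: %s", k, exc)
    if len(summaries) < 6:
        raise ValueError(
            f"only {len(summaries)} usable events ({len(exclusions)} excluded)"
        )

    maps = group_maps(summaries, config)
    rows = []
    for (direction, eb, hb), m in maps.items():
        for ci, ch in enumerate(m.channels):
            rows.append({
                "direction": direction, "eeg_band": eb, "hrv_band": hb,
                "channel": ch, "p": m.p[ci],
                "effect_sign": int(m.effect_sign[ci]),
                "raw_significant": bool(m.raw_significant[ci]),
                "cluster_id": int(m.cluster_id[ci]),
                "corrected_significant": bool(m.corrected_significant[ci]),
            })
    stat_df = pd.DataFrame(rows)
    stat_df.to_csv(out / "stat_maps.csv", index=False)

    trend_rows = []
    for key in maps:
        tr = group_trends(summaries, key)
        for mi, v in enumerate(tr["trend"]):
            trend_rows.append({
                "direction": key[0], "eeg_band": key[1], "hrv_band": key[2],
                "minute": mi, "z": v, "sem": tr["sem"][mi],
            })
    trend_df = pd.DataFrame(trend_rows)
    trend_df.to_csv(out / "trends.csv", index=False)

    _write_coeff_table(summaries, out / "phase_medians.csv")

    manifest = {
        "config": dataclasses.asdict(config),
        "n_events_in": len(events),
        "n_events_used": len(summaries),
        "exclusions": exclusions,
        "band_pairs": [list(k) for k in BAND_PAIRS],
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)

    if config.render_maps:
        _render_all_maps(maps, out)

    return {"maps": maps, "summaries": summaries,
            "stat_table": stat_df, "trend_table": trend_df,
            "manifest": manifest}


def _as_event(ev):
    if hasattr(ev, "recording"):            # SimOutput
        return ev.recording, ev.annotations[0]
    rec, ann = ev
    return rec, ann


def _write_coeff_table(summaries, path) -> None:
    rows = []
    for s in summaries:
        for (direction, eb, hb), phases in s.phase_medians.items():
            for phase, vals in phases.items():
                for ci, ch in enumerate(s.channels):
                    rows.append({
                        "event_id": s.event_id, "phase": phase,
                        "direction": direction, "eeg_band": eb,
                        "hrv_band": hb, "channel": ch,
                        "median_coeff": vals[ci],
                    })
    pd.DataFrame(rows).to_csv(path, index=False)


def _render_all_maps(maps, out: pathlib.Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    for (direction, eb, hb), m in maps.items():
        xy = montage_xy(m.channels)
        fig, ax = plt.subplots(figsize=(3, 3))
        group_stats.render_topomap(
            1.0 - m.p, xy, ax=ax,
            significant=m.corrected_significant, sign=m.effect_sign,
            title=f"{direction} {eb}/{hb}",
        )
        name = f"{direction}_{eb}_{hb}.png".replace("->", "-")
        fig.savefig(fig_dir / name, dpi=100)
        plt.close(fig)
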