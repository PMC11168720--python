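"""Self-contained verification runs of the package's headline properties.

Each function recomputes one property from scratch - simulating inputs,
running the estimators or the full pipeline, and measuring the result -
and returns a dict of scalar metrics.  ``run_all`` executes every check
and collects the metrics under short descriptive names (this backs
``scripts/acceptance.py`` and the acceptance test suite).

Problem sizes are chosen for a single-CPU desk run: series-level oracles
use 600-point grids and 100 seeds; the end-to-end planted-effect study
uses 16-event cohorts at 10-min windows over 20 seeded repetitions with
the analysis restricted to the planted band pair.
"""

from __future__ import annotations

import itertools

import numpy as np

from . import band_power, group_stats, pipeline, sdg_core, synthetic_data
from .sdg_core import IPFMParams
from .types import BandPowerSeries, get_band


def _series(name, t, arr, amplitude=False, channel="Cz"):
    power = arr**2 / 2.0 if amplitude else arr
    return BandPowerSeries(band=get_band(name), t_s=t, power=power,
                           channel=channel)


# ---------------------------------------------------------------------------
# 1. forward-inverse consistency
# ---------------------------------------------------------------------------

def forward_inverse_consistency(seed: int = 0, n_seeds: int = 100) -> dict:
    """Noiseless round trip of both estimators (exactness) and noisy
    recovery (20 dB additive noise on the response) over ``n_seeds``."""
    t, y, drv, _ = synthetic_data.simulate_coupled_series(
        "BtH", 600, coeff=0.3, intercept=2.0, seed=seed
    )
    r = sdg_core.estimate_bth(_series("LF", t, y, amplitude=True),
                              _series("theta", t, drv))
    ok = ~r.degenerate
    bth_err = float(np.nanmax(np.abs(r.coeff[ok] - 0.3) / 0.3))

    t, y, drv, _ = synthetic_data.simulate_coupled_series(
        "HtB", 600, coeff=0.5, eta=0.8, seed=seed + 1
    )
    r = sdg_core.estimate_htb(_series("delta", t, y, amplitude=True),
                              _series("LF", t, drv))
    ok = ~r.degenerate
    htb_err = float(np.nanmax(np.abs(r.coeff[ok] - 0.5) / 0.5))

    # 20 dB: noise std = signal amplitude / 10 (steady-state response)
    true_k, eta = 0.5, 0.8
    steady = true_k * 1.0 / (1.0 - eta)
    errs = []
    for s in range(n_seeds):
        t, y, drv, _ = synthetic_data.simulate_coupled_series(
            "HtB", 600, coeff=true_k, eta=eta,
            noise_std=steady / 10.0, seed=seed * n_seeds + s,
        )
        r = sdg_core.estimate_htb(_series("delta", t, y, amplitude=True),
                                  _series("LF", t, drv), window_s=120.0)
        errs.append(np.nanmedian(np.abs(r.coeff - true_k)) / true_k)
    return {
        "bth_noiseless_max_rel_err": bth_err,
        "htb_noiseless_max_rel_err": htb_err,
        "htb_20db_median_abs_err_pct": float(100.0 * np.median(errs)),
    }


# ---------------------------------------------------------------------------
# 2. IPFM closed forms
# ---------------------------------------------------------------------------

def ipfm_closed_forms(seed: int = 0) -> dict:
    out = {}
    for bpm, name in ((60.0, "rr_s_at_60bpm"), (75.0, "rr_s_at_75bpm")):
        beats = sdg_core.ipfm_generate(
            lambda t: np.zeros_like(t), IPFMParams(hr_ref_bpm=bpm), 60.0
        )
        out[name] = float(np.mean(np.diff(beats)))
    beats = sdg_core.ipfm_generate(
        lambda t: 0.05 * np.sin(2 * np.pi * 0.25 * t),
        IPFMParams(hr_ref_bpm=60.0), 300.0,
    )
    from .preprocess import RRSeries, interpolate_rr

    rrs = interpolate_rr(RRSeries.from_beats(beats))
    hf = band_power.hrv_band_power(rrs.rr4hz, "HF")
    lf = band_power.hrv_band_power(rrs.rr4hz, "LF")
    hf_med = float(np.median(hf.power[hf.valid]))
    lf_med = float(np.median(lf.power[lf.valid]))
    out["hf_tone_hf_to_lf_power_ratio"] = hf_med / max(lf_med, 1e-30)
    return out


# ---------------------------------------------------------------------------
# 3. Wilcoxon exactness
# ---------------------------------------------------------------------------

def wilcoxon_enumeration_oracle(d: np.ndarray) -> float:
    """Brute-force two-sided signed-rank p over all 2^n sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        ranks[np.array(signs, dtype=bool)].sum()
        for signs in itertools.product([0, 1], repeat=n)
    ])
    lo = np.mean(ws <= w_obs + 1e-12)
    hi = np.mean(ws >= w_obs - 1e-12)
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_exactness(seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    for n in range(3, 13):
        for _ in range(4):
            d = rng.standard_normal(n) * rng.uniform(0.5, 2.0)
            # occasionally force ties and zeros
            if rng.uniform() < 0.3 and n > 4:
                d[1] = d[0]
            p_impl = group_stats.wilcoxon_paired_p(d)
            p_oracle = wilcoxon_enumeration_oracle(d)
            max_dev = max(max_dev, abs(p_impl - p_oracle))
    p6 = group_stats.wilcoxon_paired_p(np.abs(rng.standard_normal(6)) + 0.1)
    return {
        "wilcoxon_max_abs_dev_from_enumeration": float(max_dev),
        "wilcoxon_n6_all_positive_p": float(p6),
    }


# ---------------------------------------------------------------------------
# 4. cluster-permutation calibration
# ---------------------------------------------------------------------------

def cluster_null_calibration(seed: int = 0, n_reps: int = 200,
                             n_events: int = 38, n_channels: int = 29,
                             n_perm: int = 200) -> dict:
    """Family-wise error of the corrected maps under a global null."""
    from .types import STANDARD_CHANNELS, montage_xy

    labels = list(STANDARD_CHANNELS[:n_channels])
    xy = montage_xy(labels)
    adj = group_stats.delaunay_adjacency(xy)
    n_fp = 0
    size1 = 0
    for rep in range(n_reps):
        pre, post, _ = synthetic_data.simulate_summary_cohort(
            n_events, n_channels, seed=seed * n_reps + rep
        )
        raw = group_stats.wilcoxon_paired_map(pre, post, labels, alpha=0.01)
        corr = group_stats.cluster_permutation_correct(
            raw, pre - post, adj, min_cluster=2, n_perm=n_perm,
            seed=seed * n_reps + rep,
        )
        sig = np.asarray(corr.corrected_significant)
        if sig.any():
            n_fp += 1
            comps = group_stats._components(sig, adj)
            size1 += sum(1 for c in comps if len(c) < 2)
    return {
        "cluster_null_fwer": n_fp / n_reps,
        "cluster_null_size1_reported": size1,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# 5/6. planted-effect recovery end to end
# ---------------------------------------------------------------------------

PLANTED_KEY = ("HtB", "delta", "LF")


def _planted_run(seed: int, n_events: int, window_min: int,
                 n_perm: int) -> dict:
    # study conditions: marked preictal elevation (3x base) with postictal
    # suppression (0.25x) of the LF -> delta drive in a 10-channel central
    # patch; weak brain->heart feedback so the planted change stays in the
    # heart->brain branch
    template = synthetic_data.SimScenario(
        bth_strength=0.05,
        effects=(synthetic_data.EffectSpec(
            "HtB", "delta", "LF", pre_mult=3.0, post_mult=0.25,
        ),),
    )
    cohort = synthetic_data.simulate_cohort(n_events, template, seed=seed)
    cfg = pipeline.RunConfig(
        window_min=window_min, n_perm=n_perm, seed=seed,
        eeg_bands=("delta",), hrv_bands=("LF",),
    )
    summaries = [
        pipeline.analyze_event(s.recording, s.annotations[0], cfg)
        for s in cohort
    ]
    maps = pipeline.group_maps(summaries, cfg)
    m = maps[PLANTED_KEY]
    planted = set(synthetic_data.CENTRAL_PATCH)
    sig = {
        m.channels[i]
        for i in np.flatnonzero(np.asarray(m.corrected_significant))
    }
    tp = len(sig & planted)
    fp = len(sig - planted)
    # minute trend over the planted patch
    idx = [summaries[0].channels.index(c) for c in planted]
    mats = []
    for s in summaries:
        mm = s.minute_medians[PLANTED_KEY][idx]
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            mats.append(np.nanmean(mm, axis=0))
    tr = group_stats.trend_zscore(np.stack(mats))
    n_min = window_min
    with np.errstate(invalid="ignore"):
        trend_diff = (np.nanmean(tr["trend"][:n_min])
                      - np.nanmean(tr["trend"][n_min:]))
    effect_positive = bool(
        np.median(
            [m.effect_sign[m.channels.index(c)] for c in (sig & planted)]
            or [0]
        ) > 0
    )
    return dict(tp=tp, fp=fp, sensitivity=tp / len(planted),
                trend_pre_minus_post=float(trend_diff),
                effect_positive=effect_positive)


def planted_effect_recovery(seed: int = 0, n_runs: int = 20,
                            n_events: int = 16, window_min: int = 10,
                            n_perm: int = 300) -> dict:
    runs = [
        _planted_run(seed * 1000 + k, n_events, window_min, n_perm)
        for k in range(n_runs)
    ]
    sens = np.array([r["sensitivity"] for r in runs])
    fp_free = np.array([r["fp"] == 0 for r in runs])
    trend = np.array([r["trend_pre_minus_post"] for r in runs])
    return {
        "planted_mean_sensitivity_pct": float(100.0 * sens.mean()),
        "planted_fp_free_runs_pct": float(100.0 * fp_free.mean()),
        "planted_trend_pre_minus_post_mean_z": float(np.nanmean(trend)),
        "n_runs": n_runs,
    }


def window_robustness(seed: int = 0, n_runs: int = 3,
                      n_events: int = 16, n_perm: int = 300) -> dict:
    """Criterion-5 rerun at 5-min windows: direction must be preserved."""
    runs = [
        _planted_run(seed * 1000 + 500 + k, n_events, 5, n_perm)
        for k in range(n_runs)
    ]
    pos = [r for r in runs if r["tp"] > 0]
    same_dir = [r["effect_positive"] for r in pos]
    detected = len(pos)
    return {
        "window5_runs_detecting_effect": detected,
        "window5_direction_consistent_pct": float(
            100.0 * (np.mean(same_dir) if same_dir else 0.0)
        ),
        "window5_mean_sensitivity_pct": float(
            100.0 * np.mean([r["sensitivity"] for r in runs])
        ),
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# 7. band-power analytics
# ---------------------------------------------------------------------------

def band_power_analytics(seed: int = 0) -> dict:
    fs = 128.0
    t = np.arange(0, 120, 1.0 / fs)
    x = 10.0 * np.sin(2 * np.pi * 6.0 * t)
    bp = band_power.eeg_band_power(x, fs, "theta")
    eeg_err = abs(np.median(bp.power[bp.valid]) - 50.0) / 50.0

    t4 = np.arange(0, 600, 0.25)
    rr = 0.9 + 0.02 * np.sin(2 * np.pi * 0.25 * t4)
    hf = band_power.hrv_band_power(rr, "HF")
    hrv_err = abs(np.median(hf.power[hf.valid]) - 2e-4) / 2e-4
    return {
        "eeg_tone_power_rel_err_pct": float(100.0 * eeg_err),
        "hrv_tone_power_rel_err_pct": float(100.0 * hrv_err),
    }


# ---------------------------------------------------------------------------

def run_all(seed: int = 1, fast: bool = False) -> dict:
    """Every check; ``fast`` shrinks Monte-Carlo sizes (exploration only)."""
    out = {}
    out.update(forward_inverse_consistency(seed,
                                           n_seeds=20 if fast else 100))
    out.update(ipfm_closed_forms(seed))
    out.update(wilcoxon_exactness(seed))
    out.update(cluster_null_calibration(seed,
                                        n_reps=50 if fast else 200))
    out.update(planted_effect_recovery(seed, n_runs=3 if fast else 20))
    out.update(window_robustness(seed, n_runs=2 if fast else 3))
    out.update(band_power_analytics(seed))
    return out
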