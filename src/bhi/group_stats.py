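"""Group-level statistics on per-event coupling summaries.

The comparison of interest is paired (preictal vs postictal, one pair per
seizure event, per channel).  The chain is:

1. Shapiro-Wilk normality screen on the paired differences - if the
   majority of channels reject normality, nonparametric testing is used.
2. Two-sided Wilcoxon signed-rank test per channel (exact null
   distribution up to n = 25 paired events, normal approximation with tie
   and continuity corrections beyond; zero differences dropped).
3. Spatial cluster permutation correction: connected components of
   raw-significant channels smaller than ``min_cluster`` (default 2) are
   discarded; the remaining cluster sizes are compared against the null
   distribution of the maximum cluster size obtained by random within-event
   pre/post label swaps (sign flips of the paired differences).
4. Minute-resolution trends: per-event 1-min medians are z-scored within
   event across both phases and averaged across events.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps
from scipy.spatial import Delaunay

from .types import StatMap


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_ranks(d: np.ndarray):
    """Drop zeros, midrank |d|; returns (ranks, positive mask, n_nonzero)."""
    d = np.asarray(d, dtype=float)
    nz = d != 0
    dd = d[nz]
    ranks = sps.rankdata(np.abs(dd))
    return ranks, dd > 0, int(nz.sum())


def wilcoxon_exact_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p by dynamic programming over ranks.

    Valid with ties (midranks are doubled to integers).  The two-sided p is
    2 * min(P(W+ <= w), P(W+ >= w)) capped at 1.
    """
    ranks, pos, n = _signed_ranks(d)
    if n == 0:
        return 1.0
    r2 = np.round(2.0 * ranks).astype(int)
    w2 = int(np.round(2.0 * ranks[pos].sum()))
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    lo = dist[: w2 + 1].sum()
    hi = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def _wilcoxon_normal_p(w: np.ndarray, ranks_list) -> np.ndarray:
    """Vectorized two-sided normal-approximation p for W+ values.

    ``ranks_list`` holds the per-channel midrank vectors (zeros dropped);
    the tie correction sum(t^3 - t)/48 is applied to the variance.
    """
    p = np.ones(w.shape[-1] if w.ndim > 1 else w.size)
    mus, sds = [], []
    for ranks in ranks_list:
        n = ranks.size
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= ((counts**3 - counts).sum()) / 48.0
        mus.append(mu)
        sds.append(np.sqrt(var) if var > 0 else np.inf)
    mus = np.asarray(mus)
    sds = np.asarray(sds)
    z = (np.abs(w - mus) - 0.5) / sds
    z = np.clip(z, 0.0, None)
    return 2.0 * sps.norm.sf(z)


def wilcoxon_paired_p(d: np.ndarray, exact_max_n: int = 25) -> float:
    """Two-sided signed-rank p for one channel's paired differences."""
    ranks, pos, n = _signed_ranks(d)
    if n == 0:
        return 1.0
    if n <= exact_max_n:
        return wilcoxon_exact_p(d)
    w = ranks[pos].sum()
    return float(_wilcoxon_normal_p(np.array([w]), [ranks])[0])


def wilcoxon_paired_map(pre: np.ndarray, post: np.ndarray, channels,
                        alpha: float = 0.01,
                        exact_max_n: int = 25) -> StatMap:
    """Uncorrected per-channel signed-rank map of preictal - postictal.

    ``pre`` and ``post`` are (n_events, n_channels); requires >= 6 events.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.shape[1] != len(channels):
        raise ValueError("pre/post must be (n_events, n_channels)")
    if pre.shape[0] < 6:
        raise ValueError("need >= 6 paired events")
    d = pre - post
    p = np.array([wilcoxon_paired_p(d[:, c], exact_max_n)
                  for c in range(d.shape[1])])
    med = np.median(d, axis=0)
    sign = np.where(med >= 0, 1, -1)
    all_zero = (d == 0).all(axis=0)
    p[all_zero] = 1.0
    return StatMap(
        channels=list(channels), p=p, effect_sign=sign,
        raw_significant=p < alpha, alpha=alpha,
        meta={"n_events": pre.shape[0],
              "zero_diff_counts": (d == 0).sum(axis=0).tolist()},
    )


# ---------------------------------------------------------------------------
# Normality screen
# ---------------------------------------------------------------------------

def shapiro_wilk_screen(diffs: np.ndarray, alpha: float = 0.05) -> dict:
    """Per-channel Shapiro-Wilk on paired differences + a global branch.

    Recommends nonparametric testing when a majority of (testable)
    channels reject normality at ``alpha``.  Constant channels are flagged
    (normality undefined) and excluded from the vote.
    """
    diffs = np.asarray(diffs, dtype=float)
    n_ch = diffs.shape[1]
    p = np.full(n_ch, np.nan)
    flagged = np.zeros(n_ch, dtype=bool)
    for c in range(n_ch):
        x = diffs[:, c]
        if x.size < 3 or np.ptp(x) == 0:
            flagged[c] = True
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p[c] = sps.shapiro(x).pvalue
    testable = ~flagged
    n_reject = int((p[testable] < alpha).sum())
    majority = n_reject > testable.sum() / 2.0
    return {
        "p": p,
        "flagged": flagged,
        "n_reject": n_reject,
        "n_testable": int(testable.sum()),
        "recommend_nonparametric": bool(majority),
    }


# ---------------------------------------------------------------------------
# Adjacency and clusters
# ---------------------------------------------------------------------------

def delaunay_adjacency(xy: np.ndarray, prune_factor: float = 1.5) -> dict:
    """Channel neighbor sets from a pruned Delaunay triangulation.

    Edges longer than ``prune_factor`` times the median edge length are
    removed (they connect across the head through sparse regions).
    """
    xy = np.asarray(xy, dtype=float)
    n = xy.shape[0]
    adj = {i: set() for i in range(n)}
    if n < 3:
        for i in range(n):
            adj[i] = set(range(n)) - {i}
        return adj
    tri = Delaunay(xy)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
            edges.add((i, j))
    lengths = {e: np.linalg.norm(xy[e[0]] - xy[e[1]]) for e in edges}
    cutoff = prune_factor * np.median(list(lengths.values()))
    for (i, j), ln in lengths.items():
        if ln <= cutoff:
            adj[i].add(j)
            adj[j].add(i)
    return adj


def _components(mask: np.ndarray, adj: dict) -> list:
    """Connected components (lists of indices) of True channels."""
    seen = np.zeros(mask.size, dtype=bool)
    comps = []
    for i in np.flatnonzero(mask):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if mask[v] and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def _perm_max_cluster_sizes(d: np.ndarray, adj: dict, alpha: float,
                            n_perm: int, rng, min_cluster: int,
                            exact_max_n: int = 25) -> np.ndarray:
    """Null distribution of the max (eligible) cluster size under random
    within-event pre/post swaps, i.e. sign flips of the differences."""
    n_ev, n_ch = d.shape
    ranks_list, A_list, B_list = [], [], []
    for c in range(n_ch):
        ranks, pos, _ = _signed_ranks(d[:, c])
        ranks_list.append(ranks)
        a = np.zeros(n_ev)
        b = np.zeros(n_ev)
        nz = d[:, c] != 0
        a[nz] = ranks * pos          # contribution when event not flipped
        b[nz] = ranks * (~pos)       # contribution when event flipped
        A_list.append(a)
        B_list.append(b)
    A = np.column_stack(A_list)      # (events, channels)
    B = np.column_stack(B_list)
    flips = rng.integers(0, 2, size=(n_perm, n_ev)).astype(float)
    W = (1.0 - flips) @ A + flips @ B
    P = np.column_stack([
        _exact_or_normal_p_column(W[:, c], ranks_list[c], exact_max_n)
        for c in range(n_ch)
    ])
    sig = P < alpha
    out = np.zeros(n_perm, dtype=int)
    for k in range(n_perm):
        comps = _components(sig[k], adj)
        sizes = [len(c) for c in comps if len(c) >= min_cluster]
        out[k] = max(sizes) if sizes else 0
    return out


def _exact_or_normal_p_column(w: np.ndarray, ranks: np.ndarray,
                              exact_max_n: int) -> np.ndarray:
    n = ranks.size
    if n == 0:
        return np.ones(w.size)
    if n <= exact_max_n:
        r2 = np.round(2.0 * ranks).astype(int)
        total = int(r2.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            nxt = dist.copy()
            nxt[r:] += dist[: total + 1 - r]
            dist = nxt
        dist /= dist.sum()
        cdf = np.cumsum(dist)
        sf = np.concatenate([np.cumsum(dist[::-1])[::-1], [0.0]])
        w2 = np.clip(np.round(2.0 * w).astype(int), 0, total)
        return np.minimum(1.0, 2.0 * np.minimum(cdf[w2], sf[w2]))
    return _wilcoxon_normal_p(w, [ranks])


def cluster_permutation_correct(stat_map: StatMap, diffs: np.ndarray,
                                adj: dict, min_cluster: int = 2,
                                n_perm: int = 1000, seed: int = 0,
                                cluster_alpha: float = 0.05) -> StatMap:
    """Cluster-size permutation correction of an uncorrected map.

    Clusters of raw-significant channels smaller than ``min_cluster`` are
    dropped outright; the rest survive if their size exceeds the
    (1 - cluster_alpha) quantile of the permutation null of the maximum
    cluster size.  ``diffs`` is the (events x channels) paired-difference
    matrix the map was computed from.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unstable null")
    diffs = np.asarray(diffs, dtype=float)
    n_ch = len(stat_map.channels)
    if diffs.shape[1] != n_ch or len(adj) != n_ch:
        raise ValueError("diffs/adjacency must cover every channel")
    rng = np.random.default_rng(seed)

    comps = _components(np.asarray(stat_map.raw_significant), adj)
    eligible = [c for c in comps if len(c) >= min_cluster]

    cluster_id = np.full(n_ch, -1, dtype=int)
    corrected = np.zeros(n_ch, dtype=bool)
    cluster_p = {}
    if eligible:
        null_max = _perm_max_cluster_sizes(
            diffs, adj, stat_map.alpha, n_perm, rng, min_cluster,
        )
        for k, comp in enumerate(eligible):
            size = len(comp)
            p_clu = (1.0 + (null_max >= size).sum()) / (n_perm + 1.0)
            cluster_p[k] = float(p_clu)
            for i in comp:
                cluster_id[i] = k
            if p_clu <= cluster_alpha:
                for i in comp:
                    corrected[i] = True

    return StatMap(
        channels=stat_map.channels, p=stat_map.p,
        effect_sign=stat_map.effect_sign,
        raw_significant=stat_map.raw_significant, alpha=stat_map.alpha,
        cluster_id=cluster_id, corrected_significant=corrected,
        meta={**stat_map.meta, "n_perm": n_perm, "seed": seed,
              "min_cluster": min_cluster, "cluster_alpha": cluster_alpha,
              "cluster_p": cluster_p},
    )


# ---------------------------------------------------------------------------
# Minute trends
# ---------------------------------------------------------------------------

def trend_zscore(minute_medians: np.ndarray) -> dict:
    """Z-score each event's minute medians and average across events.

    ``minute_medians`` is (n_events, n_minutes), preictal minutes first
    then postictal minutes (both phases pooled in the z-score so pre/post
    levels stay comparable).  Zero-variance events are excluded.
    """
    m = np.asarray(minute_medians, dtype=float)
    # minutes without coefficient samples (estimation-window edges) are NaN
    # and simply do not contribute
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(m, axis=1, ddof=0)
        mu = np.nanmean(m, axis=1, keepdims=True)
    keep = np.isfinite(sd) & (sd > 0)
    if not keep.all():
        warnings.warn(
            f"{(~keep).sum()} event(s) with zero trend variance excluded",
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("no event with usable trend variance")
    z = (m[keep] - mu[keep]) / sd[keep, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return {
            "trend": np.nanmean(z, axis=0),
            "sem": np.nanstd(z, axis=0, ddof=1) / np.sqrt(z.shape[0]),
            "n_events_used": int(keep.sum()),
            "z_per_event": z,
        }


# ---------------------------------------------------------------------------
# Surrogate windows
# ---------------------------------------------------------------------------

def surrogate_window_pair(first_onset_s: float, window_len_s: float = 300.0,
                          gap_s: float = 60.0, lead_s: float = 3600.0):
    """Two interictal windows separated by a surrogate "event" gap.

    Both windows end at least ``lead_s`` before the first real seizure
    onset: pre = [T - 2W - gap, T - W - gap), post = [T - W, T) with
    T = first_onset - lead_s.  Raises if that span would start before the
    record does.
    """
    T = first_onset_s - lead_s
    start = T - 2 * window_len_s - gap_s
    if start < 0:
        raise ValueError(
            "insufficient interictal data before the first seizure"
        )
    return (
        (start, start + window_len_s),
        (T - window_len_s, T),
    )


# ---------------------------------------------------------------------------
# Topographic rendering
# ---------------------------------------------------------------------------

def render_topomap(values: np.ndarray, xy: np.ndarray, ax=None,
                   significant=None, sign=None, resolution: int = 120,
                   title: str = ""):
    """Inverse-distance-weighted scalp map on the unit head disc.

    ``values`` in [0, 1] drive color darkness (typically 1 - p or |z|);
    ``sign`` (+1/-1) selects red vs blue; channels where ``significant``
    is False render white.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    if xy.shape[0] < 3:
        raise ValueError("need >= 3 channels to interpolate a map")
    if significant is None:
        significant = np.ones(values.size, dtype=bool)
    if sign is None:
        sign = np.ones(values.size)
    signed = np.where(significant, values * sign, 0.0)

    g = np.linspace(-1.15, 1.15, resolution)
    gx, gy = np.meshgrid(g, g)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    w = 1.0 / np.maximum(d2, 1e-6)
    interp = (w * signed[None, :]).sum(1) / w.sum(1)
    interp = interp.reshape(gx.shape)
    interp[gx**2 + gy**2 > 1.15**2] = np.nan

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(interp, origin="lower", extent=[-1.15, 1.15, -1.15, 1.15],
              cmap="RdBu_r", vmin=-1, vmax=1)
    ax.scatter(xy[:, 0], xy[:, 1], s=6, c="k", zorder=3)
    circ = plt.Circle((0, 0), 1.12, fill=False, lw=1.2)
    ax.add_patch(circ)
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title, fontsize=8)
    return ax
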