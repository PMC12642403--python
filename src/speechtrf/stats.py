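"""Group-level statistics for source-space model-comparison maps.

Implements the statistical battery applied to per-subject improvement
maps and kernels: Gaussian spatial smoothing, mass-univariate one-sample
and paired t-tests with threshold-free cluster enhancement (TFCE) and
sign-flip permutation nulls, the hemispheric lateralization index
LI = R/(L+R), ROI-averaged one-sample tests, per-feature regressions with
native language as a fixed effect (dummy-coded against a baseline level),
pairwise between-language t-tests, spatiotemporal cluster-mass
permutation tests on kernels, and kernel peak extraction/comparison.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import signal as _sig
from scipy import stats as sps
import statsmodels.api as sm

from .sourcespace import GroupDataset, SourceMap, SourceSpace

__all__ = [
    "smooth_map",
    "tfce",
    "TFCEResult",
    "mass_univariate_onesample",
    "hemispheric_paired_test",
    "lateralization_index",
    "roi_summary",
    "language_regression",
    "pairwise_language_ttests",
    "ClusterResult",
    "trf_cluster_test",
    "peak_analysis",
]

EXHAUSTIVE_LIMIT = 4096  # sign-flip patterns enumerated exhaustively below this
_VAR_GUARD = 1e-12
_T_CAP = 100.0  # zero-variance guard: |t| is capped, keeping TFCE integrable
_TFCE_MAX_STEPS = 5000  # dh is coarsened for maps exceeding this many thresholds


# --------------------------------------------------------------------------
# smoothing and TFCE


def smooth_weights(space: SourceSpace, sigma: float) -> np.ndarray | None:
    """Row-normalized Gaussian weights over source distances (None if sigma=0)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return None
    d2 = ((space.coords[:, None, :] - space.coords[None, :, :]) ** 2).sum(-1)
    W = np.exp(-d2 / (2.0 * sigma**2))
    return W / W.sum(axis=1, keepdims=True)


def smooth_map(m: SourceMap, sigma: float) -> SourceMap:
    """Gaussian-weighted spatial smoothing; ``sigma=0`` is the identity."""
    W = smooth_weights(m.space, sigma)
    if W is None:
        return SourceMap(m.values.copy(), m.space)
    return SourceMap(W @ m.values, m.space)


@njit(cache=True)
def _tfce_pos(values, e0, e1, E, H, dh):
    """TFCE of a nonnegative map: sum over thresholds of extent^E * h^H * dh."""
    S = values.shape[0]
    out = np.zeros(S)
    vmax = 0.0
    for i in range(S):
        if values[i] > vmax:
            vmax = values[i]
    if vmax <= 0.0:
        return out
    if vmax / dh > _TFCE_MAX_STEPS:  # degenerate guard-capped statistics
        dh = vmax / _TFCE_MAX_STEPS
    parent = np.empty(S, dtype=np.int64)
    size = np.empty(S, dtype=np.int64)
    h = dh
    while h <= vmax + 1e-12:
        for i in range(S):
            parent[i] = i
            size[i] = 1
        for e in range(e0.shape[0]):
            a = e0[e]
            b = e1[e]
            if values[a] >= h and values[b] >= h:
                ra = a
                while parent[ra] != ra:
                    ra = parent[ra]
                rb = b
                while parent[rb] != rb:
                    rb = parent[rb]
                if ra != rb:
                    if size[ra] < size[rb]:
                        ra, rb = rb, ra
                    parent[rb] = ra
                    size[ra] += size[rb]
        inc = h**H * dh
        for i in range(S):
            if values[i] >= h:
                r = i
                while parent[r] != r:
                    r = parent[r]
                out[i] += size[r] ** E * inc
        h += dh
    return out


def tfce(
    values: np.ndarray,
    edges: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float = 0.1,
) -> np.ndarray:
    """Signed threshold-free cluster enhancement of a statistic map.

    Positive and negative values are enhanced symmetrically (the negated
    map is enhanced and subtracted).
    """
    if dh <= 0:
        raise ValueError("dh must be > 0")
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("statistic map contains non-finite values")
    e0 = np.ascontiguousarray(edges[:, 0], dtype=np.int64)
    e1 = np.ascontiguousarray(edges[:, 1], dtype=np.int64)
    pos = _tfce_pos(np.clip(v, 0.0, None), e0, e1, E, H, dh)
    neg = _tfce_pos(np.clip(-v, 0.0, None), e0, e1, E, H, dh)
    return pos - neg


@dataclass
class TFCEResult:
    t: np.ndarray
    enhanced: np.ndarray
    null_max: np.ndarray
    p: np.ndarray
    tmax: float
    p_tmax: float
    exhaustive: bool
    space: SourceSpace | None = field(repr=False, default=None)

    @property
    def n_significant(self) -> int:
        return int((self.p <= 0.05).sum())


def _onesample_t(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    m = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    sd = np.maximum(sd, _VAR_GUARD)
    return np.clip(m / (sd / np.sqrt(n)), -_T_CAP, _T_CAP)


def _sign_flips(
    n: int, n_perm: int, seed: int, method: str = "auto"
) -> tuple[np.ndarray, bool]:
    if method == "auto" and 2**n <= min(EXHAUSTIVE_LIMIT, n_perm):
        bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :] & 1
        return np.where(bits > 0, 1.0, -1.0), True
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
    return flips, False


def _tfce_max_null(
    tmaps: np.ndarray, edges: np.ndarray, E: float, H: float, dh: float
) -> np.ndarray:
    e0 = np.ascontiguousarray(edges[:, 0], dtype=np.int64)
    e1 = np.ascontiguousarray(edges[:, 1], dtype=np.int64)
    out = np.empty(len(tmaps))
    for b, t in enumerate(tmaps):
        pos = _tfce_pos(np.clip(t, 0.0, None), e0, e1, E, H, dh)
        neg = _tfce_pos(np.clip(-t, 0.0, None), e0, e1, E, H, dh)
        out[b] = max(pos.max(initial=0.0), neg.max(initial=0.0))
    return out


def _tfce_permutation_onesample(
    diffs: np.ndarray,
    space: SourceSpace,
    sigma: float,
    E: float,
    H: float,
    dh: float,
    n_perm: int,
    seed: int,
    method: str = "auto",
) -> TFCEResult:
    """Shared machinery: smooth, t, TFCE, sign-flip max-statistic null."""
    n, S = diffs.shape
    if n < 2:
        raise ValueError("at least 2 subjects required")
    W = smooth_weights(space, sigma)
    X = diffs if W is None else diffs @ W.T
    t_obs = _onesample_t(X)
    enhanced = tfce(t_obs, space.edges, E, H, dh)
    flips, exhaustive = _sign_flips(n, n_perm, seed, method)
    m = flips @ X / n
    ssq = (X**2).sum(axis=0)
    var = np.maximum((ssq[None, :] - n * m**2) / (n - 1), _VAR_GUARD**2)
    tmaps = np.clip(m / np.sqrt(var / n), -_T_CAP, _T_CAP)
    null_max = _tfce_max_null(tmaps, space.edges, E, H, dh)
    abs_enh = np.abs(enhanced)
    if exhaustive:
        p = (null_max[None, :] >= abs_enh[:, None] - 1e-12).mean(axis=1)
    else:
        exceed = (null_max[None, :] >= abs_enh[:, None] - 1e-12).sum(axis=1)
        p = (1.0 + exceed) / (1.0 + len(null_max))
    imax = int(np.argmax(abs_enh))
    return TFCEResult(
        t=t_obs,
        enhanced=enhanced,
        null_max=null_max,
        p=p,
        tmax=float(t_obs[imax]),
        p_tmax=float(p[imax]),
        exhaustive=exhaustive,
        space=space,
    )


def mass_univariate_onesample(
    maps: GroupDataset,
    sigma: float = 1.0,
    E: float = 0.5,
    H: float = 2.0,
    dh: float = 0.1,
    n_perm: int = 10_000,
    seed: int = 0,
    method: str = "auto",
) -> TFCEResult:
    """Smoothed mass-univariate one-sample t-test with TFCE.

    Family-wise p-values per source come from the sign-flip max-statistic
    distribution (exhaustive when 2^n <= 4096 fits in ``n_perm``, else
    ``n_perm`` seeded random flips; ``method='random'`` forces the
    latter).  ``tmax``/``p_tmax`` report the t value and p of the source
    with the strongest enhanced statistic.
    """
    return _tfce_permutation_onesample(
        maps.values, maps.space, sigma, E, H, dh, n_perm, seed, method
    )


def hemispheric_paired_test(
    maps: GroupDataset,
    sigma: float = 1.0,
    E: float = 0.5,
    H: float = 2.0,
    dh: float = 0.1,
    n_perm: int = 10_000,
    seed: int = 0,
) -> TFCEResult:
    """Left-vs-right paired test after mapping right sources onto the left.

    Per subject the paired right-hemisphere value is subtracted from each
    left source (left minus mapped right); the difference maps then run
    through the one-sample TFCE machinery on the left-hemisphere graph.
    Positive t favours the left hemisphere.
    """
    if maps.space.pairs is None:
        raise ValueError("source space defines no left-right pairing")
    left_idx = maps.space.pairs[:, 0]
    right_idx = maps.space.pairs[:, 1]
    diffs = maps.values[:, left_idx] - maps.values[:, right_idx]
    left_space = maps.space.subspace(left_idx)
    return _tfce_permutation_onesample(
        diffs, left_space, sigma, E, H, dh, n_perm, seed
    )


# --------------------------------------------------------------------------
# lateralization and ROI tests


def lateralization_index(L, R, clip_negative: bool = True):
    """``LI = R / (L + R)``: 0 = fully left, 0.5 = symmetric, 1 = fully right.

    Negative strengths (a predictor can worsen the model) are clipped to 0
    by default since the index is only defined for nonnegative strengths;
    ``L + R = 0`` yields NaN.
    """
    L = np.asarray(L, dtype=float)
    R = np.asarray(R, dtype=float)
    if clip_negative:
        L = np.clip(L, 0.0, None)
        R = np.clip(R, 0.0, None)
    total = L + R
    with np.errstate(invalid="ignore", divide="ignore"):
        li = np.where(total > 0, R / np.where(total > 0, total, 1.0), np.nan)
    if li.ndim == 0:
        return float(li)
    return li


def roi_summary(maps: GroupDataset, roi: np.ndarray | None = None) -> pd.DataFrame:
    """Per-subject ROI spatial means and the group one-sample t-test.

    Returns one row per group label plus a pooled 'all' row with columns
    (group, n, mean, t, df, p).  Zero-variance groups get NaN t with a
    warning instead of a spurious statistic.
    """
    mask = roi if roi is not None else maps.roi
    if mask is None:
        mask = np.ones(maps.space.n_sources, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    subject_means = maps.values[:, mask].mean(axis=1)
    rows = []
    groups = list(dict.fromkeys(maps.labels)) + ["all"]
    for g in groups:
        if g == "all":
            vals = subject_means
        else:
            idx = [i for i, l in enumerate(maps.labels) if l == g]
            vals = subject_means[idx]
        n = len(vals)
        if n < 2 or np.std(vals, ddof=1) == 0:
            warnings.warn(f"group {g!r}: degenerate sample, t undefined")
            t, p = np.nan, np.nan
        else:
            t, p = sps.ttest_1samp(vals, 0.0)
        rows.append(
            {"group": g, "n": n, "mean": float(np.mean(vals)),
             "t": float(t), "df": n - 1, "p": float(p)}
        )
    return pd.DataFrame(rows)


def language_regression(
    values: np.ndarray, labels: list[str], baseline: str = "English"
) -> pd.DataFrame:
    """OLS of a per-subject scalar on native language (dummy coded).

    The baseline language is absorbed into the intercept; every other
    level gets an estimate, t and p, mirroring a fixed-effect regression
    table.  Raises on a singular design (fewer than two groups).
    """
    values = np.asarray(values, dtype=float)
    levels = list(dict.fromkeys(labels))
    if len(levels) < 2:
        raise ValueError("regression needs at least two language groups")
    if baseline not in levels:
        baseline = levels[0]
    others = [l for l in levels if l != baseline]
    X = np.column_stack(
        [np.ones(len(values))]
        + [np.array([1.0 if l == g else 0.0 for l in labels]) for g in others]
    )
    fit = sm.OLS(values, X).fit()
    rows = [
        {"term": "intercept", "level": baseline, "estimate": fit.params[0],
         "t": fit.tvalues[0], "df": int(fit.df_resid), "p": fit.pvalues[0]}
    ]
    for j, g in enumerate(others, start=1):
        rows.append(
            {"term": "language", "level": g, "estimate": fit.params[j],
             "t": fit.tvalues[j], "df": int(fit.df_resid), "p": fit.pvalues[j]}
        )
    return pd.DataFrame(rows)


def pairwise_language_ttests(
    values: np.ndarray, labels: list[str]
) -> pd.DataFrame:
    """Independent two-sample t-tests for every pair of present groups."""
    values = np.asarray(values, dtype=float)
    levels = list(dict.fromkeys(labels))
    rows = []
    for a, b in itertools.combinations(levels, 2):
        va = values[[i for i, l in enumerate(labels) if l == a]]
        vb = values[[i for i, l in enumerate(labels) if l == b]]
        if len(va) < 2 or len(vb) < 2:
            warnings.warn(f"pair ({a}, {b}) skipped: group size < 2")
            continue
        t, p = sps.ttest_ind(va, vb)
        rows.append(
            {"group_a": a, "group_b": b, "t": float(t),
             "df": len(va) + len(vb) - 2, "p": float(p)}
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# spatiotemporal cluster test on kernels


@njit(cache=True)
def _component_roots(mask, e0, e1):
    """Union-find roots for masked nodes (-1 elsewhere)."""
    n = mask.shape[0]
    parent = np.empty(n, dtype=np.int64)
    for i in range(n):
        parent[i] = i
    for e in range(e0.shape[0]):
        a = e0[e]
        b = e1[e]
        if mask[a] and mask[b]:
            ra = a
            while parent[ra] != ra:
                ra = parent[ra]
            rb = b
            while parent[rb] != rb:
                rb = parent[rb]
            if ra != rb:
                parent[rb] = ra
    roots = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        if mask[i]:
            r = i
            while parent[r] != r:
                r = parent[r]
            roots[i] = r
    return roots


def _spacetime_edges(edges_s: np.ndarray, S: int, T: int) -> np.ndarray:
    """Edges of the space x time grid graph (node = s * T + t)."""
    out = []
    node = np.arange(S * T).reshape(S, T)
    if T > 1:
        a = node[:, :-1].ravel()
        b = node[:, 1:].ravel()
        out.append(np.column_stack([a, b]))
    for s0, s1 in edges_s:
        out.append(np.column_stack([node[s0], node[s1]]))
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(out).astype(np.int64)


def _cluster_masses(tflat, tcrit, e0, e1):
    masses = []
    members = []
    for sgn in (1.0, -1.0):
        mask = (sgn * tflat) > tcrit
        if not mask.any():
            continue
        roots = _component_roots(mask, e0, e1)
        for r in np.unique(roots[roots >= 0]):
            sel = roots == r
            masses.append(float(tflat[sel].sum()))
            members.append(np.flatnonzero(sel))
    return masses, members


def _two_sample_t(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na, nb = len(A), len(B)
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    sp = np.maximum(sp, _VAR_GUARD**2)
    t = (ma - mb) / np.sqrt(sp * (1.0 / na + 1.0 / nb))
    return np.clip(t, -_T_CAP, _T_CAP)


@dataclass
class ClusterResult:
    t: np.ndarray  # (S, T) pointwise two-sample t
    clusters: pd.DataFrame  # one row per suprathreshold cluster
    null_max_mass: np.ndarray
    t_critical: float


def trf_cluster_test(
    trfs: np.ndarray,
    labels: list[str],
    space: SourceSpace,
    lags_ms: np.ndarray | None = None,
    alpha_forming: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    roi: np.ndarray | None = None,
) -> ClusterResult:
    """Two-group spatiotemporal cluster-mass permutation test on kernels.

    ``trfs`` is ``(n_subjects, S, T)``; ``labels`` must contain exactly
    two group labels.  Pointwise two-sample t values exceeding the
    cluster-forming threshold are grouped into connected components of the
    space x time graph; the cluster statistic is the summed t (mass), and
    group-label permutations give the max-mass null.  Each cluster row
    reports its mass, p, time span, and spatial extent as a percentage of
    the (ROI) sources.
    """
    trfs = np.asarray(trfs, dtype=float)
    n, S, T = trfs.shape
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError("cluster test requires exactly two groups")
    ia = np.array([i for i, l in enumerate(labels) if l == groups[0]])
    ib = np.array([i for i, l in enumerate(labels) if l == groups[1]])
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("at least 2 subjects per group required")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        sub = space.subspace(np.flatnonzero(roi))
        return trf_cluster_test(
            trfs[:, roi, :], labels, sub, lags_ms, alpha_forming, n_perm, seed
        )
    if lags_ms is None:
        lags_ms = np.arange(T, dtype=float)
    df = len(ia) + len(ib) - 2
    tcrit = float(sps.t.ppf(1.0 - alpha_forming / 2.0, df))
    flat = trfs.reshape(n, S * T)
    edges = _spacetime_edges(space.edges, S, T)
    e0 = np.ascontiguousarray(edges[:, 0]) if len(edges) else np.empty(0, np.int64)
    e1 = np.ascontiguousarray(edges[:, 1]) if len(edges) else np.empty(0, np.int64)

    t_obs = _two_sample_t(flat[ia], flat[ib])
    masses, members = _cluster_masses(t_obs, tcrit, e0, e1)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    idx = np.arange(n)
    for b in range(n_perm):
        perm = rng.permutation(idx)
        pa, pb = perm[: len(ia)], perm[len(ia):]
        tp = _two_sample_t(flat[pa], flat[pb])
        pm, _ = _cluster_masses(tp, tcrit, e0, e1)
        null_max[b] = max((abs(m) for m in pm), default=0.0)

    rows = []
    for mass, mem in zip(masses, members):
        src = np.unique(mem // T)
        tt = mem % T
        p = (1.0 + (null_max >= abs(mass) - 1e-12).sum()) / (1.0 + n_perm)
        rows.append(
            {
                "mass": mass,
                "p": p,
                "t_start_ms": float(lags_ms[tt.min()]),
                "t_stop_ms": float(lags_ms[tt.max()]),
                "n_sources": len(src),
                "extent_pct": 100.0 * len(src) / S,
            }
        )
    clusters = pd.DataFrame(
        rows, columns=["mass", "p", "t_start_ms", "t_stop_ms", "n_sources", "extent_pct"]
    )
    if len(clusters):
        clusters = clusters.sort_values("p", kind="stable").reset_index(drop=True)
    return ClusterResult(
        t=t_obs.reshape(S, T),
        clusters=clusters,
        null_max_mass=null_max,
        t_critical=tcrit,
    )


# --------------------------------------------------------------------------
# peak analysis


def _find_peaks_signed(
    kernel: np.ndarray, lags_ms: np.ndarray, prominence_frac: float
) -> list[tuple[int, int, float, float]]:
    """(sign, ordinal, latency_ms, amplitude) peaks above the prominence floor."""
    floor = prominence_frac * np.abs(kernel).max()
    if floor <= 0:
        return []
    out = []
    for sgn in (1, -1):
        idx, _ = _sig.find_peaks(sgn * kernel, prominence=floor)
        for ordinal, i in enumerate(sorted(idx)):
            out.append((sgn, ordinal, float(lags_ms[i]), float(kernel[i])))
    return out


def peak_analysis(
    kernels: np.ndarray,
    lags_ms: np.ndarray,
    labels: list[str],
    prominence_frac: float = 0.1,
) -> pd.DataFrame:
    """Peak size/latency extraction and between-group comparison.

    ``kernels`` is ``(n_subjects, T)`` - spatially averaged kernels on a
    common lag grid.  Local extrema above ``prominence_frac`` x max |k|
    are matched across subjects by ordinal position within their sign;
    per matched peak, independent t-tests compare amplitude and latency
    between the two groups.  Returns an empty frame if no subject shows a
    peak above the floor.
    """
    kernels = np.asarray(kernels, dtype=float)
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError("peak comparison requires exactly two groups")
    per_subject = [
        _find_peaks_signed(k, lags_ms, prominence_frac) for k in kernels
    ]
    keys = sorted({(s, o) for peaks in per_subject for s, o, _, _ in peaks})
    rows = []
    for sgn, ordinal in keys:
        lat = {g: [] for g in groups}
        amp = {g: [] for g in groups}
        for subj, peaks in enumerate(per_subject):
            for s, o, l, a in peaks:
                if (s, o) == (sgn, ordinal):
                    g = labels[subj]
                    lat[g].append(l)
                    amp[g].append(a)
        n_a, n_b = len(lat[groups[0]]), len(lat[groups[1]])
        if n_a < 2 or n_b < 2:
            continue
        t_amp, p_amp = sps.ttest_ind(amp[groups[0]], amp[groups[1]])
        t_lat, p_lat = sps.ttest_ind(lat[groups[0]], lat[groups[1]])
        rows.append(
            {
                "sign": sgn,
                "ordinal": ordinal,
                "n_a": n_a,
                "n_b": n_b,
                "mean_latency_ms": float(np.mean(sum(lat.values(), []))),
                "mean_amplitude": float(np.mean(sum(amp.values(), []))),
                "t_amplitude": float(t_amp),
                "p_amplitude": float(p_amp),
                "t_latency": float(t_lat),
                "p_latency": float(p_lat),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sign", "ordinal", "n_a", "n_b", "mean_latency_ms",
            "mean_amplitude", "t_amplitude", "p_amplitude",
            "t_latency", "p_latency",
        ],
    )
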