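"""Boosting estimation of multivariate temporal response functions.

Kernels are fit by steepest coordinate descent on the l1 training error:
at every iteration each unfrozen (predictor, basis-element) coordinate is
probed with a +/- fixed step, the step with the largest training-error
reduction is applied, and a step that increases validation-segment error
is instead reverted and freezes that whole predictor.  Training ends when
every predictor is frozen.  Fourfold cross-validation splits the series
into contiguous equal segments; for each test segment the three rotations
of (two training segments, one validation segment) are fit and averaged,
and concatenated test-segment predictions give the model quality index

    q = 1 - l1(residuals) / l1(y)

on the standardized response.  The improvement of a predictor (set) is the
full-model q minus the q of the model without it, per source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse

from .basis import TRFBasis, build_design, make_basis, standardize

__all__ = [
    "CVPartition",
    "MTRF",
    "FitResult",
    "make_cv_partition",
    "boost_fit",
    "cross_validated_fit",
    "model_improvement",
    "predict",
]

DEFAULT_STEP = 0.005  # in units of the standardized response's mean |y|

# freeze reasons
FREEZE_VALIDATION = 1
FREEZE_NO_IMPROVEMENT = 2


@njit(cache=True)
def _boost_kernel(
    tr_data, tr_idx, tr_ptr, ytr,
    va_data, va_idx, va_ptr, yva,
    step, coord_pred, n_pred, max_iter,
):
    """Steepest l1 coordinate descent with validation-based freezing.

    Columns are CSC-encoded designs for the training (two concatenated
    segments) and validation segment.  Returns the coefficient vector, the
    per-predictor freeze reason/iteration, the training-error trace at
    accepted steps, and the step count.  Fully deterministic: ties resolve
    to the lowest coordinate index, and to +step over -step.
    """
    C = coord_pred.shape[0]
    coef = np.zeros(C)
    rtr = ytr.copy()
    rva = yva.copy()
    frozen = np.zeros(n_pred, dtype=np.bool_)
    freeze_reason = np.zeros(n_pred, dtype=np.int64)
    freeze_iter = np.full(n_pred, -1, dtype=np.int64)
    err_trace = np.empty(max_iter)
    train_err = 0.0
    for s in range(ytr.shape[0]):
        train_err += abs(rtr[s])
    n_frozen = 0
    n_accepted = 0
    it = 0
    while n_frozen < n_pred and it < max_iter:
        best_delta = -1e-12
        best_k = -1
        best_sign = 0.0
        for k in range(C):
            if frozen[coord_pred[k]]:
                continue
            dpos = 0.0
            dneg = 0.0
            for ii in range(tr_ptr[k], tr_ptr[k + 1]):
                x = tr_data[ii] * step
                r = rtr[tr_idx[ii]]
                a = abs(r)
                dpos += abs(r - x) - a
                dneg += abs(r + x) - a
            if dpos < best_delta:
                best_delta = dpos
                best_k = k
                best_sign = 1.0
            if dneg < best_delta:
                best_delta = dneg
                best_k = k
                best_sign = -1.0
        if best_k < 0:
            # a full sweep reduced nothing: freeze every remaining predictor
            for p in range(n_pred):
                if not frozen[p]:
                    frozen[p] = True
                    freeze_reason[p] = FREEZE_NO_IMPROVEMENT
                    freeze_iter[p] = it
                    n_frozen += 1
            break
        d = best_sign * step
        dval = 0.0
        for ii in range(va_ptr[best_k], va_ptr[best_k + 1]):
            x = va_data[ii] * d
            r = rva[va_idx[ii]]
            dval += abs(r - x) - abs(r)
        if dval > 1e-12:
            p = coord_pred[best_k]
            frozen[p] = True
            freeze_reason[p] = FREEZE_VALIDATION
            freeze_iter[p] = it
            n_frozen += 1
            it += 1
            continue
        coef[best_k] += d
        for ii in range(tr_ptr[best_k], tr_ptr[best_k + 1]):
            rtr[tr_idx[ii]] -= d * tr_data[ii]
        for ii in range(va_ptr[best_k], va_ptr[best_k + 1]):
            rva[va_idx[ii]] -= d * va_data[ii]
        train_err += best_delta
        err_trace[n_accepted] = train_err
        n_accepted += 1
        it += 1
    return coef, freeze_reason, freeze_iter, err_trace[:n_accepted], it


@dataclass
class CVPartition:
    """Four contiguous equal segments with rotating validation runs."""

    n_samples: int
    k: int
    bounds: tuple[tuple[int, int], ...]
    remainder: int = 0

    def rotations(self, test: int) -> list[tuple[tuple[int, int], int]]:
        """For a test segment, the (train pair, validation) rotations."""
        others = [i for i in range(self.k) if i != test]
        out = []
        for val in others:
            train = tuple(i for i in others if i != val)
            out.append((train, val))
        return out


def make_cv_partition(n_samples: int, k: int = 4) -> CVPartition:
    if n_samples < 2 * k:
        raise ValueError("series too short to partition")
    size = n_samples // k
    bounds = []
    for i in range(k):
        stop = (i + 1) * size if i < k - 1 else n_samples
        bounds.append((i * size, stop))
    return CVPartition(n_samples, k, tuple(bounds), remainder=n_samples - k * size)


@dataclass
class MTRF:
    """Per-predictor basis coefficients plus fit provenance."""

    coef: np.ndarray  # (n_predictors, n_elements)
    basis: TRFBasis
    predictor_names: tuple[str, ...]
    freeze_reason: np.ndarray | None = None
    freeze_iter: np.ndarray | None = None
    err_trace: np.ndarray | None = None
    n_steps: int = 0
    pred_center: np.ndarray | None = None
    pred_scale: np.ndarray | None = None
    resp_center: float = 0.0
    resp_scale: float = 1.0

    def kernels(self) -> np.ndarray:
        """Lag-domain kernels, shape (n_predictors, n_lags)."""
        return self.basis.kernel(self.coef)


@dataclass
class FitResult:
    """Cross-validated fit of one response source set."""

    mtrf: list[MTRF]  # one averaged mTRF per source
    quality: np.ndarray  # (n_sources,)
    l1_residuals: np.ndarray
    l1_y: np.ndarray
    predicted: np.ndarray  # standardized-scale prediction, (n, n_sources)
    partition: CVPartition = field(repr=False, default=None)


def _as_matrix(predictors) -> tuple[np.ndarray, tuple[str, ...], float]:
    if isinstance(predictors, np.ndarray):
        X = np.atleast_2d(predictors.T).T
        names = tuple(f"x{i}" for i in range(X.shape[1]))
        return X, names, 0.0
    tracks = list(predictors)
    fs = tracks[0].fs
    for t in tracks:
        if t.fs != fs or len(t) != len(tracks[0]):
            raise ValueError("predictor tracks must share rate and length")
    X = np.column_stack([t.values for t in tracks])
    names = tuple(t.name for t in tracks)
    return X, names, fs


def _segment_designs(
    Xs: np.ndarray, basis: TRFBasis, partition: CVPartition
) -> list[np.ndarray]:
    """Per-segment stacked design (len_seg, P*M), predictor-major columns."""
    designs = []
    for lo, hi in partition.bounds:
        cols = [build_design(Xs[lo:hi, p], basis) for p in range(Xs.shape[1])]
        designs.append(np.concatenate(cols, axis=1))
    return designs


def _csc(parts: list[np.ndarray]):
    m = sparse.csc_matrix(np.concatenate(parts, axis=0) if len(parts) > 1 else parts[0])
    return m.data, m.indices.astype(np.int64), m.indptr.astype(np.int64)


def boost_fit(
    predictors,
    response: np.ndarray,
    train_segments: tuple[int, int],
    validation_segment: int,
    basis: TRFBasis,
    step: float = DEFAULT_STEP,
    partition: CVPartition | None = None,
) -> MTRF:
    """Single boosting run on explicit train/validation segments.

    Predictors and response are standardized internally; the step is in
    units of the standardized response scale.  Mostly useful directly in
    tests - `cross_validated_fit` drives the full protocol.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    X, names, _ = _as_matrix(predictors)
    P = X.shape[1]
    Xs = np.empty_like(X)
    centers = np.empty(P)
    scales = np.empty(P)
    for p in range(P):
        Xs[:, p], centers[p], scales[p] = standardize(X[:, p])
    ys, yc, ysc = standardize(np.asarray(response, dtype=float))
    if partition is None:
        partition = make_cv_partition(len(ys))
    designs = _segment_designs(Xs, basis, partition)
    M = basis.n_elements
    coord_pred = np.repeat(np.arange(P, dtype=np.int64), M)
    tr = [designs[i] for i in train_segments]
    ytr = np.concatenate([ys[slice(*partition.bounds[i])] for i in train_segments])
    yva = ys[slice(*partition.bounds[validation_segment])]
    td, ti, tp = _csc(tr)
    vd, vi, vp = _csc([designs[validation_segment]])
    coef, reason, fiter, trace, n_it = _boost_kernel(
        td, ti, tp, ytr, vd, vi, vp, yva, step, coord_pred, P, 2_000_000
    )
    return MTRF(
        coef=coef.reshape(P, M),
        basis=basis,
        predictor_names=names,
        freeze_reason=reason,
        freeze_iter=fiter,
        err_trace=trace,
        n_steps=n_it,
        pred_center=centers,
        pred_scale=scales,
        resp_center=yc,
        resp_scale=ysc,
    )


def cross_validated_fit(
    predictors,
    response: np.ndarray,
    k: int = 4,
    step: float = DEFAULT_STEP,
    basis: TRFBasis | None = None,
) -> FitResult:
    """Fourfold cross-validated boosting fit; deterministic given inputs.

    ``response`` may be 1-D (one source) or ``(n, n_sources)``.  Designs
    are shared across sources; every source is fit independently, exactly
    as each virtual source dipole is in the source-space analysis.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    X, names, fs = _as_matrix(predictors)
    if basis is None:
        basis = make_basis(fs=fs if fs > 0 else 100.0)
    Y = np.asarray(response, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, S = Y.shape
    if len(X) != n:
        raise ValueError("predictors and response must have equal length")
    P = X.shape[1]
    M = basis.n_elements
    Xs = np.empty_like(X)
    centers = np.empty(P)
    scales = np.empty(P)
    for p in range(P):
        Xs[:, p], centers[p], scales[p] = standardize(X[:, p])
    partition = make_cv_partition(n, k)
    designs = _segment_designs(Xs, basis, partition)
    coord_pred = np.repeat(np.arange(P, dtype=np.int64), M)

    # CSC caches shared across sources
    pair_csc: dict[tuple[int, int], tuple] = {}
    seg_csc = [_csc([designs[i]]) for i in range(k)]
    for test in range(k):
        for train, _ in partition.rotations(test):
            if train not in pair_csc:
                pair_csc[train] = _csc([designs[train[0]], designs[train[1]]])

    mtrfs: list[MTRF] = []
    quality = np.empty(S)
    l1_res = np.empty(S)
    l1_y = np.empty(S)
    predicted = np.empty((n, S))
    for s in range(S):
        ys, yc, ysc = standardize(Y[:, s])
        fold_coefs = []
        for test in range(k):
            run_coefs = []
            for train, val in partition.rotations(test):
                ytr = np.concatenate(
                    [ys[slice(*partition.bounds[i])] for i in train]
                )
                yva = ys[slice(*partition.bounds[val])]
                td, ti, tp = pair_csc[train]
                vd, vi, vp = seg_csc[val]
                coef, *_ = _boost_kernel(
                    td, ti, tp, ytr, vd, vi, vp, yva,
                    step, coord_pred, P, 2_000_000,
                )
                run_coefs.append(coef)
            fold_coef = np.mean(run_coefs, axis=0)
            fold_coefs.append(fold_coef)
            lo, hi = partition.bounds[test]
            predicted[lo:hi, s] = designs[test] @ fold_coef
        resid = ys - predicted[:, s]
        l1_res[s] = np.abs(resid).sum()
        l1_y[s] = np.abs(ys).sum()
        quality[s] = 1.0 - l1_res[s] / l1_y[s]
        mtrfs.append(
            MTRF(
                coef=np.mean(fold_coefs, axis=0).reshape(P, M),
                basis=basis,
                predictor_names=names,
                pred_center=centers,
                pred_scale=scales,
                resp_center=yc,
                resp_scale=ysc,
            )
        )
    return FitResult(
        mtrf=mtrfs,
        quality=quality,
        l1_residuals=l1_res,
        l1_y=l1_y,
        predicted=predicted,
        partition=partition,
    )


def quality_index(y: np.ndarray, y_pred: np.ndarray) -> float:
    """``1 - l1(residuals)/l1(y)``; 1 for perfect prediction, 0 for null."""
    y = np.asarray(y, dtype=float)
    denom = np.abs(y).sum()
    if denom == 0:
        raise ValueError("response is identically zero")
    return 1.0 - np.abs(y - y_pred).sum() / denom


def predict(mtrf: MTRF, predictors) -> np.ndarray:
    """Predicted response (standardized scale) for new predictor tracks.

    Tracks are standardized with the mTRF's recorded centers/scales; the
    prediction is the sum over predictors of the kernel convolutions.
    """
    X, names, fs = _as_matrix(predictors)
    if X.shape[1] != mtrf.coef.shape[0]:
        raise ValueError("predictor count does not match the mTRF")
    if fs > 0 and fs != mtrf.basis.fs:
        raise ValueError("track rate does not match the mTRF basis")
    out = np.zeros(len(X))
    for p in range(X.shape[1]):
        xs = (X[:, p] - mtrf.pred_center[p]) / mtrf.pred_scale[p]
        D = build_design(xs, mtrf.basis)
        out += D @ mtrf.coef[p]
    return out


def model_improvement(
    full_predictors,
    reduced_predictors,
    response: np.ndarray,
    k: int = 4,
    step: float = DEFAULT_STEP,
    basis: TRFBasis | None = None,
) -> np.ndarray:
    """Per-source quality-index gain of the full over the reduced model.

    Both fits share the partition (determined by the series length), the
    basis, and the step, so the difference isolates the omitted
    predictor(s).  The reduced predictor set must be a subset of the full
    set (matched by track name).
    """
    Xf, names_f, _ = _as_matrix(full_predictors)
    Xr, names_r, _ = _as_matrix(reduced_predictors)
    if not set(names_r) <= set(names_f):
        raise ValueError("reduced predictor set must be a subset of the full set")
    if len(names_r) == len(names_f):
        Y = np.asarray(response, dtype=float)
        S = 1 if Y.ndim == 1 else Y.shape[1]
        return np.zeros(S)
    full = cross_validated_fit(full_predictors, response, k, step, basis)
    red = cross_validated_fit(reduced_predictors, response, k, step, basis)
    return full.quality - red.quality
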