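"""Variance-stabilizing normalization of raw intensity matrices.

A simplified array-affine calibration followed by the generalized-log
transform, plus a quantile-normalization alternative. Probe-level
summarization and background correction are out of scope; calibration
operates on probeset summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from coosig.datatypes import NORMALIZED, RAW, ExpressionMatrix

DEFAULT_TRIM = 0.10


def glog_transform(y, c: float):
    """Generalized-log transform log2((y + sqrt(y^2 + c)) / 2).

    Strictly increasing in ``y``, defined for y <= 0, and asymptotically
    equal to log2(y) for large y.
    """
    if c <= 0:
        raise ValueError(f"glog offset c must be positive, got {c}")
    y = np.asarray(y, dtype=float)
    out = np.log2((y + np.sqrt(y * y + c)) / 2.0)
    return out if out.ndim else float(out)


def glog_inverse(z, c: float):
    """Inverse of :func:`glog_transform`: y = 2^z - c / (4 * 2^z)."""
    if c <= 0:
        raise ValueError(f"glog offset c must be positive, got {c}")
    z = np.asarray(z, dtype=float)
    w = np.exp2(z)
    out = w - c / (4.0 * w)
    return out if out.ndim else float(out)


@dataclass
class NormalizationModel:
    """Per-array affine calibration (offset, scale) plus a glog offset."""

    offsets: np.ndarray  # a_s, one per array
    scales: np.ndarray  # b_s > 0, one per array
    glog_c: float

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if np.any(self.scales <= 0):
            raise ValueError("per-array scales must be positive")
        if self.glog_c <= 0:
            raise ValueError("glog offset must be positive")

    def apply(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        """Calibrate each array and glog-transform; flags output normalized."""
        if len(self.offsets) != matrix.n_samples:
            raise ValueError("model was fitted on a different number of arrays")
        calibrated = (matrix.values - self.offsets[None, :]) / self.scales[None, :]
        transformed = glog_transform(calibrated, self.glog_c)
        return ExpressionMatrix(
            probeset_ids=list(matrix.probeset_ids),
            sample_ids=list(matrix.sample_ids),
            values=transformed,
            scale=NORMALIZED,
            annotation=dict(matrix.annotation),
        )


def _estimate_glog_offset(xs: np.ndarray) -> float:
    """Glog offset c = (additive noise sd / multiplicative noise sd)^2.

    Estimated from rank-matched rows after a crude median-scale alignment:
    between-array spread at low intensity gives the additive component,
    relative spread at high intensity the multiplicative one. This is the
    offset at which the glog transform stabilizes variance under an
    additive-plus-multiplicative error model.
    """
    med = np.median(xs, axis=0)
    med = np.where(med == 0, 1.0, med)
    aligned = xs / (med / med.mean())[None, :]
    row_mean = aligned.mean(axis=1)
    row_var = aligned.var(axis=1, ddof=1)
    lo = row_mean <= np.quantile(row_mean, 0.25)
    hi = row_mean >= np.quantile(row_mean, 0.75)
    add_var = float(np.mean(row_var[lo]))
    mult_var = float(np.mean(row_var[hi] / np.maximum(row_mean[hi], 1e-12) ** 2))
    if mult_var <= 0 or add_var <= 0:
        # degenerate (e.g. replicate-free or identical arrays): any positive
        # offset gives a monotone transform; use a scale-based default
        return float(np.median(row_mean) ** 2 + 1.0)
    return add_var / mult_var


def _trimmed_spread(values: np.ndarray, trim: float) -> float:
    # mean squared deviation from the row mean, keeping the (1-trim) rows
    # with smallest deviation — least-trimmed-sum flavour
    dev = values - values.mean(axis=1, keepdims=True)
    row_ss = (dev * dev).sum(axis=1)
    keep = max(1, int(np.ceil(len(row_ss) * (1.0 - trim))))
    return float(np.sort(row_ss)[:keep].sum())


def fit_vsn_calibration(
    matrix: ExpressionMatrix,
    trim: float = DEFAULT_TRIM,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> NormalizationModel:
    """Fit per-array affine calibration for the glog transform.

    Rank-matches rows across arrays (quantile alignment), then iteratively
    chooses per-array (offset, scale) to minimize the trimmed between-array
    spread of the glog-transformed values. Deterministic.
    """
    if matrix.scale != RAW:
        raise ValueError("calibration expects a raw-scale matrix")
    if matrix.n_samples < 2:
        raise ValueError("calibration requires at least 2 arrays")
    x = matrix.values
    if np.any(np.ptp(x, axis=0) == 0):
        raise ValueError("constant array encountered; cannot calibrate")

    # rank-match: sort each column so row r holds each array's r-th order
    # statistic — robust correspondence without assuming shared row effects
    xs = np.sort(x, axis=0)
    n_arrays = x.shape[1]
    c = _estimate_glog_offset(xs)

    offsets = np.quantile(xs, 0.05, axis=0).astype(float) * 0.0  # start at zero
    scales = np.maximum(xs.std(axis=0) / xs.std(axis=0).mean(), 1e-9)

    def transformed(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return glog_transform((xs - a[None, :]) / b[None, :], c)

    prev = _trimmed_spread(transformed(offsets, scales), trim)
    for _ in range(max_iter):
        ref = np.median(transformed(offsets, scales), axis=1)
        ref_lin = glog_inverse(ref, c)
        for s in range(n_arrays):
            # least squares on the glog-inverse scale: x_s ≈ a_s + b_s * ref
            A = np.column_stack([np.ones_like(ref_lin), ref_lin])
            resid_w = np.ones(len(ref_lin))
            for _inner in range(3):
                W = resid_w[:, None]
                coef, *_ = np.linalg.lstsq(A * W, xs[:, s] * resid_w, rcond=None)
                resid = xs[:, s] - A @ coef
                cut = np.quantile(np.abs(resid), 1.0 - trim)
                resid_w = (np.abs(resid) <= cut).astype(float)
            a_s, b_s = coef
            if b_s > 1e-9:
                offsets[s], scales[s] = a_s, b_s
        # fix the overall gauge: mean offset 0-centered scale geometric mean 1
        gm = np.exp(np.mean(np.log(scales)))
        scales /= gm
        cur = _trimmed_spread(transformed(offsets, scales), trim)
        if abs(prev - cur) < tol * (1.0 + abs(prev)):
            break
        prev = cur

    return NormalizationModel(offsets=offsets, scales=scales, glog_c=c)


def vsn_normalize(matrix: ExpressionMatrix, trim: float = DEFAULT_TRIM) -> ExpressionMatrix:
    """Convenience: fit calibration on ``matrix`` and apply it."""
    return fit_vsn_calibration(matrix, trim=trim).apply(matrix)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column to the mean order-statistic distribution; ties averaged."""
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 arrays")
    x = matrix.values
    if not np.all(np.isfinite(x)):
        raise ValueError("missing values not supported")
    order = np.argsort(x, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(x.shape[0])
    for j in range(x.shape[1]):
        ranks[order[:, j], j] = rows
    target = np.sort(x, axis=0).mean(axis=1)
    out = target[ranks]
    # average target values over tied input entries within each column
    for j in range(x.shape[1]):
        col = x[:, j]
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if np.any(counts > 1):
            sums = np.zeros(len(uniq))
            np.add.at(sums, inv, out[:, j])
            out[:, j] = (sums / counts)[inv]
    return ExpressionMatrix(
        probeset_ids=list(matrix.probeset_ids),
        sample_ids=list(matrix.sample_ids),
        values=out,
        scale=matrix.scale,
        annotation=dict(matrix.annotation),
    )
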