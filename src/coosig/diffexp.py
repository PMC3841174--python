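"""Paired differential expression with empirical-Bayes moderation.

Pipeline: estimate a consensus intra-block (patient) correlation, fit each
gene by generalized least squares under that correlation, shrink the
per-gene variances toward a scaled-F prior (d0, s0^2) estimated by
digamma/trigamma moment matching, and adjust p-values by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from coosig.datatypes import CorrelationEstimate, ExpressionMatrix, SampleDesign

FNE_UP = "FNE-up"
OCE_UP = "OCE-up"

_CLAMP = 0.99
_TRIM = 0.15


def estimate_consensus_correlation(
    matrix: ExpressionMatrix, design: SampleDesign
) -> CorrelationEstimate:
    """Consensus intra-patient residual correlation across genes.

    Per gene, residuals after removing cell-type means are cross-multiplied
    over same-block sample pairs and normalized by the residual sum of
    squares of the samples involved, giving a per-gene correlation in
    [-1, 1]. The per-gene values are atanh-transformed, 15%-trimmed-mean
    averaged, and mapped back by tanh; the consensus is clamped to
    (-0.99, 0.99).
    """
    if matrix.sample_ids != design.sample_ids:
        raise ValueError("matrix samples and design samples must match in order")
    blocks = design.blocks()
    usable = {b: idx for b, idx in blocks.items() if len(idx) >= 2}
    if len(usable) < 2:
        raise ValueError("need at least 2 patient blocks with >= 2 samples each")

    x = matrix.values
    ct = np.asarray(design.cell_types)
    resid = x.copy()
    for level in np.unique(ct):
        cols = ct == level
        resid[:, cols] -= resid[:, cols].mean(axis=1, keepdims=True)

    pair_i: list[int] = []
    pair_j: list[int] = []
    for idx in usable.values():
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                pair_i.append(idx[a])
                pair_j.append(idx[b])
    members = sorted(set(pair_i) | set(pair_j))

    cross = (resid[:, pair_i] * resid[:, pair_j]).sum(axis=1)
    ss = (resid[:, members] ** 2).sum(axis=1)
    ok = ss > 0
    if not np.any(ok):
        raise ValueError("all blocks degenerate: zero residual variation")
    r = np.clip(2.0 * cross[ok] / ss[ok], -0.999999, 0.999999)
    z = np.arctanh(r)
    consensus = float(np.tanh(stats.trim_mean(z, _TRIM)))
    consensus = float(np.clip(consensus, -_CLAMP, _CLAMP))
    return CorrelationEstimate(consensus=consensus, atanh_correlations=z)


@dataclass
class PairedGLSFit:
    """Per-gene paired-contrast fits: effect, unscaled variance, residual variance."""

    probeset_ids: list[str]
    beta: np.ndarray  # FNE minus OCE contrast per gene
    unscaled_var: float  # v_g, identical across genes for a shared design
    s2: np.ndarray  # residual variance per gene
    df_residual: int  # d_g, identical across genes
    correlation: float


def _design_matrix(design: SampleDesign) -> np.ndarray:
    fne = np.asarray([1.0 if c == "FNE" else 0.0 for c in design.cell_types])
    return np.column_stack([np.ones(design.n_samples), fne])


def _block_covariance(design: SampleDesign, rho: float) -> np.ndarray:
    n = design.n_samples
    v = np.eye(n)
    for idx in design.blocks().values():
        for a in range(len(idx)):
            for b in range(len(idx)):
                if a != b:
                    v[idx[a], idx[b]] = rho
    return v


def fit_paired_gls(
    matrix: ExpressionMatrix, design: SampleDesign, rho: float
) -> PairedGLSFit:
    """Generalized least squares per gene with intra-block correlation ``rho``.

    Covariance is the identity except ``rho`` between same-block samples;
    the reported effect is the FNE-minus-OCE contrast. With ``rho = 0`` this
    reduces to the ordinary difference of cell-type means.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError(f"correlation must lie in (-1, 1), got {rho}")
    if matrix.sample_ids != design.sample_ids:
        raise ValueError("matrix samples and design samples must match in order")
    X = _design_matrix(design)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("singular design: cell-type contrast not estimable")
    V = _block_covariance(design, rho)
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    XtVinvX = XtVinv @ X
    coef_cov = np.linalg.inv(XtVinvX)
    hat = coef_cov @ XtVinv  # (p, n): maps y -> beta-hat

    Y = matrix.values  # (genes, n)
    betas = Y @ hat.T  # (genes, p)
    fitted = betas @ X.T
    resid = Y - fitted
    df = design.n_samples - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    # GLS residual quadratic form per gene
    s2 = np.einsum("gi,ij,gj->g", resid, Vinv, resid) / df
    contrast = np.array([0.0, 1.0])
    v_g = float(contrast @ coef_cov @ contrast)
    return PairedGLSFit(
        probeset_ids=list(matrix.probeset_ids),
        beta=betas[:, 1],
        unscaled_var=v_g,
        s2=np.maximum(s2, 0.0),
        df_residual=df,
        correlation=rho,
    )


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 200) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection."""
    if y <= 0:
        return np.inf
    lo, hi = 1e-8, 1e8
    while special.polygamma(1, lo) < y:
        lo /= 10.0
        if lo < 1e-300:
            return lo
    while special.polygamma(1, hi) > y:
        hi *= 10.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * (1.0 + lo):
            break
    return 0.5 * (lo + hi)


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled-F variance prior by moment matching.

    Matches the mean and variance of log(s^2) to the scaled-F model using
    digamma/trigamma identities; returns ``d0 = inf`` when the observed
    spread of log variances is no larger than the sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10:
        raise ValueError("need at least 10 genes to estimate the variance prior")
    # guard zero variances (limma offsets log by a tiny amount similarly)
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_bar))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0sq = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def moderate_statistics(
    fit: PairedGLSFit, annotation: dict[str, str] | None = None
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-statistics and BH-adjusted p-values.

    Returns a table with columns probeset_id, symbol, log2fc, s2, df,
    d0, s0sq, s2_moderated, t_moderated, p_value, q_value, direction.
    """
    d = fit.df_residual
    d0, s0sq = estimate_variance_prior(fit.s2, d)
    if np.isinf(d0):
        s2_mod = np.full_like(fit.s2, s0sq)
        df_total = np.inf
    else:
        s2_mod = (d0 * s0sq + d * fit.s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_mod * fit.unscaled_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, fit.beta / se, np.sign(fit.beta) * np.inf)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    q = bh_adjust(p)
    annotation = annotation or {}
    symbols = [annotation.get(pid) for pid in fit.probeset_ids]
    return pd.DataFrame(
        {
            "probeset_id": fit.probeset_ids,
            "symbol": symbols,
            "log2fc": fit.beta,
            "s2": fit.s2,
            "df": d,
            "d0": d0,
            "s0sq": s0sq,
            "s2_moderated": s2_mod,
            "t_moderated": t_mod,
            "p_value": p,
            "q_value": q,
            "direction": np.where(fit.beta >= 0, FNE_UP, OCE_UP),
        }
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [p, 1])."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def run_paired_diffexp(
    matrix: ExpressionMatrix, design: SampleDesign
) -> tuple[pd.DataFrame, CorrelationEstimate]:
    """Full differential-expression pass: correlation, GLS, moderation, FDR."""
    corr = estimate_consensus_correlation(matrix, design)
    fit = fit_paired_gls(matrix, design, corr.consensus)
    table = moderate_statistics(fit, matrix.annotation)
    return table, corr


def rank_de_table(table: pd.DataFrame) -> pd.DataFrame:
    """Total order for 'most highly significant': ascending p, then
    descending |moderated t|, then probeset id."""
    key = table.assign(_abs_t=lambda t: -t["t_moderated"].abs())
    return table.loc[
        key.sort_values(["p_value", "_abs_t", "probeset_id"], kind="stable").index
    ]
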