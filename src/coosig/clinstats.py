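"""Hypothesis tests linking the classification to clinical variables.

Includes the tie-corrected Mann-Whitney variant (normal approximation,
no continuity correction) used for the small two-group count tables,
Fisher's exact test, proportional-odds ordinal association, Welch's t,
the log-rank test, Cox proportional-hazards regression (Efron ties), and
the permuted-signature null ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from coosig.datatypes import FT_LIKE, ClinicalTable, ExpressionMatrix
from coosig.mixture import DegenerateMixtureError, fit_two_component_mixture
from coosig.signature import random_signature, score_samples


@dataclass
class AssociationReport:
    """One test's outcome: statistic, p-value, group sizes, optional extras."""

    test: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    df: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


def mann_whitney_tiecorrected(group_a, group_b) -> AssociationReport:
    """Two-sided Mann-Whitney test, tie-corrected normal approximation.

    U is computed from midranks; the null variance is
    ``(n1*n2/12) * ((N+1) - sum(t^3 - t) / (N*(N-1)))`` where t runs over
    tie-group sizes. No continuity correction is applied.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    assert abs((u1 + u2) - n1 * n2) < 1e-9

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n_total * (n_total - 1))
    var_u = (n1 * n2 / 12.0) * ((n_total + 1) - tie_term)
    if var_u <= 0:
        warnings.warn("all values tied: Mann-Whitney variance is zero; p = 1")
        return AssociationReport(
            test="mann_whitney",
            statistic=float(u1),
            p_value=1.0,
            group_sizes=(n1, n2),
            extras={"z": 0.0},
        )
    z = (u1 - n1 * n2 / 2.0) / np.sqrt(var_u)
    p = 2.0 * stats.norm.sf(abs(z))
    return AssociationReport(
        test="mann_whitney",
        statistic=float(u1),
        p_value=float(min(p, 1.0)),
        group_sizes=(n1, n2),
        extras={"z": float(z), "var_u": float(var_u)},
    )


_FISHER_ENUM_LIMIT = 10**6


def fisher_exact(
    table,
    mc_iterations: int = 100_000,
    seed: int = 0,
    force_monte_carlo: bool = False,
) -> AssociationReport:
    """Fisher's exact test for a 2xK contingency table.

    2x2 tables use the exact hypergeometric two-sided p (sum of tables at
    least as extreme). Larger tables are enumerated exactly when the
    enumeration cost is below 10^6 tables, otherwise a seeded Monte-Carlo
    p over tables sampled with fixed margins is returned.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2xK table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("empty margin in contingency table")
    row_sizes = tuple(int(x) for x in t.sum(axis=1))
    if t.shape[1] == 2:
        _, p = stats.fisher_exact(t, alternative="two-sided")
        return AssociationReport(
            test="fisher_exact", statistic=float(t[0, 0]), p_value=float(p),
            group_sizes=row_sizes,
        )

    col_sums = t.sum(axis=0)
    row_sums = t.sum(axis=1)
    n = int(t.sum())

    def log_prob(first_row: np.ndarray) -> float:
        second = col_sums - first_row
        if np.any(second < 0):
            return -np.inf
        lp = (
            gammaln(row_sums + 1).sum()
            + gammaln(col_sums + 1).sum()
            - gammaln(n + 1)
            - gammaln(first_row + 1).sum()
            - gammaln(second + 1).sum()
        )
        return float(lp)

    # enumeration cost ~ product over cols of (min(row0, col) + 1)
    cost = int(np.prod([min(row_sums[0], c) + 1 for c in col_sums]))
    obs_lp = log_prob(t[0])
    if cost <= _FISHER_ENUM_LIMIT and not force_monte_carlo:
        total = 0.0
        extreme = 0.0

        def recurse(col: int, remaining: int, prefix: list[int]) -> None:
            nonlocal total, extreme
            if col == len(col_sums) - 1:
                if remaining > col_sums[col]:
                    return
                row = np.array(prefix + [remaining])
                lp = log_prob(row)
                pr = np.exp(lp)
                total += pr
                if lp <= obs_lp + 1e-9:
                    extreme += pr
                return
            for v in range(min(remaining, col_sums[col]) + 1):
                recurse(col + 1, remaining - v, prefix + [v])

        recurse(0, int(row_sums[0]), [])
        p = extreme / total
        method = "enumeration"
    else:
        rng = np.random.default_rng(seed)
        # sample tables with fixed margins by permuting column memberships
        pool = np.repeat(np.arange(len(col_sums)), col_sums)
        hits = 0
        for _ in range(mc_iterations):
            rng.shuffle(pool)
            first = np.bincount(pool[: row_sums[0]], minlength=len(col_sums))
            if log_prob(first) <= obs_lp + 1e-9:
                hits += 1
        p = (hits + 1) / (mc_iterations + 1)
        method = "monte_carlo"
    return AssociationReport(
        test="fisher_exact",
        statistic=float(t[0, 0]),
        p_value=float(min(p, 1.0)),
        group_sizes=row_sizes,
        extras={"method": method},
    )


def proportional_odds_assoc(outcome, group) -> AssociationReport:
    """Proportional-odds (ordinal logistic) association of an ordinal outcome
    with a binary class; p from the 1-df likelihood-ratio test against the
    intercept-only model."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    y = pd.Series(outcome).reset_index(drop=True)
    g = pd.Series(group).reset_index(drop=True)
    keep = y.notna() & g.notna()
    y, g = y[keep], g[keep]
    levels = np.sort(y.unique())
    if len(levels) < 2:
        raise ValueError("outcome needs at least 2 observed levels")
    classes = np.sort(g.unique())
    if len(classes) != 2:
        raise ValueError("group must be binary with both classes present")
    x = (g == classes[1]).astype(float).to_numpy()[:, None]
    y_codes = pd.Categorical(y, categories=levels, ordered=True).codes

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(y_codes, x, distr="logit")
        try:
            res = model.fit(method="bfgs", maxiter=500, disp=False)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            res = model.fit(method="nm", maxiter=2000, disp=False)
            converged = False
    llf_full = float(res.llf)
    counts = np.bincount(y_codes, minlength=len(levels))
    llf_null = float(np.sum(counts[counts > 0] * np.log(counts[counts > 0] / counts.sum())))
    lrt = max(0.0, 2.0 * (llf_full - llf_null))
    p = float(stats.chi2.sf(lrt, df=1))
    extras = {"log_odds": float(res.params[0]), "converged": converged}
    if not converged:
        warnings.warn("proportional-odds fit did not fully converge (possible separation)")
    return AssociationReport(
        test="proportional_odds_lrt",
        statistic=lrt,
        p_value=p,
        group_sizes=(int((g == classes[0]).sum()), int((g == classes[1]).sum())),
        df=1,
        extras=extras,
    )


def welch_t(group_a, group_b) -> AssociationReport:
    """Welch's unequal-variance two-sided t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    df = float(res.df)
    return AssociationReport(
        test="welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=(a.size, b.size),
        df=df,
    )


def logrank_test(times, events, groups) -> AssociationReport:
    """Two-group log-rank test: chi-square from observed-minus-expected
    events with hypergeometric variance at each distinct event time."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("log-rank test requires exactly 2 groups")
    if e.sum() == 0:
        warnings.warn("no events observed; log-rank p = 1")
        return AssociationReport(
            test="logrank", statistic=0.0, p_value=1.0,
            group_sizes=(int((g == labels[0]).sum()), int((g == labels[1]).sum())), df=1,
        )
    in1 = g == labels[1]
    o_minus_e = 0.0
    var = 0.0
    for tt in np.unique(t[e == 1]):
        at_risk = t >= tt
        n_risk = at_risk.sum()
        n1_risk = (at_risk & in1).sum()
        d = int(((t == tt) & (e == 1)).sum())
        d1 = int(((t == tt) & (e == 1) & in1).sum())
        o_minus_e += d1 - d * n1_risk / n_risk
        if n_risk > 1:
            var += (
                d
                * (n1_risk / n_risk)
                * (1 - n1_risk / n_risk)
                * (n_risk - d)
                / (n_risk - 1)
            )
    if var == 0:
        chi2 = 0.0
        p = 1.0
    else:
        chi2 = o_minus_e**2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    return AssociationReport(
        test="logrank",
        statistic=float(chi2),
        p_value=p,
        group_sizes=(int((~in1).sum()), int(in1.sum())),
        df=1,
        extras={"o_minus_e": float(o_minus_e), "variance": float(var)},
    )


def cox_score_test_binary(times, events, group) -> AssociationReport:
    """Cox partial-likelihood score test at beta = 0 for one binary covariate
    (Breslow form; equals the log-rank statistic in the absence of ties)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(group, dtype=float)
    u = 0.0
    info = 0.0
    for tt in np.unique(t[e == 1]):
        at_risk = t >= tt
        xbar = x[at_risk].mean()
        d_mask = (t == tt) & (e == 1)
        d = int(d_mask.sum())
        u += x[d_mask].sum() - d * xbar
        info += d * (np.mean(x[at_risk] ** 2) - xbar**2)
    chi2 = u**2 / info if info > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if info > 0 else 1.0
    return AssociationReport(
        test="cox_score_binary", statistic=float(chi2), p_value=p,
        group_sizes=(int((x == 0).sum()), int((x == 1).sum())), df=1,
    )


def cox_ph(
    times, events, covariates: pd.DataFrame, duration_name: str = "time"
) -> pd.DataFrame:
    """Cox proportional-hazards regression (Efron ties, Newton-Raphson).

    Returns one row per covariate: coefficient, hazard ratio, standard
    error, Wald z and p. Warns on monotone likelihood (e.g. no events in a
    class).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceWarning

    df = covariates.copy().reset_index(drop=True)
    df[duration_name] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=int)
    if df["_event"].sum() < 1:
        raise ValueError("Cox regression requires at least one event")
    fitter = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("always", ConvergenceWarning)
        fitter.fit(df, duration_col=duration_name, event_col="_event")
    summary = fitter.summary
    return pd.DataFrame(
        {
            "covariate": summary.index,
            "coef": summary["coef"].to_numpy(),
            "hazard_ratio": summary["exp(coef)"].to_numpy(),
            "se": summary["se(coef)"].to_numpy(),
            "z": summary["z"].to_numpy(),
            "p_value": summary["p"].to_numpy(),
        }
    ).reset_index(drop=True)


def kaplan_meier_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier survival-curve coordinates (time, survival, at-risk)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    rows = [(0.0, 1.0, int(t.size))]
    surv = 1.0
    for tt in np.unique(t[e == 1]):
        n_risk = int((t >= tt).sum())
        d = int(((t == tt) & (e == 1)).sum())
        surv *= 1.0 - d / n_risk
        rows.append((float(tt), surv, n_risk))
    return pd.DataFrame(rows, columns=["time", "survival", "n_at_risk"])


@dataclass
class PermutationNullResult:
    """Per-permutation association p-values under random signatures."""

    n_permutations: int
    p_values: pd.DataFrame  # one row per permutation, one column per test
    alpha: float
    n_failures: int = 0

    @property
    def fraction_significant(self) -> dict[str, float]:
        if self.p_values.empty:
            return {}
        return {
            col: float((self.p_values[col] < self.alpha).mean())
            for col in self.p_values.columns
        }


def _class_vector(labels) -> np.ndarray:
    return np.asarray([1 if lab == FT_LIKE else 0 for lab in labels])


def associate_clinical(
    labels, clinical: ClinicalTable, mc_iterations: int = 100_000, seed: int = 0
) -> dict[str, AssociationReport]:
    """Grade/stage by proportional-odds LRT; subtype by Fisher's exact test."""
    cls = _class_vector(labels)
    df = clinical.table
    out: dict[str, AssociationReport] = {}
    for col in ("grade", "stage"):
        vals = df[col]
        if vals.notna().sum() and vals.dropna().nunique() >= 2:
            out[col] = proportional_odds_assoc(vals, pd.Series(cls))
    sub = df["subtype"]
    if sub.notna().any():
        keep = sub.notna()
        levels = sorted(sub[keep].unique())
        table = np.array(
            [
                [int(((cls == c) & keep & (sub == lv)).sum()) for lv in levels]
                for c in (0, 1)
            ]
        )
        cols_ok = table.sum(axis=0) > 0
        table = table[:, cols_ok]
        if table.shape[1] >= 2 and np.all(table.sum(axis=1) > 0):
            out["subtype"] = fisher_exact(table, mc_iterations=mc_iterations, seed=seed)
    return out


def permutation_signature_null(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    k_per_direction: int,
    n_permutations: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> PermutationNullResult:
    """Null ensemble: random signatures scored, mixture-classified, and
    associated with grade/stage/subtype; reports each permutation's
    p-values and the fraction reaching p < alpha. Stage failures are
    counted, not fatal."""
    if n_permutations < 0:
        raise ValueError("n_permutations must be non-negative")
    clinical = clinical.aligned_to(matrix.sample_ids)
    rng = np.random.default_rng(seed)
    rows = []
    failures = 0
    for i in range(n_permutations):
        try:
            sig = random_signature(
                matrix.probeset_ids, matrix.annotation, k_per_direction, rng
            )
            scores = score_samples(matrix, sig)
            model = fit_two_component_mixture(
                scores.scores, variance_mode="shared", seed=int(rng.integers(2**31))
            )
            reports = associate_clinical(
                model.labels, clinical, seed=int(rng.integers(2**31))
            )
            rows.append({name: rep.p_value for name, rep in reports.items()})
        except (ValueError, DegenerateMixtureError, RuntimeError):
            failures += 1
    p_values = pd.DataFrame(rows)
    return PermutationNullResult(
        n_permutations=n_permutations,
        p_values=p_values,
        alpha=alpha,
        n_failures=failures,
    )
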