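"""Two-component 1-D Gaussian mixture for tumor stratification.

EM with seeded restarts; the component with the larger mean is labeled
FT-like. Under ``variance_mode="auto"`` both the shared- and
separate-variance families are fitted and the lower BIC wins.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from coosig.datatypes import FT_LIKE, OV_LIKE, MixtureModel

_TOL = 1e-8
_MAX_ITER = 1000
_N_RESTARTS = 10
_MIN_SD_FRACTION = 1e-6


class DegenerateMixtureError(RuntimeError):
    """Raised when every EM restart collapses."""


_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _npdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    # inline normal pdf: scipy's call overhead dominates tight EM loops
    z = (x - mu) / sd
    return _INV_SQRT_2PI / sd * np.exp(-0.5 * z * z)


def _loglik(x: np.ndarray, pi: float, mu: np.ndarray, sd: np.ndarray) -> float:
    dens = (1.0 - pi) * _npdf(x, mu[0], sd[0]) + pi * _npdf(x, mu[1], sd[1])
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def _em_once(
    x: np.ndarray,
    pi: float,
    mu: np.ndarray,
    sd: np.ndarray,
    shared_variance: bool,
    min_sd: float,
) -> tuple[float, np.ndarray, np.ndarray, float, int]:
    ll = _loglik(x, pi, mu, sd)
    for it in range(1, _MAX_ITER + 1):
        # E step: responsibility of component 1 (the pi component)
        d0 = (1.0 - pi) * _npdf(x, mu[0], sd[0])
        d1 = pi * _npdf(x, mu[1], sd[1])
        tot = np.maximum(d0 + d1, 1e-300)
        g1 = d1 / tot
        g0 = 1.0 - g1
        n1 = g1.sum()
        n0 = g0.sum()
        if n0 < 1e-10 or n1 < 1e-10:
            raise DegenerateMixtureError("a component lost all its mass")
        pi = n1 / x.size
        mu = np.array([(g0 * x).sum() / n0, (g1 * x).sum() / n1])
        if shared_variance:
            var = float((g0 * (x - mu[0]) ** 2 + g1 * (x - mu[1]) ** 2).sum() / x.size)
            sd = np.array([np.sqrt(var)] * 2)
        else:
            v0 = float((g0 * (x - mu[0]) ** 2).sum() / n0)
            v1 = float((g1 * (x - mu[1]) ** 2).sum() / n1)
            sd = np.sqrt(np.array([v0, v1]))
        if np.any(sd < min_sd):
            raise DegenerateMixtureError("component variance collapsed")
        new_ll = _loglik(x, pi, mu, sd)
        if new_ll < ll - 1e-6 * (1.0 + abs(ll)):
            raise AssertionError("EM log-likelihood decreased")  # pragma: no cover
        if abs(new_ll - ll) < _TOL:
            ll = new_ll
            break
        ll = new_ll
    return ll, mu, sd, pi, it


def _initializations(x: np.ndarray, rng: np.random.Generator):
    spread = x.std()
    qs = [(0.25, 0.75), (0.15, 0.85), (0.35, 0.65)]
    for qlo, qhi in qs:
        yield 0.5, np.quantile(x, [qlo, qhi]), np.array([spread, spread]) * 0.7
    for _ in range(_N_RESTARTS - len(qs)):
        mu = rng.choice(x, size=2, replace=False).astype(float)
        pi = rng.uniform(0.2, 0.8)
        s = spread * rng.uniform(0.3, 1.0)
        yield pi, np.sort(mu), np.array([s, s])


def _fit_family(
    x: np.ndarray, shared_variance: bool, seed: int
) -> tuple[float, np.ndarray, np.ndarray, float, int]:
    rng = np.random.default_rng(seed)
    min_sd = max(x.std() * _MIN_SD_FRACTION, 1e-12)
    best = None
    for pi0, mu0, sd0 in _initializations(x, rng):
        try:
            result = _em_once(x, pi0, mu0.copy(), sd0.copy(), shared_variance, min_sd)
        except DegenerateMixtureError:
            continue
        if best is None or result[0] > best[0]:
            best = result
    if best is None:
        raise DegenerateMixtureError("all EM restarts collapsed")
    return best


def fit_two_component_mixture(
    scores, variance_mode: str = "auto", seed: int = 0
) -> MixtureModel:
    """Fit a two-component Gaussian mixture to 1-D score values.

    Parameters
    ----------
    scores : array-like
        At least 10 distinct values.
    variance_mode : {"shared", "separate", "auto"}
        "auto" fits both variants and keeps the lower BIC
        (BIC = -2 logL + params * log n).
    seed : int
        Seeds the random restarts; the fit is reproducible.
    """
    x = np.asarray(scores, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    if np.unique(x).size < 10:
        raise ValueError("need at least 10 distinct score values")
    if variance_mode not in ("shared", "separate", "auto"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")

    candidates = []
    modes = ["shared", "separate"] if variance_mode == "auto" else [variance_mode]
    for mode in modes:
        shared = mode == "shared"
        ll, mu, sd, pi, iters = _fit_family(x, shared, seed)
        n_params = 4 if shared else 5
        bic = -2.0 * ll + n_params * np.log(x.size)
        candidates.append((bic, mode, ll, mu, sd, pi, iters))
    bic, mode, ll, mu, sd, pi, iters = min(candidates, key=lambda c: c[0])

    # orient: FT-like is the larger-mean component
    if mu[1] >= mu[0]:
        mean_ov, mean_ft = mu[0], mu[1]
        sd_ov, sd_ft = sd[0], sd[1]
        pi_ft = pi
    else:
        mean_ov, mean_ft = mu[1], mu[0]
        sd_ov, sd_ft = sd[1], sd[0]
        pi_ft = 1.0 - pi
    if mean_ov == mean_ft:
        raise DegenerateMixtureError("components collapsed to one mean")

    d_ov = (1.0 - pi_ft) * stats.norm.pdf(x, mean_ov, sd_ov)
    d_ft = pi_ft * stats.norm.pdf(x, mean_ft, sd_ft)
    posterior = d_ft / np.maximum(d_ov + d_ft, 1e-300)
    labels = [FT_LIKE if p >= 0.5 else OV_LIKE for p in posterior]
    return MixtureModel(
        mixing_ft=float(pi_ft),
        mean_ov=float(mean_ov),
        mean_ft=float(mean_ft),
        sd_ov=float(sd_ov),
        sd_ft=float(sd_ft),
        variance_mode=mode,
        log_likelihood=float(ll),
        bic=float(bic),
        posterior=posterior,
        labels=labels,
        n_iterations=iters,
    )


def posterior_ft(model: MixtureModel, scores) -> np.ndarray:
    """Posterior probability of FT-like membership for arbitrary scores."""
    x = np.asarray(scores, dtype=float)
    d_ov = (1.0 - model.mixing_ft) * stats.norm.pdf(x, model.mean_ov, model.sd_ov)
    d_ft = model.mixing_ft * stats.norm.pdf(x, model.mean_ft, model.sd_ft)
    return d_ft / np.maximum(d_ov + d_ft, 1e-300)


def classify_samples(model: MixtureModel, scores=None) -> dict:
    """Hard labels (posterior >= 0.5) plus a subgroup summary.

    When ``scores`` is given the summary includes subgroup mean scores.
    """
    labels = np.asarray(model.labels)
    summary: dict = {
        "n_ft_like": int((labels == FT_LIKE).sum()),
        "n_ov_like": int((labels == OV_LIKE).sum()),
        "mixing_ft": model.mixing_ft,
        "variance_mode": model.variance_mode,
        "bic": model.bic,
    }
    if scores is not None:
        x = np.asarray(scores, dtype=float)
        for name, mask in ((FT_LIKE, labels == FT_LIKE), (OV_LIKE, labels == OV_LIKE)):
            key = "mean_score_ft" if name == FT_LIKE else "mean_score_ov"
            summary[key] = float(x[mask].mean()) if mask.any() else np.nan
    return {"labels": list(model.labels), "summary": summary}
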