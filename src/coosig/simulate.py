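"""Synthetic data generators with the statistical structure the pipeline assumes.

Two generators: a paired cell-line design (patients x cell types, intra-
patient correlation, planted differential expression with gene-level
variance heterogeneity drawn from a scaled inverse-chi-square so the
empirical-Bayes moderation model is exactly satisfied) and a tumor cohort
whose signature scores follow a two-component Gaussian mixture with
class-linked ordinal/categorical covariates and class-linked exponential
survival under independent uniform censoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from coosig.datatypes import (
    NORMALIZED,
    RAW,
    SUBTYPE_LEVELS,
    ClinicalTable,
    ExpressionMatrix,
    SampleDesign,
    Signature,
)


@dataclass
class CellLineSimConfig:
    n_probesets: int = 2000
    n_patients: int = 2
    intra_patient_correlation: float = 0.5
    n_de_per_direction: int = 50
    effect_size: float = 2.0  # log2 units
    variance_prior_df: float = 4.0  # d0_true
    variance_prior_scale: float = 0.05  # s0sq_true
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    n_replicates: int = 1  # arrays per patient x cell type
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probesets <= 0 or self.n_patients <= 0 or self.n_replicates <= 0:
            raise ValueError("dimensions must be positive")
        if not -1.0 < self.intra_patient_correlation < 1.0:
            raise ValueError("intra-patient correlation must lie in (-1, 1)")
        if self.n_de_per_direction < 0:
            raise ValueError("n_de_per_direction must be non-negative")
        if 2 * self.n_de_per_direction > self.n_probesets:
            raise ValueError("too many planted DE probesets for the matrix size")
        if self.variance_prior_df <= 0 or self.variance_prior_scale <= 0:
            raise ValueError("variance prior parameters must be positive")


@dataclass
class CohortSimConfig:
    n_tumors: int = 200
    mixing_proportion: float = 0.5  # P(FT-like)
    class_mean_shift: float = 1.0  # per signature probeset, log2 units
    class_sd: float = 0.5
    hazard_ratio: float = 2.0  # FT-like vs OV-like
    censoring_rate: float = 0.2
    baseline_hazard: float = 0.05
    clinical_odds: float = 3.0  # odds multiplier linking FT class to covariates
    n_extra_probesets: int = 200
    baseline_mean: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors <= 0:
            raise ValueError("n_tumors must be positive")
        if not 0.0 < self.mixing_proportion < 1.0:
            raise ValueError("mixing proportion must lie in (0, 1)")
        if self.class_sd <= 0:
            raise ValueError("class_sd must be positive")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.clinical_odds <= 0:
            raise ValueError("clinical_odds must be positive")


def simulate_paired_cell_lines(
    config: CellLineSimConfig,
) -> tuple[ExpressionMatrix, SampleDesign, pd.DataFrame]:
    """Simulate the paired two-cell-type design.

    Gene-wise true variances are drawn from a scaled inverse-chi-square
    with df ``variance_prior_df`` and scale ``variance_prior_scale``;
    within-patient residuals share correlation rho; the first
    ``n_de_per_direction`` probesets are shifted +effect_size in FNE, the
    next block +effect_size in OCE. Deterministic under the config seed.

    Returns (matrix, design, truth) where truth lists the planted DE
    probesets with their direction.
    """
    rng = np.random.default_rng(config.seed)
    n_g = config.n_probesets
    rho = config.intra_patient_correlation

    sample_ids, blocks, cell_types = [], [], []
    for p in range(config.n_patients):
        for ct in ("FNE", "OCE"):
            for r in range(config.n_replicates):
                suffix = f"_r{r + 1}" if config.n_replicates > 1 else ""
                sample_ids.append(f"{ct}_patient{p + 1}{suffix}")
                blocks.append(f"patient{p + 1}")
                cell_types.append(ct)
    design = SampleDesign(sample_ids, blocks, cell_types)
    n_s = design.n_samples

    d0, s0sq = config.variance_prior_df, config.variance_prior_scale
    sigma2 = d0 * s0sq / rng.chisquare(d0, size=n_g)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_g)
    values = np.tile(baseline[:, None], (1, n_s))

    half = config.effect_size / 2.0
    fne_cols = np.array([ct == "FNE" for ct in cell_types])
    n_de = config.n_de_per_direction
    values[:n_de, fne_cols] += half
    values[:n_de, ~fne_cols] -= half
    values[n_de : 2 * n_de, fne_cols] -= half
    values[n_de : 2 * n_de, ~fne_cols] += half

    # correlated residuals per patient block via Cholesky of the block matrix
    per_block = 2 * config.n_replicates
    block_cov = np.full((per_block, per_block), rho)
    np.fill_diagonal(block_cov, 1.0)
    chol = np.linalg.cholesky(block_cov)
    resid = np.empty((n_g, n_s))
    for idx in design.blocks().values():
        z = rng.standard_normal((n_g, len(idx)))
        resid[:, idx] = z @ chol.T
    values += resid * np.sqrt(sigma2)[:, None]

    probeset_ids = [f"PS{str(i).zfill(6)}_at" for i in range(n_g)]
    annotation = {pid: f"GENE{i}" for i, pid in enumerate(probeset_ids)}
    matrix = ExpressionMatrix(
        probeset_ids=probeset_ids,
        sample_ids=sample_ids,
        values=values,
        scale=NORMALIZED,
        annotation=annotation,
    )
    truth = pd.DataFrame(
        {
            "probeset_id": probeset_ids[: 2 * n_de],
            "direction": ["FNE-up"] * n_de + ["OCE-up"] * n_de,
            "effect_size": [config.effect_size] * n_de + [-config.effect_size] * n_de,
        }
    )
    return matrix, design, truth


def distort_to_raw(
    matrix: ExpressionMatrix,
    rng: np.random.Generator,
    offset_sd: float = 20.0,
    scale_spread: float = 0.5,
) -> ExpressionMatrix:
    """Map a normalized (log2) matrix to raw intensities with per-array
    affine distortion — fodder for calibration tests."""
    linear = np.exp2(matrix.values)
    n_s = matrix.n_samples
    offsets = np.abs(rng.normal(0.0, offset_sd, size=n_s))
    scales = np.exp(rng.uniform(-scale_spread, scale_spread, size=n_s))
    raw = linear * scales[None, :] + offsets[None, :]
    return ExpressionMatrix(
        probeset_ids=list(matrix.probeset_ids),
        sample_ids=list(matrix.sample_ids),
        values=raw,
        scale=RAW,
        annotation=dict(matrix.annotation),
    )


def _uniform_censoring_horizon(
    rates: np.ndarray, target_rate: float
) -> float:
    """Horizon c such that uniform(0, c) censoring yields the target overall
    censoring probability for exponential event times with the given rates."""

    def censored_prob(c: float) -> float:
        # P(C < T) for C ~ U(0, c), T ~ Exp(rate): (1 - exp(-rate*c)) / (rate*c)
        lam_c = rates * c
        return float(np.mean((1.0 - np.exp(-lam_c)) / lam_c))

    lo, hi = 1e-9, 1e9
    # censored_prob decreases in c from ~1 to ~0
    return float(optimize.brentq(lambda c: censored_prob(c) - target_rate, lo, hi))


def _draw_survival(
    rng: np.random.Generator, rates: np.ndarray, censoring_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    event_times = rng.exponential(1.0 / rates)
    if censoring_rate <= 0:
        return event_times, np.ones(rates.size, dtype=int)
    horizon = _uniform_censoring_horizon(rates, censoring_rate)
    censor_times = rng.uniform(0.0, horizon, size=rates.size)
    observed = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)
    observed = np.maximum(observed, 1e-9)  # times strictly positive
    return observed, events


def _proportional_odds_draw(
    rng: np.random.Generator, n_levels: int, shift: np.ndarray
) -> np.ndarray:
    """Sample ordinal levels from a proportional-odds model with evenly
    spaced cutpoints and per-sample linear shift."""
    cuts = np.linspace(-1.0, 1.0, n_levels - 1)
    eta = shift[:, None] - cuts[None, :]
    cum = 1.0 / (1.0 + np.exp(-eta))  # P(Y > k)
    u = rng.uniform(size=shift.size)
    greater = u[:, None] < cum
    return greater.sum(axis=1)


def simulate_tumor_cohort(
    config: CohortSimConfig, signature: Signature
) -> tuple[ExpressionMatrix, ClinicalTable, np.ndarray]:
    """Simulate a tumor cohort whose signature scores are a two-Gaussian mixture.

    Signature-probeset expression is shifted by latent class in the
    direction of each probeset's weight, so the score separates the FT-like
    and OV-like classes; non-signature probesets are class-independent
    noise. Survival is exponential with the configured hazard ratio
    (FT-like vs OV-like) under independent uniform censoring; grade/stage
    follow a proportional-odds link to class and subtype follows
    class-linked categorical odds.

    Returns (matrix, clinical, latent) where latent[i] = 1 for FT-like.
    """
    if len(signature) == 0:
        raise ValueError("signature must be non-empty")
    rng = np.random.default_rng(config.seed)
    n = config.n_tumors
    latent = (rng.uniform(size=n) < config.mixing_proportion).astype(int)

    sig_ids = signature.probeset_ids
    weights = np.array([e.weight for e in signature], dtype=float)
    extra_ids = [f"BG{str(i).zfill(6)}_at" for i in range(config.n_extra_probesets)]
    probeset_ids = sig_ids + extra_ids

    n_rows = len(probeset_ids)
    values = rng.normal(config.baseline_mean, config.class_sd, size=(n_rows, n))
    # class shift along each signature probeset's weight direction
    shift = config.class_mean_shift * weights[:, None] * latent[None, :]
    values[: len(sig_ids), :] += shift

    sample_ids = [f"tumor{str(i).zfill(4)}" for i in range(n)]
    annotation = {e.probeset_id: e.symbol for e in signature}
    annotation.update({pid: f"BGGENE{i}" for i, pid in enumerate(extra_ids)})
    matrix = ExpressionMatrix(
        probeset_ids=probeset_ids,
        sample_ids=sample_ids,
        values=values,
        scale=NORMALIZED,
        annotation=annotation,
    )

    # clinical covariates: proportional-odds link for grade/stage,
    # class-linked categorical odds for subtype
    log_odds = np.log(config.clinical_odds)
    shift_vec = log_odds * latent.astype(float)
    grade = _proportional_odds_draw(rng, 3, shift_vec) + 1  # levels 1..3
    stage = _proportional_odds_draw(rng, 4, shift_vec) + 1  # levels 1..4
    base_probs = np.array([0.4, 0.25, 0.15, 0.1, 0.1])
    subtype = np.empty(n, dtype=object)
    for i in range(n):
        w = base_probs.copy()
        if latent[i] == 1:
            w[0] *= config.clinical_odds  # FT-like enriched for serous
        w /= w.sum()
        subtype[i] = SUBTYPE_LEVELS[rng.choice(len(w), p=w)]

    rates = config.baseline_hazard * np.where(latent == 1, config.hazard_ratio, 1.0)
    dfs_time, dfs_event = _draw_survival(rng, rates, config.censoring_rate)
    os_time, os_event = _draw_survival(rng, rates * 0.6, config.censoring_rate)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "grade": grade,
                "stage": stage,
                "subtype": subtype,
                "age": np.round(rng.normal(60.0, 10.0, size=n), 1),
                "residual_disease": rng.integers(0, 2, size=n),
                "dfs_time": dfs_time,
                "dfs_event": dfs_event,
                "os_time": os_time,
                "os_event": os_event,
            }
        )
    )
    return matrix, clinical, latent


def default_signature() -> Signature:
    """A fixed 10-entry signature usable as a simulation input."""
    from coosig.datatypes import SignatureEntry

    ft = [("SIG_FT1_at", "FTG1"), ("SIG_FT2_at", "FTG2"), ("SIG_FT3_at", "FTG3"),
          ("SIG_FT4_at", "FTG4"), ("SIG_FT5_at", "FTG5")]
    ov = [("SIG_OV1_at", "OVG1"), ("SIG_OV2_at", "OVG2"), ("SIG_OV3_at", "OVG3"),
          ("SIG_OV4_at", "OVG4"), ("SIG_OV5_at", "OVG5")]
    entries = [SignatureEntry(p, s, +1) for p, s in ft]
    entries += [SignatureEntry(p, s, -1) for p, s in ov]
    return Signature(entries)
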