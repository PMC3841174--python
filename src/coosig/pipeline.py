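"""End-to-end configured runs: simulate or load, then DE -> signature ->
score -> classify -> associate -> survival -> permutation null.

The config is a flat key=value text file; every tunable has an explicit
default recorded in the run log, and identical config+seed gives
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from coosig import __version__
from coosig import clinstats, io
from coosig.datatypes import ClinicalTable, ExpressionMatrix, SampleDesign
from coosig.diffexp import run_paired_diffexp
from coosig.mixture import classify_samples, fit_two_component_mixture
from coosig.normalize import quantile_normalize, vsn_normalize
from coosig.signature import score_samples, select_signature
from coosig.simulate import (
    CellLineSimConfig,
    CohortSimConfig,
    simulate_paired_cell_lines,
    simulate_tumor_cohort,
)

logger = logging.getLogger("coosig")

# every tunable with its default; None marks a required key
CONFIG_SCHEMA: dict[str, object] = {
    "mode": "simulate",  # simulate | files
    "seed": 0,
    "k_per_direction": None,  # required
    "fdr_threshold": 0.05,
    "variance_mode": "auto",
    "n_permutations": 100,
    "alpha": 0.05,
    "normalization": "none",  # none | vsn | quantile
    # simulation recipe
    "sim_n_probesets": 2000,
    "sim_n_patients": 2,
    "sim_rho": 0.5,
    "sim_n_de_per_direction": 25,
    "sim_effect_size": 2.0,
    "sim_d0": 4.0,
    "sim_s0sq": 0.05,
    "sim_n_tumors": 200,
    "sim_mixing": 0.5,
    "sim_class_shift": 1.0,
    "sim_class_sd": 0.5,
    "sim_hazard_ratio": 2.0,
    "sim_censoring": 0.2,
    "sim_clinical_odds": 3.0,
    # file-mode inputs
    "cell_matrix": "",
    "cell_design": "",
    "annotation": "",
    "tumor_matrix": "",
    "clinical": "",
}

_INT_KEYS = {"seed", "k_per_direction", "n_permutations", "sim_n_probesets",
             "sim_n_patients", "sim_n_de_per_direction", "sim_n_tumors"}
_FLOAT_KEYS = {"fdr_threshold", "alpha", "sim_rho", "sim_effect_size", "sim_d0",
               "sim_s0sq", "sim_mixing", "sim_class_shift", "sim_class_sd",
               "sim_hazard_ratio", "sim_censoring", "sim_clinical_odds"}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def parse_config_file(path) -> dict:
    """Parse a flat key=value config file (# comments, blank lines allowed)."""
    raw: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        if "=" not in ln:
            raise ConfigError(f"malformed config line (expected key=value): {ln!r}")
        key, value = ln.split("=", 1)
        raw[key.strip()] = value.strip()
    return validate_config(raw)


def validate_config(raw: dict) -> dict:
    """Apply defaults, coerce types, and reject unknown/missing keys."""
    unknown = set(raw) - set(CONFIG_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    config: dict[str, object] = {}
    for key, default in CONFIG_SCHEMA.items():
        if key in raw:
            value: object = raw[key]
        elif default is None:
            raise ConfigError(f"missing required config key: {key}")
        else:
            value = default
        if key in _INT_KEYS:
            value = int(value)
        elif key in _FLOAT_KEYS:
            value = float(value)
        config[key] = value
    if config["mode"] not in ("simulate", "files"):
        raise ConfigError(f"mode must be 'simulate' or 'files', got {config['mode']!r}")
    if config["k_per_direction"] < 1:
        raise ConfigError("k_per_direction must be >= 1")
    return config


def _config_hash(config: dict) -> str:
    text = "\n".join(f"{k}={config[k]}" for k in sorted(config))
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, exc) from exc
        return inner
    return wrap


@_stage("inputs")
def _load_inputs(config: dict):
    if config["mode"] == "simulate":
        cell_cfg = CellLineSimConfig(
            n_probesets=config["sim_n_probesets"],
            n_patients=config["sim_n_patients"],
            intra_patient_correlation=config["sim_rho"],
            n_de_per_direction=config["sim_n_de_per_direction"],
            effect_size=config["sim_effect_size"],
            variance_prior_df=config["sim_d0"],
            variance_prior_scale=config["sim_s0sq"],
            seed=config["seed"],
        )
        cell_matrix, design, _truth = simulate_paired_cell_lines(cell_cfg)
        return cell_matrix, design, None, None
    ann = config["annotation"] or None
    cell_matrix = io.read_expression_matrix(
        config["cell_matrix"], format="tsv", annotation_path=ann
    )
    design = io.read_design(config["cell_design"])
    tumor_matrix = io.read_expression_matrix(
        config["tumor_matrix"], format="tsv", annotation_path=ann
    )
    clinical = io.read_clinical_table(config["clinical"])
    return cell_matrix, design, tumor_matrix, clinical


@_stage("normalize")
def _normalize(matrix: ExpressionMatrix, method: str) -> ExpressionMatrix:
    if method == "none":
        return matrix
    if method == "vsn":
        return vsn_normalize(matrix)
    if method == "quantile":
        return quantile_normalize(matrix)
    raise ValueError(f"unknown normalization {method!r}")


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage and write TSV outputs plus a run log under ``outdir``.

    Returns the in-memory result bundle.
    """
    config = validate_config({k: v for k, v in config.items()})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    rng = np.random.default_rng(seed)

    cell_matrix, design, tumor_matrix, clinical = _load_inputs(config)
    cell_matrix = _normalize(cell_matrix, config["normalization"])

    de_table, corr = _run_diffexp(cell_matrix, design)
    signature = _run_signature(de_table, config)

    if tumor_matrix is None:
        tumor_matrix, clinical, _latent = _simulate_cohort(config, signature)

    scores = _run_scoring(tumor_matrix, signature)
    model = _run_classify(scores, config, seed)
    associations = _run_associate(model, clinical, tumor_matrix, rng)
    survival = _run_survival(model, clinical, tumor_matrix)
    permutation = _run_permutation(tumor_matrix, clinical, config)

    _write_outputs(
        outdir, config, corr, de_table, signature, scores, model,
        associations, survival, permutation,
    )
    return {
        "de_table": de_table,
        "correlation": corr,
        "signature": signature,
        "scores": scores,
        "mixture": model,
        "associations": associations,
        "survival": survival,
        "permutation": permutation,
    }


@_stage("diffexp")
def _run_diffexp(matrix, design):
    return run_paired_diffexp(matrix, design)


@_stage("signature")
def _run_signature(de_table, config):
    return select_signature(
        de_table,
        k_per_direction=config["k_per_direction"],
        fdr_threshold=config["fdr_threshold"],
    )


@_stage("simulate_cohort")
def _simulate_cohort(config, signature):
    cohort_cfg = CohortSimConfig(
        n_tumors=config["sim_n_tumors"],
        mixing_proportion=config["sim_mixing"],
        class_mean_shift=config["sim_class_shift"],
        class_sd=config["sim_class_sd"],
        hazard_ratio=config["sim_hazard_ratio"],
        censoring_rate=config["sim_censoring"],
        clinical_odds=config["sim_clinical_odds"],
        seed=config["seed"] + 1,
    )
    return simulate_tumor_cohort(cohort_cfg, signature)


@_stage("score")
def _run_scoring(tumor_matrix, signature):
    return score_samples(tumor_matrix, signature)


@_stage("classify")
def _run_classify(scores, config, seed):
    return fit_two_component_mixture(
        scores.scores, variance_mode=config["variance_mode"], seed=seed
    )


@_stage("associate")
def _run_associate(model, clinical: ClinicalTable, tumor_matrix, rng):
    clinical = clinical.aligned_to(tumor_matrix.sample_ids)
    reports = clinstats.associate_clinical(
        model.labels, clinical, seed=int(rng.integers(2**31))
    )
    return pd.DataFrame(
        [
            {
                "covariate": name,
                "test": rep.test,
                "statistic": rep.statistic,
                "p_value": rep.p_value,
            }
            for name, rep in reports.items()
        ]
    )


@_stage("survival")
def _run_survival(model, clinical: ClinicalTable, tumor_matrix):
    clinical = clinical.aligned_to(tumor_matrix.sample_ids)
    df = clinical.table
    cls = np.asarray([1 if lab == "FT-like" else 0 for lab in model.labels])
    rows = []
    for prefix in ("dfs", "os"):
        tcol, ecol = f"{prefix}_time", f"{prefix}_event"
        ok = df[tcol].notna() & df[ecol].notna()
        if ok.sum() < 2 or len(np.unique(cls[ok.to_numpy()])) < 2:
            continue
        rep = clinstats.logrank_test(
            df.loc[ok, tcol], df.loc[ok, ecol].astype(int), cls[ok.to_numpy()]
        )
        rows.append(
            {"endpoint": prefix, "test": "logrank",
             "statistic": rep.statistic, "p_value": rep.p_value}
        )
        covs = pd.DataFrame({"ft_like": cls[ok.to_numpy()].astype(float)})
        for extra in ("grade", "stage", "age", "residual_disease"):
            vals = pd.to_numeric(df.loc[ok, extra], errors="coerce")
            if vals.notna().all() and vals.nunique() > 1:
                covs[extra] = vals.to_numpy(dtype=float)
        if "subtype" in df.columns and df.loc[ok, "subtype"].notna().all():
            serous = (df.loc[ok, "subtype"] == "serous").astype(float)
            if serous.nunique() > 1:
                covs["serous"] = serous.to_numpy()
        try:
            cox = clinstats.cox_ph(
                df.loc[ok, tcol].to_numpy(), df.loc[ok, ecol].astype(int).to_numpy(), covs
            )
            for r in cox.itertuples():
                rows.append(
                    {"endpoint": prefix, "test": f"cox[{r.covariate}]",
                     "statistic": r.hazard_ratio, "p_value": r.p_value}
                )
        except Exception as exc:  # noqa: BLE001 - survival stage is best-effort per endpoint
            logger.warning("Cox fit failed for %s: %s", prefix, exc)
    return pd.DataFrame(rows)


@_stage("permute")
def _run_permutation(tumor_matrix, clinical, config):
    return clinstats.permutation_signature_null(
        tumor_matrix,
        clinical,
        k_per_direction=config["k_per_direction"],
        n_permutations=config["n_permutations"],
        alpha=config["alpha"],
        seed=config["seed"] + 2,
    )


@_stage("write_outputs")
def _write_outputs(
    outdir: Path, config, corr, de_table, signature, scores, model,
    associations, survival, permutation,
):
    de_table.to_csv(outdir / "de_results.tsv", sep="\t", index=False, float_format="%.10g")
    io.write_signature(signature, outdir / "signature.tsv")
    io.write_scores(scores, outdir / "scores.tsv")
    pd.DataFrame(
        {
            "sample_id": scores.sample_ids,
            "score": scores.scores,
            "posterior_ft": model.posterior,
            "label": model.labels,
        }
    ).to_csv(outdir / "classification.tsv", sep="\t", index=False, float_format="%.10g")
    associations.to_csv(outdir / "associations.tsv", sep="\t", index=False, float_format="%.10g")
    survival.to_csv(outdir / "survival.tsv", sep="\t", index=False, float_format="%.10g")
    permutation.p_values.to_csv(
        outdir / "permutation_null.tsv", sep="\t", index=False, float_format="%.10g"
    )

    log_lines = [
        f"coosig version: {__version__}",
        f"config hash: {_config_hash(config)}",
        f"consensus correlation: {corr.consensus:.6f}",
        f"mixture: pi_ft={model.mixing_ft:.6f} mu_ov={model.mean_ov:.6f} "
        f"mu_ft={model.mean_ft:.6f} sd_ov={model.sd_ov:.6f} sd_ft={model.sd_ft:.6f} "
        f"mode={model.variance_mode} bic={model.bic:.6f}",
        f"permutation failures: {permutation.n_failures}",
        "config:",
    ]
    log_lines += [f"  {k}={config[k]}" for k in sorted(config)]
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
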