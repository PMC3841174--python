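"""Core domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RAW = "raw"
NORMALIZED = "normalized"

CELL_TYPES = ("FNE", "OCE")
FT_LIKE = "FT-like"
OV_LIKE = "OV-like"

SUBTYPE_LEVELS = ("serous", "endometrioid", "clear cell", "mucinous", "other")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Probesets-by-samples intensity matrix with gene-symbol annotation.

    Parameters
    ----------
    probeset_ids : list of str
        Unique row identifiers (opaque strings).
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_probesets, n_samples)
        Intensities; linear scale when ``scale == "raw"``, glog2/log2 scale
        when ``scale == "normalized"``.
    scale : {"raw", "normalized"}
    annotation : dict
        probeset_id -> gene symbol; probesets may be missing (no symbol).
        Symbols are upper-cased on construction.
    """

    probeset_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = NORMALIZED
    annotation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probeset_ids = [str(p) for p in self.probeset_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.probeset_ids, "probeset")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probeset_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probeset_ids)} probesets x {len(self.sample_ids)} samples"
            )
        if self.scale not in (RAW, NORMALIZED):
            raise ValueError(f"scale must be 'raw' or 'normalized', got {self.scale!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        self.annotation = {
            str(k): str(v).upper() for k, v in self.annotation.items() if v is not None
        }

    @property
    def n_probesets(self) -> int:
        return len(self.probeset_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.probeset_ids)}

    def symbol_of(self, probeset_id: str) -> str | None:
        return self.annotation.get(probeset_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probeset_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(
            probeset_ids=list(self.probeset_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, cols],
            scale=self.scale,
            annotation=dict(self.annotation),
        )


@dataclass
class SampleDesign:
    """Paired design: each sample belongs to one patient block and one cell type."""

    sample_ids: list[str]
    patient_blocks: list[str]
    cell_types: list[str]

    def __post_init__(self) -> None:
        if not (len(self.sample_ids) == len(self.patient_blocks) == len(self.cell_types)):
            raise ValueError("design columns must have equal length")
        _check_unique(self.sample_ids, "sample")
        for ct in self.cell_types:
            if ct not in CELL_TYPES:
                raise ValueError(f"unknown cell type {ct!r}; expected one of {CELL_TYPES}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def blocks(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, b in enumerate(self.patient_blocks):
            out.setdefault(b, []).append(i)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "patient_block": self.patient_blocks,
                "cell_type": self.cell_types,
            }
        )


@dataclass(frozen=True)
class SignatureEntry:
    probeset_id: str
    symbol: str
    weight: int

    def __post_init__(self) -> None:
        if self.weight not in (+1, -1):
            raise ValueError(f"weight must be +1 or -1, got {self.weight}")


@dataclass
class Signature:
    """Ordered set of (probeset, symbol, +/-1 weight) defining the score."""

    entries: list[SignatureEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("signature must be non-empty")
        symbols = [e.symbol for e in self.entries]
        _check_unique(symbols, "gene symbol")
        _check_unique([e.probeset_id for e in self.entries], "probeset")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def probeset_ids(self) -> list[str]:
        return [e.probeset_id for e in self.entries]

    @property
    def weights(self) -> dict[str, int]:
        return {e.probeset_id: e.weight for e in self.entries}

    def negated(self) -> "Signature":
        return Signature(
            [SignatureEntry(e.probeset_id, e.symbol, -e.weight) for e in self.entries]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probeset_id": [e.probeset_id for e in self.entries],
                "symbol": [e.symbol for e in self.entries],
                "weight": [e.weight for e in self.entries],
            }
        )


@dataclass
class ScoreSet:
    """Per-sample weighted signature score and the count of probesets used."""

    sample_ids: list[str]
    scores: np.ndarray
    n_used: np.ndarray
    dropped_probesets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.n_used = np.asarray(self.n_used, dtype=int)
        if not (len(self.sample_ids) == self.scores.size == self.n_used.size):
            raise ValueError("score columns must have equal length")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "score": self.scores, "n_used": self.n_used}
        )


@dataclass
class CorrelationEstimate:
    """Consensus intra-block correlation with the per-gene atanh-scale values."""

    consensus: float
    atanh_correlations: np.ndarray

    def __post_init__(self) -> None:
        if not -1.0 < self.consensus < 1.0:
            raise ValueError("consensus correlation must lie in (-1, 1)")


@dataclass
class MixtureModel:
    """Two-component 1-D Gaussian mixture fit of score values.

    The component with the larger mean is the FT-like component; ``posterior``
    holds per-sample posterior probability of FT-like membership.
    """

    mixing_ft: float
    mean_ov: float
    mean_ft: float
    sd_ov: float
    sd_ft: float
    variance_mode: str
    log_likelihood: float
    bic: float
    posterior: np.ndarray
    labels: list[str]
    n_iterations: int = 0

    def __post_init__(self) -> None:
        if not self.mean_ov < self.mean_ft:
            raise ValueError("mean_ov must be strictly below mean_ft")
        if self.sd_ov <= 0 or self.sd_ft <= 0:
            raise ValueError("component standard deviations must be positive")
        if not 0.0 < self.mixing_ft < 1.0:
            raise ValueError("mixing proportion must lie in (0, 1)")
        self.posterior = np.asarray(self.posterior, dtype=float)

    def parameter_count(self) -> int:
        return 4 if self.variance_mode == "shared" else 5


@dataclass
class ClinicalTable:
    """Per-tumor clinical covariates and survival endpoints.

    ``grade`` and ``stage`` are ordinal codes (0-based, ascending severity)
    with NaN for missing; ``subtype`` is a categorical string or None; times
    are positive reals with NaN for missing; events are 0/1 with NaN for
    missing.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id",)
    FIELDS = (
        "sample_id",
        "grade",
        "stage",
        "subtype",
        "age",
        "residual_disease",
        "dfs_time",
        "dfs_event",
        "os_time",
        "os_event",
    )

    def __post_init__(self) -> None:
        df = self.table.copy()
        if "sample_id" not in df.columns:
            raise ValueError("clinical table requires a sample_id column")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id in clinical table: {dup!r}")
        for col in self.FIELDS:
            if col not in df.columns:
                df[col] = np.nan
        for tcol in ("dfs_time", "os_time"):
            t = pd.to_numeric(df[tcol], errors="coerce")
            if (t <= 0).any():
                raise ValueError(f"{tcol} must be strictly positive where present")
            df[tcol] = t
        for ecol in ("dfs_event", "os_event", "residual_disease"):
            e = pd.to_numeric(df[ecol], errors="coerce")
            bad = e.dropna()[~e.dropna().isin([0, 1])]
            if len(bad):
                raise ValueError(f"{ecol} must be 0/1, found {bad.iloc[0]}")
            df[ecol] = e
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def __len__(self) -> int:
        return len(self.table)

    def aligned_to(self, sample_ids: list[str]) -> "ClinicalTable":
        """Subset and order rows to match ``sample_ids`` (all must be present)."""
        idx = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in idx.index]
        if missing:
            raise KeyError(f"samples missing from clinical table: {missing[:5]}")
        sub = idx.loc[sample_ids].reset_index()
        return ClinicalTable(sub)
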