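"""Readers and writers for the formats the pipeline touches.

Supports plain TSV matrices, the GEO Series Matrix dialect
(!-prefixed metadata with a !series_matrix_table_begin/end block),
TSV/CSV clinical tables, and the signature/score/design TSV outputs.
No network retrieval: files are always local.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from coosig.datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    SampleDesign,
    ScoreSet,
    Signature,
    SignatureEntry,
)

logger = logging.getLogger("coosig")

DEFAULT_GRADE_LEVELS = ["1", "2", "3"]
DEFAULT_STAGE_LEVELS = ["I", "II", "III", "IV"]
SUBTYPE_ALIASES = {
    "serous": "serous",
    "ser": "serous",
    "endometrioid": "endometrioid",
    "endo": "endometrioid",
    "clear cell": "clear cell",
    "clearcell": "clear cell",
    "clear_cell": "clear cell",
    "mucinous": "mucinous",
    "muc": "mucinous",
}


def _strip_quotes(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == '"' and token[-1] == '"':
        token = token[1:-1]
    return token


def _read_annotation(path) -> dict[str, str]:
    """Two-column probeset->symbol table (TSV or CSV, optional header)."""
    ann: dict[str, str] = {}
    text = Path(path).read_text()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    for i, row in enumerate(csv.reader(text.splitlines(), delimiter=delim)):
        if not row or not row[0].strip():
            continue
        key = _strip_quotes(row[0])
        if i == 0 and key.lower() in ("probeset_id", "probeset", "id", "probe_id"):
            continue
        symbol = _strip_quotes(row[1]) if len(row) > 1 else ""
        if symbol:
            ann[key] = symbol.upper()
    return ann


def _parse_matrix_lines(lines: list[str], origin: str) -> tuple[list[str], list[str], np.ndarray]:
    header = next(csv.reader([lines[0]], delimiter="\t"))
    if len(header) < 2:
        raise ValueError(f"malformed header in {origin}: need id column + samples")
    sample_ids = [_strip_quotes(h) for h in header[1:]]
    probeset_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = next(csv.reader([line], delimiter="\t"))
        pid = _strip_quotes(parts[0])
        if pid in seen:
            raise ValueError(f"duplicate probeset id in {origin}: {pid!r}")
        seen.add(pid)
        if len(parts) != len(sample_ids) + 1:
            raise ValueError(
                f"row {pid!r} in {origin} has {len(parts) - 1} values; "
                f"expected {len(sample_ids)}"
            )
        probeset_ids.append(pid)
        rows.append([float(_strip_quotes(v)) for v in parts[1:]])
    return probeset_ids, sample_ids, np.asarray(rows, dtype=float)


def read_expression_matrix(
    path,
    format: str = "tsv",
    annotation_path=None,
    scale: str = "normalized",
) -> ExpressionMatrix:
    """Read a probesets-by-samples matrix from TSV or GEO Series Matrix.

    The Series Matrix dialect skips !-prefixed metadata lines and parses
    the table between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end``. An optional two-column annotation table
    (probeset -> gene symbol) is joined; unannotated probesets are retained
    with a missing symbol.
    """
    path = Path(path)
    text = path.read_text()
    if format == "series_matrix":
        lines = text.splitlines()
        try:
            start = next(
                i for i, ln in enumerate(lines)
                if ln.strip().lower().startswith("!series_matrix_table_begin")
            )
        except StopIteration:
            raise ValueError(f"{path}: no !series_matrix_table_begin marker") from None
        try:
            end = next(
                i for i, ln in enumerate(lines)
                if ln.strip().lower().startswith("!series_matrix_table_end")
            )
        except StopIteration:
            end = len(lines)
        table_lines = [ln for ln in lines[start + 1 : end] if ln.strip()]
    elif format == "tsv":
        table_lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    if not table_lines:
        raise ValueError(f"{path}: empty matrix table")
    probeset_ids, sample_ids, values = _parse_matrix_lines(table_lines, str(path))

    annotation = _read_annotation(annotation_path) if annotation_path else {}
    annotation = {p: annotation[p] for p in probeset_ids if p in annotation}
    n_missing = len(probeset_ids) - len(annotation)
    logger.info(
        "read %s: %d probesets x %d samples (%d without gene symbol)",
        path, len(probeset_ids), len(sample_ids), n_missing,
    )
    return ExpressionMatrix(
        probeset_ids=probeset_ids,
        sample_ids=sample_ids,
        values=values,
        scale=scale,
        annotation=annotation,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_frame().to_csv(path, sep="\t", index_label="probeset_id", float_format="%.10g")


def write_annotation(annotation: dict[str, str], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("probeset_id\tsymbol\n")
        for pid, sym in annotation.items():
            fh.write(f"{pid}\t{sym}\n")


def _map_ordinal(series: pd.Series, levels: list[str], name: str) -> pd.Series:
    mapping = {lv: i for i, lv in enumerate(levels)}
    out = []
    for v in series:
        if pd.isna(v) or str(v).strip() == "":
            out.append(np.nan)
            continue
        token = str(v).strip()
        if token.endswith(".0"):
            token = token[:-2]
        if token in mapping:
            out.append(mapping[token])
        else:
            logger.warning("unknown %s level %r mapped to missing", name, token)
            out.append(np.nan)
    return pd.Series(out, index=series.index, dtype=float)


def read_clinical_table(
    path,
    grade_levels: list[str] | None = None,
    stage_levels: list[str] | None = None,
) -> ClinicalTable:
    """Read a TSV/CSV clinical table with configurable ordinal level orderings.

    Unknown ordinal levels map to missing with a logged warning; rows with
    non-positive survival times are rejected and logged.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")

    grade_levels = grade_levels or DEFAULT_GRADE_LEVELS
    stage_levels = stage_levels or DEFAULT_STAGE_LEVELS
    if "grade" in df.columns:
        df["grade"] = _map_ordinal(df["grade"], grade_levels, "grade")
    if "stage" in df.columns:
        df["stage"] = _map_ordinal(df["stage"], stage_levels, "stage")
    if "subtype" in df.columns:
        def norm_subtype(v):
            if pd.isna(v) or not str(v).strip():
                return None
            token = str(v).strip().lower()
            if token in SUBTYPE_ALIASES:
                return SUBTYPE_ALIASES[token]
            return "other"
        df["subtype"] = df["subtype"].map(norm_subtype)

    for tcol in ("dfs_time", "os_time"):
        if tcol in df.columns:
            t = pd.to_numeric(df[tcol], errors="coerce")
            bad = t.notna() & (t <= 0)
            if bad.any():
                for sid in df.loc[bad, "sample_id"]:
                    logger.warning("rejecting sample %r: non-positive %s", sid, tcol)
                df = df[~bad]
    return ClinicalTable(df.reset_index(drop=True))


def write_clinical_table(clinical: ClinicalTable, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clinical.table.to_csv(path, sep="\t", index=False)


def write_design(design: SampleDesign, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_design(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleDesign(
        sample_ids=list(df["sample_id"]),
        patient_blocks=list(df["patient_block"]),
        cell_types=list(df["cell_type"]),
    )


def write_signature(signature: Signature, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    signature.to_frame().to_csv(path, sep="\t", index=False)


def read_signature(path) -> Signature:
    df = pd.read_csv(path, sep="\t", dtype={"probeset_id": str, "symbol": str})
    entries = [
        SignatureEntry(str(r.probeset_id), str(r.symbol), int(r.weight))
        for r in df.itertuples()
    ]
    return Signature(entries)


def write_scores(scores: ScoreSet, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    scores.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def intersection_report(
    matrix: ExpressionMatrix, clinical: ClinicalTable
) -> dict[str, list[str]]:
    """Explicit sample-id reconciliation; never silently reindexes."""
    expr = set(matrix.sample_ids)
    clin = set(clinical.sample_ids)
    return {
        "shared": sorted(expr & clin),
        "expression_only": sorted(expr - clin),
        "clinical_only": sorted(clin - expr),
    }
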