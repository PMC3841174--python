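"""Build the +/-1-weighted cell-of-origin signature and score cohorts.

The signature takes, per direction, the most highly significant
differentially expressed probesets with unique gene symbols; a sample's
score is the sum of its normalized expression over those probesets, with
FT-origin probesets weighted +1 and ovary-origin probesets weighted -1, so
a higher score means more FT-like.
"""

from __future__ import annotations

import numpy as np

from coosig.datatypes import (
    NORMALIZED,
    ExpressionMatrix,
    ScoreSet,
    Signature,
    SignatureEntry,
)
from coosig.diffexp import FNE_UP, OCE_UP, rank_de_table

DEFAULT_K = 5
DEFAULT_FDR = 0.05


def select_signature(
    de_table,
    k_per_direction: int = DEFAULT_K,
    fdr_threshold: float = DEFAULT_FDR,
) -> Signature:
    """Select the top-k significant probesets per direction, unique symbols.

    Probesets are ranked by ascending p, then descending \\|moderated t\\|,
    then probeset id; among probesets sharing a gene symbol only the
    best-ranked is eligible. Probesets without a symbol are ineligible.
    """
    if k_per_direction < 1:
        raise ValueError("k_per_direction must be >= 1")
    ranked = rank_de_table(de_table)
    significant = ranked[ranked["q_value"] < fdr_threshold]

    entries: list[SignatureEntry] = []
    for direction, weight in ((FNE_UP, +1), (OCE_UP, -1)):
        taken: list[SignatureEntry] = []
        seen_symbols = {e.symbol for e in entries}
        block = significant[significant["direction"] == direction]
        for _, row in block.iterrows():
            sym = row["symbol"]
            if sym is None or (isinstance(sym, float) and np.isnan(sym)):
                continue
            sym = str(sym).upper()
            if sym in seen_symbols:
                continue
            taken.append(SignatureEntry(str(row["probeset_id"]), sym, weight))
            seen_symbols.add(sym)
            if len(taken) == k_per_direction:
                break
        if len(taken) < k_per_direction:
            raise ValueError(
                f"insufficient eligible probesets for direction {direction}: "
                f"needed {k_per_direction}, found {len(taken)}"
            )
        entries.extend(taken)
    return Signature(entries)


def score_samples(matrix: ExpressionMatrix, signature: Signature) -> ScoreSet:
    """Sum of +/-1-weighted normalized expression over signature probesets.

    Signature probesets absent from the matrix are dropped from the sum;
    ``n_used`` records how many remain and ``dropped_probesets`` which ids
    were unavailable. Higher score means more FT-like.
    """
    if matrix.scale != NORMALIZED:
        raise ValueError("scoring requires a normalized matrix")
    row_index = matrix.row_index()
    present = [e for e in signature if e.probeset_id in row_index]
    dropped = [e.probeset_id for e in signature if e.probeset_id not in row_index]
    if not present:
        raise ValueError("no signature probesets present in the matrix")
    plus_rows = [row_index[e.probeset_id] for e in present if e.weight == +1]
    minus_rows = [row_index[e.probeset_id] for e in present if e.weight == -1]
    # sum each direction separately so equal values cancel exactly
    scores = np.zeros(matrix.n_samples)
    if plus_rows:
        scores += matrix.values[plus_rows, :].sum(axis=0)
    if minus_rows:
        scores -= matrix.values[minus_rows, :].sum(axis=0)
    n_used = np.full(matrix.n_samples, len(present), dtype=int)
    return ScoreSet(
        sample_ids=list(matrix.sample_ids),
        scores=scores,
        n_used=n_used,
        dropped_probesets=dropped,
    )


def random_signature(
    probeset_ids: list[str],
    annotation: dict[str, str],
    k_per_direction: int,
    rng: np.random.Generator,
) -> Signature:
    """Draw a random signature honoring gene-symbol uniqueness.

    Samples 2k probesets without replacement such that no two share a
    symbol, then assigns k weights +1 and k weights -1. Deterministic given
    the generator state.
    """
    annotated = [(p, annotation[p]) for p in probeset_ids if annotation.get(p)]
    symbols = {s for _, s in annotated}
    need = 2 * k_per_direction
    if len(symbols) < need:
        raise ValueError(
            f"universe has {len(symbols)} distinct symbols; need {need}"
        )
    order = rng.permutation(len(annotated))
    chosen: list[tuple[str, str]] = []
    seen: set[str] = set()
    for i in order:
        pid, sym = annotated[i]
        if sym in seen:
            continue
        chosen.append((pid, sym))
        seen.add(sym)
        if len(chosen) == need:
            break
    entries = [
        SignatureEntry(pid, sym, +1 if j < k_per_direction else -1)
        for j, (pid, sym) in enumerate(chosen)
    ]
    return Signature(entries)


def zscore_matrix(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Optional per-probeset z-standardization across samples (off by default
    in scoring; provided for cross-platform use)."""
    x = matrix.values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return ExpressionMatrix(
        probeset_ids=list(matrix.probeset_ids),
        sample_ids=list(matrix.sample_ids),
        values=(x - mu) / sd,
        scale=matrix.scale,
        annotation=dict(matrix.annotation),
    )
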