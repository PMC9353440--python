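"""Mutated-gene expression, single-cell, and mass-spectrometry evidence.

The expression value attributed to a mutation is

    mutant_expression = (mutated reads / total reads) * gene expression

computed from RNA read support at the variant locus. Candidates from
unexpressed mutations are removed from the main track (kept in an audit
table); single-cell support requires admitted cells (QUAL > 10, DP > 20)
carrying the variant, and MS support requires an exact peptide-sequence
match (optionally treating I and L as equivalent, since mass
spectrometry cannot distinguish them).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .peptides import CandidatePeptide

__all__ = [
    "MutationExpression",
    "ScMutationRow",
    "mutant_expression",
    "expression_filter",
    "flag_sc_detected",
    "flag_ms_detected",
    "read_expression_table",
    "read_sc_table",
]


def mutant_expression(mutated_reads: int, total_reads: int, gene_expression: float) -> float:
    """(mutated reads / total reads) * gene expression; 0 when no coverage."""
    if mutated_reads < 0 or total_reads < 0 or gene_expression < 0:
        raise ValueError("counts and expression must be non-negative")
    if mutated_reads > total_reads:
        raise ValueError(
            f"mutated_reads ({mutated_reads}) exceeds total_reads ({total_reads})"
        )
    if total_reads == 0:
        return 0.0
    return (mutated_reads / total_reads) * gene_expression


@dataclass(frozen=True)
class MutationExpression:
    """RNA read support and gene expression for one variant."""

    variant_key: str
    mutated_reads: int
    total_reads: int
    gene_expression: float

    @property
    def mutant_expression(self) -> float:
        return mutant_expression(self.mutated_reads, self.total_reads, self.gene_expression)


@dataclass(frozen=True)
class ScMutationRow:
    """One cell's evidence for one variant in single-cell RNA data."""

    variant_key: str
    barcode: str
    detected: bool
    qual: float
    dp: int


def expression_filter(
    candidates: Sequence[CandidatePeptide],
    expr: Mapping[str, MutationExpression],
    min_mutant_expression: float = 0.0,
) -> tuple[list[CandidatePeptide], list[tuple[CandidatePeptide, str]]]:
    """Drop candidates whose mutation shows no mutant expression.

    A candidate is kept (``expressed=True``) iff its variant has an RNA
    row with mutant_expression strictly above the threshold. Returns
    (kept, audit) where audit pairs each removed candidate with a
    reason; kept + audited partition the input.
    """
    kept: list[CandidatePeptide] = []
    audit: list[tuple[CandidatePeptide, str]] = []
    for c in candidates:
        row = expr.get(c.source_variant.key)
        if row is None:
            audit.append((c, "no_rna_row"))
        elif row.mutant_expression > min_mutant_expression:
            kept.append(c.with_(expressed=True))
        else:
            audit.append((c, "unexpressed"))
    return kept, audit


def flag_sc_detected(
    candidates: Sequence[CandidatePeptide],
    sc_rows: Sequence[ScMutationRow],
    min_cells: int = 1,
    min_qual: float = 10.0,
    min_dp: int = 20,
) -> tuple[list[CandidatePeptide], dict[str, list[str]]]:
    """Mark candidates whose mutation is seen in single-cell RNA data.

    A cell is admitted when QUAL > ``min_qual`` and DP > ``min_dp``
    (strict inequalities); a variant counts as detected with at least
    ``min_cells`` admitted carrier cells. Also returns the variant ->
    barcode mapping for downstream cluster labeling.
    """
    cells: dict[str, list[str]] = {}
    for r in sc_rows:
        if r.detected and r.qual > min_qual and r.dp > min_dp:
            cells.setdefault(r.variant_key, []).append(r.barcode)
    out = [
        c.with_(sc_detected=len(cells.get(c.source_variant.key, [])) >= min_cells)
        for c in candidates
    ]
    return out, cells


def flag_ms_detected(
    candidates: Sequence[CandidatePeptide],
    ms_peptides: Sequence[str],
    il_equivalent: bool = False,
) -> list[CandidatePeptide]:
    """Mark candidates whose sequence was observed by mass spectrometry.

    Default matching is exact residue identity; with ``il_equivalent``
    isoleucine and leucine are collapsed before comparison.
    """
    def canon(seq: str) -> str:
        seq = seq.upper()
        return seq.replace("I", "L") if il_equivalent else seq

    observed = {canon(p) for p in ms_peptides}
    return [c.with_(ms_detected=canon(c.sequence) in observed) for c in candidates]


# ---------------------------------------------------------------------------
# I/O

def read_expression_table(path: str | Path) -> dict[str, MutationExpression]:
    """TSV columns: variant_key, mutated_reads, total_reads, gene_expression."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["variant_key"]] = MutationExpression(
                variant_key=row["variant_key"],
                mutated_reads=int(row["mutated_reads"]),
                total_reads=int(row["total_reads"]),
                gene_expression=float(row["gene_expression"]),
            )
    return out


def read_sc_table(path: str | Path) -> list[ScMutationRow]:
    """TSV columns: variant_key, barcode, detected, qual, dp."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(ScMutationRow(
                variant_key=row["variant_key"],
                barcode=row["barcode"],
                detected=row["detected"].strip().lower() in ("1", "true", "yes"),
                qual=float(row["qual"]),
                dp=int(row["dp"]),
            ))
    return rows
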