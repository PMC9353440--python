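"""Somatic variant model, the five-criterion filter cascade, and TMB.

High-confidence somatic calls are obtained from annotated tumor/normal
variant tables by a cascade of read-support filters:

    C1  tumor depth >= 10 and normal depth >= 10
    C2  tumor alt-supporting reads >= 3
    C3  tumor allele fraction >= 0.05
    C4  normal allele fraction <= 0.01
    C5  panel-of-normals frequency < 0.05, OR
        panel frequency >= 0.05 and tumor allele fraction >= 0.30

Tumor mutational burden (TMB) is the count of passing coding mutations
(SNVs and indels) per megabase of coding sequence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SomaticVariant",
    "FilterDecision",
    "read_variant_table",
    "apply_somatic_filters",
    "compute_tmb",
    "write_decision_table",
]

VARIANT_CLASSES = ("SNV", "insertion", "deletion")
EFFECTS = ("missense", "nonframeshift_indel", "synonymous", "frameshift", "other")

#: Criterion identifiers in cascade order.
CRITERIA = ("C1", "C2", "C3", "C4", "C5")


@dataclass(frozen=True)
class SomaticVariant:
    """One annotated somatic call with tumor/normal read statistics.

    Coordinates are 1-based; ``panel_freq`` is the fraction of a
    panel of normals carrying the variant.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    effect: str
    gene: str
    transcript_id: str
    protein_change: str
    tumor_depth: int
    normal_depth: int
    tumor_alt_reads: int
    tumor_af: float
    normal_af: float
    panel_freq: float
    in_coding: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.vclass not in VARIANT_CLASSES:
            raise ValueError(f"unknown vclass {self.vclass!r}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        for name in ("tumor_af", "normal_af", "panel_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tumor_alt_reads > self.tumor_depth:
            raise ValueError(
                f"tumor_alt_reads ({self.tumor_alt_reads}) exceeds "
                f"tumor_depth ({self.tumor_depth})"
            )
        if min(self.tumor_depth, self.normal_depth, self.tumor_alt_reads) < 0:
            raise ValueError("read counts must be non-negative")
        is_snv = len(self.ref) == 1 and len(self.alt) == 1
        if (self.vclass == "SNV") != is_snv:
            raise ValueError(
                f"vclass {self.vclass!r} inconsistent with alleles "
                f"{self.ref}>{self.alt}"
            )

    @property
    def key(self) -> str:
        """Canonical variant key ``chrom:pos:ref:alt``."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the filter cascade for one variant."""

    variant: SomaticVariant
    passed: bool
    failed_criteria: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_criteria) == 0):
            raise ValueError("passed must equal 'failed_criteria is empty'")


def _failed_criteria(v: SomaticVariant) -> tuple[str, ...]:
    failed = []
    if v.tumor_depth < 10 or v.normal_depth < 10:
        failed.append("C1")
    if v.tumor_alt_reads < 3:
        failed.append("C2")
    if v.tumor_af < 0.05:
        failed.append("C3")
    if v.normal_af > 0.01:
        failed.append("C4")
    # C5: common-in-panel variants are rescued only at high tumor AF
    if not (v.panel_freq < 0.05 or (v.panel_freq >= 0.05 and v.tumor_af >= 0.30)):
        failed.append("C5")
    return tuple(failed)


def apply_somatic_filters(variants: Sequence[SomaticVariant]) -> list[FilterDecision]:
    """Apply the five-criterion cascade; order-preserving, never raises."""
    out = []
    for v in variants:
        failed = _failed_criteria(v)
        out.append(FilterDecision(variant=v, passed=not failed, failed_criteria=failed))
    return out


def compute_tmb(decisions: Iterable[FilterDecision], coding_mb: float = 34.0) -> float:
    """Mutations per megabase: passing coding variants / ``coding_mb``.

    The coding-region size is configurable; 34 Mb is a conventional
    whole-exome coding footprint.
    """
    if coding_mb <= 0:
        raise ValueError(f"coding_mb must be > 0, got {coding_mb}")
    n = sum(1 for d in decisions if d.passed and d.variant.in_coding)
    return n / coding_mb


# ---------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "vclass", "effect", "gene", "transcript_id",
    "protein_change", "tumor_depth", "normal_depth", "tumor_alt_reads",
    "tumor_af", "normal_af", "panel_freq", "in_coding",
]

_INFO_KEYS = {
    "TDP": "tumor_depth", "NDP": "normal_depth", "TAD": "tumor_alt_reads",
    "TAF": "tumor_af", "NAF": "normal_af", "PFREQ": "panel_freq",
    "GENE": "gene", "TXID": "transcript_id", "PCHG": "protein_change",
    "EFFECT": "effect",
}


def _classify(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


def _parse_fraction(raw: str, name: str, lineno: int) -> float:
    try:
        v = float(raw)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed fraction for {name!r}: {raw!r}") from exc
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"line {lineno}: {name} out of [0, 1]: {v}")
    return v


def _read_tsv(path: Path) -> list[SomaticVariant]:
    variants = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _TSV_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            variants.append(
                SomaticVariant(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    vclass=row["vclass"],
                    effect=row["effect"],
                    gene=row["gene"],
                    transcript_id=row["transcript_id"],
                    protein_change=row["protein_change"],
                    tumor_depth=int(row["tumor_depth"]),
                    normal_depth=int(row["normal_depth"]),
                    tumor_alt_reads=int(row["tumor_alt_reads"]),
                    tumor_af=_parse_fraction(row["tumor_af"], "tumor_af", lineno),
                    normal_af=_parse_fraction(row["normal_af"], "normal_af", lineno),
                    panel_freq=_parse_fraction(row["panel_freq"], "panel_freq", lineno),
                    in_coding=row["in_coding"].strip().lower() in ("1", "true", "yes"),
                )
            )
    return variants


def _read_vcf(path: Path) -> list[SomaticVariant]:
    from cyvcf2 import VCF

    variants = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            alts = rec.ALT or []
            info = dict(rec.INFO)
            for key in _INFO_KEYS:
                if key not in info:
                    raise ValueError(
                        f"{path}: record {rec.CHROM}:{rec.POS} missing INFO field {key!r}"
                    )

            def per_alt(key: str, i: int):
                val = info[key]
                if isinstance(val, tuple):
                    return val[i]
                return val

            # multi-allelic records are split: criteria are per-allele
            for i, alt in enumerate(alts):
                effect = str(per_alt("EFFECT", i))
                variants.append(
                    SomaticVariant(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        vclass=_classify(rec.REF, alt),
                        effect=effect,
                        gene=str(per_alt("GENE", i)),
                        transcript_id=str(per_alt("TXID", i)),
                        protein_change=str(per_alt("PCHG", i)),
                        tumor_depth=int(per_alt("TDP", i)),
                        normal_depth=int(per_alt("NDP", i)),
                        tumor_alt_reads=int(per_alt("TAD", i)),
                        tumor_af=float(per_alt("TAF", i)),
                        normal_af=float(per_alt("NAF", i)),
                        panel_freq=float(per_alt("PFREQ", i)),
                        in_coding=bool(int(info.get("CODING", 1))),
                    )
                )
    finally:
        vcf.close()
    return variants


def read_variant_table(path: str | Path, format: str | None = None) -> list[SomaticVariant]:
    """Read somatic variants from a VCF 4.2 or TSV file.

    ``format`` is ``"vcf"`` or ``"tsv"``; inferred from the suffix when
    omitted. Every record is validated against the type invariants and
    1-based coordinates are preserved. Multi-allelic VCF records are
    split into one variant per alternate allele.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def read_decision_table(path: str | Path) -> list[FilterDecision]:
    """Read back a TSV written by :func:`write_decision_table`."""
    decisions = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            v = SomaticVariant(
                chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"],
                alt=row["alt"], vclass=row["vclass"], effect=row["effect"],
                gene=row["gene"], transcript_id=row["transcript_id"],
                protein_change=row["protein_change"],
                tumor_depth=int(row["tumor_depth"]),
                normal_depth=int(row["normal_depth"]),
                tumor_alt_reads=int(row["tumor_alt_reads"]),
                tumor_af=float(row["tumor_af"]),
                normal_af=float(row["normal_af"]),
                panel_freq=float(row["panel_freq"]),
                in_coding=row["in_coding"].strip().lower() in ("1", "true", "yes"),
            )
            failed = tuple(c for c in row["failed_criteria"].split(",") if c)
            decisions.append(FilterDecision(v, passed=not failed, failed_criteria=failed))
    return decisions


def write_decision_table(decisions: Sequence[FilterDecision], path: str | Path) -> None:
    """Write filter decisions as TSV (variant columns + passed + failed_criteria)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS + ["passed", "failed_criteria"])
        for d in decisions:
            v = d.variant
            writer.writerow(
                [getattr(v, c) for c in _TSV_COLUMNS]
                + [int(d.passed), ",".join(d.failed_criteria)]
            )
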