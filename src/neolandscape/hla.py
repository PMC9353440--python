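"""HLA class I alleles at 4-digit resolution and consensus derivation.

Typing tools disagree; the conservative convention is to keep only the
alleles all tools report (set intersection), first across typers for one
sample and then across the tissue, organoid, and PBMC samples of one
patient. Only those consensus alleles restrict peptide candidates.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "HlaAllele",
    "HlaAlleleSet",
    "consensus_across_typers",
    "consensus_across_samples",
    "read_typer_table",
    "write_allele_sets",
]

_ALLELE_RE = re.compile(r"^(?:HLA-)?([ABC])\*(\d{2,3}):(\d{2,3})")


@dataclass(frozen=True, order=True)
class HlaAllele:
    """A 4-digit (two-field) HLA class I allele, e.g. ``A*11:01``."""

    locus: str
    group: str
    protein: str

    def __post_init__(self) -> None:
        if self.locus not in ("A", "B", "C"):
            raise ValueError(f"locus must be A/B/C, got {self.locus!r}")
        if not (self.group.isdigit() and self.protein.isdigit()):
            raise ValueError(f"allele fields must be numeric: {self}")

    @classmethod
    def parse(cls, text: str) -> "HlaAllele":
        """Parse ``A*11:01`` / ``HLA-A*11:01:01:02`` (extra fields truncated)."""
        m = _ALLELE_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse HLA allele {text!r}")
        return cls(locus=m.group(1), group=m.group(2), protein=m.group(3))

    def __str__(self) -> str:
        return f"{self.locus}*{self.group}:{self.protein}"


@dataclass
class HlaAlleleSet:
    """The alleles one source (typer or consensus) reports for one sample."""

    sample_id: str
    source: str
    alleles: frozenset[HlaAllele] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.alleles = frozenset(self.alleles)

    def by_locus(self, locus: str) -> frozenset[HlaAllele]:
        return frozenset(a for a in self.alleles if a.locus == locus)


def consensus_across_typers(results: Sequence[HlaAlleleSet]) -> HlaAlleleSet:
    """Intersect the allele sets reported by several typing tools.

    Requires at least two result sets sharing one sample_id. Alleles a
    tool omits are dropped; fully discordant loci end up empty and are
    logged.
    """
    if len(results) < 2:
        raise ValueError("consensus requires at least 2 typer results")
    ids = {r.sample_id for r in results}
    if len(ids) != 1:
        raise ValueError(f"results mix sample_ids: {sorted(ids)}")
    alleles = frozenset.intersection(*(r.alleles for r in results))
    dropped = frozenset.union(*(r.alleles for r in results)) - alleles
    if dropped:
        logger.warning(
            "sample %s: %d allele(s) not shared by all typers: %s",
            results[0].sample_id, len(dropped),
            ", ".join(str(a) for a in sorted(dropped)),
        )
    if not alleles:
        logger.warning("sample %s: empty typer consensus", results[0].sample_id)
    return HlaAlleleSet(sample_id=results[0].sample_id, source="consensus", alleles=alleles)


def consensus_across_samples(
    tissue: HlaAlleleSet, organoid: HlaAlleleSet, pbmc: HlaAlleleSet
) -> HlaAlleleSet:
    """Alleles shared by a patient's tissue, organoid, and PBMC samples."""
    alleles = tissue.alleles & organoid.alleles & pbmc.alleles
    if not alleles:
        logger.warning("no alleles shared across tissue/organoid/PBMC")
    return HlaAlleleSet(sample_id=tissue.sample_id, source="consensus", alleles=alleles)


def read_typer_table(path: str | Path) -> list[HlaAlleleSet]:
    """Read typer outputs from TSV columns (sample_id, source, allele)."""
    groups: dict[tuple[str, str], set[HlaAllele]] = {}
    order: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = (row["sample_id"], row["source"])
            if key not in groups:
                groups[key] = set()
                order.append(key)
            groups[key].add(HlaAllele.parse(row["allele"]))
    return [
        HlaAlleleSet(sample_id=s, source=src, alleles=frozenset(groups[(s, src)]))
        for s, src in order
    ]


def write_allele_sets(sets: Iterable[HlaAlleleSet], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "source", "allele"])
        for s in sets:
            for a in sorted(s.alleles):
                writer.writerow([s.sample_id, s.source, str(a)])
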