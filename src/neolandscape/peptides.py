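"""Mutant protein construction and 9-11mer candidate peptide enumeration.

Missense SNVs and in-frame (nonframeshift) indels are applied to the
coding sequence of their transcript, the mutant CDS is translated, and
every 9-11 residue window that overlaps the mutated region and does not
occur in the wild-type protein becomes a candidate peptide, paired with
each consensus HLA class I allele of the patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

from .hla import HlaAllele, HlaAlleleSet
from .variants import SomaticVariant

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "MutantProtein",
    "CandidatePeptide",
    "PresentationScores",
    "build_mutant_protein",
    "enumerate_candidate_peptides",
    "pair_with_alleles",
    "read_transcript_models",
    "write_peptides_fasta",
]

PEPTIDE_LENGTHS = (9, 10, 11)


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code, trimming at the first stop."""
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    stop = prot.find("*")
    return prot if stop < 0 else prot[:stop]


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's CDS and its translated protein."""

    transcript_id: str
    gene: str
    cds_sequence: str
    protein_sequence: str = ""

    def __post_init__(self) -> None:
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(self.cds_sequence)} "
                "not divisible by 3"
            )
        full = str(Seq(self.cds_sequence).translate())
        if "*" in full[:-1]:
            raise ValueError(f"{self.transcript_id}: internal stop codon")
        derived = full.rstrip("*")
        if not self.protein_sequence:
            object.__setattr__(self, "protein_sequence", derived)
        elif self.protein_sequence != derived:
            raise ValueError(
                f"{self.transcript_id}: protein_sequence does not match "
                "translated CDS"
            )


@dataclass(frozen=True)
class MutantProtein:
    """Wild-type/mutant protein pair with the affected residue interval.

    ``affected_interval`` is 1-based inclusive in mutant coordinates. For
    deletions it marks the two residues flanking the junction — the only
    place novel sequence can arise.
    """

    source_variant: SomaticVariant
    wild_type: str
    mutant: str
    affected_interval: tuple[int, int]
    premature_stop: bool = False

    def __post_init__(self) -> None:
        if not self.premature_stop:
            if self.mutant == self.wild_type:
                raise ValueError("mutant protein identical to wild type")
            lo, hi = self.affected_interval
            if not (1 <= lo <= hi <= len(self.mutant)):
                raise ValueError(
                    f"affected_interval {self.affected_interval} outside "
                    f"mutant bounds 1..{len(self.mutant)}"
                )


@dataclass(frozen=True)
class PresentationScores:
    """Presentation features for one peptide-allele pair.

    ``binding_rank`` is a percentile in [0, 100] (lower = stronger MHC
    binding); ``cleavage`` and ``tap`` are normalized proteasomal
    C-terminal cleavage and TAP transport efficiencies in [0, 1];
    ``combined`` multiplies cleavage and TAP; ``immunogenicity`` is the
    final combined score in [0, 1].
    """

    binding_rank: float
    cleavage: float
    tap: float
    combined: float
    immunogenicity: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.binding_rank <= 100.0:
            raise ValueError(f"binding_rank out of [0, 100]: {self.binding_rank}")
        for name in ("cleavage", "tap", "combined", "immunogenicity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0, 1]: {v}")


@dataclass(frozen=True)
class CandidatePeptide:
    """A mutant 9-11mer paired with one HLA allele, plus evidence flags."""

    sequence: str
    allele: Optional[HlaAllele]
    source_variant: SomaticVariant
    mutated_offsets: tuple[int, ...]
    scores: Optional[PresentationScores] = None
    expressed: bool = False
    sc_detected: bool = False
    ms_detected: bool = False
    hsn: bool = False
    selected: bool = False

    def __post_init__(self) -> None:
        if not 9 <= len(self.sequence) <= 11:
            raise ValueError(f"peptide length {len(self.sequence)} outside 9-11")
        if not self.mutated_offsets:
            raise ValueError("peptide must contain at least one mutated offset")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def with_(self, **changes) -> "CandidatePeptide":
        return replace(self, **changes)


class VariantRejected(ValueError):
    """The variant is outside the admissible missense/in-frame scope."""


def _apply_to_cds(cds: str, v: SomaticVariant) -> str:
    i = v.pos - 1
    if not (0 <= i and i + len(v.ref) <= len(cds)):
        raise VariantRejected(
            f"{v.key}: position outside CDS of length {len(cds)}"
        )
    if cds[i : i + len(v.ref)] != v.ref:
        raise VariantRejected(
            f"{v.key}: reference allele mismatch "
            f"(CDS has {cds[i:i + len(v.ref)]!r})"
        )
    return cds[:i] + v.alt + cds[i + len(v.ref):]


def build_mutant_protein(tx: TranscriptModel, v: SomaticVariant) -> MutantProtein:
    """Apply a missense SNV or in-frame indel to a transcript and diff.

    Frameshifts and variants outside the CDS are rejected with the rule
    named; a variant creating an immediate stop is flagged
    (``premature_stop=True``) and yields no peptides downstream.
    """
    if v.effect not in ("missense", "nonframeshift_indel"):
        raise VariantRejected(
            f"{v.key}: effect {v.effect!r} not in missense/nonframeshift scope"
        )
    if (len(v.alt) - len(v.ref)) % 3 != 0:
        raise VariantRejected(
            f"{v.key}: indel length difference {len(v.alt) - len(v.ref)} "
            "is not a multiple of 3 (frameshift)"
        )
    wt = tx.protein_sequence
    mut = translate_cds(_apply_to_cds(tx.cds_sequence, v))

    if mut == wt:
        raise VariantRejected(f"{v.key}: synonymous at protein level")
    if len(mut) < len(wt) + (len(v.alt) - len(v.ref)) // 3:
        # protein shorter than the frame predicts: a new stop codon arose
        logger.warning("%s: premature stop codon; no peptides generated", v.key)
        return MutantProtein(v, wt, mut, (1, 1), premature_stop=True)

    # maximal common prefix/suffix delimit the novel residues
    lo = 0
    limit = min(len(wt), len(mut))
    while lo < limit and wt[lo] == mut[lo]:
        lo += 1
    hi = 0
    while hi < limit - lo and wt[-1 - hi] == mut[-1 - hi]:
        hi += 1
    changed = (lo + 1, len(mut) - hi)  # 1-based inclusive, mutant coords
    if changed[0] > changed[1]:
        # pure deletion: mark the two junction-flanking residues
        changed = (max(1, lo), min(len(mut), lo + 1))
    return MutantProtein(v, wt, mut, changed)


def enumerate_candidate_peptides(
    mp: MutantProtein, lengths: Iterable[int] = PEPTIDE_LENGTHS
) -> list[tuple[str, tuple[int, ...]]]:
    """All windows of the requested lengths covering the mutated region.

    Returns (sequence, mutated_offsets) pairs where offsets are 0-based
    positions within the peptide that fall in the affected interval.
    Windows whose sequence occurs in the wild-type protein are excluded;
    duplicates by sequence are collapsed.
    """
    lengths = sorted(set(lengths))
    if not lengths:
        raise ValueError("lengths must be nonempty")
    if any(l < 9 or l > 11 for l in lengths):
        raise ValueError(f"lengths must be within {PEPTIDE_LENGTHS}")
    if mp.premature_stop:
        return []
    lo, hi = mp.affected_interval
    seen: set[str] = set()
    out: list[tuple[str, tuple[int, ...]]] = []
    for L in lengths:
        # 1-based window starts overlapping [lo, hi]
        start_min = max(1, lo - L + 1)
        start_max = min(len(mp.mutant) - L + 1, hi)
        for s in range(start_min, start_max + 1):
            seq = mp.mutant[s - 1 : s - 1 + L]
            if seq in seen or seq in mp.wild_type:
                continue
            seen.add(seq)
            offsets = tuple(i for i in range(L) if lo <= s + i <= hi)
            out.append((seq, offsets))
    return out


def pair_with_alleles(
    peptides: Sequence[tuple[str, tuple[int, ...]]],
    alleles: HlaAlleleSet,
    source_variant: SomaticVariant,
) -> list[CandidatePeptide]:
    """Cross product of peptides and consensus alleles."""
    if not alleles.alleles:
        logger.warning(
            "sample %s: empty consensus allele set; no candidates", alleles.sample_id
        )
        return []
    return [
        CandidatePeptide(
            sequence=seq, allele=a, source_variant=source_variant,
            mutated_offsets=offsets,
        )
        for seq, offsets in peptides
        for a in sorted(alleles.alleles)
    ]


# ---------------------------------------------------------------------------
# I/O

def read_transcript_models(
    fasta_path: str | Path, gene_table_path: str | Path
) -> dict[str, TranscriptModel]:
    """Load CDS FASTA plus a 2-column transcript_id<TAB>gene table."""
    from Bio import SeqIO

    genes: dict[str, str] = {}
    with open(gene_table_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tid, gene = line.split("\t")[:2]
            if tid == "transcript_id":
                continue
            genes[tid] = gene
    by_gene = {g: t for t, g in genes.items()}
    models = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        # FASTA records may be keyed by transcript id or by gene/contig name
        tid = rec.id if rec.id in genes else by_gene.get(rec.id)
        if tid is None:
            raise ValueError(f"transcript {rec.id} missing from gene table")
        models[tid] = TranscriptModel(
            transcript_id=tid, gene=genes[tid], cds_sequence=str(rec.seq)
        )
    return models


def write_peptides_fasta(candidates: Sequence[CandidatePeptide], path: str | Path) -> None:
    """Peptide FASTA; headers carry variant key, gene, allele, and length."""
    with open(path, "w") as fh:
        for i, c in enumerate(candidates):
            fh.write(
                f">pep{i}|{c.source_variant.key}|{c.source_variant.gene}"
                f"|{c.allele}|len{c.length}\n{c.sequence}\n"
            )
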