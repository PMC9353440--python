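"""Synthetic paired tissue/organoid cohorts with a full truth ledger.

The generator emulates the data structure of a paired-sample
neoantigen study: per patient, a tissue and an organoid somatic
variant set with a planted shared fraction; SNV trinucleotide contexts
drawn from a chosen signature mixture so that spectrum refitting is
testable; tumor/normal read statistics designed to straddle every
filter threshold; a panel-of-normals frequency column with a spike
above 0.05 to exercise the rescue clause; 4-digit HLA-A/B/C typings
from three simulated typers across tissue/organoid/PBMC; RNA
expression with mutant read support; a single-cell mutation table; an
MS-detected peptide list; and recurrent hotspot mutations (TP53 by
default, planted at a configurable cohort frequency).

Every latent quantity (realized shared fractions, signature mixture,
expressed subsets, hotspot carriers, per-criterion failure design
probabilities) is recorded in a truth ledger for recovery tests.
Shared fractions are realized exactly at the count level, so overlap
statistics recover the ledger values exactly rather than in
expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .expression import MutationExpression, ScMutationRow
from .hla import HlaAllele, HlaAlleleSet
from .peptides import TranscriptModel, build_mutant_protein, enumerate_candidate_peptides
from .signatures import CONTEXT_LABELS, synthetic_signature_catalog
from .variants import SomaticVariant

__all__ = [
    "CohortSpec",
    "PatientData",
    "Cohort",
    "generate_reference",
    "generate_paired_cohort",
    "write_cohort",
]

_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Common HLA class I alleles with plausible East-Asian-leaning pool
#: frequencies (normalized per locus at sampling time).
DEFAULT_HLA_POOL: dict[str, float] = {
    "A*11:01": 0.30, "A*24:02": 0.25, "A*02:01": 0.20, "A*33:03": 0.15, "A*30:01": 0.10,
    "B*40:01": 0.25, "B*46:01": 0.20, "B*58:01": 0.20, "B*13:01": 0.20, "B*15:01": 0.15,
    "C*07:02": 0.30, "C*01:02": 0.25, "C*03:04": 0.20, "C*08:01": 0.15, "C*06:02": 0.10,
}


@dataclass
class DepthModel:
    """Read-statistic design: per-criterion failure probabilities.

    Each probability is the designed chance that a variant fails the
    corresponding filter criterion; ``p_panel_rescue`` is the chance
    that a passing variant sits in the panel spike (frequency >= 0.05)
    and is rescued by a high tumor allele fraction.
    """

    p_fail_depth: float = 0.05       # C1
    p_fail_alt_reads: float = 0.05   # C2
    p_fail_tumor_af: float = 0.05    # C3
    p_fail_normal_af: float = 0.05   # C4
    p_fail_panel: float = 0.05       # C5
    p_panel_rescue: float = 0.05


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_pairs: int = 27
    mutations_per_sample: float = 90.0
    # Beta(4.8, 2.18) truncated to [0.28, 0.89] has mean 0.6673
    shared_fraction_beta: tuple[float, float] = (4.8, 2.18)
    shared_fraction_range: tuple[float, float] = (0.28, 0.89)
    shared_fraction_fixed: Optional[float] = None
    # deamination- and aflatoxin-style processes on a clock-like background:
    # C>T/G>A is the dominant class while the C>A signature stays prominent
    signature_mixture: dict[str, float] = field(
        default_factory=lambda: {"sbs1_like": 0.35, "sbs5_like": 0.30, "sbs24_like": 0.35}
    )
    hotspot_spec: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("TP53", "R90S", 0.43)]
    )
    depth_model: DepthModel = field(default_factory=DepthModel)
    hla_pool: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HLA_POOL))
    p_organoid_hla_loss: float = 0.04
    p_typer_dropout: float = 0.05
    indel_fraction: float = 0.08
    p_expressed: float = 0.7
    expression_lognormal: tuple[float, float] = (2.0, 1.0)
    rna_depth_mean: float = 50.0
    p_sc_detected: float = 0.15
    n_ms_peptides: int = 2
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (300, 1500)
    seed: int = 0

    def validate(self) -> None:
        w = sum(self.signature_mixture.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"signature mixture weights sum to {w}, expected 1")
        for name, _, freq in self.hotspot_spec:
            if not 0 <= freq <= 1:
                raise ValueError(f"hotspot {name}: frequency {freq} outside [0, 1]")
        if self.shared_fraction_fixed is not None and not (
            0 <= self.shared_fraction_fixed <= 1
        ):
            raise ValueError("shared_fraction_fixed outside [0, 1]")
        if self.n_pairs < 1 or self.mutations_per_sample <= 0:
            raise ValueError("infeasible cohort size")


@dataclass
class PatientData:
    """All generated inputs for one tissue/organoid pair."""

    patient_id: str
    tissue_variants: list[SomaticVariant]
    organoid_variants: list[SomaticVariant]
    typer_sets: dict[str, list[HlaAlleleSet]]  # sample type -> 3 typer outputs
    expression: dict[str, dict[str, MutationExpression]]  # sample type -> key -> row
    sc_rows: list[ScMutationRow]
    clinical: dict


@dataclass
class Cohort:
    """One synthetic cohort plus its truth ledger."""

    spec: CohortSpec
    reference: dict[str, str]
    transcripts: dict[str, TranscriptModel]
    patients: list[PatientData]
    ms_peptides: list[str]
    truth: dict


def generate_reference(
    n_genes: int = 40,
    gene_length_range: tuple[int, int] = (300, 1500),
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, TranscriptModel]]:
    """Deterministic mini reference: one contig per gene, contig == CDS.

    CDS lengths are multiples of 3, sampled from stop-free codons with
    a terminal stop. The first gene is named TP53 and carries an
    arginine codon (CGC) at residue 90 so the default hotspot is
    plantable; variant positions are 1-based CDS coordinates.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = gene_length_range
    reference: dict[str, str] = {}
    transcripts: dict[str, TranscriptModel] = {}
    for g in range(n_genes):
        gene = "TP53" if g == 0 else f"GENE{g:03d}"
        length = int(rng.integers(lo, hi + 1))
        if gene == "TP53":
            length = max(length, 600)
        n_codons = max(length // 3, 2)
        codons = [_CODONS[i] for i in rng.integers(0, len(_CODONS), size=n_codons - 1)]
        if gene == "TP53":
            codons[89] = "CGC"  # Arg90; C>A at codon pos 1 gives AGC (Ser)
        cds = "".join(codons) + "TAA"
        reference[gene] = cds
        transcripts[f"TX_{gene}"] = TranscriptModel(
            transcript_id=f"TX_{gene}", gene=gene, cds_sequence=cds
        )
    return reference, transcripts


def _context_index(reference: dict[str, str]) -> dict[tuple[str, str, str], list[tuple[str, int]]]:
    """Map canonical (5', pyrimidine ref, 3') triplets to genome positions.

    Positions whose reference base is a purine are indexed under the
    reverse-complement triplet (they host the variant on the other
    strand). Terminal stop codons and flank-less edge positions are
    excluded.
    """
    index: dict[tuple[str, str, str], list[tuple[str, int]]] = {}
    for gene, seq in reference.items():
        for i in range(1, len(seq) - 4):  # skip edges and the stop codon
            five, ref, three = seq[i - 1], seq[i], seq[i + 1]
            if ref in "CT":
                key = (five, ref, three)
            else:
                key = (_COMP[three], _COMP[ref], _COMP[five])
            index.setdefault(key, []).append((gene, i + 1))
    return index


def _parse_channel(label: str) -> tuple[str, str, str, str]:
    five, rest = label.split("[")
    sub, three = rest.split("]")
    ref, alt = sub.split(">")
    return five, ref, alt, three


def _snv_consequence(cds: str, pos: int, alt: str) -> tuple[str, str]:
    """(effect, protein_change) of substituting ``alt`` at 1-based ``pos``."""
    ci = (pos - 1) // 3
    codon = cds[ci * 3 : ci * 3 + 3]
    off = (pos - 1) % 3
    mut_codon = codon[:off] + alt + codon[off + 1 :]
    wt_aa = str(Seq(codon).translate())
    mut_aa = str(Seq(mut_codon).translate())
    if mut_aa == wt_aa:
        return "synonymous", f"{wt_aa}{ci + 1}{wt_aa}"
    if mut_aa == "*" or wt_aa == "*":
        return "other", f"{wt_aa}{ci + 1}{mut_aa}"
    return "missense", f"{wt_aa}{ci + 1}{mut_aa}"


def _draw_read_stats(rng: np.random.Generator, dm: DepthModel) -> dict:
    """Realize read statistics honoring the designed failure flags."""
    fail_c1 = rng.random() < dm.p_fail_depth
    fail_c2 = rng.random() < dm.p_fail_alt_reads
    fail_c3 = rng.random() < dm.p_fail_tumor_af
    fail_c4 = rng.random() < dm.p_fail_normal_af
    fail_c5 = rng.random() < dm.p_fail_panel

    if fail_c1:
        if rng.random() < 0.5:
            tumor_depth = int(rng.integers(5, 10))
            normal_depth = int(rng.integers(30, 200))
        else:
            tumor_depth = int(rng.integers(30, 200))
            normal_depth = int(rng.integers(5, 10))
    else:
        tumor_depth = int(rng.integers(30, 200))
        normal_depth = int(rng.integers(30, 200))

    tumor_af = float(rng.uniform(0.005, 0.049)) if fail_c3 else float(rng.uniform(0.08, 0.6))
    normal_af = float(rng.uniform(0.02, 0.2)) if fail_c4 else float(rng.uniform(0.0, 0.01))

    if fail_c5:
        panel_freq = float(rng.uniform(0.05, 0.3))
        if tumor_af >= 0.30:  # failing C5 requires AF below the rescue bar
            tumor_af = float(rng.uniform(0.08, 0.29))
    elif (not fail_c3) and rng.random() < dm.p_panel_rescue:
        panel_freq = float(rng.uniform(0.05, 0.3))
        tumor_af = float(rng.uniform(0.30, 0.6))
    else:
        panel_freq = float(rng.uniform(0.0, 0.049))

    if fail_c2:
        tumor_alt_reads = int(rng.integers(0, 3))
    else:
        tumor_alt_reads = min(max(3, round(tumor_af * tumor_depth)), tumor_depth)
    return dict(
        tumor_depth=tumor_depth, normal_depth=normal_depth,
        tumor_alt_reads=tumor_alt_reads, tumor_af=tumor_af,
        normal_af=normal_af, panel_freq=panel_freq,
    )


def _make_variant(
    rng: np.random.Generator,
    spec: CohortSpec,
    reference: dict[str, str],
    ctx_index: dict,
    channel_probs: np.ndarray,
    used: set[tuple[str, int]],
) -> Optional[SomaticVariant]:
    """One random variant: signature-driven SNV or in-frame deletion."""
    if rng.random() < spec.indel_fraction:
        for _ in range(30):
            gene = list(reference)[int(rng.integers(0, len(reference)))]
            cds = reference[gene]
            pos = int(rng.integers(4, len(cds) - 7))
            if (gene, pos) in used:
                continue
            ref = cds[pos - 1 : pos + 3]
            alt = ref[0]
            mut_cds = cds[: pos] + cds[pos + 3 :]
            prot = str(Seq(mut_cds[: len(mut_cds) - len(mut_cds) % 3]).translate())
            if "*" in prot[:-1]:
                continue  # deletion created a premature stop; retry
            used.add((gene, pos))
            stats = _draw_read_stats(rng, spec.depth_model)
            return SomaticVariant(
                chrom=gene, pos=pos, ref=ref, alt=alt, vclass="deletion",
                effect="nonframeshift_indel", gene=gene,
                transcript_id=f"TX_{gene}", protein_change="inframe_del",
                in_coding=True, **stats,
            )
        return None
    for _ in range(50):
        ch = int(rng.choice(96, p=channel_probs))
        five, refpyr, altpyr, three = _parse_channel(CONTEXT_LABELS[ch])
        sites = ctx_index.get((five, refpyr, three))
        if not sites:
            continue
        gene, pos = sites[int(rng.integers(0, len(sites)))]
        if (gene, pos) in used:
            continue
        base = reference[gene][pos - 1]
        ref, alt = (refpyr, altpyr) if base in "CT" else (_COMP[refpyr], _COMP[altpyr])
        effect, pchg = _snv_consequence(reference[gene], pos, alt)
        used.add((gene, pos))
        stats = _draw_read_stats(rng, spec.depth_model)
        return SomaticVariant(
            chrom=gene, pos=pos, ref=ref, alt=alt, vclass="SNV", effect=effect,
            gene=gene, transcript_id=f"TX_{gene}", protein_change=pchg,
            in_coding=True, **stats,
        )
    return None


def _sample_hla(rng: np.random.Generator, pool: dict[str, float]) -> frozenset[HlaAllele]:
    alleles: set[HlaAllele] = set()
    for locus in "ABC":
        names = [a for a in pool if a.startswith(locus)]
        p = np.array([pool[a] for a in names])
        p = p / p.sum()
        for _ in range(2):  # diploid; homozygosity collapses in the set
            alleles.add(HlaAllele.parse(names[int(rng.choice(len(names), p=p))]))
    return frozenset(alleles)


def generate_paired_cohort(
    spec: CohortSpec,
    reference: dict[str, str] | None = None,
    transcripts: dict[str, TranscriptModel] | None = None,
) -> Cohort:
    """Generate a full in-memory cohort with its truth ledger.

    One child random stream per artifact (variants, read depths, HLA,
    expression, single cell) keeps stages reproducible when parts of the
    spec change.
    """
    spec.validate()
    if reference is None or transcripts is None:
        reference, transcripts = generate_reference(
            spec.n_genes, spec.gene_length_range, seed=spec.seed
        )
    root = np.random.default_rng(spec.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("variants", "hla", "expression", "sc", "clinical"),
            root.spawn(5),
        )
    }

    catalog = synthetic_signature_catalog()
    mix = spec.signature_mixture
    unknown = set(mix) - set(catalog.columns)
    if unknown:
        raise ValueError(f"unknown signature ids in mixture: {sorted(unknown)}")
    channel_probs = np.zeros(96)
    for sig, w in mix.items():
        channel_probs += w * catalog[sig].to_numpy()
    channel_probs = channel_probs / channel_probs.sum()
    ctx_index = _context_index(reference)

    rng_v = streams["variants"]
    hotspot_carriers: dict[str, list[str]] = {name: [] for name, _, _ in spec.hotspot_spec}
    patients: list[PatientData] = []
    truth_pairs = []

    for p in range(spec.n_pairs):
        pid = f"P{p + 1:02d}"
        used: set[tuple[str, int]] = set()

        union_n = max(int(rng_v.poisson(spec.mutations_per_sample)), 2)
        if spec.shared_fraction_fixed is not None:
            s_frac = spec.shared_fraction_fixed
        else:
            a, b = spec.shared_fraction_beta
            lo_f, hi_f = spec.shared_fraction_range
            while True:  # truncated Beta via rejection
                s_frac = float(rng_v.beta(a, b))
                if lo_f <= s_frac <= hi_f:
                    break
        n_shared = int(round(s_frac * union_n))
        n_private = union_n - n_shared
        n_only_t = int(rng_v.binomial(n_private, 0.5))
        n_only_o = n_private - n_only_t

        # planted hotspots live in the shared core
        planted: list[SomaticVariant] = []
        for name, pchg, freq in spec.hotspot_spec:
            if rng_v.random() < freq and name in reference:
                # default: R90S via CGC->AGC, codon position 1 of residue 90
                pos = 89 * 3 + 1
                used.add((name, pos))
                stats = _draw_read_stats(rng_v, spec.depth_model)
                planted.append(SomaticVariant(
                    chrom=name, pos=pos, ref=reference[name][pos - 1], alt="A",
                    vclass="SNV", effect="missense", gene=name,
                    transcript_id=f"TX_{name}", protein_change=pchg,
                    in_coding=True, **stats,
                ))
                hotspot_carriers[name].append(pid)

        def draw_many(n: int) -> list[SomaticVariant]:
            out = []
            while len(out) < n:
                v = _make_variant(rng_v, spec, reference, ctx_index, channel_probs, used)
                if v is not None:
                    out.append(v)
            return out

        n_extra_shared = max(n_shared - len(planted), 0)
        shared = planted + draw_many(n_extra_shared)
        only_t = draw_many(n_only_t)
        only_o = draw_many(n_only_o)
        tissue = sorted(shared + only_t, key=lambda v: (v.chrom, v.pos))
        organoid = sorted(shared + only_o, key=lambda v: (v.chrom, v.pos))

        # HLA: PBMC genotype is truth; tissue matches; organoid may lose one
        rng_h = streams["hla"]
        genotype = _sample_hla(rng_h, spec.hla_pool)
        per_sample = {"pbmc": genotype, "tissue": genotype}
        org_alleles = set(genotype)
        if len(org_alleles) > 1 and rng_h.random() < spec.p_organoid_hla_loss:
            org_alleles.discard(sorted(org_alleles)[int(rng_h.integers(0, len(org_alleles)))])
        per_sample["organoid"] = frozenset(org_alleles)
        typer_sets: dict[str, list[HlaAlleleSet]] = {}
        for stype, alleles in per_sample.items():
            sets = []
            for t in range(1, 4):
                reported = set(alleles)
                if len(reported) > 1 and rng_h.random() < spec.p_typer_dropout:
                    reported.discard(
                        sorted(reported)[int(rng_h.integers(0, len(reported)))]
                    )
                sets.append(HlaAlleleSet(
                    sample_id=f"{pid}_{stype}", source=f"typer{t}",
                    alleles=frozenset(reported),
                ))
            typer_sets[stype] = sets

        # RNA expression per sample
        rng_e = streams["expression"]
        expression: dict[str, dict[str, MutationExpression]] = {}
        expressed_truth: dict[str, list[str]] = {}
        mu, sigma = spec.expression_lognormal
        for stype, variants in (("tissue", tissue), ("organoid", organoid)):
            rows = {}
            expressed = []
            for v in variants:
                total = int(rng_e.poisson(spec.rna_depth_mean))
                if rng_e.random() < spec.p_expressed and total > 0:
                    frac = min(max(v.tumor_af, 0.05), 1.0)
                    mutated = int(rng_e.binomial(total, frac))
                    if mutated == 0:
                        mutated = 1
                else:
                    mutated = 0
                gene_expr = float(rng_e.lognormal(mu, sigma))
                rows[v.key] = MutationExpression(
                    variant_key=v.key, mutated_reads=mutated,
                    total_reads=total, gene_expression=gene_expr,
                )
                if mutated > 0 and gene_expr > 0:
                    expressed.append(v.key)
            expression[stype] = rows
            expressed_truth[stype] = expressed

        # single-cell table for the organoid
        rng_s = streams["sc"]
        sc_rows: list[ScMutationRow] = []
        sc_truth: list[str] = []
        for v in organoid:
            if rng_s.random() < spec.p_sc_detected:
                n_cells = int(rng_s.integers(1, 6))
                for c in range(n_cells):
                    sc_rows.append(ScMutationRow(
                        variant_key=v.key, barcode=f"{pid}-BC{v.pos}-{c}",
                        detected=True, qual=float(rng_s.uniform(11, 60)),
                        dp=int(rng_s.integers(21, 120)),
                    ))
                sc_truth.append(v.key)
            elif rng_s.random() < 0.05:
                # sub-threshold rows exercise the QUAL/DP admission rule
                sc_rows.append(ScMutationRow(
                    variant_key=v.key, barcode=f"{pid}-BClow-{v.pos}",
                    detected=True, qual=float(rng_s.uniform(0, 10)),
                    dp=int(rng_s.integers(1, 20)),
                ))

        rng_c = streams["clinical"]
        clinical = {
            "stage_group": "I-IIIA" if rng_c.random() < 18 / 27 else "IIIB-IV",
            "age": int(rng_c.integers(35, 80)),
            "sex": "M" if rng_c.random() < 0.75 else "F",
            "afp_high": bool(rng_c.random() < 0.5),
            "mvi": "M0" if rng_c.random() < 0.6 else "M1+",
        }

        patients.append(PatientData(
            patient_id=pid, tissue_variants=tissue, organoid_variants=organoid,
            typer_sets=typer_sets, expression=expression, sc_rows=sc_rows,
            clinical=clinical,
        ))
        tkeys = {v.key for v in tissue}
        okeys = {v.key for v in organoid}
        realized_shared = len(tkeys & okeys)
        realized_union = len(tkeys | okeys)
        truth_pairs.append({
            "patient_id": pid,
            "n_tissue": len(tissue), "n_organoid": len(organoid),
            "n_shared": realized_shared, "n_union": realized_union,
            "shared_fraction": realized_shared / realized_union,
            "expressed": expressed_truth,
            "sc_detected_variants": sorted(sc_truth),
            "hla_genotype": sorted(str(a) for a in genotype),
            "organoid_hla": sorted(str(a) for a in per_sample["organoid"]),
        })

    # MS list: a few real mutant 9mers from early patients' shared missense SNVs
    ms_peptides: list[str] = []
    for patient in patients:
        if len(ms_peptides) >= spec.n_ms_peptides:
            break
        shared_keys = {v.key for v in patient.tissue_variants} & {
            v.key for v in patient.organoid_variants
        }
        for v in patient.tissue_variants:
            if v.key in shared_keys and v.effect == "missense" and v.vclass == "SNV":
                mp = build_mutant_protein(transcripts[v.transcript_id], v)
                if mp.premature_stop:
                    continue
                windows = enumerate_candidate_peptides(mp, lengths=(9,))
                if windows:
                    ms_peptides.append(windows[0][0])
                    break

    truth = {
        "spec": {
            "n_pairs": spec.n_pairs,
            "mutations_per_sample": spec.mutations_per_sample,
            "signature_mixture": dict(spec.signature_mixture),
            "hotspot_spec": [list(h) for h in spec.hotspot_spec],
            "depth_model": asdict(spec.depth_model),
            "seed": spec.seed,
        },
        "pairs": truth_pairs,
        "hotspot_carriers": {k: sorted(v) for k, v in hotspot_carriers.items()},
        "ms_peptides": list(ms_peptides),
        "mean_shared_fraction": float(
            np.mean([t["shared_fraction"] for t in truth_pairs])
        ),
    }
    return Cohort(
        spec=spec, reference=reference, transcripts=transcripts,
        patients=patients, ms_peptides=ms_peptides, truth=truth,
    )


# ---------------------------------------------------------------------------
# File emission (the exact dialects the pipeline reads)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=TDP,Number=A,Type=Integer,Description="Tumor depth">
##INFO=<ID=NDP,Number=A,Type=Integer,Description="Normal depth">
##INFO=<ID=TAD,Number=A,Type=Integer,Description="Tumor alt-supporting reads">
##INFO=<ID=TAF,Number=A,Type=Float,Description="Tumor allele fraction">
##INFO=<ID=NAF,Number=A,Type=Float,Description="Normal allele fraction">
##INFO=<ID=PFREQ,Number=A,Type=Float,Description="Panel-of-normals frequency">
##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol">
##INFO=<ID=TXID,Number=A,Type=String,Description="Transcript id">
##INFO=<ID=PCHG,Number=A,Type=String,Description="Protein change">
##INFO=<ID=EFFECT,Number=A,Type=String,Description="Variant effect">
##INFO=<ID=CODING,Number=1,Type=Integer,Description="1 if in coding region">
"""


def write_variant_vcf(
    variants: Sequence[SomaticVariant], contigs: dict[str, str], path: Path
) -> None:
    """Plain-text single-sample VCF 4.2 with the pipeline's INFO keys."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name in sorted(contigs):
            fh.write(f"##contig=<ID={name},length={len(contigs[name])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            info = (
                f"TDP={v.tumor_depth};NDP={v.normal_depth};TAD={v.tumor_alt_reads};"
                f"TAF={v.tumor_af:.6f};NAF={v.normal_af:.6f};PFREQ={v.panel_freq:.6f};"
                f"GENE={v.gene};TXID={v.transcript_id};PCHG={v.protein_change};"
                f"EFFECT={v.effect};CODING={int(v.in_coding)}"
            )
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n")


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Emit a cohort as files (FASTA, VCFs, TSVs, truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "reference.fasta", "w") as fh:
        for gene in sorted(cohort.reference):
            fh.write(f">{gene}\n{cohort.reference[gene]}\n")
    with open(outdir / "transcripts.tsv", "w") as fh:
        fh.write("transcript_id\tgene\n")
        for tid in sorted(cohort.transcripts):
            fh.write(f"{tid}\t{cohort.transcripts[tid].gene}\n")

    hla_rows = []
    for patient in cohort.patients:
        for stype in ("tissue", "organoid", "pbmc"):
            for s in patient.typer_sets[stype]:
                for a in sorted(s.alleles):
                    hla_rows.append((s.sample_id, s.source, str(a)))
        for stype, variants in (
            ("tissue", patient.tissue_variants),
            ("organoid", patient.organoid_variants),
        ):
            write_variant_vcf(
                variants, cohort.reference,
                outdir / f"{patient.patient_id}_{stype}.vcf",
            )
            with open(outdir / f"{patient.patient_id}_{stype}_expression.tsv", "w") as fh:
                fh.write("variant_key\tmutated_reads\ttotal_reads\tgene_expression\n")
                for key in sorted(patient.expression[stype]):
                    r = patient.expression[stype][key]
                    fh.write(
                        f"{r.variant_key}\t{r.mutated_reads}\t{r.total_reads}"
                        f"\t{r.gene_expression:.6f}\n"
                    )
        with open(outdir / f"{patient.patient_id}_organoid_sc.tsv", "w") as fh:
            fh.write("variant_key\tbarcode\tdetected\tqual\tdp\n")
            for r in patient.sc_rows:
                fh.write(f"{r.variant_key}\t{r.barcode}\t{int(r.detected)}\t{r.qual:.2f}\t{r.dp}\n")

    with open(outdir / "hla_typers.tsv", "w") as fh:
        fh.write("sample_id\tsource\tallele\n")
        for sid, src, allele in hla_rows:
            fh.write(f"{sid}\t{src}\t{allele}\n")
    with open(outdir / "ms_peptides.txt", "w") as fh:
        for p in cohort.ms_peptides:
            fh.write(p + "\n")
    with open(outdir / "clinical.tsv", "w") as fh:
        fh.write("patient_id\tstage_group\tage\tsex\tafp_high\tmvi\n")
        for patient in cohort.patients:
            c = patient.clinical
            fh.write(
                f"{patient.patient_id}\t{c['stage_group']}\t{c['age']}\t{c['sex']}"
                f"\t{int(c['afp_high'])}\t{c['mvi']}\n"
            )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    return outdir
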