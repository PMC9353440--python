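"""End-to-end orchestration of the neoantigen landscape stages.

Stage order mirrors the analysis funnel: simulate (or ingest) ->
somatic filter -> HLA consensus -> peptide enumeration -> presentation
scoring -> evidence integration (expression / single-cell / MS, HSN
flagging, validation selection) -> concordance and signature reports.
Each stage reads and writes plain files under one run directory, so
chaining the stage subcommands is byte-identical to a monolithic run;
the manifest records record counts at every stage boundary plus
digests of every output file.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import concordance as cc
from . import expression as ex
from . import hla as hl
from . import scoring as sc
from . import signatures as sg
from . import simulate as sim
from . import variants as va
from . import peptides as pe

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "STAGES"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterOptions(_Strict):
    coding_mb: float = Field(34.0, gt=0)


class ScorerOptions(_Strict):
    name: str = "mock"
    seed: int = 0
    combiner: str = "rank_cleavage_tap"


class HsnOptions(_Strict):
    top_fraction: float = Field(0.30, gt=0, le=1)
    pool: str = "tissue"  # cohort-pooled tissue candidates set the cutoff


class ExpressionOptions(_Strict):
    enabled: bool = True
    min_mutant_expression: float = 0.0
    il_equivalent_ms: bool = False
    sc_min_cells: int = 1


class SelectOptions(_Strict):
    k_min: int = Field(10, ge=1)
    prefer_tp53: bool = True


class SignatureOptions(_Strict):
    prune_below: float = Field(0.06, ge=0, lt=1)


class CohortOptions(_Strict):
    n_pairs: int = Field(27, ge=1)
    mutations_per_sample: float = Field(90.0, gt=0)
    shared_fraction_mean: Optional[float] = None
    hotspot_frequency: float = Field(0.43, ge=0, le=1)
    n_genes: int = Field(40, ge=1)


class RunConfig(_Strict):
    """Validated, fully defaulted run configuration (schema version 1)."""

    schema_version: int = 1
    seed: int = 0
    input_dir: Optional[str] = None  # None => simulate
    cohort: CohortOptions = CohortOptions()
    filter: FilterOptions = FilterOptions()
    scorer: ScorerOptions = ScorerOptions()
    hsn: HsnOptions = HsnOptions()
    expression: ExpressionOptions = ExpressionOptions()
    select: SelectOptions = SelectOptions()
    signatures: SignatureOptions = SignatureOptions()


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; all schema errors are reported."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def _cohort_spec(cfg: RunConfig) -> sim.CohortSpec:
    spec = sim.CohortSpec(
        n_pairs=cfg.cohort.n_pairs,
        mutations_per_sample=cfg.cohort.mutations_per_sample,
        n_genes=cfg.cohort.n_genes,
        seed=cfg.seed,
    )
    if cfg.cohort.shared_fraction_mean is not None:
        m = cfg.cohort.shared_fraction_mean
        spec.shared_fraction_beta = (7.2 * m, 7.2 * (1 - m))
    spec.hotspot_spec = [("TP53", "R90S", cfg.cohort.hotspot_frequency)]
    return spec


def _patient_ids(inputs: Path) -> list[str]:
    return sorted(p.name.split("_tissue")[0] for p in inputs.glob("*_tissue.vcf"))


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    inputs = outdir / "inputs"
    cohort = sim.generate_paired_cohort(_cohort_spec(cfg))
    sim.write_cohort(cohort, inputs)
    n_var = sum(
        len(p.tissue_variants) + len(p.organoid_variants) for p in cohort.patients
    )
    return {"patients": len(cohort.patients), "variants_emitted": n_var}


def stage_filter(cfg: RunConfig, outdir: Path) -> dict:
    inputs = Path(cfg.input_dir) if cfg.input_dir else outdir / "inputs"
    fdir = outdir / "filtered"
    fdir.mkdir(parents=True, exist_ok=True)
    counts = {"in": 0, "passed": 0}
    tmb_rows = []
    for pid in _patient_ids(inputs):
        for stype in ("tissue", "organoid"):
            variants = va.read_variant_table(inputs / f"{pid}_{stype}.vcf", "vcf")
            decisions = va.apply_somatic_filters(variants)
            va.write_decision_table(decisions, fdir / f"{pid}_{stype}_decisions.tsv")
            tmb = va.compute_tmb(decisions, cfg.filter.coding_mb)
            tmb_rows.append((pid, stype, tmb))
            counts["in"] += len(variants)
            counts["passed"] += sum(d.passed for d in decisions)
    with open(fdir / "tmb.tsv", "w") as fh:
        fh.write("patient_id\tsample_type\ttmb\n")
        for pid, stype, tmb in tmb_rows:
            fh.write(f"{pid}\t{stype}\t{tmb!r}\n")
    return counts


def stage_hla(cfg: RunConfig, outdir: Path) -> dict:
    inputs = Path(cfg.input_dir) if cfg.input_dir else outdir / "inputs"
    hdir = outdir / "hla"
    hdir.mkdir(parents=True, exist_ok=True)
    typer_sets = hl.read_typer_table(inputs / "hla_typers.tsv")
    by_sample: dict[str, list[hl.HlaAlleleSet]] = {}
    for s in typer_sets:
        by_sample.setdefault(s.sample_id, []).append(s)
    patient_consensus: list[hl.HlaAlleleSet] = []
    per_sample: list[hl.HlaAlleleSet] = []
    pids = sorted({sid.rsplit("_", 1)[0] for sid in by_sample})
    for pid in pids:
        cons = {}
        for stype in ("tissue", "organoid", "pbmc"):
            cons[stype] = hl.consensus_across_typers(by_sample[f"{pid}_{stype}"])
            per_sample.append(cons[stype])
        shared = hl.consensus_across_samples(cons["tissue"], cons["organoid"], cons["pbmc"])
        patient_consensus.append(hl.HlaAlleleSet(pid, "consensus", shared.alleles))
    hl.write_allele_sets(per_sample, hdir / "sample_consensus.tsv")
    hl.write_allele_sets(patient_consensus, hdir / "patient_consensus.tsv")
    return {
        "patients": len(pids),
        "consensus_alleles": sum(len(s.alleles) for s in patient_consensus),
    }


def _load_patient_alleles(outdir: Path) -> dict[str, hl.HlaAlleleSet]:
    sets = hl.read_typer_table(outdir / "hla" / "patient_consensus.tsv")
    return {s.sample_id: s for s in sets}


def stage_enumerate(cfg: RunConfig, outdir: Path) -> dict:
    inputs = Path(cfg.input_dir) if cfg.input_dir else outdir / "inputs"
    pdir = outdir / "peptides"
    pdir.mkdir(parents=True, exist_ok=True)
    transcripts = pe.read_transcript_models(
        inputs / "reference.fasta", inputs / "transcripts.tsv"
    )
    alleles = _load_patient_alleles(outdir)
    counts = {"eligible_variants": 0, "candidates": 0}
    for pid in _patient_ids(inputs):
        for stype in ("tissue", "organoid"):
            decisions = va.read_decision_table(
                outdir / "filtered" / f"{pid}_{stype}_decisions.tsv"
            )
            candidates: list[pe.CandidatePeptide] = []
            for d in decisions:
                v = d.variant
                if not d.passed or v.effect not in ("missense", "nonframeshift_indel"):
                    continue
                counts["eligible_variants"] += 1
                mp = pe.build_mutant_protein(transcripts[v.transcript_id], v)
                windows = pe.enumerate_candidate_peptides(mp)
                candidates.extend(pe.pair_with_alleles(windows, alleles[pid], v))
            # one candidate per (sequence, allele) across a gene's transcripts
            seen: set[tuple[str, str]] = set()
            unique = []
            for c in candidates:
                key = (c.sequence, str(c.allele))
                if key not in seen:
                    seen.add(key)
                    unique.append(c)
            counts["candidates"] += len(unique)
            with open(pdir / f"{pid}_{stype}_peptides.tsv", "w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(["sequence", "allele", "variant_key", "mutated_offsets"])
                for c in unique:
                    w.writerow([
                        c.sequence, str(c.allele), c.source_variant.key,
                        ",".join(map(str, c.mutated_offsets)),
                    ])
    return counts


def _load_candidates(cfg: RunConfig, outdir: Path, pid: str, stype: str) -> list[pe.CandidatePeptide]:
    decisions = va.read_decision_table(
        outdir / "filtered" / f"{pid}_{stype}_decisions.tsv"
    )
    by_key = {d.variant.key: d.variant for d in decisions}
    out = []
    with open(outdir / "peptides" / f"{pid}_{stype}_peptides.tsv", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(pe.CandidatePeptide(
                sequence=row["sequence"],
                allele=hl.HlaAllele.parse(row["allele"]),
                source_variant=by_key[row["variant_key"]],
                mutated_offsets=tuple(int(i) for i in row["mutated_offsets"].split(",")),
            ))
    return out


def stage_score(cfg: RunConfig, outdir: Path) -> dict:
    inputs = Path(cfg.input_dir) if cfg.input_dir else outdir / "inputs"
    sdir = outdir / "scored"
    sdir.mkdir(parents=True, exist_ok=True)
    spec = sc.ScorerSpec(name=cfg.scorer.name, seed=cfg.scorer.seed)
    n = 0
    for pid in _patient_ids(inputs):
        for stype in ("tissue", "organoid"):
            cands = _load_candidates(cfg, outdir, pid, stype)
            scored = sc.score_candidates(cands, spec, cfg.scorer.combiner)
            sc.write_scored_table(scored, sdir / f"{pid}_{stype}_scored.tsv")
            n += len(scored)
    return {"scored": n}


def _load_scored(cfg: RunConfig, outdir: Path, pid: str, stype: str) -> list[pe.CandidatePeptide]:
    cands = _load_candidates(cfg, outdir, pid, stype)
    spec = sc.ScorerSpec(name=cfg.scorer.name, seed=cfg.scorer.seed)
    return sc.score_candidates(cands, spec, cfg.scorer.combiner)


def stage_integrate(cfg: RunConfig, outdir: Path) -> dict:
    """Evidence flags, HSN flagging, and per-patient validation selection."""
    inputs = Path(cfg.input_dir) if cfg.input_dir else outdir / "inputs"
    idir = outdir / "integrated"
    idir.mkdir(parents=True, exist_ok=True)
    pids = _patient_ids(inputs)

    ms_path = inputs / "ms_peptides.txt"
    ms_list = (
        [l.strip() for l in open(ms_path) if l.strip()] if ms_path.exists() else []
    )

    # pooled HSN cutoff from the tissue candidate pool
    pool: list[pe.CandidatePeptide] = []
    per_sample: dict[tuple[str, str], list[pe.CandidatePeptide]] = {}
    for pid in pids:
        for stype in ("tissue", "organoid"):
            cands = _load_scored(cfg, outdir, pid, stype)
            per_sample[(pid, stype)] = cands
            if stype == cfg.hsn.pool or cfg.hsn.pool == "both":
                pool.extend(cands)
    if pool:
        _, cutoff = sc.flag_hsn(pool, cfg.hsn.top_fraction)
    else:
        cutoff = float("inf")

    counts = {"main_track": 0, "audited": 0, "hsn": 0, "selected": 0}
    hsn_loads = []
    for pid in pids:
        for stype in ("tissue", "organoid"):
            cands = per_sample[(pid, stype)]
            cands = [
                c.with_(hsn=(c.scores.immunogenicity >= cutoff)) for c in cands
            ]
            if cfg.expression.enabled:
                expr = ex.read_expression_table(
                    inputs / f"{pid}_{stype}_expression.tsv"
                )
                kept, audit = ex.expression_filter(
                    cands, expr, cfg.expression.min_mutant_expression
                )
            else:
                kept, audit = [c.with_(expressed=True) for c in cands], []
            sc_path = inputs / f"{pid}_organoid_sc.tsv"
            if stype == "organoid" and sc_path.exists():
                rows = ex.read_sc_table(sc_path)
                kept, _cells = ex.flag_sc_detected(
                    kept, rows, min_cells=cfg.expression.sc_min_cells
                )
            kept = ex.flag_ms_detected(kept, ms_list, cfg.expression.il_equivalent_ms)
            if stype == "organoid" and kept:
                kept = sc.select_for_validation(
                    kept, k_min=cfg.select.k_min, prefer_tp53=cfg.select.prefer_tp53
                )
            sc.write_scored_table(kept, idir / f"{pid}_{stype}_integrated.tsv")
            with open(idir / f"{pid}_{stype}_audit.tsv", "w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(["peptide", "allele", "variant_key", "reason"])
                for c, reason in audit:
                    w.writerow([c.sequence, str(c.allele), c.source_variant.key, reason])
            counts["main_track"] += len(kept)
            counts["audited"] += len(audit)
            counts["hsn"] += sum(c.hsn for c in kept)
            counts["selected"] += sum(c.selected for c in kept)
            hsn_loads.append((pid, stype, sum(c.hsn for c in kept), len(kept)))
    with open(idir / "hsn_summary.json", "w") as fh:
        json.dump(
            {
                "cutoff": cutoff,
                "pool_size": len(pool),
                "per_sample": [
                    {"patient_id": p, "sample_type": s, "hsn": h, "candidates": n}
                    for p, s, h, n in hsn_loads
                ],
            },
            fh, indent=1, sort_keys=True,
        )
    return counts


def stage_concordance(cfg: RunConfig, outdir: Path) -> dict:
    inputs = Path(cfg.input_dir) if cfg.input_dir else outdir / "inputs"
    rdir = outdir / "reports"
    rdir.mkdir(parents=True, exist_ok=True)
    pids = _patient_ids(inputs)

    pairs = []
    tmb = {}
    with open(outdir / "filtered" / "tmb.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            tmb[(row["patient_id"], row["sample_type"])] = float(row["tmb"])
    loads: dict[str, dict[str, tuple[int, int]]] = {}
    clinical = {}
    clin_path = inputs / "clinical.tsv"
    if clin_path.exists():
        with open(clin_path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                clinical[row["patient_id"]] = row
    for pid in pids:
        sets = {}
        peps = {}
        for stype in ("tissue", "organoid"):
            decisions = va.read_decision_table(
                outdir / "filtered" / f"{pid}_{stype}_decisions.tsv"
            )
            sets[stype] = frozenset(d.variant.key for d in decisions if d.passed)
            cands = _read_integrated(outdir, pid, stype)
            peps[stype] = frozenset(f"{c['peptide']}|{c['allele']}" for c in cands)
            loads.setdefault(pid, {})[stype] = (
                len(cands), sum(int(c["hsn"]) for c in cands)
            )
        pairs.append(cc.PairedSample(
            patient_id=pid,
            tissue_variants=sets["tissue"], organoid_variants=sets["organoid"],
            tissue_peptides=peps["tissue"], organoid_peptides=peps["organoid"],
            clinical=clinical.get(pid, {}),
        ))

    with open(rdir / "overlap.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([
            "patient_id", "level", "only_tissue", "only_organoid", "shared",
            "shared_fraction",
        ])
        fractions = []
        for p in pairs:
            for level in ("mutation", "peptide"):
                try:
                    ov = cc.pair_overlap(p, level)
                except ValueError:
                    continue
                w.writerow([
                    p.patient_id, level, ov.only_tissue, ov.only_organoid,
                    ov.shared, f"{float(ov.shared_fraction):.6f}",
                ])
                if level == "mutation":
                    fractions.append(float(ov.shared_fraction))

    stats: dict = {
        "mean_shared_fraction": float(np.mean(fractions)),
        "min_shared_fraction": float(np.min(fractions)),
        "max_shared_fraction": float(np.max(fractions)),
    }

    if len(pairs) >= 2:
        m = cc.cross_similarity_matrix(pairs)
        with open(rdir / "similarity.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["organoid\\tissue"] + pids)
            for i, pid in enumerate(pids):
                w.writerow([pid] + [f"{x:.6f}" for x in m[i]])
        off = m[~np.eye(len(pids), dtype=bool)]
        stats["similarity_diag_mean"] = float(np.diag(m).mean())
        stats["similarity_offdiag_max"] = float(off.max()) if off.size else 0.0

    if len(pids) >= 3:
        t_tmb = [tmb[(pid, "tissue")] for pid in pids]
        o_tmb = [tmb[(pid, "organoid")] for pid in pids]
        stats["tmb"] = cc.paired_cohort_stats(t_tmb, o_tmb)
        t_load = [loads[pid]["tissue"][0] for pid in pids]
        o_load = [loads[pid]["organoid"][0] for pid in pids]
        stats["neoantigen_load"] = cc.paired_cohort_stats(t_load, o_load)
        t_hsn = [float(loads[pid]["tissue"][1]) for pid in pids]
        o_hsn = [float(loads[pid]["organoid"][1]) for pid in pids]
        if np.std(t_hsn) > 0 and np.std(o_hsn) > 0:
            stats["hsn_load"] = cc.paired_cohort_stats(t_hsn, o_hsn)
        stats["tmb_vs_neoantigen_tissue"] = cc.paired_cohort_stats(t_tmb, t_load)

    if clinical:
        early = [
            float(loads[pid]["tissue"][0]) for pid in pids
            if clinical[pid]["stage_group"] == "I-IIIA"
        ]
        late = [
            float(loads[pid]["tissue"][0]) for pid in pids
            if clinical[pid]["stage_group"] == "IIIB-IV"
        ]
        if len(early) >= 2 and len(late) >= 2:
            stats["neoantigen_by_stage"] = cc.group_compare(
                [early, late], design="unpaired_t"
            )

    with open(rdir / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)
    return {"pairs": len(pairs)}


def _read_integrated(outdir: Path, pid: str, stype: str) -> list[dict]:
    path = outdir / "integrated" / f"{pid}_{stype}_integrated.tsv"
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def stage_signatures(cfg: RunConfig, outdir: Path) -> dict:
    inputs = Path(cfg.input_dir) if cfg.input_dir else outdir / "inputs"
    rdir = outdir / "reports"
    rdir.mkdir(parents=True, exist_ok=True)
    from Bio import SeqIO

    reference = {
        r.id: str(r.seq) for r in SeqIO.parse(str(inputs / "reference.fasta"), "fasta")
    }
    catalog = sg.synthetic_signature_catalog()
    rows = []
    for pid in _patient_ids(inputs):
        for stype in ("tissue", "organoid"):
            decisions = va.read_decision_table(
                outdir / "filtered" / f"{pid}_{stype}_decisions.tsv"
            )
            snvs = [d.variant for d in decisions if d.passed and d.variant.vclass == "SNV"]
            spectrum = sg.build_spectrum(snvs, reference)
            if spectrum.total == 0:
                continue
            exp = sg.refit_exposures(spectrum, catalog, cfg.signatures.prune_below)
            for sig in sorted(exp.exposures):
                rows.append((pid, stype, sig, exp.exposures[sig], exp.residual))
    with open(rdir / "exposures.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["patient_id", "sample_type", "signature", "exposure", "residual"])
        for pid, stype, sig, e, r in rows:
            w.writerow([pid, stype, sig, f"{e:.6f}", f"{r:.6f}"])
    return {"exposure_rows": len(rows)}


STAGES = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "hla": stage_hla,
    "enumerate": stage_enumerate,
    "score": stage_score,
    "integrate": stage_integrate,
    "concordance": stage_concordance,
    "signatures": stage_signatures,
}


def _digest_tree(outdir: Path) -> dict[str, str]:
    digests = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            digests[str(p.relative_to(outdir))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    return digests


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run every stage in order and write a self-describing manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_names = list(STAGES)
    if cfg.input_dir is not None:
        stage_names.remove("simulate")
    manifest: dict = {"config": cfg.model_dump(), "stages": {}}
    for name in stage_names:
        logger.info("stage %s starting", name)
        try:
            manifest["stages"][name] = STAGES[name](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done: %s", name, manifest["stages"][name])
    manifest["digests"] = _digest_tree(outdir)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
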