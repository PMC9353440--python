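"""Presentation scoring, immunogenic-potential combination, HSN flagging,
and candidate selection for validation.

The presentation predictor is pluggable: any callable mapping a
(peptide, allele) pair to binding rank / cleavage / TAP features can be
registered. The packaged ``mock`` scorer is a seeded hash-to-[0,1] map,
so whole pipelines are deterministic and testable offline; it makes no
claim to biophysical accuracy.

The default combined score is

    immunogenicity = (1 - binding_rank/100) * cleavage * tap

which is monotone increasing in each favorable component and bounded in
[0, 1]. High-score neoantigens (HSNs) are the pooled top 30% of the
cohort's score distribution; the cutoff is the minimum flagged score and
ties at the cutoff share its fate.
"""

from __future__ import annotations

import csv
import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .peptides import CandidatePeptide, PresentationScores

logger = logging.getLogger(__name__)

__all__ = [
    "ScorerSpec",
    "score_presentation",
    "combine_immunogenicity",
    "score_candidates",
    "flag_hsn",
    "select_for_validation",
    "write_scored_table",
]


@dataclass(frozen=True)
class ScorerSpec:
    """Names a presentation scorer; same spec + peptide + allele => same scores."""

    name: str = "mock"
    seed: int = 0
    parameters: tuple[tuple[str, object], ...] = field(default_factory=tuple)

    @classmethod
    def from_mapping(cls, m: Mapping) -> "ScorerSpec":
        params = {k: v for k, v in m.items() if k not in ("name", "seed")}
        return cls(
            name=m.get("name", "mock"),
            seed=int(m.get("seed", 0)),
            parameters=tuple(sorted(params.items())),
        )


def _hash_unit(*parts: object) -> float:
    """Deterministic map of the parts to a float in [0, 1)."""
    h = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:8], "big") / 2**64


def _mock_features(peptide: str, allele: str, spec: ScorerSpec) -> tuple[float, float, float]:
    # binding rank skewed toward weak binding, like real percentile ranks
    u = _hash_unit(spec.seed, "rank", peptide, allele)
    rank = 100.0 * u ** 0.5
    cleavage = _hash_unit(spec.seed, "cleavage", peptide)
    tap = _hash_unit(spec.seed, "tap", peptide)
    return rank, cleavage, tap


_SCORERS: dict[str, Callable[[str, str, ScorerSpec], tuple[float, float, float]]] = {
    "mock": _mock_features,
}


def register_scorer(
    name: str, fn: Callable[[str, str, ScorerSpec], tuple[float, float, float]]
) -> None:
    """Register a presentation predictor returning (binding_rank, cleavage, tap)."""
    _SCORERS[name] = fn


def combine_immunogenicity(s: PresentationScores, combiner: str = "rank_cleavage_tap") -> float:
    """Combine presentation features into one immunogenic-potential score."""
    if combiner == "rank_cleavage_tap":
        return (1.0 - s.binding_rank / 100.0) * s.cleavage * s.tap
    if combiner == "rank_only":
        return 1.0 - s.binding_rank / 100.0
    raise ValueError(f"unknown combiner {combiner!r}")


def score_presentation(
    p: CandidatePeptide, scorer: ScorerSpec, combiner: str = "rank_cleavage_tap"
) -> PresentationScores:
    """Compute presentation features and the combined score for one candidate."""
    if not 9 <= len(p.sequence) <= 11:
        raise ValueError(f"unsupported peptide length {len(p.sequence)}")
    if scorer.name not in _SCORERS:
        raise ValueError(f"unknown scorer {scorer.name!r}")
    rank, cleavage, tap = _SCORERS[scorer.name](p.sequence, str(p.allele), scorer)
    partial = PresentationScores(
        binding_rank=rank, cleavage=cleavage, tap=tap, combined=cleavage * tap
    )
    immuno = combine_immunogenicity(partial, combiner)
    return PresentationScores(
        binding_rank=rank, cleavage=cleavage, tap=tap,
        combined=cleavage * tap, immunogenicity=immuno,
    )


def score_candidates(
    candidates: Sequence[CandidatePeptide],
    scorer: ScorerSpec,
    combiner: str = "rank_cleavage_tap",
) -> list[CandidatePeptide]:
    """Score a batch, order-preserving."""
    return [c.with_(scores=score_presentation(c, scorer, combiner)) for c in candidates]


def flag_hsn(
    candidates: Sequence[CandidatePeptide], top_fraction: float = 0.30
) -> tuple[list[CandidatePeptide], float]:
    """Flag the top ``top_fraction`` of candidates by score as HSNs.

    The top ceil(top_fraction * N) scores are flagged; the returned
    cutoff is the minimum flagged score and any ties at the cutoff are
    flagged too. Input order is preserved in the returned list.
    """
    if not candidates:
        raise ValueError("flag_hsn requires at least one scored candidate")
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError(f"top_fraction out of (0, 1]: {top_fraction}")
    scores = []
    for c in candidates:
        if c.scores is None:
            raise ValueError("all candidates must be scored before HSN flagging")
        scores.append(c.scores.immunogenicity)
    k = math.ceil(top_fraction * len(scores))
    cutoff = sorted(scores, reverse=True)[k - 1]
    flagged = [c.with_(hsn=(c.scores.immunogenicity >= cutoff)) for c in candidates]
    return flagged, cutoff


def select_for_validation(
    candidates: Sequence[CandidatePeptide],
    k_min: int = 10,
    prefer_tp53: bool = True,
) -> list[CandidatePeptide]:
    """Pick one patient's peptides for synthesis and T-cell testing.

    All MS-detected peptides are taken first, then all TP53-derived
    ones, then the highest-scoring remainder until at least ``k_min``
    are selected. Ties break by (score desc, sequence lexicographic), so
    the choice is deterministic and input-order invariant. If fewer than
    ``k_min`` candidates exist, all are selected with a warning.
    """
    def sort_key(c: CandidatePeptide):
        s = c.scores.immunogenicity if c.scores else 0.0
        return (-s, c.sequence, str(c.allele))

    pool = sorted(candidates, key=sort_key)
    if len(pool) < k_min:
        logger.warning(
            "only %d candidates available (< k_min=%d); selecting all",
            len(pool), k_min,
        )
        return [c.with_(selected=True) for c in pool]

    chosen: list[CandidatePeptide] = []
    chosen_ids: set[int] = set()
    for tier in (
        lambda c: c.ms_detected,
        (lambda c: c.source_variant.gene == "TP53") if prefer_tp53 else (lambda c: False),
    ):
        for i, c in enumerate(pool):
            if i not in chosen_ids and tier(c):
                chosen_ids.add(i)
                chosen.append(c)
    for i, c in enumerate(pool):
        if len(chosen) >= k_min:
            break
        if i not in chosen_ids:
            chosen_ids.add(i)
            chosen.append(c)
    chosen_set = {(c.sequence, str(c.allele)) for c in chosen}
    return [
        c.with_(selected=(c.sequence, str(c.allele)) in chosen_set) for c in pool
    ]


def write_scored_table(candidates: Sequence[CandidatePeptide], path: str | Path) -> None:
    """TSV of scored candidates with all evidence flags."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "peptide", "allele", "variant", "gene", "length", "binding_rank",
            "cleavage", "tap", "combined", "immunogenicity", "expressed",
            "sc_detected", "ms_detected", "hsn", "selected",
        ])
        for c in candidates:
            s = c.scores
            writer.writerow([
                c.sequence, str(c.allele), c.source_variant.key,
                c.source_variant.gene, c.length,
                f"{s.binding_rank:.6f}" if s else "",
                f"{s.cleavage:.6f}" if s else "",
                f"{s.tap:.6f}" if s else "",
                f"{s.combined:.6f}" if s else "",
                f"{s.immunogenicity:.9f}" if s else "",
                int(c.expressed), int(c.sc_detected), int(c.ms_detected),
                int(c.hsn), int(c.selected),
            ])
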