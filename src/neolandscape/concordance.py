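"""Paired tissue/organoid concordance, cohort statistics, and landscape
summaries.

The per-patient overlap statistic is the shared fraction with union
denominator: shared / (only_tissue + only_organoid + shared). The
cross-sample similarity matrix holds the Jaccard index of each
organoid's variant set against every tissue's; a faithful pairing shows
a dominant diagonal. Cohort statistics (Spearman correlation, paired
and unpaired t tests, one-way ANOVA with LSD post-hoc, Pearson's
chi-squared) follow the standard formulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .peptides import CandidatePeptide

__all__ = [
    "PairedSample",
    "OverlapSummary",
    "pair_overlap",
    "cross_similarity_matrix",
    "paired_cohort_stats",
    "group_compare",
    "landscape_summary",
]

SNV_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class PairedSample:
    """One patient's tissue and organoid variant/peptide sets."""

    patient_id: str
    tissue_variants: frozenset[str] = field(default_factory=frozenset)
    organoid_variants: frozenset[str] = field(default_factory=frozenset)
    tissue_peptides: frozenset[str] = field(default_factory=frozenset)
    organoid_peptides: frozenset[str] = field(default_factory=frozenset)
    clinical: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tissue_variants = frozenset(self.tissue_variants)
        self.organoid_variants = frozenset(self.organoid_variants)
        self.tissue_peptides = frozenset(self.tissue_peptides)
        self.organoid_peptides = frozenset(self.organoid_peptides)


@dataclass(frozen=True)
class OverlapSummary:
    """Counts of tissue-only / organoid-only / shared items for one pair."""

    only_tissue: int
    only_organoid: int
    shared: int

    @property
    def union(self) -> int:
        return self.only_tissue + self.only_organoid + self.shared

    @property
    def shared_fraction(self) -> Fraction:
        """Exact shared / union as a rational number."""
        return Fraction(self.shared, self.union)

    @property
    def proportions(self) -> tuple[Fraction, Fraction, Fraction]:
        u = self.union
        return (
            Fraction(self.only_tissue, u),
            Fraction(self.only_organoid, u),
            Fraction(self.shared, u),
        )


def pair_overlap(p: PairedSample, level: str = "mutation") -> OverlapSummary:
    """Exact set arithmetic on one pair at mutation or peptide level."""
    if level == "mutation":
        t, o = p.tissue_variants, p.organoid_variants
    elif level == "peptide":
        t, o = p.tissue_peptides, p.organoid_peptides
    else:
        raise ValueError(f"unknown level {level!r}")
    if not t and not o:
        raise ValueError(f"{p.patient_id}: both sets empty at level {level!r}")
    shared = len(t & o)
    return OverlapSummary(
        only_tissue=len(t) - shared, only_organoid=len(o) - shared, shared=shared
    )


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def cross_similarity_matrix(
    cohort: Sequence[PairedSample], measure: str = "jaccard"
) -> np.ndarray:
    """Organoid (rows) x tissue (columns) similarity of variant sets.

    ``measure`` is ``jaccard`` (set overlap) or ``pearson`` (correlation
    of binary membership vectors over the cohort's variant universe).
    """
    if len(cohort) < 2:
        raise ValueError("similarity matrix requires >= 2 patients")
    n = len(cohort)
    if measure == "jaccard":
        m = np.zeros((n, n))
        for i, pi in enumerate(cohort):
            for j, pj in enumerate(cohort):
                m[i, j] = _jaccard(pi.organoid_variants, pj.tissue_variants)
        return m
    if measure == "pearson":
        universe = sorted(
            set().union(*(p.tissue_variants | p.organoid_variants for p in cohort))
        )
        idx = {k: i for i, k in enumerate(universe)}
        org = np.zeros((n, len(universe)))
        tis = np.zeros((n, len(universe)))
        for i, p in enumerate(cohort):
            for k in p.organoid_variants:
                org[i, idx[k]] = 1.0
            for k in p.tissue_variants:
                tis[i, idx[k]] = 1.0
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if org[i].std() == 0 or tis[j].std() == 0:
                    m[i, j] = 0.0
                else:
                    m[i, j] = np.corrcoef(org[i], tis[j])[0, 1]
        return m
    raise ValueError(f"unknown measure {measure!r}")


def paired_cohort_stats(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Spearman rank correlation and two-tailed paired t for two per-patient
    value lists (e.g. tissue vs organoid TMB).

    Spearman uses average ranks for ties with the t approximation for
    the p-value; both follow the textbook formulations.
    """
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    rho, rho_p = stats.spearmanr(x, y)
    t, t_p = stats.ttest_rel(x, y)
    return {
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "paired_t": float(t),
        "paired_p": float(t_p),
    }


def _anova_lsd(groups: Sequence[Sequence[float]]) -> dict:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    f, p = stats.f_oneway(*arrays)
    # Fisher's LSD: pairwise t with the pooled within-group MSE
    n_total = sum(len(a) for a in arrays)
    k = len(arrays)
    df_within = n_total - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_within
    pairwise = {}
    for i, j in combinations(range(k), 2):
        ni, nj = len(arrays[i]), len(arrays[j])
        se = np.sqrt(mse * (1 / ni + 1 / nj))
        if se == 0:
            t_ij, p_ij = 0.0, 1.0
        else:
            t_ij = (arrays[i].mean() - arrays[j].mean()) / se
            p_ij = 2 * stats.t.sf(abs(t_ij), df_within)
        pairwise[(i, j)] = {"t": float(t_ij), "p": float(p_ij)}
    return {"F": float(f), "p": float(p), "lsd": pairwise}


def group_compare(
    values: Sequence, groups: Sequence | None = None, design: str = "unpaired_t"
) -> dict:
    """Compare groups by unpaired t, one-way ANOVA + LSD, or chi-squared.

    For ``unpaired_t`` and ``anova_lsd``, ``values`` is a list of group
    value lists (``groups`` optionally names them). For ``chisq``,
    ``values`` is a contingency table of counts.
    """
    if design == "chisq":
        table = np.asarray(values, dtype=float)
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        return {"chi2": float(chi2), "p": float(p), "dof": int(dof)}
    grouped = [np.asarray(g, dtype=float) for g in values]
    if len(grouped) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in grouped):
        raise ValueError("each group needs n >= 2 for t/ANOVA")
    if design == "unpaired_t":
        if len(grouped) != 2:
            raise ValueError("unpaired_t takes exactly 2 groups")
        if np.array_equal(grouped[0], grouped[1]):
            return {"t": 0.0, "p": 1.0}
        t, p = stats.ttest_ind(grouped[0], grouped[1])
        return {"t": float(t), "p": float(p)}
    if design == "anova_lsd":
        return _anova_lsd(grouped)
    raise ValueError(f"unknown design {design!r}")


def snv_class(ref: str, alt: str) -> str:
    """Pyrimidine-reference substitution class of a SNV (G>A -> C>T etc.)."""
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    cls = f"{ref}>{alt}"
    if cls not in SNV_CLASSES:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    return cls


def landscape_summary(candidates: Sequence[CandidatePeptide]) -> dict:
    """Stratified landscape of one sample's scored candidates.

    Returns counts by peptide length and HLA locus, mean immunogenic
    score per stratum, and the pyrimidine-reference SNV class spectrum
    of the unique underlying mutations (fractions summing to 1).
    """
    by_length = {L: 0 for L in (9, 10, 11)}
    by_locus = {l: 0 for l in ("A", "B", "C")}
    score_len: dict[int, list[float]] = {L: [] for L in (9, 10, 11)}
    score_loc: dict[str, list[float]] = {l: [] for l in ("A", "B", "C")}
    variants: dict[str, tuple[str, str]] = {}
    for c in candidates:
        by_length[c.length] += 1
        locus = c.allele.locus if c.allele else "A"
        by_locus[locus] += 1
        if c.scores is not None:
            score_len[c.length].append(c.scores.immunogenicity)
            score_loc[locus].append(c.scores.immunogenicity)
        v = c.source_variant
        if v.vclass == "SNV":
            variants[v.key] = (v.ref, v.alt)
    spectrum = {cls: 0 for cls in SNV_CLASSES}
    for ref, alt in variants.values():
        spectrum[snv_class(ref, alt)] += 1
    total_snv = sum(spectrum.values())
    return {
        "n_candidates": len(candidates),
        "by_length": by_length,
        "by_locus": by_locus,
        "mean_score_by_length": {
            L: (float(np.mean(v)) if v else float("nan")) for L, v in score_len.items()
        },
        "mean_score_by_locus": {
            l: (float(np.mean(v)) if v else float("nan")) for l, v in score_loc.items()
        },
        "snv_class_fractions": {
            cls: (n / total_snv if total_snv else 0.0) for cls, n in spectrum.items()
        },
        "n_snv_mutations": total_snv,
    }
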