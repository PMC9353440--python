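"""Paired overlap statistics, similarity matrices, and statistical tests
checked against independent closed-form oracles."""

from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as spstats

from neolandscape.concordance import (
    OverlapSummary,
    PairedSample,
    cross_similarity_matrix,
    group_compare,
    landscape_summary,
    pair_overlap,
    paired_cohort_stats,
    snv_class,
)
from neolandscape.hla import HlaAllele
from neolandscape.peptides import CandidatePeptide, PresentationScores

from conftest import make_variant


def pair(tissue, organoid, pid="P1"):
    return PairedSample(pid, frozenset(tissue), frozenset(organoid))


# --------------------------------------------------------------------------
# closed-form oracles, written independently of the implementation

def oracle_spearman(x, y):
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rho = np.sum((rx - rx.mean()) * (ry - ry.mean())) / np.sqrt(
        np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2)
    )
    n = len(x)
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * spstats.t.sf(abs(t), n - 2)
    return rho, p


def oracle_paired_t(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    return t, 2 * spstats.t.sf(abs(t), n - 1)


def oracle_unpaired_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return t, 2 * spstats.t.sf(abs(t), na + nb - 2)


def oracle_anova(groups):
    groups = [np.asarray(g, float) for g in groups]
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = sum(len(g) for g in groups) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    return f, spstats.f.sf(f, dfb, dfw), ssw / dfw, dfw


def oracle_chi2(table):
    table = np.asarray(table, float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    chi2 = ((table - expected) ** 2 / expected).sum()
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, spstats.chi2.sf(chi2, dof)


# --------------------------------------------------------------------------

class TestPairOverlap:
    def test_identical_sets(self):
        p = pair({"a", "b"}, {"a", "b"})
        assert pair_overlap(p).shared_fraction == 1

    def test_disjoint_sets(self):
        p = pair({"a"}, {"b"})
        assert pair_overlap(p).shared_fraction == 0

    def test_union_denominator_exact_rational(self):
        # 7 keys in the union, 2 shared: 2/7 = 28.57%
        p = pair({"a", "b", "c", "d", "s1", "s2"}, {"e", "s1", "s2"})
        ov = pair_overlap(p)
        assert ov.shared_fraction == Fraction(2, 7)
        assert float(100 * ov.shared_fraction) == pytest.approx(28.57, abs=0.005)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            t = {f"k{i}" for i in rng.choice(60, size=rng.integers(1, 30), replace=False)}
            o = {f"k{i}" for i in rng.choice(60, size=rng.integers(1, 30), replace=False)}
            if not (t or o):
                continue
            assert sum(pair_overlap(pair(t, o)).proportions) == 1

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            pair_overlap(pair(set(), set()))


class TestSimilarityMatrix:
    def test_disjoint_universes_identity_pattern(self):
        cohort = [pair({"a1", "a2"}, {"a1", "a2"}, "P1"), pair({"b1"}, {"b1"}, "P2")]
        m = cross_similarity_matrix(cohort)
        assert np.allclose(np.diag(m), 1.0)
        assert m[0, 1] == 0.0 and m[1, 0] == 0.0

    def test_entries_in_unit_interval(self, small_cohort):
        cohort = [
            pair({v.key for v in p.tissue_variants},
                 {v.key for v in p.organoid_variants}, p.patient_id)
            for p in small_cohort.patients
        ]
        m = cross_similarity_matrix(cohort)
        assert ((m >= 0) & (m <= 1)).all()

    def test_diagonal_dominance_on_synthetic_pairs(self, small_cohort):
        cohort = [
            pair({v.key for v in p.tissue_variants},
                 {v.key for v in p.organoid_variants}, p.patient_id)
            for p in small_cohort.patients
        ]
        m = cross_similarity_matrix(cohort)
        off = m[~np.eye(len(cohort), dtype=bool)]
        assert np.diag(m).mean() > off.max()

    def test_requires_two_patients(self):
        with pytest.raises(ValueError):
            cross_similarity_matrix([pair({"a"}, {"a"})])


class TestPairedStats:
    def test_perfect_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = paired_cohort_stats(x, [2 * v for v in x])
        assert out["spearman_rho"] == pytest.approx(1.0)

    def test_reverse_ranks(self):
        x = [1.0, 2.0, 3.0, 4.0]
        out = paired_cohort_stats(x, x[::-1])
        assert out["spearman_rho"] == pytest.approx(-1.0)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            x = rng.normal(size=n)
            y = 0.6 * x + rng.normal(size=n)
            out = paired_cohort_stats(list(x), list(y))
            rho, rho_p = oracle_spearman(x, y)
            t, t_p = oracle_paired_t(x, y)
            assert out["spearman_rho"] == pytest.approx(rho, abs=1e-9)
            assert out["spearman_p"] == pytest.approx(rho_p, abs=1e-9)
            assert out["paired_t"] == pytest.approx(t, abs=1e-9)
            assert out["paired_p"] == pytest.approx(t_p, abs=1e-9)

    def test_ties_use_average_ranks(self):
        x = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0]
        y = [2.0, 1.0, 2.0, 5.0, 4.0, 4.0]
        out = paired_cohort_stats(x, y)
        rho, _ = oracle_spearman(x, y)
        assert out["spearman_rho"] == pytest.approx(rho, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_cohort_stats([1, 2, 3], [1, 2])


class TestGroupCompare:
    def test_identical_groups_t_zero(self):
        out = group_compare([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], design="unpaired_t")
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_uniform_contingency_chi2_zero(self):
        out = group_compare([[10, 10], [10, 10]], design="chisq")
        assert out["chi2"] == pytest.approx(0.0)

    def test_unpaired_t_matches_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            a = rng.normal(0, 1, size=int(rng.integers(5, 30)))
            b = rng.normal(0.5, 1.2, size=int(rng.integers(5, 30)))
            out = group_compare([list(a), list(b)], design="unpaired_t")
            t, p = oracle_unpaired_t(a, b)
            assert out["t"] == pytest.approx(t, abs=1e-9)
            assert out["p"] == pytest.approx(p, abs=1e-9)

    def test_anova_lsd_matches_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            groups = [
                list(rng.normal(mu, 1, size=int(rng.integers(4, 20))))
                for mu in (0.0, 0.4, 1.0)
            ]
            out = group_compare(groups, design="anova_lsd")
            f, p, mse, dfw = oracle_anova(groups)
            assert out["F"] == pytest.approx(f, abs=1e-9)
            assert out["p"] == pytest.approx(p, abs=1e-9)
            for (i, j), res in out["lsd"].items():
                a, b = np.asarray(groups[i]), np.asarray(groups[j])
                se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
                t = (a.mean() - b.mean()) / se
                assert res["t"] == pytest.approx(t, abs=1e-9)
                assert res["p"] == pytest.approx(2 * spstats.t.sf(abs(t), dfw), abs=1e-9)

    def test_chi2_matches_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            table = rng.integers(5, 60, size=(2, 3))
            out = group_compare(table, design="chisq")
            chi2, p = oracle_chi2(table)
            assert out["chi2"] == pytest.approx(chi2, abs=1e-9)
            assert out["p"] == pytest.approx(p, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([[1.0], [1.0, 2.0]], design="unpaired_t")


class TestLandscape:
    def _candidate(self, seq, locus="A", ref="C", alt="T", pos=100, score=0.1):
        v = make_variant(pos=pos, ref=ref, alt=alt)
        return CandidatePeptide(
            seq, HlaAllele(locus, "11", "01"), v, (4,),
            scores=PresentationScores(10.0, 0.5, 0.5, 0.25, score),
        )

    def test_all_9mers(self):
        cands = [self._candidate("ACDEFGHIK", pos=i + 1) for i in range(5)]
        out = landscape_summary(cands)
        assert out["by_length"] == {9: 5, 10: 0, 11: 0}

    def test_counts_conserved(self):
        rng = np.random.default_rng(31)
        seqs = ["ACDEFGHIK", "ACDEFGHIKL", "ACDEFGHIKLM"]
        cands = [
            self._candidate(seqs[rng.integers(0, 3)], locus="ABC"[rng.integers(0, 3)],
                            pos=int(rng.integers(1, 500)))
            for _ in range(60)
        ]
        out = landscape_summary(cands)
        assert sum(out["by_length"].values()) == 60
        assert sum(out["by_locus"].values()) == 60

    def test_snv_class_canonicalization(self):
        assert snv_class("G", "A") == "C>T"
        assert snv_class("A", "C") == "T>G"
        assert snv_class("C", "T") == "C>T"

    def test_biased_spectrum_recovered(self):
        # 60% C>T mutations by construction: observed within 3 SE
        rng = np.random.default_rng(32)
        n = 400
        cands = []
        for i in range(n):
            if rng.random() < 0.60:
                ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
            else:
                ref, alt = ("C", "A") if rng.random() < 0.5 else ("T", "G")
            cands.append(self._candidate("ACDEFGHIK", ref=ref, alt=alt, pos=i + 1))
        out = landscape_summary(cands)
        se = np.sqrt(0.6 * 0.4 / n)
        assert abs(out["snv_class_fractions"]["C>T"] - 0.60) < 3 * se
        assert sum(out["snv_class_fractions"].values()) == pytest.approx(1.0)
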