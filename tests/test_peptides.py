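"""Mutant protein construction and candidate window enumeration."""

import numpy as np
import pytest
from Bio.Seq import Seq

from neolandscape.hla import HlaAllele, HlaAlleleSet
from neolandscape.peptides import (
    CandidatePeptide,
    TranscriptModel,
    VariantRejected,
    build_mutant_protein,
    enumerate_candidate_peptides,
    pair_with_alleles,
    translate_cds,
)

from conftest import make_variant

CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def random_tx(rng, n_codons) -> TranscriptModel:
    cds = "".join(CODONS[i] for i in rng.integers(0, len(CODONS), n_codons)) + "TAA"
    return TranscriptModel("TX", "G", cds)


def brute_force_windows(wt: str, mut: str, interval, lengths=(9, 10, 11)) -> set[str]:
    """All distinct mutant substrings of the requested lengths that touch
    the affected interval and do not occur in the wild-type protein."""
    lo, hi = interval
    out = set()
    for L in lengths:
        for s in range(1, len(mut) - L + 2):
            if s + L - 1 < lo or s > hi:
                continue
            seq = mut[s - 1 : s - 1 + L]
            if seq not in wt:
                out.add(seq)
    return out


def make_missense(rng, tx: TranscriptModel):
    """A random missense SNV within the transcript, if one can be found."""
    for _ in range(100):
        pos = int(rng.integers(1, len(tx.cds_sequence) - 3))
        ref = tx.cds_sequence[pos - 1]
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        v = make_variant(chrom=tx.gene, pos=pos, ref=ref, alt=alt,
                         transcript_id=tx.transcript_id)
        ci = (pos - 1) // 3
        codon = tx.cds_sequence[ci * 3 : ci * 3 + 3]
        off = (pos - 1) % 3
        mut_aa = str(Seq(codon[:off] + alt + codon[off + 1:]).translate())
        wt_aa = str(Seq(codon).translate())
        if mut_aa != wt_aa and mut_aa != "*":
            return v
    return None


class TestTranscriptModel:
    def test_translation_is_derived(self):
        tx = TranscriptModel("T", "G", "ATGGCCAAGTAA")
        assert tx.protein_sequence == "MAK"

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            TranscriptModel("T", "G", "ATGTAAGCCAAG")

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            TranscriptModel("T", "G", "ATGGC")


class TestBuildMutantProtein:
    def test_missense_single_residue(self):
        # R -> S at residue 90 of a 131-codon protein
        rng = np.random.default_rng(42)
        codons = [CODONS[i] for i in rng.integers(0, len(CODONS), 130)]
        codons[89] = "CGC"
        tx = TranscriptModel("TX", "G", "".join(codons) + "TAA")
        v = make_variant(pos=89 * 3 + 1, ref="C", alt="A", transcript_id="TX")
        mp = build_mutant_protein(tx, v)
        assert mp.affected_interval == (90, 90)
        assert mp.mutant[89] == "S" and mp.wild_type[89] == "R"
        diffs = [i for i, (a, b) in enumerate(zip(mp.wild_type, mp.mutant)) if a != b]
        assert diffs == [89]

    def test_inframe_deletion_junction(self):
        # oracle: translate the mutant CDS independently and diff
        rng = np.random.default_rng(7)
        for _ in range(25):
            tx = random_tx(rng, 60)
            pos = int(rng.integers(4, len(tx.cds_sequence) - 10))
            ref = tx.cds_sequence[pos - 1 : pos + 3]
            v = make_variant(chrom="G", pos=pos, ref=ref, alt=ref[0],
                             effect="nonframeshift_indel", transcript_id="TX")
            mut_cds = tx.cds_sequence[:pos] + tx.cds_sequence[pos + 3:]
            expected = translate_cds(mut_cds)
            if "*" in str(Seq(mut_cds).translate())[:-1]:
                continue
            mp = build_mutant_protein(tx, v)
            assert mp.mutant == expected
            assert len(mp.mutant) == len(mp.wild_type) - 1
            lo, hi = mp.affected_interval
            assert 1 <= lo <= hi <= len(mp.mutant)
            assert hi - lo <= 1  # junction-flanking residues only

    def test_frameshift_rejected(self):
        tx = TranscriptModel("T", "G", "ATGGCCAAGGTCTAA")
        v = make_variant(pos=4, ref="G", alt="GTT", effect="nonframeshift_indel")
        with pytest.raises(VariantRejected, match="frameshift"):
            build_mutant_protein(tx, v)

    def test_out_of_scope_effect_rejected(self):
        tx = TranscriptModel("T", "G", "ATGGCCAAGGTCTAA")
        with pytest.raises(VariantRejected, match="scope"):
            build_mutant_protein(tx, make_variant(pos=4, effect="frameshift", ref="G", alt="T"))

    def test_reference_mismatch_rejected(self):
        tx = TranscriptModel("T", "G", "ATGGCCAAGGTCTAA")
        with pytest.raises(VariantRejected, match="mismatch"):
            build_mutant_protein(tx, make_variant(pos=4, ref="C", alt="T"))

    def test_premature_stop_flagged_no_peptides(self):
        tx = TranscriptModel("T", "G", "ATGTCATGGGCCAAGGTCGGATCATTCGGCTTCTAA")
        # TGG (W, residue 3) -> TGA (stop)
        v = make_variant(pos=9, ref="G", alt="A")
        mp = build_mutant_protein(tx, v)
        assert mp.premature_stop
        assert enumerate_candidate_peptides(mp) == []


class TestEnumeration:
    def _interior_case(self):
        rng = np.random.default_rng(0)
        while True:
            tx = random_tx(rng, 131)
            v = make_missense(rng, tx)
            if v is None:
                continue
            mp = build_mutant_protein(tx, v)
            lo, _ = mp.affected_interval
            if 12 <= lo <= len(mp.mutant) - 11:
                return mp

    def test_interior_missense_yields_30_windows(self):
        mp = self._interior_case()
        windows = enumerate_candidate_peptides(mp, lengths=(9, 10, 11))
        assert len(windows) == 30
        by_len = {L: sum(1 for s, _ in windows if len(s) == L) for L in (9, 10, 11)}
        assert by_len == {9: 9, 10: 10, 11: 11}

    def test_terminal_missense_truncated(self):
        rng = np.random.default_rng(1)
        while True:
            tx = random_tx(rng, 40)
            v = make_missense_at_first_codon(rng, tx)
            if v is not None:
                break
        mp = build_mutant_protein(tx, v)
        windows = enumerate_candidate_peptides(mp, lengths=(9,))
        assert len(windows) == 1
        assert windows[0][0] == mp.mutant[:9]
        assert windows[0][1] == (0,)

    def test_wild_type_windows_excluded(self):
        # a mutant that repeats wild-type sequence in some windows
        wt_cds = "ATG" + "GCC" * 30 + "AAG" + "GCC" * 5 + "TAA"
        tx = TranscriptModel("T", "G", wt_cds)
        v = make_variant(pos=3 * 31 + 1, ref="A", alt="G")  # K32 -> E or similar
        mp = build_mutant_protein(tx, v)
        for seq, _ in enumerate_candidate_peptides(mp):
            assert seq not in mp.wild_type

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        n_checked = 0
        while n_checked < 100:
            tx = random_tx(rng, int(rng.integers(15, 66)))
            if rng.random() < 0.3:
                pos = int(rng.integers(4, len(tx.cds_sequence) - 10))
                ref = tx.cds_sequence[pos - 1 : pos + 3]
                v = make_variant(chrom="G", pos=pos, ref=ref, alt=ref[0],
                                 effect="nonframeshift_indel", transcript_id="TX")
                from Bio.Seq import Seq as _S
                mut_cds = tx.cds_sequence[:pos] + tx.cds_sequence[pos + 3:]
                if "*" in str(_S(mut_cds).translate())[:-1]:
                    continue
            else:
                v = make_missense(rng, tx)
                if v is None:
                    continue
            mp = build_mutant_protein(tx, v)
            got = {s for s, _ in enumerate_candidate_peptides(mp)}
            want = brute_force_windows(mp.wild_type, mp.mutant, mp.affected_interval)
            assert got == want
            n_checked += 1

    def test_every_window_contains_mutated_offset(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            tx = random_tx(rng, 50)
            v = make_missense(rng, tx)
            if v is None:
                continue
            mp = build_mutant_protein(tx, v)
            lo, hi = mp.affected_interval
            for seq, offsets in enumerate_candidate_peptides(mp):
                assert offsets
                start = mp.mutant.index(seq) if seq in mp.mutant else None
                assert seq in mp.mutant

    def test_empty_lengths_rejected(self):
        mp = self._interior_case()
        with pytest.raises(ValueError):
            enumerate_candidate_peptides(mp, lengths=())


def make_missense_at_first_codon(rng, tx):
    for _ in range(50):
        pos = int(rng.integers(1, 4))
        ref = tx.cds_sequence[pos - 1]
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        ci = 0
        codon = tx.cds_sequence[:3]
        mut_codon = codon[:pos - 1] + alt + codon[pos:]
        wt_aa, mut_aa = str(Seq(codon).translate()), str(Seq(mut_codon).translate())
        if mut_aa != wt_aa and mut_aa != "*":
            return make_variant(pos=pos, ref=ref, alt=alt, transcript_id="TX")
    return None


class TestPairing:
    def _windows_and_alleles(self, n_alleles):
        windows = [(f"ACDEFGH{chr(65 + i // 26)}{chr(65 + i % 26)}", (4,)) for i in range(30)]
        alleles = HlaAlleleSet(
            "P1", "consensus",
            frozenset(
                HlaAllele("ABC"[i % 3], f"{10 + i:02d}", "01") for i in range(n_alleles)
            ),
        )
        return windows, alleles

    def test_cross_product_count(self):
        windows, alleles = self._windows_and_alleles(6)
        out = pair_with_alleles(windows, alleles, make_variant())
        assert len(out) == 180
        assert all(isinstance(c, CandidatePeptide) for c in out)

    def test_empty_allele_set_gives_no_candidates(self):
        windows, _ = self._windows_and_alleles(1)
        empty = HlaAlleleSet("P1", "consensus", frozenset())
        assert pair_with_alleles(windows, empty, make_variant()) == []

    def test_loci_restricted_to_abc(self):
        with pytest.raises(ValueError):
            HlaAllele("D", "01", "01")
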