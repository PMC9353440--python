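"""From a missense variant to HLA-paired 9-11mer candidate peptides.

Generates a small synthetic transcriptome, plants an R90S substitution
in TP53, enumerates every mutant window overlapping the changed
residue, and pairs the windows with a patient's consensus alleles.
"""

from neolandscape import (
    HlaAllele, SomaticVariant, build_mutant_protein,
    enumerate_candidate_peptides, generate_reference, pair_with_alleles,
)
from neolandscape.hla import HlaAlleleSet

reference, transcripts = generate_reference(n_genes=5, seed=42)
tx = transcripts["TX_TP53"]

v = SomaticVariant(
    chrom="TP53", pos=89 * 3 + 1, ref="C", alt="A", vclass="SNV",
    effect="missense", gene="TP53", transcript_id="TX_TP53",
    protein_change="R90S", tumor_depth=80, normal_depth=60,
    tumor_alt_reads=24, tumor_af=0.3, normal_af=0.0, panel_freq=0.0,
)

mp = build_mutant_protein(tx, v)
print(f"protein length {len(mp.wild_type)} aa; affected interval "
      f"{mp.affected_interval} ({mp.wild_type[89]}->{mp.mutant[89]} at residue 90)")

windows = enumerate_candidate_peptides(mp, lengths=(9, 10, 11))
print(f"{len(windows)} candidate windows (9+10+11 = 30 for an interior site)")
print("example 9mer:", windows[0][0], "mutated offsets", windows[0][1])

alleles = HlaAlleleSet("P01", "consensus", frozenset({
    HlaAllele("A", "11", "01"), HlaAllele("A", "24", "02"),
    HlaAllele("B", "40", "01"), HlaAllele("C", "07", "02"),
}))
candidates = pair_with_alleles(windows, alleles, v)
print(f"{len(windows)} windows x {len(alleles.alleles)} alleles = "
      f"{len(candidates)} peptide-allele candidates")
print("Each candidate is a peptide absent from the wild-type protein, so "
      "every one is a potential neoantigen for that HLA allele.")
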