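"""Consensus HLA class I alleles across typing tools and sample types.

Three typers disagree slightly on one sample; the consensus keeps only
alleles every tool reports, then intersects tissue, organoid, and PBMC.
"""

from neolandscape import HlaAllele, consensus_across_samples, consensus_across_typers
from neolandscape.hla import HlaAlleleSet


def hset(sample, source, *names):
    return HlaAlleleSet(sample, source, frozenset(HlaAllele.parse(n) for n in names))


tissue = consensus_across_typers([
    hset("P01_tissue", "typer1", "A*11:01", "A*24:02", "B*40:01", "C*07:02"),
    hset("P01_tissue", "typer2", "A*11:01", "A*24:02", "B*40:01", "C*07:02"),
    hset("P01_tissue", "typer3", "A*11:01", "A*24:02", "B*40:01"),  # drops C*07:02
])
print("tissue consensus:  ", ", ".join(str(a) for a in sorted(tissue.alleles)))

organoid = hset("P01_organoid", "consensus", "A*11:01", "B*40:01", "C*07:02")
pbmc = hset("P01_pbmc", "consensus", "A*11:01", "A*24:02", "B*40:01", "C*07:02")
shared = consensus_across_samples(tissue, organoid, pbmc)
print("patient consensus: ", ", ".join(str(a) for a in sorted(shared.alleles)))
print("Only alleles typed concordantly in every tool AND present in tissue, "
      "organoid, and PBMC restrict the peptide candidates; discordant "
      "alleles (like the organoid's missing A*24:02) are dropped.")
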