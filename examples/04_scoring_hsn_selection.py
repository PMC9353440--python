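"""Presentation scoring, the pooled HSN cutoff, and validation selection.

Scores a synthetic candidate pool with the seeded mock scorer, flags
the top 30% as high-score neoantigens (HSNs), and picks peptides for
validation with MS/TP53 preference.
"""

import numpy as np

from neolandscape import flag_hsn, select_for_validation
from neolandscape.scoring import ScorerSpec, score_candidates
from neolandscape.simulate import CohortSpec, generate_paired_cohort
from neolandscape.peptides import build_mutant_protein, enumerate_candidate_peptides, pair_with_alleles
from neolandscape.hla import HlaAllele, HlaAlleleSet

cohort = generate_paired_cohort(CohortSpec(n_pairs=2, mutations_per_sample=40, seed=3))
alleles = HlaAlleleSet("P01", "consensus", frozenset({
    HlaAllele("A", "11", "01"), HlaAllele("B", "40", "01"),
}))

candidates = []
for v in cohort.patients[0].tissue_variants:
    if v.effect not in ("missense", "nonframeshift_indel"):
        continue
    mp = build_mutant_protein(cohort.transcripts[v.transcript_id], v)
    candidates.extend(pair_with_alleles(enumerate_candidate_peptides(mp), alleles, v))

scored = score_candidates(candidates, ScorerSpec(name="mock", seed=0))
scores = [c.scores.immunogenicity for c in scored]
print(f"{len(scored)} scored candidates; median immunogenic-potential score "
      f"{np.median(scores):.4g} (range {min(scores):.3g}-{max(scores):.3g})")

flagged, cutoff = flag_hsn(scored, top_fraction=0.30)
n_hsn = sum(c.hsn for c in flagged)
print(f"HSN cutoff {cutoff:.6g}: {n_hsn}/{len(flagged)} peptides flagged "
      f"({100 * n_hsn / len(flagged):.1f}%)")

selected = [c for c in select_for_validation(flagged, k_min=10) if c.selected]
print(f"{len(selected)} peptides selected for validation "
      f"(TP53-derived: {sum(c.source_variant.gene == 'TP53' for c in selected)})")
print("Selection takes all MS-detected peptides first, then TP53-derived "
      "ones, then fills to at least 10 by descending score.")
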