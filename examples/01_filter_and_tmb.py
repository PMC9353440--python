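"""Apply the five-criterion somatic filter cascade and compute TMB.

Builds a handful of variants straddling the thresholds, filters them,
and reports tumor mutational burden over a 34 Mb coding footprint.
"""

from neolandscape import SomaticVariant, apply_somatic_filters, compute_tmb


def variant(pos, **kw):
    base = dict(
        chrom="TP53", pos=pos, ref="C", alt="T", vclass="SNV",
        effect="missense", gene="TP53", transcript_id="TX_TP53",
        protein_change="R90S", tumor_depth=80, normal_depth=60,
        tumor_alt_reads=20, tumor_af=0.25, normal_af=0.0, panel_freq=0.0,
    )
    base.update(kw)
    return SomaticVariant(**base)


variants = [
    variant(101),                                        # clean somatic call
    variant(202, tumor_depth=8, tumor_alt_reads=2),      # too shallow (C1, C2)
    variant(303, normal_af=0.04),                        # germline leakage (C4)
    variant(404, panel_freq=0.12, tumor_af=0.20),        # common in panel (C5)
    variant(505, panel_freq=0.12, tumor_af=0.45),        # panel-common, rescued
]

decisions = apply_somatic_filters(variants)
for d in decisions:
    verdict = "PASS" if d.passed else f"fail {','.join(d.failed_criteria)}"
    print(f"  {d.variant.key:<16} AF={d.variant.tumor_af:.2f} "
          f"panel={d.variant.panel_freq:.2f}  -> {verdict}")

tmb = compute_tmb(decisions, coding_mb=34.0)
print(f"passed {sum(d.passed for d in decisions)}/{len(decisions)} variants; "
      f"TMB = {tmb:.4f} mutations/Mb")
print("The rescue clause keeps panel-common variants only when the tumor "
      "allele fraction is at least 0.30.")
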