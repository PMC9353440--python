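"""End-to-end run on a small synthetic paired cohort.

Simulates eight tissue/organoid pairs, runs every pipeline stage, and
prints the concordance and landscape headline numbers.
"""

import json
import tempfile
from pathlib import Path

from neolandscape import RunConfig, run_pipeline

cfg = RunConfig(seed=7, cohort={"n_pairs": 8, "mutations_per_sample": 60})

with tempfile.TemporaryDirectory() as tmp:
    outdir = Path(tmp) / "run"
    manifest = run_pipeline(cfg, outdir)
    for stage, counts in manifest["stages"].items():
        print(f"  {stage:<12} {counts}")
    stats = json.loads((outdir / "reports" / "stats.json").read_text())
    print(f"mean shared mutation fraction "
          f"{100 * stats['mean_shared_fraction']:.2f}% "
          f"(range {100 * stats['min_shared_fraction']:.2f}-"
          f"{100 * stats['max_shared_fraction']:.2f}%)")
    print(f"similarity matrix: mean diagonal Jaccard "
          f"{stats['similarity_diag_mean']:.3f} vs max off-diagonal "
          f"{stats['similarity_offdiag_max']:.3f}")
    print(f"TMB tissue vs organoid Spearman rho "
          f"{stats['tmb']['spearman_rho']:.3f} (p {stats['tmb']['spearman_p']:.3g})")
print("Each organoid's mutation set resembles its own tissue far more than "
      "any other patient's, and paired burdens correlate across the cohort.")
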