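import numpy as np
import pytest

from neolandscape.variants import SomaticVariant


def make_variant(**overrides) -> SomaticVariant:
    """A variant passing every filter criterion unless overridden."""
    base = dict(
        chrom="GENE001", pos=100, ref="C", alt="T", vclass="SNV",
        effect="missense", gene="GENE001", transcript_id="TX_GENE001",
        protein_change="A34V", tumor_depth=50, normal_depth=40,
        tumor_alt_reads=10, tumor_af=0.20, normal_af=0.0, panel_freq=0.0,
        in_coding=True,
    )
    base.update(overrides)
    if base["vclass"] == "SNV" and (len(base["ref"]) != 1 or len(base["alt"]) != 1):
        base["vclass"] = "insertion" if len(base["alt"]) > len(base["ref"]) else "deletion"
    return SomaticVariant(**base)


def random_variant(rng: np.random.Generator) -> SomaticVariant:
    """A random variant spanning all filter-relevant regimes."""
    tumor_depth = int(rng.integers(0, 120))
    return make_variant(
        pos=int(rng.integers(1, 1000)),
        tumor_depth=tumor_depth,
        normal_depth=int(rng.integers(0, 120)),
        tumor_alt_reads=int(rng.integers(0, tumor_depth + 1)),
        tumor_af=float(rng.uniform(0, 0.7)),
        normal_af=float(rng.uniform(0, 0.05)),
        panel_freq=float(rng.uniform(0, 0.15)),
        in_coding=bool(rng.random() < 0.9),
    )


@pytest.fixture(scope="session")
def small_reference():
    from neolandscape.simulate import generate_reference

    return generate_reference(n_genes=12, gene_length_range=(300, 900), seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    from neolandscape.simulate import CohortSpec, generate_paired_cohort

    spec = CohortSpec(n_pairs=5, mutations_per_sample=35, seed=101)
    return generate_paired_cohort(spec)
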