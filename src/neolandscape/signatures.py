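"""96-channel trinucleotide mutation spectra and signature refitting.

Every somatic SNV is assigned to one of 96 channels: 6 substitution
classes with pyrimidine reference (C>A, C>G, C>T, T>A, T>C, T>G) times
4 possible 5' flanking bases times 4 possible 3' flanking bases.
Purine-reference calls are reverse-complemented onto the pyrimidine
strand with flanks swapped and complemented.

A sample's spectrum is attributed to known single-base-substitution
(SBS) signatures by refitting: the normalized spectrum is decomposed
onto a fixed 96 x K probability matrix by non-negative least squares,
signatures contributing below a pruning threshold are removed, and the
fit is re-run until stable (the deconstructSigs-style procedure, not
de-novo factorization).

Because a curated catalog cannot be redistributed here, the module
ships :func:`synthetic_signature_catalog`, a programmatically built
SYNTHETIC catalog whose columns imitate the qualitative shape of
familiar signatures (spontaneous-deamination C>T at CpG, flat clock-like,
aflatoxin-style C>A, ...). Any real 96 x K matrix can be supplied
instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .concordance import SNV_CLASSES, _COMPLEMENT
from .variants import SomaticVariant

__all__ = [
    "CONTEXT_LABELS",
    "MutationSpectrum",
    "SignatureExposure",
    "build_spectrum",
    "refit_exposures",
    "synthetic_signature_catalog",
]

_BASES = ("A", "C", "G", "T")

#: Canonical channel order: substitution class (C>A..T>G), then 5' flank
#: (A,C,G,T), then 3' flank (A,C,G,T). Labels look like ``A[C>T]G``.
CONTEXT_LABELS: tuple[str, ...] = tuple(
    f"{five}[{cls}]{three}"
    for cls in SNV_CLASSES
    for five in _BASES
    for three in _BASES
)
_CHANNEL_INDEX = {label: i for i, label in enumerate(CONTEXT_LABELS)}


def canonical_context(ref: str, alt: str, five: str, three: str) -> str:
    """Pyrimidine-strand channel label for a SNV and its flanking bases."""
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    label = f"{five}[{ref}>{alt}]{three}"
    if label not in _CHANNEL_INDEX:
        raise ValueError(f"invalid context {label}")
    return label


@dataclass
class MutationSpectrum:
    """Counts over the 96 canonical trinucleotide channels."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError(f"spectrum must have 96 channels, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("cannot normalize an empty spectrum")
        return self.counts / self.total

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXT_LABELS), name="count")


@dataclass
class SignatureExposure:
    """Non-negative relative signature contributions for one spectrum."""

    exposures: dict[str, float]
    residual: float
    pruned: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.exposures.values()):
            raise ValueError("exposures must be non-negative")
        if sum(self.exposures.values()) > 1 + 1e-9:
            raise ValueError("exposures must sum to <= 1")


def build_spectrum(
    snvs: Sequence[SomaticVariant], reference: Mapping[str, str]
) -> MutationSpectrum:
    """Tally SNVs into the 96-channel spectrum using flanking reference bases.

    ``reference`` maps contig name to its sequence (any object whose
    ``[chrom]`` is sliceable works, e.g. a dict or a FASTA accessor).
    Variants at contig edges (no flank) are skipped with a warning.
    """
    import logging

    counts = np.zeros(96)
    for v in snvs:
        if v.vclass != "SNV":
            continue
        seq = reference[v.chrom]
        i = v.pos - 1
        if i < 1 or i + 1 >= len(seq):
            logging.getLogger(__name__).warning(
                "%s: no flanking base at contig edge; skipped", v.key
            )
            continue
        five, ref, three = str(seq[i - 1]).upper(), str(seq[i]).upper(), str(seq[i + 1]).upper()
        if ref != v.ref:
            raise ValueError(f"{v.key}: reference base mismatch ({ref!r})")
        counts[_CHANNEL_INDEX[canonical_context(v.ref, v.alt, five, three)]] += 1
    return MutationSpectrum(counts)


def refit_exposures(
    spectrum: MutationSpectrum,
    signatures: pd.DataFrame,
    prune_below: float = 0.06,
) -> SignatureExposure:
    """Attribute a spectrum to fixed signatures by iterative NNLS refitting.

    ``signatures`` is a 96 x K DataFrame (rows ordered as
    :data:`CONTEXT_LABELS`, columns are signature ids, each column a
    probability vector). Signatures whose fitted weight falls below
    ``prune_below`` are removed and the fit re-run until stable; final
    weights are renormalized to sum to at most 1. ``residual`` is the
    L2 reconstruction error on the normalized spectrum.
    """
    if spectrum.total == 0:
        raise ValueError("cannot refit a zero spectrum")
    if list(signatures.index) != list(CONTEXT_LABELS):
        signatures = signatures.reindex(list(CONTEXT_LABELS))
        if signatures.isna().any().any():
            raise ValueError("signature matrix rows must cover the 96 channels")
    b = spectrum.normalized()
    active = list(signatures.columns)
    pruned: list[str] = []
    w = np.zeros(len(active))
    while True:
        A = signatures[active].to_numpy()
        w, _ = nnls(A, b)
        drop = [sig for sig, wi in zip(active, w) if wi < prune_below]
        if not drop or len(drop) == len(active):
            break
        pruned.extend(drop)
        active = [s for s in active if s not in drop]
    total = w.sum()
    if total > 1.0:
        w = w / total
    residual = float(np.linalg.norm(signatures[active].to_numpy() @ w - b))
    exposures = {sig: float(wi) for sig, wi in zip(active, w) if wi > 0}
    return SignatureExposure(exposures=exposures, residual=residual, pruned=tuple(pruned))


def synthetic_signature_catalog(n_extra: int = 3, seed: int = 20240901) -> pd.DataFrame:
    """Build a SYNTHETIC 96 x K signature catalog (deterministic).

    Columns imitate the qualitative shape of well-known mutational
    processes without reproducing any curated catalog's numbers:

    - ``sbs1_like``  — C>T concentrated at NpCpG (5-methylcytosine
      deamination, clock-like)
    - ``sbs5_like``  — flat, spread over all channels (clock-like)
    - ``sbs24_like`` — C>A dominated (aflatoxin-style exposure)
    - ``sbs16_like`` — T>C enriched at ApTpN
    - ``sbs3_like``  — near-uniform, slightly C>G tilted
    plus ``n_extra`` smooth random signatures for a richer basis.
    All columns are probability vectors over :data:`CONTEXT_LABELS`.
    """
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}

    def channel_mask(cls: str | None = None, three: str | None = None,
                     five: str | None = None) -> np.ndarray:
        m = np.zeros(96)
        for i, label in enumerate(CONTEXT_LABELS):
            c5, rest = label.split("[")
            sub, c3 = rest.split("]")
            if cls is not None and sub != cls:
                continue
            if three is not None and c3 != three:
                continue
            if five is not None and c5 != five:
                continue
            m[i] = 1.0
        return m

    base = 0.08 * np.ones(96)

    sig = channel_mask("C>T", three="G") * 12.0 + base
    cols["sbs1_like"] = sig / sig.sum()

    sig = np.ones(96) + 0.25 * rng.random(96)
    cols["sbs5_like"] = sig / sig.sum()

    sig = channel_mask("C>A") * 6.0 + channel_mask("C>A", five="G") * 6.0 + base
    cols["sbs24_like"] = sig / sig.sum()

    sig = channel_mask("T>C", five="A") * 10.0 + channel_mask("T>C") * 1.5 + base
    cols["sbs16_like"] = sig / sig.sum()

    # broad but structured, so it is separable from the flat clock-like column
    sig = (0.4 * np.ones(96) + channel_mask("C>G") * 2.5
           + channel_mask("T>A") * 1.5 + 0.2 * rng.random(96))
    cols["sbs3_like"] = sig / sig.sum()

    for k in range(n_extra):
        sig = rng.dirichlet(np.full(96, 0.8))
        cols[f"synthetic_{k + 1}"] = sig

    return pd.DataFrame(cols, index=list(CONTEXT_LABELS))
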