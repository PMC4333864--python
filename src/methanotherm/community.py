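"""T-RFLP profile processing, in silico T-RF prediction, and clone-library statistics.

Terminal restriction fragment length polymorphism (T-RFLP) fingerprints an
archaeal community by the length of the fluorescently labeled terminal
fragment each 16S rRNA amplicon yields after restriction digestion (TaqI,
cutting T^CGA, in this pipeline). Fragment sizes act as taxon proxies via a
reference map built from in silico digestion of clone sequences. Clone
libraries are summarized by Good's coverage and analytic rarefaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq
from scipy.special import gammaln

logger = logging.getLogger(__name__)

TAQI_SITE = "TCGA"
TAQI_CUT_OFFSET = 1  # TaqI cuts T^CGA: labeled fragment ends after the T

_VALID_BASES = set("ACGTN")


class CommunityError(ValueError):
    pass


@dataclass
class TrflpProfile:
    """One T-RFLP profile: labeled-fragment sizes (bp) with peak heights.

    ``percent`` holds the percent abundance A_p of each peak (percent of the
    summed peak height); ``diverse_percent`` accumulates the mass of minor
    peaks removed by :func:`filter_minor` (reported as "Diverse", never
    renormalized away).
    """

    temperature_C: float
    day: float
    replicate: str
    trf_bp: list[int]
    heights: list[float]
    percent: list[float] | None = None
    diverse_percent: float = 0.0

    def __post_init__(self) -> None:
        if len(self.trf_bp) != len(self.heights):
            raise CommunityError("trf_bp and heights length mismatch")
        if len(set(self.trf_bp)) != len(self.trf_bp):
            raise CommunityError("duplicate T-RF sizes within one profile")
        if any(h < 0 for h in self.heights):
            raise CommunityError("negative peak height")


@dataclass
class TrfReferenceMap:
    """Fragment-size -> candidate-taxa lookup built from in silico digestion."""

    entries: dict[int, list[str]]

    def __post_init__(self) -> None:
        for bp, taxa in self.entries.items():
            if bp < 1:
                raise CommunityError(f"T-RF size must be >= 1 bp, got {bp}")
            if not taxa:
                raise CommunityError(f"empty taxon list for {bp} bp")


@dataclass
class CloneLibrary:
    """Clone counts per OTU for one library, with Good's coverage."""

    label: str
    otu_counts: list[int]

    @property
    def N(self) -> int:
        return int(sum(self.otu_counts))

    @property
    def n1(self) -> int:
        return sum(1 for c in self.otu_counts if c == 1)

    @property
    def coverage_percent(self) -> float:
        return goods_coverage(self.otu_counts)


def relative_abundance(profile: TrflpProfile) -> TrflpProfile:
    """Compute percent abundances A_p = 100 * height / sum(heights)."""
    total = float(sum(profile.heights))
    if total <= 0:
        raise CommunityError("all-zero profile: cannot compute percent abundances")
    profile.percent = [100.0 * h / total for h in profile.heights]
    return profile


def filter_minor(profile: TrflpProfile, threshold: float = 1.0) -> TrflpProfile:
    """Drop peaks with A_p <= threshold (strict > retains), pooling their mass.

    Retained percents are reported as-is (not renormalized); the removed mass
    appears in ``diverse_percent``.
    """
    if profile.percent is None:
        raise CommunityError("percents not computed; call relative_abundance first")
    keep = [i for i, p in enumerate(profile.percent) if p > threshold]
    removed = sum(p for i, p in enumerate(profile.percent) if i not in set(keep))
    return TrflpProfile(
        temperature_C=profile.temperature_C,
        day=profile.day,
        replicate=profile.replicate,
        trf_bp=[profile.trf_bp[i] for i in keep],
        heights=[profile.heights[i] for i in keep],
        percent=[profile.percent[i] for i in keep],
        diverse_percent=profile.diverse_percent + removed,
    )


def _validate_seq(sequence: str) -> str:
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise CommunityError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def orient_to_label(amplicon: str, labeled_primer: str = "reverse") -> str:
    """Return the amplicon read 5'->3' from the fluorescently labeled end.

    Clone sequences are deposited in the forward (sense) orientation; when the
    label sits on the reverse primer (as with 6-FAM Ar915r here), the labeled
    terminal fragment is measured on the reverse complement.
    """
    seq = _validate_seq(amplicon)
    if labeled_primer == "forward":
        return seq
    if labeled_primer == "reverse":
        return str(Seq(seq).reverse_complement())
    raise CommunityError(f"labeled_primer must be 'forward' or 'reverse', got {labeled_primer!r}")


def insilico_trf(
    amplicon: str, site: str = TAQI_SITE, cut_offset: int = TAQI_CUT_OFFSET
) -> tuple[int, bool]:
    """Predicted labeled-fragment length from in silico restriction digestion.

    ``amplicon`` must already read 5'->3' from the labeled primer end (see
    :func:`orient_to_label`). Scanning from position 0, the first exact
    occurrence of ``site`` determines the cut: fragment length = occurrence
    index + ``cut_offset`` (for TaqI's T^CGA the labeled fragment ends just
    after the T). Ambiguous bases (N) never match. Returns
    ``(length, cut_occurred)``; with no site the full length is returned with
    ``cut_occurred = False``.
    """
    seq = _validate_seq(amplicon)
    if not seq:
        raise CommunityError("empty sequence")
    if not site:
        raise CommunityError("empty recognition site")
    idx = seq.find(site.upper())
    if idx < 0:
        return len(seq), False
    return idx + cut_offset, True


def assign_taxa(
    trf_bp: int, refmap: TrfReferenceMap, tolerance_bp: int = 1
) -> list[str]:
    """All candidate taxa whose reference T-RF lies within +-tolerance_bp.

    Electrophoretic sizing drifts by about a base pair against in silico
    lengths, hence the default tolerance. Ambiguity (several taxa sharing a
    fragment size) is preserved; an empty list means unassigned.
    """
    if not refmap.entries:
        raise CommunityError("empty reference map")
    taxa: list[str] = []
    for ref_bp, ref_taxa in sorted(refmap.entries.items()):
        if abs(ref_bp - trf_bp) <= tolerance_bp:
            for t in ref_taxa:
                if t not in taxa:
                    taxa.append(t)
    return taxa


def build_reference_map(
    taxa_trfs: Iterable[tuple[str, int]]
) -> TrfReferenceMap:
    """Collect (taxon, trf_bp) pairs into a fragment-size lookup."""
    entries: dict[int, list[str]] = {}
    for taxon, bp in taxa_trfs:
        entries.setdefault(int(bp), [])
        if taxon not in entries[bp]:
            entries[bp].append(taxon)
    return TrfReferenceMap(entries=entries)


def goods_coverage(otu_counts: Sequence[int]) -> float:
    """Good's coverage (1 - n1/N) * 100, n1 = singleton OTUs, N = total clones."""
    counts = [int(c) for c in otu_counts if c > 0]
    if not counts:
        raise CommunityError("empty library")
    n = sum(counts)
    n1 = sum(1 for c in counts if c == 1)
    return (1.0 - n1 / n) * 100.0


def rarefaction_curve(
    otu_counts: Sequence[int], depths: Sequence[int]
) -> list[float]:
    """Expected OTU richness at each subsampling depth (without replacement).

    Analytic expectation E[S_m] = sum_i (1 - C(N - N_i, m) / C(N, m)), computed
    with log-gamma arithmetic for numerical stability at large N.
    """
    counts = np.array([c for c in otu_counts if c > 0], dtype=int)
    if counts.size == 0:
        raise CommunityError("empty library")
    n = int(counts.sum())
    out = []
    for m in depths:
        m = int(m)
        if m < 0 or m > n:
            raise CommunityError(f"depth {m} exceeds library size {n}")
        if m == 0:
            out.append(0.0)
            continue
        # log C(N-Ni, m) - log C(N, m); term is 0 when N - Ni < m
        expected = 0.0
        for ni in counts:
            rem = n - int(ni)
            if rem < m:
                expected += 1.0
            else:
                log_ratio = (
                    gammaln(rem + 1) - gammaln(m + 1) - gammaln(rem - m + 1)
                    - (gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1))
                )
                expected += 1.0 - float(np.exp(log_ratio))
        out.append(expected)
    return out


def rarefaction_resample(
    otu_counts: Sequence[int], depths: Sequence[int], reps: int = 1000, seed: int = 0
) -> list[float]:
    """Monte-Carlo rarefaction (subsampling without replacement): oracle for
    the analytic curve."""
    counts = [int(c) for c in otu_counts if c > 0]
    if not counts:
        raise CommunityError("empty library")
    pool = np.repeat(np.arange(len(counts)), counts)
    rng = np.random.default_rng(seed)
    out = []
    for m in depths:
        m = int(m)
        if m > len(pool):
            raise CommunityError(f"depth {m} exceeds library size {len(pool)}")
        richness = np.empty(reps)
        for r in range(reps):
            draw = rng.choice(pool, size=m, replace=False)
            richness[r] = np.unique(draw).size
        out.append(float(richness.mean()))
    return out
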