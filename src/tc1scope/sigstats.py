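"""piRNA signature statistics per element: strand composition, length spectra,
positional base frequencies (sequence-logo matrices), coverage profiles,
the ping-pong 10-nt 5'-overlap spectrum, and overlap with reference piRNA
sequence sets.

The ping-pong signature: secondary piRNA biogenesis produces sense/antisense
read pairs whose 5' ends overlap by exactly 10 nt, so the 5'-overlap spectrum
of a piRNA population peaks sharply at 10.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .srmap import AlignmentHit
from .synthdata import SmallRead

__all__ = [
    "LengthSpectrum",
    "PositionBaseMatrix",
    "CoverageProfile",
    "OverlapSpectrum",
    "strand_composition",
    "length_spectrum",
    "positional_base_matrix",
    "coverage_profile",
    "pingpong_overlap_spectrum",
    "reference_set_overlap",
    "five_prime_position",
]


class ParameterError(ValueError):
    pass


class EmptyInputError(ValueError):
    pass


class ContractError(ValueError):
    """An upstream filter guarantee was violated."""


@dataclass(frozen=True)
class LengthSpectrum:
    counts: dict[int, int]  # per length 20..32

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def modal_length(self) -> int:
        best = max(self.counts.values())
        return min(l for l, c in self.counts.items() if c == best)

    def fraction_in(self, lo: int, hi: int) -> float:
        inside = sum(c for l, c in self.counts.items() if lo <= l <= hi)
        return inside / self.total if self.total else 0.0


@dataclass(frozen=True)
class PositionBaseMatrix:
    """Per-position base frequencies over reads covering the position.

    ``freq`` is indexed by 1-based position with columns A, C, G, U (T is
    reported as U); ``information_content`` is in bits, 2 + sum f*log2 f.
    """

    freq: pd.DataFrame
    information_content: np.ndarray
    coverage: np.ndarray


@dataclass(frozen=True)
class CoverageProfile:
    sense: np.ndarray
    antisense: np.ndarray
    mode: str  # "five_prime_only" | "all_positions"


@dataclass(frozen=True)
class OverlapSpectrum:
    counts: dict[int, float]  # overlap 1..32

    @property
    def modal_overlap(self) -> int:
        best = max(self.counts.values())
        return min(d for d, c in self.counts.items() if c == best)


def five_prime_position(hit: AlignmentHit) -> int:
    """5'-end position of a hit on the reference forward strand."""
    return hit.start if hit.strand == "+" else hit.start + hit.length - 1


def strand_composition(element_hits) -> tuple[float, float]:
    """(sense_fraction, antisense_fraction) of element-specific contributions.

    Accepts a sequence of strand characters ('+'/'-'), of AlignmentHit, or a
    DataFrame with a ``strand`` column.
    """
    if isinstance(element_hits, pd.DataFrame):
        strands = list(element_hits["strand"])
    else:
        strands = [h.strand if isinstance(h, AlignmentHit) else h for h in element_hits]
    if not strands:
        raise EmptyInputError("strand_composition requires at least one read")
    n = len(strands)
    sense = sum(1 for s in strands if s == "+")
    return sense / n, (n - sense) / n


def length_spectrum(reads, lo: int = 20, hi: int = 32) -> LengthSpectrum:
    """Exact length histogram over the selected range (inclusive)."""
    lengths = [r.length if isinstance(r, (SmallRead, AlignmentHit)) else int(r) for r in reads]
    counts = {l: 0 for l in range(lo, hi + 1)}
    for l in lengths:
        if not lo <= l <= hi:
            raise ContractError(f"read length {l} outside [{lo}, {hi}]; upstream filter violated")
        counts[l] += 1
    return LengthSpectrum(counts)


def positional_base_matrix(reads: list[SmallRead], k: int = 32) -> PositionBaseMatrix:
    """Base frequencies per 1-based read position, over reads covering it.

    T is reported as U. Information content per position is
    ``2 + sum_b f_b log2 f_b`` with ``0*log 0 = 0``; IC is in [0, 2] bits.
    """
    if not reads:
        raise EmptyInputError("positional_base_matrix requires at least one read")
    k = min(k, max(r.length for r in reads))
    bases = "ACGT"
    counts = np.zeros((k, 4), dtype=float)
    for r in reads:
        for p, ch in enumerate(r.sequence[:k]):
            counts[p, bases.index(ch)] += 1
    coverage = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / coverage[:, None]
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    ic = np.where(coverage > 0, ic, np.nan)
    df = pd.DataFrame(freq, index=pd.RangeIndex(1, k + 1, name="position"), columns=["A", "C", "G", "U"])
    return PositionBaseMatrix(freq=df, information_content=ic, coverage=coverage)


def coverage_profile(
    element_hits: list[AlignmentHit],
    ref_len: int,
    mode: str = "five_prime_only",
) -> CoverageProfile:
    """Per-position read coverage of one reference, tallied separately per
    strand.

    ``five_prime_only`` adds 1 at each read's 5'-end position (plus-strand 5'
    = start; minus-strand 5' = start + length - 1); ``all_positions`` adds 1
    at every covered position.
    """
    if mode not in ("five_prime_only", "all_positions"):
        raise ParameterError(f"unknown mode {mode!r}")
    sense = np.zeros(ref_len, dtype=np.int64)
    anti = np.zeros(ref_len, dtype=np.int64)
    for h in element_hits:
        if h.start < 0 or h.start + h.length > ref_len:
            raise ContractError(f"hit {h} outside reference of length {ref_len}")
        arr = sense if h.strand == "+" else anti
        if mode == "five_prime_only":
            arr[five_prime_position(h)] += 1
        else:
            arr[h.start : h.start + h.length] += 1
    return CoverageProfile(sense=sense, antisense=anti, mode=mode)


def pingpong_overlap_spectrum(element_hits: list[AlignmentHit], max_overlap: int = 32) -> OverlapSpectrum:
    """Sense-antisense 5'-end overlap spectrum.

    For every (sense 5' = s, antisense 5' = a) combination on the same
    reference with a >= s, the overlap is a - s + 1; overlaps in 1..32
    increment the spectrum weighted by the product of read multiplicities at
    the two 5' positions. Computed from per-position 5'-end multiplicity
    histograms, not by pair enumeration. The spectrum is empty (all zeros) if
    either strand is absent.
    """
    by_ref: dict[str, tuple[defaultdict, defaultdict]] = {}
    for h in element_hits:
        s_hist, a_hist = by_ref.setdefault(h.ref_id, (defaultdict(int), defaultdict(int)))
        if h.strand == "+":
            s_hist[five_prime_position(h)] += 1
        else:
            a_hist[five_prime_position(h)] += 1
    counts = {d: 0.0 for d in range(1, max_overlap + 1)}
    for s_hist, a_hist in by_ref.values():
        for s, ns in s_hist.items():
            for d in range(1, max_overlap + 1):
                na = a_hist.get(s + d - 1)
                if na:
                    counts[d] += ns * na
    return OverlapSpectrum(counts)


def reference_set_overlap(
    reads: list[SmallRead],
    reference_sequences,
    distinct: bool = False,
) -> float:
    """Fraction of reads whose full sequence exactly matches any reference
    sequence (same strand).

    With ``distinct=True`` the fraction is over distinct read sequences rather
    than read instances.
    """
    refset = set(reference_sequences)
    if not refset:
        raise ParameterError("reference set must be non-empty")
    if distinct:
        seqs = {r.sequence for r in reads}
        if not seqs:
            raise EmptyInputError("no reads")
        return sum(1 for s in seqs if s in refset) / len(seqs)
    if not reads:
        raise EmptyInputError("no reads")
    return sum(1 for r in reads if r.sequence in refset) / len(reads)
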