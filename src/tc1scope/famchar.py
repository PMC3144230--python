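"""Characterize a transposon family in a genome: extract copies by in-silico
PCR, compute pairwise percent identities, cluster by single linkage, and
annotate the element structure (terminal inverted repeats, direct repeats,
ORF intactness, length summary).

Coordinates are 0-based half-open internally; written reports use 1-based
inclusive coordinates (see :mod:`tc1scope.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Seq import Seq
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._seq import encode, revcomp

__all__ = [
    "ExtractedLocus",
    "IdentityMatrix",
    "IRAnnotation",
    "DirectRepeat",
    "OrfStatus",
    "insilico_pcr",
    "global_identity",
    "all_vs_all_identity",
    "single_linkage",
    "detect_terminal_inverted_repeats",
    "detect_direct_repeats",
    "align_to_consensus",
    "orient_to_consensus",
    "classify_orf",
    "family_summary",
]


class ParameterError(ValueError):
    pass


class CoverageError(ValueError):
    """The copy-to-consensus alignment does not cover the reference ORF."""


@dataclass(frozen=True)
class ExtractedLocus:
    """One in-silico PCR amplicon, reported 5'->3' on the genome + strand."""

    chrom: str
    interval: tuple[int, int]
    strand: str
    sequence: str

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass(frozen=True)
class IdentityMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, percent, diagonal 100

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass(frozen=True)
class IRAnnotation:
    left: tuple[int, int]
    right: tuple[int, int]
    length: int
    percent_identity: float


@dataclass(frozen=True)
class DirectRepeat:
    left: tuple[int, int]
    right: tuple[int, int]
    length: int


@dataclass(frozen=True)
class OrfStatus:
    copy_id: str
    status: str  # "intact" | "disrupted"
    reason: str  # "none" | "premature_stop" | "frameshift" | "missing_start"


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    """Global affine-gap aligner: match +2, mismatch -1, open -5, extend -1."""
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -1
    a.open_gap_score = -5
    a.extend_gap_score = -1
    return a


def _identity_from_alignment(aln) -> float:
    """Percent identity = 100 * matches / alignment columns, counting internal
    gap columns and excluding terminal-overhang columns."""
    t, q = aln.target, aln.query
    coords = aln.coordinates
    steps = []
    for k in range(coords.shape[1] - 1):
        t0, t1 = int(coords[0, k]), int(coords[0, k + 1])
        q0, q1 = int(coords[1, k]), int(coords[1, k + 1])
        steps.append((t0, t1, q0, q1))
    # trim terminal overhangs (leading/trailing gap-only steps)
    while steps and (steps[0][1] - steps[0][0] == 0 or steps[0][3] - steps[0][2] == 0):
        steps.pop(0)
    while steps and (steps[-1][1] - steps[-1][0] == 0 or steps[-1][3] - steps[-1][2] == 0):
        steps.pop()
    columns = 0
    matches = 0
    for t0, t1, q0, q1 in steps:
        dt, dq = t1 - t0, q1 - q0
        columns += max(dt, dq)
        if dt == dq:
            matches += sum(1 for x, y in zip(t[t0:t1], q[q0:q1]) if x == y)
    if columns == 0:
        return 0.0
    return 100.0 * matches / columns


def global_identity(a: str, b: str) -> float:
    """Percent identity of the global alignment of two DNA sequences.

    Symmetric in its arguments (the pair is canonically ordered before
    alignment so tie-breaking between co-optimal alignments cannot differ).
    """
    if not a or not b:
        raise ParameterError("global_identity requires non-empty sequences")
    x, y = (a, b) if a <= b else (b, a)
    aln = _aligner().align(x, y)[0]
    return _identity_from_alignment(aln)


def align_to_consensus(copy_seq: str, consensus_seq: str):
    """Global alignment of a copy (query) against the consensus (target)."""
    if not copy_seq or not consensus_seq:
        raise ParameterError("alignment requires non-empty sequences")
    return _aligner().align(consensus_seq, copy_seq)[0]


def _mismatch_positions(genome: np.ndarray, primer: np.ndarray, max_mismatch: int) -> np.ndarray:
    n = len(genome) - len(primer) + 1
    if n <= 0:
        return np.empty(0, dtype=int)
    mism = np.zeros(n, dtype=np.int32)
    for j, pb in enumerate(primer):
        mism += genome[j : j + n] != pb
    return np.nonzero(mism <= max_mismatch)[0]


def insilico_pcr(
    genome: dict[str, str],
    primer: str,
    max_amplicon: int = 2000,
    max_mismatch: int | None = None,
) -> list[ExtractedLocus]:
    """Extract amplicons delimited by a primer and its downstream reverse
    complement.

    Finds all primer occurrences with at most ``max_mismatch`` substitutions
    (no indels) on both strands, then pairs each forward occurrence with the
    nearest downstream reverse-complement occurrence such that the amplicon
    (both primer sites included) is at most ``max_amplicon`` long. Sites are
    consumed left to right, so amplicons never share a primer site. Default
    ``max_mismatch`` is floor(0.07 * |primer|).
    """
    if not primer:
        raise ParameterError("primer must be non-empty")
    if max_amplicon <= 2 * len(primer):
        raise ParameterError("max_amplicon must exceed twice the primer length")
    if max_mismatch is None:
        max_mismatch = int(0.07 * len(primer))
    p = encode(primer)
    p_rc = encode(revcomp(primer))
    plen = len(primer)
    loci: list[ExtractedLocus] = []
    for chrom in sorted(genome):
        g = encode(genome[chrom])
        fwd = _mismatch_positions(g, p, max_mismatch)
        rev = _mismatch_positions(g, p_rc, max_mismatch)
        used_rev = np.zeros(len(rev), dtype=bool)
        ri = 0
        for f in fwd:
            # advance to the first unused reverse site starting after this
            # forward site's first base
            while ri < len(rev) and (used_rev[ri] or rev[ri] <= f):
                ri += 1
            j = ri
            while j < len(rev):
                if not used_rev[j] and rev[j] > f:
                    end = int(rev[j]) + plen
                    if end - f > max_amplicon:
                        j = len(rev)  # nearest candidate already too far
                        break
                    used_rev[j] = True
                    seq = genome[chrom][f:end]
                    loci.append(ExtractedLocus(chrom, (int(f), end), "+", seq))
                    break
                j += 1
    return loci


def all_vs_all_identity(loci: dict[str, str] | list[ExtractedLocus]) -> IdentityMatrix:
    """Apply :func:`global_identity` to every unordered pair of sequences."""
    if isinstance(loci, list):
        seqs = {f"{l.chrom}:{l.interval[0]}-{l.interval[1]}": l.sequence for l in loci}
    else:
        seqs = dict(loci)
    if not seqs:
        raise ParameterError("at least one locus is required")
    ids = tuple(seqs)
    n = len(ids)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                values[i, j] = values[j, i] = global_identity(seqs[ids[i]], seqs[ids[j]])
            except ParameterError as e:
                raise ParameterError(f"pair ({ids[i]}, {ids[j]}): {e}") from e
    return IdentityMatrix(ids, values)


def single_linkage(matrix: IdentityMatrix, threshold: float) -> list[list[str]]:
    """Single-linkage clusters at the given percent-identity threshold.

    Clusters are the connected components of the graph with an edge wherever
    identity >= threshold. Output order is deterministic: clusters sorted by
    their smallest member id, members ascending.
    """
    if not 0 <= threshold <= 100:
        raise ParameterError(f"threshold must be in [0, 100], got {threshold}")
    ids = list(matrix.ids)
    n = len(ids)
    if n == 1:
        return [[ids[0]]]
    dist = 100.0 - np.asarray(matrix.values, dtype=float)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="single")
    labels = fcluster(Z, t=(100.0 - threshold) + 1e-9, criterion="distance")
    groups: dict[int, list[str]] = {}
    for ident, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(ident)
    clusters = [sorted(members) for members in groups.values()]
    clusters.sort(key=lambda c: c[0])
    return clusters


def detect_terminal_inverted_repeats(
    seq: str,
    min_len: int = 30,
    min_identity: float = 90.0,
) -> IRAnnotation | None:
    """Detect a terminal inverted repeat anchored at both sequence ends.

    The 5' terminal window is compared base-by-base against the reverse
    complement of the 3' terminal window; the reported length maximizes
    ``matches(L) - (min_identity/100) * L`` over ``L``, which places the
    boundary at the point where local match density drops below the identity
    threshold. Returns ``None`` if no window of at least ``min_len`` reaches
    ``min_identity``.
    """
    if len(seq) < 2 * min_len:
        raise ParameterError("sequence shorter than twice min_len")
    half = len(seq) // 2
    left = encode(seq[:half])
    right_rc = encode(revcomp(seq[-half:]))
    match = (left == right_rc).astype(np.float64)
    cum = np.cumsum(match)
    lengths = np.arange(1, half + 1)
    score = cum - (min_identity / 100.0) * lengths
    valid = lengths >= min_len
    if not valid.any():
        return None
    best = score.copy()
    best[~valid] = -np.inf
    # largest L on ties
    L = int(len(best) - 1 - np.argmax(best[::-1]))
    length = L + 1
    identity = 100.0 * cum[L] / length
    if identity < min_identity:
        return None
    return IRAnnotation(left=(0, length), right=(len(seq) - length, len(seq)), length=length, percent_identity=identity)


def detect_direct_repeats(seq: str, ir: IRAnnotation, k: int = 17) -> list[DirectRepeat]:
    """Maximal exact substrings of length >= k shared by the two IR intervals
    in the same orientation. Longest first; ties by leftmost occurrence.
    Intervals are absolute coordinates on ``seq``.
    """
    if k < 8:
        raise ParameterError("k must be >= 8")
    lo_l, hi_l = ir.left
    lo_r, hi_r = ir.right
    left = seq[lo_l:hi_l]
    right = seq[lo_r:hi_r]
    index: dict[str, list[int]] = {}
    for j in range(len(right) - k + 1):
        index.setdefault(right[j : j + k], []).append(j)
    found: set[tuple[int, int, int]] = set()
    for i in range(len(left) - k + 1):
        for j in index.get(left[i : i + k], ()):
            bi, bj = i, j
            while bi > 0 and bj > 0 and left[bi - 1] == right[bj - 1]:
                bi -= 1
                bj -= 1
            n = k + (i - bi)
            while bi + n < len(left) and bj + n < len(right) and left[bi + n] == right[bj + n]:
                n += 1
            found.add((bi, bj, n))
    reps = [
        DirectRepeat(left=(lo_l + bi, lo_l + bi + n), right=(lo_r + bj, lo_r + bj + n), length=n)
        for bi, bj, n in found
        if n >= k
    ]
    reps.sort(key=lambda r: (-r.length, r.left[0], r.right[0]))
    return reps


def _project(coords: np.ndarray, pos: int) -> int:
    """Map a consensus (target) coordinate to the copy (query) coordinate via
    alignment coordinates; positions inside a copy deletion map to the block
    edge."""
    t, q = coords[0], coords[1]
    for k in range(len(t) - 1):
        if t[k] <= pos <= t[k + 1]:
            if t[k + 1] == t[k]:  # insertion in copy at this point
                return int(q[k])
            if q[k + 1] == q[k]:  # deletion in copy spanning pos
                return int(q[k])
            return int(q[k] + (pos - t[k]))
    raise CoverageError(f"consensus position {pos} outside alignment")


def classify_orf(
    copy_seq: str,
    orf_interval: tuple[int, int],
    alignment,
    copy_id: str = "",
) -> OrfStatus:
    """Classify a copy's transposase ORF by projecting the consensus ORF
    through a copy-to-consensus global alignment.

    Disruption reasons, checked in order: ``frameshift`` if the net indel
    length inside the ORF is not a multiple of 3; ``premature_stop`` if the
    projected ORF translation stops before the final codon; ``missing_start``
    if the projected start codon is not ATG.
    """
    s, e = orf_interval
    coords = alignment.coordinates
    t0, t1 = int(coords[0, 0]), int(coords[0, -1])
    if s < t0 or e > t1:
        raise CoverageError("alignment does not cover the consensus ORF interval")
    cs = _project(coords, s)
    ce = _project(coords, e)
    sub = copy_seq[cs:ce]
    if (len(sub) - (e - s)) % 3 != 0:
        return OrfStatus(copy_id, "disrupted", "frameshift")
    # stop-check precedes start-check: a premature stop is the stronger signal
    prot = str(Seq(sub[: len(sub) - len(sub) % 3]).translate())
    if "*" in prot[:-1]:
        return OrfStatus(copy_id, "disrupted", "premature_stop")
    if not sub.startswith("ATG"):
        return OrfStatus(copy_id, "disrupted", "missing_start")
    return OrfStatus(copy_id, "intact", "none")


def orient_to_consensus(seq: str, consensus_seq: str, k: int = 12) -> tuple[str, str]:
    """Orient an extracted copy to the consensus sense strand.

    Returns ``(oriented_sequence, strand)`` where strand is the extracted
    sequence's orientation relative to the consensus. Uses shared k-mer counts
    (cheap and robust at family-level identity); falls back to alignment score
    only on a tie.
    """
    kmers = {consensus_seq[i : i + k] for i in range(len(consensus_seq) - k + 1)}
    fwd = sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] in kmers)
    rc = revcomp(seq)
    rev = sum(1 for i in range(len(rc) - k + 1) if rc[i : i + k] in kmers)
    if fwd == rev:
        fwd_score = _aligner().score(consensus_seq, seq)
        rev_score = _aligner().score(consensus_seq, rc)
        return (seq, "+") if fwd_score >= rev_score else (rc, "-")
    return (seq, "+") if fwd > rev else (rc, "-")


def family_summary(
    loci: list[ExtractedLocus] | list[str],
    statuses: list[OrfStatus] | None = None,
    identity: IdentityMatrix | None = None,
) -> dict:
    """Copy count, length statistics, pairwise-identity summary and intact-ORF
    census for one element family."""
    if not loci:
        raise ParameterError("family_summary requires at least one locus")
    lengths = [len(l) if isinstance(l, str) else l.length for l in loci]
    out = {
        "n_copies": len(lengths),
        "mean_length": float(np.mean(lengths)),
        "min_length": int(min(lengths)),
        "max_length": int(max(lengths)),
        "n_intact": sum(1 for s in statuses if s.status == "intact") if statuses is not None else None,
        "min_identity": None,
        "median_identity": None,
    }
    if identity is not None and len(identity.ids) > 1:
        off = identity.values[np.triu_indices(len(identity.ids), k=1)]
        out["min_identity"] = float(off.min())
        out["median_identity"] = float(np.median(off))
    return out
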