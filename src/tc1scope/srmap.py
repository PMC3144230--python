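"""Small-RNA read preprocessing and exact-match mapping.

Mirrors a standard small-RNA-seq workflow: 3' adapter clipping, exclusion of
reads with uncalled bases or shorter than 15 nt, selection of 20-32-nt reads,
exact full-length mapping to references on both strands, element-specific
assignment (reads hitting more than one element family, or any non-TE
reference, are excluded; multiple hits within one family count once), and
reads-per-million normalization.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from ._seq import revcomp
from .synthdata import SmallRead

__all__ = [
    "AlignmentHit",
    "preprocess_reads",
    "select_lengths",
    "exact_map",
    "assign_to_elements",
    "rpm_normalize",
    "hits_to_frame",
]

DEFAULT_ADAPTER = "ATCTCGTATGCCGTCTTCTGCTTG"
MIN_KEEP_LEN = 15
MIN_ADAPTER_MATCH = 5


class ParameterError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    """One exact full-length match of a read on a reference.

    ``start`` is 0-based on the reference forward strand; a minus-strand hit
    means the reverse complement of the read equals the reference substring.
    """

    read_id: str
    ref_id: str
    start: int
    strand: str
    length: int


def _clip_adapter(seq: str, adapter: str) -> str:
    """Truncate at the leftmost position >= 1 where the remainder of the read
    matches a prefix of the adapter of at least MIN_ADAPTER_MATCH nt (or runs
    to the read end). Reads with no such occurrence are kept whole."""
    n = len(seq)
    for p in range(1, n - MIN_ADAPTER_MATCH + 1):
        k = 0
        mx = min(len(adapter), n - p)
        while k < mx and seq[p + k] == adapter[k]:
            k += 1
        if k >= MIN_ADAPTER_MATCH:
            return seq[:p]
    return seq


def preprocess_reads(
    raw_reads: list[SmallRead],
    adapter: str = DEFAULT_ADAPTER,
) -> tuple[list[SmallRead], dict[str, int]]:
    """Adapter-clip and filter raw reads.

    Returns the retained reads and a tally of dropped reads by reason
    (``mis_read`` for reads containing N after clipping, ``too_short`` for
    clipped reads below 15 nt).
    """
    if not adapter:
        raise ParameterError("adapter must be non-empty")
    kept: list[SmallRead] = []
    dropped = {"mis_read": 0, "too_short": 0}
    for r in raw_reads:
        seq = _clip_adapter(r.sequence, adapter)
        if "N" in seq:
            dropped["mis_read"] += 1
        elif len(seq) < MIN_KEEP_LEN:
            dropped["too_short"] += 1
        else:
            kept.append(SmallRead(r.read_id, seq))
    return kept, dropped


def select_lengths(reads: list[SmallRead], lo: int = 20, hi: int = 32) -> list[SmallRead]:
    """Retain reads with lo <= length <= hi (inclusive both ends)."""
    if lo > hi:
        raise ParameterError(f"lo ({lo}) must be <= hi ({hi})")
    return [r for r in reads if lo <= r.length <= hi]


def exact_map(reads: list[SmallRead], references: dict[str, str]) -> list[AlignmentHit]:
    """Every exact full-length occurrence of each read on either strand of
    every reference.

    All distinct read sequences and their reverse complements are indexed in a
    hash table keyed by sequence; windows of each distinct read length are
    slid across each reference. Minus-strand hits report forward-strand start
    coordinates.
    """
    if not references:
        raise ParameterError("references must be non-empty")
    table: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for r in reads:
        table[r.sequence].append((r.read_id, "+"))
        table[revcomp(r.sequence)].append((r.read_id, "-"))
    lengths = sorted({r.length for r in reads})
    hits: list[AlignmentHit] = []
    for ref_id in sorted(references):
        ref = references[ref_id]
        for l in lengths:
            for i in range(len(ref) - l + 1):
                entries = table.get(ref[i : i + l])
                if entries:
                    for read_id, strand in entries:
                        hits.append(AlignmentHit(read_id, ref_id, i, strand, l))
    return hits


def hits_to_frame(hits: list[AlignmentHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.read_id, h.ref_id, h.start, h.strand, h.length) for h in hits],
        columns=["read_id", "ref", "start0", "strand", "length"],
    )


def assign_to_elements(
    hits: list[AlignmentHit],
    family_of_ref: dict[str, str],
    other_refs: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Element-specific read assignment.

    A read contributes if and only if all its hits fall within exactly one
    element family; hits on several copies or several positions of the same
    family count as one contribution. Reads also hitting any non-TE reference
    (``other_refs``) or a second family are excluded. The contribution strand
    is the majority hit strand relative to the element's ORF orientation (the
    references' forward strand); strand ties are excluded and logged.

    Returns ``(counts, contributions, exclusions)``: per-family counts
    (specific/sense/antisense, rpm unset), one row per contributing read
    (read_id, family, strand), and an exclusion tally.
    """
    other_refs = other_refs or set()
    by_read: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        if h.ref_id not in other_refs and h.ref_id not in family_of_ref:
            raise ConfigurationError(f"reference {h.ref_id!r} has no family label and is not in other_refs")
        by_read[h.read_id].append(h)

    exclusions = {"multi_family": 0, "other_ref": 0, "strand_tie": 0}
    contrib_rows = []
    for read_id in sorted(by_read):
        rhits = by_read[read_id]
        if any(h.ref_id in other_refs for h in rhits):
            if any(h.ref_id in family_of_ref for h in rhits):
                exclusions["other_ref"] += 1
            continue
        families = {family_of_ref[h.ref_id] for h in rhits}
        if len(families) > 1:
            exclusions["multi_family"] += 1
            continue
        family = families.pop()
        n_plus = sum(1 for h in rhits if h.strand == "+")
        n_minus = len(rhits) - n_plus
        if n_plus == n_minus:
            exclusions["strand_tie"] += 1
            continue
        strand = "+" if n_plus > n_minus else "-"
        contrib_rows.append((read_id, family, strand))

    contributions = pd.DataFrame(contrib_rows, columns=["read_id", "family", "strand"])
    families = sorted(set(family_of_ref.values()))
    rows = []
    for fam in families:
        sub = contributions[contributions.family == fam]
        sense = int((sub.strand == "+").sum())
        anti = int((sub.strand == "-").sum())
        rows.append(dict(element=fam, specific=sense + anti, sense=sense, antisense=anti, rpm=float("nan")))
    counts = pd.DataFrame(rows, columns=["element", "specific", "sense", "antisense", "rpm"])
    return counts, contributions, exclusions


def rpm_normalize(counts: pd.DataFrame, normalization_total: int) -> pd.DataFrame:
    """Reads-per-million scaling of per-family specific counts.

    The denominator is conventionally the number of preprocessed,
    length-selected reads that match the genome exactly; raw counts are
    preserved.
    """
    if normalization_total <= 0:
        raise ParameterError(f"normalization_total must be > 0, got {normalization_total}")
    out = counts.copy()
    out["rpm"] = 1e6 * out["specific"] / normalization_total
    return out
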