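"""Seeded synthetic fixtures: a Tc1/mariner-like consensus element, genomes with
planted mutated copies, and small-RNA libraries with piRNA-like statistical
structure (antisense bias, 1U/10A positional bias, 10-nt ping-pong overlaps),
together with machine-readable ground truth.

The generator emulates the study conditions the analysis modules assume: a
~1.6-kb DNA transposon whose transposase ORF is flanked by 199-bp terminal
inverted repeats carrying 17-bp direct repeats, a few hundred >93%-identical
genomic copies of which only a handful retain an intact ORF, and 20-32-nt
small-RNA libraries that are mostly antisense to the element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import DNA_ALPHABET, STOP_CODONS, random_dna, revcomp, substream

__all__ = [
    "ElementArchitecture",
    "ElementConsensus",
    "SignatureParams",
    "SmallRead",
    "LENGTH_WEIGHTS_27_28",
    "LENGTH_WEIGHTS_24_25",
    "build_consensus_element",
    "plant_copies",
    "simulate_pirna_reads",
    "simulate_background_reads",
]

READ_LENGTHS = np.arange(20, 33)

# Length spectra over 20..32 nt. The main preset peaks at 27-28 nt with ~95% of
# mass in 23..30 nt; the alternative preset peaks at 24-25 nt (some Tc1-like
# families show the shorter mode).
LENGTH_WEIGHTS_27_28 = np.array(
    [0.005, 0.005, 0.015, 0.04, 0.07, 0.09, 0.13, 0.23, 0.21, 0.12, 0.06, 0.015, 0.01]
)
LENGTH_WEIGHTS_24_25 = np.array(
    [0.01, 0.02, 0.06, 0.12, 0.22, 0.20, 0.13, 0.09, 0.07, 0.04, 0.03, 0.006, 0.004]
)


class ParameterError(ValueError):
    """A constructor or operation argument violates its contract."""


class CapacityError(ValueError):
    """The genome cannot host the requested copies without overlap."""


@dataclass(frozen=True)
class ElementArchitecture:
    """Structural blueprint of the consensus element.

    Layout: left IR | spacer | transposase ORF | spacer (with PAS) | right IR,
    with the right IR the exact reverse complement of the left and one direct
    repeat embedded at the same offset of each IR in identical orientation.
    """

    total_len: int = 1581
    ir_len: int = 199
    dr_len: int = 17
    orf_len: int = 1020  # multiple of 3, includes the stop codon
    pas_motif: str = "AATAAA"
    seed: int = 0

    def validate(self) -> None:
        if self.total_len < 2 * self.ir_len + self.orf_len:
            raise ParameterError(
                "architecture invariant violated: total_len >= 2*ir_len + orf_len "
                f"(got total_len={self.total_len}, ir_len={self.ir_len}, orf_len={self.orf_len})"
            )
        if not (self.ir_len > self.dr_len > 0):
            raise ParameterError(
                f"architecture invariant violated: ir_len > dr_len > 0 (got {self.ir_len}, {self.dr_len})"
            )
        if self.orf_len % 3 != 0:
            raise ParameterError(f"architecture invariant violated: orf_len mod 3 = 0 (got {self.orf_len})")
        if self.orf_len < 9:
            raise ParameterError("orf_len must allow start + >=1 internal codon + stop")
        if self.ir_len < 2 * self.dr_len + 2:
            raise ParameterError(
                "ir_len must be >= 2*dr_len + 2 so each IR can host the direct repeat "
                "in identical orientation on both termini"
            )


@dataclass(frozen=True)
class ElementConsensus:
    """A consensus transposon sequence plus its structural annotation.

    Intervals are 0-based half-open on the element's sense strand (the strand
    carrying the transposase ORF).
    """

    id: str
    sequence: str
    ir_left: tuple[int, int]
    ir_right: tuple[int, int]
    dr_intervals: tuple[tuple[int, int], ...]
    orf_interval: tuple[int, int]
    orf_frame: int
    pas_interval: tuple[int, int] | None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def orf_sequence(self) -> str:
        return self.sequence[self.orf_interval[0] : self.orf_interval[1]]


@dataclass(frozen=True)
class SmallRead:
    read_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SignatureParams:
    """Parameters of the simulated transposon-derived small-RNA library.

    ``u1_prob``/``a10_prob`` give the marginal probability of U at position 1
    of antisense reads and A at position 10 of sense reads (the non-favoured
    bases share the remainder uniformly); ``None`` disables the bias so every
    read is an exact substring of the element (or its reverse complement).
    ``pingpong_fraction`` is the fraction of reads emitted as members of
    sense/antisense couples whose 5' ends overlap by exactly 10 nt.
    """

    n_reads: int = 10_000
    antisense_fraction: float = 0.943
    pingpong_fraction: float = 0.1
    u1_prob: float | None = 0.8
    a10_prob: float | None = 0.8
    length_weights: np.ndarray = field(default_factory=lambda: LENGTH_WEIGHTS_27_28.copy())
    seed: int = 0

    def validate(self) -> None:
        for name in ("antisense_fraction", "pingpong_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for name in ("u1_prob", "a10_prob"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1] or None, got {v}")
        w = np.asarray(self.length_weights, dtype=float)
        if w.shape != (13,):
            raise ParameterError("length_weights must cover lengths 20..32 (13 weights)")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ParameterError("length_weights must be non-negative and sum to 1")
        if self.n_reads < 0:
            raise ParameterError("n_reads must be non-negative")


def _random_orf(rng: np.random.Generator, orf_len: int) -> str:
    """ATG + random non-stop codons + one stop codon."""
    n_internal = orf_len // 3 - 2
    sense_codons = [a + b + c for a in DNA_ALPHABET for b in DNA_ALPHABET for c in DNA_ALPHABET]
    sense_codons = [c for c in sense_codons if c not in STOP_CODONS and c != "ATG"]
    body = "".join(rng.choice(sense_codons) for _ in range(n_internal))
    stop = rng.choice(sorted(STOP_CODONS))
    return "ATG" + body + stop


def _max_shared_direct_run(left: str, right: str, k_floor: int = 4) -> int:
    """Length of the longest substring shared by ``left`` and ``right`` in the
    same orientation (simple seed-and-extend over k_floor-mers)."""
    best = 0
    index: dict[str, list[int]] = {}
    for j in range(len(right) - k_floor + 1):
        index.setdefault(right[j : j + k_floor], []).append(j)
    for i in range(len(left) - k_floor + 1):
        for j in index.get(left[i : i + k_floor], ()):
            if i > 0 and j > 0 and left[i - 1] == right[j - 1]:
                continue  # not run-maximal; counted at its leftmost seed
            n = k_floor
            while i + n < len(left) and j + n < len(right) and left[i + n] == right[j + n]:
                n += 1
            best = max(best, n)
    return best


def _build_ir(rng: np.random.Generator, ir_len: int, dr_len: int) -> tuple[str, str, int, int]:
    """Left IR carrying the DR at offset ``o`` and revcomp(DR) at the mirrored
    offset, so that the right IR (revcomp of the left) carries the DR at the
    same offset ``o`` in direct orientation.

    Rejection-sampled until the longest same-orientation substring shared by
    the two IRs is exactly ``dr_len`` (i.e. the planted repeat, not a chance
    extension of it).
    """
    o = max(1, (ir_len - 2 * dr_len) // 3)
    m = ir_len - dr_len - o  # mirrored offset
    for _ in range(200):
        dr = random_dna(rng, dr_len)
        ir = list(random_dna(rng, ir_len))
        ir[o : o + dr_len] = dr
        ir[m : m + dr_len] = revcomp(dr)
        left = "".join(ir)
        if _max_shared_direct_run(left, revcomp(left), k_floor=min(4, dr_len)) == dr_len:
            return left, dr, o, m
    raise RuntimeError("could not sample an IR with an exact-length direct repeat")


def build_consensus_element(arch: ElementArchitecture | None = None) -> ElementConsensus:
    """Build the synthetic consensus element for the given architecture.

    Deterministic for a fixed ``arch.seed``. The right IR is the exact reverse
    complement of the left IR; when spacers are non-empty the first base inside
    each IR is forced to break the terminal palindrome, so the element's
    terminal inverted repeat has length exactly ``ir_len``.
    """
    arch = arch or ElementArchitecture()
    arch.validate()
    rng = substream(arch.seed, 0)

    interior = arch.total_len - 2 * arch.ir_len
    spacer_total = interior - arch.orf_len
    sp1_len = spacer_total // 2
    sp2_len = spacer_total - sp1_len

    ir_left_seq, _dr, o, m = _build_ir(rng, arch.ir_len, arch.dr_len)
    orf_seq = _random_orf(rng, arch.orf_len)
    sp1 = random_dna(rng, sp1_len)
    sp2 = random_dna(rng, sp2_len)

    pas_interval: tuple[int, int] | None = None
    pas_len = len(arch.pas_motif)
    if sp2_len >= pas_len:
        # PAS sits at the very end of the 3' spacer, flush against the right IR.
        pas_off = sp2_len - pas_len
        sp2 = sp2[:pas_off] + arch.pas_motif
        pas_start = arch.ir_len + sp1_len + arch.orf_len + pas_off
        pas_interval = (pas_start, pas_start + pas_len)

    # Break the palindrome just inside the IRs so the terminal inverted repeat
    # is exactly ir_len long. The base paired with sp1[0] across the element is
    # the last base before the right IR (end of sp2, possibly the PAS tail).
    inner_right = sp2[-1] if sp2_len else orf_seq[-1]
    if sp1_len > 0:
        forbidden = revcomp(inner_right)
        if sp1[0] == forbidden:
            repl = [b for b in DNA_ALPHABET if b != forbidden]
            sp1 = repl[int(rng.integers(0, 3))] + sp1[1:]

    sequence = ir_left_seq + sp1 + orf_seq + sp2 + revcomp(ir_left_seq)
    assert len(sequence) == arch.total_len

    orf_start = arch.ir_len + sp1_len
    ir_right_start = arch.total_len - arch.ir_len
    dr_intervals = (
        (o, o + arch.dr_len),
        (ir_right_start + o, ir_right_start + o + arch.dr_len),
    )
    return ElementConsensus(
        id="Tc1-like_synthetic",
        sequence=sequence,
        ir_left=(0, arch.ir_len),
        ir_right=(ir_right_start, arch.total_len),
        dr_intervals=dr_intervals,
        orf_interval=(orf_start, orf_start + arch.orf_len),
        orf_frame=0,
        pas_interval=pas_interval,
    )


def _mutate_copy(
    rng: np.random.Generator,
    consensus: ElementConsensus,
    sub_rate: float,
    keep_orf: bool,
) -> tuple[str, int, int]:
    """Point-mutate one copy. Returns (sequence, n_substitutions, n_indels).

    Intact copies only receive substitutions that cannot disrupt the ORF (the
    start and stop codons are spared and no stop codon is created). Disrupted
    copies additionally receive one frameshifting 1-nt deletion or one
    premature stop substitution inside the ORF.
    """
    seq = list(consensus.sequence)
    orf_s, orf_e = consensus.orf_interval
    n_subs = 0
    positions = np.nonzero(rng.random(len(seq)) < sub_rate)[0]
    for pos in positions:
        old = seq[pos]
        choices = [b for b in DNA_ALPHABET if b != old]
        new = choices[rng.integers(0, 3)]  # uniform over the three other bases
        if keep_orf and orf_s <= pos < orf_e:
            codon_idx = (pos - orf_s) // 3
            n_codons = (orf_e - orf_s) // 3
            if codon_idx == 0 or codon_idx == n_codons - 1:
                continue  # spare start and stop codons
            c0 = orf_s + 3 * codon_idx
            codon = seq[c0:c0 + 3]
            codon[pos - c0] = new
            if "".join(codon) in STOP_CODONS:
                continue  # never create a premature stop in an intact copy
        seq[pos] = new
        n_subs += 1

    n_indels = 0
    if not keep_orf:
        n_codons = (orf_e - orf_s) // 3
        if rng.random() < 0.5:
            # frameshift: 1-nt deletion in the ORF interior
            pos = int(rng.integers(orf_s + 3, orf_e - 3))
            del seq[pos]
            n_indels = 1
        else:
            # premature stop mid-ORF
            codon_idx = int(rng.integers(2, n_codons - 2))
            c0 = orf_s + 3 * codon_idx
            seq[c0:c0 + 3] = "TAA"
            n_subs += sum(1 for a, b in zip("TAA", consensus.sequence[c0:c0 + 3]) if a != b)
    return "".join(seq), n_subs, n_indels


def plant_copies(
    genome_len: int,
    n_chrom: int,
    consensus: ElementConsensus,
    n_copies: int,
    sub_rate: float = 0.02,
    n_intact: int | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant point-mutated element copies into an i.i.d. random genome.

    Returns ``(genome, truth)`` where ``genome`` maps chromosome name to
    sequence and ``truth`` is a table with one row per planted copy
    (copy_id, chrom, start, end, strand, subs, indels, orf_intact, identity).
    Copies are placed at uniformly drawn non-overlapping loci, fully contained
    in one chromosome, each on a uniformly random strand. Exactly ``n_intact``
    copies keep an intact ORF; the rest receive a frameshift or premature stop.
    """
    if n_intact is None:
        n_intact = n_copies
    if n_intact > n_copies:
        raise ParameterError(f"n_intact ({n_intact}) must be <= n_copies ({n_copies})")
    if n_chrom < 1:
        raise ParameterError("n_chrom must be >= 1")
    elen = len(consensus)
    if n_copies * elen > genome_len:
        raise CapacityError(
            f"genome of {genome_len} bp cannot host {n_copies} non-overlapping copies of {elen} bp"
        )
    rng = substream(seed, 1)

    chrom_lens = [genome_len // n_chrom] * n_chrom
    chrom_lens[0] += genome_len - sum(chrom_lens)
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    arrays = {nm: np.frombuffer(random_dna(rng, ln).encode(), dtype=np.uint8).copy() for nm, ln in zip(names, chrom_lens)}

    # uniform non-overlapping placement by rejection
    placed: dict[str, list[tuple[int, int]]] = {nm: [] for nm in names}
    loci: list[tuple[str, int]] = []
    total = sum(chrom_lens)
    attempts = 0
    while len(loci) < n_copies:
        attempts += 1
        if attempts > 1000 * max(n_copies, 1):
            raise CapacityError("could not place copies without overlap (genome too crowded)")
        u = int(rng.integers(0, total))
        ci = 0
        while u >= chrom_lens[ci]:
            u -= chrom_lens[ci]
            ci += 1
        nm = names[ci]
        if u + elen > chrom_lens[ci]:
            continue
        if any(not (u + elen <= s or u >= e) for s, e in placed[nm]):
            continue
        placed[nm].append((u, u + elen))
        loci.append((nm, u))

    intact_flags = np.array([True] * n_intact + [False] * (n_copies - n_intact))
    rows = []
    for i, (nm, start) in enumerate(loci):
        keep = bool(intact_flags[i])
        copy_seq, n_subs, n_indels = _mutate_copy(rng, consensus, sub_rate, keep_orf=keep)
        strand = "+" if rng.random() < 0.5 else "-"
        insert = copy_seq if strand == "+" else revcomp(copy_seq)
        end = start + len(insert)
        arrays[nm][start:end] = np.frombuffer(insert.encode(), dtype=np.uint8)
        # a 1-nt deletion shortens the copy; shift the remainder is avoided by
        # leaving the freed genome base as background (copy interval shrinks)
        identity = 100.0 * (elen - n_subs - n_indels) / elen
        rows.append(
            dict(
                copy_id=f"copy{i + 1:03d}",
                chrom=nm,
                start=int(start),
                end=int(end),
                strand=strand,
                subs=int(n_subs),
                indels=int(n_indels),
                orf_intact=keep,
                identity=identity,
            )
        )

    genome = {nm: arrays[nm].tobytes().decode("ascii") for nm in names}
    truth = pd.DataFrame(
        rows, columns=["copy_id", "chrom", "start", "end", "strand", "subs", "indels", "orf_intact", "identity"]
    )
    return genome, truth


_NON = {"T": "ACG", "A": "CGT"}


def _biased_base(rng: np.random.Generator, favoured: str, prob: float | None, current: str) -> str:
    if prob is None:
        return current
    if rng.random() < prob:
        return favoured
    others = _NON[favoured]
    return others[rng.integers(0, 3)]


def simulate_pirna_reads(
    consensus: ElementConsensus,
    params: SignatureParams,
) -> tuple[list[SmallRead], pd.DataFrame]:
    """Simulate transposon-derived small-RNA reads from the consensus.

    Reads are DNA (T, not U). Strands are drawn Bernoulli(antisense_fraction);
    a ``pingpong_fraction`` of reads is emitted as sense/antisense couples whose
    5' ends overlap by exactly 10 nt on the element; position-1 U bias applies
    to antisense reads and position-10 A bias to sense reads. Truth columns:
    read_id, source, strand (+/- relative to the element), pos5 (element
    coordinate of the 5' end), length, pingpong, partner.
    """
    params.validate()
    L = len(consensus)
    if L <= 32 + 10:
        raise ParameterError("consensus must be longer than 42 nt")
    rng = substream(params.seed, 2)
    n = params.n_reads
    seq = consensus.sequence

    antisense = rng.random(n) < params.antisense_fraction
    lengths = rng.choice(READ_LENGTHS, size=n, p=np.asarray(params.length_weights, dtype=float))

    sense_idx = np.nonzero(~antisense)[0]
    anti_idx = np.nonzero(antisense)[0]
    k_pairs = min(int(round(params.pingpong_fraction * n / 2)), len(sense_idx), len(anti_idx))
    paired_sense = rng.permutation(sense_idx)[:k_pairs]
    paired_anti = rng.permutation(anti_idx)[:k_pairs]
    partner = {}
    pos5 = np.empty(n, dtype=int)

    for s_i, a_i in zip(paired_sense, paired_anti):
        ls, la = int(lengths[s_i]), int(lengths[a_i])
        s_min = max(0, la - 10)
        s_max = min(L - ls, L - 10)
        s = int(rng.integers(s_min, s_max + 1))
        pos5[s_i] = s
        pos5[a_i] = s + 9  # antisense 5' end; overlap = (s+9) - s + 1 = 10
        partner[s_i] = a_i
        partner[a_i] = s_i

    unpaired = np.setdiff1d(np.arange(n), np.array(list(partner), dtype=int), assume_unique=False)
    for i in unpaired:
        l = int(lengths[i])
        if antisense[i]:
            pos5[i] = int(rng.integers(l - 1, L))
        else:
            pos5[i] = int(rng.integers(0, L - l + 1))

    reads: list[SmallRead] = []
    rows = []
    for i in range(n):
        l = int(lengths[i])
        p = int(pos5[i])
        if antisense[i]:
            sub = revcomp(seq[p - l + 1 : p + 1])
            sub = _biased_base(rng, "T", params.u1_prob, sub[0]) + sub[1:]
            strand = "-"
        else:
            sub = seq[p : p + l]
            if l >= 10:
                sub = sub[:9] + _biased_base(rng, "A", params.a10_prob, sub[9]) + sub[10:]
            strand = "+"
        rid = f"sim{i:06d}"
        reads.append(SmallRead(rid, sub))
        rows.append(
            dict(
                read_id=rid,
                source=consensus.id,
                strand=strand,
                pos5=p,
                length=l,
                pingpong=i in partner,
                partner=f"sim{partner[i]:06d}" if i in partner else "",
            )
        )
    truth = pd.DataFrame(rows, columns=["read_id", "source", "strand", "pos5", "length", "pingpong", "partner"])
    return reads, truth


def simulate_background_reads(
    transcripts: dict[str, str],
    n: int,
    length_range: tuple[int, int] = (20, 32),
    seed: int = 0,
) -> tuple[list[SmallRead], pd.DataFrame]:
    """Uniform degradation-like fragments from non-TE transcripts.

    Position, strand and length are uniform; truth ``source`` is "background".
    """
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise ParameterError(f"invalid length_range {length_range}")
    if n > 0 and not transcripts:
        raise ParameterError("transcript set is empty but n > 0")
    for tid, tseq in transcripts.items():
        if len(tseq) <= hi:
            raise ParameterError(f"transcript {tid} shorter than length_range upper bound")
    rng = substream(seed, 3)
    names = sorted(transcripts)
    reads: list[SmallRead] = []
    rows = []
    for i in range(n):
        tid = names[rng.integers(0, len(names))]
        tseq = transcripts[tid]
        l = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(tseq) - l + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        sub = tseq[start : start + l]
        if strand == "-":
            sub = revcomp(sub)
        rid = f"bg{i:06d}"
        reads.append(SmallRead(rid, sub))
        rows.append(
            dict(
                read_id=rid,
                source="background",
                strand=strand,
                pos5=start if strand == "+" else start + l - 1,
                length=l,
                pingpong=False,
                partner="",
            )
        )
    truth = pd.DataFrame(rows, columns=["read_id", "source", "strand", "pos5", "length", "pingpong", "partner"])
    return reads, truth
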