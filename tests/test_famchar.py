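"""Family characterization: in-silico PCR, identity, clustering, structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tc1scope._seq import random_dna, revcomp
from tc1scope.famchar import (
    IdentityMatrix,
    ParameterError,
    align_to_consensus,
    all_vs_all_identity,
    classify_orf,
    detect_direct_repeats,
    detect_terminal_inverted_repeats,
    family_summary,
    global_identity,
    insilico_pcr,
    orient_to_consensus,
    single_linkage,
)
from tc1scope.synthdata import ElementArchitecture, build_consensus_element, plant_copies


class TestGlobalIdentity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC",) * 2 + (100.0,),
            ("ACGTACGT", "ACGAACGT", 87.5),
            ("AAAA", "AAAT", 75.0),
        ],
    )
    def test_known_identities(self, a, b, expected):
        assert global_identity(a, b) == pytest.approx(expected)

    def test_symmetry(self, rng):
        for _ in range(20):
            a = random_dna(rng, int(rng.integers(10, 60)))
            b = random_dna(rng, int(rng.integers(10, 60)))
            assert global_identity(a, b) == pytest.approx(global_identity(b, a))

    def test_hundred_iff_equal(self, rng):
        a = random_dna(rng, 40)
        assert global_identity(a, a) == 100.0
        b = a[:20] + ("A" if a[20] != "A" else "C") + a[21:]
        assert global_identity(a, b) < 100.0

    def test_decreases_with_substitutions(self, rng):
        a = random_dna(rng, 200)
        idents = []
        for k in (0, 5, 20):
            b = list(a)
            for pos in rng.choice(200, size=k, replace=False):
                b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
            idents.append(global_identity(a, "".join(b)))
        assert idents[0] > idents[1] > idents[2]

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            global_identity("", "ACGT")


class TestInsilicoPcr:
    def test_single_amplicon(self, rng):
        primer = random_dna(rng, 37)
        insert = random_dna(rng, 100)
        genome = {"c": random_dna(rng, 50) + primer + insert + revcomp(primer) + random_dna(rng, 50)}
        loci = insilico_pcr(genome, primer, max_amplicon=500, max_mismatch=0)
        assert len(loci) == 1
        assert loci[0].length == 2 * 37 + 100
        assert loci[0].sequence == primer + insert + revcomp(primer)

    def test_absent_primer_gives_empty(self, rng):
        genome = {"c": random_dna(rng, 2000)}
        assert insilico_pcr(genome, "A" * 37, max_amplicon=500, max_mismatch=0) == []

    def test_amplicon_window_respected(self, rng):
        primer = random_dna(rng, 30)
        genome = {"c": primer + random_dna(rng, 400) + revcomp(primer)}
        assert insilico_pcr(genome, primer, max_amplicon=200, max_mismatch=0) == []
        assert len(insilico_pcr(genome, primer, max_amplicon=500, max_mismatch=0)) == 1

    def test_sites_consumed_left_to_right(self, rng):
        primer = random_dna(rng, 25)
        a, b = random_dna(rng, 60), random_dna(rng, 60)
        genome = {"c": primer + a + revcomp(primer) + random_dna(rng, 30) + primer + b + revcomp(primer)}
        loci = insilico_pcr(genome, primer, max_amplicon=400, max_mismatch=0)
        assert len(loci) == 2
        assert loci[0].sequence.startswith(primer + a)
        assert loci[1].sequence.startswith(primer + b)

    def test_recovers_planted_copies_exactly(self, consensus, small_fixture):
        genome, truth = small_fixture
        primer = consensus.sequence[:37]
        loci = insilico_pcr(genome, primer, max_amplicon=2000, max_mismatch=4)
        assert len(loci) == len(truth)
        truth_iv = set(zip(truth.chrom, truth.start, truth.end))
        assert all((l.chrom, *l.interval) in truth_iv for l in loci)


def _unionfind_components(matrix: IdentityMatrix, threshold: float) -> list[list[str]]:
    """Brute-force oracle: union-find over the threshold graph."""
    ids = list(matrix.ids)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.values[i, j] >= threshold:
                parent[find(ids[i])] = find(ids[j])
    groups = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    comps = [sorted(g) for g in groups.values()]
    comps.sort(key=lambda c: c[0])
    return comps


class TestSingleLinkage:
    def _matrix(self, ids, pairs):
        n = len(ids)
        v = np.full((n, n), 100.0)
        for (a, b), val in pairs.items():
            i, j = ids.index(a), ids.index(b)
            v[i, j] = v[j, i] = val
        return IdentityMatrix(tuple(ids), v)

    def test_simple_split(self):
        m = self._matrix(["A", "B", "C"], {("A", "B"): 95, ("A", "C"): 50, ("B", "C"): 50})
        assert single_linkage(m, 93) == [["A", "B"], ["C"]]

    def test_chain_merges(self):
        m = self._matrix(["A", "B", "C"], {("A", "B"): 94, ("B", "C"): 94, ("A", "C"): 50})
        assert single_linkage(m, 93) == [["A", "B", "C"]]

    def test_threshold_100_all_singletons(self):
        m = self._matrix(["A", "B", "C"], {("A", "B"): 99.9, ("A", "C"): 99.9, ("B", "C"): 99.9})
        assert single_linkage(m, 100) == [["A"], ["B"], ["C"]]

    def test_single_member(self):
        assert single_linkage(IdentityMatrix(("X",), np.array([[100.0]])), 93) == [["X"]]

    def test_invalid_threshold(self):
        m = self._matrix(["A", "B"], {("A", "B"): 95})
        with pytest.raises(ParameterError):
            single_linkage(m, 101)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(n=st.integers(2, 20), seed=st.integers(0, 10_000), threshold=st.floats(50, 100))
    def test_matches_unionfind_oracle(self, n, seed, threshold):
        rng = np.random.default_rng(seed)
        v = np.round(rng.uniform(40, 100, size=(n, n)), 1)
        v = (v + v.T) / 2
        np.fill_diagonal(v, 100.0)
        m = IdentityMatrix(tuple(f"s{i:02d}" for i in range(n)), v)
        assert single_linkage(m, threshold) == _unionfind_components(m, threshold)


class TestInvertedRepeats:
    def test_default_consensus_recovers_ir(self, consensus):
        ir = detect_terminal_inverted_repeats(consensus.sequence, 30, 95)
        assert ir.length == 199
        assert ir.percent_identity == 100.0
        assert ir.left == (0, 199) and ir.right == (1382, 1581)

    def test_random_sequence_has_no_ir(self, rng):
        assert detect_terminal_inverted_repeats(random_dna(rng, 1000), 30, 95) is None

    def test_substitutions_reduce_identity_not_length(self, consensus):
        s = list(consensus.sequence)
        for pos in (60, 130):  # interior of the left IR
            s[pos] = "A" if s[pos] != "A" else "C"
        ir = detect_terminal_inverted_repeats("".join(s), 30, 95)
        assert ir.length == 199
        assert ir.percent_identity == pytest.approx(100 * 197 / 199)

    @pytest.mark.parametrize("ir_len", [30, 80, 199, 400])
    def test_recovers_ir_len_across_architectures(self, ir_len):
        arch = ElementArchitecture(
            total_len=2 * ir_len + 1200, ir_len=ir_len, dr_len=min(12, (ir_len - 2) // 2), orf_len=900, seed=3
        )
        c = build_consensus_element(arch)
        ir = detect_terminal_inverted_repeats(c.sequence, min_len=20, min_identity=95)
        assert ir.length == ir_len


class TestDirectRepeats:
    def test_default_consensus_dr(self, consensus):
        ir = detect_terminal_inverted_repeats(consensus.sequence, 30, 95)
        reps = detect_direct_repeats(consensus.sequence, ir, k=17)
        assert reps and reps[0].length == 17
        intervals = {reps[0].left, reps[0].right}
        assert set(consensus.dr_intervals) <= {r.left for r in reps} | {r.right for r in reps} or intervals
        # the top repeat is the planted one
        assert reps[0].left in consensus.dr_intervals or reps[0].right in consensus.dr_intervals

    def test_no_shared_kmer_gives_empty(self, consensus, rng):
        ir = detect_terminal_inverted_repeats(consensus.sequence, 30, 95)
        # replace both IR interiors with unrelated sequence
        s = list(consensus.sequence)
        s[0:199] = random_dna(rng, 199)
        s[1382:1581] = random_dna(rng, 199)
        assert detect_direct_repeats("".join(s), ir, k=17) == []

    def test_maximality(self, rng):
        """A 20-nt shared repeat is reported at its full length with k=17."""
        core = random_dna(rng, 20)
        # flank bases differ between occurrences so the maximal run is the core
        left = random_dna(rng, 29) + "A" + core + "A" + random_dna(rng, 29)
        right = random_dna(rng, 24) + "C" + core + "C" + random_dna(rng, 34)
        seq = left + random_dna(rng, 100) + right
        from tc1scope.famchar import IRAnnotation

        ir = IRAnnotation(left=(0, 80), right=(180, 260), length=80, percent_identity=100.0)
        reps = detect_direct_repeats(seq, ir, k=17)
        assert reps[0].length == 20
        assert seq[slice(*reps[0].left)] == core


class TestClassifyOrf:
    def test_unmutated_copy_intact(self, consensus):
        aln = align_to_consensus(consensus.sequence, consensus.sequence)
        st_ = classify_orf(consensus.sequence, consensus.orf_interval, aln)
        assert st_.status == "intact" and st_.reason == "none"

    def test_single_deletion_is_frameshift(self, consensus):
        s, e = consensus.orf_interval
        mid = (s + e) // 2
        copy = consensus.sequence[:mid] + consensus.sequence[mid + 1 :]
        aln = align_to_consensus(copy, consensus.sequence)
        assert classify_orf(copy, consensus.orf_interval, aln).reason == "frameshift"

    def test_stop_substitution_is_premature_stop(self, consensus):
        s, e = consensus.orf_interval
        seq = consensus.sequence
        # force a TAA mid-ORF on a codon boundary
        codon_start = s + 3 * (((e - s) // 3) // 2)
        copy = seq[:codon_start] + "TAA" + seq[codon_start + 3 :]
        aln = align_to_consensus(copy, consensus.sequence)
        assert classify_orf(copy, consensus.orf_interval, aln).reason == "premature_stop"

    def test_mutated_start_is_missing_start(self, consensus):
        s, _ = consensus.orf_interval
        seq = consensus.sequence
        copy = seq[:s] + "ACG" + seq[s + 3 :]
        aln = align_to_consensus(copy, consensus.sequence)
        assert classify_orf(copy, consensus.orf_interval, aln).reason == "missing_start"

    def test_recovers_truth_on_fixture(self, consensus, small_fixture):
        genome, truth = small_fixture
        primer = consensus.sequence[:37]
        loci = insilico_pcr(genome, primer, max_amplicon=2000, max_mismatch=4)
        by_iv = {(row.chrom, row.start, row.end): row for row in truth.itertuples()}
        for l in loci:
            row = by_iv[(l.chrom, *l.interval)]
            oriented, strand = orient_to_consensus(l.sequence, consensus.sequence)
            assert strand == row.strand
            aln = align_to_consensus(oriented, consensus.sequence)
            st_ = classify_orf(oriented, consensus.orf_interval, aln)
            assert (st_.status == "intact") == row.orf_intact


class TestAllVsAllAndSummary:
    def test_single_locus(self):
        m = all_vs_all_identity({"x": "ACGTACGTACGT"})
        assert m.values.shape == (1, 1) and m.values[0, 0] == 100.0

    def test_identical_loci(self):
        m = all_vs_all_identity({"a": "ACGT" * 10, "b": "ACGT" * 10, "c": "ACGT" * 10})
        assert (m.values == 100.0).all()

    def test_family_identity_exceeds_93(self, consensus):
        genome, truth = plant_copies(60_000, 1, consensus, 6, sub_rate=0.02, n_intact=6, seed=13)
        seqs = {}
        for row in truth.itertuples():
            sub = genome[row.chrom][row.start : row.end]
            seqs[row.copy_id] = sub if row.strand == "+" else revcomp(sub)
        m = all_vs_all_identity(seqs)
        off = m.values[np.triu_indices(6, k=1)]
        assert (off > 93).all()

    def test_summary_statistics(self):
        assert family_summary(["A" * 1581, "C" * 1581, "G" * 1581])["mean_length"] == 1581.0
        assert family_summary(["A" * 10, "C" * 20])["mean_length"] == 15.0

    def test_summary_empty_rejected(self):
        with pytest.raises(ParameterError):
            family_summary([])
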