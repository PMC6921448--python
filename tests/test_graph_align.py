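import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svgraph.errors import AlignmentInputError
from svgraph.graph_align import (
    AlignmentParams,
    GraphAlignment,
    align_read_to_graph,
    count_breakpoint_support,
    has_unique_kmer,
    is_uniquely_mapped,
    reverse_complement,
    supports_edge,
    supports_node,
)
from svgraph.graph_model import (
    AlleleGraph,
    DELETION,
    GraphParams,
    SequenceNode,
    SVRecord,
    build_graph,
    enumerate_breakpoints,
)

from conftest import random_sequence
from oracles import linear_smith_waterman

PARAMS = AlignmentParams()


def graph_oracle_score(read, graph, params=PARAMS):
    """Max linear SW score over enumerated allele-path sequences, both strands."""
    best = 0
    for allele in graph.allele_paths:
        seq = graph.allele_sequence(allele)
        for r in (read, reverse_complement(read)):
            best = max(
                best,
                linear_smith_waterman(
                    r, seq, params.match, params.mismatch, params.gap_open, params.gap_extend
                ),
            )
    return best


def single_node_graph(seq):
    n1 = SequenceNode("a", seq[: len(seq) // 2])
    n2 = SequenceNode("b", seq[len(seq) // 2 :])
    return AlleleGraph(
        [n1, n2], {("a", "b"): frozenset({"REF"})}, {"REF": ["a", "b"]}, DELETION, "a", "b"
    )


class TestAlignReadToGraph:
    def test_exact_substring_scores_full_match(self, deletion_graph, reference_seq):
        read = reference_seq[4900:4980]
        alns = align_read_to_graph(read, deletion_graph)
        assert alns[0].score == 80 * PARAMS.match
        assert alns[0].path == ("LF",)
        assert alns[0].mismatches == 0

    def test_alt_junction_read_uses_alt_edge(self, deletion_graph, reference_seq):
        read = reference_seq[4925:5000] + reference_seq[5300:5375]
        alns = align_read_to_graph(read, deletion_graph)
        assert len(alns) == 1
        assert alns[0].path == ("LF", "RF")
        assert alns[0].score == graph_oracle_score(read, deletion_graph)

    def test_ref_junction_read_uses_ref_path(self, deletion_graph, reference_seq):
        read = reference_seq[4950:5000] + reference_seq[5000:5100]
        alns = align_read_to_graph(read, deletion_graph)
        assert alns[0].path == ("LF", "DEL")

    def test_mismatched_read_score_matches_oracle(self, deletion_graph, reference_seq):
        read = list(reference_seq[4925:5000] + reference_seq[5300:5375])
        read[5] = "A" if read[5] != "A" else "C"
        read[80] = "A" if read[80] != "A" else "C"
        read = "".join(read)
        alns = align_read_to_graph(read, deletion_graph)
        assert alns[0].score == graph_oracle_score(read, deletion_graph)
        assert alns[0].mismatches == 2

    def test_gapped_read_score_matches_oracle(self, deletion_graph, reference_seq):
        read = reference_seq[4900:4960] + reference_seq[4965:5000]  # 5 bp deletion in read
        alns = align_read_to_graph(read, deletion_graph)
        assert alns[0].score == graph_oracle_score(read, deletion_graph)

    def test_reverse_strand_read(self, deletion_graph, reference_seq):
        read = reverse_complement(reference_seq[4925:5000] + reference_seq[5300:5375])
        alns = align_read_to_graph(read, deletion_graph)
        assert alns[0].strand == "-"
        assert alns[0].score == 150

    def test_strand_symmetry(self, deletion_graph, reference_seq):
        read = list(reference_seq[4930:5000] + reference_seq[5300:5380])
        read[7] = "A" if read[7] != "A" else "C"
        read = "".join(read)
        fwd = align_read_to_graph(read, deletion_graph)
        rev = align_read_to_graph(reverse_complement(read), deletion_graph)
        assert fwd[0].score == rev[0].score

    def test_homopolymer_read_has_cooptimal_alignments(self):
        graph = single_node_graph("A" * 40)
        alns = align_read_to_graph("A" * 10, graph, PARAMS)
        assert len(alns) >= 2
        assert not is_uniquely_mapped(alns)

    def test_empty_read_raises(self, deletion_graph):
        with pytest.raises(AlignmentInputError):
            align_read_to_graph("", deletion_graph)

    def test_read_overhanging_flank_is_clipped(self, deletion_graph, reference_seq):
        # 40 bases precede the left flank: local alignment clips them
        read = reference_seq[4810:4900]
        alns = align_read_to_graph(read, deletion_graph)
        assert alns[0].score == 50 * PARAMS.match
        assert alns[0].score == graph_oracle_score(read, deletion_graph)

    @given(
        seed=st.integers(min_value=0, max_value=10_000),
        read_len=st.integers(min_value=12, max_value=40),
        n_mut=st.integers(min_value=0, max_value=3),
    )
    @settings(max_examples=40, deadline=None)
    def test_score_equals_path_oracle_random_graphs(self, seed, read_len, n_mut):
        r = np.random.default_rng(seed)
        ref = {"c": "".join(r.choice(list("ACGT"), 400))}
        start = int(r.integers(60, 200))
        length = int(r.integers(10, 60))
        rec = SVRecord("c", start, start + length, DELETION)
        g = build_graph(rec, ref, GraphParams(read_length=int(r.integers(20, 60))))
        hap = g.allele_sequence("ALT") if r.random() < 0.5 else g.allele_sequence("REF")
        off = int(r.integers(0, max(1, len(hap) - read_len)))
        read = list(hap[off : off + read_len])
        for _ in range(n_mut):
            p = int(r.integers(0, len(read)))
            read[p] = "ACGT"[int(r.integers(0, 4))]
        read = "".join(read)
        alns = align_read_to_graph(read, g)
        expected = graph_oracle_score(read, g)
        got = alns[0].score if alns else 0
        assert got == expected


class TestUniqueness:
    def test_single_best_is_unique(self):
        mk = lambda s: GraphAlignment("r", "+", ("a",), {"a": 10}, s, 0, 10, "a", 0, "a", 10)
        assert is_uniquely_mapped([mk(42), mk(40), mk(17)])

    def test_tie_not_unique(self):
        mk = lambda s: GraphAlignment("r", "+", ("a",), {"a": 10}, s, 0, 10, "a", 0, "a", 10)
        assert not is_uniquely_mapped([mk(42), mk(42)])

    def test_empty_not_unique(self):
        assert not is_uniquely_mapped([])


class TestUniqueKmer:
    def test_insertion_read_has_unique_kmer(self, insertion_graph, insertion_record):
        read = insertion_record.alt_seq[:40]
        assert has_unique_kmer(read, insertion_graph, 16)

    def test_repeat_read_has_no_unique_kmer(self):
        repeat = "ACGTAC" * 30
        g = single_node_graph(repeat)
        read = repeat[10:40]  # every k-mer tiles the repeat many times
        assert not has_unique_kmer(read, g, 6)
        # brute-force check: every 6-mer of the read occurs > once in the graph
        allk = {}
        for node in g.nodes.values():
            s = node.sequence
            for i in range(len(s) - 5):
                allk[s[i : i + 6]] = allk.get(s[i : i + 6], 0) + 1
        for i in range(len(read) - 5):
            assert allk.get(read[i : i + 6], 0) != 1

    def test_k_longer_than_read(self, deletion_graph):
        assert not has_unique_kmer("ACGT", deletion_graph, 16)

    def test_reverse_strand_kmers_count(self, insertion_graph, insertion_record):
        read = reverse_complement(insertion_record.alt_seq[:40])
        assert has_unique_kmer(read, insertion_graph, 16)

    def test_edge_spanning_kmers_included(self, deletion_graph, reference_seq):
        # a k-mer straddling the ALT junction occurs once, on the junction only
        junction = reference_seq[4992:5000] + reference_seq[5300:5308]
        assert len(junction) == 16
        assert has_unique_kmer(junction, deletion_graph, 16)


class TestSupport:
    def _aln(self, path, overlaps, read_length=150):
        return GraphAlignment(
            "r", "+", tuple(path), dict(overlaps), 100, 0, read_length, path[0], 0, path[-1], 1
        )

    def test_supports_node_threshold(self, deletion_graph):
        aln = self._aln(("LF", "DEL"), {"LF": 15, "DEL": 135})
        assert supports_node(aln, "LF", deletion_graph, PARAMS)
        aln2 = self._aln(("LF", "DEL"), {"LF": 14, "DEL": 136})
        assert not supports_node(aln2, "LF", deletion_graph, PARAMS)

    def test_short_node_threshold_is_node_length(self, reference):
        rec = SVRecord("chr1", 8000, 8000, "insertion", alt_seq="ACGTACGT")  # 8 bp node
        g = build_graph(rec, reference, GraphParams(read_length=150))
        aln = self._aln(("LF", "INS", "RF"), {"LF": 80, "INS": 8, "RF": 62})
        assert supports_node(aln, "INS", g, PARAMS)
        aln2 = self._aln(("LF", "INS", "RF"), {"LF": 80, "INS": 7, "RF": 63})
        assert not supports_node(aln2, "INS", g, PARAMS)

    def test_supports_edge_requires_both_nodes(self, deletion_graph):
        good = self._aln(("LF", "RF"), {"LF": 75, "RF": 75})
        assert supports_edge(good, ("LF", "RF"), deletion_graph, PARAMS)
        thin = self._aln(("LF", "RF"), {"LF": 5, "RF": 145})
        assert not supports_edge(thin, ("LF", "RF"), deletion_graph, PARAMS)

    def test_edge_not_on_path(self, deletion_graph):
        aln = self._aln(("LF", "DEL"), {"LF": 75, "DEL": 75})
        assert not supports_edge(aln, ("LF", "RF"), deletion_graph, PARAMS)


class TestBreakpointCounts:
    def _junction_read(self, reference_seq, alt, offset=25):
        if alt:
            return reference_seq[4925 + offset : 5000] + reference_seq[5300 : 5375 + offset]
        return reference_seq[4925 + offset : 5000] + reference_seq[5000 : 5075 + offset]

    def test_bookkeeping(self, deletion_graph, reference_seq):
        bps = enumerate_breakpoints(deletion_graph)
        alns = []
        for i in range(10):
            alns += align_read_to_graph(self._junction_read(reference_seq, True, i), deletion_graph)
        for i in range(10):
            alns += align_read_to_graph(self._junction_read(reference_seq, False, i), deletion_graph)
        counts = count_breakpoint_support(bps[0], alns, deletion_graph)
        assert counts.count("ALT") == 10
        assert counts.count("REF") == 10
        assert counts.neither == 0
        assert counts.total == 20

    def test_no_reads_all_zero(self, deletion_graph):
        bps = enumerate_breakpoints(deletion_graph)
        counts = count_breakpoint_support(bps[0], [], deletion_graph)
        assert counts.total == 0 and counts.neither == 0

    def test_thin_crossing_read_counts_as_neither(self, deletion_graph, reference_seq):
        read = reference_seq[4995:5000] + reference_seq[5300:5445]  # 5 bp on LF side
        alns = align_read_to_graph(read, deletion_graph)
        bps = enumerate_breakpoints(deletion_graph)
        counts = count_breakpoint_support(bps[0], alns, deletion_graph)
        assert counts.total == 1
        assert counts.neither == 1

    def test_short_event_read_counts_at_both_breakpoints(self, reference, reference_seq):
        rec = SVRecord("chr1", 5000, 5060, DELETION, id="small")
        g = build_graph(rec, reference, GraphParams(read_length=150))
        read = reference_seq[4930:5000] + reference_seq[5060:5140]  # spans both breakpoints
        alns = align_read_to_graph(read, g)
        bp1, bp2 = enumerate_breakpoints(g)
        c1 = count_breakpoint_support(bp1, alns, g)
        c2 = count_breakpoint_support(bp2, alns, g)
        assert c1.count("ALT") == 1 and c2.count("ALT") == 1

    def test_removing_a_read_never_increases_counts(self, deletion_graph, reference_seq):
        reads = [self._junction_read(reference_seq, i % 2 == 0, i) for i in range(8)]
        alns = [align_read_to_graph(r, deletion_graph)[0] for r in reads]
        bp = enumerate_breakpoints(deletion_graph)[0]
        full = count_breakpoint_support(bp, alns, deletion_graph)
        reduced = count_breakpoint_support(bp, alns[1:], deletion_graph)
        for h in full.haplotypes:
            assert reduced.count(h) <= full.count(h)
        assert reduced.neither <= full.neither and reduced.total <= full.total
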