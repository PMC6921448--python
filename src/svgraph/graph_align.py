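"""Junction-aware local realignment of reads to an allele graph.

The dynamic program is a plain (non-striped) affine-gap Smith-Waterman
whose recurrence is extended across graph junctions: the first column of
every node is seeded with the element-wise maximum over the last columns
of all in-neighbor nodes.  Scores are exactly those of running linear
Smith-Waterman over every allele-path sequence and taking the maximum,
which is the contract the tests enforce.

Reads are aligned on both strands; all co-optimal alignments (distinct
graph locations attaining the best score) are returned so that the
unique-mapping filter can be applied downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import AlignmentInputError
from .graph_model import AlleleGraph, Breakpoint, Edge

__all__ = [
    "AlignmentParams",
    "GraphAlignment",
    "BreakpointCounts",
    "align_read_to_graph",
    "is_uniquely_mapped",
    "has_unique_kmer",
    "supports_node",
    "supports_edge",
    "count_breakpoint_support",
    "reverse_complement",
]

NEG = -(2**30)

_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and support parameters for graph realignment."""

    match: int = 1
    mismatch: int = -4
    gap_open: int = 6  # positive cost
    gap_extend: int = 1  # positive cost
    min_overlap_fraction: float = 0.10
    kmer_size: int = 16
    max_cooptimal: int = 64

    def __post_init__(self) -> None:
        if not (0 < self.min_overlap_fraction <= 1):
            raise ValueError("min_overlap_fraction must be in (0, 1]")
        if self.kmer_size < 1:
            raise ValueError("kmer_size must be >= 1")
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open cost must be >= gap_extend cost")

    def min_overlap_bases(self, read_length: int) -> int:
        return int(math.ceil(self.min_overlap_fraction * read_length))


@dataclass
class GraphAlignment:
    """One local alignment of a read through the graph."""

    read_id: str
    strand: str  # "+" | "-"
    path: Tuple[str, ...]
    node_overlaps: Dict[str, int]  # read bases aligned within each node
    score: int
    mismatches: int
    read_length: int
    start_node: str
    start_offset: int  # 0-based offset of first aligned node base
    end_node: str
    end_offset: int  # node bases consumed in the end node
    read_start: int = 0
    read_end: int = 0
    is_unique: bool = False

    @property
    def location(self) -> Tuple:
        return (self.strand, self.path, self.start_node, self.start_offset)


# ---------------------------------------------------------------------------
# DP kernels

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def encode(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE.get(c, 4) for c in seq.upper()], dtype=np.int8)


def _fill_python(read, node, H0, E0, match, mismatch, gapo, gape):
    m = read.shape[0]
    n = node.shape[0]
    H = np.empty((m + 1, n + 1), dtype=np.int64)
    E = np.empty((m + 1, n + 1), dtype=np.int64)
    F = np.empty((m + 1, n + 1), dtype=np.int64)
    H[:, 0] = H0
    E[:, 0] = E0
    F[:, 0] = NEG
    for j in range(1, n + 1):
        H[0, j] = 0
        E[0, j] = max(H[0, j - 1] - gapo, E[0, j - 1] - gape)
        F[0, j] = NEG
        c = node[j - 1]
        for i in range(1, m + 1):
            e = max(H[i, j - 1] - gapo, E[i, j - 1] - gape)
            f = max(H[i - 1, j] - gapo, F[i - 1, j] - gape)
            s = match if (read[i - 1] == c and c < 4 and read[i - 1] < 4) else mismatch
            d = H[i - 1, j - 1] + s
            h = d
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
    return H, E, F


try:  # optional acceleration; semantics identical to _fill_python
    from numba import njit

    _fill_fast = njit(cache=False)(_fill_python)
except Exception:  # pragma: no cover - numba always present in target env
    _fill_fast = None


def _fill_numpy(read, node, H0, E0, match, mismatch, gapo, gape):
    """Column-vectorized fill; valid because gap_open >= gap_extend makes
    opening a vertical gap from an open gap always dominated."""
    m = read.shape[0]
    n = node.shape[0]
    H = np.empty((m + 1, n + 1), dtype=np.int64)
    E = np.empty((m + 1, n + 1), dtype=np.int64)
    F = np.empty((m + 1, n + 1), dtype=np.int64)
    H[:, 0] = H0
    E[:, 0] = E0
    F[:, 0] = NEG
    idx = np.arange(m + 1, dtype=np.int64)
    read64 = read.astype(np.int64)
    for j in range(1, n + 1):
        c = node[j - 1]
        sub = np.where((read64 == c) & (c < 4) & (read64 < 4), match, mismatch)
        diag = np.empty(m + 1, dtype=np.int64)
        diag[0] = NEG
        diag[1:] = H[:-1, j - 1] + sub
        Ej = np.maximum(H[:, j - 1] - gapo, E[:, j - 1] - gape)
        G = np.maximum(np.maximum(diag, Ej), 0)
        acc = np.maximum.accumulate(G + idx * gape)
        Fj = np.empty(m + 1, dtype=np.int64)
        Fj[0] = NEG
        Fj[1:] = acc[:-1] - gapo - (idx[1:] - 1) * gape
        H[:, j] = np.maximum(G, Fj)
        H[0, j] = 0
        E[:, j] = Ej
        F[:, j] = Fj
    return H, E, F


def _fill(read, node, H0, E0, params: AlignmentParams):
    args = (read, node, H0, E0, params.match, params.mismatch, params.gap_open, params.gap_extend)
    if _fill_fast is not None:
        return _fill_fast(*args)
    return _fill_numpy(*args)


# ---------------------------------------------------------------------------
# Alignment driver


def _path_layout(graph: AlleleGraph):
    """Cache allele-path sequences with node boundary offsets."""
    layout = getattr(graph, "_path_layout", None)
    if layout is None:
        layout = []
        for allele in sorted(graph.allele_paths):
            path = graph.allele_paths[allele]
            seq = graph.allele_sequence(allele)
            bounds = []
            off = 0
            for nid in path:
                ln = len(graph.nodes[nid])
                bounds.append((off, off + ln, nid))
                off += ln
            layout.append((allele, seq, bounds))
        graph._path_layout = layout
    return layout


def _exact_match_alignments(
    seq: str,
    graph: AlleleGraph,
    params: AlignmentParams,
    strand: str,
    read_id: str,
) -> List[GraphAlignment]:
    """All full-length exact occurrences of the read on any allele path.

    When any exist, they are exactly the co-optimal alignments (score =
    match x read length cannot be exceeded), so the DP can be skipped.
    """
    L = len(seq)
    out: List[GraphAlignment] = []
    seen = set()
    for _, path_seq, bounds in _path_layout(graph):
        start = path_seq.find(seq)
        while start != -1:
            end = start + L
            covered = [b for b in bounds if b[0] < end and b[1] > start]
            path = tuple(nid for _, _, nid in covered)
            s0, _, start_nid = covered[0]
            e0, _, end_nid = covered[-1]
            key = (strand, path, start_nid, start - s0)
            if key not in seen:
                seen.add(key)
                overlaps = {
                    nid: min(e, end) - max(s, start) for s, e, nid in covered
                }
                out.append(
                    GraphAlignment(
                        read_id=read_id,
                        strand=strand,
                        path=path,
                        node_overlaps=overlaps,
                        score=L * params.match,
                        mismatches=0,
                        read_length=L,
                        start_node=start_nid,
                        start_offset=start - s0,
                        end_node=end_nid,
                        end_offset=end - e0,
                        read_start=0,
                        read_end=L,
                    )
                )
            start = path_seq.find(seq, start + 1)
    return out


def _node_codes(graph: AlleleGraph) -> Dict[str, np.ndarray]:
    codes = getattr(graph, "_node_codes", None)
    if codes is None:
        codes = {nid: encode(node.sequence) for nid, node in graph.nodes.items()}
        graph._node_codes = codes
    return codes


def _align_strand(
    read_codes: np.ndarray,
    read_seq: str,
    graph: AlleleGraph,
    params: AlignmentParams,
    strand: str,
    read_id: str,
) -> Tuple[int, List[GraphAlignment]]:
    m = read_codes.shape[0]
    topo = getattr(graph, "_topo_cache", None)
    if topo is None:
        topo = graph.topological_order()
        graph._topo_cache = topo
    mats: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    codes = _node_codes(graph)
    preds_of = getattr(graph, "_preds_cache", None)
    if preds_of is None:
        preds_of = {nid: graph.predecessors(nid) for nid in topo}
        graph._preds_cache = preds_of
    for nid in topo:
        node_codes = codes[nid]
        preds = preds_of[nid]
        if preds:
            H0 = np.full(m + 1, NEG, dtype=np.int64)
            E0 = np.full(m + 1, NEG, dtype=np.int64)
            for p in preds:
                Hp, Ep, _ = mats[p]
                np.maximum(H0, Hp[:, -1], out=H0)
                np.maximum(E0, Ep[:, -1], out=E0)
            np.maximum(H0, 0, out=H0)
        else:
            H0 = np.zeros(m + 1, dtype=np.int64)
            E0 = np.full(m + 1, NEG, dtype=np.int64)
        mats[nid] = _fill(read_codes, node_codes, H0, E0, params)

    best = 0
    for nid in topo:
        s = int(mats[nid][0][:, 1:].max(initial=0))
        if s > best:
            best = s
    if best <= 0:
        return 0, []

    alignments: List[GraphAlignment] = []
    seen = set()
    for nid in topo:
        H = mats[nid][0]
        ends = np.argwhere(H[:, 1:] == best)
        for i, j1 in ends:
            aln = _traceback(graph, mats, codes, read_codes, nid, int(i), int(j1) + 1, params, best)
            aln.read_id = read_id
            aln.strand = strand
            if aln.location not in seen:
                seen.add(aln.location)
                alignments.append(aln)
            if len(alignments) >= params.max_cooptimal:
                return best, alignments
    return best, alignments


def _traceback(
    graph: AlleleGraph,
    mats,
    codes,
    read_codes: np.ndarray,
    node_id: str,
    i: int,
    j: int,
    params: AlignmentParams,
    score: int,
) -> GraphAlignment:
    gapo, gape = params.gap_open, params.gap_extend
    end_node, end_offset, read_end = node_id, j, i
    per_node_reads: Dict[str, int] = {node_id: 0}
    path_rev: List[str] = [node_id]
    mismatches = 0
    state = "H"
    while True:
        H, E, F = mats[node_id]
        if j == 0:  # junction boundary
            preds = graph.predecessors(node_id)
            val = H[i, 0] if state == "H" else E[i, 0]
            if state == "H" and (not preds or val == 0):
                start_node, start_offset, read_start = node_id, 0, i
                break
            jumped = False
            for p in preds:
                Hp, Ep, _ = mats[p]
                ref = Hp[i, -1] if state == "H" else Ep[i, -1]
                if ref == val:
                    node_id = p
                    j = Hp.shape[1] - 1
                    path_rev.append(p)
                    per_node_reads.setdefault(p, 0)
                    jumped = True
                    break
            if not jumped:  # pragma: no cover - DP consistency guard
                raise RuntimeError("traceback failed at junction")
            continue
        if state == "H":
            val = H[i, j]
            if val == 0:
                start_node, start_offset, read_start = node_id, j, i
                break
            if i >= 1:
                ri, cj = read_codes[i - 1], codes[node_id][j - 1]
                s = params.match if (ri == cj and ri < 4 and cj < 4) else params.mismatch
                if val == H[i - 1, j - 1] + s:
                    if s == params.mismatch:
                        mismatches += 1
                    per_node_reads[node_id] += 1
                    i -= 1
                    j -= 1
                    continue
            if val == E[i, j]:
                state = "E"
                continue
            if i >= 1 and val == F[i, j]:
                state = "F"
                continue
            raise RuntimeError("traceback failed in H state")  # pragma: no cover
        if state == "E":  # consume node char j, move left
            val = E[i, j]
            if val == H[i, j - 1] - gapo:
                state = "H"
            elif val == E[i, j - 1] - gape:
                state = "E"
            else:  # pragma: no cover
                raise RuntimeError("traceback failed in E state")
            j -= 1
            continue
        # state == "F": consume read base, stay in column
        val = F[i, j]
        if val == H[i - 1, j] - gapo:
            state = "H"
        elif val == F[i - 1, j] - gape:
            state = "F"
        else:  # pragma: no cover
            raise RuntimeError("traceback failed in F state")
        per_node_reads[node_id] += 1
        i -= 1
        continue

    path = tuple(reversed(path_rev))
    return GraphAlignment(
        read_id="",
        strand="+",
        path=path,
        node_overlaps=dict(per_node_reads),
        score=score,
        mismatches=mismatches,
        read_length=read_codes.shape[0],
        start_node=start_node,
        start_offset=start_offset,
        end_node=end_node,
        end_offset=end_offset,
        read_start=read_start,
        read_end=read_end,
    )


def align_read_to_graph(
    read,
    graph: AlleleGraph,
    params: AlignmentParams = AlignmentParams(),
    both_strands: bool = True,
) -> List[GraphAlignment]:
    """Align one read (both strands) and return all co-optimal alignments."""
    if isinstance(read, str):
        seq, read_id = read, ""
    else:
        seq = getattr(read, "sequence", None) or getattr(read, "seq", None)
        read_id = getattr(read, "name", "") or ""
    if not seq:
        raise AlignmentInputError("empty read")
    seq = seq.upper()
    rc = reverse_complement(seq)
    if "N" not in seq and params.match > 0:
        exact = _exact_match_alignments(seq, graph, params, "+", read_id)
        if both_strands:
            exact += _exact_match_alignments(rc, graph, params, "-", read_id)
        if exact:
            return exact
    fwd = encode(seq)
    best_f, alns_f = _align_strand(fwd, seq, graph, params, "+", read_id)
    if not both_strands:
        return alns_f
    best_r, alns_r = _align_strand(encode(rc), rc, graph, params, "-", read_id)
    if best_f > best_r:
        return alns_f
    if best_r > best_f:
        return alns_r
    return alns_f + alns_r


def is_uniquely_mapped(alignments: Sequence[GraphAlignment]) -> bool:
    """True iff exactly one alignment attains the maximum score."""
    if not alignments:
        return False
    best = max(a.score for a in alignments)
    return sum(1 for a in alignments if a.score == best) == 1


def has_unique_kmer(read, graph: AlleleGraph, k: int) -> bool:
    """True iff the read (either strand) contains a k-mer occurring exactly
    once among the graph's node and edge-spanning k-mers."""
    seq = read if isinstance(read, str) else (getattr(read, "sequence", "") or "")
    seq = seq.upper()
    if k > len(seq):
        return False
    counts = graph.kmer_counts(k)
    for s in (seq, reverse_complement(seq)):
        for i in range(len(s) - k + 1):
            if counts.get(s[i : i + k], 0) == 1:
                return True
    return False


def supports_node(aln: GraphAlignment, node_id: str, graph: AlleleGraph, params: AlignmentParams) -> bool:
    """A read supports a node when its alignment overlaps it by at least
    min(ceil(fraction x read length), node length) bases."""
    node_len = len(graph.nodes[node_id])
    threshold = min(params.min_overlap_bases(aln.read_length), node_len)
    return aln.node_overlaps.get(node_id, 0) >= threshold


def supports_edge(aln: GraphAlignment, edge: Edge, graph: AlleleGraph, params: AlignmentParams) -> bool:
    """A read supports an edge when its path contains the edge and it
    supports both endpoint nodes."""
    if edge not in zip(aln.path, aln.path[1:]):
        return False
    return supports_node(aln, edge[0], graph, params) and supports_node(aln, edge[1], graph, params)


def edge_haplotype(graph: AlleleGraph, edge: Edge) -> str:
    """Haplotype key of a connecting edge: its allele label set."""
    return "/".join(sorted(graph.edges[edge]))


@dataclass
class BreakpointCounts:
    """Per-breakpoint read support, keyed by haplotype (allele label)."""

    breakpoint_name: str
    haplotypes: Tuple[str, ...]
    counts: Dict[str, int] = field(default_factory=dict)
    strands: Dict[str, List[int]] = field(default_factory=dict)  # hap -> [fwd, rev]
    neither: int = 0
    neither_strands: List[int] = field(default_factory=lambda: [0, 0])

    def __post_init__(self) -> None:
        for h in self.haplotypes:
            self.counts.setdefault(h, 0)
            self.strands.setdefault(h, [0, 0])

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.neither

    def count(self, hap: str) -> int:
        return self.counts.get(hap, 0)

    def pooled_with(self, other: "BreakpointCounts") -> "BreakpointCounts":
        if set(self.haplotypes) != set(other.haplotypes):
            raise ValueError("cannot pool counts over different haplotype sets")
        out = BreakpointCounts(
            breakpoint_name=f"{self.breakpoint_name}+{other.breakpoint_name}",
            haplotypes=self.haplotypes,
        )
        for h in self.haplotypes:
            out.counts[h] = self.counts[h] + other.counts[h]
            out.strands[h] = [
                self.strands[h][0] + other.strands[h][0],
                self.strands[h][1] + other.strands[h][1],
            ]
        out.neither = self.neither + other.neither
        out.neither_strands = [
            self.neither_strands[0] + other.neither_strands[0],
            self.neither_strands[1] + other.neither_strands[1],
        ]
        return out


def count_breakpoint_support(
    breakpoint: Breakpoint,
    alignments: Sequence[GraphAlignment],
    graph: AlleleGraph,
    params: AlignmentParams = AlignmentParams(),
) -> BreakpointCounts:
    """Tally breakpoint-crossing reads per haplotype.

    ``alignments`` must hold one accepted (unique, unique-kmer) alignment
    per read.  A read crosses the breakpoint when its path contains any
    of the connecting edges; it supports haplotype h when it supports
    that edge under the overlap criteria, and counts as "neither"
    otherwise.
    """
    haps = tuple(edge_haplotype(graph, e) for e in breakpoint.edges)
    counts = BreakpointCounts(breakpoint_name=breakpoint.name, haplotypes=haps)
    for aln in alignments:
        pairs = set(zip(aln.path, aln.path[1:]))
        crossing = [e for e in breakpoint.edges if e in pairs]
        if not crossing:
            continue
        strand_idx = 0 if aln.strand == "+" else 1
        supported = None
        for e in crossing:
            if supports_edge(aln, e, graph, params):
                supported = e
                break
        if supported is not None:
            h = edge_haplotype(graph, supported)
            counts.counts[h] += 1
            counts.strands[h][strand_idx] += 1
        else:
            counts.neither += 1
            counts.neither_strands[strand_idx] += 1
    return counts
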