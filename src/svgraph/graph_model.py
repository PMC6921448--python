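"""Local allele graphs for structural variants.

Each candidate SV is represented by a small directed acyclic sequence
graph: two flank nodes plus an allele-specific middle structure.  Paths
labeled by allele name (``REF``, ``ALT``) spell the reference and
alternative haplotype sequences across the locus.  A *breakpoint* is a
node side (outgoing or incoming) with two or more connected edges.

Coordinates are 0-based half-open throughout this module; conversion to
and from 1-based VCF coordinates happens in :mod:`svgraph.io_layer`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .errors import (
    MissingAltSequenceError,
    ReferenceFetchError,
    UnsupportedSVTypeError,
)

__all__ = [
    "SequenceNode",
    "AlleleGraph",
    "Breakpoint",
    "SVRecord",
    "GraphParams",
    "build_graph",
    "split_long_nodes",
    "enumerate_breakpoints",
]

IUPAC_CHARS = frozenset("ACGTUNRYSWKMBDHV")

DELETION = "deletion"
INSERTION = "insertion"
SWAP = "swap"
SV_TYPES = (DELETION, INSERTION, SWAP)

REF_LABEL = "REF"
ALT_LABEL = "ALT"

Edge = Tuple[str, str]


@dataclass(frozen=True)
class SequenceNode:
    """A graph node holding at least one nucleotide of sequence."""

    id: str
    sequence: str
    origin: str = "explicit"  # "reference-fetched" | "explicit"
    reference_span: Optional[Tuple[str, int, int]] = None  # (contig, start, end), 0-based half-open

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"node {self.id!r}: sequence must be at least one base")
        bad = set(self.sequence.upper()) - IUPAC_CHARS
        if bad:
            raise ValueError(f"node {self.id!r}: non-IUPAC characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Breakpoint:
    """A node side with >= 2 connected edges."""

    node_id: str
    side: str  # "outgoing" | "incoming"
    edges: Tuple[Edge, ...]
    edge_labels: Tuple[frozenset, ...]

    @property
    def name(self) -> str:
        return f"{self.node_id}:{self.side}"


@dataclass(frozen=True)
class SVRecord:
    """A normalized candidate SV.

    ``start``/``end`` delimit the replaced reference sequence, 0-based
    half-open.  For an insertion ``start == end`` (insertion point).
    ``alt_seq`` is the sequence replacing the span (empty for a pure
    deletion).
    """

    contig: str
    start: int
    end: int
    sv_type: str
    alt_seq: str = ""
    id: str = "."
    genotype: Optional[str] = None  # truth annotation used by the simulator

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"record {self.id}: end < start")
        if self.sv_type not in SV_TYPES:
            raise UnsupportedSVTypeError(f"record {self.id}: sv_type {self.sv_type!r}")

    @property
    def pos_1based(self) -> int:
        """1-based VCF POS of the anchor base preceding the event."""
        return self.start

    @property
    def ref_length(self) -> int:
        return self.end - self.start

    @property
    def sv_length(self) -> int:
        if self.sv_type == DELETION:
            return self.ref_length
        if self.sv_type == INSERTION:
            return len(self.alt_seq)
        return max(self.ref_length, len(self.alt_seq))


@dataclass(frozen=True)
class GraphParams:
    """Construction parameters; flank length defaults to one read length."""

    read_length: int = 150
    flank_length: Optional[int] = None

    @property
    def flank(self) -> int:
        return self.read_length if self.flank_length is None else self.flank_length


class AlleleGraph:
    """Directed acyclic sequence graph with labeled allele paths."""

    def __init__(
        self,
        nodes: Sequence[SequenceNode],
        edges: Mapping[Edge, frozenset],
        allele_paths: Mapping[str, Sequence[str]],
        sv_type: str,
        source: str,
        sink: str,
        record: Optional[SVRecord] = None,
    ) -> None:
        self.nodes: Dict[str, SequenceNode] = {n.id: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise ValueError("duplicate node ids")
        self.edges: Dict[Edge, frozenset] = {e: frozenset(l) for e, l in edges.items()}
        self.allele_paths: Dict[str, List[str]] = {a: list(p) for a, p in allele_paths.items()}
        self.sv_type = sv_type
        self.source = source
        self.sink = sink
        self.record = record
        self._kmer_counts: Optional[Dict[str, int]] = None
        self.validate()

    # -- structure ---------------------------------------------------------

    def out_edges(self, node_id: str) -> List[Edge]:
        return [e for e in self.edges if e[0] == node_id]

    def in_edges(self, node_id: str) -> List[Edge]:
        return [e for e in self.edges if e[1] == node_id]

    def predecessors(self, node_id: str) -> List[str]:
        return sorted(e[0] for e in self.in_edges(node_id))

    def successors(self, node_id: str) -> List[str]:
        return sorted(e[1] for e in self.out_edges(node_id))

    def topological_order(self) -> List[str]:
        indeg = {n: 0 for n in self.nodes}
        for _, v in self.edges:
            indeg[v] += 1
        ready = sorted(n for n, d in indeg.items() if d == 0)
        order: List[str] = []
        while ready:
            n = ready.pop(0)
            order.append(n)
            for m in self.successors(n):
                indeg[m] -= 1
                if indeg[m] == 0:
                    ready.append(m)
            ready.sort()
        if len(order) != len(self.nodes):
            raise ValueError("graph contains a cycle")
        return order

    def allele_sequence(self, allele: str) -> str:
        return "".join(self.nodes[n].sequence for n in self.allele_paths[allele])

    def validate(self) -> None:
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u},{v}) references unknown node")
        self.topological_order()  # raises on cycles
        covered: Dict[Edge, set] = {e: set() for e in self.edges}
        for allele, path in self.allele_paths.items():
            if not path or path[0] != self.source or path[-1] != self.sink:
                raise ValueError(f"allele {allele}: path must run source->sink")
            for u, v in zip(path, path[1:]):
                if (u, v) not in self.edges:
                    raise ValueError(f"allele {allele}: missing edge ({u},{v})")
                if allele not in self.edges[(u, v)]:
                    raise ValueError(f"allele {allele}: edge ({u},{v}) not labeled")
                covered[(u, v)].add(allele)
        for e, labels in self.edges.items():
            if not labels:
                raise ValueError(f"edge {e}: carries no allele label")

    # -- serialization -----------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "sv_type": self.sv_type,
            "nodes": [
                {
                    "id": n.id,
                    "sequence": n.sequence,
                    "origin": n.origin,
                    "reference_span": list(n.reference_span) if n.reference_span else None,
                }
                for n in (self.nodes[i] for i in self.topological_order())
            ],
            "edges": [
                {"from": u, "to": v, "alleles": sorted(self.edges[(u, v)])}
                for u, v in sorted(self.edges)
            ],
            "allele_paths": {a: list(p) for a, p in self.allele_paths.items()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_json_dict(), **kwargs)

    # -- k-mer index (used by the unique-kmer read filter) -----------------

    def kmer_counts(self, k: int) -> Dict[str, int]:
        """Multiset of graph k-mers: per-node k-mers plus edge-spanning ones."""
        if self._kmer_counts is not None and self._kmer_k == k:
            return self._kmer_counts
        counts: Dict[str, int] = {}

        def add(seq: str, lo: int = 0, hi: Optional[int] = None) -> None:
            hi = len(seq) - k + 1 if hi is None else hi
            for i in range(max(lo, 0), hi):
                if i + k <= len(seq):
                    kmer = seq[i : i + k]
                    counts[kmer] = counts.get(kmer, 0) + 1

        for node in self.nodes.values():
            add(node.sequence)
        for u, v in self.edges:
            left = self.nodes[u].sequence[-(k - 1) :]
            right = self.nodes[v].sequence[: k - 1]
            joined = left + right
            # only k-mers straddling the junction (avoid re-counting node k-mers)
            start = max(0, len(left) - (k - 1))
            end = min(len(joined) - k + 1, len(left))
            for i in range(start, end):
                kmer = joined[i : i + k]
                counts[kmer] = counts.get(kmer, 0) + 1
        self._kmer_counts = counts
        self._kmer_k = k
        return counts


def _fetch(reference, contig: str, start: int, end: int) -> str:
    """Fetch reference sequence, 0-based half-open, via faidx-like accessors."""
    if start < 0:
        raise ReferenceFetchError(f"{contig}:{start}-{end}: negative start")
    try:
        if hasattr(reference, "fetch"):  # pysam.FastaFile
            seq = reference.fetch(contig, start, end)
        elif hasattr(reference, "keys") or hasattr(reference, "__getitem__"):
            seq = str(reference[contig][start:end])
        else:  # pragma: no cover - defensive
            raise TypeError(f"unsupported reference accessor {type(reference)!r}")
    except (KeyError, ValueError, IndexError, TypeError) as exc:
        raise ReferenceFetchError(f"{contig}:{start}-{end}: {exc}") from exc
    seq = str(seq).upper()
    if len(seq) != end - start:
        raise ReferenceFetchError(
            f"{contig}:{start}-{end}: fetched {len(seq)} bases, expected {end - start}"
        )
    return seq


def build_graph(record: SVRecord, reference, params: GraphParams = GraphParams()) -> AlleleGraph:
    """Build the allele graph for one SV record.

    Deletion: REF path traverses the deleted-sequence node, ALT is a
    flank-to-flank edge.  Insertion: mirror image.  Swap: two parallel
    middle nodes.  Flank nodes hold one read length of reference
    sequence on each side by default.
    """
    if record.sv_type not in SV_TYPES:
        raise UnsupportedSVTypeError(record.sv_type)
    if record.sv_type in (INSERTION, SWAP) and not record.alt_seq:
        raise MissingAltSequenceError(f"record {record.id}: {record.sv_type} without ALT sequence")
    flank = params.flank
    contig = record.contig
    lf_start = max(0, record.start - flank)
    lf = SequenceNode(
        "LF",
        _fetch(reference, contig, lf_start, record.start),
        origin="reference-fetched",
        reference_span=(contig, lf_start, record.start),
    )
    rf = SequenceNode(
        "RF",
        _fetch(reference, contig, record.end, record.end + flank),
        origin="reference-fetched",
        reference_span=(contig, record.end, record.end + flank),
    )
    nodes = [lf, rf]
    edges: Dict[Edge, frozenset] = {}
    if record.sv_type == DELETION:
        mid = SequenceNode(
            "DEL",
            _fetch(reference, contig, record.start, record.end),
            origin="reference-fetched",
            reference_span=(contig, record.start, record.end),
        )
        nodes.append(mid)
        edges[("LF", "DEL")] = frozenset({REF_LABEL})
        edges[("DEL", "RF")] = frozenset({REF_LABEL})
        edges[("LF", "RF")] = frozenset({ALT_LABEL})
        paths = {REF_LABEL: ["LF", "DEL", "RF"], ALT_LABEL: ["LF", "RF"]}
    elif record.sv_type == INSERTION:
        mid = SequenceNode("INS", record.alt_seq.upper(), origin="explicit")
        nodes.append(mid)
        edges[("LF", "INS")] = frozenset({ALT_LABEL})
        edges[("INS", "RF")] = frozenset({ALT_LABEL})
        edges[("LF", "RF")] = frozenset({REF_LABEL})
        paths = {REF_LABEL: ["LF", "RF"], ALT_LABEL: ["LF", "INS", "RF"]}
    else:  # swap
        refnode = SequenceNode(
            "REFSEQ",
            _fetch(reference, contig, record.start, record.end),
            origin="reference-fetched",
            reference_span=(contig, record.start, record.end),
        )
        altnode = SequenceNode("ALTSEQ", record.alt_seq.upper(), origin="explicit")
        nodes.extend([refnode, altnode])
        edges[("LF", "REFSEQ")] = frozenset({REF_LABEL})
        edges[("REFSEQ", "RF")] = frozenset({REF_LABEL})
        edges[("LF", "ALTSEQ")] = frozenset({ALT_LABEL})
        edges[("ALTSEQ", "RF")] = frozenset({ALT_LABEL})
        paths = {REF_LABEL: ["LF", "REFSEQ", "RF"], ALT_LABEL: ["LF", "ALTSEQ", "RF"]}
    return AlleleGraph(nodes, edges, paths, record.sv_type, "LF", "RF", record=record)


def split_long_nodes(graph: AlleleGraph, read_length: int) -> AlleleGraph:
    """Replace nodes longer than 2x read length with their two breakpoint-
    proximal ends (one read length each), preserving allele path labels.

    Idempotent: resulting nodes are exactly ``read_length`` long.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    threshold = 2 * read_length
    long_nodes = [n for n in graph.nodes.values() if len(n) > threshold]
    if not long_nodes:
        return graph
    replacements: Dict[str, Tuple[SequenceNode, SequenceNode]] = {}
    for node in long_nodes:
        span_a = span_b = None
        if node.reference_span is not None:
            contig, s, e = node.reference_span
            span_a = (contig, s, s + read_length)
            span_b = (contig, e - read_length, e)
        a = SequenceNode(node.id + ".a", node.sequence[:read_length], node.origin, span_a)
        b = SequenceNode(node.id + ".b", node.sequence[-read_length:], node.origin, span_b)
        replacements[node.id] = (a, b)

    nodes: List[SequenceNode] = []
    for node in graph.nodes.values():
        if node.id in replacements:
            nodes.extend(replacements[node.id])
        else:
            nodes.append(node)

    edges: Dict[Edge, frozenset] = {}
    for (u, v), labels in graph.edges.items():
        nu = replacements[u][1].id if u in replacements else u
        nv = replacements[v][0].id if v in replacements else v
        edges[(nu, nv)] = labels

    paths: Dict[str, List[str]] = {}
    for allele, path in graph.allele_paths.items():
        new_path: List[str] = []
        for nid in path:
            if nid in replacements:
                a, b = replacements[nid]
                new_path.extend([a.id, b.id])
                key = (a.id, b.id)
                edges[key] = edges.get(key, frozenset()) | {allele}
            else:
                new_path.append(nid)
        paths[allele] = new_path

    source = replacements[graph.source][0].id if graph.source in replacements else graph.source
    sink = replacements[graph.sink][1].id if graph.sink in replacements else graph.sink
    return AlleleGraph(nodes, edges, paths, graph.sv_type, source, sink, record=graph.record)


def _node_sort_key(graph: AlleleGraph, node_id: str, topo_index: Mapping[str, int]):
    node = graph.nodes[node_id]
    if node.reference_span is not None:
        return (0, node.reference_span[1], node.reference_span[2], topo_index[node_id])
    return (1, 0, 0, topo_index[node_id])


def enumerate_breakpoints(graph: AlleleGraph) -> List[Breakpoint]:
    """One breakpoint per node side with >= 2 connected edges.

    Order is deterministic: by node reference coordinate (topological
    position for non-reference nodes), outgoing side before incoming.
    """
    topo = graph.topological_order()
    topo_index = {n: i for i, n in enumerate(topo)}
    found: List[Tuple[tuple, Breakpoint]] = []
    for node_id in topo:
        for side, edges in (("outgoing", graph.out_edges(node_id)), ("incoming", graph.in_edges(node_id))):
            if len(edges) >= 2:
                edges = sorted(edges)
                bp = Breakpoint(
                    node_id,
                    side,
                    tuple(edges),
                    tuple(graph.edges[e] for e in edges),
                )
                side_rank = 0 if side == "outgoing" else 1
                found.append(((*_node_sort_key(graph, node_id, topo_index), side_rank), bp))
    found.sort(key=lambda t: t[0])
    return [bp for _, bp in found]
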