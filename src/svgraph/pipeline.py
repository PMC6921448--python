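"""End-to-end genotyping: graph build -> read extraction -> realignment
-> breakpoint genotyping -> decision tree."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .breakpoint_genotyper import GenotypingParams, genotype_breakpoint
from .errors import SVGraphError
from .graph_align import (
    AlignmentParams,
    align_read_to_graph,
    count_breakpoint_support,
    has_unique_kmer,
    is_uniquely_mapped,
)
from .graph_model import GraphParams, SVRecord, build_graph, enumerate_breakpoints, split_long_nodes
from .io_layer import Read, extract_reads
from .sv_genotyper import SVGenotype, combine_breakpoints

logger = logging.getLogger(__name__)

__all__ = ["genotype_record", "genotype_many"]


def genotype_record(
    record: SVRecord,
    reference,
    reads_or_bam,
    gparams: GenotypingParams,
    aparams: AlignmentParams = AlignmentParams(),
    graph_params: Optional[GraphParams] = None,
) -> SVGenotype:
    """Genotype one SV from a BAM path/handle or a pre-extracted read list."""
    graph_params = graph_params or GraphParams(read_length=gparams.read_length)
    graph = build_graph(record, reference, graph_params)
    graph = split_long_nodes(graph, graph_params.read_length)
    breakpoints = enumerate_breakpoints(graph)
    if len(breakpoints) != 2:
        raise SVGraphError(
            f"{record.id}: expected 2 breakpoints, found {len(breakpoints)}"
        )

    if isinstance(reads_or_bam, (list, tuple)):
        reads: Sequence[Read] = reads_or_bam
    else:
        reads = extract_reads(reads_or_bam, record, gparams.read_length)

    accepted = []
    for read in reads:
        alignments = align_read_to_graph(read, graph, aparams)
        if not alignments or not is_uniquely_mapped(alignments):
            continue
        if not has_unique_kmer(read, graph, aparams.kmer_size):
            continue
        accepted.append(alignments[0])

    bp_genotypes = []
    for bp in breakpoints:
        counts = count_breakpoint_support(bp, accepted, graph, aparams)
        bp_genotypes.append(genotype_breakpoint(counts, gparams))
    return combine_breakpoints(bp_genotypes[0], bp_genotypes[1], gparams)


def genotype_many(
    records: Sequence[SVRecord],
    reference,
    bam,
    gparams: GenotypingParams,
    aparams: AlignmentParams = AlignmentParams(),
) -> List[Optional[SVGenotype]]:
    """Genotype a batch of records; failures yield None and are logged."""
    out: List[Optional[SVGenotype]] = []
    for record in records:
        try:
            out.append(genotype_record(record, reference, bam, gparams, aparams))
        except SVGraphError as exc:
            logger.warning("failed to genotype %s: %s", record.id, exc)
            out.append(None)
    return out
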