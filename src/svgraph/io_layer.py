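"""VCF/BAM plumbing: parse candidate SVs, extract reads, write genotyped VCF.

All conversion between 1-based VCF coordinates and the package's
internal 0-based half-open convention happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pysam

from .errors import BamAccessError, VcfFormatError
from .graph_model import DELETION, INSERTION, SWAP, SVRecord
from .sv_genotyper import SVGenotype

__all__ = [
    "Read",
    "parse_sv_vcf",
    "extract_reads",
    "write_genotyped_vcf",
    "estimate_read_length",
    "vcf_pos_to_internal",
    "internal_to_vcf_pos",
]

logger = logging.getLogger(__name__)

INS_SEQ_INFO_KEYS = ("SEQ", "INSSEQ", "SVINSSEQ")


def vcf_pos_to_internal(pos_1based: int) -> int:
    """1-based VCF POS (anchor base) -> 0-based start of the affected span."""
    return pos_1based


def internal_to_vcf_pos(start0: int) -> int:
    """0-based start of the affected span -> 1-based VCF POS (anchor base)."""
    return start0


@dataclass(frozen=True)
class Read:
    """A read queued for graph realignment (full sequence, no clipping)."""

    name: str
    sequence: str
    qualities: Optional[str] = None
    is_first_mate: bool = True
    is_reverse: bool = False

    @property
    def key(self) -> Tuple[str, bool]:
        return (self.name, self.is_first_mate)


def _classify_resolved(ref: str, alt: str, start0_anchor: int) -> Optional[Tuple[int, int, str, str]]:
    """Strip the shared prefix of a sequence-resolved REF/ALT pair and
    classify.  Returns (start, end, alt_seq, sv_type) or None."""
    p = 0
    while p < len(ref) and p < len(alt) and ref[p].upper() == alt[p].upper():
        p += 1
    ref_rem = ref[p:]
    alt_rem = alt[p:]
    start = start0_anchor + p
    if ref_rem and not alt_rem:
        return start, start + len(ref_rem), "", DELETION
    if alt_rem and not ref_rem:
        return start, start, alt_rem.upper(), INSERTION
    if ref_rem and alt_rem:
        return start, start + len(ref_rem), alt_rem.upper(), SWAP
    return None


def parse_sv_vcf(
    path: str,
    min_sv_length: int = 50,
    enforce_min_length: bool = True,
    sample: Optional[str] = None,
    skipped: Optional[list] = None,
) -> List[SVRecord]:
    """Parse a VCF of candidate SVs into normalized records.

    Multi-allelic records are decomposed into one record per ALT.
    Symbolic ``<DEL>`` needs END (or SVLEN); symbolic ``<INS>`` needs an
    inserted sequence in INFO (SEQ/INSSEQ/SVINSSEQ) and is otherwise
    rejected with a logged reason.  Records shorter than
    ``min_sv_length`` are skipped when the length policy is enforced.
    """

    def skip(reason: str, rec_id: str) -> None:
        logger.info("skipping %s: %s", rec_id, reason)
        if skipped is not None:
            skipped.append((rec_id, reason))

    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"{path}: {exc}") from exc

    records: List[SVRecord] = []
    with vcf:
        for rec in vcf:
            rid = rec.id or f"{rec.chrom}:{rec.pos}"
            gt_str = None
            if sample is not None and sample in rec.samples:
                gt = rec.samples[sample].get("GT")
                if gt is not None and None not in gt:
                    gt_str = "/".join(str(a) for a in sorted(gt))
            for alt in rec.alts or ():
                if alt.startswith("<"):
                    sym = alt.strip("<>").split(":")[0]
                    if sym == "DEL":
                        start = rec.start + 1  # deleted span begins after the anchor base
                        end = rec.stop
                        if end <= start:
                            skip("symbolic <DEL> without usable END", rid)
                            continue
                        parsed = (start, end, "", DELETION)
                    elif sym == "INS":
                        seq = None
                        for key in INS_SEQ_INFO_KEYS:
                            if key in rec.info:
                                val = rec.info[key]
                                seq = val[0] if isinstance(val, tuple) else val
                                break
                        if not seq:
                            skip("symbolic <INS> without inserted sequence", rid)
                            continue
                        parsed = (rec.start + 1, rec.start + 1, str(seq).upper(), INSERTION)
                    else:
                        skip(f"unsupported symbolic ALT <{sym}>", rid)
                        continue
                else:
                    cls = _classify_resolved(rec.ref, alt, rec.start)
                    if cls is None:
                        skip("REF and ALT identical after normalization", rid)
                        continue
                    parsed = cls
                start, end, alt_seq, sv_type = parsed
                record = SVRecord(
                    contig=rec.chrom,
                    start=start,
                    end=end,
                    sv_type=sv_type,
                    alt_seq=alt_seq,
                    id=rid,
                    genotype=gt_str,
                )
                if enforce_min_length and record.sv_length < min_sv_length:
                    skip(f"SV length {record.sv_length} < {min_sv_length}", rid)
                    continue
                records.append(record)
    return records


def estimate_read_length(bam_path: str, n: int = 1000) -> int:
    """Median read length over the first ``n`` records of the BAM."""
    lengths: List[int] = []
    with pysam.AlignmentFile(bam_path) as bam:
        for read in bam.head(n):
            if read.query_sequence:
                lengths.append(len(read.query_sequence))
    if not lengths:
        raise BamAccessError(f"{bam_path}: no reads with sequence found")
    lengths.sort()
    return lengths[len(lengths) // 2]


def extract_reads(bam, record: SVRecord, read_length: int) -> List[Read]:
    """Reads overlapping [start - l, end + l] (inclusive of abutting
    reads) plus their mates wherever mapped.  Duplicates, secondary and
    supplementary alignments are excluded; each read is returned once.
    """
    own = isinstance(bam, str)
    af = pysam.AlignmentFile(bam) if own else bam
    try:
        window_start = max(0, record.start - read_length - 1)
        window_end = record.end + read_length + 1
        try:
            fetched = list(af.fetch(record.contig, window_start, window_end))
        except ValueError as exc:
            raise BamAccessError(f"fetch failed (missing index?): {exc}") from exc

        reads: Dict[Tuple[str, bool], Read] = {}
        mates_needed = []
        for r in fetched:
            if r.is_duplicate or r.is_secondary or r.is_supplementary or r.is_unmapped:
                continue
            if not r.query_sequence:
                continue
            read = Read(
                name=r.query_name,
                sequence=r.query_sequence,
                qualities=r.qual,
                is_first_mate=not r.is_read2,
                is_reverse=r.is_reverse,
            )
            reads.setdefault(read.key, read)
            if r.is_paired and not r.mate_is_unmapped:
                mate_in_window = (
                    r.next_reference_name == record.contig
                    and window_start - read_length <= r.next_reference_start < window_end
                )
                if not mate_in_window:
                    mates_needed.append(r)
        for r in mates_needed:
            key = (r.query_name, r.is_read2)  # the mate's key
            if key in reads:
                continue
            try:
                for m in af.fetch(r.next_reference_name, r.next_reference_start, r.next_reference_start + 1):
                    if (
                        m.query_name == r.query_name
                        and m.is_read1 != r.is_read1
                        and not (m.is_secondary or m.is_supplementary or m.is_duplicate)
                        and m.query_sequence
                    ):
                        mate = Read(
                            name=m.query_name,
                            sequence=m.query_sequence,
                            qualities=m.qual,
                            is_first_mate=not m.is_read2,
                            is_reverse=m.is_reverse,
                        )
                        reads.setdefault(mate.key, mate)
                        break
            except (ValueError, OSError) as exc:
                logger.warning("mate fetch failed for %s: %s", r.query_name, exc)
        return list(reads.values())
    finally:
        if own:
            af.close()


def _build_header(
    contigs: Mapping[str, int],
    samples: Sequence[str],
    params_line: Optional[str] = None,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig, length in contigs.items():
        header.contigs.add(contig, length=length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("SVLEN", 1, "Integer", "Length of the variant")
    header.info.add("SEQ", 1, "String", "Inserted sequence")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("FT", 1, "String", "Per-sample filter: PASS or failure reason")
    header.formats.add("DP", 1, "Integer", "Breakpoint-crossing read count (both breakpoints)")
    header.formats.add("AD", ".", "Integer", "Reads supporting each allele (REF, ALT)")
    header.formats.add("GQ", 1, "Integer", "Phred-scaled genotype quality")
    if params_line:
        header.add_line(f"##svgraph_params={params_line}")
    for s in samples:
        header.add_sample(s)
    return header


def write_genotyped_vcf(
    records: Sequence[SVRecord],
    genotypes: Mapping[str, Sequence[Optional[SVGenotype]]],
    samples: Sequence[str],
    path: str,
    reference=None,
    contigs: Optional[Mapping[str, int]] = None,
    params_line: Optional[str] = None,
) -> str:
    """Write a (multi-sample) genotyped VCF.

    ``genotypes[sample]`` must align index-wise with ``records``.  With a
    reference accessor, alleles are written sequence-resolved; without
    one, symbolic ``<DEL>``/``<INS>`` records are emitted.
    """
    for s in samples:
        if len(genotypes[s]) != len(records):
            raise VcfFormatError(f"sample {s}: genotype list does not align with records")
    if contigs is None:
        contigs = {}
        for r in records:
            contigs[r.contig] = max(contigs.get(r.contig, 0), r.end + 1000)
    header = _build_header(contigs, samples, params_line)
    try:
        out = pysam.VariantFile(path, "w", header=header)
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"{path}: {exc}") from exc
    with out:
        for i, r in enumerate(records):
            pos0_anchor = max(0, r.start - 1)
            if reference is not None:
                anchor = _fetch_base(reference, r.contig, pos0_anchor)
                replaced = _fetch_span(reference, r.contig, r.start, r.end)
                ref_allele = anchor + replaced
                alt_allele = anchor + r.alt_seq
            else:
                if r.sv_type == SWAP:
                    raise VcfFormatError("swap records need a reference to be written")
                ref_allele = "N"
                alt_allele = f"<{'DEL' if r.sv_type == DELETION else 'INS'}>"
            rec = out.new_record(
                contig=r.contig,
                start=pos0_anchor,
                alleles=(ref_allele, alt_allele),
                id=r.id if r.id != "." else None,
            )
            rec.stop = r.end
            rec.info["SVTYPE"] = {DELETION: "DEL", INSERTION: "INS", SWAP: "SWAP"}[r.sv_type]
            svlen = -r.ref_length if r.sv_type == DELETION else len(r.alt_seq)
            rec.info["SVLEN"] = svlen
            if r.sv_type == INSERTION and reference is None:
                rec.info["SEQ"] = r.alt_seq
            for s in samples:
                g = genotypes[s][i]
                fmt = rec.samples[s]
                if g is None:
                    fmt["GT"] = (None, None)
                    fmt["FT"] = "no_genotype"
                    continue
                a, b = (int(x) for x in g.vcf_gt.split("/"))
                fmt["GT"] = (a, b)
                fmt["FT"] = g.filter_label
                fmt["DP"] = g.depth
                ad = g.allele_depths()
                fmt["AD"] = (ad.get("REF", 0), ad.get("ALT", 0))
                fmt["GQ"] = int(round(g.gq))
            out.write(rec)
    return path


def _fetch_base(reference, contig: str, pos0: int) -> str:
    return _fetch_span(reference, contig, pos0, pos0 + 1)


def _fetch_span(reference, contig: str, start: int, end: int) -> str:
    if start >= end:
        return ""
    if hasattr(reference, "fetch"):
        return str(reference.fetch(contig, start, end)).upper()
    return str(reference[contig][start:end]).upper()
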