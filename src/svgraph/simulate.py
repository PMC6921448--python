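"""Fully synthetic truth data: diploid haplotypes with known SV genotypes,
paired-end reads written to an indexed BAM, and breakpoint-corrupted
input VCFs.

Reads are placed at their true origin coordinates by default, so the
mapping layer introduces no noise and genotyping errors are attributable
to the genotyper.  All randomness flows from the config seed; identical
configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .errors import SimulationError
from .graph_align import reverse_complement
from .graph_model import DELETION, INSERTION, SVRecord, SWAP

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "simulate_truth",
    "simulate_reads",
    "corrupt_breakpoints",
    "write_fasta",
    "write_truth_vcf",
]

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    ref_length: int = 1_000_000
    contig: str = "sim1"
    n_sv: int = 100
    deletion_fraction: float = 0.5  # remainder are insertions
    sv_length_range: Tuple[int, int] = (50, 1000)
    genotype_probs: Tuple[float, float, float] = (0.25, 0.5, 0.25)  # 0/0, 0/1, 1/1
    tr_fraction: float = 0.0
    tr_unit_range: Tuple[int, int] = (2, 6)
    read_length: int = 150
    depth: float = 30.0
    error_rate: float = 0.005
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    breakpoint_shift: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.deletion_fraction, self.tr_fraction, self.error_rate):
            if not (0.0 <= rate <= 1.0):
                raise SimulationError("rates must be in [0, 1]")
        if abs(sum(self.genotype_probs) - 1.0) > 1e-9:
            raise SimulationError("genotype probabilities must sum to 1")


@dataclass
class HapBlock:
    """Maps a haplotype interval back to reference coordinates."""

    hap_start: int
    hap_end: int
    ref_start: int  # for 'alt' blocks: the anchor reference position
    is_ref: bool

    def ref_pos(self, hap_pos: int) -> int:
        if self.is_ref:
            return self.ref_start + (hap_pos - self.hap_start)
        return self.ref_start


@dataclass
class Haplotype:
    sequence: str
    blocks: List[HapBlock]

    def map_to_reference(self, hap_pos: int) -> int:
        lo, hi = 0, len(self.blocks) - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if self.blocks[mid].hap_end <= hap_pos:
                lo = mid + 1
            else:
                hi = mid
        return self.blocks[lo].ref_pos(hap_pos)


@dataclass
class SimTruth:
    config: SimulationConfig
    reference: str
    records: List[SVRecord]
    in_tr: List[bool]
    haplotypes: Tuple[Haplotype, Haplotype]
    phases: List[Tuple[int, int]]  # per record: alt allele on (hap1, hap2)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def simulate_truth(config: SimulationConfig) -> SimTruth:
    """Simulate a reference, non-overlapping SVs with genotypes, and the
    two haplotype sequences of one diploid sample.

    SVs are spaced so that every locus is a singleton (> 150 bp from any
    neighbor) and read-extraction windows do not overlap.
    """
    rng = np.random.default_rng(config.seed)
    L = config.ref_length
    max_len = config.sv_length_range[1]
    margin = 2 * config.read_length + 100
    slot = (L - 2 * margin) // max(config.n_sv, 1)
    spacing_needed = max_len + 2 * config.read_length + 200
    if slot < spacing_needed:
        raise SimulationError(
            f"cannot place {config.n_sv} SVs of up to {max_len} bp in {L} bp "
            f"(need slot >= {spacing_needed}, have {slot})"
        )
    ref = _random_sequence(rng, L)

    n_tr = int(round(config.tr_fraction * config.n_sv))
    tr_flags = np.zeros(config.n_sv, dtype=bool)
    tr_flags[:n_tr] = True
    rng.shuffle(tr_flags)

    records: List[SVRecord] = []
    in_tr: List[bool] = []
    phases: List[Tuple[int, int]] = []
    gt_codes = rng.choice(3, size=config.n_sv, p=list(config.genotype_probs))

    for i in range(config.n_sv):
        slot_start = margin + i * slot
        lo, hi = config.sv_length_range
        sv_len = int(rng.integers(lo, hi + 1))
        is_del = rng.random() < config.deletion_fraction
        pos = int(slot_start + rng.integers(0, max(1, slot - sv_len - spacing_needed + max_len)))

        if tr_flags[i]:
            unit_len = int(rng.integers(config.tr_unit_range[0], config.tr_unit_range[1] + 1))
            unit = _random_sequence(rng, unit_len)
            sv_len = max(unit_len, (sv_len // unit_len) * unit_len)
            array_len = sv_len + 2 * config.read_length
            n_units = array_len // unit_len + 2
            array = np.tile(unit, n_units)[:array_len]
            arr_start = pos - config.read_length
            ref[arr_start : arr_start + array_len] = array
            alt_seq = "" if is_del else np.tile(unit, sv_len // unit_len + 1)[:sv_len]
        else:
            alt_seq = "" if is_del else _random_sequence(rng, sv_len)

        if is_del:
            record = SVRecord(
                contig=config.contig,
                start=pos,
                end=pos + sv_len,
                sv_type=DELETION,
                id=f"sv{i}",
            )
        else:
            record = SVRecord(
                contig=config.contig,
                start=pos,
                end=pos,
                sv_type=INSERTION,
                alt_seq="".join(chr(b) for b in alt_seq),
                id=f"sv{i}",
            )
        gt = int(gt_codes[i])
        if gt == 0:
            phase = (0, 0)
        elif gt == 2:
            phase = (1, 1)
        else:
            phase = (1, 0) if rng.random() < 0.5 else (0, 1)
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}[gt]
        records.append(dataclasses.replace(record, genotype=gt_str))
        in_tr.append(bool(tr_flags[i]))
        phases.append(phase)

    ref_str = ref.tobytes().decode("ascii")
    haps = tuple(
        _build_haplotype(ref_str, records, [p[h] for p in phases]) for h in range(2)
    )
    return SimTruth(config, ref_str, records, in_tr, haps, phases)


def _build_haplotype(reference: str, records: Sequence[SVRecord], carries: Sequence[int]) -> Haplotype:
    parts: List[str] = []
    blocks: List[HapBlock] = []
    hap_pos = 0
    ref_pos = 0
    for rec, carry in zip(records, carries):
        if not carry:
            continue
        seg = reference[ref_pos : rec.start]
        if seg:
            blocks.append(HapBlock(hap_pos, hap_pos + len(seg), ref_pos, True))
            parts.append(seg)
            hap_pos += len(seg)
        if rec.alt_seq:
            blocks.append(HapBlock(hap_pos, hap_pos + len(rec.alt_seq), rec.start, False))
            parts.append(rec.alt_seq)
            hap_pos += len(rec.alt_seq)
        ref_pos = rec.end
    tail = reference[ref_pos:]
    if tail:
        blocks.append(HapBlock(hap_pos, hap_pos + len(tail), ref_pos, True))
        parts.append(tail)
        hap_pos += len(tail)
    return Haplotype("".join(parts), blocks)


def _apply_errors(seq: np.ndarray, rng: np.random.Generator, rate: float) -> np.ndarray:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(seq.shape[0]) < rate)[0]
    if hits.size:
        seq = seq.copy()
        shifts = rng.integers(1, 4, size=hits.size)
        code = np.zeros(256, dtype=np.uint8)
        code[BASES] = np.arange(4)
        seq[hits] = BASES[(code[seq[hits]] + shifts) % 4]
    return seq


def simulate_reads(truth: SimTruth, bam_path: str, seed: Optional[int] = None) -> str:
    """Write paired-end reads from both haplotypes to a sorted, indexed BAM.

    Reads are placed at the reference coordinate of their true origin on
    the haplotype; pairs are drawn uniformly at depth d/2 per haplotype.
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    l = config.read_length
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": config.contig, "LN": config.ref_length}],
        }
    )
    segments: List[Tuple[int, pysam.AlignedSegment]] = []
    quals = pysam.qualitystring_to_array("I" * l)
    for hap_idx, hap in enumerate(truth.haplotypes):
        hap_arr = np.frombuffer(hap.sequence.encode("ascii"), dtype=np.uint8)
        hap_len = hap_arr.shape[0]
        n_pairs = int(round(config.depth / 2.0 * hap_len / (2.0 * l)))
        frags = np.maximum(rng.normal(config.insert_mean, config.insert_sd, n_pairs), 2 * l)
        frags = np.minimum(frags.astype(np.int64), hap_len)
        starts = rng.integers(0, hap_len - frags + 1)
        for pair_idx in range(n_pairs):
            f = int(starts[pair_idx])
            frag = int(frags[pair_idx])
            r1 = _apply_errors(hap_arr[f : f + l], rng, config.error_rate)
            r2_start = f + frag - l
            r2 = _apply_errors(hap_arr[r2_start : r2_start + l], rng, config.error_rate)
            p1 = hap.map_to_reference(f)
            p2 = hap.map_to_reference(r2_start)
            name = f"sim{hap_idx}_{pair_idx}"
            for mate_idx, (seq, pos, mate_pos) in enumerate(((r1, p1, p2), (r2, p2, p1))):
                a = pysam.AlignedSegment(header)
                a.query_name = name
                a.query_sequence = seq.tobytes().decode("ascii")
                a.flag = (
                    0x1 | 0x2 | (0x20 | 0x40 if mate_idx == 0 else 0x10 | 0x80)
                )
                a.reference_id = 0
                a.reference_start = min(pos, config.ref_length - 1)
                a.mapping_quality = 60
                a.cigartuples = [(0, l)]
                a.next_reference_id = 0
                a.next_reference_start = min(mate_pos, config.ref_length - 1)
                a.template_length = frag if mate_idx == 0 else -frag
                a.query_qualities = quals
                segments.append((a.reference_start, a))
    segments.sort(key=lambda t: t[0])
    with pysam.AlignmentFile(bam_path, "wb", header=header) as out:
        for _, a in segments:
            out.write(a)
    pysam.index(bam_path)
    return bam_path


def corrupt_breakpoints(
    records: Sequence[SVRecord],
    shift: int,
    seed: int = 0,
    contig_length: Optional[int] = None,
) -> List[SVRecord]:
    """Shift each SV's breakpoints by +/- ``shift`` bases (direction random,
    seeded), preserving deletion lengths.  Out-of-bounds records are
    dropped and logged."""
    if shift < 0:
        raise SimulationError("shift must be non-negative")
    rng = np.random.default_rng(seed)
    out: List[SVRecord] = []
    for rec in records:
        delta = int(rng.choice((-shift, shift))) if shift else 0
        start = rec.start + delta
        end = rec.end + delta
        if start < 1 or (contig_length is not None and end >= contig_length):
            logger.info("dropping %s: shifted out of bounds", rec.id)
            continue
        out.append(dataclasses.replace(rec, start=start, end=end))
    return out


def write_fasta(path: str, contig: str, sequence: str, width: int = 80) -> str:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")
    try:
        pysam.faidx(path)
    except pysam.SamtoolsError:  # pragma: no cover
        pass
    return path


def write_truth_vcf(truth: SimTruth, path: str, records: Optional[Sequence[SVRecord]] = None) -> str:
    """Write truth (or corrupted) records with their known genotypes."""
    import pysam as _pysam

    records = truth.records if records is None else records
    header = _pysam.VariantHeader()
    header.contigs.add(truth.config.contig, length=truth.config.ref_length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("SVLEN", 1, "Integer", "Length of the variant")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample("TRUTH")
    with _pysam.VariantFile(path, "w", header=header) as out:
        for rec in records:
            pos0 = rec.start - 1
            anchor = truth.reference[pos0]
            ref_allele = anchor + truth.reference[rec.start : rec.end]
            alt_allele = anchor + rec.alt_seq
            vrec = out.new_record(
                contig=rec.contig,
                start=pos0,
                alleles=(ref_allele, alt_allele),
                id=rec.id,
            )
            vrec.stop = rec.end
            vrec.info["SVTYPE"] = "DEL" if rec.sv_type == DELETION else "INS"
            vrec.info["SVLEN"] = -rec.ref_length if rec.sv_type == DELETION else len(rec.alt_seq)
            gt = rec.genotype or "./."
            parts = gt.split("/")
            vrec.samples["TRUTH"]["GT"] = tuple(
                None if p == "." else int(p) for p in parts
            )
            out.write(vrec)
    return path


def write_manifest(truth: SimTruth, path: str, extra: Optional[Dict] = None) -> str:
    data = {
        "config": dataclasses.asdict(truth.config),
        "n_records": len(truth.records),
        "in_tr": truth.in_tr,
        "genotypes": [r.genotype for r in truth.records],
    }
    if extra:
        data.update(extra)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
    return path
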