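"""Population-scale helpers: EM allele-frequency priors under HWE, the
HWE exact-test filter, SV merge/match rules, evaluation metrics, and
breakpoint-deviation measurement."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import GenotypingError, MatchError
from .graph_model import DELETION, INSERTION, SVRecord

__all__ = [
    "EMResult",
    "em_allele_frequency",
    "hwe_fisher_test",
    "merge_svs",
    "exclude_clustered",
    "match_to_truth",
    "MatchResult",
    "breakpoint_deviation",
    "BreakpointDeviation",
    "dosage",
]


def dosage(gt: Optional[str]) -> int:
    """Dosage coding: 0 for homozygous reference and missing genotypes,
    1 for heterozygotes, 2 for homozygous alternative."""
    if gt is None or "." in gt:
        return 0
    alts = sum(1 for a in gt.replace("|", "/").split("/") if a == "1")
    return min(alts, 2)


# ---------------------------------------------------------------------------
# EM genotype priors under HWE


@dataclass
class EMResult:
    allele_frequency: float
    priors: Tuple[float, float, float]  # (p^2, 2pq, q^2) over (0/0, 0/1, 1/1)
    log_likelihoods: List[float]
    n_iter: int


def em_allele_frequency(
    likelihoods: Sequence[Sequence[float]],
    tol: float = 1e-8,
    max_iter: int = 500,
    q_init: float = 0.5,
) -> EMResult:
    """Estimate the ALT allele frequency q from per-sample genotype
    likelihoods (columns: hom-ref, het, hom-alt) by EM under HWE.

    E-step weights each genotype by HWE priors (p^2, 2pq, q^2) times its
    likelihood; M-step sets q to the weighted ALT allele count over 2N.
    """
    L = np.asarray(likelihoods, dtype=float)
    if L.ndim != 2 or L.shape[1] != 3:
        raise GenotypingError("likelihoods must be an N x 3 array")
    if not np.all(np.isfinite(L)) or np.any(L < 0):
        raise GenotypingError("likelihoods must be finite and non-negative")
    if np.any(L.sum(axis=1) <= 0):
        raise GenotypingError("each sample needs a positive likelihood somewhere")
    n = L.shape[0]
    q = float(q_init)
    trajectory: List[float] = []
    for it in range(1, max_iter + 1):
        p = 1.0 - q
        priors = np.array([p * p, 2.0 * p * q, q * q])
        joint = L * priors
        norm = joint.sum(axis=1, keepdims=True)
        trajectory.append(float(np.sum(np.log(norm))))
        w = joint / norm
        q_new = float((w[:, 1].sum() + 2.0 * w[:, 2].sum()) / (2.0 * n))
        if abs(q_new - q) < tol:
            q = q_new
            break
        q = q_new
    p = 1.0 - q
    return EMResult(q, (p * p, 2.0 * p * q, q * q), trajectory, it)


# ---------------------------------------------------------------------------
# HWE exact test


def hwe_fisher_test(
    n_hom_ref: int, n_het: int, n_hom_alt: int, threshold: float = 1e-4
) -> Tuple[float, bool]:
    """Exact conditional test of the heterozygote count given the allele
    counts (two-sided, summing all outcomes no more probable than the
    observation).  Passes iff p >= threshold."""
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise GenotypingError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0, True
    rare = min(2 * n_hom_alt + n_het, 2 * n_hom_ref + n_het)
    if rare == 0:
        return 1.0, True

    def log_weight(h: int) -> float:
        n_rare_hom = (rare - h) // 2
        n_common_hom = n - h - n_rare_hom
        return (
            math.lgamma(n + 1)
            - math.lgamma(n_rare_hom + 1)
            - math.lgamma(h + 1)
            - math.lgamma(n_common_hom + 1)
            + h * math.log(2.0)
        )

    hets = list(range(rare % 2, rare + 1, 2))
    logw = np.array([log_weight(h) for h in hets])
    probs = np.exp(logw - logw.max())
    probs /= probs.sum()
    p_obs = probs[hets.index(n_het)]
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    p = min(p, 1.0)
    return p, p >= threshold


# ---------------------------------------------------------------------------
# SV merging / matching


def _overlap(a: SVRecord, b: SVRecord) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _union_length(a: SVRecord, b: SVRecord) -> int:
    return max(a.end, b.end) - min(a.start, b.start)


def _reciprocal_overlap_ok(a: SVRecord, b: SVRecord, frac: float) -> bool:
    inter = _overlap(a, b)
    return inter >= frac * a.ref_length and inter >= frac * b.ref_length


def sequence_match_fraction(seq1: str, seq2: str) -> float:
    """Fraction of matching bases under a local pairwise alignment,
    relative to the longer sequence."""
    if not seq1 or not seq2:
        return 0.0
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(seq1.upper(), seq2.upper())[0]
    identities = aln.counts().identities
    return identities / max(len(seq1), len(seq2))


def same_variant(
    a: SVRecord,
    b: SVRecord,
    reciprocal: float = 0.8,
    ins_distance: int = 150,
    seq_fraction: float = 0.8,
) -> bool:
    """The merge relation: deletions are the same unless reciprocal
    overlap < 80%; insertions are the same unless > 150 bp apart or
    < 80% matching bases."""
    if a.contig != b.contig or a.sv_type != b.sv_type:
        return False
    if a.sv_type == INSERTION:
        if abs(a.start - b.start) > ins_distance:
            return False
        return sequence_match_fraction(a.alt_seq, b.alt_seq) >= seq_fraction
    return _reciprocal_overlap_ok(a, b, reciprocal)


def merge_svs(
    records: Sequence[SVRecord],
    reciprocal: float = 0.8,
    ins_distance: int = 150,
    seq_fraction: float = 0.8,
) -> List[List[SVRecord]]:
    """Cluster per-sample calls into unique SVs by transitive closure of
    the same-variant relation.  Returns clusters ordered by position."""
    idx = list(range(len(records)))
    parent = list(idx)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    order = sorted(idx, key=lambda i: (records[i].contig, records[i].start, records[i].end))
    window = max(ins_distance, 1)
    for ii, i in enumerate(order):
        a = records[i]
        for j in order[ii + 1 :]:
            b = records[j]
            if b.contig != a.contig or b.start - a.end > window:
                break
            if same_variant(a, b, reciprocal, ins_distance, seq_fraction):
                union(i, j)
    clusters: Dict[int, List[SVRecord]] = {}
    for i in order:
        clusters.setdefault(find(i), []).append(records[i])
    return sorted(clusters.values(), key=lambda c: (c[0].contig, c[0].start, c[0].end))


def exclude_clustered(
    records: Sequence[SVRecord], window: int = 150
) -> Tuple[List[SVRecord], List[SVRecord]]:
    """Split unique SVs into singletons and clustered SVs.  An SV is
    clustered when another SV lies strictly within ``window`` bp of it
    (a gap of exactly ``window`` still counts as a singleton)."""
    flagged = [False] * len(records)
    order = sorted(range(len(records)), key=lambda i: (records[i].contig, records[i].start))
    for ii in range(len(order)):
        i = order[ii]
        for jj in range(ii + 1, len(order)):
            j = order[jj]
            a, b = records[i], records[j]
            if a.contig != b.contig:
                break
            gap = max(b.start - a.end, a.start - b.end, 0)
            if b.start - a.end >= window and b.start > a.end:
                break
            if gap < window:
                flagged[i] = flagged[j] = True
    singletons = [r for r, f in zip(records, flagged) if not f]
    clustered = [r for r, f in zip(records, flagged) if f]
    return singletons, clustered


@dataclass
class MatchResult:
    tp: int
    fp: int
    truth_alt: int
    matches: List[Tuple[int, int]] = field(default_factory=list)  # (call idx, truth idx)
    genotype_concordant: int = 0

    @property
    def recall(self) -> float:
        return self.tp / self.truth_alt if self.truth_alt else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def f_score(self) -> float:
        r, p = self.recall, self.precision
        if math.isnan(r) or math.isnan(p) or (r + p) == 0:
            return float("nan")
        return 2.0 * r * p / (r + p)

    @property
    def genotype_concordance(self) -> float:
        return self.genotype_concordant / len(self.matches) if self.matches else float("nan")


def _match_records(
    call: SVRecord, truth: SVRecord, bp_distance: int, reciprocal: float
) -> bool:
    if call.contig != truth.contig or call.sv_type != truth.sv_type:
        return False
    if abs(call.start - truth.start) > bp_distance or abs(call.end - truth.end) > bp_distance:
        return False
    if call.sv_type == DELETION and not _reciprocal_overlap_ok(call, truth, reciprocal):
        return False
    return True


def match_to_truth(
    calls: Sequence[Tuple[SVRecord, str]],
    truth: Sequence[Tuple[SVRecord, str]],
    bp_distance: int = 500,
    reciprocal: float = 0.8,
) -> MatchResult:
    """Presence/absence matching of called alternative genotypes against
    a truth set.  A call with an alternative genotype is a TP when a
    truth SV with an alternative genotype matches it (breakpoints within
    500 bp; deletions additionally >= 80% reciprocal overlap) and an FP
    otherwise; recall divides TPs by the truth's alternative genotypes.
    Genotype concordance over the matched pairs is reported separately.
    """
    truth_alt_idx = [i for i, (_, gt) in enumerate(truth) if dosage(gt) > 0]
    used = set()
    tp = fp = concordant = 0
    matches: List[Tuple[int, int]] = []
    for ci, (call, call_gt) in enumerate(calls):
        if dosage(call_gt) == 0:
            continue
        candidates = [
            ti
            for ti, (trec, _) in enumerate(truth)
            if ti not in used and _match_records(call, trec, bp_distance, reciprocal)
        ]
        if candidates:
            ti = min(candidates, key=lambda t: abs(truth[t][0].start - call.start))
            used.add(ti)
            matches.append((ci, ti))
            if dosage(truth[ti][1]) > 0:
                tp += 1
                if truth[ti][1] == call_gt:
                    concordant += 1
            else:
                fp += 1
        else:
            fp += 1
    return MatchResult(tp, fp, len(truth_alt_idx), matches, concordant)


@dataclass
class BreakpointDeviation:
    start_deviation: int
    end_deviation: Optional[int] = None
    sequence_edit_distance: Optional[int] = None

    @property
    def max_deviation(self) -> int:
        devs = [abs(self.start_deviation)]
        if self.end_deviation is not None:
            devs.append(abs(self.end_deviation))
        return max(devs)


def _edit_distance(seq1: str, seq2: str) -> int:
    if not seq1:
        return len(seq2)
    if not seq2:
        return len(seq1)
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return int(-aligner.score(seq1.upper(), seq2.upper()))


def breakpoint_deviation(
    call: SVRecord,
    truth: SVRecord,
    bp_distance: int = 500,
    union_fraction: float = 0.6,
) -> BreakpointDeviation:
    """Base-pair deviation between a matched call/truth pair.

    Deletions match when breakpoints are within 500 bp and the overlap is
    no less than 60% of the union length (inclusive); insertions match on
    breakpoint distance, with sequence deviation measured as pairwise
    alignment edit distance.  Raises MatchError for unmatched pairs.
    """
    if call.contig != truth.contig or call.sv_type != truth.sv_type:
        raise MatchError("records differ in contig or type")
    if abs(call.start - truth.start) > bp_distance or abs(call.end - truth.end) > bp_distance:
        raise MatchError(f"breakpoints more than {bp_distance} bp apart")
    if call.sv_type == DELETION:
        union = _union_length(call, truth)
        if union > 0 and _overlap(call, truth) < union_fraction * union:
            raise MatchError("reciprocal overlap below the union-length threshold")
        return BreakpointDeviation(
            start_deviation=call.start - truth.start,
            end_deviation=call.end - truth.end,
        )
    return BreakpointDeviation(
        start_deviation=call.start - truth.start,
        sequence_edit_distance=_edit_distance(call.alt_seq, truth.alt_seq),
    )
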