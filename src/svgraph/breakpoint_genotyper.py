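"""Poisson genotype-likelihood model and confidence tests for one breakpoint.

Breakpoint-supporting read counts are modeled as Poisson with mean
``lambda = d * (l - m) / l`` (depth d, read length l, minimum support
overlap m).  For a heterozygous genotype the two haplotype counts are
independent Poisson draws with means ``lambda * mu_h``; for a homozygous
genotype a single draw with mean ``lambda * (1 - eps)``; reads
supporting no haplotype of the genotype are Poisson with mean
``lambda * eps``.  Posteriors combine these likelihoods with genotype
priors (uniform by default, or population priors from the EM helper).

A breakpoint genotype passes when all four confidence tests clear:
 1. more than one read aligned to the breakpoint;
 2. breakpoint depth consistent with the genomic average
    (two-sided Z test, p >= 0.01);
 3. Phred genotype quality >= 10;
 4. the Fisher strand test.  Conventionally a breakpoint fails on a
    *high* Phred-scaled strand-bias p-value, and that is the default
    here (pass iff score < threshold); set
    ``fisher_strand_verbatim=True`` to instead require score >=
    threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp
from scipy.stats import fisher_exact, norm, poisson

from .errors import GenotypingError
from .graph_align import BreakpointCounts

__all__ = [
    "GenotypingParams",
    "GenotypeLikelihoods",
    "BreakpointGenotype",
    "poisson_lambda",
    "het_likelihood",
    "hom_likelihood",
    "error_likelihood",
    "genotype_posterior",
    "depth_test",
    "fisher_strand_phred",
    "genotype_breakpoint",
]

Genotype = Tuple[str, str]


@dataclass(frozen=True)
class GenotypingParams:
    depth: float = 30.0
    read_length: int = 150
    min_overlap: Optional[int] = None  # defaults to ceil(0.1 * read_length)
    eps: float = 0.01
    mu: Tuple[float, float] = (0.5, 0.5)
    priors: Optional[Mapping[Genotype, float]] = None  # None -> uniform
    max_gq: float = 100.0
    min_reads: int = 2  # "more than one read": total must be >= 2
    depth_p_threshold: float = 0.01
    min_gq: float = 10.0
    fisher_strand_threshold: float = 30.0
    fisher_strand_verbatim: bool = False

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise GenotypingError("depth must be positive")
        if not (0 <= self.eps < 1):
            raise GenotypingError("eps must be in [0, 1)")
        if abs(sum(self.mu) - 1.0) > 1e-9:
            raise GenotypingError("haplotype fractions of a het pair must sum to 1")

    @property
    def overlap_bases(self) -> int:
        if self.min_overlap is not None:
            return self.min_overlap
        return int(math.ceil(0.1 * self.read_length))

    def lam(self, depth_multiplier: float = 1.0) -> float:
        return poisson_lambda(self.depth * depth_multiplier, self.read_length, self.overlap_bases)


def poisson_lambda(d: float, l: int, m: int) -> float:
    """Expected breakpoint-supporting read count: d * (l - m) / l."""
    if m >= l:
        raise GenotypingError(f"min overlap m={m} must be smaller than read length l={l}")
    if m < 0:
        raise GenotypingError("min overlap must be non-negative")
    if d <= 0:
        raise GenotypingError("depth must be positive")
    return d * (l - m) / l


def _log_pmf(k: int, mean: float) -> float:
    if mean < 0:
        raise GenotypingError("Poisson mean must be non-negative")
    if mean == 0.0:
        return 0.0 if k == 0 else float("-inf")
    return float(poisson.logpmf(k, mean))


def het_likelihood(counts: BreakpointCounts, h1: str, h2: str, params: GenotypingParams,
                   depth_multiplier: float = 1.0) -> float:
    """p(R_h1, R_h2 | het genotype) — product of two Poisson pmfs."""
    if h1 == h2:
        raise GenotypingError("het likelihood requires two distinct haplotypes")
    lam = params.lam(depth_multiplier)
    return math.exp(
        _log_pmf(counts.count(h1), lam * params.mu[0]) + _log_pmf(counts.count(h2), lam * params.mu[1])
    )


def hom_likelihood(counts: BreakpointCounts, h1: str, params: GenotypingParams,
                   depth_multiplier: float = 1.0) -> float:
    """p(R_h1 | hom genotype) — Poisson pmf with mean lambda * (1 - eps)."""
    lam = params.lam(depth_multiplier)
    return math.exp(_log_pmf(counts.count(h1), lam * (1.0 - params.eps)))


def error_likelihood(counts: BreakpointCounts, params: GenotypingParams,
                     depth_multiplier: float = 1.0) -> float:
    """p(R_neither | genotype) — Poisson pmf with mean lambda * eps."""
    lam = params.lam(depth_multiplier)
    return math.exp(_log_pmf(counts.neither, lam * params.eps))


@dataclass
class GenotypeLikelihoods:
    genotypes: List[Genotype]
    log_likelihoods: Dict[Genotype, float]
    posteriors: Dict[Genotype, float]
    best: Genotype
    gq: float
    lam: float

    def posterior_of_best(self) -> float:
        return self.posteriors[self.best]


def genotype_posterior(
    counts: BreakpointCounts,
    params: GenotypingParams,
    depth_multiplier: float = 1.0,
) -> GenotypeLikelihoods:
    """Posterior over all unordered haplotype pairs at one breakpoint.

    For genotype (a, b) the likelihood is the haplotype-count term (het
    or hom) times the error term evaluated at the count of reads
    supporting no haplotype of the genotype.
    """
    haps = sorted(set(counts.haplotypes))
    if len(haps) < 2:
        raise GenotypingError("breakpoint must have >= 2 connecting edges")
    lam = params.lam(depth_multiplier)
    genotypes = [tuple(sorted(g)) for g in combinations_with_replacement(haps, 2)]

    if params.priors is not None:
        priors = {g: float(params.priors[g]) for g in genotypes}
        if any(p < 0 for p in priors.values()):
            raise GenotypingError("negative genotype prior")
        total_prior = sum(priors.values())
        if total_prior <= 0:
            raise GenotypingError("genotype priors sum to zero")
    else:
        priors = {g: 1.0 for g in genotypes}
        total_prior = float(len(genotypes))

    total = counts.total
    loglik: Dict[Genotype, float] = {}
    for a, b in genotypes:
        if a != b:
            ll = _log_pmf(counts.count(a), lam * params.mu[0]) + _log_pmf(
                counts.count(b), lam * params.mu[1]
            )
            neither = total - counts.count(a) - counts.count(b)
        else:
            ll = _log_pmf(counts.count(a), lam * (1.0 - params.eps))
            neither = total - counts.count(a)
        ll += _log_pmf(neither, lam * params.eps)
        loglik[(a, b)] = ll

    logpost = np.array(
        [loglik[g] + (math.log(priors[g]) if priors[g] > 0 else float("-inf")) for g in genotypes]
    )
    if np.all(np.isinf(logpost)):
        # all genotypes impossible under the model; fall back to priors
        post = np.array([priors[g] / total_prior for g in genotypes])
    else:
        post = np.exp(logpost - logsumexp(logpost))
    posteriors = {g: float(p) for g, p in zip(genotypes, post)}
    best = max(genotypes, key=lambda g: (posteriors[g], g))
    others = 1.0 - posteriors[best]
    if others <= 10 ** (-params.max_gq / 10.0):
        gq = params.max_gq
    else:
        gq = min(params.max_gq, -10.0 * math.log10(others))
    return GenotypeLikelihoods(genotypes, loglik, posteriors, best, max(gq, 0.0), lam)


def depth_test(total_reads: int, params: GenotypingParams, depth_multiplier: float = 1.0
               ) -> Tuple[float, bool]:
    """Two-sided Z test of breakpoint depth against the genomic average.

    Returns (p-value, passed); passes iff p >= the configured threshold.
    """
    lam = params.lam(depth_multiplier)
    if lam <= 0:
        raise GenotypingError("expected depth must be positive")
    z = (total_reads - lam) / math.sqrt(lam)
    p = 2.0 * float(norm.sf(abs(z)))
    p = min(p, 1.0)
    return p, p >= params.depth_p_threshold


def fisher_strand_phred(table: Sequence[Sequence[int]]) -> float:
    """Phred-scaled two-sided Fisher exact test p-value of a 2x2
    allele-by-strand table."""
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise GenotypingError("Fisher strand test requires a 2x2 table")
    if (arr < 0).any():
        raise GenotypingError("negative counts in strand table")
    _, p = fisher_exact(arr, alternative="two-sided")
    p = max(float(p), 1e-300)
    return -10.0 * math.log10(p)


def strand_table(counts: BreakpointCounts) -> List[List[int]]:
    """2x2 forward/reverse tally for the two (top) haplotypes."""
    haps = sorted(set(counts.haplotypes), key=lambda h: (-counts.count(h), h))[:2]
    haps = sorted(haps)
    return [list(counts.strands.get(h, [0, 0])) for h in haps]


@dataclass
class BreakpointGenotype:
    likelihoods: GenotypeLikelihoods
    counts: BreakpointCounts
    flags: Dict[str, bool] = field(default_factory=dict)
    depth_p: float = float("nan")
    fisher_phred: float = float("nan")

    @property
    def passing(self) -> bool:
        return not any(self.flags.values())

    @property
    def genotype(self) -> Genotype:
        return self.likelihoods.best

    @property
    def failed_criteria(self) -> List[str]:
        return sorted(k for k, v in self.flags.items() if v)


def genotype_breakpoint(
    counts: BreakpointCounts,
    params: GenotypingParams,
    depth_multiplier: float = 1.0,
) -> BreakpointGenotype:
    """Genotype one breakpoint and apply the four confidence tests."""
    gl = genotype_posterior(counts, params, depth_multiplier)
    total = counts.total
    depth_p, depth_ok = depth_test(total, params, depth_multiplier)
    fs = fisher_strand_phred(strand_table(counts))
    if params.fisher_strand_verbatim:
        fs_ok = fs >= params.fisher_strand_threshold
    else:
        fs_ok = fs < params.fisher_strand_threshold
    flags = {
        "low_reads": total < params.min_reads,
        "bad_depth": not depth_ok,
        "low_gq": gl.gq < params.min_gq,
        "strand_bias": not fs_ok,
    }
    return BreakpointGenotype(gl, counts, flags, depth_p=depth_p, fisher_phred=fs)
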