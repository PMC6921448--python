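"""Combine the two breakpoint genotypes of an SV via the decision tree.

Branches:
  1a  both breakpoints pass, same genotype      -> that genotype, PASS
  1b  both pass, different genotypes            -> pooled re-genotype, non-PASS
  2   exactly one passes                        -> passing breakpoint's genotype, non-PASS
  3a  both fail, same genotype                  -> that genotype, non-PASS
  3b  both fail, different genotypes            -> pooled re-genotype, non-PASS

Pooling sums the two breakpoints' counts (reads spanning both
breakpoints are counted twice) and doubles the depth parameter.  Only
branch 1a yields the PASS filter label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .breakpoint_genotyper import (
    BreakpointGenotype,
    GenotypeLikelihoods,
    GenotypingParams,
    genotype_posterior,
)
from .graph_align import BreakpointCounts

__all__ = ["SVGenotype", "combine_breakpoints", "pool_and_regenotype", "variant_filter_status"]

PASS = "PASS"

BRANCH_LABELS = {
    "1a": PASS,
    "1b": "conflicting_breakpoints",
    "2": "one_breakpoint_failing",
    "3a": "both_breakpoints_failing",
    "3b": "both_breakpoints_failing",
}

ALLELE_INDEX = {"REF": 0, "ALT": 1}


def genotype_to_vcf(genotype: Tuple[str, str]) -> str:
    """Map a haplotype-label pair to a VCF GT string (e.g. 0/1)."""
    idx = sorted(ALLELE_INDEX.get(h, 1) for h in genotype)
    return f"{idx[0]}/{idx[1]}"


@dataclass
class SVGenotype:
    genotype: Optional[Tuple[str, str]]
    filter_label: str
    branch: str
    breakpoints: Tuple[BreakpointGenotype, BreakpointGenotype]
    pooled: Optional[GenotypeLikelihoods] = None

    @property
    def is_pass(self) -> bool:
        return self.filter_label == PASS

    @property
    def vcf_gt(self) -> str:
        if self.genotype is None:
            return "./."
        return genotype_to_vcf(self.genotype)

    @property
    def gq(self) -> float:
        if self.pooled is not None:
            return self.pooled.gq
        if self.branch == "2":
            passing = [bp for bp in self.breakpoints if bp.passing]
            return passing[0].likelihoods.gq if passing else min(
                bp.likelihoods.gq for bp in self.breakpoints
            )
        return min(bp.likelihoods.gq for bp in self.breakpoints)

    @property
    def depth(self) -> int:
        return sum(bp.counts.total for bp in self.breakpoints)

    def allele_depths(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for bp in self.breakpoints:
            for h, c in bp.counts.counts.items():
                out[h] = out.get(h, 0) + c
        return out

    def fails_read_or_depth_test(self) -> bool:
        """True when criteria 1 or 2 fail at either breakpoint (the rule
        that maps an SV to a reference genotype in evaluation)."""
        return any(
            bp.flags.get("low_reads", False) or bp.flags.get("bad_depth", False)
            for bp in self.breakpoints
        )

    def genotype_for_evaluation(self) -> str:
        return "0/0" if self.fails_read_or_depth_test() else self.vcf_gt


def pool_and_regenotype(
    bp1_counts: BreakpointCounts,
    bp2_counts: BreakpointCounts,
    params: GenotypingParams,
) -> GenotypeLikelihoods:
    """Re-genotype on summed counts with the depth parameter doubled."""
    pooled = bp1_counts.pooled_with(bp2_counts)
    return genotype_posterior(pooled, params, depth_multiplier=2.0)


def combine_breakpoints(
    bp1: BreakpointGenotype,
    bp2: BreakpointGenotype,
    params: GenotypingParams,
) -> SVGenotype:
    """Apply the decision tree to two breakpoint genotypes of one SV."""
    same = bp1.genotype == bp2.genotype
    pooled = None
    if bp1.passing and bp2.passing:
        if same:
            branch, gt = "1a", bp1.genotype
        else:
            branch = "1b"
            pooled = pool_and_regenotype(bp1.counts, bp2.counts, params)
            gt = pooled.best
    elif bp1.passing or bp2.passing:
        branch = "2"
        gt = (bp1 if bp1.passing else bp2).genotype
    else:
        if same:
            branch, gt = "3a", bp1.genotype
        else:
            branch = "3b"
            pooled = pool_and_regenotype(bp1.counts, bp2.counts, params)
            gt = pooled.best
    return SVGenotype(
        genotype=gt,
        filter_label=BRANCH_LABELS[branch],
        branch=branch,
        breakpoints=(bp1, bp2),
        pooled=pooled,
    )


def variant_filter_status(svgt: SVGenotype) -> str:
    """PASS only for branch 1a; otherwise the branch's failure label."""
    return BRANCH_LABELS[svgt.branch]
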