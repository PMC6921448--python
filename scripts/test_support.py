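"""Small helpers for the acceptance report."""

from svgraph.graph_align import BreakpointCounts

HAPS = ("ALT", "REF")


def make_counts(r_ref=0, r_alt=0, neither=0):
    c = BreakpointCounts("bp", HAPS)
    c.counts["REF"] = r_ref
    c.counts["ALT"] = r_alt
    c.neither = neither
    c.strands["REF"] = [r_ref - r_ref // 2, r_ref // 2]
    c.strands["ALT"] = [r_alt - r_alt // 2, r_alt // 2]
    return c
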