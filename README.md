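# svgraph

Graph-based structural-variant (SV) genotyping for short-read data.

For each candidate SV (deletion, insertion, or blockwise sequence swap)
in a VCF, `svgraph` builds a small directed acyclic sequence graph whose
labeled paths spell the reference and alternative alleles, realigns the
reads near the locus to that graph with a junction-aware affine-gap
Smith-Waterman, counts haplotype-supporting reads at each breakpoint
(a node side with two or more edges), and genotypes each breakpoint
with a Poisson read-count likelihood model. Two breakpoint genotypes
are combined into the variant-level genotype through a decision tree;
only fully concordant, confidence-filtered calls receive the `PASS`
label.

The package also ships population-level helpers (EM allele-frequency
priors under Hardy–Weinberg equilibrium, an exact HWE filter, SV
merge/match rules, benchmarking metrics, breakpoint-deviation
measurement) and a self-contained diploid read simulator, so the whole
pipeline is testable without any external data.

## CLI

```sh
# genotype candidate SVs against a BAM
svgraph genotype -r ref.fa -b sample.bam -v svs.vcf -o genotyped.vcf \
    --depth 30 --read-length 150 --eps 0.01

# simulate a truth set: FASTA + truth VCF + sorted/indexed BAM + manifest
svgraph simulate -o sim --ref-length 1000000 --n-sv 100 --depth 30 --seed 1

# HWE-filter a multi-sample VCF (exact test, p < 1e-4 fails)
svgraph hwe-filter -v merged.vcf -o annotated.vcf

# merge per-sample calls into unique SVs / benchmark against a truth set
svgraph merge -v s1.vcf -v s2.vcf -o clusters.tsv
svgraph bench --calls genotyped.vcf --truth truth.vcf
```

## Library layout

| module | role |
| --- | --- |
| `svgraph.graph_model` | allele-graph construction, long-node splitting, breakpoint enumeration |
| `svgraph.graph_align` | junction-aware Smith-Waterman, unique-mapping and unique-k-mer read filters, breakpoint support counting |
| `svgraph.breakpoint_genotyper` | Poisson genotype likelihoods, posteriors/GQ, the four confidence tests |
| `svgraph.sv_genotyper` | breakpoint-combining decision tree, pooled re-genotyping |
| `svgraph.io_layer` | VCF parsing/writing, targeted BAM read extraction |
| `svgraph.popgen` | EM priors, HWE exact test, merge/match rules, evaluation metrics |
| `svgraph.simulate` | diploid truth sets, paired-end reads, breakpoint corruption |
| `svgraph.evaluation` | simulation benchmarks and the breakpoint-shift recall curve |

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the binding acceptance criteria
(oracle equivalences, exact truth tables, fixed-seed recovery and
robustness properties). The stochastic end-to-end criteria simulate a
1 Mb genome with 100 SVs at 30× and take a few minutes each.

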