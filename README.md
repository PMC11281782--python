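# rag-offtarget

Detection and characterization of RAG-mediated off-target V(D)J recombination
from somatic structural-variant (SV) calls.

## Background

V(D)J recombination assembles antigen-receptor genes by cutting at
recombination signal sequences (RSSs): a conserved palindromic heptamer
(consensus 5′-CACAGTG) and an A-rich nonamer (consensus 5′-ACAAAAACC)
separated by a 12 or 23 bp spacer.  The genome also contains cryptic
RSS-like sequences (cRSSs) that RAG can cleave off target, producing somatic
deletions, inversions and translocations in lymphoid malignancies.  Because
RAG cleavage happens at the heptamer border, such rearrangements leave a
recognizable footprint: a **CAC immediately 3′ of the breakpoint (or its
reverse complement GTG immediately 5′), within 21 bp, at both breakpoints**.

This package implements that screen and the downstream characterization a
genomicist would run on a tumor/matched-control cohort:

- **`io_formats`** — FASTA / BEDPE / VCF-BND / GFF3 / BED12 readers and TSV
  report writers, with one internal coordinate convention (0-based
  half-open).
- **`signature`** — control subtraction, the CAC/GTG-within-21-bp screen,
  recombinant sizes and the <1 kb / 1–10 kb / >10 kb size bins.
- **`annotation`** — breakpoint assignment to exon / intron / 5′UTR / 3′UTR
  / promoter / downstream / intergenic and cancer-gene (COSMIC Cancer Gene
  Census) intersection.
- **`junctions`** — decomposition of junction sequences into flank matches,
  P nucleotides (palindromic hairpin-opening insertions), N nucleotides
  (non-templated TdT additions) and chew-back; signal / coding / hybrid
  joint classification; moment-corrected cohort chemistry estimates.
- **`motif`** — heptamer-anchored, strand-normalized position count/probability
  matrices with per-position Shannon information content (sequence logos)
  and similarity to the canonical RSS.
- **`simulate`** — a synthetic-data generator: toy genome, planted RSS/cRSS
  sites, RAG-style rearrangements with realistic junction chemistry, shared
  germline SVs, motif-free background SVs, and a complete truth table.
- **`report` / `cli`** — end-to-end orchestration from a YAML cohort config
  with TSV reports and a run manifest.

## Worked example

Simulate a sample, screen it, and produce the cohort reports:

```sh
rag-offtarget simulate --seed 5 --out demo/sim
rag-offtarget filter --genome demo/sim/ref.fa --tumor demo/sim/tumor.bedpe \
    --control demo/sim/control.bedpe --out demo/calls.tsv
# -> 12/20 SVs pass the signature
```

The filter output has one row per somatic SV with the decision and the best
per-breakpoint motif evidence:

```
sv_id  chrom1  pos1   chrom2  pos2   sv_type  is_rag_mediated  bp1_offset ...
rag0   chr3    49816  chr3    95736  DEL      1                0
rag1   chr2    60878  chr2    64000  DEL      1                0
```

A cohort config runs everything at once:

```yaml
# demo/cohort.yaml
genome: demo/sim/ref.fa
gene_models: demo/sim/genes.gff3
census: demo/sim/census.tsv
samples:
  - id: s1
    genotype: Rag1_cc
    tumor: demo/sim/tumor.bedpe
    control: demo/sim/control.bedpe
    junctions: demo/sim/junctions.fa
```

```sh
rag-offtarget run --config demo/cohort.yaml --out demo/reports
```

which prints the per-sample summary

```
sample genotype  n_svs_total  n_svs_somatic  n_rag_positive
    s1  Rag1_cc           40             20              12
```

(40 input calls, 20 left after subtracting the matched control, 12 passing
the breakpoint signature) and writes `report_samples.tsv`,
`report_feature_distribution.tsv`, `report_joints.tsv`, `report_sizes.tsv`,
`report_pn.tsv`, `report_genes.tsv` and `report_logo.tsv`.  For example,
`report_sizes.tsv` bins the intra-chromosomal recombinant sizes,

```
group    n_intra  n_inter  LT_1KB_pct  KB_1_TO_10_pct  GT_10KB_pct
Rag1_cc  10       2        10.0        20.0            70.0
```

`report_joints.tsv` gives the hybrid-joint fraction (70.0% here — the
simulated mixture), and the first rows of `report_logo.tsv` show the fully
conserved CAC of the cleavage consensus followed by degenerate positions:

```
position  A     C     G    T    ic_bits  consensus
1         0.0   24.0  0.0  0.0  2.0      C
2         24.0  0.0   0.0  0.0  2.0      A
3         0.0   24.0  0.0  0.0  2.0      C
4         16.0  3.0   4.0  1.0  0.6      A
```

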