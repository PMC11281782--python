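# Methods

## The breakpoint signature screen

RAG cleaves precisely at the border of an RSS heptamer, whose first three
bases (CAC) are the most constrained part of the motif.  An SV breakpoint
produced by off-target RAG activity therefore tends to carry a CAC just 3′
of the break on the top strand, or — when the heptamer lies on the other
strand — a GTG just 5′ of it.  The screen requires such a motif within a
window (default 21 bp, distances 0..21 inclusive, the permissive reading of
"within") at **both** breakpoints.

Scanning conventions, all configurable through `SignatureConfig`:

- Only the top strand is scanned.  "GTG to the left" on the top strand *is*
  the reverse-complement heptamer case; scanning the bottom strand as well
  would count every occurrence twice.
- Offsets are measured to the nearest motif base: the CAC's first base in
  `[pos, pos+window]`, the GTG's last base in `[pos-window, pos-1]`.  The
  breakpoint base itself may be the first motif base (offset 0).  Note the
  left-side window therefore exposes offsets `0..window-1`.
- Both orientations are accepted at either breakpoint independently; the
  screen does not tie motif orientation to the SV's strand fields.
- Windows running past a contig end are truncated, not an error.

Control subtraction removes a tumor SV when a control SV of the same type
and contig pair has both positions within a slop (default 50 bp — SV
callers rarely reproduce breakpoints exactly between libraries).

Recombinant size is `pos2 − pos1` for intra-chromosomal events, binned
`<1000`, `1000..10000` (both ends inclusive), `>10000` bp; inter-chromosomal
events have no size and are tallied separately.

## Breakpoint annotation

Gene features are indexed in interval trees.  Each breakpoint gets exactly
one label via the precedence

```
UTR5 = UTR3  >  EXON  >  INTRON  >  PROMOTER  >  DOWNSTREAM  >  INTERGENIC
```

chosen so the reported categories are mutually exclusive; ties across genes
break by nearest TSS, then lexicographic gene symbol.  A point inside one
gene's intron and another gene's promoter is an intron: gene-body membership
is the stronger claim.  Promoter = 2 kb upstream of the TSS and downstream
= 2 kb past the transcript end (strand-aware, clipped at contig bounds);
the windows are conventions, not biology, and are configurable.
Percentages are `100·count/total` rendered at one decimal, half away from
zero — the rounding used for every report in the package (e.g. 24 events
over 7 samples → 3.4).

## Junction chemistry

A junction record holds the joined sequence plus the two reference flanks
at the recorded breakpoints, read in junction orientation.  The partition

```
[left-flank match][P_left][N][P_right][right-flank match]
```

is computed by maximal matching: the longest junction prefix equal to the
left flank, the longest suffix equal to the right flank; overlapping claims
(microhomology) go to the left match by convention.  Chew-back per side is
the flank length minus the raw match, which makes it symmetric under
reverse complementation of the record.  P segments are the maximal insert
prefix (then suffix) equal to the reverse complement of the adjacent
retained flank terminus — the footprint of asymmetric hairpin opening —
called greedily left then right and capped at 10 nt (reported P lengths in
real data reach 9; the cap stops pathological palindromic matches in
low-complexity sequence).  N is the remaining middle.  When the two maximal
palindromic segments compete for the same insert bases the greedy tie-break
is inherently left-biased, so the reverse-complement symmetry of P values
holds only for non-competing junctions (empirically > 97% of simulated
ones); chew-back symmetry always holds.

Joint classification is reference-based: an end is a *signal end* when the
motif abuts the junction point (offset ≤ `signal_offset_max`, default 0) on
the **retained** side — GTG_LEFT for a left-retained end, CAC_RIGHT for a
right-retained end.  Both signal ends → signal joint, neither → coding
joint, exactly one → hybrid joint.  Tying orientation to the retained side
is deliberate: at a cut placed exactly at a heptamer border both sides of
the break see the motif in the reference, and only the retained side
determines whether the heptamer survives in the derivative chromosome.
Without a junction sequence the call is made from reference flanks alone
and flagged low-confidence.

### Cohort chemistry estimates

Maximal matching is biased as an estimator of the generating chemistry:
beyond the true boundary it keeps consuming bases that match by chance
(probability `m = Σ_b q_b²` ≈ 0.26 at 42% GC), so apparent chew-back is
under-counted and apparent P over-claimed.  `recover_chemistry_means`
applies method-of-moments corrections; for chew-back the identity

```
E[overshoot] = g · P(apparent ≥ 1),   g = m / (1 − m)
```

is exact for any chew distribution, and first-order analogues correct the P
over-claim and the N remainder.  On simulated cohorts of 1,000 junctions
the corrected means land within three standard errors of the generating
Geometric / Uniform / Poisson means; the uncorrected (apparent) values are
what `cohort_junction_stats` tabulates, since they are the observable
quantities.

## Motif logos

Flanking sequences are extracted from the best (smallest-offset) hit per
breakpoint, reading in the heptamer direction, and GTG_LEFT hits are
reverse-complemented so every sequence starts with CAC — one orientation,
no double counting.  The logo statistic is Shannon information content in
bits against a uniform 4-letter background, `IC_i = 2 + Σ_b p_ib log2 p_ib`,
without small-sample correction by default (available as a flag).  The
default window is 7 nt (the heptamer); widths up to 28 nt reach the spacer
and nonamer region.  Consensus is the per-column argmax with alphabetic
tie-break; similarity to the canonical heptamer is the probability mass on
the canonical base per position.

## The synthetic-data generator

The generator emulates exactly the structures the screen assumes, so every
pipeline stage is testable without downloads:

- **Genome** — i.i.d. bases at 42% GC (mouse-like), default 300 kb over 3
  contigs; 10 toy genes with three exons, 100 bp 5′UTR, 150 bp 3′UTR and
  random strand, tiled evenly.
- **Sites** — RSS pairs planted as heptamer + spacer + nonamer with 12/23
  spacer pairing; cRSSs as heptamers whose positions 4–7 mutate
  independently (uniform redraw) at a configurable rate with CAC fixed.
  Sites take random strand orientation; minus-strand sites are planted as
  reverse complements.
- **RAG events** — two unused sites whose orientations realize the drawn
  joint type; cuts at the heptamer-proximal edges; deletion-type retained
  sides; a configurable fraction inter-chromosomal.  Chew-back per coding
  end is shifted-Geometric(p = 0.2; mean 4 nt, the scale of nucleotide loss
  at real coding joints) capped at 20 bp; P additions Uniform{0..9} occur
  only at uncut (zero-chew) coding ends, mirroring hairpin-opening
  chemistry; N additions are Poisson(λ = 5), matching reported junction N
  lengths; signal ends join precisely.  A site is not used for a coding end
  if its flank happens to present the signal motif at the junction point,
  so every planted joint type is recoverable from the reference — the
  generator plants unambiguous ends.
- **Breakpoints** are emitted at the cut positions; chew-back lives only in
  the junction sequence.  Optional jitter (default 0) emulates caller
  imprecision, applied away from the planted heptamer so detection degrades
  gracefully as jitter approaches the window.
- **Background SVs** draw breakpoints uniformly with no motif constraint —
  they pass the screen at the base rate of the genome (~20–25% at 21 bp,
  which is why the *both-breakpoints* rule matters).  **Germline SVs** are
  duplicated into tumor and control call sets, identical by default, with a
  jitter option to stress the subtraction slop.
- The truth table records every draw (including the N segment bases), so
  each junction is exactly re-derivable from truth plus reference — tests
  use an independent reconstruction as an oracle.

What the generator does **not** model: chromatin accessibility of cRSSs,
sequencing noise or read-level artifacts, caller-specific breakpoint
conventions, copy-number context, or realistic genome composition
(repeats, isochores).  Passing tests therefore demonstrate correctness of
the screening and characterization logic under the stated generative
assumptions, not calling performance on real WGS data.

## Numerical and formatting conventions

- Internal coordinates 0-based half-open; VCF shifted ±1 at the boundary;
  BEDPE read as-is with the breakpoint at each interval start.
- Rounding half away from zero at one decimal in every report.
- All randomness flows through one `numpy` Generator per simulation;
  identical seeds give byte-identical emitted files.
- Degenerate inputs: empty call sets produce header-only reports; empty
  label lists produce empty tables (no division); groups with no
  intra-chromosomal events are omitted from size reports with a log notice.

## Problem sizes

Tests and the acceptance script run on deliberately small instances — 300 kb
genomes, cohorts of 10–50 RAG events, 1,000–10,000 simulated junctions,
1,000 random background SVs — sizes at which the exhaustive oracles
(brute-force window scans, full decomposition enumeration) are cheap and
every statistical tolerance (3 binomial/standard errors) is still
discriminating.

## Known limitations

- The screen is a motif filter, not an RSS functionality score: no
  RIC-style information scores, no nonamer/spacer model.
- Junction partitioning reports one deterministic decomposition; ambiguous
  junctions (chance matches) have no posterior over alternatives, only the
  cohort-level bias corrections described above.
- Which SV-caller breakpoint convention the 21 bp window should be measured
  against is left as configuration (`window_bp`, offset conventions
  documented) rather than guessed.
- Hybrid-joint genotype assignments and the exact published breakpoint
  totals contain internal inconsistencies in the source material; the
  package reproduces the arithmetic, not the assignments.
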