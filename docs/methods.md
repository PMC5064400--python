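# Methods

## Enrichment scan

### Model

The scan treats gene labels as a fixed attribute of an otherwise fixed gene
set: with `N` genes on the scanned contigs, `K` of them labeled, a window
containing `n` genes of which `k` are labeled is scored

    p = P(X >= k),   X ~ Hypergeometric(N, K, n),

the probability of seeing at least `k` labeled genes when `n` genes are
drawn without replacement from the genome. The tail is evaluated through
the survival function of `scipy.stats.hypergeom` (log-space internally),
never by explicit factorials; the test suite checks it against exact
integer-combinatorics enumeration for every parameter tuple with N ≤ 60 to
1e−12.

The null model conditions on gene positions and on `K`: it asks whether the
labels are exchangeable across genes, not whether genes cluster. Because
the statistic is discrete, the test is conservative — on null data the
fraction of windows below α = 0.01 is typically ~0.005, which the
calibration check exploits (mean fraction must not exceed 0.01 plus three
standard errors over 200 replicate genomes).

### Coordinate system and windows

Contigs strictly longer than `min_contig_length` (default 100 000 bp,
exclusive, "more than 100 kb" read literally) are sorted by decreasing
length — ties broken lexicographically by id so the axis is deterministic —
and concatenated into a single global axis. Windows of `W` = 100 000 bp
advance by `s` = 10 000 bp **within** each contig; trailing windows are
truncated at the contig end. Windows do not cross contig junctions by
default: a junction-spanning window would test an interval that exists only
as an artifact of contig ordering. `span_contig_junctions=True` restores
the literal concatenated-axis behaviour for comparison.

Each gene is reduced to a single anchor point, by default its floor
midpoint, so each gene contributes to a deterministic set of windows and
`Σ k` over a disjoint tiling (`s = W`) equals `K` exactly. `start` and
`any_overlap` anchoring are available; with `any_overlap` a gene can fall
in several windows and the tiling identity no longer holds.

Genes on excluded contigs are dropped from both `N` and `K` (with a logged
warning — silent data loss is forbidden). Empty windows get `p = 1` rather
than being skipped, so window counts depend only on the layout and
parameters. Windows are reported 0-based half-open (BED convention);
GFF3 input/output stays 1-based inclusive.

### Regions and overlap

Significant windows (`p < α`, strict; no multiple-testing correction by
default, matching the plain p < 0.01 convention for such genome tracks — a
Benjamini–Hochberg mode is available but off) are merged when they overlap
or abut on the same contig; the region p-value is the member minimum.
Regions never span contigs. Region-by-cluster overlap requires at least one
shared bp on the same contig; summary counts are deduplicated on both
sides. Clusters on excluded contigs are skipped with a warning.

## Cluster homology

### Alignment

Pairwise protein alignment uses Needleman–Wunsch with affine gaps
(BLOSUM62, gap existence 11, extension 1 — protein BLAST defaults; in the
aligner's convention the first gap position costs 12). End gaps are
penalised in global mode. Identity is 100 × identical pairs / alignment
columns, gap columns included; coverage is the share of the coverage-basis
sequence's residues aligned to a residue (basis `reference` by default,
because ortholog tallies are quoted out of reference-cluster genes and
fusion detection needs per-reference coverage; `query` and `shorter` are
options). A `local` (Smith–Waterman) mode with the same scoring covers the
BLAST-local reading of "identity"; identity is then computed over the local
alignment's columns. Free-end-gap ("glocal") scoring was deliberately not
used for fusion probing: with free end insertions the optimal alignment may
attach a stray terminal residue far into the query at zero cost, corrupting
segment bounds, whereas a local alignment confines the match naturally.

### Ortholog calls and assignment

A pair is orthologous when identity > 30 **and** coverage > 50, both strict
("more than"). Cluster matching aligns all query × reference pairs and
selects a one-to-one assignment that maximizes the number of qualifying
pairs, breaking ties by total identity; this is solved exactly as a linear
assignment problem (a large constant bonus per qualifying pair makes the
count dominate). Identity/coverage averages run over assigned pairs only.

### Synteny and fusions

Both gene orders are restricted to mapped genes; a breakpoint is an
unordered adjacency of the reference order absent from the query order.
The definition is strand-agnostic: a wholly reversed cluster has zero
breakpoints, and one adjacent swap costs exactly two. A query protein is a
fusion candidate when two or more reference genes, adjacent in reference
order, each meet the ortholog criteria against it (reference-based
coverage, local mode) on query segments that overlap pairwise by less than
20% of the shorter segment (configurable); maximal adjacent runs are
reported once, and fused reference genes count once each toward the
ortholog tally.

## Summary statistics

N50 is the largest length `L` such that contigs ≥ `L` sum to at least half
the assembly. GC excludes ambiguous bases from the denominator. Size-class
contig counts use strict thresholds (> 200 bp, > 100 kb). Introns are the
gaps between consecutive exons, so introns per gene equal exons − 1 and the
two means differ by exactly one — a free invariant the tests exploit. Gene
coverage of the genome is the union of gene spans (overlapping genes are
not double-counted), the only definition bounded by 100%.

## Synthetic data

The generator emulates a compact fungal genome: i.i.d. sequence at a target
GC (49% default), genes placed left-to-right with exponential gaps at one
gene per 2.7 kb, shifted-Poisson exon counts (mean 3/gene), exponential
exon (~450 bp) and intron (~95 bp) lengths floored at 30/20 bp, a 5%
base label rate, and optional planted regions whose genes are labeled at a
multiplied rate (membership by gene midpoint, probability capped at 1).
Protein clusters are diverged from a simulated reference by independent
per-residue substitution (uniform replacement over the 19 alternatives —
deliberately not substitution-matrix-biased, which is sufficient for
threshold testing), optional single-residue indels, adjacent swaps and
adjacent-pair fusions, with the intended ortholog map and realized
substitution counts recorded as ground truth. Sequential placement with
exponential gaps guarantees termination at high density (an error is raised
when the expected gene length exceeds the per-gene budget).

What the generator does **not** emulate: codon/ORF structure, repeat
content, GC heterogeneity (isochores, AT-rich blocks), gene-length/density
correlation, paralogy, or phylogenetically structured divergence. Passing
recovery tests therefore demonstrates the statistical machinery under the
stated label model, not robustness to every artifact of real assemblies.

All randomness flows through explicit integer seeds (no global RNG state);
identical configurations yield byte-identical FASTA/GFF3/TSV/JSON.

## Problem sizes and numerical choices

The replicate checks use 7 Mb null genomes (~2 300 genes, 200 seeds) for
calibration and 5 Mb genomes (one gene per 3 kb, one 100 kb planted region
at 10×, 100 seeds) for recovery — large enough that a fully contained
window holds ~33 genes and the planted signal is unambiguous, small enough
to rerun casually. The exhaustive-alignment oracle runs on sequences of at
most 10 residues, where every optimal alignment can be enumerated.
Assignment optimality is cross-checked by permutation search on clusters up
to 5×5. Region BED scores cap −log10(p) at 300. Equal alignment scores are
resolved by the aligner's deterministic first-reported traceback; equality
comparisons against the enumeration oracles use 1e−12 (tail probabilities)
and 1e−9 (scores).

## Known limitations

- The window scan tests label exchangeability only; it cannot distinguish
  label clustering from gene-density artifacts under `any_overlap`
  anchoring.
- "Global identity" of the operational ortholog rule is implemented as true
  global alignment identity by default; BLAST's local-HSP identity can be
  approximated with `mode="local"` but e-values are out of scope.
- Fusion detection considers runs of reference-adjacent genes only; a
  fusion of non-adjacent genes (after a rearrangement) is not called.
- Table-style "avg similarity" is averaged over assigned ortholog pairs;
  whether published tables average over all genes instead is not always
  stated, so cross-study comparisons should check that convention.
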