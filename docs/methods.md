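# Methods

## Problem and model

De novo transcriptome assemblies of non-model organisms are fragmented: a
single gene is frequently represented by several contigs (disjoint pieces of
its coding sequence, or near-identical allelic/isoform copies), so counting
transcripts with a family annotation badly overestimates family size.
`famexpand` implements a conservative transcript-to-gene census that turns a
set of assembly contigs plus a family-annotated reference proteome into a
*minimum* gene count per family, reported with ">=" semantics, together with
the assembly-completeness statistics (N50, length distribution, ortholog hit
ratio, multi-reference hit partitions) used to judge whether such a census is
meaningful at all.

The census procedure, per superfamily (e.g. cytochrome P450s, cathepsins):

1. **Selection.** Transcripts whose top translated hit carries a superfamily
   keyword ("cytochrome p450"; "cathepsin" / "cysteine peptidase",
   case-insensitive substring on the reference description/family label).
   Keyword groups must be disjoint; a transcript joins at most one group.
2. **Length filter.** Transcripts shorter than 250 nt are ignored for
   counting (short contigs cannot be placed reliably and inflate counts).
   This filter applies only to the census, not to OHR/N50.
3. **Isoform collapsing.** Transcripts at >= 95% nucleotide identity over
   their best local alignment, covering >= 80% of the shorter sequence, are
   single-linkage clustered as products of one gene. The representative is
   the longest member (ties: lexicographically smallest id).
4. **ORF calling.** The top hit fixes the reading frame; the maximal
   stop-free stretch of that frame containing the aligned query interval is
   the candidate ORF. It is *complete* iff a methionine occurs at or before
   the alignment start within the stretch **and** the stretch is terminated
   by a stop codon inside the transcript. If no stop-free stretch contains
   the aligned interval (a stop interrupts the alignment itself, e.g. a
   sequencing error), no ORF consistent with the alignment exists and the
   call is truncated. This containment requirement is load-bearing: without
   it, a start-bearing fragment with an error-induced premature stop is
   promoted to "complete" and splits from its partner fragment.
5. **Gene-unit resolution.** Within the clusters sharing one top-hit
   subject: every complete-ORF cluster is its own gene (a complete ORF
   cannot be a fragment of anything). Truncated clusters whose subject
   intervals do not overlap significantly are chained as fragments of one
   gene; significantly overlapping truncated clusters must be different
   genes. Two intervals overlap significantly when the overlap is at least
   `min(min_overlap, overlap_frac * shorter_interval)` residues
   (defaults 15 aa / 10%; `min_overlap=1` recovers the literal any-overlap
   rule). Clusters hitting different subjects are distinct genes by
   definition.
6. **Roll-up.** Gene units are summed per reference family and clan.

### Minimal chaining

For more than two truncated fragments the pairwise "no overlap => same gene"
rule generalises to: partition the intervals into the fewest groups that are
pairwise non-overlapping. For plain interval overlap, first-fit by sorted
start is provably minimal, but the overlap-tolerance rule makes the conflict
graph slightly non-interval: on rare random interval groups first-fit uses
one chain too many. Because the census's contract is a
*minimum* count, `resolve_gene_units` therefore uses first-fit only as an
upper bound and certifies the optimum with a branch-and-bound search over
chain assignments (cheap in practice: the bound prunes at the greedy count,
and groups are small). A set-partition enumeration oracle in the test suite
confirms exact minimality on random groups.

## Translated search

Six-frame translation (standard code; codons containing N translate to X;
stops render as `*`) followed by exhaustive affine-gap Smith-Waterman of
every frame against every reference protein - no seeding heuristics, which
is affordable at desk scale and strictly more sensitive than a heuristic
search. Scoring is BLOSUM62 with gap open 11 / extend 1 (a gap of length k
costs 11 + k); `X` scores -1 and `*` scores -4 against everything, so
alignments may pass through an in-frame stop at a penalty rather than being
split there. Per (transcript, protein) pair only the best single frame's
local alignment is kept. Significance uses Karlin-Altschul statistics with
the published gapped BLOSUM62/11-1 parameters (lambda = 0.267, K = 0.041):
bit = (lambda*S - ln K)/ln 2, E = m*n*2^-bit with m the translated frame
length and n the total database length (amino acids). E-values emulate
threshold behaviour (default cut-off 1e-3), not any particular BLAST
build's numbers; composition-based adjustment is not implemented. Alignment
ties break deterministically (smaller query start, then subject start, then
fewer columns; diagonal moves preferred within a path).

Precomputed hits in the 12-column BLAST tabular dialect can replace the
built-in aligner. Query coordinates in that format are nucleotide positions
on the forward strand with start > end marking reverse-strand hits, which
preserves the reading frame across an export/import round trip; subject
coordinates and all internal coordinates are 1-based inclusive amino acids.

## Ortholog hit ratio

OHR = (non-gap query residues in the translated top-hit alignment) /
(subject protein length). The numerator is counted in translated residues,
not nucleotides, because the denominator is a protein length - nucleotide
counting would inflate OHR about threefold. OHR can exceed 1 when the
subject side of the alignment is heavily gapped; values are reported
uncapped with a warning above 1.2. Summary fractions (> 0.5, > 0.7) use
each query's top hit only. N50 is the shortest contig length at which the
descending cumulative length reaches half the total.

## Read and contig filters

Pre-assembly read QC rejects whole reads (no trimming): length < 40 nt; any
ambiguous base; mean per-base error probability (mean of 10^(-Q/10)) above
0.01, i.e. a mean quality worse than Phred 20 on the error-probability
scale. The threshold is boundary-inclusive (an all-Q20 read is kept).
Discards are attributed to the first failing rule in the fixed order
length -> ambiguity -> quality so counts are reproducible. Assembled contigs
shorter than 150 nt are dropped before any analysis.

## Synthetic data generator

The generator produces the study conditions every end-to-end test runs
under: 20 families by default, each anchored by one random founder protein
(220-320 aa, methionine-initiated) with clans assigned round-robin
(CYP2, mitochondrial, CYP3, CYP4); per family 1-10 true genes - gene 1 an
exact reverse translation of the founder with uniform synonymous codon
choice, the rest paralogs substituted to 85% amino-acid identity (always
verified to top-hit their own founder). Each gene emits either a full-length
transcript or, with probability 0.5, two subject-disjoint fragments
(>= 90 aa each, >= 20 aa apart, anchored at the protein's ends); with
probability 0.2 an additional isoform copy at 97% observed nucleotide
identity; plus 50 junk contigs of 150-240 nt. Transcripts are emitted on a
random strand and optionally carry uniform per-base substitution errors.

Three generator choices keep the truth exactly recoverable on clean data and
are deliberate idealisations:

- fragment boundaries avoid a methionine in the first 10 aa of non-initial
  pieces, so a downstream fragment can never present as a complete ORF;
- isoform divergence is synonymous-only, so an isoform never changes its
  cluster's ORF call, and `isoform_nt_identity` describes the *observed*
  identity between sibling contigs (the synonymous budget is reduced by
  2 x base_error_rate when noise is on);
- one reference protein per family, isolating merge logic from top-hit
  ambiguity.

Real assemblies violate all three (genuine alternative splicing, non-silent
allelic variation, many confusable reference paralogs), as well as carrying
indels and chimeric contigs the generator never emits. Passing recovery
tests therefore demonstrate the correctness of the census logic under its
own assumptions, not field accuracy on real data.

Isoform candidate pairs are pre-screened by shared 15-mers (on either
strand) before exact alignment, as CD-HIT-style clusterers do. By
pigeonhole, two sequences of length L with d mismatches share a conserved
15-mer whenever (L - d)/(d + 1) >= 15, which holds for any pair near the
95% threshold at census-eligible lengths (>= 250 nt), so the screen cannot
miss a decidable pair; it merely avoids quadratic alignment work.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `e_max` | 1e-3 | translated-search significance cut-off |
| `contig_min` | 150 nt | assembly contig filter |
| `census_min` | 250 nt | census eligibility filter |
| `isoform_identity` | 0.95 | nt identity to merge isoforms |
| `isoform_coverage` | 0.80 | aligned fraction of shorter transcript |
| `min_overlap` | 15 aa | subject-overlap tolerance (1 = literal) |
| `overlap_frac` | 0.10 | overlap tolerance as fraction of shorter interval |
| gap open/extend | 11 / 1 (aa), 5 / 2 (nt) | affine gap costs |
| lambda, K | 0.267, 0.041 | gapped BLOSUM62/11-1 statistics |

## Problem sizes and numerical choices

End-to-end recovery experiments use 20 families (about 100 genes and 240
contigs against a 20-protein reference), a scale chosen so that the
exhaustive aligner keeps a full recovery run in seconds on one core while
still exercising every census rule; the same code path handles larger
inputs, for which precomputed hit tables are the intended route. Degenerate
inputs are defined: empty FASTA warns and returns an empty collection; an
empty best alignment has score 0; OHR and N50 of empty inputs are
missing/error respectively; fragmenting a too-short protein falls back to a
full-length transcript with a warning. The read-quality boundary is
inclusive within a 1e-9 relative float tolerance.

## Known limitations

- E-values are not comparable to NCBI BLAST output (no composition-based
  statistics, no hit chaining across frames, stops not split).
- The census counts are minima by construction; fragment chains can join
  fragments of different genes that tile compatibly, which preserves the
  count but mixes provenance within a chain.
- No frameshift-aware alignment: an indel-bearing transcript may split its
  hit and be counted as two fragments.
- Keyword selection inherits any annotation errors in the reference
  description/family table.
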