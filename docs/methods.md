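# Methods

## Depth model

Coverage for one chromosome is accumulated in a diff array: for every
reference-covering segment of every kept alignment, +1 is recorded at the
segment's start position and −1 one past its end; a cumulative sum then yields
per-base depth. The running sum is a 64-bit integer; the stored per-base value
is `min(depth, 32767)`, the int16 maximum, so a pathological pile-up cannot
overflow and positions downstream of a capped locus remain exact.

CIGAR semantics: `M`, `=` and `X` place read bases on the reference and
contribute coverage; `D` and `N` consume reference without coverage and split
the read into separate covering segments; `I`, `S`, `H` and `P` consume no
reference. The choice that deletion (`D`) bases are *not* covered matches
per-base pileup semantics in the htslib ecosystem; a flag
(`--count-deletions-covered`) flips it, since reasonable tools differ.

Alignment filter: unmapped, secondary, duplicate and QC-fail records are
skipped; supplementary alignments are kept because split reads genuinely
contribute depth. There is no mapping-quality floor by default (`--min-mapq`
raises one). Reads overhanging the chromosome end are clamped with a warning
rather than rejected.

All medians over integer depths use the lower-median convention for
even-length inputs (element at index `(n−1)//2` after sorting), keeping
results integral and deterministic; tie handling is otherwise undefined for a
median of integers.

## Fold-change statistics

For an SV with 0-based half-open affected interval `[start, end)`:

- **DHFFC** = median depth over `[start, end)` divided by the median of the
  pooled multiset of depths over `[start−1000, start)` and `[end, end+1000)`,
  each flank clamped to chromosome bounds. Pooling the flanks (rather than
  averaging two per-side medians) keeps the statistic well defined when one
  flank is truncated at a chromosome end. Zero-depth flank bases are
  included: masking gaps would silently change what the denominator measures.
  The 1,000-base flank default is large enough to estimate local coverage yet
  small enough to avoid commonly unsequenced regions.
- **DHBFC** = median depth over `[start, end)` divided by the expected depth
  of reference windows whose GC content matches the event's own reference
  sequence. Windows are non-overlapping 250-base tiles of the same
  chromosome; the trailing partial tile is dropped, and tiles with more than
  10% ambiguous (N) bases are excluded. GC is computed over non-N bases.
  Windows are grouped in GC bins of width 0.05 (values at an exact bin edge
  land in the upper bin; GC = 1.0 in the top bin). A bin answers directly
  when it holds at least 5 windows; sparser queries fall back to the nearest
  adequately occupied bin, then to the nearest occupied bin, ties broken
  toward lower GC — this stops a single noisy window from defining an
  expected depth on small genomes.

Both statistics use medians so that modestly inexact breakpoints perturb the
value by at most the few depth values entering or leaving the interval.

VCF coordinate normalization: for symbolic alleles with INFO `END = e`, the
affected interval is `[POS, e)` in 0-based terms — the padding base at POS is
excluded. Without `END`, `|SVLEN|` supplies the length; for sequence-resolved
deletions, `len(REF) − 1` does. Records with no resolvable positive-length
interval, and spanless types (INS, BND), receive missing values. Inversions
and CNV records get fold-changes (they have a defined span), though an
inversion is expected to be copy-neutral.

Missing values are written as the VCF missing marker, and filtering always
retains records with missing annotations: absence of depth evidence must not
delete a call. Threshold comparisons are strict (`DHFFC < 0.7`,
`DHBFC > 1.3`); boundary values fail the filter. Both conventions are
exposed as parameters.

Output: the two statistics are written as `Number=1` Float FORMAT fields
(`DHBFC`, `DHFFC`) on the selected sample only, rounded to 3 decimals; all
pre-existing record content is preserved. One sample is annotated per run;
the sample column is chosen by explicit selector, else a unique read-group SM
match, else column 0 of a single-sample VCF — ambiguity is an error, never a
guess. Chromosomes are processed sequentially and the depth profile and GC
table are built exactly once per chromosome, so run time is nearly
independent of the variant count.

## Evaluation machinery

`confusion_metrics` computes precision `tp/(tp+fp)`, recall `tp/(tp+fn)`,
F1 (harmonic mean) and FDR `fp/(tp+fp)` from supplied confusion counts,
raising a named error on zero denominators. Which calls count as tp/fp/fn is
an input labeling (from the fixture generator or an external interval
matcher); interval matching itself is out of scope. `roc_and_auc` sweeps
sensitivity/specificity over all distinct score thresholds, placing tied
scores in a single step; the trapezoidal AUC then equals the
pairwise-comparison rank statistic with ties counted ½, which the tests
verify by exhaustive pair counting and against scikit-learn.
`summarize_filter_effect` reports the percentage of false positives removed
and true positives retained by a filter, rounded to whole percentages.

## Synthetic fixtures

The generator emulates exactly the signal the statistics read: a single-
chromosome diploid genome at uniform coverage with copy-number multipliers
inside events — 1 remaining copy for a het deletion (0.5× depth), 0 for a hom
deletion, 3 for a het duplication (1.5×), 4 for a hom duplication (2×).
Defaults: haploid coverage 15 (diploid 30×, typical of a modern short-read
genome), read length 100, deterministic tiling layout, uniform 50% GC.

- *Tiling layout*: for each run of constant target depth `d`, `d` abutting
  read tilings are laid across the run (the last read truncated at the run
  boundary), giving exactly depth `d` at every base — fold-changes come out
  as exact rationals, which is what makes AUC = 1.0 and DHFFC = 0.500 sharp
  test expectations rather than approximations.
- *Poisson layout*: read starts are drawn uniformly over the run widened by
  one read length on the left and clipped to the run, making each base's
  depth exactly Poisson with mean `d`, with no edge ramps.

Reference sequences hit per-stratum GC targets by construction (exactly
`round(gc·n)` G/C bases, shuffled), so realized GC is within half a base of
the target. Reads are unpaired, all-`M`, constant quality — depth is the only
signal the method uses — with an option to rewrite reads as `M-D-M` to
exercise the segment-splitting path.

Null events: for every 0/1 or 1/1 event, a homozygous-reference event of the
same type and length is placed uniformly at random over all feasible starts
inside supplied high-confidence regions; placements with more than 10% N are
rejected and redrawn (up to 1,000 draws, then an error naming the variant).
When `write_fixture` builds the regions itself, it uses the chromosome minus
the event intervals padded by the flank length: on a synthetic genome a null
overlapping or flanking into a real event would inherit that event's depth
signal and stop being copy-neutral truth. Uniform placement is the
operationalization of "similar genomic distribution"; it does not reproduce
the clustering of real SVs.

What the generator does **not** model: sequencing error, fragment-size and
pairing structure, mappability and repeat-driven coverage dips, GC coverage
bias (coverage is independent of GC, so DHBFC's GC matching is exercised
structurally, not corrected against a real bias), and discordant-pair or
split-read breakpoint signals. Passing tests therefore demonstrate
correctness of the statistics and plumbing on idealized coverage, not
performance on real genomes.

## Problem sizes and numerical choices

Tests run on 2–40 kb chromosomes at 30×; the genotype-recovery test uses a
~330 kb chromosome holding 20 events per genotype class per SV type (1 kb
events, 3 kb spacing) plus matched nulls — small enough to run in seconds
while giving every class a non-trivial sample. The acceptance script uses a
40,000-read pile-up (to cross the 32,767 cap) and a 20 kb / 30× deletion
fixture. Fold-changes are floats; equality assertions on them are exact only
because tiling fixtures produce integer plateaus. The GC-bin index adds a
1e-9 epsilon before flooring so exact bin-edge fractions (e.g. 0.6/0.05) do
not land one bin low through floating-point division.

## Known limitations

- Per-chromosome GC tables: expected depths come from the variant's own
  chromosome, matching the sequential per-chromosome processing; on a genome
  with strong inter-chromosome coverage differences this is a feature, on a
  tiny contig it can leave bins sparse (mitigated by the occupancy fallback).
- No LOESS/regression GC correction, no mappability correction, no
  re-genotyping, no SNV allele-balance annotation, no breakpoint refinement.
- Single-sample annotation per pass; multi-sample VCFs are supported but only
  the selected sample's FORMAT column gains fields.
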