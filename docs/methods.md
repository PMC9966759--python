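# Methods

## Input model and quality filter

The unit of analysis is an in-frame CDS: frame starts at base 1, alphabet
A/C/G/T/N (U is mapped to T on input). Sequences whose length is not a
multiple of 3 are kept, with the trailing 1–2 bases ignored by all codon
counting and a warning emitted — transcriptome CDS calls are often
frame-truncated at the 3' end, and silently discarding such records would
bias composition statistics.

The quality filter removes a record when (a) its length is below 200 bp,
(b) its N fraction over the whole sequence exceeds 10%, or (c) it has
more than one in-frame stop codon strictly before its final codon. Two
readings were open: the N rule is applied to the whole sequence (we do
not distinguish internal from terminal N — the simplest testable
convention), and the terminal codon is never counted as an internal stop,
since a trailing stop is the expected end of a complete CDS. Each failing
record is tallied once under the first rule it fails, in the fixed order
short → N → stops, so reports are deterministic and the tallies plus the
pass count always equal the input count.

## Composition statistics

Base fractions are computed per codon position over complete codons, with
N excluded from numerator and denominator. Dinucleotide usage is
summarised at the 1–2, 2–3 and 3–1 codon-position junctions; 3–1 pairs
join codon *i* to codon *i+1* within a gene and never wrap across gene
boundaries. The expected frequency of a dinucleotide is the product of
the marginal base frequencies on the two sides of its junction, computed
from the same counted pairs, so observed frequencies sum to 1 and the
equal-usage reference per dinucleotide is 1/16. Genome-wide summaries
pool codons across genes (not per-gene averages); per-gene values are
available by calling the same functions on single-record lists.

## RSCU

RSCU_ij = x_ij /((1/n_i) Σ_j x_ij) within each synonymous family, with
Leu, Ser and Arg treated as single six-fold families (the CodonW
convention). Families that never occur in a gene yield NaN, never 0 — a
zero would claim observed avoidance that the data cannot support. Met and
Trp are reported as exactly 1.0 when present and are excluded from all
bias summaries. Pooled (genome-level) RSCU is computed on summed counts,
not by averaging per-gene RSCU; the two differ whenever gene lengths or
compositions vary. The 1.5/0.5 (literature) and 1.25/0.75 (display)
preferred/avoided thresholds are configuration, not hard-coded.

## ENC

Wright's estimator: for each amino acid observed n ≥ 2 times, codon
homozygosity F = (n Σp_j² − 1)/(n − 1); class means F̄_k over the 9
two-fold, 1 three-fold (Ile), 5 four-fold and 3 six-fold amino acids,
using only defined, positive F (F ≤ 0 can occur at small n and would make
1/F̄ meaningless); ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at 61
against sampling noise. When Ile is absent, F̄₃ is replaced by
(F̄₂ + F̄₄)/2 (Wright's fallback); when F̄₂, F̄₄ or F̄₆ cannot be
estimated the gene's ENC is undefined (NaN) and excluded from downstream
plots, with the exclusion count logged by the pipeline. On realistic gene
lengths (~160 codons) this affects on the order of 1% of genes.

The mutation-only expectation is ENC_exp(s) = 2 + s + 29/(s² + (1 − s)²)
evaluated on 1000 GC3 values equally spaced in [0.001, 1.000]. Note the
curve *peaks* near s = 0.5 (60.5; usage is least biased at balanced
composition) and falls to 31/32 at the extremes; it is symmetric about
0.5 only after removing the linear +s term. The deviation ratio
(ENC_exp − ENC_obs)/ENC_exp measures each gene's shortfall below the
curve at its own GC3.

**GC3 convention.** GC3 used with ENC is computed over *synonymous* third
positions — stops and the single-codon amino acids Met (ATG) and Trp
(TGG) excluded (CodonW's "GC3s"). Including Met/Trp would pin ~10% of
third positions at G regardless of mutation pressure, compressing GC3
toward the centre and breaking the 1:1 correspondence between the
mutation parameter and realised GC3 that the ENC expectation assumes.
The composition module separately reports plain GC3 over all complete
codons for descriptive tables.

## Protein indices

GRAVY is the mean Kyte–Doolittle hydropathy over translated residues;
aromaticity the fraction of Phe/Tyr/Trp. Codons containing N are skipped;
internal stops are skipped with a warning. The full 20-component
amino-acid profile is retained for the correlation screen.

## Multivariate analysis and correlation screen

PCA is performed on the genes × 59 RSCU matrix (61 sense codons minus
Met/Trp), centred per codon but not variance-scaled — RSCU values already
share a common scale by construction. NaN entries (absent families) are
imputed with the neutral value 1.0, which adds no spurious variance
direction; excluding such genes instead is available by filtering before
the call. Component signs are fixed deterministically: PC1 is oriented to
correlate non-negatively with GC3, later components by making their
largest-magnitude loading positive, so repeated runs and row
permutations give identical outputs.

The correlation screen relates ENC, PC1 and PC2 to GC3, log₂(FPKM + 1),
GRAVY, aromaticity and the first 3 PCs of the amino-acid profile matrix.
Pearson correlation on log-transformed expression is the default (matching
the R²-style reporting conventional in this literature); Spearman is a
config option. Missing values are deleted pairwise with the n per pair
reported, and Benjamini–Hochberg adjusted p-values accompany the raw ones.

## GC-conservative preferred-codon test

The 17 pairs are found by scanning the standard genetic code for
synonymous codons identical except for a third-position A↔T or C↔G swap:
two pairs for each of the five four-fold families and each of the three
six-fold families' four-fold boxes, plus Ile ATA/ATT. Per gene and pair,
relative usage = count(a)/(count(a) + count(b)), defined only when the
pair occurs; it is invariant to any composition shift multiplying both
codons equally. Per pair, relative usage is correlated across genes with
log₂(FPKM + 1); a preferred codon is called at |r| > 0.05 and p < 0.001
(both thresholds configurable). Pairs with fewer than 3 usable genes are
reported without a call; a constant expression vector yields a warning
and no calls. At n ≈ 2000 genes the p-threshold binds (it corresponds to
|r| ≈ 0.074), so the per-pair null call rate is ~0.001.

## Subset comparison

Each labelled family is compared with the unlabelled background by
two-sided Mann–Whitney U tests on ENC and on GC3 (a rank test makes no
normality assumption about either distribution); medians and n are
reported, and families with fewer than 3 usable genes get no test.

## Synthetic-data generator

The generator is the package's ground-truth instrument. Per gene: length
(in residues) lognormal with mean CDS length 489 bp including the
terminal stop (a typical insect-transcriptome mean), sdlog 0.45, floored
at 67 residues so clean genes always clear the 200 bp filter; FPKM
lognormal (meanlog 1.0, sdlog 1.5, a realistic several-decade spread);
per-gene third-position GC preference s ~ Beta(2, 2), wide enough to
trace the ENC–GC3 curve over most of its range. Residues are drawn
independently from a uniform amino-acid profile (configurable); within a
family, each available third base gets weight s/2 (G or C) or (1 − s)/2
(A or T), renormalised — so the expected synonymous GC3 equals s for
every family except Ile (whose single GC option gives s/(2 − s), a small
distortion). Under selection strength S > 0, codons in the preferred set
(default: the C-ending member of the C/G pair of each four-fold family)
receive an extra factor exp(S·z) where z ∈ [0, 1] is the gene's
expression rank, making preference grow monotonically with expression.
S = 2 puts the planted pairs' usage–expression correlation near r ≈ 0.4
at n = 2000, comfortably above the call threshold while leaving the other
12 pairs untouched (relative usage is scale-invariant within a pair).
Codon choices are independent across residues, matching the independence
assumptions of every downstream statistic.

What the generator does **not** emulate: amino-acid composition bias,
dinucleotide/neighbour dependence (e.g. CpG avoidance), isoform
redundancy, assembly artifacts, length–expression coupling, or selection
acting through anything but the planted codon set. Passing tests
therefore demonstrate correctness of the statistics and the
detectability logic under the stated model, not robustness to every
property of real transcriptomes.

Corrupted records are appended, each failing exactly one filter rule:
150 bp clean (short), 300 bp with 15% N (N-rich), 300 bp with 3 internal
stops (multi-stop) — and a record with exactly one internal stop is used
in tests to confirm the filter keeps it.

## Problem sizes and numerical choices

The validation suite runs the caller on 50 mutation-only and 20
planted-selection replicates of 2000 genes — enough that the binomial
bounds on false/true call counts are sharp (expected null total ≈ 0.85
calls over 850 pair-tests) while the whole suite stays fast. Oracle
equivalence uses 500 genes against from-definition reference
implementations at 1e−9. Ties in PCA signs are broken as described
above; correlations on constant vectors are reported NaN rather than 0;
all tables are written with a fixed float format so reruns are
byte-identical.

## Known limitations

- ENC is undefined for genes missing whole degeneracy classes; very short
  genes are noisy even when defined (the estimator is bias-corrected but
  not variance-free).
- The preferred-codon test conditions on pair occurrence; genes that never
  use a pair carry no information about it, so power varies across pairs
  with amino-acid composition.
- Neutral imputation of absent families slightly shrinks PCA variance for
  short genes with many absent families.
- Expression enters only as a single FPKM column; replicate libraries
  should be averaged (or otherwise summarised) upstream.
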