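# Methods

## The expanded alphabet

The core alphabet has twelve symbols: A, C, G, T; the modified cytosines
m (5mC), h (5hmC), f (5fC), c (5caC); and the guanines paired with each
modified cytosine, numbered 1–4 in the order of TET oxidation
(G:5mC = 1, G:5hmC = 2, G:5fC = 3, G:5caC = 4). Treating each symbol as a
base *pair* makes complementation a lossless involution (m ↔ 1, h ↔ 2, …)
and lets a single sequence represent hemi-modification: `m1` is a fully
methylated CpG, `mG` plus-strand-only methylation, `C1` minus-strand-only.

Eight ambiguity codes capture assay uncertainty: w = {f, c},
x = {m, h}, y = {C, f, c}, z = {C, m, h, f, c}, with complements 6–9 on the
guanine side. The symbol table is configurable so other modifications
(5hmU, 6mA) could be added, but none ship by default.

**Soft-masking.** Lowercase a/g/t are accepted as masked variants and
survive complementation. Lowercase `c` cannot be, because `c` *is* the
5caC symbol; core-symbol identity takes precedence. Consequently the
genome builder uppercases masked `c` on input (so the modified FASTA never
contains a spurious 5caC), and the complement of masked `g` is emitted as
unmasked `C`. This is the only place masking is not preserved.

## Modification calling

Input records follow the shape of consistent maximum-likelihood estimators
for two-channel bisulfite data: per position and strand, a 5mC level *m*,
a 5hmC level *h* (each in [0, 1], *m* + *h* ≤ 1), and a conflict count.
A simplified two-channel combiner is provided (`combine_channels`): with
WGBS estimating *m* + *h* and oxWGBS estimating *m*, the 5hmC level is the
non-negative excess, and a negative excess flags a conflict. It is a
deliberately simple consistent-estimator stand-in with the same output
contract as the full maximum-likelihood method.

Calls against a threshold *t* ∈ (0, 1], on the plus strand:

| condition                  | call |
|---------------------------|------|
| conflicts > 0             | z (irrespective of levels) |
| m ≥ t and h ≥ t           | x    |
| m ≥ t                     | m    |
| h ≥ t                     | h    |
| m + h ≥ t                 | x    |
| otherwise                 | C    |

The x call for *m* + *h* ≥ *t* uses the reasoning that if *t* suffices to
call either modification alone, the sum reaching *t* suffices to call
"methylated or hydroxymethylated". When both levels clear *t*
simultaneously (possible only for *t* ≤ 0.5) neither modification can be
confidently disambiguated, so x is the conservative call; note this means
the set of positions called specifically m is not monotone in *t* (a
position can move x → m as *t* rises), while the set of *modified*
positions (anything ≠ C) is monotone, since "modified" is equivalent to
*m* + *h* ≥ *t*. Minus-strand records must sit on the reference G and
receive the complement symbol. With a single bisulfite channel, modified
calls are x/7 (optionally relabelled m/1 for convenience, as most such
positions are simply methylated).

The builder emits one BED track per symbol containing exactly the
rewritten positions; reapplying the tracks to the unmodified assembly
reproduces the modified FASTA byte-for-byte (tested). The y/w symbols are
never produced (no input channel distinguishes f from c) but are accepted
in sequences. Records at the same (chrom, pos, strand) are merged
first-wins by default, or by maximum total level on request. Processing is
per-chromosome, so peak memory scales with the largest chromosome.

## Motifs and scanning

Motifs are column-stochastic matrices over the 12 core symbols, built from
extended-IUPAC strings (standard degeneracy codes plus the modification
ambiguity codes, each expanding uniformly). Scanning uses log-odds
scores log2(Pr(b)/f(b)) after pseudocounting m′ᵢⱼ = mᵢⱼ + α·bⱼ and
renormalizing columns. The best site per region maximizes the window
score over all offsets on both strands (reverse strand = the
reverse-complemented motif under the expanded complement map). Windows
containing ambiguity symbols (x, z, 7, 9, …) are unscorable (−∞): their
match probability is undefined, and excluding them is conservative.

Numerical tie handling: the two strand scans sum identical terms in
different orders, so scores within 1e−9 bits are treated as tied; the
reported best site takes the smallest offset, then the forward strand.
For positional tallies, a tied best score is split fractionally across its
offsets, which keeps the central-enrichment statistic unbiased; the
binomial test then uses ⌈n_central⌉, a conservative rounding. The default
site score threshold is 5 bits (a conventional scanning default),
configurable.

## Relative-entropy equalization

The relative entropy (Kullback–Leibler divergence) of a motif against a
background is D_RE = Σᵢ Σⱼ mᵢⱼ log2(mᵢⱼ/bⱼ). Modified symbols have far
smaller background frequencies than C/G, so an identical motif shape gets
sharper scores after modification — a confound, not a signal. To equalize
information content, the unmodified member of every hypothesis pair uses
the fixed pseudocount 0.1, and the modified member's per-position α solves

    1 + α·b_m·log2((1 + α·b_m)/b_m) = 1 + 0.1·b_u·log2((1 + 0.1·b_u)/b_u)

for a hemi (single-position) modification, or the two-position sum for a
complete modification. The per-position entropy terms here are evaluated
on the *unnormalized* pseudocounted entries (column sums 1 + α) and only
on entries where the raw motif frequency is positive; under this
convention — with α applied at the modified positions and 0.1
elsewhere — the solved α makes the relative entropy per column of the two
members exactly equal whenever modified columns have unit frequency, which
holds for all consensus-string motifs. For partial modifications of
genuinely mixed columns the equalization is approximate; the solver's
simplifying assumption (modified positions have frequency 1) is then not
met. Scanning, by contrast, always renormalizes columns so probabilities
are well-formed; the motif-wide pseudocount of the modified member is
n_modified_positions × α.

Root finding brackets α in (1e−12, 1e6) and uses a bracketed
bisection/secant hybrid converged to a residual below 1e−10; a pure
bisection implementation is kept in the test suite as an independent
oracle. The symmetric case b_m = b_u recovers α = 0.1 exactly.

## Central enrichment

All regions share one length L (summit-centred, width 500 by default;
regions truncated at chromosome edges are dropped and counted). For a
motif of width w there are L − w + 1 offsets; under the positional null
the best site is uniform over them, so the count landing within a central
window of r offsets is Binomial(n_scored, r/(L − w + 1)). Candidate
region widths are the odd values in [min_region, max_region] (defaults
99–100, hence a single width, 99); the smallest raw p-value wins and is
multiplied by the number of widths tested (capped at 1). Sequences with
no window above the score threshold are excluded from n_scored; if none
score, the result is flagged "no sites" with p = 1.

The binomial tail is computed by log-sum-exp over the upper pmf terms, so
p-values far below float underflow (1e−4000 and beyond) retain exact
logarithms — preference scores are differences of log10 p-values and
routinely reach hundreds or thousands.

## Scores, aggregation, classification

score = log10 p_adj(unmodified) − log10 p_adj(modified); positive favours
the modified motif. Scores are clipped to ±4000 for display only.
Replicate scores for the same (factor, motif, pattern) aggregate to the
maximum absolute value (first occurrence wins ties). Ranking keeps the
top-1 or top-3 pairs by the more significant member, min(p_unmod, p_mod)
— the choice of member is not dictated by the score definition, so the
more significant one is used — dropping pairs with min p ≥ 0.05. Motifs
partition into unmodified-preferring (score < −ε), modified-preferring
(score > ε) and neutral (|score| ≤ ε), with ε = 5. Factor-level
classification applies, in order: all scores negative → unmodified-only;
upper-quartile score ≥ 0 → modified-predominant; all scores within
[−50, 50] and not all positive → no clear preference; otherwise mixed.
Quartiles use the inclusive-median (Tukey hinge) convention; the
first-match-wins order plus an explicit "mixed" catch-all makes the
(non-exhaustive) grouping deterministic.

## Threshold grid search

The default grid is t = 0.01 … 0.99 in 0.01 steps. Regions are extracted
from the *modified* genome, so nothing except input parsing can be shared
across thresholds; each threshold rebuilds, re-extracts and re-scores.
Thresholds are independent work units and results are identical regardless
of evaluation order.

## Synthetic data

The generator emulates the statistical shape of the real inputs:
i.i.d. background sequence at a chosen GC fraction (default 0.42,
mammalian-like); non-overlapping peaks laid on a grid of cells with random
in-cell offsets; one motif instance planted per selected peak, centred on
the summit with Gaussian jitter (sd 10 bp); modified plants draw per-CpG,
per-strand levels from Beta(8, 2) (mean 0.8 — real methylated CpGs are
mostly highly methylated); background CpGs draw from Beta(1, 20) so
modified symbols occur at low but nonzero background frequency, which the
pseudocount equations require. Everything is reproducible from a single
seed, and a truth table records each plant.

What it does **not** emulate: read-level noise (simulation starts at
per-base level estimates), correlated methylation along the genome, CpG
islands and local GC structure, peak-strength heterogeneity, or motif
degeneracy in the planted instances. Passing recovery tests therefore
demonstrates that the statistical machinery is correct and calibrated on
its own assumptions, not that real datasets of a given size will reach any
particular significance.

Recovery checks use 500 peaks of 500 bp (≈ 300 kb of genome) per
replicate and 20 replicates per direction — sizes chosen so the whole
suite runs comfortably on a laptop while leaving the binomial test deep
in its asymptotic regime.

## Known limitations

- f/c (formyl/carboxyl) hypothesis patterns are supported by the editing
  machinery but not generated by default; no default caller produces them.
- The per-site score threshold is a fixed bit threshold, not a
  p-value-calibrated one.
- Ambiguity symbols in scanned sequences are unscorable rather than
  marginalized over their expansion; windows covering them never count.
- The combinatorial per-CpG hypothesis mode grows as 6^k and is capped
  (default 10 000 pairs); the default mode applies one pattern uniformly
  to all CpGs.
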