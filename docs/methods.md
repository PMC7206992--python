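# Methods

`wgdkit` re-implements, as a tested pipeline, the comparative-genomics
workflow used to detect and date ancient polyploidies from gene colinearity
and synonymous divergence, and to characterize what happened afterwards:
biased gene loss (fractionation) and unbalanced expression between the
duplicated subgenomes.  Every stage can be exercised against a synthetic
genome-history generator whose ground truth is recorded, so the package is
validated by parameter recovery rather than by fixtures.

## The model

A clade of genomes descends from a common ancestor through speciations and
whole-genome duplications (WGDs; multiplicity 2 = tetraploidization,
3 = hexaploidization).  The default study clade mirrors a core-eudicot
setting: a grape-like reference **V** retaining the ancient hexaploidy
(called ECH here) most plainly, a coffee-like genome **C** with no further
duplication, a lettuce-like lineage **L** with its own triplication, and two
Apiaceae-like lineages **D** (carrot-like, fast-evolving) and **X**
(coriander-like, slow-evolving) sharing two nested tetraploidizations
**A-beta** (58 Mya) and **A-alpha** (48 Mya) before splitting 26 Mya.

For two coding sequences, synonymous divergence Ks is estimated by the
Nei–Gojobori (1986) method: synonymous site counts from the fraction of the
three possible changes per position that preserve the amino acid,
differences averaged over all minimal substitution pathways between
differing codons (pathways through stops excluded; codon pairs whose every
pathway crosses a stop are dropped from both site and difference counts),
and the Jukes–Cantor correction `Ks = -(3/4) ln(1 - (4/3) ps)`.  Estimates
with fewer than 30 aligned codons are flagged `too_short`; `1-(4/3)ps <= 0`
is `saturated`.  Codon pairing uses a protein-level global alignment
(BLOSUM62, gap open -10, extend -0.5) back-translated to codons; equal-length
sequences (the simulator produces no indels) are paired directly.

Duplicate pairs created by one WGD share a Ks peak at
`2 * r * T` where `T` is the event age and `r` the lineage's substitution
rate per Mya.  Because lineages differ in `r`, the same event appears at
different Ks in different genomes.  The pipeline:

1. infers colinear blocks from homologous gene pairs (below),
2. estimates anchor-pair Ks and smooths each sample with a Gaussian kernel
   of width 0.05 on a uniform grid over [0, 3],
3. decomposes the curve into Gaussian components by nonlinear least squares,
4. aligns lineages on a shared event: `lambda_i = mu_ref,shared / mu_i,shared`
   rescales lineage-i Ks onto the reference clock (paralog Ks times
   `lambda_i`; ortholog Ks times the mean of the two lambdas, assuming equal
   branch shares since the split),
5. re-aligns the faster of two lineages that share a later event on that
   event, with the slower as reference (a single multiplicative factor
   cannot fix a rate change that postdates the first shared event),
6. converts corrected peaks to ages through an anchored calibration:
   `r_ref = mu_anchor / (2 T_anchor)`, `T = mu' / (2 r_ref)`, with a
   +/- one-component-sigma interval.

## Colinearity

Blocks are maximal-scoring chains of anchor pairs, strictly monotone in
gene rank on both chromosomes (same and inverted orientation handled
separately), with at most 50 intervening genes between consecutive anchors
— the gap unit is genes, not base pairs.  Chain score is the sum of anchor
homology scores; the chain DP is windowed on the first axis (the gap bound
caps the predecessor range), and chains are extracted greedily per
chromosome pair, each anchor usable once per orientation.  Blocks with
fewer than 5 anchors are discarded.  Single-linkage homology families
larger than 30 genes are removed before chaining.  The DP is verified
against brute-force enumeration of all monotone chains on small instances.

Gene duplicate classes follow the precedence WGD (block anchor) > tandem
(adjacent homolog) > proximal (homolog within 10 genes) > dispersed >
singleton.  Orthology depth per reference gene counts covering block
*regions*, not retained genes, so a locally deleted ortholog still counts
as covered — this is what makes a heavily fractionated tetraploid still
show a 1:4 correspondence.

## Mixture decomposition and component-number choice

The fit is least squares of a Gaussian sum to the *density curve* (not EM
on the raw sample), with means initialized at curve maxima, sds at three
bandwidths, and component sds bounded below by half a bandwidth.  Fits for
k components are additionally warm-started from the (k-1)-component
solution by splitting each of its components in turn; the best R² wins.
Without the warm starts, three-component fits of heavily overlapping
peak triples routinely fall into merged local optima.

Component number is chosen automatically as the smallest k that reaches
R² >= 0.95 *and* whose residual sum of squares is not reduced by a factor
of 20 or more by one further component.  The second condition is essential:
two tetraploidization peaks 0.2 apart with sd ~0.1 leave a single Gaussian
at R² ~ 0.97 — above the floor — yet a second component cuts the residual
more than 100-fold, while for a genuinely single-peaked curve an extra
component buys well under a 10-fold reduction (measured across seeds).  A
plain "smallest k with R² >= 0.95" rule would merge exactly the peak pairs
this analysis exists to separate.  When the expected event count is known
(e.g. three events in a coriander-like self sample), the pipeline fixes k;
for a single-event reference sample it selects automatically and uses the
principal (largest-weight) component to represent the event, since a
skewed single peak legitimately attracts a minor tail component.

## Event table, fractionation, loss epochs

The reference-anchored table lists every reference gene as a row; the
reference contributes `m_ref` columns (the gene and its older-polyploidy
paralogs, filled from reference-self blocks) and each genome g contributes
`m_g` ortholog columns per reference column — 3 x (1 + 1 + 3 + 4 + 4) = 39
columns in the five-genome configuration.  Orthologous blocks are
partitioned into `m_g` non-overlapping layers per reference chromosome by
greedy interval scheduling (largest blocks first), with an affinity rule:
a block preferentially joins a layer already holding its target chromosome,
because fragments of one chromosome descend from one subgenome.  More than
`m_g` mutually overlapping layers raise an error (mis-grouped events).
Four-fold layers are grouped into sibling pairs by the median divergence of
co-row gene pairs across layers (the pairing with the lowest within-pair
divergence corresponds to the youngest event).  Missing cells print as `.`.

Loss epochs are read per row by Dollo parsimony on the column hierarchy:
each maximal all-missing subtree is one loss event in the epoch of its root
edge (all columns missing -> before A-beta; one A-alpha sibling pair ->
between the events; a single column -> after A-alpha).  Both event counts
and missing-cell counts are reported, since per-gene and per-event
accounting differ.  Note the intrinsic confusion channel: two independent
same-epoch losses of both siblings are merged by parsimony into one
older-epoch event, at rate ~ f/(2-f) for per-copy loss fraction f — the
single-epoch validation scenarios therefore plant modest loss (f = 0.04)
so this stays near 2%.

Deletion-run lengths are maximal missing runs inside block-covered
reference intervals; runs truncated at a coverage boundary are excluded
from fitting (right-censoring ignored; the bias is negligible at the run
counts used).  The geometric model on support {1, 2, ...} is fitted by
MLE `p = 1/mean`, with asymptotic standard error, a chi-square
goodness-of-fit over binned lengths, and both the fraction of runs and the
fraction of removed genes in runs shorter than 10.  Observed runs are
longer than drawn segments whenever two deletions touch, so `p` is
recovered cleanly only while total loss per column is moderate; the
validation scenario uses 15% loss, where recovery is within 10%.

Windowed retention profiles (30-gene windows, step 5) are compared between
sibling columns with a two-sided sign test over windows.

## Expression

Replicate-averaged FPKM with a +1 pseudocount before log2.  A duplicate
pair is diverged in a condition when |log2 ratio| >= log2(2) (threshold
configurable; 1.5x and 3x are reported for sensitivity), and diverged
overall when diverged in any condition.  Subgenome dominance is an exact
binomial test of the higher-copy side among diverged pairs per duplicated
region pair (reference chromosome x sibling columns; regions with fewer
than 10 diverged pairs are skipped).  The one- vs two-copy comparison is a
Welch t-test per condition of log2(FPKM+1) of genes whose duplicate was
lost against the per-pair mean of fully retained pairs.

## The synthetic-data generator

Gene orders: the ancestor has `n_chromosomes x genes_per_chromosome` genes
(default 4 x 800).  Each event copies every chromosome multiplicity-fold;
the epoch after it removes segments whose start genes are uniform and whose
lengths are Geometric(p_loss = 0.3), applied to the *current* (collapsed)
gene order, until the epoch's retained fraction is reached; the last
surviving copy of an ancestral gene is protected (`keep_one_copy`).  Every
draw is recorded in the truth record, together with each extant copy's
subgenome path (e.g. `ECH:2|A-beta:0|A-alpha:1`), the expected Ks peak of
every event per genome (the rate-weighted path integral), and per-pair
divergence events.  Default per-epoch retained fractions (ECH 0.45,
A-beta 0.65, A-alpha 0.6, lettuce triplication 0.55) give coriander-like
final retention.  Loss is epoch-bound: fractionation continuing long after
a speciation is not modelled, so sister lineages that share all events also
share their retention pattern — a deliberate simplification; conclusions
about post-split divergent retention are outside what these simulations
can test.

Sequences: ancestral CDSs are uniform random non-stop codons (300-900 nt).
Along each branch, synonymous substitutions arrive as a Poisson process
with per-codon rate proportional to its current Nei-Gojobori synonymous
site count, each event choosing uniformly among the codon's synonymous
single-nucleotide neighbours; nonsynonymous events run at Ka/Ks = 0.2
(stop-creating changes suppressed).  The dose is applied in segments of
0.05 so rates track composition.  Expected pairwise Ks of two copies is
`2 * r_ref * rate * time`; `r_ref = 0.006`/Mya puts the reference ECH peak
at 1.56.  Per-gene lognormal rate factors (sd 0.15) give peaks realistic
width.  Under this process the NG estimator recovers target Ks within
~1% up to 0.6 and carries a genuine +3.5-4% pathway-counting bias near
Ks = 1; near-saturated pairs are right-skewed by the Jukes-Cantor
transform, which is why event peaks at high Ks attract tail components.

Branch rate multipliers in the default clade span 0.8-1.25 (Apiaceae stem
1.25, X tip 0.92, D tip 1.12, L 0.8, C 1.05), so uncorrected lineages
disagree on shared-event peaks by up to ~15% and the correction machinery
has real work to do.

Expression: base expression per ancestral gene is log-normal
(mu = 1.5, sigma = 1.2 on the log scale); each copy drifts independently
(log-sd 0.8 by default — without drift duplicate copies would be
near-identical and no pair would pass a fold-change rule, unlike real
duplicates); dominant-subgenome copies (A-alpha copy 0 by default) are
multiplied by delta; copies whose sibling was lost by a configurable
singleton factor; per-gene condition effects (log-sd 0.3) and replicate
noise (log-sd 0.15) multiply on top; 4 conditions x 3 replicates.

All randomness flows from one integer seed through separate derived
streams for orders, sequences, rates and expression, so gene orders are
byte-identical whether or not sequences are realized.

## Problem sizes and numerical choices

Validation runs use desk-scale problems chosen for stable estimates: the
dating recovery uses the V/D/X clade at 4 x 800 ancestral genes (~6000
self-pairs per ingroup genome; three-component fits become unstable much
below that), the geometric fit a 6 x 4300-gene single-WGD pair (>= 2000
observed runs at 15% loss), the loss-epoch and expression scenarios
4 x 500 genes.  KDE bandwidth 0.05, fit window [0, 3], grid 601 points;
mixture R² floor 0.95, improvement factor 20, at most 6 components;
curve-fit bounds keep weights nonnegative, means in-window, sds above half
a bandwidth.  Ties in the chain DP break towards more anchors, then the
smaller start rank, then 'same' orientation.

## Known limitations

* No rearrangements (inversions/translocations) in the generator; block
  breakage in real genomes fragments colinearity far more.
* The ortholog Ks correction assumes equal branch shares since the split.
* Dollo epoch counts undercount coincident sibling losses (see above).
* NG (by design) rather than maximum-likelihood Ka/Ks; no
  transition/transversion weighting.
* Date uncertainty intervals are component sigmas mapped through the
  clock, not credible intervals.
* Epoch-bound loss means no post-speciation fractionation divergence
  between sister genomes.
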