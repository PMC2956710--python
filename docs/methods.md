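# Methods

`sagekit` re-implements, as a tested pipeline, the analysis by which a
replicated LongSAGE experiment identifies genes whose expression changes as
LNCaP prostate cancer progresses in vivo from the androgen-sensitive (AS)
stage through response to androgen deprivation (RAD) to castration
recurrence (CR).  This note records the models, the defaults and the design
choices; every empirical number it mentions is computed by the test suite
or by `scripts/acceptance.py`, never asserted from memory.

## Tag extraction and the filter cascade

A LongSAGE library is sequenced as ditags: two 17-base tags ligated
tail-to-tail between NlaIII anchoring sites (`CATG`).  `tagproc` parses
each ditag into two observations (first tag read 5'→3', second
reverse-complemented — standard SAGE orientation; the anchor itself is not
part of the tag string) and applies three per-observation filters:

1. **Bad tags** — any tag containing at least one `N` base call is
   removed.  The rule is "at least one", not "exactly one": an N anywhere
   makes the tag unusable.
2. **Quality factor (QF)** — the probability that all 17 base calls are
   correct, `QF = Π_j (1 − 10^(−Q_j/10))` over the per-base Phred scores
   Q_j.  Observations with QF < 0.95 are removed.  The product-of-call
   probabilities definition follows standard Phred semantics; QF is
   monotone non-increasing in any per-base quality drop (property-tested).
3. **Linker-derived tags (LDTs)** — artifact tags created by linker
   self-ligation, removed by exact sequence match against two configurable
   linker sets (type I and type II).  The linker sequences are
   protocol-specific configuration; two fixed default 17-mers are shipped
   and used consistently by the simulator and the filter.

**Duplicate ditags are counted but not removed.**  The accounting identity

    unfiltered_total = final_total + n_bad + n_below_qf + n_ldt1 + n_ldt2

only balances when duplicates remain in the totals, and the duplicate
percentage divides the *ditag* duplicate count by the post-bad-tag *tag*
total — the one convention under which the published nine-library
composition table is integer-exact (verified by
`test_filter_cascade_accounting_reproduces_published_totals`).  A removal
mode is available for protocols that discard duplicates.

Because all three filter criteria are per-observation and independent, the
filters commute on the observations they jointly pass (tested).

## Tag-to-gene mapping

The canonical tag of a transcript is the 17 bases immediately 3' of the
3'-most `CATG` on the sense strand (sites leaving fewer than 17 downstream
bases fall back to the previous site).  Observed tags are classified
`unique_sense` (exactly one sense gene), `antisense`, `ambiguous`
(multiple sense genes, or hits in both the study and host species),
`host` (host-species contamination, e.g. mouse RNA in a xenograft-style
model), `genomic_only` (present only in a supplied genome sequence) or
`no_map`.  The candidate-gene funnel drops ambiguous and host tags
("relevant" tags), collapses multi-tag genes, drops gene-less tags, and
splits candidates into known and novel against a supplied gene list.

## Exact count-based differential expression

For a tag with count x in a library of N1 tags and y in a library of N2
tags, the null conditional law of y given x is

    P(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

i.e. y | x ~ NegBin(x+1, N1/(N1+N2)).  Tails are evaluated through the
regularized incomplete beta function (`scipy.stats.nbinom` / `binom`)
rather than by naive summation.  The two-sided p-value doubles the smaller
of the two away-from-null conditional tails, P(Y ≥ y | x) and P(X ≥ x | y),
capped at 1.  By the negative-binomial/binomial tail identity both are
tails of Binom(x+y, N2/(N1+N2)) at y, so the combination is
exchange-symmetric — p(x, y, N1, N2) = p(y, x, N2, N1) — and coincides
with the exact conditional binomial test.  (Doubling the min of the
lower/upper tails *both conditioned on x* is not exchange-symmetric; the
symmetric combination was chosen deliberately.)  The implementation agrees
with an exact rational-arithmetic oracle to better than 1e-10 relative
over x, y ∈ {0..50} and size ratios 0.5–2, and the null rejection rate at
p ≤ 0.05 stays below nominal (the test is discrete and conservative).

**Consistency rule.**  Libraries are compared pairwise within each
biological replicate (AS vs RAD, RAD vs CR, AS vs CR).  A tag counts as
consistently differentially expressed at level α only when significant at
α *with the same direction in every replicate*; direction is the sign of
the counts-per-million difference, and ties are direction "none" (never
consistent).  Counts are reported at α ∈ {0.05, 0.01, 0.001} and are
monotone in α by construction.  No multiple-testing correction is applied
by default, matching the raw-threshold design; Benjamini–Hochberg
adjustment is available as an option.

**Trend labels.**  Each consistent tag receives a letter label from a
configurable rule table over the signed significance pattern of the two
stage steps, with net-direction refinements for the non-monotone patterns
(default table in `sagekit.de.DEFAULT_TREND_RULES`, letters A–M), and a
major trend group: 1 up during progression, 2 down, 3 peak at RAD,
4 constant, 5 valley at RAD.

## Poisson-model consensus clustering

Tags entering clustering must have a combined raw count strictly greater
than 10 across one replicate's three libraries and a unique sense mapping.
Counts x over the three stages are modeled as Poisson around rates
λ_j = (Σx)·c_j for a centroid profile c (c_j ≥ 0, Σc = 1); the distance is
the Poisson deviance

    d(x, c) = Σ_j [ λ_j − x_j + x_j ln(x_j / λ_j) ],   0·ln(0/λ) = 0,

and Lloyd alternation with the maximum-likelihood centroid update
(c ∝ summed member counts) monotonically decreases total within-cluster
deviance (asserted per iteration).  Centroid entries are floored at 1e-9
to keep empty stages finite; the distance function is pluggable so an
alternative Poisson-model K-means variant can be swapped in.  "Clustering
over 100 iterations" is realized as 100 random-restart runs whose labels
are aligned by greedy centroid-correlation matching; each tag takes its
modal aligned cluster (consensus), with stability the modal fraction.  A
same-run iteration-count reading was rejected because Lloyd iterations
converge deterministically.  The number of clusters remains a user
decision; `dispersion_curve` reports best-of-restarts dispersion over a K
range (5 restarts per K by default) and suggests the elbow as the maximum
second difference of the curve.

Centroids are amalgamated into the five major trend groups by a rule with
tolerance τ = 5 percentage points on the centroid (a, r, c): group 3 if r
exceeds both ends by τ, group 5 if below both by τ, group 1/2 by the sign
of c − a, else group 4.

## Library tree

Between-library similarity uses Pearson correlation over the union tag
set, with absent tags entered as zero counts; the distance is 1 − r
(range [0, 2]).  Raw counts are correlated by default (the normalization
used historically is not recorded; a counts-per-million option exists).
Topology is neighbor joining; branch lengths are refit by nonnegative
least squares against the distance matrix, which preserves least-squares
semantics at nine leaves and reproduces the closed-form three-point
solution exactly at three leaves.  Output is Newick.

## Category enrichment

For each (cluster, term) a gene-level 2×2 table is built: cluster versus
all other clusters in the same replicate (the standard EASE population
choice), multi-tag genes counted once, unannotated genes kept in the
background cells.  `fisher` mode is the one-tailed hypergeometric upper
tail P(X ≥ a); `ease` mode recomputes it with a replaced by max(a−1, 0) —
the EASE score, a conservative penalization of single-gene categories
(EASE p ≥ Fisher p on every table, property-tested).  Enrichment is
declared at EASE p ≤ 0.05 without multiplicity correction, matching the
design; the replicate consensus counts, per (major group, term), how many
replicates show enrichment, with optional pooling of redundant terms via a
user-supplied term→category map.  No ontology-graph propagation is done;
annotation semantics live entirely in the input table.

## Signature projection

An expression matrix (genes × samples) is restricted to a gene signature,
genes are mean-centered (no variance scaling by default — scaling is an
option), and the top three principal components are extracted by SVD.
Component signs are fixed by making the largest-magnitude loading
positive, so results are deterministic across platforms.  Samples are
scored by the Pearson correlation between their gene vector and each
loading vector (scores in [−1, 1]).  Group separation in the top-3 score
space is summarized by the silhouette coefficient plus the adjusted Rand
agreement of a 2-means partition — a testable surrogate for the visual
clustering of sample groups.

## The synthetic atlas

The generator defines the study conditions under which every downstream
stage is tested.  Defaults model a full-scale experiment: 3 replicates ×
3 stages, libraries of 3×10⁵ tags over 5×10⁴ tag types.  Per library,
counts are multinomial on exactly `library_size` tags (so composition
accounting is integer-exact; an independent-Poisson mode exists) with
per-tag weights

    base abundance × trend multiplier(stage) × lognormal jitter.

* **Base abundance** ~ Gamma(shape 2): moderately heavy-tailed, a
  realistic low-count tail without the extreme sparsity that would make
  any count-based test powerless.
* **Trend multipliers** realize the five major groups at fold change
  `effect_size` (default 4): up (1, √f, f), down (f, √f, 1), peak
  (1, f, 1), constant (1, 1, 1), valley (f, 1, f).
* **Jitter** is lognormal with σ = 0.1 drawn independently per (tag,
  stage, replicate): biological variation plus the finer sub-pattern
  diversity within each major group.  Because it is independent across
  replicates it cannot create consistent false trends, which is what the
  consistency rule is designed to reject.
* Default trend mix is 80% constant with 5% in each non-constant group;
  contamination defaults (0.3% bad tags, 20% below the QF threshold,
  0.06% LDT ditags, 5% duplicate ditags) and mapping-class proportions
  (10% ambiguous, 5% antisense, 4% unmapped, 3% genomic-only, 3% host)
  are of the order observed in real libraries of this kind.

Raw ditag reads are synthesized as `CATG + tag1 + revcomp(tag2) + CATG`
with Sanger-scale integer Phred qualities: clean tag bases draw Q ∈
[30, 40] (QF ≥ 0.983, always kept at the 0.95 threshold) and low-quality
tags Q ∈ [15, 22] (QF < 0.90, always removed), so the quality filter's
behaviour on synthetic data is deterministic by construction.  Bad tags
get one base replaced by N; LDT ditags carry a linker 17-mer in both
positions; duplicate ditags are exact copies of existing reads.  Every
injection is recorded as ground truth.  With all contamination rates zero,
extraction reproduces the generating counts exactly (tested round trip).

Signature matrices for projection tests draw baseline expression N(0, 1)
and shift a random 15% gene subset by `separation` standard deviations per
group step **with a random sign per gene**: real signatures mix up- and
down-regulated genes, and a signed signature is what correlation-based
component scores can respond to (a uniform shift is invisible to a
per-sample correlation, which is location-invariant).

What the simulator does *not* emulate: sequence-composition biases,
overdispersion beyond the lognormal jitter, linker chimeras other than
pure self-ligation, host-transcript sequence content (host mapping is a
labeled class only), and any of the underlying tumour biology.  Passing
tests therefore demonstrate correctness of the computational procedure
under the stated statistical model, not performance on real libraries.

## Problem sizes used in the checks

The automated checks run at sizes chosen to make the statistical claims
sharp while keeping the suite quick: planted differential-expression
recovery uses 2,000 tag types at library size 5×10⁴ with fold change 4
(10% of tags in each non-constant group); clustering recovery uses 1,000
tag types at library size 10⁵ with five balanced groups and 100-run
consensus; enrichment detection uses 400 tag types at 2×10⁴ with planted
term rates 60% in-group / 5% background; the tree check uses 500 tag
types at 3×10⁴ with fold change 6.  At these sizes the suite observes
sensitivity and specificity above 0.8 for the consistency rule, adjusted
Rand index above 0.9 for consensus clustering, all three same-stage
clades, and silhouettes above 0.5 (planted) versus ≈ 0 (null).

## Known limitations

* The exact test's two-sidedness convention (symmetric doubled min-tail)
  is one of several defensible choices; one-sided tails conditioned on x
  are exposed (`de.ac_tails`) for users wanting the classic asymmetric
  reading.
* The published per-comparison consistent-tag counts cannot be reproduced
  without the deposited libraries; the pipeline supports ingesting such
  tag-count flat files (`tag-counts` input mode) but ships no copy.
* Trend-letter semantics beyond the documented default table are
  configuration, as the historical lettering is defined only graphically.
* Neighbor joining with NNLS branch lengths approximates a full
  least-squares topology search; at nine well-separated leaves the
  topologies coincide, but this is not guaranteed for noisy distance
  matrices.
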