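# Methods

This note records the models, conventions and design choices behind
`mtbkit`, in the order a user meets them: network construction, module
mining, the evaluation statistics, the synthetic generator, and the
validation suite.  It also states what the synthetic experiments do and do
not demonstrate about real data.

## Network construction (`mtbkit.netio`)

A network is a binary biadjacency matrix over labelled mRNA rows and miRNA
columns.  Integration follows the top-k-union recipe: each prediction
method contributes the pairs whose score reaches its k-th largest value —
ties at the cutoff are all kept, so a method can contribute slightly more
than k pairs — and the union of the per-method sets, optionally merged
with experimentally validated pairs, forms the network.  Scores are never
compared across methods; `lower_better` sources are negated on input so
that higher is always more confident within a source.  Entities are kept
only when expressed in at least `min_nonzero` of the samples (default 8 of
10); entities absent from an expression table count as not expressed.
Replicate sample columns are combined by arithmetic mean.  miRNA name
variants merge by their numeric core: one trailing letter a–z and/or a
trailing `-5p`/`-3p` arm token is stripped (e.g. `hsa-mir-121a`,
`hsa-mir-121b` → `hsa-mir-121`); the merged column targets the union of
member targets, its expression is the per-sample member mean, and ids
without a parseable core stay ungrouped.  Identifier matching is
case-sensitive after whitespace trimming; an optional two-column lookup
table remaps gene symbols, and unmapped records are dropped with a logged
count.

## Module mining (`mtbkit.core`)

The four fully-enumerable types use exact algorithms: signature hashing
for R (a row group with column signature c is a module iff every column in
c has column signature equal to the group), column- and row-signature
grouping for maximal Rmi/Rm, breadth-first search for the type L connected
components, and level-wise Apriori-style closed-set search for the maximal
bicliques (type Rgen), with candidate k-column sets merged from
(k−1)-sets sharing their first k−2 columns, supports pruned below
`min_mrnas`, and a configurable candidate cap (default 10^6) that turns
pathologically dense inputs into a clean error.

The dense loose types (Lmi, Lm, Lgen) return high-density modules rather
than maximal ones.  Seeds are the exact modules of the corresponding
restrictive type (Rmi for Lmi, Rm for Lm, size-filtered maximal bicliques
for Lgen).  Near-duplicate seeds are removed first: processing in
descending (size, density, lexicographic members) order, a seed is dropped
when the Jaccard similarity of its combined member set with a retained one
exceeds `similarity_threshold` (default 0.9).  Growth then adds one column
(Lmi, pulling in all rows supporting the added column), one row (Lm,
transposed), or one row or column without forced closure (Lgen) at a time;
an addition is admissible when the enlarged submatrix keeps density ≥ θ
(default 0.3) and the new member has at least one interaction with current
members, so the induced subgraph stays connected; among admissible
additions the one with the highest resulting density wins, ties broken by
kind then lowest index; growth stops when nothing qualifies.  Seeds below
the minimum output sizes still serve as growth seeds; the 2 mRNA × 2 miRNA
size filter applies to final output only.

Two exclusion rules, chosen where the procedure is genuinely
underdetermined, keep modules from dissolving into one another and make
the output deterministic.  First, members claimed by a previously grown
module are never candidates, and a seed any of whose members was claimed
is skipped.  Second, *foreign territory protection*: a row or column
belonging to a seed that shares no member with the module currently being
grown is not a candidate — overlapping seeds are treated as descriptions
of the same underlying module and do not protect their members, while
disjoint seeds mark other modules' territory.  Without the second rule a
single module can absorb every planted structure reachable through a
handful of spurious edges, because once a dense block is complete, any
single-edge neighbour still keeps the submatrix density far above θ = 0.3
(adding a one-edge row to a complete 5×4 block leaves density at
17/24 ≈ 0.71).  This is also the mechanism behind the miner's residual
impurity: density-qualified single-edge neighbours that are in no seed's
territory are still absorbed, so at false-positive edge rates around 2% a
recovered block typically carries one to three spurious members.  Raising
θ or requiring two supporting edges would remove them but would also
reject legitimate loosely-attached members and is not the stated rule;
we keep the θ-rule and report recovery as measured.

## Evaluation statistics (`mtbkit.expression`, `mtbkit.evalstats`)

All workflows reduce a module to a vector of pairwise statistics, then to
the fraction strictly beyond a threshold t, and compare the per-module
fraction vector against a background vector with a one-sided Wilcoxon
rank-sum test.  Conventions:

- Pearson correlations with fewer than 3 samples or zero variance are
  undefined (NaN); NaNs are excluded from both numerator and denominator
  of fraction statistics, and a module with no defined value yields NaN
  and drops out of the comparison (counts are logged).
- The conditional correlation f(R,T1|T2) splits samples at the mean of T2
  (strictly above vs the rest; equality goes to the lower group), computes
  the within-group Pearson correlations of R and T1, and averages them
  weighted by group size.  Groups smaller than 3 samples or with undefined
  correlation are excluded; a constant T2 makes the split impossible
  (NaN).  d(R,T1,T2) = f(R,T1|T2) − f(R,T1); triples are ordered, and a
  regulator must target both mRNAs by network edge, inside the module for
  foreground triples and outside it for the background.
- The Wilcoxon test uses the exact permutation distribution when the
  combined sample size is at most 12 without ties, and otherwise the
  normal approximation with midranks, tie-corrected variance and
  continuity correction.  Reported p-values are clipped to [1e-16, 1]; no
  multiple-testing correction is applied (the workflows compare parameter
  settings rather than certify individual modules), with
  Benjamini–Hochberg available behind a CLI flag.
- The random background draws, per synthetic module, one
  (n_mRNAs, n_miRNAs) pair uniformly from the observed module size list
  and samples members without replacement from the expressed pools.  The
  member sets are drawn once per run; their correlation values are
  re-thresholded for every t.  The mRNA-mRNA (positive correlation)
  analysis considers only modules with at least 3 mRNAs, so no module
  contributes a single-pair fraction.
- Module ranking for the top/bottom comparison uses the arithmetic mean of
  d over a module's eligible triples; ties at the boundary are broken by
  the module sort key (size, density, lexicographic members).  The grid
  comparison enumerates every (network, x, t) cell — 4 × 4 × 7 = 112 under
  the default grids — and counts the cells where the top half's p-value is
  at most the bottom half's.

## Enrichment (`mtbkit.enrichment`)

Term enrichment of a module's n annotated genes against a universe of N
genes uses the hypergeometric upper tail P(X ≥ k) for a term with K
universe genes and k overlap.  The EASE score is the same tail with the
overlap decremented by one (k ≤ 1 scores 1.0) — the conventional
conservative variant, configurable should a different convention be
needed.  The universe is the annotation background intersected with the
network's (expressed) mRNAs, which keeps K honest when annotation covers
genes outside the analysis.  Each module contributes its most significant
term (ties broken by term id); distributions of −log10 p are compared
foreground-greater.  Co-expression-matched backgrounds rejection-sample
size-matched sets until their mean pairwise correlation is within a
tolerance of the module's (bounded tries; a tolerance of 1 reduces to
plain size matching).  Annotations are consumed as given, without
ontology-graph propagation.

## Synthetic data (`mtbkit.synthetic`)

The generator emulates the statistical structure the workflows assume:
a 30 mRNA × 20 miRNA network with three disjoint 5 mRNA × 4 miRNA planted
blocks; within-block edges present with probability 1 − fn_rate
(default fn = 0.2), all other edges with probability fp_rate (default
0.02); expression over 10 samples.  Per sample, miRNA j has activity
a_j ~ N(0,1) and expression a_j plus Gaussian noise (sd 0.5); a block mRNA
is −β · (mean activity of the block's miRNAs) + γ·b plus noise, with
β = 0.8 (repression) and γ = 0.8 (buffering) by default; non-block mRNAs
are independent noise.  Expression is shifted by its global minimum plus a
small constant to be non-negative, which leaves every correlation
untouched.

The buffering state b is a per-sample Rademacher (±1) variable shared by a
block's mRNAs — a competing transcript that is either expressed or silent
in a given cell line.  A *Gaussian* shared factor was considered and
rejected on mathematical grounds: for jointly Gaussian (R, T1, T2) with
both targets loading symmetrically on co-regulation and on the factor,
conditioning on T2 always attenuates the R-T1 correlation (the partial
correlation is ρ(1−τ)/√((1−ρ²)(1−τ²)) with ρ = corr(R,T1) = corr(R,T2)
and τ = corr(T1,T2)), so the buffering statistic d would be positive no
matter the factor strength — the opposite of the signature the statistic
is designed to flag.  With an on/off state the mean split on T2 largely
fixes b, removing target variance unrelated to the miRNAs, and d shifts
negative relative to a γ = 0 simulation.  The shift is nonetheless small
at 10 samples: the split halves the data, and 5-sample Pearson estimates
carry an attenuation bias of the same order as the effect, so the γ
contrast is detectable only marginally at a few hundred triples — a
genuine small-sample limitation of the d statistic worth knowing before
applying it to 10 cell lines.

What passing the synthetic tests shows — and does not.  The generator
produces linear-Gaussian expression with exact block structure,
independent edge noise, and noise-free annotations; real RNA-seq is
counts-based with library-size and batch effects, real networks have
correlated errors (shared sequence motifs), and real modules overlap.
Green synthetic tests therefore certify the implementation (the
algorithms compute what they claim, the statistics are calibrated under
exchangeable nulls, the workflows detect planted signal of the stated
strength), not biological performance on any particular dataset.

## Features and classification (`mtbkit.features`)

The seven network-only features are the module's mRNA and miRNA counts,
the density of 1's inside its submatrix, the densities of the other rows
of its columns, the other columns of its rows, and both regions pooled
(empty regions count as 0, which only affects whole-matrix modules), and
the module type.  The class variable is the within-module fraction of
miRNA-mRNA correlations more negative than t = −0.1, cut into ten
equal-width classes on [0, 1] with the last class closed at 1; a variant
binning the average anti-correlation (mapped as (1 − mean r)/2) is
available behind a flag, since either summary is defensible.  The
cross-validation harness is the contribution, the learner is pluggable:
stratified k-fold (default 10, reduced with a warning when the rarest
class is smaller), per-class one-vs-rest AUC averaged within and then
across folds, seeded; the default classifier is a 100-tree random forest.
The exhaustive feature search evaluates all 2^7 − 1 = 127 subsets and
reports rankings plus inclusion frequencies among the top subsets.

## Validation problem sizes

The validation suite checks the complete-enumeration miners against
brute-force subset enumeration on 200 random matrices of 6–10 rows and
columns at densities 0.2/0.4/0.6; measures planted-block recovery over 50
generator seeds; calibrates the anti-correlation workflow on 200 null
simulations (100 random background sets each) and measures its power by
pooling module fractions over 10 planted replicates; and contrasts the
buffering d over 200 triples per condition drawn across replicate
simulations.  These sizes keep the whole suite in the tens of seconds on
one CPU while leaving the binomial tolerance bands meaningful.

## Known limitations

- The greedy dense miners are order-dependent by design; determinism comes
  from explicit tie-break rules, not from an objective being optimised.
  Single-edge neighbours that clear the density threshold are absorbed,
  so recovered modules carry a few spurious members at realistic
  false-positive rates (measured by the planted-recovery check).
- The buffering statistic d is weakly powered at 10 samples (see above).
- Weighted (score-carrying) networks are binarised upstream; no weighted
  module score is implemented.
- The comparison module list for external methods is consumed as given;
  no third-party module-discovery algorithm is re-implemented.
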