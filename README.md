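# mtbkit

Identification and evaluation of **microRNA-target biclusters (MTBs)**:
largely autonomous modules of miRNAs and mRNAs mined purely from the
connectivity of a noisy bipartite miRNA-target network, then tested against
expression and annotation data.

MicroRNAs repress their target mRNAs, and transcripts that share miRNA
response elements compete for a finite miRNA pool — the competing
endogenous RNA (ceRNA) hypothesis, under which co-targeted transcripts
buffer one another's expression.  Testing this genome-wide is hard because
miRNA-target networks assembled from target predictions and validation
databases carry many false positive and false negative edges.  `mtbkit`
addresses this by decomposing the network into small, dense, largely
self-contained modules whose internal signal can be analysed with minimal
interference from the rest of the network, and by quantifying whether those
modules carry the expression signatures the ceRNA hypothesis predicts.  It
is aimed at computational biologists studying post-transcriptional
regulation who have an interaction network (edge lists or score tables),
matched miRNA/mRNA expression over a set of samples or cell lines, and
optionally gene-function annotation.

## The model

Represent the network as a binary matrix `a_ij` whose rows are mRNAs (set
R) and columns miRNAs (set C).  An MTB is a pair of index sets (r, c).
Eight types relax, in two directions, the ideal of an all-ones submatrix
with no outside interactions:

| type | submatrix | extra out-of-module edges allowed for | count of (maximal) modules |
|------|-----------|---------------------------------------|----------------------------|
| R    | all 1's   | neither side                          | ≤ min(\|R\|, \|C\|)        |
| Rmi  | all 1's   | mRNAs only                            | ≤ \|C\| maximal            |
| Rm   | all 1's   | miRNAs only                           | ≤ \|R\| maximal            |
| Rgen | all 1's   | both sides (maximal bicliques)        | exponential in theory      |
| L    | 0's ok    | neither side (connected components)   | ≤ min(\|R\|, \|C\|)        |
| Lmi  | 0's ok    | mRNAs only                            | greedy, high-density       |
| Lm   | 0's ok    | miRNAs only                           | greedy, high-density       |
| Lgen | 0's ok    | both sides                            | greedy, high-density       |

R, Rmi, Rm and L are enumerated completely in linear time by row/column
signature hashing and breadth-first search; Rgen by level-wise
(Apriori-style) closed-set search; the dense loose types grow exact seeds
one row/column at a time while the submatrix density of 1's stays above a
threshold θ (default 0.3) and the module stays connected.

Modules are evaluated with three statistics, each summarised per module as
a *fraction beyond a threshold t* and compared to a matched background with
a one-sided Wilcoxon rank-sum test (p-values floored at 1e-16, uncorrected):

- **Anti-correlation** — Pearson correlation of each within-module
  miRNA-mRNA pair across samples, fraction more negative than t
  (t = −0.1 … −0.7), versus random size-matched sets or the same miRNAs'
  outside targets.
- **Buffering** — for a regulator R and targets T1, T2,
  `d(R,T1,T2) = f(R,T1|T2) − f(R,T1)`, where `f` is Pearson correlation and
  the conditional term averages the within-group correlations after
  splitting samples at the mean of T2.  Negative d means T2 explains part
  of the R-T1 relationship, the ceRNA signature.  Within-module triples are
  compared to triples with both targets outside the module, and modules
  ranked by mean d feed a top-vs-bottom comparison over a
  (network × x × t) grid.
- **Functional enrichment** — per module, the most significant
  hypergeometric upper-tail p (or conservative EASE score, the same tail
  with one overlap gene removed) over annotation terms, versus random,
  outside-target, or co-expression-matched gene sets.

A seeded synthetic generator plants dense blocks in a noisy network with
matched expression (tunable repression β, buffering γ) and toy annotations,
so the full pipeline is testable offline; `mtbkit.features` additionally
predicts a module's anti-correlation class from seven network-only features
with a cross-validated random forest.

## Worked example

```sh
mtb simulate --seed 7 -o demo
mtb find --network demo/network.json --type Lgen -o demo/mtbs.json
# -> found 3 Lgen MTBs -> demo/mtbs.json
mtb eval anticorr --mtbs demo/mtbs.json --network demo/network.json \
    --expr-mirna demo/expr_mirna.tsv --expr-mrna demo/expr_mrna.tsv \
    --n-random 1000 --seed 17 -o demo/anticorr.tsv
cat demo/anticorr.tsv
```

```
type	t	background	n_fg	n_bg	p_value
Lgen	-0.1	random	3	1000	0.00369787
Lgen	-0.2	random	3	1000	0.00631973
Lgen	-0.3	random	3	1000	0.0156015
Lgen	-0.4	random	3	1000	0.2316
Lgen	-0.5	random	3	1000	0.573989
Lgen	-0.6	random	3	1000	0.293356
Lgen	-0.7	random	3	1000	0.528254
```

The miner recovers the three planted modules; at moderate thresholds
(t = −0.1, −0.2) their miRNA-mRNA pairs are significantly more
anti-correlated than 1,000 random size-matched sets (p ≈ 0.004 and 0.006),
while at extreme thresholds (|t| ≥ 0.4) almost no pair in either group
qualifies and the contrast vanishes — the expected pattern when repression
is moderate relative to noise.  Functional enrichment on the same modules
(`mtb enrich`, 500 random sets) prints `enrichment p = 0.00135`: each
planted block's genes share a dedicated annotation term that random sets
of the same size do not.

The same commands run on real data: `--network` accepts an edge-list TSV
(`mirna_id`, `mrna_id` columns), expression tables are entity × sample
TSVs, and `mtbkit.netio` provides top-k score integration
(`read_prediction_table`, `select_top_k`, `build_union_network`),
expressed-entity filtering, replicate averaging and miRNA-variant grouping.

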