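# Methods

## Model and procedure

`tspath` scores candidate drugs for a disease by how strongly their
expression responses reverse the disease's *pathway-level* expression
signatures in the disease's tissue context. The procedure has five
stages; each is a pure function with files as optional contracts between
stages.

**Disease signature.** Genes are ranked by
`logFC = log2(mean(tumor)/mean(control))` over the raw (positive-scale)
expression matrix and partitioned into up- (`logFC > 0`) and
down-regulated (`logFC <= 0`, i.e. zeros count as down) sets. Ties in
logFC are broken lexicographically by gene id so the ranking is a
deterministic total order. A per-gene z-score transform (sample n−1
standard deviation) is provided for inspection and reporting, but the
fold change is always computed on the original scale: a z-scored row has
mean zero across samples, which makes a ratio of group means meaningless.
Constant rows are zeroed and flagged rather than producing NaNs. An
optional pseudocount `epsilon` (default 0) supports count-like data; with
`epsilon = 0` the logFC is invariant under global rescaling of the
matrix.

**Tissue subnetwork.** Seed disease genes anchor the extraction: the
subnetwork contains the seeds plus every direct neighbor connected by an
edge with confidence ≥ cutoff (default 0.1, compared inclusively), and
*all* edges at or above the cutoff among the selected nodes (induced
subgraph — a seed-neighbor star alone cannot produce the dense
neighborhoods this method relies on). Seeds without qualifying neighbors
stay as isolated nodes; extraction fails only if no seed exists in the
network. Topology statistics: mean degree, mean local clustering
(degree < 2 contributes 0), and average shortest path length and diameter
within the largest connected component.

**Pathway enrichment.** The DAVID-style over-representation step is an
upper-tail hypergeometric test: with a universe of `M` genes, a pathway
of `K` members and a query of `N` genes overlapping it in `x`, the
p-value is `P(X >= x)` for `X ~ Hypergeom(M, K, N)`. A pathway survives
if `x >= min_count` (default 5, and always `x >= 1`) and `p <= p_max`
(default 0.001) — raw thresholds, no multiple-testing gate; a
Benjamini–Hochberg column is emitted for information only. An
`ease = True` flag switches to the conservative EASE variant (overlap
decremented by one). The universe defaults to the union of all pathway
members; an explicit background extends it, and the query is intersected
with the universe before testing because genes outside the background
carry no information under the model. A permutation check
(`random_set_significance`) replaces the non-seed part of the extracted
gene set with uniform draws from the network and compares pathway
coverage (distinct genes captured by surviving pathways), with the
add-one empirical p-value `(1 + #{draws >= observed})/(1 + n_draws)`.
The observed gene set is an explicit argument; the draw size defaults to
`|observed \ seeds|` so null sets match the observed set's size.

**Connectivity scoring.** Each pathway signature is the pathway's members
ordered by the disease ranking and split into the disease's up/down
lists. For a query list with positions `V(1..m)` (1-based, sorted
ascending — re-ranking the common genes by drug value is equivalent) in a
drug instance of `n` genes:

    a  = max_p [ p/m − V(p)/n ]
    b  = max_p [ V(p)/n − (p−1)/m ]
    CS = a if a > b; −b if a < b; 0 if |a − b| <= 1e−12

`CS` lies in [−1, 1]; positive means the query concentrates at the top of
the drug list. The tie value 0 follows the original connectivity-map
"null connectivity" convention. An empty query (`m = 0`, e.g. a pathway
signature with no up-regulated member, or no overlap with the drug's
genes) contributes 0 rather than dropping the instance, which would bias
the per-drug instance count `k`. Per (pathway, instance),
`CS = CS_up − CS_down`; per drug, `TS = (1/k) Σ_pathways Σ_instances CS`.
TS is deliberately *summed* over pathways, so its magnitude grows with
the number of surviving pathways; a `normalize_pathways` flag divides by
the pathway count but defaults off to preserve the published form. The
same machinery scores drug–drug similarity: the reference drug's up/down
signature is built from its own per-gene mean differential value across
instances (positive mean = up), and a positive score means similar
action.

**Evaluation.** Drugs are ranked by descending `|TS|` (benchmarks rarely
orient associations), ties alphabetical; precision@x is the fraction of
the top-x drugs with any benchmark evidence (`M`, `T`, `M&T` or
`inferred` — anything but `NA`). Drug-name matching is case-insensitive
after trimming. `TS < 0` classifies a drug as putatively therapeutic.
Ablation variants share the connectivity core: `seedKS` scores the
whole-disease up/down signature; `subnetKS` restricts it to the
subnetwork's genes; `seedPathKS` enriches pathways directly from the DEG
set without the network. The DEG set for these variants defaults to all
up and all down genes (`top_q` bounds each half by |logFC| when set).
With the all-gene default, `seedPathKS`'s query saturates every pathway
and nothing passes the thresholds — the variant then returns an explicit
"no pathway enriched" status instead of scores, which is also its
documented behavior on real data of this kind. All variants use the same
`|TS|` ranking rule for comparability.

## Synthetic data: what it emulates and what it does not

`SimulationConfig` defaults define the reference scenario: 500 genes,
25 tumor / 15 control samples, 5 signal pathways of 20 genes (10 up, 10
down) plus 5 size-matched decoy pathways, 8 seed genes drawn from the
planted module, a network with dense planted module (edge probability
0.7, confidence U(0.4, 1)) over sparse background (probability 0.01,
confidence U(0.05, 0.95)), planted |logFC| of 2 (log2 units) over
lognormal baseline expression with per-sample log2 noise sd 0.3, and 20
drugs × 3 instances. Drug instance values are
`−strength(d) · planted_logfc(g) + N(0, 0.2)`: 5 drugs at strength +0.9
(reversers, the planted therapeutic truth, marked `inferred` in the
generated benchmark) and 15 at 0 (noise drugs). Negative strengths
generate mimicking drugs whose TS must come out positive; they are used
to test the sign convention. They are *not* part of the ranking-recovery
scenario because the KS statistic is symmetric up to O(1/n) under ranking
reflection: a mimicker at −0.9 ties a reverser at +0.9 in |TS|, so no
|TS|-based method can separate them — an inherent property of
magnitude ranking, not an implementation artifact.

Everything is a deterministic function of `rng_seed`. The generator
emulates planted differential structure, module concentration and
signature reversal; it does not emulate microarray noise models, batch
effects, probe-level artifacts, cell-line heterogeneity across instances,
or incomplete gene coverage between platforms. Passing recovery tests
therefore demonstrates correctness of the machinery and separability
under the stated noise, not expected precision on real cohorts.

The scenario sizes (500 genes, 20 drugs, 200 null draws in the
permutation check) were chosen as the smallest at which the planted
structure is comfortably resolvable; the whole test suite plus the
acceptance script completes in well under a minute on one CPU.

## Numerical choices and edge cases

- KS tie tolerance 1e−12; `m = 0` scores 0 with a log message.
- Hypergeometric tail via `scipy.stats.hypergeom.sf(x−1, M, K, N)`.
- All orderings (gene ranking, drug-profile ranking, drug ranking,
  subnetwork node insertion) carry explicit deterministic tie-breaks, so
  identical config + seed gives byte-identical output files.
- Expression readers average duplicate gene rows (multiple probes per
  gene), drop blank gene ids, and hard-fail on unknown samples or
  non-numeric cells, naming the offending row/column.
- Network readers keep the max confidence over duplicate edges in either
  orientation and drop self-loops with a warning; confidences outside
  [0, 1] are errors.
- Gene identifiers are opaque, case-sensitive strings (no symbol/ID
  mapping layer); drug names are matched case-insensitively after
  trimming, with no fuzzy matching.

## Known limitations

- TS magnitude is comparable only across drugs scored against the same
  signature set (it scales with pathway count).
- The hypergeometric replacement for DAVID's service will not reproduce
  DAVID's exact p-values (different background and the EASE correction);
  the `ease` flag narrows but does not close that gap.
- Pathway genes absent from the expression data are silently excluded
  from signatures (logged), so sparse platforms shrink `m` and with it
  the attainable |CS|.
- `seedKS` with the all-genes default uses a very large signature; its
  discrimination comes almost entirely from the planted genes, and it is
  reported as-is rather than tuned.
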