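# Methods

## The problem

Cluster-level analyses of single-cell RNA-seq routinely end with a wish
list: a handful of genes per cell type that can be taken to the bench as
antibody targets for flow cytometry gating or imaging. That task differs
from ordinary differential expression. A usable marker must separate the
target population from *all* other cells with a single expression
threshold, it must be detectable in most cells of the cluster, and an
antibody against its protein product must exist. Standard DE statistics
(t-test, rank-sum) reward average shifts and routinely top-rank genes
that are also expressed in related cell types.

## The margin model

Let `X` be the cells x genes matrix of normalized expression. Each gene
column is min-max scaled to `[0, 1]`:

    x̂_ij = (x_ij - min(x_j)) / (max(x_j) - min(x_j))

Constant columns are mapped to all zero; they carry no class signal and
are removed downstream. For a target type `p` the class vector is
`y_i = +1` if cell `i` belongs to `p` and `-1` otherwise (one-vs-rest).

A threshold `alpha` on a scaled column partitions cells into four sets
with strict `>` for the above-threshold side: A (true positives),
B (false negatives), C (false positives), D (true negatives). A value
exactly equal to `alpha` is classified negative. The margin score of a
threshold is

    GeneSplit(alpha) = |D| * Σ_{x∈A} y (x - alpha)
                     + |A| * Σ_{x∈D} y (x - alpha)
                     + |B| * Σ_{x∈C} y (x - alpha)

i.e. the summed distances of correctly classified cells to the
threshold, cross-weighted by the size of the other correct set, minus a
false-positive penalty weighted by the number of false negatives. The
false-negative set contributes no sum of its own: in sparse scRNA-seq
data a zero in a target cell is as likely a dropout as a biological
absence, so false negatives are deliberately penalized only mildly. A
consequence of the displayed form — implemented here verbatim — is that
the false-positive penalty vanishes entirely whenever B is empty; users
should be aware that a gene detected in every target cell is judged on
its positive margins alone.

The optimal threshold is found by exhaustive grid search over
`{0, 0.01, ..., 1.00}` (inclusive endpoints; the grid is generated as
`k * step` from integer `k` to avoid floating-point accumulation). Ties
in the maximum — common, because the score can be flat over whole
intervals — are broken toward the smallest `alpha`. Tie detection uses
an absolute tolerance of 1e-9: summation order makes mathematically
equal scores differ in the last bits at different grid points, and
without the tolerance the returned `alpha` would depend on rounding
noise rather than on the data.

Genes are ranked by the composite score

    ranking_score = GeneSplit(alpha) * TPR * TNR * FC^2

with `TPR = |A|/(|A|+|B|)`, `TNR = |D|/(|C|+|D|)` at the optimum, and

    FC = (mean(x̂, target) + sigma) / (mean(x̂, rest) + sigma),  sigma = 0.01.

FC is computed on the scaled values — the same operand the partition is
defined on — and is the plain pseudo-counted ratio by default. A
`log_fc` switch replaces it with `log2` of the ratio for users who want
effect sizes on the conventional DE scale; the ratio is the default
because the squared term then dominates the composite score for
well-separated genes, which is the intended behavior.

### Filters

Two filters remove low-quality candidates, both exposed in
`ScoringConfig`:

* detection: the gene must have raw (pre-scaling) expression > 0 in at
  least 15% of the cells of the relevant cluster — the target cluster
  for positive markers, the non-target cells for negative markers (a
  negative marker is only useful if it is actually detectable in the
  cells that express it);
* specificity: TNR at the optimal threshold must be at least 0.65.

`rank_markers` additionally drops genes whose ranking score is not
strictly positive. The two filters alone do not exclude degenerate
genes: a constant nonzero gene scales to an all-zero column, which gets
detection 1.0 and TNR 1.0 yet separates nothing. A zero or negative
margin means the gene never splits the target class and is not a
marker.

### Negative markers

Negative markers (absence marks the type) are scored by replacing the
scaled column `x̂` with `1 - x̂` and running the identical positive
pipeline. This duality is exact and is tested as such: for every gene,
the negative-direction score equals the positive-direction score of the
inverted column.

## Antibody databases

A database is a CSV (`gene_symbol,category,species,evidence,source,
antibody_registry_id,vendor_link`) with categories from the fixed
vocabulary {ICC, IHC, Flow, ICC_Mouse, IHC_Mouse, Flow_Mouse, User}.
Symbols are matched case-insensitively (mouse `Cd19` matches a human
`CD19` entry) and output always preserves the matrix spelling.
Restriction intersects the candidate gene space with the requested
categories before scoring; annotation attaches provenance columns to a
ranked table, joining multiple records per gene with `;` in vocabulary
order, and never alters ranks. The package ships a small curated
database of well-known immune-cell flow markers and mouse stromal
markers as a worked example; registry and vendor fields in it are left
empty rather than inventing identifiers. Production use is expected to
bring user databases via `load_db`.

## Baseline rankers

For benchmarking, five comparison rankers live behind the same scorer
interface (`SCORERS` registry):

* `roc` — classification power `|AUC - 0.5| * 2` of the single-gene
  classifier; AUC by the Mann-Whitney rank-sum identity with midranks,
  so ties are handled exactly and the statistic is invariant under
  monotone transforms.
* `hypergate_f1` — the maximum over the threshold grid of
  `F1 = 2PR/(P+R)` with precision/recall from the same strict-`>`
  partition; `F1 = 0` when `P + R = 0`.
* `fc` — the pseudo-counted mean ratio alone, on scaled values (the same
  operand convention as the composite score, for comparability).
* `wilcoxon`, `ttest` — two-sided rank-sum and Welch t-test p-values on
  the raw normalized values, ranked ascending; degenerate (zero
  variance) inputs map to p = 1, the worst rank, instead of NaN.

The margin method itself is registered as `maxmargin`. Its ranked list
contains only genes passing its filters; the baselines rank every gene.
True-marker rank comparisons therefore measure each method's final
user-visible output, filtering included.

## Benchmarks

Two desk-scale procedures:

* **Rank of true markers.** Given a truth set (cell type -> known
  markers), record each truth gene's 1-based position in each method's
  ordered output, pooling cell types per method. Truth genes absent
  from an output (filtered out, or not in the matrix) are reported as
  unranked and excluded from medians — reporting them separately keeps
  a method from looking good by filtering aggressively.
* **Panel clustering.** Take the union of each type's top-k markers
  (k = 2 by default), restrict the matrix to that panel, build a
  symmetrized Euclidean 15-nearest-neighbor graph, partition it with
  Leiden modularity optimization (RB-configuration, resolution 1.0,
  fixed seed), and score the partition against the given labels with
  the adjusted Rand index. Graph clustering backends are not
  bit-compatible across ecosystems, so this artifact fixes its own
  deterministic default and exposes k, resolution and seed as
  parameters.

## Synthetic data

The generator produces clustered matrices that emulate log-normalized
droplet scRNA-seq: background counts are zero-inflated negative
binomial — a Bernoulli detection mask (default rate 0.10) times
`1 + NB(mean 1.0, dispersion 0.5)` — then `log1p`. Defaults: 4 cell
types x 100 cells x 200 genes, 3 planted positive markers per type.
A planted marker is expressed in a Bernoulli(0.9) subset of its type's
cells at the background magnitude plus a log-scale shift of 2.0
(~7.4-fold); negative markers are expressed across all *other* types at
the same rate and shift and are exactly zero in the target type. These
sizes keep every planted marker comfortably above both filters while
leaving 90%+ of genes as realistic sparse background, and the full test
suite runs in well under a minute.

An effect size of zero means a null dataset: nothing is planted at all,
and the truth sets are empty. (A detection-rate boost without a mean
shift would itself shift means, so "zero effect" is interpreted as no
marker effect of any kind.)

What the generator does *not* emulate: library-size variation between
cells, batch effects, doublets, correlated gene modules, or a protein
modality. Passing the recovery benchmarks here shows the scoring
machinery is correct and well-behaved under sparsity and class
imbalance; it does not certify performance on atlas-scale real data,
where marker signals are weaker and confounded.

Generation is bit-deterministic given the spec (including its seed).
The end-to-end regression fixture is the seed-7 default dataset,
regenerated at test time; a golden marker table produced from it is
committed and compared byte-for-byte.

## Numerical choices and edge cases

* All floating-point test comparisons use absolute tolerance 1e-9
  unless a test states otherwise.
* Grid-search correctness is guarded by a brute-force oracle (pure
  Python, per-cell loops, independent of the vectorized path) on random
  small instances.
* Constant gene columns: scaled to zero (positive direction) — they can
  never acquire a positive margin and are dropped from rankings.
* Empty candidate set after database restriction yields an empty result
  list, logged, not an error.
* Duplicate gene symbols in input matrices are suffix-disambiguated
  (`.1`, `.2`, ...) with a warning rather than dropped.
* Output CSVs format floats to six significant digits so repeated runs
  are byte-identical.

## Known limitations

* Single-gene thresholds only; no combinatorial panel search.
* The composite score is unnormalized — values are comparable between
  genes within one (dataset, target) pair, not across datasets.
* The FP-penalty-vanishes-when-B-is-empty property of the margin score
  (see above) can flatter genes with perfect within-target detection;
  the TNR filter is the guard rail.
* The detection filter reads raw values, so transformations that
  change zero-ness (e.g. adding a constant) change which genes are
  *eligible*, even though every score and threshold is invariant to
  per-gene affine maps.
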