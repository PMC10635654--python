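# Methods

This note documents the statistical model, the numerical choices, and the
synthetic benchmark conditions behind `cci-delta`, in the order the
pipeline runs.

## Interaction scoring model

A ligand–receptor (LR) catalogue entry is a pair of single gene symbols
with receptor-role flags. Exactly one flag set makes the pair *directed*
(ligand must sit in the source population, receptor in the target); both
or neither set makes it *undirected*, and the pair is then evaluated in
both orientations — the (source, target) record places `partner_a` in the
source, and the mirrored record at (target, source) covers the reverse.
Multi-subunit complexes are deliberately not modelled: the downstream
analysis uses only molecule identity and direction.

For source *s*, target *t* and pair (*l*, *r*) the score is
`(mean_s(l) + mean_t(r)) / 2`, the arithmetic mean of the two cluster
means of normalized expression. The null distribution comes from global
permutations of the cell-type labels (label multiplicities preserved);
one shared permutation stream scores all triples per shuffle, which is
both the convention of the published label-shuffling tools and far
cheaper than per-triple streams. P-values use the add-one convention
`p = (1 + #{perm ≥ obs}) / (1 + B)`, so they lie in (0, 1] and the
smallest attainable value is 1/(1+B). Significance is `p ≤ α` with the
boundary included.

Defaults — B = 1000 permutations, α = 0.05, minimum expressing fraction
0.10 — mirror the published conventions of this class of tools; all are
configurable, and autocrine records (source = target) are scored and
counted like any others.

Because the score is a sum of *marginal* cluster means, an interaction
that is genuinely active between (s, t) also elevates the observed score
of every triple sharing its ligand-in-s or receptor-in-t. This is a
property of the method itself, not of this implementation, and it shapes
what the synthetic benchmarks can claim (below).

## Matrices, profiles, correlations

The count matrix tabulates significant records per ordered
(as-source, as-target) pair; declared but inactive populations keep
all-zero rows/columns so the matrix shape is stable across conditions.
Spearman correlations use average ranks for ties (ranking via
`scipy.stats.rankdata`, then Pearson on the ranks). A zero-variance
vector makes the correlation undefined; the report carries an explicit
defined-mask and NaN values rather than silently coercing to 0. It is
ambiguous whether row/column correlations are more informative on the
count matrix or on the binary profile matrices, so the pipeline computes
and labels all of them.

## Graph semantics

The interactome graph is realized as a *simple* weighted digraph over
cell-type and molecule nodes, with a path registry carrying the
per-record provenance that a simple graph cannot: every named centrality
operates on a weighted simple graph, so nothing is lost, and the registry
preserves the multigraph reading. A directed record contributes one
3-edge path and increments each edge's occurrence weight W by 1; an
undirected record registers the forward and the reversed path and
increments each of its (six, disjoint) edges once — the two mirror paths
are counted once per record, never twice. The exact conservation law is
therefore ΣW = 3 × (number of registered paths) =
3 × (directed records + 2 × undirected records), which reduces to
3 × record count for all-directed inputs.

Centralities are computed per condition graph, never on a merged one:

- degree / in-degree / out-degree: unweighted counts normalized by n−1
  (a weighted variant and an unnormalized variant are flags);
- betweenness: shortest paths under edge distance 1/W — heavier edges are
  shorter — normalized by the number of ordered node pairs excluding the
  node;
- Katz: x = αAᵀx + β with β = 1, weighted adjacency A, and attenuation
  α = (1−ε)/|λ_max|. At α = 1/|λ_max| exactly, (I − αAᵀ) is singular,
  so the attenuation is shrunk by ε = 10⁻⁶ (recorded in the report along
  with α, |λ_max| and the pre-normalization scale). The solution is a
  dense linear solve, returned with unit Euclidean norm; for an edgeless
  graph |λ_max| = 0 and the solution degenerates gracefully to the
  uniform vector. The report keeps the raw-solution norm so the
  fixed-point identity can be re-checked exactly after normalization.

## Delta classification

The classification universe is the full cross product of ordered
population pairs with the interaction catalogue — required for the
partition (absent + stable + lost + gained = universe) and margin
identities (stable + lost = earlier significant count; stable + gained =
later) to be checkable on every run. "Top-changing" reactions are ranked
by |Δ significant mean| with missing means treated as 0 and deterministic
tie-breaking (gained > lost > stable > absent, then lexicographic);
count-based gained/lost tallies per population pair are reported
alongside, since either view is defensible and the choice is surfaced in
the output header. Percent changes (later − earlier)/earlier × 100 are
emitted at four aggregation scopes (pair, as-source, as-target,
population total with the autocrine diagonal counted once) because
published per-population percentages rarely state which margin they used;
a zero earlier count yields an explicit undefined flag, never an
infinity.

## Synthetic data model

The generator emulates the *inputs* of the scoring stage, not raw
sequencing: per-type mean profiles with a planted active set, log-normal
multiplicative noise, and a controlled two-condition turnover.

- Baseline mean 1.0 for every gene in every type, on a normalized-counts
  scale. An active triple (s, t, i) multiplies the ligand mean in s and
  the receptor mean in t by `effect_size`; each (gene, type) slot is
  elevated at most once so the planted fold change is exact.
- Noise is `LogNormal(−σ²/2, σ)` per cell and gene (default σ = 0.3),
  mean-one by construction, strictly positive — so planted fold changes
  survive in expectation and values are valid normalized counts.
- Condition 2 removes each active triple with probability `loss_rate`
  and adds `Binomial(|active|, gain_rate)` fresh triples from the
  inactive pool; gains are sized relative to the active set so turnover
  stays comparable to losses, and prefer unused interaction ids so the
  planted truth stays triple-specific.
- The default active-set sampler assigns each planted triple a private
  interaction id for the same reason: with the marginal score, id reuse
  across triples makes ground truth ambiguous.

What the generator does *not* emulate: UMI counting noise, dropout /
zero inflation, ambient RNA, doublets, batch effects, or any real
biology of the labels. In particular every gene is expressed in every
cell, so the expressing-fraction filter is non-binding on synthetic
data; passing benchmarks demonstrate correctness of the statistics and
bookkeeping, not robustness to sparse real single-cell matrices.

## Benchmark conditions and what passing shows

- **Null calibration**: effect size 1, 6 types × 60 cells, 100
  interactions (3600 scored triples), 200 permutations. The fraction of
  p ≤ 0.05 should sit near 0.05; the band checked is [0.03, 0.07].
  The 100-id size was chosen because triples sharing an interaction id
  have correlated p-values (they share the gene pair), so the variance
  of the fraction is governed by the number of id blocks, not the raw
  triple count.
- **Planted recovery**: effect size 6, 6 types × 100 cells, 900 planted
  triples with private ids over an 1800-entry catalogue, gain = loss =
  0.2, 200 permutations, α = 0.05. Power is measured on planted
  condition-1 triples; classification quality as macro recall over
  {stable, lost, gained} restricted to ever-active (planted) triples.
  The restriction matters: over the full universe, baseline triples are
  (correctly) called significant 5 % of the time per condition, putting
  an irreducible ≈0.95 ceiling on any full-universe specificity — a
  property of thresholding at α, not an implementation defect. The
  one-vs-rest balanced accuracies over the full universe are still
  computed and reported for transparency.
- **Demo pipeline**: 6 types × 50 cells, 150 genes (120 LR pairs drawing
  on 45+45 shared gene pools + 60 background), 1000 permutations, two
  conditions. Used for the end-to-end determinism contract (byte-identical
  manifests under a fixed seed) and as the worked example; the shared
  gene pools make it resemble a real catalogue, where one ligand engages
  several receptors.

Benchmark sizes are the package's reference conditions; each completes in
seconds to a few minutes on one CPU with sampling error below about one
percent on every reported fraction.

## Determinism

Every stochastic operation takes a single integer seed; the pipeline
derives per-stage integer sub-seeds (< 2³¹) from it via
`numpy.random.SeedSequence`. Writers sort rows and columns
lexicographically, serialize floats with round-trip precision, and the
graph JSON sorts keys — so identical configuration and seed reproduce
every artifact byte for byte, which the manifest checksums assert.

## Known limitations

- Single-gene partners only; catalogues with complexes must be flattened
  before use.
- No multiple-testing correction across triples and no significance test
  on the *change* between conditions (by design: the delta is a
  set-algebra comparison of two thresholded tables).
- The permutation test inherits the marginal-score property discussed
  above; "significant" means elevated marginal co-expression, not joint
  single-cell co-occurrence.
- Cell-type labels are opaque case-sensitive strings; `|` is reserved
  for composite column keys.
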