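# Methods

## Problem and model

Somatic mutations can disrupt specific protein–protein interactions, not
just the proteins that carry them. Classical network smoothing (network
propagation) quantifies each *protein's* proximity to a patient's mutations
but has nothing to say about individual *interactions*. `edgesmooth`
extends smoothing to interactions by a graph transformation: every edge
{u, v} of a weighted interaction network G = (V, E, w), w ∈ [0, 1], is
subdivided by a dummy node uv, giving the adjusted network

    V′ = V ∪ { uv : {u, v} ∈ E },
    E′ = { {u, uv}, {uv, v} : {u, v} ∈ E },

so |V′| = |V| + |E| and |E′| = 2|E|, and every dummy node has degree 2.
After smoothing on G′, the value at dummy node uv *is* the score of the
interaction {u, v}.

### Half-edge weights

The two half-edges flanking a dummy node carry weight

    w′(u, uv) = w′(uv, v) = √w(u, v)        (default, "sqrt")

Interpreting a path's reliability as the product of its edge weights,
r(p) = ∏ w(u, v), the √w choice makes subdivision invisible: the lifted
path u – uv – v contributes √w · √w = w, so every path between original
nodes keeps its reliability exactly. The alternative w′ = w/2 ("half") is
provided for comparison; it multiplies each edge's contribution by w/4 and
therefore does not preserve reliability (asserted in the test suite).

### Smoothing

Per patient, the prior Y : V′ → [0, 1] is the binary somatic-mutation
indicator on original nodes (1 iff the gene is mutated in that sample) and
0 on every dummy node. The smoothed score F is the fixed point of

    F = α · S · F + (1 − α) · Y,

with S = D^(−1/2) W′ D^(−1/2) the symmetrically degree-normalized weight
operator of G′ (D = diagonal weighted degree). S is similar to the
row-stochastic random-walk operator, so its spectral radius is ≤ 1 and the
power iteration converges geometrically for any α < 1; the fixed point
equals the direct solve (1 − α)(I − αS)^(−1) Y, which the tests use as an
oracle on small graphs. Isolated original nodes have a zero operator row
and settle at F = (1 − α)Y. Because (I − αS)^(−1) = Σ αᵏ Sᵏ has
nonnegative entries, scores are nonnegative and monotone in the prior.

Boundedness: with the symmetric normalization, m[v] ≤ 1 is not a theorem
for arbitrary dense priors — a hub whose neighbours are *all* seeded can in
principle exceed 1. For the sparse binary mutation priors the method is
defined for (a few dozen seeds in networks of hundreds to tens of
thousands of genes), scores remain in [0, 1]; the cohort-level test suite
checks this on the simulated study, and no post-hoc clipping is applied
anywhere. A row-normalized operator would guarantee the bound but is not
the formulation this method follows.

### Parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.8 | weight of the network term; 1 − α anchors the prior |
| tol | 1e-6 | max-norm stopping tolerance of the iteration |
| max_iter | 1000 | iteration budget (non-convergence raises, with residual) |
| scheme | sqrt | half-edge weights √w (reliability-preserving) or w/2 |
| normalize_prior | off | optionally rescale a nonzero prior to sum 1 |

The published description of this procedure defers the exact update and
parameter values to supplementary material; here they are exposed as
configuration with the defaults above, which follow the standard
prior-anchored smoothing formulation this method extends. At tol = 1e-6
and α = 0.8 the iterate is within ≈ α/(1−α) · tol of the fixed point;
oracle tests run at tol = 1e-13 to compare against the dense solve at
1e-8.

## Cohort aggregation

Per patient, the edge-score distribution can be collapsed to its median or
maximum (the midpoint convention for even counts). Across patients, each
edge is summarized by its k-th highest score with k = ⌊n · fraction⌋; the
default fraction 0.2 reads "high in at least 20% of patients" (for a
1081-patient cohort, k = ⌊1081/5⌋ = 216). The aggregate is a raw order
statistic — no interpolation — so tied scores share an aggregate. Rankings
sort by descending aggregate with ties broken by ascending canonical
(lexicographically sorted) edge key, making top-k sets reproducible.
Both the per-patient maximum and the decile aggregate are exposed, since
either is a defensible "score" for a pooled top-edges table.

## Evaluation

**Survival screening.** For each edge, a univariate Cox proportional-
hazards model relates patient survival to that edge's propagated scores
across patients. Goodness of fit is summarized by the generalized
(Cox–Snell) R² = 1 − exp(−LRT/n), where LRT is the likelihood-ratio
statistic against the null model; this definition is isolated behind one
function so alternatives can be swapped. The covariate is standardized
before fitting (the partial likelihood ratio is affine-invariant; the
reported coefficient is rescaled back). A constant covariate returns
R² = 0 with a "constant" flag; a cohort with no observed events is an
error. The top-k edges' R² values are compared against ``n_sets`` fresh
without-replacement samples of non-top edges with a one-sided
Mann–Whitney U test ("top edges have higher R²").

**Mann–Whitney U.** Exact tie-aware enumeration of all C(n+m, n) group
assignments when both samples have ≤ 8 observations (p = P(U ≥ U_obs),
the standard non-strict convention; two-sided p measures the symmetric
deviation of U from nm/2); otherwise the tie-corrected,
continuity-corrected normal approximation.

**LBS ranking.** Per patient, an edge is labeled 1 iff either endpoint
gene carries a ligand-binding-site (LBS) mutation present in that
patient's somatic mutations — gene-level incidence, since LBS catalogs do
not name the disrupted partner. The patient's edges are ranked by
propagated score and evaluated by ROC AUC (rank statistic, mid-rank
ties), binary nDCG (each positive discounted by 1/log₂(rank + 1),
normalized by the ideal ranking; within a tied score block each positive
receives the block's average discount, which makes the value
order-independent and exactly 1 iff all positives precede all negatives),
and the two-sided Spearman correlation p-value (t-approximation). The
null redraws, per patient and permutation, the patient's LBS-gene *count*
uniformly from all network genes (count-preserving); drawing from the
patient's own mutated genes is available as an option, since the
published shuffling is not pinned down to a universe. On scale-free
networks the null's positive-edge counts vary strongly with the degree of
the drawn genes, which is the point of preserving counts rather than
edge labels. Real-vs-null differences per metric are tested with
Mann–Whitney U on per-patient real values against the pooled null.

**Docking disruption.** For an interacting pair simulated in both
receptor/ligand orientations, the disruption ratio is
min over orientations of (mutant max docking cluster size) / (wild-type
max cluster size); lower means larger predicted disruption. This is pure
arithmetic over an externally produced 4-row cluster-size table; running
docking or structure tools is out of scope.

## Synthetic study

The fixture generators emulate the data regime the method targets, with
defaults chosen as the package's study conditions:

- **Network**: Barabási–Albert preferential attachment (500 genes,
  attachment 2 → 996 edges), i.i.d. Beta(2, 2) confidence weights.
  Scale-free topology matters because both the propagation and the
  LBS-shuffle null are degree-sensitive.
- **Cohort**: 200 patients; background mutation probability 0.02 per gene
  (≈ 10–15 mutated genes per patient at 500 genes — sparse, as in real
  cohorts); 10 planted driver edges whose endpoint genes mutate at 0.25,
  planting a recoverable edge-level signal.
- **Survival**: exponential times with hazard ∝ exp(effect · z), where z
  is the standardized mean propagated score of the driver edges and the
  effect is 2 per SD; 30% independent uniform censoring. The exponential
  baseline keeps a closed-form oracle available.
- **LBS catalog**: 30% of each patient's mutated genes receive synthetic
  substitution strings (e.g. "F293L"). Real labels therefore mark edges
  near actual mutations — which propagation scores highly — while the
  shuffled null draws mostly unmutated genes; this reproduces, at desk
  scale, the separation the method shows on real cohorts.

A separate uniform G(n, m) generator builds networks of exactly the sizes
of the published interaction databases (17,204 nodes / 314,727 edges and
17,179 / 4,724,503) in seconds, to exercise the augmentation size law at
scale.

What the simulation does *not* emulate: realistic mutation spectra and
gene-length effects, the empirical degree distribution of curated PPI
databases, correlated censoring, or annotation noise in LBS catalogs.
Passing tests show the machinery is correct and that planted edge-level
signal of realistic sparsity is recovered; they do not certify effect
sizes on real cohorts.

## Numerical and design choices

- Canonical edge identity is the lexicographically sorted gene pair;
  dummy-node identifiers derive from it ("GENE1|GENE2"), so augmentation
  is deterministic and input-order-independent.
- Readers collapse duplicate pairs to the maximum weight and drop
  self-loops (a dummy node on a self-loop would create parallel
  half-edges), with counts reported for auditing; STRING combined scores
  are divided by 1000 onto [0, 1], where the documented 0.15 floor lives.
- Genes in mutation data absent from the network are kept in the matrix
  but contribute nothing to priors; the count is logged.
- The cohort propagation builds the normalized operator once and iterates
  per sample; rows are numerically identical to one-off runs.
- All randomness (simulation, random edge sets, shuffled nulls) flows
  through explicit integer seeds; repeated calls are bit-identical.
- Problem sizes used by the automated checks: oracle comparisons on
  graphs of ≤ 200 nodes; reliability preservation on 100 random graphs of
  ≤ 100 nodes × 10 paths each; the end-to-end evaluations on the default
  500-gene / 200-patient study with 100 random edge sets and 100
  permutations — sizes at which every stage has an independent oracle or
  a planted ground truth.

## Known limitations

- Scores from the symmetric operator are not provably ≤ 1 for dense
  priors (see above).
- The Cox screen is univariate by design, as a ranking evaluation — it is
  not a multivariate survival model, and no multiple-testing correction
  is applied to per-edge R² values (only set-level comparisons are made).
- Gene-level LBS labeling marks *all* edges of an LBS-mutated gene, an
  acknowledged over-labeling inherited from catalog granularity.
- Identifier mapping (Entrez ↔ symbol, isoforms) is the caller's
  responsibility; readers treat symbols as opaque labels.
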