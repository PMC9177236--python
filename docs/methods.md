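# Methods

`gango` estimates a per-subject directed ("causal") connectome from a
parcellated resting-state time-series matrix and provides the directed-
network analytics used to characterize such connectomes at the group
level. This note records the model, the estimators, the numerical
choices, and what the synthetic validation does and does not establish.

## Model and assumptions

Observations are rows of an n × p matrix X (samples × parcels), treated
as i.i.d. draws from a linear structural equation model

    x = B x + e,

where B is strictly lower-triangular under some unknown node ordering
(the wiring is acyclic) and the noise components e_i are mutually
independent and **non-Gaussian (skewed)**. Under these assumptions the
skeleton of the graph is recoverable by penalized-likelihood search,
and — unlike in the Gaussian case — the direction of each edge is
identifiable from observational data alone.

The two estimation stages deliberately split these jobs:

1. **Adjacency — greedy equivalence search with a BIC score.** Starting
   from the empty pattern, the forward phase repeatedly applies the
   best-scoring valid Insert(X, Y, T) operator while some insertion
   improves the score; the backward phase then applies the best valid
   Delete(X, Y, H) operator while some deletion improves it. Operator
   validity uses the standard clique and semi-directed-path conditions,
   and after every applied operator the state is re-completed to a
   CPDAG (consistent DAG extension, then v-structures plus Meek rules
   R1–R3; R4 is unnecessary without background knowledge). The local
   score is

       s(v, Pa) = −n·ln σ̂²(v|Pa) − c·|Pa|·ln n,

   the classic BIC up to parent-set-independent constants, with penalty
   discount c = 1 by default. Columns are z-scored first; the score is
   computed from the MLE covariance and memoized per (node, parent set).
   Because degree-based orientation from a greedy search is known to be
   unreliable while its adjacencies are accurate, the resulting pattern
   is **symmetrized**: only the unordered skeleton is kept.

2. **Orientation — pairwise robust-skew statistic.** Each adjacency
   {i, j} is oriented by the sign of

       R = ρ̂ · ( Ê[g(x)·y] − Ê[x·g(y)] ),   g(u) = ln cosh(max(u, 0)),

   computed on the standardized pair, each series sign-flipped to
   positive skewness first. R > 0 reads x→y. The statistic is
   antisymmetric by construction; an exact zero (measure-zero) is
   resolved lower-index → higher-index with a logged warning. The
   functional form is the outlier-robust member of the pairwise
   likelihood-ratio family for skewed LiNGAM pairs; its sign convention
   is pinned by a simulation oracle (identifiable pairs with b = 0.8,
   exponential noise, n = 2400 orient correctly in ≈100% of runs) and
   degrades to chance under Gaussian noise, which motivates the gate.

**Skewness gate.** Orientation is only attempted when the subject's
data are demonstrably skewed: per-parcel |skewness| (biased moment form
m₃/m₂^{3/2}; the small-sample factor cancels in the rank comparison) is
compared against |skewness| of p freshly drawn standard-normal series
of the same length with a one-tailed Wilcoxon rank-sum test (α = 0.05).
The pipeline refuses to orient on a failed gate unless forced.
Near-constant parcels are excluded with a logged warning.

## Network analytics

- **Centralities**: indegree, outdegree, total degree; raw
  (unnormalized) directed betweenness with endpoints excluded. Raw
  counts are used because all comparisons are within a fixed p, and
  they match hand-enumeration oracles exactly.
- **Participation**: P_i = 1 − Σ_s (κ_is/K_i)², with κ restricted to
  incoming, outgoing, or all connections; P_i ≡ 0 when K_i = 0.
- **Global efficiency**: mean of 1/d(i, j) over ordered pairs,
  unreachable pairs contributing 0; directed distances for connectomes,
  undirected for correlation comparison graphs.
- **Hub null**: random digraphs with the observed node count and edge
  counts drawn from Normal(m_mean, m_sd), rounded and clipped. Nodal
  values are pooled across all surrogate graphs and hubs are nodes
  above the pooled 95th percentile (pooling, rather than per-graph
  percentiles, treats the null as one distribution). Heavy-tail tests
  rank-sum compare per-graph skewness of the centrality distributions,
  observed vs surrogate.
- **Correlation comparison graphs**: Pearson matrix, top 15% of
  positive off-diagonal values (proportional cost), or exactly the
  connectome's edge count (density-matched); positive correlations
  only.

## Group statistics

- **Inter-network connectivity**: per module a and partner b, the
  shared count C[a,b] + C[b,a] is Wilcoxon signed-rank tested against
  the equal-spread null (a's out-of-module total divided by N_M − 1),
  BH–FDR corrected over all ordered tests. Surviving pairs are masked
  at paired Cohen's d ≥ 0.2 (mean of subject differences over their
  SD). Direction: the proportion C[a,b]/(C[a,b]+C[b,a]) tested against
  0.5 on connected pairs, FDR corrected. Note the equal-spread null is
  a substantive hypothesis: under uniform node-level wiring it holds
  only for equal-sized modules (expected shared counts scale with the
  partner module's size), and the calibration suites use equal-sized
  modules for exactly that reason.
- **Sender/receiver**: per module, subject-level mean nodal outdegree
  vs indegree, signed-rank, FDR over modules. Edge-free modules are
  reported balanced with a degenerate flag.
- **Friedman + Nemenyi**: module means per subject; if the Friedman
  test (module as within-subject factor) is significant, all-pairs
  Nemenyi on mean ranks with |R_i − R_j|/√(k(k+1)/12n) referred to the
  studentized-range distribution (×√2, df = ∞). The post-hoc is
  implemented directly (mean-rank form); the Friedman statistic comes
  from scipy. Fully tied designs return p = 1 rather than erroring.
- **Wilcoxon handling**: zero differences discarded; exact null for
  ≤ 25 pairs, normal approximation with continuity correction above.
- **Virtual lesions**: per module, nodes are deleted in random order
  (10 orders by default, averaged) while tracking percent change in
  global efficiency from the intact baseline; one random whole-graph
  schedule (length = largest module) is the control, giving N_M + 1
  curves. The summary per curve is the mean pointwise slope in percent
  per deleted node — unit deletion steps, not fraction-of-module, since
  module sizes differ. Curves always store the (0 deletions, 0%)
  baseline point. Single-node deltas E(g − v) − E(g) complement the
  schedules. Deleting a fully disconnected node *raises* efficiency
  (it stops contributing zeros to the average); so, counter to first
  intuition, does deleting a leaf of a reciprocal star (its distance-2
  pairs are the longest in the graph).

## Synthetic data

The generator emulates the statistical regime the pipeline assumes:
sparse random weighted DAGs with an exact edge count
(round(density·p(p−1)/2); default density 2.25%), weights uniform on
±[0.3, 0.8] (strong enough to detect at n ≈ 2400, weak enough to avoid
near-determinism), and noise that is exponential(1) standardized to
zero mean and unit variance by default (theoretical skewness 2, giving
closed-form checks), with gamma and Gaussian alternatives. Rows are
i.i.d.: no temporal autocorrelation, no hemodynamics, no measurement
noise spectra, no spatial structure. Passing tests therefore establish
correctness of the estimators under the model's own assumptions — not
robustness to autocorrelated, filtered, or otherwise realistic
recordings, which real preprocessing pipelines must address upstream.

## Numerical choices

- Score improvements must exceed 10⁻⁹ to count as "> 0", making
  termination robust to floating-point noise without changing behavior
  on real score differences.
- Operator tie-breaks are lexicographic by (X, Y, sorted subset);
  identical inputs give identical outputs.
- Residual variances below 10⁻¹² raise a numerical-rank error
  (collinear parents); constant columns are rejected up front.
- Variance floor 10⁻¹² also defines "degenerate" series for the gate
  and orientation stages.
- Every stochastic stage derives a sub-seed < 2³¹ from the master seed
  and a stage tag via `SeedSequence`, so cohorts, gates, nulls, and
  lesion orders are independently reproducible.

## Validation problem sizes

The test suite validates at desk scale: exhaustive-oracle agreement on
all 25 three-node structures × 20 replicates (n = 2000); adjacency
recovery on p = 20, 5%-density DAGs (20 replicates); orientation on
1000 identifiable pairs plus 1000 Gaussian controls; gate calibration
on 1000 Gaussian replicates (p = 60, n = 400) and power at the full
p = 360, n = 2400; hub-null calibration at p = 100 with 200 surrogates;
group-statistics calibration and planted-effect recovery on 12–20
subject cohorts at p = 24–60; and a deterministic 10-subject, p = 40
end-to-end run. The acceptance script re-measures the same quantities
at comparable sizes.

## Known limitations

- At n = 2000 the BIC-optimal pattern on 5%-dense p = 20 graphs
  typically contains one or two extra adjacencies whose score gain
  genuinely exceeds the BIC penalty; adjacency recall is ~1.0 while
  precision plateaus around 0.87–0.90. This is a property of the score
  at that sample size, not of the search: the search provably returns
  higher-scoring structures than the truth on those runs.
- The orientation stage resolves exactly one direction per adjacency
  and cannot represent reciprocal (two-cycle) connections.
- Greedy search is exact on the equivalence-class oracle at small p
  but carries no global-optimality guarantee at large p.
- All group tests inherit the usual caveats of rank tests on small
  cohorts (exact null only for ≤ 25 nonzero pairs, symmetry assumption
  for signed ranks).
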