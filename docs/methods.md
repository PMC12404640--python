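# Methods

This note documents the models, numerical choices, and design decisions
behind `bcnet`, and what the synthetic validation does and does not show.

## Modularity and the seeded optimizer

Community structure is scored by the weighted modularity with a resolution
parameter,

Q(γ) = (1/2m) Σ_ij [A_ij − γ k_i k_j / (2m)] δ(c_i, c_j),

where A is the streamline-count adjacency matrix, k_i the node strength,
and 2m the total weight. The optimizer is the standard locally greedy
two-phase scheme: repeated single-node moves to the neighboring community
with the largest positive gain, then aggregation of communities into
super-nodes, iterated until no coarsening occurs. Numerical choices:

* a move must improve Q by more than 1e-10 to be accepted (guards against
  float-noise cycling); gain ties resolve to the lowest community id;
* the only randomness is the node-visit order, drawn from a generator
  seeded per run; sub-seeds for ensemble replicate r at grid index g are
  `SeedSequence([master, g, r])`, so any single run is reproducible in
  isolation;
* self-loop weight created by aggregation is excluded from move gains (it
  is invariant to the node's community).

The optimizer is greedy and can stop in local optima; ensembles (defaults
below) are the mitigation, exactly as in common practice. On an exhaustive
fixture set of small graphs (n ≤ 7), the best of 50 seeded runs attains
the enumerated global maximum (tested to 1e-12).

## Partition stability and resolution selection

At each γ in 1.0..4.0 (step 0.1; 31 values), an ensemble of `n_opt`
(default 100) seeded runs is scored by the mean pairwise z-Rand: the
number of node pairs co-assigned in both partitions, standardized by its
mean M₁M₂/M and closed-form variance under independent label
permutations. The subject's γ* is the argmax of mean stability; ties go
to the smallest γ (coarser, more interpretable modules — the selection
rule must be stated since stability plateaus are common). A partition of
all singletons or a single block has zero null variance; by default this
raises an error, and a config option (`zrand_degenerate="nan"`) instead
emits NaN so a sweep can skip degenerate resolutions (NaN resolutions are
excluded from the argmax). The per-γ pairwise reading of "mean z-Rand"
is used, matching peak-stability selection.

## Consensus partitioning

Agreement-matrix consensus: the n×n co-assignment frequency matrix of the
ensemble is computed, entries at or below the permutation-chance level
(mean over partitions of the within-partition pair fraction) are zeroed,
and the thresholded matrix is re-clustered with the same optimizer at
γ = 1, iterating (max 10 rounds) until the re-clustered ensemble is
unanimous. Unanimous input returns unchanged; total disagreement falls
back to singletons. Re-clustering uses min(ensemble size, 32) runs.

## Boundary-controllability ranking

A node is *boundary* if it has at least one positive-weight edge to a node
in another community. The hierarchy is built top-down at the subject's γ*:
level-0 boundary nodes straddle the top-level consensus communities; each
community subgraph with ≥ 4 nodes is re-partitioned (same γ, consensus as
above), and if it splits, its internal boundary nodes not already
classified form the next level; recursion continues into sub-communities.
The 4-node floor prevents meaningless sub-partitions. Disconnected
components separate naturally at the top level (merging across zero weight
never gains); isolated nodes end interior with strength 0 and take the
lowest ranks.

Ranks are assigned in blocks: level 0 gets the top |B₀| ranks, level 1 the
next block, and terminal interior nodes the lowest, ordered by strength.
Within a boundary block, nodes are ordered by the magnitude of their
loading in the leading eigenvector of that level's coupling matrix (the
adjacency restricted to cross-community edges), so nodes mediating more
inter-community weight rank higher; a `cross_strength` ordering (total
cross-community weight) is available as a config alternative, because the
within-block convention is a reconstruction — only the ranks, not the raw
eigenvector scalars, are treated as comparable between subjects, which is
also why the pipeline's outputs are integer ranks. Residual ties break by
ascending node index, making every ranking a strict permutation of 1..N.

## Synthetic cohorts

The generator emulates the *statistical* structure the analysis assumes,
not anatomy:

* **Network**: n = 60 nodes (a 234-node run is configuration only — set
  `n_nodes=234, modules_per_hemisphere=3`), two hemisphere super-blocks of
  3 modules each; expected edge weights are within-module 30, between-
  module (same hemisphere) 3, cross-hemisphere background 0.6, drawn
  Poisson (negative binomial optional for overdispersion) with lognormal
  node propensities (σ = 0.3) for degree heterogeneity. One designated
  node per module carries a homotopic bridge edge (mean 10) to its mirror
  node. Counts of this size give clean planted modules (the optimizer
  recovers them at γ = 1 in ≥ 95% of seeds) while leaving genuine
  stochastic variability in the rankings.
* **Lesion**: a random fraction (default 0.3) of one super-block's nodes
  is deleted (rows/columns zeroed) and surviving edges touching that block
  are attenuated (default × 0.5, re-rounded). The lesion-volume proxy is
  the edge mass lost, monotone in the fraction by construction.
* **Behavior** (lesioned subjects only): phonological-error proportion is
  β₀ + β₁·(rank of the designated contralesional bridge node / N) + noise,
  with β₀ = 0.5, β₁ = −0.3, σ = 0.05; the baseline is set so the planted
  linear relation stays strictly inside [0, 1] over the achievable rank
  range — clipping would otherwise bend the generating model away from
  linearity and bias slope recovery. Semantic errors are drawn
  independently of controllability (the planted null); severity (WAB-AQ)
  and naming accuracy are noisy functions of lesion load; a subset
  (default 50 of 60) has naming data, the rest get missing values.

What passing tests show — and don't. The lesion raises the designated
contralesional node's rank because removing and attenuating one
hemisphere's edges shifts the cross-community coupling eigenvector toward
the intact hemisphere; the paired sign test on this shift is the
qualitative analogue of elevated contralesional controllability after
stroke. The synthetic shift is hemisphere-wide rather than focal to one
region, the planted behavior model is linear by construction, and the
generated marginal distributions (e.g. mean error proportions) are not
matched to any empirical sample — so passing tests validate the pipeline's
inferential machinery, not anatomical claims about real connectomes.
Generation-time rankings use a fixed γ = 1.5 and small ensembles
(`bc_n_opt = 8`); on these strongly modular networks the consensus ranking
is insensitive to ensemble size (rank range 0 over 20 master seeds in the
stability test).

## Statistics

* Rank-sum tests report W = Mann–Whitney U of the first sample (ties
  counted ½), the convention of R's `wilcox.test`; exact permutation p
  when the smaller sample has ≤ 8 observations and no ties, else the
  normal approximation with tie and continuity corrections.
* MAD is scaled by 1.4826 (normal consistency) by default, configurable.
* FDR correction is Benjamini–Hochberg, applied across the per-region
  rank-sum tests that follow the omnibus interaction test.
* The group × region test is a proportional-odds cumulative-logit model on
  BC ranks binned into pooled deciles (hundreds of distinct rank levels
  give unstable threshold estimates; the bin count is configurable).
  Interaction contrasts are reported against the target region as
  reference: a negative contrast means the group shift elsewhere is
  smaller than at the target.
* Behavioral regressions are OLS with listwise deletion (counts logged).
  Outcomes are z-scored within the analysis sample by default; BC rank
  enters raw. The acceptance script disables outcome z-scoring so slopes
  are on the raw proportion-per-rank scale.

## Problem sizes in the shipped checks

The test suite and acceptance script run everything at n = 60 nodes.
The acceptance script uses the full 31-point γ grid with `n_opt = 16`
ensembles for its 122-subject cohort, 40 paired seeds for the lesion
shift, 100 cohorts of n = 50 for CI coverage of the planted slope, and
200 replicates for type-I calibration (10 independent rank cohorts × 20
behavioral redraws — under the null the behavioral noise is the only
random quantity entering the test statistic, so redrawing it against
fixed ranks samples the same null). These sizes were chosen to make the
stochastic checks reproducible in minutes on one CPU.

## Known limitations

* The within-block eigenvector ordering is one defensible convention; a
  different convention permutes ranks within blocks (config-exposed).
* The greedy optimizer's ensembles approximate, not guarantee, the global
  modularity optimum at n where enumeration is impossible.
* Stability plateaus can make γ* sensitive to the tie rule at the listed
  grid spacing; the whole sweep is serialized so this is auditable.
* The synthetic cohort's group difference is hemisphere-wide; analyses of
  regional focality on synthetic data test machinery, not biology.
* The proportional-odds model treats within-subject region ranks as
  independent observations, as in the analysis it reproduces; the
  rank-sum follow-ups are the robustness hedge.
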