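# Methods

## Pipeline

`conncompare` compares two cohorts ("A", the reference, and "B", the
altered group) of ROI-level functional data in four stages.

**Connectivity.** Pearson correlation between every pair of ROI time
courses, Fisher-transformed (z = atanh r).  |r| is clipped to 1 − 1e−7
before atanh so perfect correlations stay finite; this changes no
statistic materially because clipped values occur only for degenerate
inputs.  The diagonal is fixed at 0 and (i,i) pairs are never
enumerated downstream.

**Edge-wise statistics.** Per connection, a two-sample t statistic with
pooled variance (sign convention: positive = stronger in group B).  A
Welch variant is available behind `edge_test: welch`; pooled is the
default because the reference distribution is empirical anyway — the
p-value comes from full label permutations of the pooled cohort, sampled
without enforcing uniqueness (exhaustive enumeration is infeasible at
realistic cohort sizes), with the add-one estimator
p = (1 + #{|t_perm| ≥ |t_obs|}) / (N_per + 1), which cannot return 0.
Edges with zero pooled variance get t = 0 with a logged warning.
Multiplicity is handled by Benjamini–Hochberg step-up on the permutation
p-values at level q.  Defaults: N_per = 10,000, q = 0.05.

**Graph metrics.** Each subject's z-matrix is proportionally thresholded:
the k = round(density·m) largest entries by signed value are kept
(half-away-from-zero rounding; ties at the cutoff broken toward the
lexicographically lower edge index), negatives among the survivors are
zeroed and counted — the quality function and efficiency below assume
nonnegative weights, and at the default densities (0.10–0.25, step 0.05)
surviving negatives are rare.  Modularity

    Q = (1/v) Σ_ij (A_ij − s_i s_j / v) δ(m_i, m_j)

is summed over ordered pairs (s_i node strength, v network cost) and
maximized by a standard two-phase Louvain: local moves to the
neighboring module with maximal Q gain (ties keep the current module,
with a 1e−12 improvement threshold), then module aggregation, repeated
to convergence.  The node sweep order is shuffled per run from the seed;
`best_louvain` keeps the best of n runs (defaults: 100 subject-level,
1000 group-level).  Weighted global efficiency uses edge lengths 1/A_ij,
Dijkstra shortest paths, and averages 1/d_ij over ordered pairs;
disconnected pairs contribute 0.  Both measures are normalized by their
mean over 100 null networks per graph.  The null model randomizes the
binary topology by double-edge swaps — 10× the edge count *attempted*
swaps, so the procedure is O(E) regardless of acceptance rate and
degenerate graphs (e.g. a triangle) simply keep their topology — and
then permutes the original weight multiset onto the new edges.  Degree
sequence and weight multiset are therefore preserved exactly; the
strength sequence is *not* preserved, a documented limitation of this
null class.  Group comparison uses the tie-corrected normal
approximation of the Wilcoxon rank-sum test (z signed so positive means
group B ranks higher); the p-value is exact for small untied samples
(both n ≤ 8) and 2Φ(−|z|) otherwise.  The variance-ratio test reports
F = var(A)/var(B) with (n_A−1, n_B−1) degrees of freedom, two-sided.
Group inferences are reported on normalized Q and E (raw values are also
emitted); headline results are read at the 0.25 density, with all
densities in the report.

**Module structure.** The group-averaged network keeps each edge's mean
z when a two-tailed one-sample t-test against zero survives BH-FDR at q
(the unmasked mean matrix is available behind `mask_group_average:
false`); surviving negative means are zeroed and logged.  The consensus
partition is the highest-Q division over n restarted Louvain runs on the
masked network.  Modules are compared to label sets with the overlap
coefficient |A ∩ B| / min(|A|,|B|); nodes labeled "none" stay inside
their modules but form no label set.  Cross-group module matching is
greedy by decreasing overlap — with the handful of modules that
realistic decompositions produce, greedy and optimal assignment agree,
and the full cross-overlap matrix is always emitted so users can
re-derive the matching.  Module names are taken from the
maximum-overlap a priori label, never hard-coded.

## Synthetic cohorts

The generator emulates denoised, band-limited multi-subject ROI time
series at the level that matters for this pipeline: a block (modular)
population correlation structure with `r_within` = 0.5 inside planted
systems and `r_between` = 0.1 across them, sampled i.i.d. Gaussian per
timepoint.  Pearson correlation is invariant to temporal autocorrelation
in expectation, so none is modeled by default; an AR(1) knob
(`ar_coeff`) exists for sensitivity checks.  Group B differs by

- `coupling_delta` (default 0.15 in the demo study): added to every
  between-module correlation, i.e. more between-module coupling and
  hence a *less modular* network — the direction of the segregation
  finding the pipeline is built to detect; and
- `effect_edges`: per-edge Fisher-z shifts (demo: ten at −0.4, five at
  +0.4), applied by z-shifting the target correlation and re-projecting
  the matrix to the nearest correlation matrix (eigenvalue clipping at
  0, diagonal rescaled), since arbitrary entry edits can break positive
  semidefiniteness.

Demo cohort sizes mirror a typical single-site study: 21 subjects per
group, 282 timepoints.  The demo parcellation is scaled down to 40 nodes
in four systems of 10; with four equal systems, within-system pairs are
22.6% of all pairs, so at the 25% headline density between-system edges
survive thresholding and a coupling difference can reach the graph —
with three systems of 10 (31% within pairs) it could not, which is worth
remembering when designing variants.

What the generator does **not** emulate: hemodynamics, motion or
physiological artifacts, scanner drift, and — importantly — between-
subject heterogeneity of the population covariance (all subjects are
i.i.d. draws from one group-level matrix).  Passing tests therefore
demonstrate correctness and calibration of the machinery, not
performance under realistic inter-subject variability, where effective
power is lower.

## Validation suites and problem sizes

The test suite checks every closed-form toy (disjoint cliques, complete
graphs, short paths), agreement with deliberately naive oracles
(double-loop modularity, Floyd–Warshall efficiency, exhaustive partition
search on ≤ 8 nodes), null calibration (permutation p-value uniformity
over 200 null datasets; realized FDR over 500 all-null replicates;
Q_norm, E_norm within 0.1 of 1 on random graphs, which are their own
null class), and parameter recovery (planted |Δz| = 0.4 effects at 30
subjects/group detected with power ≥ 0.9; the coupling manipulation
lowering group-B normalized modularity in ≥ 90% of 50 replicates at 20
subjects/group).  The calibration and recovery suites run at reduced
settings chosen to keep the whole suite around five minutes on one CPU
— 15–20 nulls, 5–20 Louvain restarts, 199–999 permutations, 7–60-node
graphs — since the quantities being checked (uniformity, FDR bounds,
normalization ratios, detection rates) are insensitive to these counts
beyond the Monte-Carlo noise the assertions already budget for.

## Numerical choices

- Fisher clip 1 − 1e−7; correlation domain tolerance 1e−9.
- Threshold rounding half away from zero; cutoff ties broken by lower
  edge index, making thresholding reproducible across platforms.
- Louvain gain threshold 1e−12 (ties keep the current module).
- Matrix symmetry validated at 1e−8 on read, then exactly symmetrized;
  I/O round-trips are exact to 1e−12 (17-significant-digit text).
- Seeds: one master seed; stage s, item k uses
  `SeedSequence(seed, spawn_key=(s, k))`, so per-subject parallelism
  cannot change any result.  Consensus and subject metrics are
  bit-reproducible given (seed, n_runs).

## Known limitations

- The rewiring null preserves degree, not strength; normalized metrics
  inherit that null class's assumptions.
- Permutation sampling with replacement slightly over-disperses p-values
  at very small N_per; the add-one estimator keeps them valid.
- Greedy module matching can in principle differ from optimal assignment
  when modules are many and overlaps near-tied; the emitted cross-overlap
  matrix is the ground truth in that case.
- The group-averaged consensus Q is reported raw (not null-normalized),
  while subject-level Q is reported normalized; the two are not on the
  same scale.
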