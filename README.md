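# conncompare

Two-group comparison of weighted functional connectomes: edge-wise
permutation statistics with FDR control, normalized graph measures of
segregation and integration, and data-driven modular decomposition
matched against a priori large-scale networks.

## The problem

Resting-state fMRI studies routinely ask whether a clinical or
developmental condition re-shapes whole-brain functional organization:
which individual connections differ between two groups, whether the
network as a whole is more or less segregated, and whether the
data-driven community structure departs from the canonical large-scale
systems (visual, auditory, default mode, fronto-parietal, ...).
`conncompare` implements that comparison pipeline for ROI-level data, and
ships a seeded synthetic-cohort generator with planted ground truth so
that every stage can be validated end to end — the published group
numbers themselves come from human data that is not redistributable, so
the package's claims are about the *method*, exercised on cohorts whose
correct answer is known by construction.

## The model

Per subject, ROI time series give a Pearson correlation matrix that is
Fisher-transformed, z = atanh(r).  On top of these z-matrices:

- **Edge-wise comparison.** For each of the m = n(n−1)/2 connections, a
  two-sample t statistic (pooled variance by default), a permutation
  p-value from N_per label reshuffles of the pooled cohort with the
  add-one estimator p = (1 + #{|t_perm| ≥ |t_obs|}) / (N_per + 1), and a
  Benjamini–Hochberg step-up decision at level q.  Significant edges are
  tallied per pair of large-scale-network labels, stronger and weaker
  separately.  At the customary 258-ROI whole-brain parcellation,
  m = 33,153.

- **Segregation and integration.** Each z-matrix is proportionally
  thresholded to keep the top 10–25% of connections (5% steps).  On the
  resulting weighted graph A, modularity

      Q = (1/v) Σ_ij (A_ij − s_i s_j / v) δ(m_i, m_j),

  with node strength s_i = Σ_j A_ij and cost v = Σ_ij A_ij, is maximized
  by restarted Louvain; weighted global efficiency is
  E_glo = ⟨1/d_ij⟩ with shortest paths over edge lengths 1/A_ij.  Both
  are normalized by their mean over degree-preserving rewired null
  networks, and groups are compared with the Wilcoxon rank-sum test and
  a variance-ratio F test.

- **Module structure.** Each group's mean network (edges surviving a
  one-sample FDR test against zero) is decomposed by best-of-N Louvain
  consensus; data-driven modules are matched to the 13 a priori
  large-scale networks with the overlap coefficient
  overlap(A,B) = |A ∩ B| / min(|A|,|B|), which is 1 exactly when one set
  contains the other.

## Worked example

The numbered scripts under `analysis/` run two synthetic studies — one
with fifteen planted edge effects (|Δz| = 0.4, ten weaker and five
stronger in group B), one with between-module correlation raised by 0.15
in group B — each with 21 subjects per group and 282 timepoints on a
40-node, four-system parcellation:

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_build_connectivity.py
python analysis/03_edgewise_differences.py
python analysis/04_graph_metrics.py
python analysis/05_module_structure.py
```

With the default seed this prints, among other lines:

```
780 connections tested: 6 stronger, 10 weaker in group B
planted effects recovered: 15/15
q_norm: A = 3.031 +- 0.028, B = 3.004 +- 0.029, rank-sum z = -2.86 (p = 0.0043), F(20, 20) = 0.91 (p = 0.8289)
group A: 4 consensus modules, Q = 0.3720, named ['default_mode', 'fronto_parietal', 'somatomotor_hand', 'visual']
group B: 4 consensus modules, Q = 0.1435, named ['default_mode', 'fronto_parietal', 'somatomotor_hand', 'visual']
```

Reading: the edge-wise stage recovers exactly the planted 10-weaker /
5-stronger pattern (one false positive); the coupling manipulation
lowers group B's normalized modularity (rank-sum z = −2.86) while both
groups still decompose into the four planted systems, with group B's
group-averaged network markedly less modular (consensus Q 0.14 vs 0.37).

The same pipeline is scriptable from one config file:

```bash
conncompare run --config demo.yaml --seed 1 --out results/run
```

with subcommands `simulate`, `connectivity`, `edgewise`, `graph`,
`modules`, `report` for stage-wise execution; every stage is
reproducible bit-for-bit from the master seed.

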