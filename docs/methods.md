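# Methods

## Scope and data model

The package analyzes whole-brain structural connectomes whose nodes are
the 116 regions of the macrolabel (AAL) parcellation and whose edges are
streamline counts from deterministic tractography.  The entry point is
the per-subject count matrix; image preprocessing and tractography are
upstream of the package.  The atlas ships as a label/hemisphere table;
voxel counts of region masks are attached per cohort (in real use, from
the registration; in simulation, drawn once per cohort).

## Network construction

**Voxel normalization.**  Dividing streamlines by the voxels of the
*target* mask is direction-dependent for a symmetric count matrix, so
the symmetrized form `w_ij = mean(c_ij/v_j, c_ij/v_i)` is used: it honors
the ratio while preserving symmetry.  Regions with empty masks raise an
error naming the region.

**Thresholding.**  The cohort is first rescaled by the single maximum
edge weight pooled over all networks (the strongest edge anywhere
becomes 1).  Because per-network rank-based removal is scale-invariant,
this global reference affects the comparability of stored weights, not
which edges survive.  Each network then loses its weakest nonzero edges,
weakest first, until density ≤ the target (default 50%); networks
already at or below target are only rescaled.  Pruning removes
`floor(0.10 · E)` of the weakest remaining edges per network, reading
"bottom 10% of weakest streamlines" as an edge-count rule — the
connectomics dialect consistent with final densities near 30%.  Both
stages break ties deterministically by (weight, lexicographic node-label
pair), so builds are bit-reproducible.  Order of operations: global
rescale → proportional threshold → prune.

**Group averaging** is the edgewise arithmetic mean of the thresholded
subject networks of one group.

## Graph measures

Path-based measures run on the connection-length matrix `L = 1/w`
(stronger = shorter).  The "total-weight" normalization mode divides all
weights by the network's total (undirected) weight sum before computing
path length, efficiency, and clustering; this makes the three global
measures invariant to global rescaling of raw weights and hence
comparable across subjects.  The exact algebraic form of this
normalization is a convention of this package (the literature it follows
states the intent, not the formula); outputs are labeled with the mode,
and mode "none" exists for oracle tests against brute-force enumeration.

* Characteristic path length: mean of finite shortest-path lengths over
  ordered pairs; disconnected pairs are excluded and counted (they do
  not occur in practice at ~30% density, but the policy is defined).
* Global efficiency: mean of inverse shortest-path lengths, `1/∞ = 0`.
* Clustering: Onnela geometric-mean-of-triangle-weights formulation with
  weights rescaled by their maximum (the standard weighted-clustering
  convention of the toolbox ecosystem this follows); degree-<2 nodes
  get 0.
* Degree and strength are computed on the stored (thresholded) weights
  and ignore the normalization mode.
* Betweenness: Brandes shortest-path node betweenness on the length
  matrix with fractional sharing among equal-length paths, divided by
  `(n−1)(n−2)` so values lie in [0, 1].

## Communities and hubs

**Louvain consensus.**  The weighted Louvain algorithm is run 100 times
from distinct seeded substreams; a node-pair agreement matrix over the
runs is thresholded at 0.5 and re-clustered with Louvain until ten
reruns agree (standard consensus clustering).  The consensus partition's
Q is recomputed on the original network; all per-iteration Q values are
retained.  Resolution is fixed at 1.  Module labels are canonicalized by
descending size.  Q ≤ 0.3 is treated as the random-network range; the
planted five-module cohorts score Q ≈ 0.65.

**Participation and hub classes.**  PI uses binary (degree-based)
module-edge counts by default — it accompanies degree-based hub tables —
with a weighted variant available.  Hubs are nodes of the group-averaged
network whose degree or strength is ≥ mean + 1 sample SD (the two bases
evaluated independently; a node can be both).  A degenerate SD of 0
yields no hubs.  Classification: provincial PI ≤ 0.3, connector
0.3 < PI ≤ 0.75, else unclassified.  The published sources of this
taxonomy state the two ranges inconsistently in places; the low-PI =
provincial reading (the convention of the hub literature) is the
default, with the swapped reading behind a flag.

**Group comparison.**  Modules of two partitions are matched by optimal
assignment (Hungarian algorithm on the node-overlap contingency table);
migrations are nodes whose matched module changes, and per-module size
change is `(size_B − size_A)/size_A · 100`.  Hub comparison keys on
(node, basis): shared/gained/lost sets plus provincial↔connector status
changes.

## Group inference

* **Nodal permutation tests**: statistic = difference of group means
  (reported as the standard difference score, SDS); subject labels are
  shuffled (default 10,000 iterations) and the two-sided p-value uses
  the add-one estimator `(1 + #{|null| ≥ |obs|})/(n_perm + 1)`, which is
  exactly discrete-uniform under exchangeability (verified by χ² in
  development and by a KS/binomial calibration test in the suite).  An
  exhaustive-enumeration mode replaces sampling for small groups.
  α = .016 is Bonferroni over the three nodal metrics (0.05/3); node-level
  multiplicity is not additionally corrected.
* **Global ANOVA**: split-plot design (between: group; within: metric),
  the only design whose denominator dfs are (2, 45) and (4, 90) for
  16/17/15 subjects × 3 metrics.  Post hoc univariate F-tests run only
  when the omnibus group effect or interaction is significant at .05.
* **Clinical correlates**: Spearman rank correlation (midrank ties),
  two-sided p, joined to nodal metrics of nodes flagged by the
  permutation tests.
* **Demographics**: pooled-variance two-sample t (Welch by flag; a
  summary-statistic mode works from mean/SD/n) and Fisher's exact test
  for 2×2 categorical tables.

## Synthetic cohort generator

The generator emulates the *structure* of a three-group tractography
study, not the imaging physics:

* **Structural support**: a mask of anatomically present edges drawn
  once per cohort — within-module pairs connect with probability 0.90,
  between-module pairs 0.18 — shared by all subjects, keeping the
  group-averaged network at ~33% density as in real whole-brain
  connectomes.  Without a shared support the subject-union of noisy
  edges saturates the group network.
* **Counts**: negative-binomial per edge (dispersion r = 0.6, i.e.
  strongly overdispersed, as streamline counts are), with rates scaled
  by within/between-module weight scales (30 vs 6) and by
  `sqrt(v_i v_j)` of log-normal voxel counts (mean 1500, σ = 0.4), so
  voxel normalization downstream is non-trivial.
* **Hubs**: subcortical/parietal connector hubs (putamen, thalamus,
  precuneus, hippocampus, right caudate, left insula; rate and
  connection-probability multipliers 1.6–1.8) and provincial vermal
  hubs (×2.0 within-module with between-module support attenuated to
  0.25), mirroring the degree/strength hub architecture of group-level
  connectome tables.  The provincial multipliers are set so that every
  planted hub clears the mean + 1 SD criterion in ≥90% of seeds — a
  planted hub must actually be a hub for recovery tests to be
  well-posed.
* **Group effects**: multiplicative row/column shifts of a region's
  counts in one group (right SMA ×1.3 in LD; left insula ×0.8/×0.75 in
  LD/WC, degrading its hub; right ACC ×0.75 in WC), preserving symmetry
  and integrality.
* **Clinical covariates**: group marginals follow the emulated cohort
  table (e.g., LD onset 37.4 ± 12.6 y, duration 19.2 ± 9.7 y); age is
  exactly onset + duration, so the decomposition invariant holds by
  construction (age SD is then mildly inflated relative to the marginal,
  an accepted trade-off).  Rank correlations with a region's planted
  nodal strength are injected through a Gaussian copula at
  `r = 2 sin(π ρ_s/6)`, which targets Spearman's ρ directly.
* **Determinism**: all randomness flows through one seed via spawned
  substreams; identical (config, seed) yields bit-identical files.

What the generator does **not** emulate: spatial geometry and distance-
dependent connectivity, hemispheric asymmetries, subject-level atlas
deformation, tractography biases (gyral bias, false positives), or
missing data.  Passing recovery tests therefore demonstrates that the
pipeline's inference machinery is correct and calibrated under the
planted model — not that the biological findings of any particular
study would replicate.

## Numerical choices and problem sizes

Tie-breaks everywhere are deterministic (weight, then label pair).
Betweenness and path measures use Dijkstra on `1/w`.  Permutation
p-values can never be 0 (add-one).  Spearman targets are verified
against a simulated null: at n = 15 the 95% |ρ| quantile is ≈ 0.50, so
per-seed bands use the simulated quantile rather than a nominal figure.
Recovery tests run 20 generator seeds with 50 consensus iterations
(the full 100 iterations are used for single-cohort checks and the
acceptance script); power checks use 50 cohorts at n_perm = 500, and
permutation calibration 2,000 null datasets at n_perm = 500 — sizes
chosen so the whole suite completes in about a minute while keeping
Monte-Carlo error well below the tested margins.

## Known limitations

* The total-weight normalization is a declared convention; absolute
  values of the global measures are comparable only within one mode.
* Consensus Louvain is stochastic; stability is near-total on modular
  networks but the consensus of a truly random network is arbitrary
  (its Q, the quantity of interest, is stable).
* Fisher's exact test is limited to 2×2 tables; multi-level categorical
  variables need pairwise comparisons.
* The generator's group effects act on a single region's row/column;
  distributed or correlated multi-region effects are out of scope.
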