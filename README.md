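# connectoscope

Whole-brain **structural connectome analysis** for task-specific focal
dystonia-style group studies: from per-subject streamline-count matrices
over a 116-region atlas to thresholded weighted networks, graph-theoretical
measures, community and hub taxonomy, and group-level statistical inference —
together with a synthetic cohort generator that plants known modules, hubs,
nodal group effects and clinical correlations so that every stage of the
pipeline can be validated against ground truth.

It is written for researchers analyzing diffusion-tractography connectomes
(e.g., comparing patient groups such as laryngeal dystonia and writer's
cramp against healthy controls) who want a tested, reproducible
implementation of the standard streamline-count network workflow.

## The pipeline

Starting from a symmetric count matrix `C` (streamlines between atlas
regions) and per-region mask voxel counts `v`:

1. **Voxel normalization** — `w_ij = mean(c_ij/v_j, c_ij/v_i)`, the
   symmetrized ratio of streamline count to target-mask voxels,
   controlling for gray-matter volume differences.
2. **Proportional thresholding** — all networks are rescaled by the
   single maximum edge weight pooled over the cohort; each network then
   loses its weakest edges until density ≤ 50%.
3. **Pruning** — the bottom 10% of each network's weakest edges is
   removed to suppress spurious connections.
4. **Graph measures** — characteristic path length `L` (mean shortest
   path on the connection-length matrix `1/w`), global efficiency `E`
   (mean inverse shortest path), Onnela weighted clustering `C`,
   all computed after dividing weights by the network's total weight;
   nodal degree `k_i`, strength `s_i`, and betweenness centrality `b_i`
   normalized by `(n−1)(n−2)`.
5. **Communities and hubs** — 100-iteration weighted Louvain with
   consensus clustering; modularity `Q = Σ_c (e_c/W − (d_c/2W)²)`;
   hubs are nodes with degree or strength ≥ mean + 1 SD of the
   group-averaged network, classified by participation index
   `PI_i = 1 − Σ_m (κ_im/k_i)²` into provincial (PI ≤ 0.3),
   connector (0.3 < PI ≤ 0.75), or unclassified.
6. **Group inference** — split-plot ANOVA (group × metric) for the
   global measures; 10,000-iteration permutation tests on nodal metrics
   at α = .016 with standard difference scores (SDS = patient mean −
   control mean); Spearman correlations of clinical covariates with
   significantly altered nodal metrics; pooled-t / Fisher demographic
   comparisons.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
simulated 48-subject cohort (16 controls, 17 LD, 15 WC):

```bash
python analysis/01_simulate_cohort.py 1
python analysis/02_build_networks.py
python analysis/03_graph_metrics.py
python analysis/04_communities_hubs.py 1
python analysis/05_group_inference.py 1
```

Output of steps 02 and 04 (seed 1):

```
group LD: averaged density 32.9%
group WC: averaged density 32.9%
group controls: averaged density 32.9%
subject densities: 24.4%-25.2% (all <= 50% by construction, ~10% pruned)
controls: 5 modules, Q = 0.654, 29 hub records
LD: 5 modules, Q = 0.656, 28 hub records
WC: 5 modules, Q = 0.655, 28 hub records
LD vs controls: 0 hub gains, 1 losses, 0 status changes, 0 module migrations
WC vs controls: 0 hub gains, 1 losses, 0 status changes, 0 module migrations
```

The five planted modules are recovered exactly (Q ≈ 0.65 indicates
strong community structure; random networks of this size and density
score Q ≈ 0.14), and both patient groups lose the left insular strength
hub that the generator degraded in them.  Step 05 then finds the planted
nodal effects and clinical correlate:

```
ANOVA group effect F(2,45) = 0.62, p = 0.540
LD: 7 node-metric differences at p <= 0.016
  Insula_L strength: SDS = -0.57, p = 0.0018
WC: 8 node-metric differences at p <= 0.016
  Insula_L strength: SDS = -0.58, p = 0.0016
  Cingulum_Ant_R strength: SDS = -0.51, p = 0.0001
clinical correlates: 3 of 60 at p <= .05
  LD onset_age ~ Insula_L:strength: rho = 0.67, p = 0.003
```

SDS is the difference of group means on that metric; negative values
mean the patient group is lower.  The global ANOVA is null — global
integration/segregation is preserved while regional organization changes,
the typical focal-dystonia pattern.

A `connectoscope` command-line tool exposes the same stages
(`simulate`, `build`, `metrics`, `community`, `hubs`, `infer`, `run`,
`export`); see `connectoscope --help`.

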