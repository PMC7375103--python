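"""End-to-end pipeline: simulate/load -> build -> metrics -> communities ->
hubs -> group inference, with a manifest recording every parameter.

The stages mirror the connectome analysis workflow: per-subject networks
are voxel-normalized, cohort-rescaled, proportionally thresholded to the
target density and pruned; group-averaged networks are partitioned by
consensus Louvain and their hub taxonomy extracted; nodal metrics are
compared between each patient group and controls by permutation test;
clinical covariates are correlated with the nodal metrics at regions
flagged as significantly different.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .build import group_average, normalize_streamlines, proportional_threshold, prune_weak
from .community import compare_hubs, identify_hubs, louvain_partition
from .inference import anova_global, permutation_test, significance_filter, spearman
from .metrics import global_metrics, nodal_metric_table
from .synthetic import CohortConfig, default_config, generate_cohort

logger = logging.getLogger("connectoscope")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    density_target: float = 0.5
    prune_fraction: float = 0.10
    normalization: str = "total-weight"
    louvain_iterations: int = 100
    n_perm: int = 10_000
    alpha: float = 0.016
    anova_alpha: float = 0.05
    seed: int = 0
    control_group: str = "controls"
    cohort: CohortConfig | None = None  # None -> default synthetic cohort

    def __post_init__(self) -> None:
        if not 0 < self.density_target <= 1:
            raise ValueError("density_target must be in (0, 1]")
        if not 0 <= self.prune_fraction < 1:
            raise ValueError("prune_fraction must be in [0, 1)")
        if self.louvain_iterations < 1 or self.n_perm < 1:
            raise ValueError("iteration counts must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, default=lambda o: getattr(o, "__dict__", str(o)))


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: object
    subject_networks: dict[str, list]
    group_networks: dict[str, object]
    group_densities: dict[str, float]
    partitions: dict[str, object]
    hubs: dict[str, list]
    hub_comparisons: dict[str, object]
    global_table: pd.DataFrame
    anova: list
    nodal_results: dict[str, list]
    correlations: list
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig | None = None, out_dir=None) -> PipelineResult:
    """Run every stage on a (by default synthetic) cohort.

    Deterministic for a fixed config: the cohort seed, the Louvain
    consensus streams, and the permutation streams all derive from
    ``config.seed``.
    """
    config = config or PipelineConfig()
    ss = np.random.SeedSequence(config.seed)
    seed_cohort, seed_louvain, seed_perm = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    manifest: dict = {"stages": [], "parameters": json.loads(config.to_json())}

    t0 = _stage("simulate")
    cohort_cfg = config.cohort or default_config(seed=seed_cohort)
    cohort = generate_cohort(cohort_cfg)
    manifest["stages"].append({"name": "simulate", "seconds": time.perf_counter() - t0,
                               "n_subjects": len(cohort.matrices)})

    t0 = _stage("build")
    normalized = [normalize_streamlines(m) for m in cohort.matrices]
    thresholded = proportional_threshold(normalized, config.density_target)
    pruned = [prune_weak(net, config.prune_fraction) for net in thresholded]
    groups = [g.name for g in cohort_cfg.groups]
    subject_networks = {g: [n for n in pruned if n.group == g] for g in groups}
    group_networks = {g: group_average(nets, g) for g, nets in subject_networks.items()}
    group_densities = {g: net.density for g, net in group_networks.items()}
    manifest["stages"].append({"name": "build", "seconds": time.perf_counter() - t0,
                               "group_densities": group_densities})

    t0 = _stage("metrics")
    rows = []
    for g, nets in subject_networks.items():
        for net in nets:
            gm = global_metrics(net, config.normalization)
            for metric, value in (
                ("char_path_length", gm.char_path_length),
                ("global_efficiency", gm.global_efficiency),
                ("clustering_coefficient", gm.clustering_coefficient),
            ):
                rows.append({"subject": net.subject_id, "group": g,
                             "metric": metric, "value": value})
    global_table = pd.DataFrame(rows)
    nodal_tables = {
        g: {net.subject_id: nodal_metric_table(net, config.normalization) for net in nets}
        for g, nets in subject_networks.items()
    }
    manifest["stages"].append({"name": "metrics", "seconds": time.perf_counter() - t0})

    t0 = _stage("community")
    partitions = {
        g: louvain_partition(net, config.louvain_iterations, seed=seed_louvain)
        for g, net in group_networks.items()
    }
    hubs = {g: identify_hubs(group_networks[g], partitions[g]) for g in groups}
    control = config.control_group
    hub_comparisons = {
        g: compare_hubs(hubs[control], hubs[g], partitions[control], partitions[g])
        for g in groups
        if g != control
    }
    manifest["stages"].append({
        "name": "community", "seconds": time.perf_counter() - t0,
        "n_modules": {g: p.n_modules for g, p in partitions.items()},
        "q": {g: p.q for g, p in partitions.items()},
    })

    t0 = _stage("inference")
    anova = anova_global(global_table, alpha=config.anova_alpha)
    nodal_results: dict[str, list] = {}
    labels = cohort.atlas.region_labels
    for g in groups:
        if g == control:
            continue
        results = []
        for metric in ("degree", "strength", "betweenness"):
            patients = np.stack(
                [t[metric].to_numpy() for t in nodal_tables[g].values()]
            )
            controls_v = np.stack(
                [t[metric].to_numpy() for t in nodal_tables[control].values()]
            )
            for i, label in enumerate(labels):
                results.append(
                    permutation_test(
                        patients[:, i], controls_v[:, i],
                        n_perm=config.n_perm, seed=seed_perm + i,
                        alpha=config.alpha, node=label, metric=metric,
                    )
                )
        nodal_results[g] = results
    significant = {g: significance_filter(r, config.alpha) for g, r in nodal_results.items()}

    correlations = []
    clinical = cohort.clinical
    for g in groups:
        if g == control:
            continue
        sub = clinical[clinical["group"] == g].set_index("subject")
        for res in significant[g]:
            idx = labels.index(res.node)
            metric_by_subject = {
                sid: t[res.metric].iloc[idx] for sid, t in nodal_tables[g].items()
            }
            for var in ("duration", "onset_age", "bfm_movement", "bfm_disability"):
                x = sub[var].to_numpy(dtype=float)
                y = np.array([metric_by_subject[s] for s in sub.index])
                ok = ~np.isnan(x)
                if ok.sum() >= 5 and np.ptp(x[ok]) > 0 and np.ptp(y[ok]) > 0:
                    correlations.append(
                        spearman(x[ok], y[ok], clinical_variable=f"{g}:{var}",
                                 node_metric=f"{res.node}:{res.metric}")
                    )
    manifest["stages"].append({"name": "inference", "seconds": time.perf_counter() - t0,
                               "n_significant": {g: len(r) for g, r in significant.items()}})

    result = PipelineResult(
        config=config, cohort=cohort, subject_networks=subject_networks,
        group_networks=group_networks, group_densities=group_densities,
        partitions=partitions, hubs=hubs, hub_comparisons=hub_comparisons,
        global_table=global_table, anova=anova, nodal_results=nodal_results,
        correlations=correlations, manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cio.write_cohort(result.cohort, out / "cohort")
    for g, net in result.group_networks.items():
        cio.write_network_tsv(net, out / f"group_{g}.tsv")
        part = result.partitions[g]
        (out / f"partition_{g}.json").write_text(json.dumps({
            "assignment": part.assignment.tolist(), "q": part.q,
            "n_modules": part.n_modules, "method": part.method,
            "iteration_qs": list(part.iteration_qs),
        }, indent=1))
        hub_rows = [dataclasses.asdict(h) for h in result.hubs[g]]
        pd.DataFrame(hub_rows).to_csv(out / f"hubs_{g}.tsv", sep="\t", index=False)
        cio.export_graphml(net, out / f"group_{g}.graphml", part, result.hubs[g])
    result.global_table.to_csv(out / "global_metrics.tsv", sep="\t", index=False)
    for g, results in result.nodal_results.items():
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            out / f"nodal_tests_{g}.tsv", sep="\t", index=False
        )
    pd.DataFrame([dataclasses.asdict(a) for a in result.anova]).to_csv(
        out / "anova.tsv", sep="\t", index=False
    )
    pd.DataFrame([dataclasses.asdict(c) for c in result.correlations]).to_csv(
        out / "clinical_correlations.tsv", sep="\t", index=False
    )
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1, default=float))
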