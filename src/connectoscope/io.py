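"""Plain-text I/O: adjacency TSV, atlas/clinical tables, manifests, GraphML.

Adjacency matrices are written as TSV with the region labels as both the
header row and an index column, so files are self-describing and
round-trip against an atlas.  Provenance of derived networks goes to a
JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .atlas import AtlasSpec
from .build import StreamlineMatrix, WeightedNetwork

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_network_tsv",
    "read_network_tsv",
    "write_cohort",
    "read_cohort_matrices",
    "export_graphml",
]


def write_matrix_tsv(matrix: StreamlineMatrix, path) -> None:
    df = pd.DataFrame(
        matrix.counts, index=matrix.atlas.region_labels, columns=matrix.atlas.region_labels
    )
    df.to_csv(path, sep="\t", index_label="region")


def read_matrix_tsv(path, atlas: AtlasSpec, subject_id: str, group: str) -> StreamlineMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if tuple(df.columns) != atlas.region_labels:
        raise ValueError(f"{path}: column labels do not match the atlas")
    return StreamlineMatrix(df.to_numpy(dtype=np.int64), atlas, subject_id, group)


def write_network_tsv(net: WeightedNetwork, path, sidecar: bool = True) -> None:
    df = pd.DataFrame(net.weights, index=net.atlas.region_labels, columns=net.atlas.region_labels)
    df.to_csv(path, sep="\t", index_label="region", float_format="%.10g")
    if sidecar:
        meta = {
            "subject_id": net.subject_id,
            "group": net.group,
            "provenance": list(net.provenance),
            "density": net.density,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_network_tsv(path, atlas: AtlasSpec) -> WeightedNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if tuple(df.columns) != atlas.region_labels:
        raise ValueError(f"{path}: column labels do not match the atlas")
    meta_path = Path(str(path) + ".json")
    subject_id, group, provenance = "", "", ("loaded",)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        subject_id = meta.get("subject_id", "")
        group = meta.get("group", "")
        provenance = tuple(meta.get("provenance", [])) or ("loaded",)
    return WeightedNetwork(
        df.to_numpy(dtype=float), atlas, subject_id=subject_id, group=group, provenance=provenance
    )


def _config_to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _config_to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_config_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_cohort(cohort, out_dir) -> Path:
    """Write a synthetic cohort: per-subject TSVs, atlas, clinical, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m in cohort.matrices:
        write_matrix_tsv(m, out / f"{m.subject_id}.tsv")
    cohort.atlas.to_frame().to_csv(out / "atlas.tsv", sep="\t", index=False)
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    manifest = {
        "config": _config_to_jsonable(cohort.config),
        "seed": cohort.config.seed,
        "planted_modules": cohort.planted_modules.tolist(),
        "subjects": [m.subject_id for m in cohort.matrices],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_cohort_matrices(in_dir, atlas: AtlasSpec) -> list[StreamlineMatrix]:
    """Load every per-subject matrix named in a cohort manifest."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    clinical = pd.read_csv(in_dir / "clinical.tsv", sep="\t")
    group_of = dict(zip(clinical["subject"], clinical["group"]))
    return [
        read_matrix_tsv(in_dir / f"{sid}.tsv", atlas, sid, group_of.get(sid, ""))
        for sid in manifest["subjects"]
    ]


def export_graphml(net: WeightedNetwork, path, partition=None, hubs=None) -> None:
    """GraphML export with module, hub and metric node attributes."""
    from .metrics import nodal_degree, nodal_strength

    G = nx.Graph()
    degree = nodal_degree(net)
    strength = nodal_strength(net)
    hub_by_node: dict[str, list] = {}
    for h in hubs or []:
        hub_by_node.setdefault(h.node, []).append(h)
    for i, label in enumerate(net.atlas.region_labels):
        attrs = {
            "label": label,
            "hemisphere": net.atlas.hemisphere[i],
            "degree": int(degree[i]),
            "strength": float(strength[i]),
        }
        if partition is not None:
            attrs["module"] = int(partition.assignment[i])
        node_hubs = hub_by_node.get(label, [])
        attrs["hub_basis"] = ",".join(sorted(h.basis for h in node_hubs))
        attrs["hub_class"] = node_hubs[0].klass if node_hubs else ""
        G.add_node(label, **attrs)
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    for i, j in zip(iu, ju):
        w = net.weights[i, j]
        if w > 0:
            G.add_edge(
                net.atlas.region_labels[i], net.atlas.region_labels[j], weight=float(w)
            )
    nx.write_graphml(G, path)
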