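"""Compute integration, segregation, and nodal-influence measures.

For every subject network: characteristic path length, global efficiency
and mean clustering (total-weight normalized), plus per-node degree,
strength and betweenness tables.  Writes results/metrics/.
"""

from pathlib import Path

import pandas as pd

from connectoscope.atlas import load_atlas_tsv
from connectoscope.io import read_network_tsv
from connectoscope.metrics import global_metrics, nodal_metric_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    atlas = load_atlas_tsv(ROOT / "cohort" / "atlas.tsv")
    clinical = pd.read_csv(ROOT / "cohort" / "clinical.tsv", sep="\t")
    out = ROOT / "metrics"
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for row in clinical.itertuples():
        net = read_network_tsv(ROOT / "networks" / f"{row.subject}.tsv", atlas)
        gm = global_metrics(net, normalization="total-weight")
        rows.append({"subject": row.subject, "group": row.group, **gm.to_dict()})
        nodal_metric_table(net).to_csv(out / f"{row.subject}.tsv", sep="\t", index=False)
    table = pd.DataFrame(rows)
    table.to_csv(out / "global_metrics.tsv", sep="\t", index=False)
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)

    summary = table.groupby("group")[
        ["char_path_length", "global_efficiency", "clustering_coefficient"]
    ].agg(["mean", "std"])
    print("global metrics by group (total-weight normalized):")
    print(summary.round(4).to_string())
    if (table["n_disconnected_pairs"] > 0).any():
        print("warning: disconnected node pairs present in some networks")


if __name__ == "__main__":
    main()
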