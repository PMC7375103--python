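"""Community structure and hub taxonomy of the group-averaged networks.

Partitions each group network with 100-iteration consensus Louvain,
identifies degree/strength hubs (mean + 1 SD) with provincial/connector
classes, and tabulates module migrations and hub gains/losses/status
changes of each patient group against controls.  Writes
results/communities/.
"""

import dataclasses
import json
import sys
from pathlib import Path

import pandas as pd

from connectoscope.atlas import load_atlas_tsv
from connectoscope.community import compare_hubs, identify_hubs, louvain_partition
from connectoscope.io import export_graphml, read_network_tsv

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1] / "results"
GROUPS = ("controls", "LD", "WC")


def main() -> None:
    atlas = load_atlas_tsv(ROOT / "cohort" / "atlas.tsv")
    out = ROOT / "communities"
    out.mkdir(parents=True, exist_ok=True)

    nets, parts, hubs = {}, {}, {}
    for group in GROUPS:
        nets[group] = read_network_tsv(ROOT / "networks" / f"group_{group}.tsv", atlas)
        parts[group] = louvain_partition(nets[group], n_iterations=100, seed=SEED)
        hubs[group] = identify_hubs(nets[group], parts[group])
        (out / f"partition_{group}.json").write_text(json.dumps({
            "assignment": parts[group].assignment.tolist(),
            "q": parts[group].q, "n_modules": parts[group].n_modules,
            "method": parts[group].method,
        }, indent=1))
        pd.DataFrame([dataclasses.asdict(h) for h in hubs[group]]).to_csv(
            out / f"hubs_{group}.tsv", sep="\t", index=False
        )
        export_graphml(nets[group], out / f"group_{group}.graphml",
                       parts[group], hubs[group])
        print(f"{group}: {parts[group].n_modules} modules, Q = {parts[group].q:.3f}, "
              f"{len(hubs[group])} hub records")

    for patient in ("LD", "WC"):
        cmp = compare_hubs(hubs["controls"], hubs[patient],
                           parts["controls"], parts[patient])
        report = {
            "shared": sorted(map(list, cmp.shared)),
            "gained": sorted(map(list, cmp.gained)),
            "lost": sorted(map(list, cmp.lost)),
            "status_changes": [list(s) for s in cmp.status_changes],
            "module_migrations": [list(m) for m in cmp.module_migrations],
            "module_size_changes_pct": {
                str(k): round(v, 1) for k, v in cmp.module_size_changes.items()
            },
        }
        (out / f"comparison_{patient}.json").write_text(json.dumps(report, indent=1))
        print(f"{patient} vs controls: {len(cmp.gained)} hub gains, "
              f"{len(cmp.lost)} losses, {len(cmp.status_changes)} status changes, "
              f"{len(cmp.module_migrations)} module migrations")


if __name__ == "__main__":
    main()
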