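"""Generate the study-structured synthetic cohort.

Draws 48 subjects (16 controls, 17 laryngeal dystonia, 15 writer's
cramp) of 116-region streamline-count matrices with 5 planted modules,
a subcortical hub architecture, group-level nodal effects, and clinical
covariates, and writes everything under results/cohort/.
"""

import sys
from pathlib import Path

from connectoscope.io import write_cohort
from connectoscope.synthetic import default_config, generate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = generate_cohort(default_config(seed=SEED))
    out = write_cohort(cohort, OUT / "cohort")
    by_group = cohort.clinical.groupby("group").size()
    print(f"wrote {len(cohort.matrices)} subjects to {out}")
    print(by_group.to_string())
    print(f"planted modules: {len(set(cohort.planted_modules.tolist()))}")
    print(f"atlas: {cohort.atlas.n_regions} regions, "
          f"voxel counts {min(cohort.atlas.voxel_counts)}-{max(cohort.atlas.voxel_counts)}")


if __name__ == "__main__":
    main()
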