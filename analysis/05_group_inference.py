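"""Group-level inference: global ANOVA, nodal permutation tests, clinical
correlates, and demographics.

Runs the split-plot ANOVA over the three global metrics, 10,000-iteration
permutation tests on every node x metric (alpha = .016), Spearman
correlations of clinical covariates with the significantly altered nodal
metrics, and the demographic comparison table.  Writes results/inference/.
"""

import dataclasses
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from connectoscope.inference import (
    anova_global,
    demographics_compare,
    permutation_test,
    significance_filter,
    spearman,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1] / "results"
N_PERM = 10_000
ALPHA = 0.016


def main() -> None:
    mdir = ROOT / "metrics"
    clinical = pd.read_csv(ROOT / "cohort" / "clinical.tsv", sep="\t")
    out = ROOT / "inference"
    out.mkdir(parents=True, exist_ok=True)

    global_table = pd.read_csv(mdir / "global_metrics.tsv", sep="\t")
    long = global_table.melt(
        id_vars=["subject", "group"],
        value_vars=["char_path_length", "global_efficiency", "clustering_coefficient"],
        var_name="metric", value_name="value",
    )
    anova = anova_global(long)
    pd.DataFrame([dataclasses.asdict(a) for a in anova]).to_csv(
        out / "anova.tsv", sep="\t", index=False
    )
    by_effect = {a.effect: a for a in anova}
    g, gx = by_effect["group"], by_effect["group x metric"]
    print(f"ANOVA group effect F({g.df_num},{g.df_den}) = {g.f_value:.2f}, p = {g.p:.3f}")
    print(f"ANOVA interaction F({gx.df_num},{gx.df_den}) = {gx.f_value:.2f}, p = {gx.p:.3f}")

    tables = {
        row.subject: pd.read_csv(mdir / f"{row.subject}.tsv", sep="\t")
        for row in clinical.itertuples()
    }
    groups = dict(zip(clinical["subject"], clinical["group"]))
    labels = next(iter(tables.values()))["label"].tolist()

    all_results = {}
    for patient_group in ("LD", "WC"):
        results = []
        for metric in ("degree", "strength", "betweenness"):
            pa = np.stack([t[metric].to_numpy() for s, t in tables.items()
                           if groups[s] == patient_group])
            co = np.stack([t[metric].to_numpy() for s, t in tables.items()
                           if groups[s] == "controls"])
            for i, label in enumerate(labels):
                results.append(permutation_test(
                    pa[:, i], co[:, i], n_perm=N_PERM, seed=SEED * 100_000 + i,
                    alpha=ALPHA, node=label, metric=metric,
                ))
        frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
        frame["significant"] = frame["p"] <= ALPHA
        frame.to_csv(out / f"nodal_tests_{patient_group}.tsv", sep="\t", index=False)
        sig = significance_filter(results, ALPHA)
        all_results[patient_group] = (results, sig)
        print(f"{patient_group}: {len(sig)} node-metric differences at p <= {ALPHA}")
        for r in sig:
            print(f"  {r.node} {r.metric}: SDS = {r.sds:.2f}, p = {r.p:.4f}")

    corr_rows = []
    for patient_group, (_, sig) in all_results.items():
        sub = clinical[clinical["group"] == patient_group].set_index("subject")
        for r in sig:
            idx = labels.index(r.node)
            y = np.array([tables[s][r.metric].iloc[idx] for s in sub.index])
            for var in ("duration", "onset_age", "bfm_movement", "bfm_disability"):
                x = sub[var].to_numpy(dtype=float)
                if np.isnan(x).all() or np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue
                res = spearman(x, y, clinical_variable=var,
                               node_metric=f"{r.node}:{r.metric}")
                corr_rows.append({"group": patient_group,
                                  **dataclasses.asdict(res)})
    if corr_rows:
        corr = pd.DataFrame(corr_rows)
        corr.to_csv(out / "clinical_correlations.tsv", sep="\t", index=False)
        sig_corr = corr[corr["p"] <= 0.05]
        print(f"clinical correlates: {len(sig_corr)} of {len(corr)} at p <= .05")
        for row in sig_corr.itertuples():
            print(f"  {row.group} {row.clinical_variable} ~ {row.node_metric}: "
                  f"rho = {row.rho:.2f}, p = {row.p:.3f}")

    demo_rows = []
    for a, b in (("LD", "WC"), ("controls", "LD"), ("controls", "WC")):
        ca = clinical[clinical["group"] == a]
        cb = clinical[clinical["group"] == b]
        cont = ("age", "onset_age", "duration", "bfm_movement", "bfm_disability") \
            if "controls" not in (a, b) else ("age",)
        table = demographics_compare(ca, cb, continuous=cont)
        table.insert(0, "comparison", f"{a} vs {b}")
        demo_rows.append(table)
    demo = pd.concat(demo_rows, ignore_index=True)
    demo.to_csv(out / "demographics.tsv", sep="\t", index=False)
    print(f"demographics: min p = {demo['p'].min():.2f} "
          f"({'no' if (demo['p'] > 0.05).all() else 'some'} group differences)")


if __name__ == "__main__":
    main()
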