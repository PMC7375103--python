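"""Group-level statistics: permutation tests, split-plot ANOVA, Spearman
correlations, and demographic-table comparisons.

Nodal metrics (degree, strength, betweenness) are compared between a
patient and a control group with a nonparametric permutation test on the
difference of group means: subject labels are shuffled (default 10,000
iterations), the two-sided p-value uses the add-one estimator
``p = (1 + #{|null| >= |obs|}) / (n_perm + 1)``, and results carry the
standard difference score SDS = mean(patients) - mean(controls).  With
three nodal metrics per node, the significance level 0.016 (~0.05/3) is
the Bonferroni-corrected default.

The three global metrics are compared across groups with a split-plot
ANOVA (between-subject factor: group; within-subject factor: metric);
for the study's design counts of 16/17/15 subjects and 3 metrics the
group effect has df (2, 45) and the interaction df (4, 90).  Post hoc
univariate F-tests per metric follow only when the omnibus is
significant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "PermutationResult",
    "AnovaResult",
    "CorrelationResult",
    "permutation_test",
    "compute_sds",
    "anova_global",
    "spearman",
    "demographics_compare",
    "significance_filter",
]


@dataclass(frozen=True)
class PermutationResult:
    node: str
    metric: str
    mean_a: float
    mean_b: float
    sds: float
    p: float
    n_permutations: int
    alpha: float
    exact: bool = False

    @property
    def significant(self) -> bool:
        return self.p <= self.alpha


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    df_num: int
    df_den: int
    f_value: float
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    clinical_variable: str
    node_metric: str
    rho: float
    p: float
    n: int


def compute_sds(mean_patients: float, mean_controls: float) -> float:
    """Standard difference score: patient minus control group mean."""
    return mean_patients - mean_controls


def permutation_test(
    values_a,
    values_b,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.016,
    node: str = "",
    metric: str = "",
    exact: bool = False,
) -> PermutationResult:
    """Two-sided permutation test on the difference of group means.

    Group A is the patient group (its mean enters the SDS first).  With
    ``exact=True`` the full set of label assignments is enumerated and
    the p-value is the exact proportion ``#{|null| >= |obs|} / n_total``
    (only sensible for small groups); otherwise ``n_perm`` random
    shuffles with the add-one estimator.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 subjects per group")
    pooled = np.concatenate([a, b])
    n_a, n_tot = a.size, a.size + b.size
    observed = a.mean() - b.mean()

    if exact:
        null = np.array(
            [
                pooled[list(idx)].mean()
                - np.delete(pooled, list(idx)).mean()
                for idx in itertools.combinations(range(n_tot), n_a)
            ]
        )
        p = float(np.count_nonzero(np.abs(null) >= np.abs(observed) - 1e-12) / null.size)
        n_used = null.size
    else:
        rng = np.random.default_rng(seed)
        # one shuffle per row, vectorized
        perm = rng.permuted(np.broadcast_to(pooled, (n_perm, n_tot)), axis=1)
        null = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
        p = float((1 + np.count_nonzero(np.abs(null) >= np.abs(observed) - 1e-12)) / (n_perm + 1))
        n_used = n_perm
    return PermutationResult(
        node=node,
        metric=metric,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sds=compute_sds(float(a.mean()), float(b.mean())),
        p=p,
        n_permutations=n_used,
        alpha=alpha,
        exact=exact,
    )


def anova_global(
    metric_values: pd.DataFrame,
    alpha: float = 0.05,
    posthoc: bool = True,
) -> list[AnovaResult]:
    """Split-plot ANOVA for the global metrics across groups.

    ``metric_values`` is long-form with columns ``subject``, ``group``,
    ``metric``, ``value``; every subject must have every metric.  Reports
    the group main effect and group x metric interaction; when either is
    significant at ``alpha`` (and ``posthoc``), appends per-metric
    univariate one-way F-tests.
    """
    required = {"subject", "group", "metric", "value"}
    if not required <= set(metric_values.columns):
        raise ValueError(f"need columns {sorted(required)}")
    counts = metric_values.groupby("subject")["metric"].nunique()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: every subject needs every metric")

    table = pg.mixed_anova(
        data=metric_values, dv="value", within="metric", subject="subject", between="group"
    )
    by_source = {row["Source"]: row for _, row in table.iterrows()}
    results = [
        AnovaResult("group", int(by_source["group"]["DF1"]), int(by_source["group"]["DF2"]),
                    float(by_source["group"]["F"]), float(by_source["group"]["p_unc"])),
        AnovaResult("group x metric", int(by_source["Interaction"]["DF1"]),
                    int(by_source["Interaction"]["DF2"]),
                    float(by_source["Interaction"]["F"]),
                    float(by_source["Interaction"]["p_unc"])),
    ]
    omnibus_significant = any(r.p <= alpha for r in results)
    if posthoc and omnibus_significant:
        for metric, sub in metric_values.groupby("metric"):
            groups = [g["value"].to_numpy() for _, g in sub.groupby("group")]
            f, p = stats.f_oneway(*groups)
            k, n = len(groups), sum(len(g) for g in groups)
            results.append(AnovaResult(f"posthoc:{metric}", k - 1, n - k, float(f), float(p)))
    return results


def spearman(
    clinical_values,
    metric_values,
    clinical_variable: str = "",
    node_metric: str = "",
) -> CorrelationResult:
    """Spearman rank correlation (midrank ties) with two-sided p."""
    x = np.asarray(clinical_values, dtype=float)
    y = np.asarray(metric_values, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples required")
    if x.size < 5:
        raise ValueError("need n >= 5 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one variable; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(clinical_variable, node_metric, float(rho), float(p), int(x.size))


def _t_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Pooled-variance two-sample t from summary statistics."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), float(res.pvalue), n1 + n2 - 2


def demographics_compare(
    clinical_a: pd.DataFrame,
    clinical_b: pd.DataFrame,
    continuous: tuple[str, ...] = ("age", "onset_age", "duration", "bfm_movement", "bfm_disability"),
    categorical: tuple[str, ...] = ("sex",),
    welch: bool = False,
) -> pd.DataFrame:
    """Pairwise demographic comparison of two groups.

    Continuous variables get a two-sample t test (pooled variance by
    default, Welch by flag); categorical variables a Fisher's exact test
    on the 2xK contingency table (K must be 2).  Returns a table of
    (variable, test, statistic, p).
    """
    rows = []
    for var in continuous:
        if var not in clinical_a.columns or var not in clinical_b.columns:
            continue
        x = clinical_a[var].dropna().to_numpy(dtype=float)
        y = clinical_b[var].dropna().to_numpy(dtype=float)
        if x.size < 2 or y.size < 2:
            raise ValueError(f"need at least 2 observations per group for {var!r}")
        res = stats.ttest_ind(x, y, equal_var=not welch)
        rows.append({"variable": var, "test": "welch-t" if welch else "t",
                     "statistic": float(res.statistic), "p": float(res.pvalue)})
    for var in categorical:
        if var not in clinical_a.columns or var not in clinical_b.columns:
            continue
        levels = sorted(set(clinical_a[var]) | set(clinical_b[var]))
        if len(levels) != 2:
            raise ValueError(f"Fisher's exact needs exactly 2 levels for {var!r}")
        table = [
            [int((clinical_a[var] == lv).sum()) for lv in levels],
            [int((clinical_b[var] == lv).sum()) for lv in levels],
        ]
        _, p = stats.fisher_exact(table)
        rows.append({"variable": var, "test": "fisher", "statistic": np.nan, "p": float(p)})
    return pd.DataFrame(rows)


def demographics_compare_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled two-sample t from (mean, SD, n) summaries: (t, df, two-sided p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    t, p, df = _t_from_summary(mean1, sd1, n1, mean2, sd2, n2)
    return t, df, p


def significance_filter(results, alpha: float = 0.016):
    """Retain results with p <= alpha (boundary inclusive)."""
    return [r for r in results if r.p <= alpha]
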