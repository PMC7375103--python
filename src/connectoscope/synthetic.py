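"""Synthetic multi-subject cohorts of streamline-count connectomes.

Emulates the output of deterministic whole-brain tractography over a
116-region atlas: per-subject symmetric integer count matrices with

* planted modular structure -- ``n_modules`` communities with
  overdispersed negative-binomial edge counts, denser within than
  between modules,
* a subcortical hub architecture -- configurable regions whose incident
  edge rates are multiplied up, so they emerge as degree/strength hubs
  of the group-averaged network,
* group-level nodal effects -- multiplicative (or additive) shifts of a
  region's row/column counts in one group, the ground truth for
  permutation tests,
* clinical covariates (age, sex, onset age, duration, severity scores)
  whose group marginals follow the emulated three-cohort design
  (16 controls / 17 laryngeal dystonia / 15 writer's cramp), with
  optional rank correlations to a region's planted nodal metric via a
  Gaussian copula.

Edge rates are scaled by the voxel counts of the endpoint region masks
(drawn once per atlas, log-normal), so the downstream voxel
normalization is non-trivial.  All randomness flows through one seeded
generator; identical (config, seed) gives bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import AtlasSpec, draw_voxel_counts, load_default_atlas
from .build import StreamlineMatrix

__all__ = [
    "CohortConfig",
    "GroupSpec",
    "ClinicalMarginals",
    "Cohort",
    "generate_cohort",
    "plant_group_effect",
    "generate_clinical",
    "default_config",
]

# Table-1-style clinical marginals per group: mean/SD pairs, sex as F:M.
@dataclass(frozen=True)
class ClinicalMarginals:
    age: tuple[float, float] = (55.3, 11.3)
    onset_age: tuple[float, float] | None = None
    duration: tuple[float, float] | None = None
    bfm_movement: tuple[float, float] | None = None
    bfm_disability: tuple[float, float] | None = None
    sex_f_m: tuple[int, int] = (10, 6)


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_subjects: int
    clinical: ClinicalMarginals = field(default_factory=ClinicalMarginals)
    is_patient: bool = False


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs besides the atlas and the seed."""

    groups: tuple[GroupSpec, ...]
    n_modules: int = 5
    within_weight_scale: float = 30.0
    between_weight_scale: float = 6.0
    within_connect_prob: float = 0.90
    between_connect_prob: float = 0.18
    provincial_attenuation: float = 0.25  # between-module support damping for provincial hubs
    dispersion: float = 0.6  # negative-binomial size parameter r
    mean_voxels: float = 1500.0
    # (region, strength multiplier[, scope]); scope "connector" (default)
    # boosts all incident edges, "provincial" boosts within-module edges
    # and attenuates between-module support
    hub_nodes: tuple[tuple, ...] = ()
    group_effects: tuple[tuple[str, str, float], ...] = ()  # (group, region, multiplier)
    clinical_correlations: tuple[tuple[str, str, str, float], ...] = ()  # (group, variable, region, rho)
    seed: int = 0

    def validate(self, atlas: AtlasSpec) -> None:
        if self.n_modules > atlas.n_regions:
            raise ValueError("n_modules cannot exceed the number of regions")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if not self.within_weight_scale > self.between_weight_scale >= 0:
            raise ValueError("need within_weight_scale > between_weight_scale >= 0")
        if not (0 < self.within_connect_prob <= 1 and 0 < self.between_connect_prob <= 1):
            raise ValueError("connection probabilities must be in (0, 1]")
        for g in self.groups:
            if g.n_subjects < 2:
                raise ValueError(f"group {g.name!r} needs at least 2 subjects")
        for spec in self.hub_nodes:
            region, mult = spec[0], spec[1]
            atlas.index_of(region)
            if mult <= 0:
                raise ValueError(f"hub multiplier for {region!r} must be positive")
            if len(spec) > 2 and spec[2] not in ("connector", "provincial"):
                raise ValueError(f"unknown hub scope {spec[2]!r} for {region!r}")
        for _, region, _ in self.group_effects:
            atlas.index_of(region)
        for _, _, region, rho in self.clinical_correlations:
            atlas.index_of(region)
            if not -1 <= rho <= 1:
                raise ValueError(f"target rank correlation {rho} outside [-1, 1]")


@dataclass(frozen=True)
class Cohort:
    matrices: tuple[StreamlineMatrix, ...]
    clinical: pd.DataFrame
    atlas: AtlasSpec
    planted_modules: np.ndarray  # module id per region
    config: CohortConfig

    def group(self, name: str) -> list[StreamlineMatrix]:
        return [m for m in self.matrices if m.group == name]


def default_config(seed: int = 0) -> CohortConfig:
    """The emulated study conditions: 16/17/15 cohort, 5 modules, subcortical hubs."""
    return CohortConfig(
        groups=(
            GroupSpec("controls", 16, ClinicalMarginals(age=(55.3, 11.3), sex_f_m=(10, 6))),
            GroupSpec(
                "LD", 17,
                ClinicalMarginals(
                    age=(56.6, 13.2), onset_age=(37.4, 12.6), duration=(19.2, 9.7),
                    bfm_movement=(3.6, 2.5), bfm_disability=(2.1, 0.9),
                    sex_f_m=(10, 7),
                ),
                is_patient=True,
            ),
            GroupSpec(
                "WC", 15,
                ClinicalMarginals(
                    age=(53.7, 11.7), onset_age=(37.7, 10.3), duration=(16.1, 10.7),
                    bfm_movement=(4.3, 2.6), bfm_disability=(1.7, 0.8),
                    sex_f_m=(9, 6),
                ),
                is_patient=True,
            ),
        ),
        hub_nodes=(
            ("Putamen_L", 1.8), ("Putamen_R", 1.8),
            ("Thalamus_L", 1.7), ("Thalamus_R", 1.7),
            ("Precuneus_L", 1.7), ("Precuneus_R", 1.7),
            ("Hippocampus_L", 1.6), ("Hippocampus_R", 1.6),
            ("Caudate_R", 1.6),
            ("Insula_L", 1.6),
            ("Vermis_1_2", 2.0, "provincial"), ("Vermis_10", 2.0, "provincial"),
        ),
        group_effects=(
            # LD: premotor increase; both groups: insular hub degradation;
            # WC: cingulate decrease -- the common/distinct nodal pattern
            ("LD", "Supp_Motor_Area_R", 1.3),
            ("LD", "Insula_L", 0.8),
            ("WC", "Cingulum_Ant_R", 0.75),
            ("WC", "Insula_L", 0.75),
        ),
        clinical_correlations=(
            ("LD", "duration", "Caudate_L", -0.50),
            ("LD", "onset_age", "Insula_L", 0.51),
            ("WC", "bfm_movement", "Pallidum_R", 0.63),
            ("WC", "onset_age", "Occipital_Sup_L", 0.51),
        ),
        seed=seed,
    )


def planted_module_labels(n_regions: int, n_modules: int) -> np.ndarray:
    """Deterministic near-equal split of the region order into modules."""
    return np.sort(np.arange(n_regions) % n_modules)


def _edge_rates(
    atlas: AtlasSpec, config: CohortConfig, modules: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Expected streamline count per edge: support x module structure x hubs x voxels.

    A structural support mask is drawn once per cohort (anatomy is shared
    across subjects): within-module pairs connect with
    ``within_connect_prob``, between-module pairs with
    ``between_connect_prob``; hub regions boost both the connection
    probability and the count rate of their incident edges.  The support
    mask keeps the group-averaged network near the ~30% density regime
    of whole-brain structural connectomes instead of saturating under
    the subject-union of noisy edges.
    """
    n = atlas.n_regions
    v = np.asarray(atlas.voxel_counts, dtype=float)
    voxel_factor = np.sqrt(np.outer(v, v)) / config.mean_voxels
    same = modules[:, None] == modules[None, :]
    lam = np.where(same, config.within_weight_scale, config.between_weight_scale) * voxel_factor
    p_connect = np.where(same, config.within_connect_prob, config.between_connect_prob)

    rate_boost = np.ones((n, n))
    prob_boost = np.ones((n, n))
    for spec in config.hub_nodes:
        region, mult = spec[0], spec[1]
        scope = spec[2] if len(spec) > 2 else "connector"
        i = atlas.index_of(region)
        if scope == "connector":
            rate_boost[i, :] = np.maximum(rate_boost[i, :], mult)
            prob_boost[i, :] = np.maximum(prob_boost[i, :], mult)
        else:  # provincial: concentrate the boost inside the hub's module
            rate_boost[i, same[i]] = np.maximum(rate_boost[i, same[i]], mult)
            prob_boost[i, same[i]] = np.maximum(prob_boost[i, same[i]], mult)
            prob_boost[i, ~same[i]] = np.minimum(
                prob_boost[i, ~same[i]], config.provincial_attenuation
            )
    rate_boost = np.maximum(rate_boost, rate_boost.T)
    prob_boost_sym = np.maximum(prob_boost, prob_boost.T)
    # a provincial hub's attenuation wins over the neutral 1.0 of its partner
    atten = np.minimum(prob_boost, prob_boost.T)
    prob_boost_sym = np.where(atten < 1.0, atten, prob_boost_sym)
    lam = lam * rate_boost
    p_connect = np.minimum(p_connect * prob_boost_sym, 0.95)
    iu, ju = np.triu_indices(n, k=1)
    support = np.zeros((n, n), dtype=bool)
    keep = rng.random(iu.size) < p_connect[iu, ju]
    support[iu[keep], ju[keep]] = True
    support |= support.T
    lam = np.where(support, lam, 0.0)
    np.fill_diagonal(lam, 0.0)
    return lam


def _nb_draw(rng: np.random.Generator, lam: np.ndarray, r: float) -> np.ndarray:
    """Symmetric negative-binomial counts with mean lam, dispersion r."""
    n = lam.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mean = lam[iu, ju]
    p = r / (r + np.maximum(mean, 1e-12))
    draws = np.where(mean > 0, rng.negative_binomial(r, p), 0)
    counts = np.zeros((n, n), dtype=np.int64)
    counts[iu, ju] = draws
    counts[ju, iu] = draws
    return counts


def plant_group_effect(
    matrices: list[StreamlineMatrix],
    region: str,
    multiplier: float | None = None,
    additive: int | None = None,
    group: str | None = None,
) -> list[StreamlineMatrix]:
    """Shift a region's row/column counts in the designated group.

    Multiplicative (counts rounded back to integers) or additive (added
    to nonzero entries).  Symmetry and integrality are preserved; an
    additive shift that would drive any count negative raises.
    """
    if (multiplier is None) == (additive is None):
        raise ValueError("specify exactly one of multiplier or additive")
    out = []
    for m in matrices:
        if group is not None and m.group != group:
            out.append(m)
            continue
        i = m.atlas.index_of(region)
        c = m.counts.copy()
        row = c[i, :].astype(float)
        if multiplier is not None:
            new_row = np.round(row * multiplier)
        else:
            new_row = np.where(row > 0, row + additive, row)
        if np.any(new_row < 0):
            raise ValueError(f"effect on {region!r} produces negative counts")
        c[i, :] = new_row.astype(np.int64)
        c[:, i] = c[i, :]
        c[i, i] = 0
        out.append(StreamlineMatrix(c, m.atlas, m.subject_id, m.group))
    return out


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Blom rank-based normal scores (ties get midranks)."""
    ranks = stats.rankdata(values)
    return stats.norm.ppf((ranks - 0.375) / (len(values) + 0.25))


def generate_clinical(
    config: CohortConfig,
    nodal_ground_truth: dict[str, pd.DataFrame],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Clinical covariate table with copula-planted rank correlations.

    ``nodal_ground_truth`` maps group name to a subjects x regions frame
    of planted nodal strengths.  For each configured correlation the
    variable's Gaussian latent is mixed with the normal scores of the
    region's metric at copula correlation ``r = 2 sin(pi * rho / 6)``,
    which targets Spearman's rho; variables without a configured
    correlation are drawn independently.  Controls get n/a for the
    disorder variables.  Age decomposes exactly as onset_age + duration.
    """
    corr_lookup = {
        (group, var): (region, rho)
        for group, var, region, rho in config.clinical_correlations
    }
    rows = []
    for g in config.groups:
        n = g.n_subjects
        truth = nodal_ground_truth.get(g.name)

        def latent(var: str) -> np.ndarray:
            noise = rng.standard_normal(n)
            if (g.name, var) in corr_lookup and truth is not None:
                region, rho = corr_lookup[(g.name, var)]
                r = 2.0 * np.sin(np.pi * rho / 6.0)
                z_metric = _normal_scores(truth[region].to_numpy())
                return r * z_metric + np.sqrt(max(0.0, 1.0 - r**2)) * noise
            return noise

        cm = g.clinical
        n_f, n_m = cm.sex_f_m
        sex = np.array(["F"] * n_f + ["M"] * n_m)[:n]
        if len(sex) < n:
            sex = np.concatenate([sex, ["F"] * (n - len(sex))])
        record = {
            "subject": [f"{g.name}_{i:02d}" for i in range(n)],
            "group": g.name,
            "sex": sex,
        }
        if g.is_patient and cm.duration is not None and cm.onset_age is not None:
            # onset and duration carry the latents; age = onset + duration
            # exactly, so the decomposition invariant holds by construction
            onset = np.round(np.clip(cm.onset_age[0] + cm.onset_age[1] * latent("onset_age"), 5.0, None), 1)
            dur = np.round(np.clip(cm.duration[0] + cm.duration[1] * latent("duration"), 0.5, None), 1)
            record["age"] = np.round(onset + dur, 1)
            record["onset_age"] = onset
            record["duration"] = dur
            for var, marg in (("bfm_movement", cm.bfm_movement), ("bfm_disability", cm.bfm_disability)):
                vals = np.clip(marg[0] + marg[1] * latent(var), 0.0, None)
                record[var] = np.round(vals, 1)
        else:
            record["age"] = np.round(cm.age[0] + cm.age[1] * latent("age"), 1)
            record["onset_age"] = np.nan
            record["duration"] = np.nan
            record["bfm_movement"] = np.nan
            record["bfm_disability"] = np.nan
        rows.append(pd.DataFrame(record))
    return pd.concat(rows, ignore_index=True)


def generate_cohort(
    config: CohortConfig | None = None,
    atlas: AtlasSpec | None = None,
    seed: int | None = None,
) -> Cohort:
    """Draw a full cohort: matrices, planted modules, clinical table.

    The atlas (default: packaged 116-region macrolabel) gets log-normal
    voxel counts attached; each subject's counts are independent
    negative-binomial draws around the shared edge-rate matrix; group
    effects are planted afterwards; clinical covariates are generated
    against the post-effect nodal strengths.
    """
    if config is None:
        config = default_config()
    if seed is not None:
        config = CohortConfig(**{**config.__dict__, "seed": seed})
    base_atlas = atlas or load_default_atlas()
    config.validate(base_atlas)
    ss = np.random.SeedSequence(config.seed)
    rng_atlas, rng_support, rng_counts, rng_clinical = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    atlas_v = (
        base_atlas
        if base_atlas.voxel_counts is not None
        else draw_voxel_counts(base_atlas, rng_atlas, config.mean_voxels)
    )
    modules = planted_module_labels(atlas_v.n_regions, config.n_modules)
    lam = _edge_rates(atlas_v, config, modules, rng_support)

    matrices: list[StreamlineMatrix] = []
    for g in config.groups:
        for i in range(g.n_subjects):
            counts = _nb_draw(rng_counts, lam, config.dispersion)
            matrices.append(StreamlineMatrix(counts, atlas_v, f"{g.name}_{i:02d}", g.name))

    for group, region, mult in config.group_effects:
        matrices = plant_group_effect(matrices, region, multiplier=mult, group=group)

    truth = {}
    for g in config.groups:
        strengths = np.stack([m.counts.sum(axis=0) for m in matrices if m.group == g.name])
        truth[g.name] = pd.DataFrame(strengths, columns=atlas_v.region_labels)

    clinical = generate_clinical(config, truth, rng_clinical)
    return Cohort(tuple(matrices), clinical, atlas_v, modules, config)
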