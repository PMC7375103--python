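"""Cohort generator: determinism, planted structure, effects, clinical copula."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from connectoscope.atlas import load_default_atlas
from connectoscope.build import (
    group_average,
    normalize_streamlines,
    proportional_threshold,
    prune_weak,
)
from connectoscope.community import louvain_partition
from connectoscope.synthetic import (
    CohortConfig,
    GroupSpec,
    default_config,
    generate_cohort,
    plant_group_effect,
)


def small_config(seed=0, **overrides):
    cfg = CohortConfig(
        groups=(GroupSpec("controls", 4), GroupSpec("patients", 4, is_patient=True)),
        seed=seed,
    )
    return dataclasses.replace(cfg, **overrides)


def adjusted_rand(a, b):
    from scipy.special import comb

    a, b = np.asarray(a), np.asarray(b)
    ids_a, ids_b = np.unique(a), np.unique(b)
    contingency = np.array(
        [[np.count_nonzero((a == ca) & (b == cb)) for cb in ids_b] for ca in ids_a]
    )
    sum_comb = comb(contingency, 2).sum()
    sum_a = comb(contingency.sum(axis=1), 2).sum()
    sum_b = comb(contingency.sum(axis=0), 2).sum()
    n = comb(len(a), 2)
    expected = sum_a * sum_b / n
    max_index = (sum_a + sum_b) / 2
    return (sum_comb - expected) / (max_index - expected)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        c1 = generate_cohort(default_config(seed=42))
        c2 = generate_cohort(default_config(seed=42))
        for m1, m2 in zip(c1.matrices, c2.matrices):
            np.testing.assert_array_equal(m1.counts, m2.counts)
        assert c1.clinical.equals(c2.clinical)
        assert c1.atlas.voxel_counts == c2.atlas.voxel_counts

    def test_different_seeds_differ(self):
        c1 = generate_cohort(small_config(seed=1))
        c2 = generate_cohort(small_config(seed=2))
        assert any(
            not np.array_equal(m1.counts, m2.counts)
            for m1, m2 in zip(c1.matrices, c2.matrices)
        )


class TestPlantedStructure:
    def test_matrices_valid(self):
        cohort = generate_cohort(small_config(seed=5))
        for m in cohort.matrices:
            assert m.counts.shape == (116, 116)
            np.testing.assert_array_equal(m.counts, m.counts.T)
            assert np.all(np.diag(m.counts) == 0)
            assert np.issubdtype(m.counts.dtype, np.integer)
            assert np.all(m.counts >= 0)

    def test_within_module_counts_exceed_between(self):
        cohort = generate_cohort(small_config(seed=6))
        mods = cohort.planted_modules
        same = mods[:, None] == mods[None, :]
        np.fill_diagonal(same, False)
        c = cohort.matrices[0].counts
        assert c[same].mean() > c[~same & ~np.eye(116, dtype=bool)].mean()

    def test_zero_between_scale_gives_block_diagonal(self):
        cohort = generate_cohort(small_config(seed=7, between_weight_scale=0.0))
        mods = cohort.planted_modules
        between = mods[:, None] != mods[None, :]
        for m in cohort.matrices:
            assert not np.any(m.counts[between])

    def test_unknown_region_rejected(self):
        with pytest.raises(KeyError):
            generate_cohort(small_config(hub_nodes=(("NoSuchRegion", 2.0),)))

    def test_too_many_modules_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(small_config(n_modules=500))


def test_module_recovery_across_seeds():
    """Consensus Louvain on the group-averaged thresholded network recovers
    the 5 planted communities with ARI >= 0.9 and finds every planted hub,
    across 20 generator seeds."""
    from connectoscope.community import identify_hubs

    ok_ari = 0
    ok_hubs = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = default_config(seed=100 + seed)
        cohort = generate_cohort(cfg)
        nets = [normalize_streamlines(m) for m in cohort.matrices]
        nets = proportional_threshold(nets, 0.5)
        nets = [prune_weak(n, 0.10) for n in nets]
        ctrl = group_average([n for n in nets if n.group == "controls"], "controls")
        part = louvain_partition(ctrl, n_iterations=50, seed=seed)
        if adjusted_rand(cohort.planted_modules, part.assignment) >= 0.9:
            ok_ari += 1
        hub_set = {h.node for h in identify_hubs(ctrl, part)}
        planted = {spec[0] for spec in cfg.hub_nodes}
        if planted <= hub_set:
            ok_hubs += 1
    assert ok_ari >= 0.9 * n_seeds
    assert ok_hubs >= 0.9 * n_seeds


class TestPlantGroupEffect:
    def test_identity_multiplier(self):
        cohort = generate_cohort(small_config(seed=8, group_effects=()))
        out = plant_group_effect(list(cohort.matrices), "Insula_L", multiplier=1.0)
        for m0, m1 in zip(cohort.matrices, out):
            np.testing.assert_array_equal(m0.counts, m1.counts)

    def test_doubling_doubles_strength(self):
        cohort = generate_cohort(small_config(seed=9, group_effects=()))
        region = "Putamen_L"
        idx = cohort.atlas.index_of(region)
        out = plant_group_effect(
            list(cohort.matrices), region, multiplier=2.0, group="patients"
        )
        base = np.mean(
            [m.counts[idx].sum() for m in cohort.matrices if m.group == "patients"]
        )
        shifted = np.mean([m.counts[idx].sum() for m in out if m.group == "patients"])
        ctrl0 = np.mean(
            [m.counts[idx].sum() for m in cohort.matrices if m.group == "controls"]
        )
        ctrl1 = np.mean([m.counts[idx].sum() for m in out if m.group == "controls"])
        assert shifted == pytest.approx(2 * base, rel=1e-6)
        assert ctrl1 == ctrl0

    def test_symmetry_and_integrality_preserved(self):
        cohort = generate_cohort(small_config(seed=10))
        out = plant_group_effect(list(cohort.matrices), "Thalamus_R", multiplier=1.37)
        for m in out:
            np.testing.assert_array_equal(m.counts, m.counts.T)
            assert np.issubdtype(m.counts.dtype, np.integer)

    def test_negative_counts_rejected(self):
        cohort = generate_cohort(small_config(seed=11))
        with pytest.raises(ValueError, match="negative"):
            plant_group_effect(list(cohort.matrices), "Insula_L", additive=-10**9)


def test_planted_effect_detected_with_power():
    """A large (>=1 within-group SD) multiplicative nodal effect at n=16 per
    group is rejected by the permutation test at alpha=.016 in >=80% of
    cohorts.  The x1.5 strength multiplier yields d >= 1 across cohorts."""
    from connectoscope.inference import permutation_test

    region = "Insula_R"
    rejections = 0
    n_cohorts = 50
    for seed in range(n_cohorts):
        cfg = CohortConfig(
            groups=(GroupSpec("controls", 16), GroupSpec("patients", 16, is_patient=True)),
            group_effects=(("patients", region, 1.5),),
            seed=3000 + seed,
        )
        cohort = generate_cohort(cfg)
        idx = cohort.atlas.index_of(region)
        pa = [m.counts[idx].sum() for m in cohort.matrices if m.group == "patients"]
        co = [m.counts[idx].sum() for m in cohort.matrices if m.group == "controls"]
        res = permutation_test(pa, co, n_perm=500, seed=seed, alpha=0.016)
        if res.significant:
            rejections += 1
    assert rejections >= 0.8 * n_cohorts


class TestClinical:
    def test_structure_and_decomposition(self):
        clinical = generate_cohort(default_config(seed=12)).clinical
        assert len(clinical) == 48
        assert set(clinical["group"]) == {"controls", "LD", "WC"}
        patients = clinical[clinical["group"] != "controls"]
        np.testing.assert_allclose(
            patients["onset_age"] + patients["duration"], patients["age"], atol=0.2
        )
        assert (patients["duration"] >= 0).all()
        assert (patients[["bfm_movement", "bfm_disability"]] >= 0).all().all()
        assert clinical.loc[clinical["group"] == "controls", "onset_age"].isna().all()

    def test_invalid_target_correlation_rejected(self):
        with pytest.raises(ValueError, match="rank correlation"):
            generate_cohort(
                small_config(
                    clinical_correlations=(("patients", "duration", "Insula_L", 1.5),)
                )
            )

    def test_perfect_correlation_is_monotone(self):
        cfg = small_config(
            seed=13,
            groups=(
                GroupSpec("controls", 4),
                GroupSpec(
                    "patients", 15,
                    dataclasses.replace(default_config().groups[2].clinical),
                    is_patient=True,
                ),
            ),
            clinical_correlations=(("patients", "bfm_movement", "Putamen_L", 1.0),),
        )
        cohort = generate_cohort(cfg)
        idx = cohort.atlas.index_of("Putamen_L")
        strengths = [
            m.counts[idx].sum() for m in cohort.matrices if m.group == "patients"
        ]
        bfm = cohort.clinical.loc[
            cohort.clinical["group"] == "patients", "bfm_movement"
        ].to_numpy()
        rho = stats.spearmanr(strengths, bfm).statistic
        assert rho >= 0.99  # ties from rounding can shave a hair off 1.0

    @pytest.mark.parametrize("target", [-0.76, 0.0])
    def test_target_correlation_realized(self, target):
        """Realized Spearman rho across seeds stays near the copula target:
        +-0.15 on the median, and within the simulated null/target 95% band
        per seed (null band from an in-test permutation simulation)."""
        rhos = []
        marginals = dataclasses.replace(default_config().groups[2].clinical)
        for seed in range(40):
            cfg = small_config(
                seed=5000 + seed,
                groups=(
                    GroupSpec("controls", 2),
                    GroupSpec("patients", 15, marginals, is_patient=True),
                ),
                clinical_correlations=(
                    ("patients", "bfm_disability", "Caudate_L", target),
                ),
            )
            cohort = generate_cohort(cfg)
            idx = cohort.atlas.index_of("Caudate_L")
            s = [m.counts[idx].sum() for m in cohort.matrices if m.group == "patients"]
            y = cohort.clinical.loc[
                cohort.clinical["group"] == "patients", "bfm_disability"
            ].to_numpy()
            rhos.append(stats.spearmanr(s, y).statistic)
        rhos = np.array(rhos)
        assert abs(np.median(rhos) - target) <= 0.15
        if target == -0.76:
            # emulates the onset/severity correlate: 95% of seeds in band
            assert np.mean((rhos >= -0.95) & (rhos <= -0.45)) >= 0.85
        else:
            # null band: simulated 95% quantile of |rho| at n=15 (~0.50)
            rng = np.random.default_rng(0)
            null = np.abs(
                [
                    stats.spearmanr(rng.permutation(15), np.arange(15)).statistic
                    for _ in range(2000)
                ]
            )
            band = np.quantile(null, 0.95)
            assert np.mean(np.abs(rhos) <= band) >= 0.85


def test_voxel_counts_shared_across_subjects():
    cohort = generate_cohort(small_config(seed=14))
    assert cohort.atlas.voxel_counts is not None
    assert all(m.atlas.voxel_counts == cohort.atlas.voxel_counts for m in cohort.matrices)
    assert min(cohort.atlas.voxel_counts) >= 1


def test_default_atlas_is_116_regions():
    atlas = load_default_atlas()
    assert atlas.n_regions == 116
    assert len(set(atlas.region_labels)) == 116
    assert set(atlas.hemisphere) == {"L", "R", "M"}
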