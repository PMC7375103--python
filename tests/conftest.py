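import numpy as np
import pytest

from connectoscope.atlas import AtlasSpec
from connectoscope.build import (
    WeightedNetwork,
    group_average,
    normalize_streamlines,
    proportional_threshold,
    prune_weak,
)
from connectoscope.synthetic import default_config, generate_cohort


def toy_atlas(n: int, voxels=None) -> AtlasSpec:
    labels = tuple(f"R{i:02d}" for i in range(n))
    hemis = tuple("L" if i % 2 == 0 else "R" for i in range(n))
    atlas = AtlasSpec(labels, hemis)
    if voxels is not None:
        atlas = atlas.with_voxel_counts(voxels)
    return atlas


def network_from_weights(w, voxels=None) -> WeightedNetwork:
    w = np.asarray(w, dtype=float)
    return WeightedNetwork(w, toy_atlas(w.shape[0], voxels), subject_id="toy", group="toy")


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (16 controls / 17 LD / 15 WC), seed 1."""
    return generate_cohort(default_config(seed=1))


@pytest.fixture(scope="session")
def built_networks(cohort):
    """Normalized, thresholded (50%), pruned (10%) subject networks."""
    nets = [normalize_streamlines(m) for m in cohort.matrices]
    nets = proportional_threshold(nets, 0.5)
    return [prune_weak(n, 0.10) for n in nets]


@pytest.fixture(scope="session")
def control_network(built_networks):
    return group_average(
        [n for n in built_networks if n.group == "controls"], "controls"
    )


@pytest.fixture(scope="session")
def control_partition(control_network):
    from connectoscope.community import louvain_partition

    return louvain_partition(control_network, n_iterations=50, seed=11)
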