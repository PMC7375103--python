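"""From raw streamline counts to normalized, thresholded weighted networks.

The construction scheme is the two-stage thresholding used for
streamline-count connectomes:

1. each subject's count matrix is normalized by the voxel counts of the
   region masks (controlling for gray-matter volume differences),
2. all networks of a cohort are rescaled by the single maximum edge
   weight pooled over the cohort, and each network is proportionally
   thresholded to a target density (default 50%) by removing its weakest
   edges,
3. the bottom fraction (default 10%) of each network's weakest remaining
   edges is pruned to suppress residual spurious connections.

Voxel normalization of symmetric counts is direction-dependent
(streamlines/voxels-in-target differs by which endpoint is "target"), so
the symmetrized weight ``w_ij = mean(c_ij / v_j, c_ij / v_i)`` is used.

All tie-breaking is deterministic: edges are ranked by (weight, then
lexicographic node-label pair), so re-running a build is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .atlas import AtlasSpec

__all__ = [
    "StreamlineMatrix",
    "WeightedNetwork",
    "normalize_streamlines",
    "proportional_threshold",
    "prune_weak",
    "density",
    "group_average",
]


def _check_square_symmetric(a: np.ndarray, what: str) -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{what} must be square, got shape {a.shape}")
    if not np.allclose(a, a.T):
        raise ValueError(f"{what} must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError(f"{what} must have a zero diagonal")
    if np.any(a < 0):
        raise ValueError(f"{what} must be non-negative")


@dataclass(frozen=True)
class StreamlineMatrix:
    """Raw symmetric streamline counts over the atlas regions of one subject."""

    counts: np.ndarray
    atlas: AtlasSpec
    subject_id: str
    group: str

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        _check_square_symmetric(counts, "streamline count matrix")
        if counts.shape[0] != self.atlas.n_regions:
            raise ValueError(
                f"matrix is {counts.shape[0]}x{counts.shape[0]} but atlas has "
                f"{self.atlas.n_regions} regions"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.round(counts)):
                raise ValueError("streamline counts must be integers")
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class WeightedNetwork:
    """Symmetric non-negative weighted adjacency with provenance trail."""

    weights: np.ndarray
    atlas: AtlasSpec
    subject_id: str = ""
    group: str = ""
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        _check_square_symmetric(w, "weight matrix")
        if w.shape[0] != self.atlas.n_regions:
            raise ValueError("weight matrix does not match atlas size")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def density(self) -> float:
        return density(self)

    def with_weights(self, weights: np.ndarray, step: str) -> "WeightedNetwork":
        return replace(self, weights=weights, provenance=self.provenance + (step,))


def normalize_streamlines(m: StreamlineMatrix) -> WeightedNetwork:
    """Voxel-normalize a count matrix into a weighted network.

    ``w_ij = mean(c_ij / v_j, c_ij / v_i)`` -- the symmetrized ratio of
    streamline count to the target-mask voxel count.  Raises if the atlas
    has no voxel counts or any region mask is empty.
    """
    if m.atlas.voxel_counts is None:
        raise ValueError("atlas has no voxel counts; cannot normalize")
    v = np.asarray(m.atlas.voxel_counts, dtype=float)
    zero = np.flatnonzero(v < 1)
    if zero.size:
        names = ", ".join(m.atlas.region_labels[i] for i in zero)
        raise ValueError(f"voxel count < 1 for region(s): {names}")
    c = m.counts.astype(float)
    w = 0.5 * (c / v[np.newaxis, :] + c / v[:, np.newaxis])
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(
        weights=w,
        atlas=m.atlas,
        subject_id=m.subject_id,
        group=m.group,
        provenance=("normalize_streamlines(voxel-symmetrized)",),
    )


def _edge_order(net: WeightedNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nonzero upper-triangle edges sorted weakest-first.

    Deterministic ordering: ascending weight, ties by lexicographic
    (label_i, label_j) pair.
    """
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    w = net.weights[iu, ju]
    nz = w > 0
    iu, ju, w = iu[nz], ju[nz], w[nz]
    labels = np.asarray(net.atlas.region_labels, dtype=object)
    order = np.lexsort((labels[ju], labels[iu], w))
    return iu[order], ju[order], w[order]


def density(net: WeightedNetwork) -> float:
    """Fraction of possible off-diagonal node pairs with a nonzero edge."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    iu, ju = np.triu_indices(n, k=1)
    return float(np.count_nonzero(net.weights[iu, ju])) / (n * (n - 1) / 2)


def proportional_threshold(
    networks: list[WeightedNetwork], target_density: float = 0.5
) -> list[WeightedNetwork]:
    """Cohort-referenced rescale followed by per-network proportional thresholding.

    All weights are divided by the single maximum edge weight pooled over
    the cohort (so the strongest edge anywhere becomes 1.0); then each
    network loses its weakest nonzero edges, weakest first, until its
    density is at or below ``target_density``.  Networks already at or
    below the target are only rescaled.
    """
    if not 0 < target_density <= 1:
        raise ValueError("target_density must be in (0, 1]")
    if not networks:
        raise ValueError("empty cohort")
    pooled_max = max(float(net.weights.max()) for net in networks)
    if pooled_max == 0:
        raise ValueError("all networks are empty; nothing to threshold")

    out = []
    for net in networks:
        w = net.weights / pooled_max
        rescaled = net.with_weights(w, f"rescale(pooled_max={pooled_max:.6g})")
        n = net.n_nodes
        n_pairs = n * (n - 1) // 2
        iu, ju, _ = _edge_order(rescaled)
        n_edges = iu.size
        max_keep = int(np.floor(target_density * n_pairs))
        n_remove = max(0, n_edges - max_keep)
        if n_remove:
            w = w.copy()
            w[iu[:n_remove], ju[:n_remove]] = 0.0
            w[ju[:n_remove], iu[:n_remove]] = 0.0
        out.append(
            rescaled.with_weights(
                w, f"proportional_threshold({target_density:g}, removed={n_remove})"
            )
        )
    return out


def prune_weak(net: WeightedNetwork, fraction: float = 0.10) -> WeightedNetwork:
    """Zero out the ``floor(fraction * E)`` weakest nonzero edges."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    iu, ju, _ = _edge_order(net)
    n_remove = int(np.floor(fraction * iu.size))
    w = net.weights
    if n_remove:
        w = w.copy()
        w[iu[:n_remove], ju[:n_remove]] = 0.0
        w[ju[:n_remove], iu[:n_remove]] = 0.0
    return net.with_weights(w, f"prune_weak({fraction:g}, removed={n_remove})")


def group_average(networks: list[WeightedNetwork], group: str = "") -> WeightedNetwork:
    """Edgewise arithmetic mean of a group's (thresholded) networks."""
    if not networks:
        raise ValueError("empty group")
    atlas = networks[0].atlas
    for net in networks[1:]:
        if net.atlas.region_labels != atlas.region_labels:
            raise ValueError("cannot average networks over different atlases")
    mean = np.mean([net.weights for net in networks], axis=0)
    return WeightedNetwork(
        weights=mean,
        atlas=atlas,
        subject_id=f"group_mean:{group or networks[0].group}",
        group=group or networks[0].group,
        provenance=(f"group_average(n={len(networks)})",),
    )
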