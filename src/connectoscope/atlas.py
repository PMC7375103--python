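"""Region atlas: the node identity space of every network in the pipeline.

An :class:`AtlasSpec` carries the ordered region labels of a whole-brain
parcellation, a hemisphere tag per region, and the per-region voxel counts
of the region masks.  The default atlas is the 116-region macrolabel
(AAL) parcellation commonly used for whole-brain structural connectomes:
45 paired cerebral regions, 9 paired cerebellar lobules, and 8 midline
vermal regions.  Voxel counts are not part of the packaged label table --
they belong to a particular (here: simulated) registration of the atlas
to subject space and are attached by the cohort generator or loaded from
an atlas metadata TSV.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AtlasSpec", "load_default_atlas", "load_atlas_tsv"]


@dataclass(frozen=True)
class AtlasSpec:
    """Ordered region labels with hemisphere tags and mask voxel counts.

    Parameters
    ----------
    region_labels
        Unique region names, in matrix row/column order.
    hemisphere
        Per-region tag: ``"L"``, ``"R"`` or ``"M"`` (midline).
    voxel_counts
        Positive integer voxels per region mask, or ``None`` when the
        atlas has not been attached to a subject space yet.
    """

    region_labels: tuple[str, ...]
    hemisphere: tuple[str, ...]
    voxel_counts: tuple[int, ...] | None = None
    _index: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if len(self.hemisphere) != len(self.region_labels):
            raise ValueError("hemisphere tags must match region count")
        if self.voxel_counts is not None:
            if len(self.voxel_counts) != len(self.region_labels):
                raise ValueError("voxel_counts must match region count")
            bad = [l for l, v in zip(self.region_labels, self.voxel_counts) if v < 1]
            if bad:
                raise ValueError(f"voxel count < 1 for region(s): {', '.join(bad)}")
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.region_labels)}
        )

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"region {label!r} not in atlas") from None

    def with_voxel_counts(self, voxel_counts) -> "AtlasSpec":
        """Return a copy with voxel counts attached."""
        return AtlasSpec(
            self.region_labels,
            self.hemisphere,
            tuple(int(v) for v in voxel_counts),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"label": self.region_labels, "hemisphere": self.hemisphere}
        if self.voxel_counts is not None:
            data["voxel_count"] = self.voxel_counts
        return pd.DataFrame(data)


def load_atlas_tsv(path) -> AtlasSpec:
    """Read an atlas metadata TSV (columns: label, hemisphere[, voxel_count])."""
    df = pd.read_csv(path, sep="\t")
    voxels = None
    if "voxel_count" in df.columns:
        voxels = tuple(int(v) for v in df["voxel_count"])
    return AtlasSpec(tuple(df["label"]), tuple(df["hemisphere"]), voxels)


def load_default_atlas() -> AtlasSpec:
    """The packaged 116-region macrolabel atlas (labels only, no voxel counts)."""
    ref = importlib.resources.files("connectoscope.data") / "macrolabel116.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_atlas_tsv(path)


def draw_voxel_counts(
    atlas: AtlasSpec, rng: np.random.Generator, mean_voxels: float = 1500.0, sigma: float = 0.4
) -> AtlasSpec:
    """Attach log-normally distributed mask sizes to an atlas.

    Region masks are subject-invariant after registration, so one draw per
    atlas is shared across the cohort.  ``mean_voxels`` is the target mean
    mask size in voxels; ``sigma`` the log-scale spread.
    """
    mu = np.log(mean_voxels) - sigma**2 / 2.0
    counts = np.maximum(1, np.round(rng.lognormal(mu, sigma, atlas.n_regions))).astype(int)
    return atlas.with_voxel_counts(counts)
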