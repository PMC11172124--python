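"""Distance-transform shell partition and per-layer intensity profiles.

Each segmented nucleus is mapped through an exact Euclidean distance
transform (every foreground voxel gets its distance to the nearest
background voxel centre) and partitioned into K concentric 3D layers of
equal distance width. Layer numbering follows the nuclear geometry: layer 1
holds the distance-maximal voxels at the nuclear centre, layer K abuts the
envelope. Normalization is per nucleus (by that nucleus's maximum distance
d_max), so nuclei of different sizes and heights all yield K layers.

Intensity statistics are always taken on the *raw* image: smoothing is a
segmentation aid only, since it would redistribute signal across shells and
bias the centre-to-periphery gradient the analysis is designed to measure.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import ndimage

from .errors import DegenerateDataError, ValidationError
from .io import VolumeImage
from .segment import LabelMask

__all__ = [
    "DistanceMap",
    "ShellAssignment",
    "RadialProfile",
    "distance_transform",
    "assign_shells",
    "layer_profile",
]


@dataclass(frozen=True)
class DistanceMap:
    """Per-voxel shortest distance to the nearest background voxel.

    ``dist`` is strictly positive exactly on foreground and 0 on background.
    In ``physical`` mode distances are in µm with axis steps weighted by the
    voxel spacing (a 0.21 µm Z step counts 4.2x a 0.05 µm XY pixel); in
    ``isotropic`` mode distances are in voxel units with unit steps.
    """

    dist: np.ndarray
    spacing_um: tuple[float, float, float]
    metric_mode: str


@dataclass(frozen=True)
class ShellAssignment:
    """Integer layer per voxel: 0 background, 1 = centre ... K = periphery."""

    layer: np.ndarray
    K: int
    per_nucleus_dmax: dict[int, float]


@dataclass(frozen=True)
class RadialProfile:
    """Per-nucleus vector of K layer mean intensities and voxel counts.

    ``mean_intensity[l-1]`` is NaN where ``voxel_count[l-1] == 0`` (a layer
    can be empty for large K on small or thin nuclei); empty layers are
    reported missing, never imputed.
    """

    nucleus_id: int
    source_id: str
    condition: str
    K: int
    mean_intensity: np.ndarray
    voxel_count: np.ndarray

    @property
    def missing_layers(self) -> np.ndarray:
        return np.flatnonzero(self.voxel_count == 0) + 1

    @property
    def total_voxels(self) -> int:
        return int(self.voxel_count.sum())


def distance_transform(labels: LabelMask, metric_mode: str = "physical") -> DistanceMap:
    """Exact Euclidean distance of each foreground voxel to background.

    Computed on the union foreground: every nucleus is bounded by
    background after border clearing, so per-nucleus distances equal global
    ones for non-touching nuclei. The distance is measured to the nearest
    *background voxel centre*, so foreground voxels adjacent to background
    carry one axis step, not zero.
    """
    if metric_mode not in ("physical", "isotropic"):
        raise ValidationError(f"metric_mode must be 'physical' or 'isotropic', got {metric_mode!r}")
    sampling = labels.spacing_um if metric_mode == "physical" else (1.0, 1.0, 1.0)
    fg = labels.labels > 0
    dist = ndimage.distance_transform_edt(fg, sampling=sampling)
    return DistanceMap(dist, labels.spacing_um, metric_mode)


def assign_shells(dmap: DistanceMap, labels: LabelMask, K: int) -> ShellAssignment:
    """Partition each nucleus into K equal-width concentric distance bins.

    With ``d_max`` the maximum distance inside a nucleus and normalized
    depth ``nd = d / d_max`` in (0, 1], the layer is::

        layer = K + 1 - ceil(K * nd)

    i.e. equal-width half-open bins (lower-exclusive, upper-inclusive):
    the distance-maximal voxels land in layer 1 (nuclear centre) and the
    boundary-adjacent voxels in layer K.
    """
    if K < 1:
        raise ValidationError(f"K must be >= 1, got {K}")
    grid = labels.labels
    if dmap.dist.shape != grid.shape:
        raise ValidationError("distance map and label mask shapes differ")
    layer = np.zeros(grid.shape, dtype=np.int32)
    per_nucleus_dmax: dict[int, float] = {}
    dmax_all = ndimage.maximum(dmap.dist, labels=grid, index=labels.ids) if labels.ids.size else []
    for nucleus_id, d_max in zip(labels.ids, np.atleast_1d(dmax_all)):
        d_max = float(d_max)
        if not np.isfinite(d_max) or d_max <= 0:
            raise DegenerateDataError(
                f"nucleus {int(nucleus_id)} has d_max={d_max}: no interior to partition"
            )
        sel = grid == nucleus_id
        nd = dmap.dist[sel] / d_max
        ell = K + 1 - np.ceil(K * nd).astype(np.int64)
        np.clip(ell, 1, K, out=ell)  # guards float round-off at bin edges
        layer[sel] = ell
        per_nucleus_dmax[int(nucleus_id)] = d_max
    return ShellAssignment(layer, K, per_nucleus_dmax)


def layer_profile(
    raw: VolumeImage, shells: ShellAssignment, labels: LabelMask
) -> list[RadialProfile]:
    """Mean raw intensity per (nucleus, layer), with voxel counts.

    Layer means are simple averages of the unsmoothed intensities over the
    voxels carrying that nucleus label and layer index.
    """
    if raw.shape != labels.labels.shape or raw.shape != shells.layer.shape:
        raise ValidationError("raw volume, shells and labels must share one shape")
    K = shells.K
    profiles: list[RadialProfile] = []
    intensities = raw.voxels.astype(np.float64)
    for nucleus_id in labels.ids:
        sel = labels.labels == nucleus_id
        lay = shells.layer[sel]
        counts = np.bincount(lay, minlength=K + 1)[1:]
        sums = np.bincount(lay, weights=intensities[sel], minlength=K + 1)[1:]
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        profiles.append(
            RadialProfile(
                nucleus_id=int(nucleus_id),
                source_id=raw.source_id,
                condition=raw.condition,
                K=K,
                mean_intensity=means,
                voxel_count=counts.astype(np.int64),
            )
        )
    return profiles
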