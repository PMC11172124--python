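"""Reading Z-stacks and writing tabular/mask outputs.

Conventions
-----------
* Volumes are indexed ``(Z, Y, X)``; TIFF page order maps to Z.
* ``spacing_um`` is ``(dz, dy, dx)`` in micrometres and always comes from
  the caller (config/CLI), never from TIFF resolution tags, which are
  unreliable across writer dialects.
* Intensities keep their native dtype on load; no rescaling is applied,
  mirroring acquisition at fixed laser/gain settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ValidationError

__all__ = [
    "VolumeImage",
    "load_stack",
    "write_stack",
    "write_mask",
    "write_profiles",
    "write_ro_summaries",
    "write_comparisons",
]


def _check_spacing(spacing_um: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_um)
    if len(spacing) != 3:
        raise ValidationError(f"spacing_um must have 3 entries (dz, dy, dx), got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValidationError(f"spacing_um entries must be positive and finite, got {spacing}")
    return spacing  # type: ignore[return-value]


@dataclass(frozen=True)
class VolumeImage:
    """A single-channel 3D intensity grid with physical voxel spacing.

    Parameters
    ----------
    voxels
        3D array of non-negative finite intensities, axis order (Z, Y, X).
    spacing_um
        Voxel pitch ``(dz, dy, dx)`` in micrometres. The acquisition this
        package models used (0.21, 0.05, 0.05).
    condition
        Free-text experimental group label (e.g. ``"minusDTT"``).
    source_id
        Identifier of the originating image, used in all tabular outputs.
    """

    voxels: np.ndarray
    spacing_um: tuple[float, float, float]
    condition: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValidationError(f"voxels must be 3D (Z, Y, X), got ndim={vox.ndim}")
        if any(n < 2 for n in vox.shape):
            raise ValidationError(f"each axis needs >= 2 planes, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ValidationError("voxels contain non-finite values")
        if vox.min() < 0:
            raise ValidationError("voxels contain negative intensities")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing_um", _check_spacing(self.spacing_um))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing_um
        return dz * dy * dx

    def with_voxels(self, voxels: np.ndarray) -> "VolumeImage":
        """Same metadata, new intensity grid."""
        return VolumeImage(voxels, self.spacing_um, self.condition, self.source_id)


def load_stack(
    path: str | Path,
    spacing_um: Sequence[float],
    condition: str = "",
    source_id: str | None = None,
) -> VolumeImage:
    """Read a multi-page greyscale TIFF as a (Z, Y, X) volume.

    Pages map to Z in file order. Intensities are returned in the file's
    native dtype without rescaling. Multi-channel (RGB/samples) files are
    rejected: this pipeline analyses one marker channel at a time.
    """
    path = Path(path)
    spacing = _check_spacing(spacing_um)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            axes = series.axes
            arr = series.asarray()
    except (OSError, ValueError, IndexError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if "S" in axes or "C" in axes:
        raise FormatError(
            f"{path}: multi-channel TIFF (axes {axes!r}); expected a single greyscale channel"
        )
    if arr.ndim == 2:
        raise FormatError(f"{path}: single-page TIFF (axes {axes!r}); a Z-stack needs >= 2 pages")
    if arr.ndim != 3:
        raise FormatError(f"{path}: unsupported TIFF layout with axes {axes!r} (ndim={arr.ndim})")
    return VolumeImage(arr, spacing, condition, source_id or path.stem)


def write_stack(voxels: np.ndarray, path: str | Path) -> None:
    """Write a 3D array as a multi-page TIFF, one page per Z plane."""
    voxels = np.asarray(voxels)
    if voxels.ndim != 3:
        raise ValidationError(f"expected a 3D array, got ndim={voxels.ndim}")
    # explicit photometric: trailing axes of length 3/4 must not be guessed
    # as RGB(A) samples
    tifffile.imwrite(Path(path), voxels, photometric="minisblack")


def write_mask(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label mask as a multi-page TIFF (uint16/uint32)."""
    labels = np.asarray(labels)
    dtype = np.uint16 if labels.max(initial=0) < 2**16 else np.uint32
    write_stack(labels.astype(dtype), path)


_PROFILE_COLUMNS = [
    "source_id",
    "nucleus_id",
    "layer_index",
    "mean_intensity",
    "voxel_count",
    "condition",
]


def profiles_to_frame(profiles: Iterable) -> pd.DataFrame:
    """Flatten RadialProfile objects to one row per (source, nucleus, layer)."""
    profiles = list(profiles)
    ks = {p.K for p in profiles}
    if len(ks) > 1:
        raise ValidationError(f"profiles mix several layer counts K: {sorted(ks)}")
    rows = []
    for p in profiles:
        for layer in range(1, p.K + 1):
            count = int(p.voxel_count[layer - 1])
            mean = float(p.mean_intensity[layer - 1]) if count > 0 else np.nan
            rows.append((p.source_id, p.nucleus_id, layer, mean, count, p.condition))
    frame = pd.DataFrame(rows, columns=_PROFILE_COLUMNS)
    return frame.sort_values(["source_id", "nucleus_id", "layer_index"], kind="stable").reset_index(
        drop=True
    )


def write_profiles(profiles: Iterable, path: str | Path) -> None:
    """Write per-layer profiles as CSV (header-only for an empty collection)."""
    profiles_to_frame(profiles).to_csv(Path(path), index=False)


def write_ro_summaries(summaries: Iterable, path: str | Path) -> None:
    """Write region-of-interest summaries (one row per group x RO) as CSV."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "condition": s.condition,
                "ro_index": s.ro_index,
                "layer_lo": s.layer_range[0],
                "layer_hi": s.layer_range[1],
                "mean": s.mean,
                "sem": s.sem,
                "n": s.n,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["condition", "ro_index", "layer_lo", "layer_hi", "mean", "sem", "n"]
    )
    frame.sort_values(["condition", "ro_index"], kind="stable").to_csv(Path(path), index=False)


def write_comparisons(comparisons: Iterable, path: str | Path) -> None:
    """Write two-group test results (one row per layer or RO) as CSV."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "unit": c.unit,
                "index": c.index,
                "group_a": c.group_a,
                "group_b": c.group_b,
                "mean_a": c.mean_a,
                "mean_b": c.mean_b,
                "sem_a": c.sem_a,
                "sem_b": c.sem_b,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "t": c.t,
                "p": c.p,
                "significant": c.significant,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "unit", "index", "group_a", "group_b", "mean_a", "mean_b",
            "sem_a", "sem_b", "n_a", "n_b", "t", "p", "significant",
        ],
    )
    frame.sort_values(["unit", "index"], kind="stable").to_csv(Path(path), index=False)
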