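"""Automatic carotid-artery IDIF extraction from 4-D dynamic PET.

A threshold-free, multi-VOI scheme: inside a trimmed search volume, the
10, 100 and 1000 highest-intensity voxels of one early "bolus" frame
define three nested VOIs.  Per-frame VOI medians give three
image-derived input functions (IDIF_10/100/1000) carrying progressively
more partial-volume dilution; together they are the input channels of
the GP input-function model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import (
    FrameSchedule,
    TimeActivityCurve,
    resample_to_1s,
    window_0_to_6min,
)

__all__ = [
    "DynamicImage",
    "VoiMask",
    "IdifSet",
    "trim_search_volume",
    "select_threshold_frame",
    "extract_carotid_vois",
    "extract_idif",
    "run_idif_pipeline",
    "DEFAULT_XY_TRIM",
    "DEFAULT_Z_TRIM",
    "DEFAULT_THRESHOLD_FRACTION",
    "DEFAULT_VOI_SIZES",
]

DEFAULT_XY_TRIM = 20
DEFAULT_Z_TRIM = 5
DEFAULT_THRESHOLD_FRACTION = 0.25
DEFAULT_VOI_SIZES = (10, 100, 1000)


@dataclass(frozen=True)
class DynamicImage:
    """4-D voxel array (x, y, z, frame) in kBq/mL with frame timing."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        object.__setattr__(self, "voxels", v)
        if v.ndim != 4:
            raise ValueError("dynamic image must be 4-D (x, y, z, frame)")
        if v.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"image has {v.shape[3]} frames but schedule has {self.schedule.n_frames}"
            )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]


@dataclass(frozen=True)
class VoiMask:
    """Boolean voxel selection over the spatial grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 3:
            raise ValueError("VOI mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass(frozen=True)
class IdifSet:
    """The three carotid IDIF channels of one scan, on a shared grid."""

    idif10: TimeActivityCurve
    idif100: TimeActivityCurve
    idif1000: TimeActivityCurve

    threshold_frame: int = -1

    def channels(self) -> tuple[TimeActivityCurve, TimeActivityCurve, TimeActivityCurve]:
        return (self.idif10, self.idif100, self.idif1000)


def trim_search_volume(
    img: DynamicImage, xy_trim: int = DEFAULT_XY_TRIM, z_trim: int = DEFAULT_Z_TRIM
) -> VoiMask:
    """Interior search region: drop ``xy_trim`` voxels from each x/y edge
    and ``z_trim`` slices from each z end, removing edge-slice noise."""
    nx, ny, nz = img.spatial_shape
    if nx <= 2 * xy_trim or ny <= 2 * xy_trim or nz <= 2 * z_trim:
        raise ValueError("trim exceeds the image extent")
    mask = np.zeros(img.spatial_shape, dtype=bool)
    mask[xy_trim : nx - xy_trim, xy_trim : ny - xy_trim, z_trim : nz - z_trim] = True
    return VoiMask(mask)


def select_threshold_frame(
    img: DynamicImage,
    gm_mask: VoiMask,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> int:
    """First frame whose grey-matter total intensity exceeds a fraction
    of the maximum of that frame-wise graph (strict inequality)."""
    if gm_mask.n_voxels == 0:
        raise ValueError("grey-matter mask is empty")
    sums = img.voxels[gm_mask.mask, :].sum(axis=0)
    top = float(sums.max())
    if top <= 0:
        raise ValueError("image is all-zero within the grey-matter mask")
    above = np.nonzero(sums > threshold_fraction * top)[0]
    return int(above[0])


def extract_carotid_vois(
    img: DynamicImage,
    frame: int,
    search: VoiMask,
    sizes: tuple[int, ...] = DEFAULT_VOI_SIZES,
) -> tuple[VoiMask, ...]:
    """Top-k highest-intensity voxels of one frame, for each VOI size.

    Selection is within the search region only.  Ties at the cutoff
    intensity break by ascending linear voxel index (stable sort), so
    the result is deterministic; with distinct intensities the VOIs are
    nested by construction.
    """
    kmax = max(sizes)
    if search.n_voxels < kmax:
        raise ValueError(f"search region has {search.n_voxels} voxels, need >= {kmax}")
    vol = img.voxels[..., frame]
    flat = np.where(search.mask.ravel(), vol.ravel(), -np.inf)
    order = np.argsort(-flat, kind="stable")
    out = []
    for k in sizes:
        m = np.zeros(flat.shape, dtype=bool)
        m[order[:k]] = True
        out.append(VoiMask(m.reshape(img.spatial_shape)))
    return tuple(out)


def extract_idif(img: DynamicImage, voi: VoiMask) -> TimeActivityCurve:
    """Per-frame median over the VOI voxels (even counts: mean of the two
    central values), on the frame-midpoint grid."""
    if voi.n_voxels == 0:
        raise ValueError("VOI is empty")
    vals = np.median(img.voxels[voi.mask, :], axis=0)
    return TimeActivityCurve(img.schedule.frame_mid, vals, grid_kind="frame-based")


def run_idif_pipeline(
    img: DynamicImage,
    gm_mask: VoiMask,
    xy_trim: int = DEFAULT_XY_TRIM,
    z_trim: int = DEFAULT_Z_TRIM,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    sizes: tuple[int, ...] = DEFAULT_VOI_SIZES,
) -> IdifSet:
    """Full IDIF extraction: trim, pick the bolus frame, take top-k VOIs,
    median TACs, interpolate to 1 s and window to 0-6 min."""
    search = trim_search_volume(img, xy_trim=xy_trim, z_trim=z_trim)
    frame = select_threshold_frame(img, gm_mask, threshold_fraction=threshold_fraction)
    vois = extract_carotid_vois(img, frame, search, sizes=sizes)
    curves = [
        window_0_to_6min(resample_to_1s(extract_idif(img, voi), img.schedule)) for voi in vois
    ]
    return IdifSet(*curves, threshold_frame=frame)
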