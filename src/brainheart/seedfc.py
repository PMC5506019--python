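"""Static seed-based functional connectivity.

A seed region of interest (a sphere around a published coordinate, e.g. the
posterior cingulate or ventromedial prefrontal hub of the default mode
network, or bilateral amygdala / nucleus accumbens) yields one mean time
series per session; its Pearson correlation against every grey-matter voxel
gives a connectivity map, variance-stabilized by Fisher's r-to-z transform
before group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import TimeSeriesImage

__all__ = ["ROIMask", "ZMap", "make_sphere_roi", "roi_timeseries", "fc_map", "fisher_z"]

R_CLIP = 1.0 - 1e-7


@dataclass
class ROIMask:
    """Spherical seed region: name, world-space centre, and member voxels."""

    name: str
    center_mm: np.ndarray
    radius_mm: float
    voxels: np.ndarray  # (n, 3) integer voxel indices

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.voxels.size == 0:
            raise ValueError(f"ROI '{self.name}' has no voxels")


@dataclass
class ZMap:
    """Voxelwise Fisher-z connectivity map over an analysis mask."""

    values: np.ndarray  # flat, one per in-mask voxel
    mask: np.ndarray  # boolean 3D analysis mask
    seed_name: str
    session_label: str = ""
    flagged: np.ndarray | None = None  # constant-voxel flags

    def to_volume(self) -> np.ndarray:
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask] = self.values
        return vol


def make_sphere_roi(
    name: str,
    center_mm,
    radius_mm: float,
    grid_shape: tuple[int, int, int],
    affine: np.ndarray,
) -> ROIMask:
    """All voxels whose centre lies within ``radius_mm`` of ``center_mm``."""
    center_mm = np.asarray(center_mm, dtype=float)
    affine = np.asarray(affine, dtype=float)
    inv = np.linalg.inv(affine)
    center_vox = (inv @ np.append(center_mm, 1.0))[:3]
    if ((center_vox < -0.5) | (center_vox > np.array(grid_shape) - 0.5)).any():
        raise ValueError(f"ROI centre {center_mm} outside image bounds")
    idx = np.indices(grid_shape).reshape(3, -1).T  # (V, 3)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    dist = np.linalg.norm(world - center_mm, axis=1)
    voxels = idx[dist <= radius_mm]
    if voxels.size == 0:
        raise ValueError(
            f"sphere of radius {radius_mm} mm at {center_mm} contains no voxel centres"
        )
    return ROIMask(name=name, center_mm=center_mm, radius_mm=radius_mm, voxels=voxels)


def roi_timeseries(img: TimeSeriesImage, roi: ROIMask) -> np.ndarray:
    """Per-volume mean over the ROI's voxels."""
    vox = roi.voxels
    if (vox < 0).any() or (vox >= np.array(img.grid_shape)).any():
        raise ValueError(f"ROI '{roi.name}' extends outside the image grid")
    return img.data[vox[:, 0], vox[:, 1], vox[:, 2], :].mean(axis=0)


def fc_map(
    img: TimeSeriesImage,
    seed_series: np.ndarray,
    mask: np.ndarray,
    seed_name: str = "",
    session_label: str = "",
) -> ZMap:
    """Pearson correlation of the seed series with every in-mask voxel,
    returned as a Fisher-z map. Constant voxels are NaN with a flag."""
    seed = np.asarray(seed_series, dtype=float).ravel()
    if seed.size != img.n_volumes:
        raise ValueError("seed series length must equal n_volumes")
    if seed.size < 3:
        raise ValueError("need at least 3 volumes")
    if seed.std() == 0:
        raise ValueError("constant seed series")
    mask = np.asarray(mask, dtype=bool)
    ts = img.data[mask]  # (V, t)
    ts_c = ts - ts.mean(axis=1, keepdims=True)
    sd = ts_c.std(axis=1)
    seed_c = seed - seed.mean()
    flagged = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ts_c @ seed_c) / (seed.size * sd * seed_c.std())
    r[flagged] = np.nan
    return ZMap(
        values=fisher_z(r),
        mask=mask,
        seed_name=seed_name,
        session_label=session_label,
        flagged=flagged,
    )


def fisher_z(r):
    """Fisher r-to-z: atanh(r) with r clipped to (-1+1e-7, 1-1e-7).

    Odd and strictly increasing; NaNs propagate.
    """
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    return z if z.ndim else float(z)
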