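"""Temporal preprocessing of 4D BOLD images.

The pipeline applied here is the temporal half of a conventional
resting-state stream: discard the first volumes acquired before the
magnetization reaches steady state, optionally smooth each volume with a 3D
Gaussian kernel, regress out nuisance signals (six rigid-body motion
parameters plus mean white-matter and CSF signals), and band-pass filter
each voxel series to the low-frequency band (0.009-0.08 Hz) where
resting-state correlations live.

Spatial preprocessing (realignment, coregistration, stereotactic
normalization) is out of scope: inputs are assumed to share a common grid,
which holds by construction for synthetic cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "TimeSeriesImage",
    "discard_initial_volumes",
    "extract_tissue_means",
    "regress_nuisance",
    "bandpass",
    "smooth",
    "preprocess_session",
]


@dataclass
class TimeSeriesImage:
    """A 4D voxel-by-time signal with grid geometry and repetition time.

    ``data`` is an (x, y, z, t) float array; ``affine`` maps voxel indices to
    world millimetres; ``tr_s`` is the time between successive volumes.
    """

    data: np.ndarray
    tr_s: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (x, y, z, t) data, got {self.data.ndim}D")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    def timeseries_2d(self) -> np.ndarray:
        """Return a (time, voxel) view-copy of the data."""
        return self.data.reshape(-1, self.n_volumes).T


def discard_initial_volumes(img: TimeSeriesImage, n_discard: int = 5) -> TimeSeriesImage:
    """Drop the first ``n_discard`` volumes (magnetization stabilization)."""
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= img.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {img.n_volumes} volumes"
        )
    if n_discard == 0:
        return replace(img, data=img.data.copy())
    return replace(img, data=img.data[..., n_discard:].copy())


def extract_tissue_means(
    img: TimeSeriesImage, masks: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-volume mean signal over each tissue mask, one column per tissue."""
    cols = {}
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img.grid_shape:
            raise ValueError(f"mask '{name}' shape {mask.shape} != grid {img.grid_shape}")
        if not mask.any():
            raise ValueError(f"mask '{name}' is empty")
        cols[name] = img.data[mask].mean(axis=0)
    return pd.DataFrame(cols)


def regress_nuisance(
    img: TimeSeriesImage, confounds: pd.DataFrame | np.ndarray
) -> TimeSeriesImage:
    """OLS-residualize every voxel series against the confounds plus intercept.

    Residuals are orthogonal to every confound column and to the constant,
    so the output has zero temporal mean per voxel.
    """
    conf = np.asarray(confounds, dtype=float)
    if conf.ndim == 1:
        conf = conf[:, None]
    if conf.shape[0] != img.n_volumes:
        raise ValueError(
            f"confound rows ({conf.shape[0]}) != n_volumes ({img.n_volumes})"
        )
    if not np.isfinite(conf).all():
        raise ValueError("confounds contain non-finite values")
    design = np.column_stack([np.ones(img.n_volumes), conf])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        names = (
            list(confounds.columns)
            if isinstance(confounds, pd.DataFrame)
            else [f"c{i}" for i in range(conf.shape[1])]
        )
        bad = _collinear_columns(design, names)
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    ts = img.timeseries_2d()  # (t, v)
    beta, *_ = np.linalg.lstsq(design, ts, rcond=None)
    resid = ts - design @ beta
    out = resid.T.reshape(img.data.shape)
    return replace(img, data=out)


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Name confound columns that do not add rank (intercept is column 0)."""
    bad = []
    kept = design[:, :1]
    for j in range(1, design.shape[1]):
        cand = np.column_stack([kept, design[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            bad.append(names[j - 1])
        else:
            kept = cand
    return bad


def bandpass(
    img: TimeSeriesImage, low_hz: float = 0.009, high_hz: float = 0.08, order: int = 2
) -> TimeSeriesImage:
    """Zero-phase Butterworth band-pass of every voxel series.

    Forward-backward filtering (sosfiltfilt) doubles the effective order and
    cancels phase shifts; the DC component is removed along with all
    frequencies outside [low_hz, high_hz].
    """
    nyq = 0.5 / img.tr_s
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high_hz ({high_hz}) must be below Nyquist ({nyq})")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / img.tr_s, output="sos")
    out = signal.sosfiltfilt(sos, img.data, axis=3)
    return replace(img, data=np.ascontiguousarray(out))


def smooth(img: TimeSeriesImage, fwhm_mm: float = 6.0) -> TimeSeriesImage:
    """Per-volume 3D Gaussian smoothing with the kernel given as FWHM in mm."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return replace(img, data=img.data.copy())
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / img.voxel_size_mm
    out = ndimage.gaussian_filter(
        img.data, sigma=tuple(sigma_vox) + (0.0,), mode="constant"
    )
    return replace(img, data=out)


def preprocess_session(
    img: TimeSeriesImage,
    motion: pd.DataFrame,
    tissue_masks: dict[str, np.ndarray],
    n_discard: int = 5,
    fwhm_mm: float = 0.0,
    low_hz: float = 0.009,
    high_hz: float = 0.08,
) -> TimeSeriesImage:
    """Fixed-order temporal pipeline: trim -> smooth -> nuisance -> band-pass.

    ``motion`` must have one row per acquired volume; it is trimmed together
    with the image before building the confound table (6 motion columns plus
    white-matter and CSF means).
    """
    if len(motion) != img.n_volumes:
        raise ValueError("motion table rows must match acquired volumes")
    img = discard_initial_volumes(img, n_discard)
    motion = motion.iloc[n_discard:].reset_index(drop=True)
    if fwhm_mm > 0:
        img = smooth(img, fwhm_mm)
    tissues = extract_tissue_means(img, tissue_masks)
    confounds = pd.concat([motion.reset_index(drop=True), tissues], axis=1)
    img = regress_nuisance(img, confounds)
    return bandpass(img, low_hz, high_hz)
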