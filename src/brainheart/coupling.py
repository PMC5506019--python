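"""Sliding-window dynamic connectivity and the brain-heart coupling statistic.

Dynamic functional connectivity is computed in 60 s windows slid in 10 s
steps across each session (25 windows over a 300 s scan at TR = 2 s).
Heart rate averaged on the same window grid gives a parallel windowed
series, and the per-subject temporal-synchronization statistic is the
Pearson correlation between windowed FC and windowed HR across windows.
Group inference on those per-subject correlations (one-sample t on Fisher-z
values, FDR over network edges or cluster-FWE over voxels) lives in
:mod:`brainheart.stats` and is orchestrated by :func:`group_sync`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seedfc import fisher_z

__all__ = [
    "WindowGrid",
    "WindowedSeries",
    "WindowedFC",
    "window_grid",
    "sliding_fc",
    "fc_hr_sync",
    "group_sync",
]


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window scheme anchored to the session's analysis start."""

    window_s: float
    step_s: float
    n_windows: int
    window_starts_s: tuple[float, ...]
    tr_s: float

    @property
    def volumes_per_window(self) -> int:
        return int(round(self.window_s / self.tr_s))

    def volume_slices(self) -> list[slice]:
        """Volume-index slice per window."""
        out = []
        for start in self.window_starts_s:
            i0 = int(round(start / self.tr_s))
            out.append(slice(i0, i0 + self.volumes_per_window))
        return out


@dataclass
class WindowedSeries:
    """One value per window, with explicit missing/low-quality flags."""

    grid: WindowGrid
    values: np.ndarray
    flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[-1] != self.grid.n_windows:
            raise ValueError("values last axis must equal n_windows")
        if self.flagged is None:
            self.flagged = ~np.isfinite(self.values)
        self.flagged = np.asarray(self.flagged, dtype=bool)


@dataclass
class WindowedFC(WindowedSeries):
    """Per-window Fisher-z connectivity for one edge or a stack of targets.

    ``values`` has shape (n_windows,) for a single edge, or
    (n_targets, n_windows) for a voxel/edge stack.
    """


def window_grid(
    n_volumes: int, tr_s: float, window_s: float = 60.0, step_s: float = 10.0
) -> WindowGrid:
    """Build the sliding-window grid: floor((T - window)/step) + 1 windows.

    The first window starts at 0 s (the first retained volume); every window
    lies fully inside the session.
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    duration = n_volumes * tr_s
    if duration < window_s:
        raise ValueError(
            f"session of {duration:g}s shorter than one {window_s:g}s window"
        )
    n_windows = int(np.floor((duration - window_s) / step_s)) + 1
    starts = tuple(i * step_s for i in range(n_windows))
    return WindowGrid(
        window_s=window_s,
        step_s=step_s,
        n_windows=n_windows,
        window_starts_s=starts,
        tr_s=tr_s,
    )


def sliding_fc(
    series_a: np.ndarray,
    series_b: np.ndarray,
    grid: WindowGrid,
) -> WindowedFC:
    """Windowed Pearson correlation between two series, Fisher-z transformed.

    ``series_b`` may be 1D (single target) or (n_targets, n_volumes) for a
    voxel stack; windows where either series is constant are flagged NaN.
    """
    a = np.asarray(series_a, dtype=float).ravel()
    b = np.atleast_2d(np.asarray(series_b, dtype=float))
    if a.size != b.shape[1]:
        raise ValueError("series lengths differ")
    single = np.asarray(series_b).ndim == 1
    n_targets = b.shape[0]
    z = np.full((n_targets, grid.n_windows), np.nan)
    flagged = np.zeros_like(z, dtype=bool)
    for w, sl in enumerate(grid.volume_slices()):
        aw = a[sl]
        bw = b[:, sl]
        sa = aw.std()
        sb = bw.std(axis=1)
        bad = (sb == 0) | (sa == 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = ((bw - bw.mean(axis=1, keepdims=True)) @ (aw - aw.mean())) / (
                aw.size * sa * sb
            )
        r[bad] = np.nan
        flagged[:, w] = bad
        z[:, w] = fisher_z(r)
    if single:
        return WindowedFC(grid=grid, values=z[0], flagged=flagged[0])
    return WindowedFC(grid=grid, values=z, flagged=flagged)


def fc_hr_sync(wfc: WindowedFC, whr: WindowedSeries) -> np.ndarray:
    """Per-target Pearson correlation between windowed FC and windowed HR.

    Windows flagged or non-finite in either input are dropped pairwise;
    targets with fewer than 3 complete paired windows, or with zero variance
    in either series over the paired windows, yield NaN (explicitly missing,
    never silently zero).
    """
    if wfc.grid.n_windows != whr.grid.n_windows:
        raise ValueError("FC and HR window grids differ")
    fc = np.atleast_2d(wfc.values)
    fc_flag = np.atleast_2d(wfc.flagged)
    hr_ok = np.isfinite(whr.values) & ~whr.flagged
    out = np.full(fc.shape[0], np.nan)
    for k in range(fc.shape[0]):
        ok = hr_ok & np.isfinite(fc[k]) & ~fc_flag[k]
        if ok.sum() < 3:
            continue
        x, y = fc[k, ok], whr.values[ok]
        if x.std() == 0 or y.std() == 0:
            continue
        out[k] = np.corrcoef(x, y)[0, 1]
    return out[0] if np.asarray(wfc.values).ndim == 1 else out


def group_sync(
    subject_r: np.ndarray,
    mode: str = "edges",
    q: float = 0.05,
    grid_shape: tuple[int, int, int] | None = None,
    mask: np.ndarray | None = None,
    cdt_p: float = 0.005,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
):
    """Group-level test of FC-HR synchronization across subjects.

    Subject correlations are Fisher-z transformed and tested against zero
    with a one-sample t-test. Edge-wise results (``mode='edges'``) are
    corrected by Benjamini-Hochberg FDR at ``q``; voxel-wise results
    (``mode='voxels'``) by permutation max-cluster-size FWE with a
    cluster-defining threshold ``cdt_p``.

    Returns ``(StatResult, FDRResult)`` for edges or
    ``(StatResult, ClusterTable)`` for voxels.
    """
    from . import stats as bstats
    from .seedfc import fisher_z as _fz

    r = np.asarray(subject_r, dtype=float)
    valid = np.isfinite(r).all(axis=tuple(range(1, r.ndim))) if r.ndim > 1 else np.isfinite(r)
    if int(valid.sum()) < 3:
        raise ValueError("need >= 3 subjects with non-missing synchronization")
    z = _fz(r[valid])
    res = bstats.one_sample_t(z)
    if mode == "edges":
        fdr = bstats.fdr_bh(res.p_map, q=q)
        return res, fdr
    if mode == "voxels":
        if grid_shape is None:
            raise ValueError("grid_shape required for voxelwise inference")
        table = bstats.cluster_inference(
            z,
            grid_shape=grid_shape,
            mask=mask,
            cdt_p=cdt_p,
            n_perm=n_perm,
            scheme="sign_flip",
            alpha=alpha,
            seed=seed,
        )
        return res, table
    raise ValueError(f"unknown mode {mode!r}")
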