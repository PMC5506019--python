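"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a five-session intervention study: baseline rest,
two 5-minute audio-visual interventions (a positive "gratitude" and a
negative "resentment" condition, counterbalanced across subjects), each
followed by rest. Every session is 155 volumes at TR = 2 s; the two
intervention sessions additionally carry a 50 Hz fingertip PPG recording.

Each network's BOLD signal is a band-limited (0.009-0.08 Hz) latent time
course — a sum of random-phase sinusoids plus a small AR(1) jitter —
shared by all voxels of the network with voxel-specific loadings, Gaussian
noise, and optional leakage of motion/tissue confounds. Inter-network
correlations are imposed by Cholesky mixing of independent sources, so
condition effects on named edges and subject-level behaviour-linked edge
deviations are injected directly into the target correlation matrix.

Brain-heart coupling is exact by construction: windowed heart rate is
built as sync_rho x standardized windowed FC of the designated edge plus
orthogonalized noise on the shared 60 s / 10 s window grid, then beat
intervals are back-filled and rendered as one Gaussian pulse per beat on
the 50 Hz PPG grid. All ground truth (latents, per-window FC and HR, beat
times) is retained so every injected effect is recoverable by brute force
before the pipeline runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coupling import window_grid
from .physio import PPGTrace
from .preprocess import TimeSeriesImage

__all__ = [
    "NetworkAtlas",
    "CouplingSpec",
    "BehaviorEffect",
    "SessionTruth",
    "SessionBundle",
    "SubjectData",
    "CohortDataset",
    "AtlasCapacityError",
    "make_network_atlas",
    "simulate_session",
    "simulate_cohort",
    "write_dataset",
    "read_image",
    "atlas_network_series",
    "NETWORK_NAMES",
    "SESSION_ORDERS",
]

NETWORK_NAMES = ["dmn", "temporolimbic", "salience", "fp_left", "fp_right"]
SEED_NAMES = ["pcc", "vmpfc", "amygdala_l", "amygdala_r", "na_l", "na_r"]
# which network hosts each named seed point (DMN hubs, limbic amygdalae,
# striatal accumbens grouped with the salience block in this toy geometry)
SEED_NETWORK = {
    "pcc": 1, "vmpfc": 1,
    "amygdala_l": 2, "amygdala_r": 2,
    "na_l": 3, "na_r": 3,
}
SESSION_ORDERS = {
    "I": ["rest_baseline", "gratitude", "rest_post_gratitude",
          "resentment", "rest_post_resentment"],
    "II": ["rest_baseline", "resentment", "rest_post_resentment",
           "gratitude", "rest_post_gratitude"],
}
INTERVENTIONS = ("gratitude", "resentment")


class AtlasCapacityError(ValueError):
    """Grid too small to host the requested number of network blocks."""


@dataclass
class NetworkAtlas:
    """Block atlas: per-voxel network labels plus named seed coordinates.

    Labels are 0 (background), 1..K (networks); two extra contiguous blocks
    serve as white-matter and CSF compartments. Every network block is a
    contiguous cube of at least 27 voxels.
    """

    grid_shape: tuple[int, int, int]
    labels: np.ndarray
    seed_points: dict[str, tuple[int, int, int]]
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    voxel_size_mm: float = 3.0

    @property
    def n_networks(self) -> int:
        return int(self.labels.max())

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    @property
    def analysis_mask(self) -> np.ndarray:
        """Grey-matter analogue: everything except the WM and CSF blocks.

        Includes noise-only background voxels deliberately: they keep the
        network indicator maps linearly independent of the spatial constant
        (the K disjoint blocks would otherwise span only K - 1 contrast
        directions after voxel centering, making single-network components
        unrecoverable), and they provide true-null voxels for calibrating
        voxelwise inference.
        """
        return ~(self.wm_mask | self.csf_mask)

    def network_mask(self, k: int) -> np.ndarray:
        return self.labels == k

    def seed_mm(self, name: str) -> np.ndarray:
        return (self.affine @ np.append(self.seed_points[name], 1.0))[:3]


@dataclass
class BehaviorEffect:
    """Linear link from a standardized behavioral score to an edge's FC.

    The subject's target correlation on ``edge`` is shifted by
    ``slope * standardized_score + N(0, noise_sd)``.
    """

    edge: tuple[int, int]
    slope: float
    noise_sd: float = 0.15


@dataclass
class CouplingSpec:
    """All injectable condition effects and nuisance levels of the cohort.

    Defaults are the study conditions the generator emulates: a -3 bpm mean
    HR shift in the gratitude condition (between-subject difference sd
    6 bpm), FC-HR coupling of strength ``sync_rho`` on ``sync_edge`` during
    the gratitude intervention, condition-specific FC changes on named
    edges, and an anxiety-linked edge mimicking the observed negative
    behaviour-connectivity correlation (~ -0.4).
    """

    hr_baseline_bpm: float = 70.0
    hr_condition_delta_bpm: float = -3.0
    hr_delta_condition: str = "gratitude"
    hr_subject_sd_bpm: float = 7.0
    hr_delta_sd_bpm: float = 6.0
    hr_window_sd_bpm: float = 3.0
    sync_edge: tuple[int, int] = (1, 2)
    sync_rho: float = 0.6
    sync_condition: str = "gratitude"
    sync_edge_base_r: float = 0.3
    # background FC defaults to zero: any shared background correlation
    # mechanically propagates the FC-HR coupling from sync_edge onto every
    # edge sharing a node with it (windowed-FC fluctuations of two edges
    # correlate in proportion to the correlation of their non-shared nodes),
    # contradicting the contract that sync_edge alone carries the coupling
    base_edge_r: float = 0.0
    fc_effects: dict = field(
        default_factory=lambda: {
            "gratitude": {(4, 5): 0.25},
            "rest_post_gratitude": {(2, 3): -0.3},
        }
    )
    behavior_effects: dict = field(
        default_factory=lambda: {"hads_anxiety": BehaviorEffect(edge=(2, 5), slope=-0.07)}
    )
    noise_sd: float = 0.5
    confound_leak: float = 0.1
    n_volumes: int = 155
    tr_s: float = 2.0
    n_discard: int = 5
    ppg_rate_hz: float = 50.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.sync_rho) > 1:
            raise ValueError("|sync_rho| must be <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 30 <= self.hr_baseline_bpm <= 200:
            raise ValueError("hr_baseline_bpm must lie in [30, 200]")
        a, b = self.sync_edge
        if a == b:
            raise ValueError("sync_edge must join two distinct networks")
        self.sync_edge = (min(a, b), max(a, b))


@dataclass
class SessionTruth:
    """Ground truth retained for brute-force recovery checks."""

    condition: str
    latents: np.ndarray  # (n_volumes, K), pre-noise network time courses
    target_corr: np.ndarray  # (K, K) target correlation matrix
    realized_corr: np.ndarray  # sample correlation of latents (full session)
    window_fc_z: np.ndarray | None = None  # sync-edge windowed z (trimmed grid)
    window_hr_target_bpm: np.ndarray | None = None  # solver target per-window HR
    window_hr_bpm: np.ndarray | None = None  # realized per-window mean of beat HR
    beat_times_ms: np.ndarray | None = None  # PPG-local beat times
    mean_hr_bpm: float | None = None
    sync_r: float | None = None  # realized corr(window_hr_bpm, window_fc_z)


@dataclass
class SessionBundle:
    condition: str
    image: TimeSeriesImage | None
    motion: pd.DataFrame
    ppg: PPGTrace | None
    truth: SessionTruth


@dataclass
class SubjectData:
    subject_id: str
    order_set: str
    sessions: dict[str, SessionBundle]  # keyed by condition label
    hr_baseline_bpm: float
    hr_delta_bpm: float

    @property
    def session_order(self) -> list[str]:
        return SESSION_ORDERS[self.order_set]


@dataclass
class CohortDataset:
    atlas: NetworkAtlas
    spec: CouplingSpec
    subjects: list[SubjectData]
    behaviors: pd.DataFrame
    manifest: dict | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def make_network_atlas(
    grid_shape: tuple[int, int, int] = (16, 16, 8),
    n_networks: int = 5,
    seed: int = 0,
    block: int = 3,
    voxel_size_mm: float = 3.0,
) -> NetworkAtlas:
    """Partition the grid into disjoint contiguous cubic network blocks.

    ``n_networks`` blocks of ``block``^3 voxels (>= 27) are placed on a
    coarse cell grid, plus two extra blocks for the white-matter and CSF
    compartments. Deterministic for a fixed seed.
    """
    if n_networks < 2:
        raise ValueError("need at least 2 networks")
    grid_shape = tuple(int(g) for g in grid_shape)
    cells = tuple(g // block for g in grid_shape)
    n_cells = int(np.prod(cells))
    needed = n_networks + 2  # networks + WM + CSF
    if n_cells < needed:
        raise AtlasCapacityError(
            f"grid {grid_shape} fits {n_cells} blocks of {block}^3 voxels; "
            f"{needed} needed ({n_networks} networks + WM + CSF)"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_cells)[:needed]
    labels = np.zeros(grid_shape, dtype=int)
    wm = np.zeros(grid_shape, dtype=bool)
    csf = np.zeros(grid_shape, dtype=bool)
    origins = []
    for rank, cell in enumerate(order):
        ci = np.unravel_index(cell, cells)
        sl = tuple(slice(c * block, (c + 1) * block) for c in ci)
        origins.append(tuple(c * block for c in ci))
        if rank < n_networks:
            labels[sl] = rank + 1
        elif rank == n_networks:
            wm[sl] = True
        else:
            csf[sl] = True
    seed_points: dict[str, tuple[int, int, int]] = {}
    for name in SEED_NAMES:
        net = min(SEED_NETWORK[name], n_networks)
        vox = np.argwhere(labels == net)
        # distinct voxels per seed name within the block, deterministically
        idx = SEED_NAMES.index(name) % len(vox)
        seed_points[name] = tuple(int(v) for v in vox[idx])
    return NetworkAtlas(
        grid_shape=grid_shape,
        labels=labels,
        seed_points=seed_points,
        wm_mask=wm,
        csf_mask=csf,
        voxel_size_mm=voxel_size_mm,
    )


# ---------------------------------------------------------------------------
# latent dynamics

PASS_BAND = (0.009, 0.08)
_SINE_BAND = (0.012, 0.07)  # inside the pass band, clear of its edges
_N_SINES = 8
_AR_FRAC = 0.05  # variance fraction of the AR(1) jitter


def _band_limited_source(n: int, tr_s: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance source: random-phase sinusoids in-band + AR(1) jitter."""
    t = np.arange(n) * tr_s
    freqs = rng.uniform(*_SINE_BAND, size=_N_SINES)
    phases = rng.uniform(0, 2 * np.pi, size=_N_SINES)
    amps = rng.uniform(0.5, 1.0, size=_N_SINES)
    s = (amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None])).sum(axis=0)
    ar = np.empty(n)
    ar[0] = rng.standard_normal()
    eps = rng.standard_normal(n)
    for i in range(1, n):
        ar[i] = 0.95 * ar[i - 1] + eps[i]
    s = (s - s.mean()) / s.std()
    ar = (ar - ar.mean()) / ar.std()
    out = np.sqrt(1 - _AR_FRAC) * s + np.sqrt(_AR_FRAC) * ar
    return (out - out.mean()) / out.std()


def _nearest_corr(c: np.ndarray, floor: float = 0.01) -> np.ndarray:
    """Eigenvalue-clipped positive-definite repair of a correlation matrix."""
    w, v = np.linalg.eigh(c)
    if w.min() > floor:
        return c
    w = np.clip(w, floor, None)
    c2 = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(c2))
    return c2 / np.outer(d, d)


def _target_corr_matrix(
    n_networks: int,
    spec: CouplingSpec,
    condition: str,
    edge_adjust: dict[tuple[int, int], float] | None = None,
) -> np.ndarray:
    """Assemble the session's target inter-network correlation matrix."""
    c = np.full((n_networks, n_networks), spec.base_edge_r)
    np.fill_diagonal(c, 1.0)

    def bump(edge, dr):
        a, b = sorted(edge)
        if b > n_networks:
            raise ValueError(f"edge {edge} references a network absent from the atlas")
        c[a - 1, b - 1] += dr
        c[b - 1, a - 1] += dr

    bump(spec.sync_edge, spec.sync_edge_base_r - spec.base_edge_r)
    for edge, dr in spec.fc_effects.get(condition, {}).items():
        bump(tuple(edge), dr)
    for edge, dr in (edge_adjust or {}).items():
        bump(tuple(edge), dr)
    off = ~np.eye(n_networks, dtype=bool)
    c[off] = np.clip(c[off], -0.85, 0.85)
    return _nearest_corr(c)


# ---------------------------------------------------------------------------
# heart rate and PPG synthesis

_PULSE_SIGMA_S = 0.100 / 2.355  # Gaussian pulse, 100 ms FWHM


def _window_average_matrix(n_blocks: int, blocks_per_window: int, n_windows: int) -> np.ndarray:
    a = np.zeros((n_windows, n_blocks))
    for w in range(n_windows):
        a[w, w : w + blocks_per_window] = 1.0 / blocks_per_window
    return a


def _synthesize_hr(
    window_z: np.ndarray,
    spec: CouplingSpec,
    rho: float,
    mean_hr: float,
    step_s: float,
    window_s: float,
    pre_s: float,
    total_analysis_s: float,
    rng: np.random.Generator,
):
    """Build beat times whose windowed mean HR correlates exactly ``rho``
    with the standardized windowed FC ``window_z``.

    Returns (beat times in analysis seconds, target per-window HR).
    """
    n_w = window_z.size
    zs = (window_z - window_z.mean()) / window_z.std()
    if abs(rho) < 1:
        # smooth (AR(1)) noise: overlapping windows make the FC series smooth,
        # so the HR residual must be comparably smooth or the back-filled
        # beat-interval series oscillates unphysiologically
        e = np.empty(n_w)
        e[0] = rng.standard_normal()
        for i in range(1, n_w):
            e[i] = 0.8 * e[i - 1] + 0.6 * rng.standard_normal()
        e = e - e.mean() - zs * (e @ zs) / (zs @ zs)  # orthogonal to zs
        e = e / e.std()
        dev = rho * zs + np.sqrt(1 - rho**2) * e
    else:
        dev = np.sign(rho) * zs
    h = mean_hr + spec.hr_window_sd_bpm * dev

    # back-fill 10 s block HR levels whose window means reproduce h exactly;
    # among the exact solutions pick the smoothest (minimal second
    # differences), then clip to a physiological band: the 6-block averaging
    # amplifies window-to-window changes 6-fold, and an unregularized
    # solution swings into implausible beat intervals
    blocks_per_window = int(round(window_s / step_s))
    n_blocks = int(round(total_analysis_s / step_s))
    a = _window_average_matrix(n_blocks, blocks_per_window, n_w)
    # smoothness-penalized solve: the 6-block averaging amplifies
    # window-to-window changes about 6-fold, so an exact (min-norm) solution
    # swings into implausible beat intervals; a small second-difference
    # penalty tames the swings at a sub-bpm cost in window-mean fidelity
    lap = np.diff(np.eye(n_blocks), n=2, axis=0)
    normal = a.T @ a + 0.01 * (lap.T @ lap) + 1e-9 * np.eye(n_blocks)

    def solve_blocks(target: np.ndarray) -> np.ndarray:
        d0 = np.linalg.solve(normal, a.T @ (target - target.mean()))
        # keep intervals inside the beat-validity band with margin
        return np.clip(target.mean() + d0, max(35.0, 0.45 * mean_hr),
                       min(220.0, 2.2 * mean_hr))

    def render_beats(block_hr: np.ndarray) -> np.ndarray:
        out = []
        t = -pre_s
        while t < total_analysis_s:
            out.append(t)
            i = min(max(int(t // step_s), 0), n_blocks - 1)
            t += 60.0 / float(block_hr[i])
        return np.array(out)

    def realized_window_means(beats: np.ndarray) -> np.ndarray:
        # same convention as the measurement path: mean of instantaneous HR
        # samples whose interval midpoints fall in [start, start + window)
        ib = np.diff(beats)
        mids = beats[:-1] + ib / 2
        inst = 60.0 / ib
        out = np.empty(n_w)
        for w in range(n_w):
            sel = (mids >= w * step_s) & (mids < w * step_s + window_s)
            out[w] = inst[sel].mean() if sel.any() else h[w]
        return out

    # beat quantization biases the per-window mean (more beats land in
    # faster stretches); a few fixed-point corrections of the solve target
    # cancel that bias so the realized windowed HR tracks h closely
    target = h.copy()
    best_beats, best_err = None, np.inf
    for _ in range(8):
        beats = render_beats(solve_blocks(target))
        err = realized_window_means(beats) - h
        # faster stretches contribute more beats, so the session mean of
        # instantaneous HR runs ~var/mean above the target.  Correct the
        # window *shape* with the demeaned error and the session mean with
        # the scalar bias: the two components are orthogonal, and a uniform
        # shift of the window means leaves windowed correlations unchanged.
        shape_err = err - err.mean()
        bias = float((60.0 / np.diff(beats)).mean() - mean_hr)
        score = float(np.sqrt(np.mean(shape_err**2) + bias**2))
        if score < best_err:
            best_beats, best_err = beats, score
        target = target - 0.7 * (shape_err + bias)  # damped for stability
    return best_beats, h


def _render_ppg(
    beat_times_s: np.ndarray, duration_s: float, rate_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Gaussian pulse (100 ms FWHM) per beat on the sampling grid."""
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    x = np.zeros_like(t)
    half = 4 * _PULSE_SIGMA_S
    for tb in beat_times_s:
        i0 = max(0, int((tb - half) * rate_hz))
        i1 = min(t.size, int((tb + half) * rate_hz) + 1)
        x[i0:i1] += np.exp(-0.5 * ((t[i0:i1] - tb) / _PULSE_SIGMA_S) ** 2)
    x += 0.01 * rng.standard_normal(t.size)  # sensor noise floor
    return x


# ---------------------------------------------------------------------------
# sessions and cohorts

def _windowed_edge_z(latents: np.ndarray, edge, spec: CouplingSpec) -> np.ndarray:
    """Windowed Fisher z of the edge's latent pair on the trimmed grid."""
    from .coupling import sliding_fc

    a, b = edge
    trimmed = latents[spec.n_discard :, :]
    grid = window_grid(trimmed.shape[0], spec.tr_s)
    wfc = sliding_fc(trimmed[:, a - 1], trimmed[:, b - 1], grid)
    return np.asarray(wfc.values)


def simulate_session(
    atlas: NetworkAtlas,
    spec: CouplingSpec,
    condition: str,
    seed: int | np.random.SeedSequence = 0,
    edge_adjust: dict[tuple[int, int], float] | None = None,
    hr_baseline_bpm: float | None = None,
    hr_delta_bpm: float | None = None,
    include_image: bool = True,
) -> SessionBundle:
    """Simulate one scanning session for one subject.

    Rest sessions produce an image and motion table; intervention sessions
    ("gratitude"/"resentment") additionally produce a PPG trace whose
    windowed HR is coupled (strength ``spec.sync_rho``, during
    ``spec.sync_condition`` only) to the windowed FC of ``spec.sync_edge``.
    ``include_image=False`` skips voxel-data synthesis for physiology-only
    studies. Deterministic given the seed.
    """
    k = atlas.n_networks
    a, b = spec.sync_edge
    if condition == spec.sync_condition and (a > k or b > k):
        raise ValueError(f"sync_edge {spec.sync_edge} absent from a {k}-network atlas")
    rng = np.random.default_rng(seed)
    n, tr = spec.n_volumes, spec.tr_s
    min_vols = int(round(60.0 / tr))  # one analysis window
    if n - spec.n_discard < min_vols:
        raise ValueError("session shorter than one analysis window")

    target = _target_corr_matrix(k, spec, condition, edge_adjust)
    sources = np.column_stack([_band_limited_source(n, tr, rng) for _ in range(k)])
    chol = np.linalg.cholesky(target)
    latents = sources @ chol.T  # (n, K)
    realized = np.corrcoef(latents.T)

    truth = SessionTruth(
        condition=condition,
        latents=latents,
        target_corr=target,
        realized_corr=realized,
    )

    ppg = None
    if condition in INTERVENTIONS:
        base = spec.hr_baseline_bpm if hr_baseline_bpm is None else hr_baseline_bpm
        delta = (
            spec.hr_condition_delta_bpm if hr_delta_bpm is None else hr_delta_bpm
        ) if condition == spec.hr_delta_condition else 0.0
        mean_hr = float(np.clip(base + delta, 35.0, 190.0))
        window_z = _windowed_edge_z(latents, spec.sync_edge, spec)
        rho = spec.sync_rho if condition == spec.sync_condition else 0.0
        grid = window_grid(n - spec.n_discard, tr)
        pre_s = spec.n_discard * tr
        beats_s, h = _synthesize_hr(
            window_z, spec, rho, mean_hr,
            step_s=grid.step_s, window_s=grid.window_s, pre_s=pre_s,
            total_analysis_s=(n - spec.n_discard) * tr, rng=rng,
        )
        ppg_samples = _render_ppg(beats_s + pre_s, n * tr, spec.ppg_rate_hz, rng)
        ppg = PPGTrace(samples=ppg_samples, rate_hz=spec.ppg_rate_hz, start_time_s=-pre_s)
        truth.window_fc_z = window_z
        truth.window_hr_target_bpm = h
        truth.beat_times_ms = (beats_s + pre_s) * 1000.0
        ibi_s = np.diff(beats_s)
        hr_inst = 60.0 / ibi_s
        mid_s = (beats_s[:-1] + beats_s[1:]) / 2.0
        realized = np.array(
            [
                hr_inst[(mid_s >= s0) & (mid_s < s0 + grid.window_s)].mean()
                for s0 in grid.window_starts_s
            ]
        )
        truth.window_hr_bpm = realized
        truth.mean_hr_bpm = float(hr_inst.mean())
        truth.sync_r = float(np.corrcoef(realized, window_z)[0, 1])

    # motion: six small-amplitude smooth random walks
    motion = np.cumsum(0.02 * rng.standard_normal((n, 6)), axis=0)
    motion_df = pd.DataFrame(
        motion, columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    )

    image = None
    if include_image:
        data = np.zeros(atlas.grid_shape + (n,))
        wm_sig = np.cumsum(0.05 * rng.standard_normal(n))
        csf_sig = np.cumsum(0.05 * rng.standard_normal(n))
        leak = spec.confound_leak * (wm_sig + csf_sig + motion[:, 0])
        for j in range(1, k + 1):
            mask = atlas.network_mask(j)
            nv = int(mask.sum())
            loadings = np.clip(rng.normal(1.0, 0.1, size=nv), 0.2, None)
            sig = loadings[:, None] * latents[:, j - 1][None, :] + leak[None, :]
            data[mask] = sig
        data[atlas.wm_mask] = wm_sig + 0.1 * rng.standard_normal(
            (int(atlas.wm_mask.sum()), n)
        )
        data[atlas.csf_mask] = csf_sig + 0.1 * rng.standard_normal(
            (int(atlas.csf_mask.sum()), n)
        )
        if spec.noise_sd > 0:
            data += spec.noise_sd * rng.standard_normal(data.shape)
        image = TimeSeriesImage(data=data, tr_s=tr, affine=atlas.affine)

    return SessionBundle(
        condition=condition, image=image, motion=motion_df, ppg=ppg, truth=truth
    )


_HADS_SCORES = ("hads_anxiety", "hads_depression")
_SDT_SCORES = ("sdt_autonomy", "sdt_competence", "sdt_relatedness")


def _draw_behaviors(n_subjects: int, rng: np.random.Generator) -> pd.DataFrame:
    """HADS subscales as integers 0-21, SDT subscales continuous (1-7)."""
    rows = {"subject_id": [f"sub-{i + 1:02d}" for i in range(n_subjects)]}
    for name in _HADS_SCORES:
        raw = np.round(rng.normal(8.0, 4.0, size=n_subjects))
        rows[name] = np.clip(raw, 0, 21).astype(int)
    for name in _SDT_SCORES:
        rows[name] = np.clip(rng.normal(4.5, 1.0, size=n_subjects), 1.0, 7.0)
    return pd.DataFrame(rows)


def simulate_cohort(
    n_subjects: int,
    spec: CouplingSpec | None = None,
    atlas: NetworkAtlas | None = None,
    design: str = "counterbalanced",
    seed: int | None = None,
    include_images: bool = True,
    conditions: list[str] | None = None,
) -> CohortDataset:
    """Simulate a full counterbalanced cohort.

    Subjects alternate between the two session orders (set I: gratitude
    first; set II: resentment first). Per-subject seeds derive
    deterministically from the master seed; behavioural scores are drawn
    first and linked to their target edges via ``spec.behavior_effects``.
    ``conditions`` restricts simulation to a subset of the five sessions
    (seed derivation is unchanged, so the generated sessions are identical
    to the corresponding sessions of the full cohort).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if design != "counterbalanced":
        raise ValueError(f"unknown design {design!r}")
    spec = spec or CouplingSpec()
    atlas = atlas or make_network_atlas(seed=spec.random_seed)
    master = spec.random_seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    rng = np.random.default_rng(ss.spawn(1)[0])
    behaviors = _draw_behaviors(n_subjects, rng)

    # behaviour-linked edge deviations, per subject
    edge_adjusts: list[dict[tuple[int, int], float]] = [dict() for _ in range(n_subjects)]
    for score_name, eff in spec.behavior_effects.items():
        s = behaviors[score_name].to_numpy(dtype=float)
        sd = s.std()
        z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
        dev = eff.slope * z + eff.noise_sd * rng.standard_normal(n_subjects)
        for i in range(n_subjects):
            edge = tuple(sorted(eff.edge))
            edge_adjusts[i][edge] = edge_adjusts[i].get(edge, 0.0) + dev[i]

    subject_seeds = ss.spawn(n_subjects)
    subjects = []
    for i in range(n_subjects):
        order_set = "I" if i % 2 == 0 else "II"
        srng = np.random.default_rng(subject_seeds[i])
        hr_base = spec.hr_baseline_bpm + spec.hr_subject_sd_bpm * srng.standard_normal()
        hr_delta = spec.hr_condition_delta_bpm + spec.hr_delta_sd_bpm * srng.standard_normal()
        session_seeds = subject_seeds[i].spawn(len(SESSION_ORDERS[order_set]))
        sessions = {}
        for j, condition in enumerate(SESSION_ORDERS[order_set]):
            if conditions is not None and condition not in conditions:
                continue
            sessions[condition] = simulate_session(
                atlas,
                spec,
                condition,
                seed=session_seeds[j],
                edge_adjust=edge_adjusts[i],
                hr_baseline_bpm=hr_base,
                hr_delta_bpm=hr_delta,
                include_image=include_images,
            )
        subjects.append(
            SubjectData(
                subject_id=behaviors["subject_id"].iloc[i],
                order_set=order_set,
                sessions=sessions,
                hr_baseline_bpm=float(hr_base),
                hr_delta_bpm=float(hr_delta),
            )
        )
    return CohortDataset(atlas=atlas, spec=spec, subjects=subjects, behaviors=behaviors)


# ---------------------------------------------------------------------------
# on-disk representation

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _save_nifti(path: Path, data: np.ndarray, affine: np.ndarray) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def read_image(path: str | Path, tr_s: float = 2.0) -> TimeSeriesImage:
    """Load a 4D NIfTI back into a :class:`TimeSeriesImage`."""
    import nibabel as nib

    img = nib.load(str(path))
    return TimeSeriesImage(
        data=np.asarray(img.dataobj, dtype=float), tr_s=tr_s, affine=img.affine
    )


def write_dataset(
    dataset: CohortDataset, directory: str | Path, overwrite: bool = False
) -> dict:
    """Write the cohort to disk and return the checksummed manifest.

    Layout: NIfTI-1 images (RAS diagonal affine), 6-column TSV motion
    tables, single-column 50 Hz CSV PPG traces, TSV behaviours, NIfTI atlas
    labels and tissue masks, and ``manifest.json`` with per-file SHA-256
    checksums. Refuses a non-empty target directory unless ``overwrite``.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} is not empty; pass overwrite=True to replace it"
        )
    directory.mkdir(parents=True, exist_ok=True)
    atlas = dataset.atlas
    files: dict[str, str] = {}

    def record(path: Path) -> None:
        files[str(path.relative_to(directory))] = _sha256(path)

    _save_nifti(directory / "atlas_labels.nii", atlas.labels.astype(np.float64), atlas.affine)
    record(directory / "atlas_labels.nii")
    for name, mask in (("wm_mask.nii", atlas.wm_mask), ("csf_mask.nii", atlas.csf_mask)):
        _save_nifti(directory / name, mask.astype(np.float64), atlas.affine)
        record(directory / name)
    dataset.behaviors.to_csv(directory / "behaviors.tsv", sep="\t", index=False)
    record(directory / "behaviors.tsv")

    for subj in dataset.subjects:
        sdir = directory / subj.subject_id
        sdir.mkdir(exist_ok=True)
        for j, condition in enumerate(subj.session_order, start=1):
            bundle = subj.sessions[condition]
            stem = f"ses-{j}_{condition}"
            if bundle.image is not None:
                _save_nifti(sdir / f"{stem}_bold.nii", bundle.image.data, bundle.image.affine)
                record(sdir / f"{stem}_bold.nii")
            bundle.motion.to_csv(sdir / f"{stem}_motion.tsv", sep="\t", index=False)
            record(sdir / f"{stem}_motion.tsv")
            if bundle.ppg is not None:
                np.savetxt(sdir / f"{stem}_ppg.csv", bundle.ppg.samples, fmt="%.10g")
                record(sdir / f"{stem}_ppg.csv")

    manifest = {
        "n_subjects": dataset.n_subjects,
        "session_orders": {s.subject_id: s.order_set for s in dataset.subjects},
        "tr_s": dataset.spec.tr_s,
        "n_volumes": dataset.spec.n_volumes,
        "ppg_rate_hz": dataset.spec.ppg_rate_hz,
        "random_seed": dataset.spec.random_seed,
        "files": files,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    dataset.manifest = manifest
    return manifest


def atlas_network_series(img: TimeSeriesImage, atlas: NetworkAtlas) -> np.ndarray:
    """Mean time course per atlas network, as a (time, K) matrix."""
    return np.column_stack(
        [img.data[atlas.network_mask(k)].mean(axis=0) for k in range(1, atlas.n_networks + 1)]
    )
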