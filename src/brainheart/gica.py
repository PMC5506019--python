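"""Temporal-concatenation group ICA (TC-GICA) and inter-network connectivity.

The decomposition follows the standard three-step recipe for resting-state
group ICA: (1) each subject's concatenated sessions (750 volumes) are
reduced to 30 temporal principal components; (2) the 30-per-subject
components are stacked across subjects (e.g. 30 x 32 = 960 rows), reduced
to 20 group dimensions and whitened; (3) the whitened group data are
unmixed with extended infomax ICA into 20 spatial component maps, which
dual regression carries back to per-subject, per-session time courses
(spatial regression) and spatial maps (temporal regression). Template
matching selects the five components of interest (default mode,
temporolimbic, salience, and left/right frontoparietal analogues), whose
stage-1 time courses define the 5 x 5 inter-network Fisher-z connectivity
matrix per session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import kurtosis

from .preprocess import TimeSeriesImage
from .seedfc import fisher_z

__all__ = [
    "SubjectPCs",
    "ICDecomposition",
    "FCMatrix",
    "ConvergenceError",
    "subject_pca",
    "concatenate_pcs",
    "group_pca_whiten",
    "infomax_ica",
    "dual_regression",
    "match_templates",
    "internetwork_fc",
]


class ConvergenceError(RuntimeError):
    """ICA failed to converge within the iteration budget."""

    def __init__(self, msg: str, last_update: float):
        super().__init__(msg)
        self.last_update = last_update


@dataclass
class SubjectPCs:
    """First-level temporal PCA of one subject's concatenated sessions.

    ``components`` is (n_pcs, n_voxels): orthonormal principal directions of
    the voxel-space covariance (rows have unit norm, Gram = identity).
    """

    subject_id: str
    components: np.ndarray
    variance_explained: float


@dataclass
class ICDecomposition:
    """Group spatial maps plus per-subject dual-regression outputs."""

    group_maps: np.ndarray  # (n_components, n_voxels), unit variance each
    mixing: np.ndarray  # unmixing applied to whitened data, (k, k)
    subject_timecourses: dict = field(default_factory=dict)  # (subj, session) -> (t, k)
    subject_maps: dict = field(default_factory=dict)  # (subj, session) -> (k, v)
    matched: dict = field(default_factory=dict)  # template name -> component index
    matched_sign: dict = field(default_factory=dict)  # template name -> +-1
    n_iterations: int = 0
    low_kurtosis: np.ndarray | None = None  # near-Gaussian component flags

    @property
    def n_components(self) -> int:
        return self.group_maps.shape[0]


@dataclass
class FCMatrix:
    """Symmetric network-by-network Fisher-z connectivity for one session."""

    labels: list[str]
    z_values: np.ndarray
    session_label: str = ""

    def edge(self, a: str, b: str) -> float:
        return float(self.z_values[self.labels.index(a), self.labels.index(b)])

    def unique_edges(self) -> dict[tuple[str, str], float]:
        k = len(self.labels)
        return {
            (self.labels[i], self.labels[j]): float(self.z_values[i, j])
            for i in range(k)
            for j in range(i + 1, k)
        }


def _stack_sessions(sessions: list[TimeSeriesImage]) -> np.ndarray:
    """Concatenate sessions in time into a (total_t, n_voxels) matrix."""
    mats = [img.timeseries_2d() for img in sessions]
    vox = {m.shape[1] for m in mats}
    if len(vox) != 1:
        raise ValueError("sessions have mismatched voxel grids")
    return np.vstack(mats)


def subject_pca(
    sessions: list[TimeSeriesImage] | np.ndarray,
    n_pcs: int = 30,
    subject_id: str = "",
) -> SubjectPCs:
    """First-level temporal PCA: reduce the concatenated volumes to
    ``n_pcs`` components ordered by explained variance.

    Accepts either a list of preprocessed session images or a prebuilt
    (time, voxel) matrix.
    """
    x = sessions if isinstance(sessions, np.ndarray) else _stack_sessions(sessions)
    x = x - x.mean(axis=0)
    t, v = x.shape
    if n_pcs >= min(t, v) + 1:
        raise ValueError(f"n_pcs={n_pcs} too large for data of shape {(t, v)}")
    # economy SVD: rows of Vt are orthonormal voxel-space directions
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    explained = float(var[:n_pcs].sum() / var.sum())
    return SubjectPCs(
        subject_id=subject_id, components=vt[:n_pcs], variance_explained=explained
    )


def concatenate_pcs(all_subjects: list[SubjectPCs]) -> np.ndarray:
    """Stack every subject's components into one group matrix.

    With the study defaults (30 components x 32 subjects) this yields 960
    rows over the common voxel grid.
    """
    if not all_subjects:
        raise ValueError("no subjects to concatenate")
    shapes = {s.components.shape for s in all_subjects}
    if len({sh[0] for sh in shapes}) != 1 or len({sh[1] for sh in shapes}) != 1:
        raise ValueError(f"subjects have mismatched component dimensions: {shapes}")
    return np.vstack([s.components for s in all_subjects])


def group_pca_whiten(group_matrix: np.ndarray, n_dims: int = 20):
    """Second-level PCA to ``n_dims`` rows, whitened across voxels.

    Returns ``(whitened, unwhiten)`` where ``whitened`` (n_dims, n_voxels)
    has identity row covariance and ``unwhiten @ whitened`` reconstructs the
    input's projection onto the retained subspace.
    """
    g = np.asarray(group_matrix, dtype=float)
    g = g - g.mean(axis=1, keepdims=True)
    if n_dims > min(g.shape):
        raise ValueError(f"n_dims={n_dims} exceeds data rank bound {min(g.shape)}")
    u, s, vt = np.linalg.svd(g, full_matrices=False)
    tol = s[0] * max(g.shape) * np.finfo(float).eps
    if (s[:n_dims] <= tol).any():
        raise ValueError(
            f"covariance degenerate at {n_dims} dims (numerical rank "
            f"{int((s > tol).sum())})"
        )
    v = g.shape[1]
    whitened = np.sqrt(v) * vt[:n_dims]
    unwhiten = u[:, :n_dims] * (s[:n_dims] / np.sqrt(v))
    return whitened, unwhiten


def infomax_ica(
    whitened: np.ndarray,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    lrate: float | None = None,
    extended: bool = True,
    kurtosis_floor: float = 0.1,
) -> ICDecomposition:
    """Extended infomax ICA on whitened data (components x voxels).

    Natural-gradient updates W <- W + lr (I - K tanh(u) u^T/n - u u^T/n) W
    with per-component sign switching between super- and sub-Gaussian
    nonlinearities (K = +-1 re-estimated from the source kurtosis), an
    annealed learning rate, and convergence declared when the relative
    update norm falls below ``tol``. Indeterminacies are fixed by scaling
    each spatial map to unit variance and orienting it to nonnegative
    skewness; components whose excess kurtosis stays within
    ``kurtosis_floor`` of zero (near-Gaussian, hence non-identifiable) are
    flagged and a warning is emitted.
    """
    x = np.asarray(whitened, dtype=float)
    k, n = x.shape
    rng = np.random.default_rng(seed)
    w = np.linalg.qr(rng.standard_normal((k, k)))[0]
    if lrate is None:
        lrate = 0.01 / np.log(max(k, 2))
    signs = np.ones(k)
    identity = np.eye(k)
    last_norm = np.inf
    converged = False
    n_iter = 0
    prev_dw = None
    best_norm = np.inf
    best_iter = 0
    lrate_cap = 0.5
    for n_iter in range(1, max_iter + 1):
        u = w @ x
        if extended:
            signs = np.sign(kurtosis(u, axis=1, fisher=True) + 1e-12)
        g = np.tanh(u)
        grad = identity - (signs[:, None] * g) @ u.T / n - (u @ u.T) / n
        dw = lrate * grad @ w
        # angle-adaptive rate: grow while successive updates stay aligned
        # (slow drift along flat, near-Gaussian directions), shrink when they
        # reverse (oscillation around the fixed point)
        if prev_dw is not None:
            denom = np.linalg.norm(dw) * np.linalg.norm(prev_dw)
            cos = float(dw.ravel() @ prev_dw.ravel()) / denom if denom > 0 else 0.0
            if cos < 0.5:
                lrate *= 0.7
                dw = 0.7 * dw
            elif cos > 0.9 and lrate < lrate_cap:
                lrate *= 1.05
        prev_dw = dw
        w_new = w + dw
        last_norm = float(np.linalg.norm(dw) / np.linalg.norm(w))
        w = w_new
        if last_norm < tol:
            converged = True
            break
        # plateau annealing: orbiting a fixed point keeps the update norm
        # roughly constant; monotonically shrinking the rate ceiling shrinks
        # the orbit radius so the iterate genuinely approaches the fixed point
        if last_norm < best_norm:
            best_norm, best_iter = last_norm, n_iter
        elif n_iter - best_iter > 100:
            lrate_cap *= 0.8
            lrate = min(lrate, lrate_cap)
            best_iter = n_iter
    if not converged:
        raise ConvergenceError(
            f"infomax did not converge in {max_iter} iterations "
            f"(last relative update {last_norm:.2e})",
            last_update=last_norm,
        )
    maps = w @ x
    # fix scale and sign: unit-variance maps, nonnegative skewness
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    maps = maps / sd
    skew = ((maps - maps.mean(axis=1, keepdims=True)) ** 3).mean(axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    maps = maps * flip[:, None]
    w = (flip[:, None] / sd) * w
    kurt = kurtosis(maps, axis=1, fisher=True)
    low_kurt = np.abs(kurt) < kurtosis_floor
    if low_kurt.any():
        warnings.warn(
            f"{int(low_kurt.sum())} component(s) are near-Gaussian "
            "(|excess kurtosis| below floor); their separation is not identifiable",
            RuntimeWarning,
            stacklevel=2,
        )
    return ICDecomposition(
        group_maps=maps, mixing=w, n_iterations=n_iter, low_kurtosis=low_kurt
    )


def dual_regression(
    session: TimeSeriesImage | np.ndarray, group_maps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage least squares from group maps to subject time courses/maps.

    Stage 1 regresses each volume on the variance-normalized spatial maps
    (across voxels) to obtain per-component time courses; stage 2 regresses
    each voxel's series on those (un-normalized) time courses to obtain the
    subject's spatial maps. Returns ``(timecourses (t, k), maps (k, v))``.
    """
    x = session.timeseries_2d() if isinstance(session, TimeSeriesImage) else np.asarray(session, dtype=float)
    m = np.asarray(group_maps, dtype=float)
    if m.shape[1] != x.shape[1]:
        raise ValueError("group maps and session have mismatched voxel counts")
    sd = m.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant group map")
    m_norm = m / sd
    if np.linalg.matrix_rank(m_norm) < m_norm.shape[0]:
        raise ValueError("rank-deficient group maps")
    # stage 1: spatial regression, design = maps over voxels
    tc, *_ = np.linalg.lstsq(m_norm.T, x.T, rcond=None)  # (k, t)
    tc = tc.T
    # stage 2: temporal regression, design = stage-1 time courses
    smaps, *_ = np.linalg.lstsq(tc, x, rcond=None)  # (k, v)
    return tc, smaps


def match_templates(
    ic_maps: np.ndarray,
    templates: dict[str, np.ndarray],
    floor: float = 0.2,
) -> tuple[dict[str, int], dict[str, int], dict[str, float]]:
    """Injective assignment of templates to components maximizing total
    absolute spatial correlation (solved exactly by the Hungarian method).

    Returns ``(assignment, signs, correlations)`` keyed by template name;
    ``signs`` records a -1 where the best match is anticorrelated. Raises if
    any matched |correlation| falls below ``floor``.
    """
    maps = np.asarray(ic_maps, dtype=float)
    names = list(templates)
    t = np.vstack([np.asarray(templates[n], dtype=float).ravel() for n in names])
    if maps.shape[0] < len(names):
        raise ValueError("fewer components than templates")
    tz = (t - t.mean(axis=1, keepdims=True)) / t.std(axis=1, keepdims=True)
    mz = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
    corr = tz @ mz.T / t.shape[1]  # (n_templates, n_components)
    rows, cols = linear_sum_assignment(-np.abs(corr))
    assignment, signs, corrs = {}, {}, {}
    for r, c in zip(rows, cols):
        name = names[r]
        if abs(corr[r, c]) < floor:
            raise ValueError(
                f"network '{name}' unmatched: best |correlation| "
                f"{abs(corr[r, c]):.3f} below floor {floor}"
            )
        assignment[name] = int(c)
        signs[name] = 1 if corr[r, c] >= 0 else -1
        corrs[name] = float(abs(corr[r, c]))
    return assignment, signs, corrs


def internetwork_fc(
    timecourses: np.ndarray, labels: list[str], session_label: str = ""
) -> FCMatrix:
    """Pairwise Fisher-z connectivity among matched network time courses.

    ``timecourses`` is (t, k) with one column per network in ``labels``.
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    if tc.shape[1] != len(labels):
        raise ValueError("one label per time-course column required")
    sd = tc.std(axis=0)
    if (sd == 0).any():
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time course for network(s): {bad}")
    r = np.corrcoef(tc.T)
    z = fisher_z(r)
    np.fill_diagonal(z, np.nan)
    return FCMatrix(labels=list(labels), z_values=z, session_label=session_label)
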