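"""Group-level inference for connectivity maps and network edges.

Parametric tests (one-sample and paired t, one-way repeated-measures ANOVA,
covariate regression) are computed vectorized over targets (voxels or
network edges). Multiple-comparison control follows two routes: cluster-level
family-wise error by permutation of the maximum suprathreshold cluster size
(sign-flipping for one-sample designs, within-subject condition swaps for
paired designs, covariate shuffling for regressions), and Benjamini-Hochberg
FDR for small families such as the 10 network edges. Post-hoc pairwise
comparisons after a significant RM-ANOVA are Bonferroni-corrected over the
three condition pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "Cluster",
    "ClusterTable",
    "FDRResult",
    "one_sample_t",
    "paired_t",
    "rm_anova",
    "posthoc_pairwise",
    "regress_covariate",
    "cluster_inference",
    "label_clusters",
    "fdr_bh",
]


@dataclass
class StatResult:
    """Per-target statistic with degrees of freedom and uncorrected p."""

    stat_map: np.ndarray
    df: tuple
    p_map: np.ndarray
    contrast_label: str = ""
    flagged: np.ndarray | None = None  # zero-variance or otherwise untestable

    def __post_init__(self) -> None:
        self.stat_map = np.atleast_1d(np.asarray(self.stat_map, dtype=float))
        self.p_map = np.atleast_1d(np.asarray(self.p_map, dtype=float))
        if self.flagged is None:
            self.flagged = ~np.isfinite(self.stat_map)


@dataclass
class Cluster:
    peak_mm: tuple
    n_voxels: int
    peak_stat: float
    p_fwe: float


@dataclass
class ClusterTable:
    clusters: list[Cluster]
    cdt_p: float
    n_permutations: int
    connectivity_rule: int
    labels: np.ndarray | None = None  # 3D cluster-label volume

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_fwe < alpha]


@dataclass
class FDRResult:
    significant: np.ndarray
    p_adjusted: np.ndarray
    q: float


def _t_from_values(x: np.ndarray, null_mean: float = 0.0):
    """Vectorized one-sample t over axis 0; zero-variance columns -> NaN."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:  # (n_subjects,) -> single target
        x = x[:, None]
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    flagged = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean - null_mean) / (sd / np.sqrt(n))
    # zero variance: exactly at the null -> t = 0; off the null -> undefined
    t = np.where(flagged, np.where(mean == null_mean, 0.0, np.nan), t)
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    return t, p, n - 1, flagged


def one_sample_t(
    values: np.ndarray, null_mean: float = 0.0, contrast_label: str = ""
) -> StatResult:
    """One-sample t-test against ``null_mean``: t = (mean - mu) / (sd/sqrt(n)).

    ``values`` is (n_subjects,) or (n_subjects, n_targets); df = n - 1,
    two-tailed p. Zero-variance targets are flagged NaN.
    """
    t, p, df, flagged = _t_from_values(values, null_mean)
    return StatResult(stat_map=t, df=(df,), p_map=p, contrast_label=contrast_label, flagged=flagged)


def paired_t(
    values_a: np.ndarray, values_b: np.ndarray, contrast_label: str = ""
) -> StatResult:
    """Paired t-test: one-sample t on the per-subject differences a - b."""
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"mismatched subject sets: {a.shape} vs {b.shape}")
    return one_sample_t(
        np.asarray(values_a, dtype=float) - np.asarray(values_b, dtype=float),
        contrast_label=contrast_label,
    )


def rm_anova(values: np.ndarray, contrast_label: str = "") -> StatResult:
    """One-way within-subject (repeated-measures) ANOVA.

    ``values`` is (n_subjects, k_conditions) or (n_subjects, k, n_targets).
    The subject main effect is removed from the error term, so F is
    invariant to adding any constant to one subject's entire row.
    F df = (k - 1, (n - 1)(k - 1)); no sphericity correction by default.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
        squeeze = True
    else:
        squeeze = False
    if not np.isfinite(x).all():
        raise ValueError("missing cells in repeated-measures design")
    n, k, m = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    grand = x.mean(axis=(0, 1))
    cond_mean = x.mean(axis=0)  # (k, m)
    subj_mean = x.mean(axis=1)  # (n, m)
    ss_cond = n * ((cond_mean - grand) ** 2).sum(axis=0)
    ss_subj = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_total = ((x - grand) ** 2).sum(axis=(0, 1))
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_cond / df1) / (ss_err / df2)
    flagged = ss_err == 0
    f = np.where(flagged & (ss_cond == 0), 0.0, f)
    p = sps.f.sf(f, df1, df2)
    f_out = f[0] if squeeze else f
    p_out = p[0] if squeeze else p
    return StatResult(
        stat_map=f_out, df=(df1, df2), p_map=p_out, contrast_label=contrast_label,
        flagged=flagged if not squeeze else flagged[:1],
    )


_PAIRS = ((0, 1), (0, 2), (1, 2))


def posthoc_pairwise(values: np.ndarray) -> dict[tuple[int, int], StatResult]:
    """Bonferroni-corrected paired t-tests for all three condition pairs.

    Raw two-tailed p-values are multiplied by 3 and capped at 1.
    """
    x = np.asarray(values, dtype=float)
    if x.shape[1] != 3:
        raise ValueError("post-hoc pairwise comparisons expect 3 conditions")
    out = {}
    for i, j in _PAIRS:
        res = paired_t(x[:, i], x[:, j], contrast_label=f"cond{i}-cond{j}")
        res.p_map = np.minimum(res.p_map * 3.0, 1.0)
        out[(i, j)] = res
    return out


def regress_covariate(
    maps: np.ndarray, score: np.ndarray, contrast_label: str = ""
) -> StatResult:
    """Per-target OLS of map value on a behavioral score plus intercept.

    Returns the slope t-statistic with df = n - 2. Perfect fits produce
    infinite t (flagged); a constant score is an error.
    """
    y = np.atleast_2d(np.asarray(maps, dtype=float).T).T  # (n, m)
    if y.ndim == 1:
        y = y[:, None]
    s = np.asarray(score, dtype=float).ravel()
    n = s.size
    if y.shape[0] != n:
        raise ValueError("maps and score must have the same number of subjects")
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if s.std() == 0:
        raise ValueError("constant behavioral score")
    sc = s - s.mean()
    sxx = (sc**2).sum()
    slope = (y.T @ sc) / sxx
    fitted = np.outer(sc, slope) + y.mean(axis=0)
    sse = ((y - fitted) ** 2).sum(axis=0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sse / df / sxx)
        t = slope / se
    flagged = se == 0
    t = np.where(flagged, np.inf * np.sign(slope), t)
    p = 2.0 * sps.t.sf(np.abs(t), df=df)
    return StatResult(stat_map=t, df=(df,), p_map=p, contrast_label=contrast_label, flagged=flagged)


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)


def label_clusters(
    suprathreshold: np.ndarray, connectivity: int = 18
) -> tuple[np.ndarray, list[int]]:
    """Connected-component labelling of a 3D boolean mask.

    Returns the label volume and the size of each cluster (label i has size
    ``sizes[i-1]``), using the 6/18/26-neighbour rule requested.
    """
    mask = np.asarray(suprathreshold, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("expected a 3D mask")
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1)).astype(int)
    return labels, list(sizes)


def _stat_for_scheme(scheme, data, data_b, score, null_mean=0.0):
    if scheme == "sign_flip":
        t, p, df, _ = _t_from_values(data, null_mean)
        return t, p
    if scheme == "condition_swap":
        if data.ndim == 3:  # k-condition design: within-subject F test
            res = rm_anova(data)
            return res.stat_map, res.p_map
        t, p, df, _ = _t_from_values(data - data_b)
        return t, p
    if scheme == "score_permute":
        res = regress_covariate(data, score)
        return res.stat_map, res.p_map
    raise ValueError(f"unknown permutation scheme {scheme!r}")


def cluster_inference(
    data: np.ndarray,
    grid_shape: tuple[int, int, int],
    cdt_p: float = 0.001,
    n_perm: int = 999,
    scheme: str = "sign_flip",
    mask: np.ndarray | None = None,
    data_b: np.ndarray | None = None,
    score: np.ndarray | None = None,
    alpha: float = 0.05,
    connectivity: int = 18,
    seed: int | None = None,
    affine: np.ndarray | None = None,
) -> ClusterTable:
    """Permutation max-cluster-size FWE inference on a voxel grid.

    ``data`` is (n_subjects, n_voxels) over the in-mask voxels (or over the
    full flattened grid when ``mask`` is None). The observed statistic map is
    thresholded two-tailed at the cluster-defining threshold ``cdt_p``;
    positive and negative suprathreshold voxels are labelled separately. The
    null distribution of the maximum cluster size (over both signs) is built
    from ``n_perm`` permutations under the named exchangeability scheme:

    - ``sign_flip``: random per-subject sign flips (one-sample designs);
    - ``condition_swap``: random within-subject swaps of the two conditions
      (requires ``data_b``);
    - ``score_permute``: random shuffles of the covariate (requires
      ``score``).

    Each cluster's p_fwe = (1 + #{null max >= observed size}) / (n_perm + 1),
    which is never below 1/(n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    data = np.asarray(data, dtype=float)
    multi_condition = data.ndim == 3  # (n_subjects, k_conditions, n_voxels)
    if multi_condition and scheme != "condition_swap":
        raise ValueError("3D condition-stacked data requires scheme='condition_swap'")
    if scheme == "condition_swap" and not multi_condition:
        if data_b is None:
            raise ValueError("condition_swap requires data_b")
        data_b = np.asarray(data_b, dtype=float)
        if data_b.shape != data.shape:
            raise ValueError("data and data_b shapes differ")
    elif data_b is not None:
        raise ValueError(f"data_b is incompatible with scheme {scheme!r}")
    if scheme == "score_permute":
        if score is None:
            raise ValueError("score_permute requires score")
        score = np.asarray(score, dtype=float).ravel()
    elif score is not None:
        raise ValueError(f"score is incompatible with scheme {scheme!r}")

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != tuple(grid_shape):
            raise ValueError("mask shape must equal grid_shape")
    n_vox = int(mask.sum()) if mask is not None else int(np.prod(grid_shape))
    if data.shape[-1] != n_vox:
        raise ValueError("data columns must match the number of in-mask voxels")

    rng = np.random.default_rng(seed)
    n = data.shape[0]

    def stat_and_p(d, d_b=None, sc=None):
        return _stat_for_scheme(scheme, d, d_b, sc)

    def max_cluster_size(t, p):
        vol_p = np.full(grid_shape, 1.0)
        vol_t = np.zeros(grid_shape)
        if mask is not None:
            vol_p[mask] = p
            vol_t[mask] = t
        else:
            vol_p = p.reshape(grid_shape)
            vol_t = t.reshape(grid_shape)
        supra = (vol_p < cdt_p) & np.isfinite(vol_t)
        best = 0
        for sign_mask in (supra & (vol_t > 0), supra & (vol_t < 0)):
            if sign_mask.any():
                _, sizes = label_clusters(sign_mask, connectivity)
                if sizes:
                    best = max(best, max(sizes))
        return best

    t_obs, p_obs = stat_and_p(data, data_b, score)

    null_max = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        if scheme == "sign_flip":
            flips = rng.choice([-1.0, 1.0], size=n)[:, None]
            t_b, p_b = stat_and_p(data * flips)
        elif scheme == "condition_swap" and multi_condition:
            perm = np.stack([rng.permutation(data.shape[1]) for _ in range(n)])
            t_b, p_b = stat_and_p(data[np.arange(n)[:, None], perm, :])
        elif scheme == "condition_swap":
            swap = rng.random(n) < 0.5
            a_b = np.where(swap[:, None], data_b, data)
            b_b = np.where(swap[:, None], data, data_b)
            t_b, p_b = stat_and_p(a_b, b_b)
        else:
            t_b, p_b = stat_and_p(data, sc=rng.permutation(score))
        null_max[b] = max_cluster_size(t_b, p_b)

    # observed clusters, both signs, with peak coordinates in world mm
    vol_p = np.full(grid_shape, 1.0)
    vol_t = np.zeros(grid_shape)
    if mask is not None:
        vol_p[mask] = p_obs
        vol_t[mask] = t_obs
    else:
        vol_p = p_obs.reshape(grid_shape)
        vol_t = t_obs.reshape(grid_shape)
    supra = (vol_p < cdt_p) & np.isfinite(vol_t)
    aff = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    clusters: list[Cluster] = []
    label_vol = np.zeros(grid_shape, dtype=int)
    next_label = 1
    for sign in (1, -1):
        sign_mask = supra & ((vol_t > 0) if sign > 0 else (vol_t < 0))
        if not sign_mask.any():
            continue
        labels, sizes = label_clusters(sign_mask, connectivity)
        for lab, size in enumerate(sizes, start=1):
            members = labels == lab
            label_vol[members] = next_label
            next_label += 1
            tv = np.where(members, np.abs(vol_t), -np.inf)
            peak = np.unravel_index(np.argmax(tv), grid_shape)
            peak_mm = tuple((aff @ np.append(peak, 1.0))[:3])
            p_fwe = (1.0 + int((null_max >= size).sum())) / (n_perm + 1.0)
            clusters.append(
                Cluster(peak_mm=peak_mm, n_voxels=int(size),
                        peak_stat=float(vol_t[peak]), p_fwe=float(p_fwe))
            )
    clusters.sort(key=lambda c: c.n_voxels, reverse=True)
    return ClusterTable(
        clusters=clusters, cdt_p=cdt_p, n_permutations=n_perm,
        connectivity_rule=connectivity, labels=label_vol,
    )


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up FDR control over a family of tests."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return FDRResult(significant=reject, p_adjusted=p_adj, q=q)
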