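"""Mass-univariate voxel-wise regression of gray matter on linguistic scores.

The model at every voxel is ordinary least squares

    gm_v = b0 + b1 * score + b2 * sex + b3 * education + b4 * TIV + e,

with ``t = b1 / SE(b1)`` and, by default, a one-sided p-value for positive
associations (higher perplexity, larger volume).  Inference follows the
uncorrected-voxel-threshold + cluster-extent convention (p < 0.001, k >= 100)
with an optional Benjamini-Hochberg FDR pass, and ROI-restricted peak tests
on atlas masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .volume_io import ROIMask, VolumeImage, stack_cohort, voxel_to_world

__all__ = [
    "DesignMatrix",
    "GLMResult",
    "Cluster",
    "build_design",
    "default_mask",
    "fit_voxelwise",
    "threshold_and_cluster",
    "fdr_correct",
    "roi_analysis",
    "group_difference_tmap",
    "clusters_to_frame",
]

logger = logging.getLogger(__name__)

#: cluster connectivity -> scipy structuring-element rank
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class DesignMatrix:
    """Participants-by-regressors design with named columns.

    Column order is fixed: intercept, tested score, then covariates.  Rows
    are complete cases only; ``n_dropped`` records how many rows were lost.
    """

    matrix: np.ndarray
    columns: list[str]
    participant_ids: list[str]
    tested: str
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def tested_index(self) -> int:
        return self.columns.index(self.tested)


@dataclass
class GLMResult:
    """Voxel-wise OLS maps for one tested regressor.

    ``t`` and ``p`` are defined where ``mask`` is true and NaN elsewhere.
    ``p`` is one-sided (P[T_df >= t]) for ``direction='positive'``,
    one-sided for negative effects, or two-sided.
    """

    beta: np.ndarray  # (n_regressors, x, y, z)
    t: np.ndarray
    p: np.ndarray
    df: int
    mask: np.ndarray
    affine: np.ndarray
    columns: list[str]
    tested: str
    direction: str = "positive"
    sigma2: np.ndarray | None = None


@dataclass
class Cluster:
    """A connected suprathreshold component of the statistic map."""

    n_voxels: int
    peak_t: float
    peak_ijk: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    name: str | None = None


def _find_collinear(x: np.ndarray, columns: Sequence[str]) -> list[str]:
    bad = []
    for j in range(x.shape[1]):
        others = np.delete(x, j, axis=1)
        resid = x[:, j] - others @ np.linalg.lstsq(others, x[:, j], rcond=None)[0]
        denom = np.linalg.norm(x[:, j]) + 1e-300
        if np.linalg.norm(resid) / denom < 1e-8:
            bad.append(columns[j])
    return bad


def build_design(
    table: pd.DataFrame,
    scores: pd.DataFrame,
    tested: str = "pp_1g",
    covariates: Sequence[str] = ("sex", "education_years", "tiv_ml"),
) -> DesignMatrix:
    """Assemble the regression design from the cohort table and score table.

    Joins on ``participant_id``, keeps complete cases (logging the dropped
    count), and verifies full column rank, naming the collinear columns on
    failure.
    """
    merged = table.merge(scores, on="participant_id", how="inner")
    needed = [tested, *covariates]
    missing_cols = [c for c in needed if c not in merged.columns]
    if missing_cols:
        raise ValueError(f"missing design columns: {missing_cols}")
    complete = merged.dropna(subset=needed)
    n_dropped = len(merged) - len(complete)
    if n_dropped:
        logger.info("build_design: dropped %d incomplete rows", n_dropped)
    columns = ["intercept", tested, *covariates]
    x = np.column_stack(
        [np.ones(len(complete))] + [complete[c].to_numpy(dtype=float) for c in needed]
    )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _find_collinear(x, columns)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return DesignMatrix(
        matrix=x,
        columns=columns,
        participant_ids=list(complete["participant_id"].astype(str)),
        tested=tested,
        n_dropped=n_dropped,
    )


def default_mask(data4d: np.ndarray, fraction: float = 0.1) -> np.ndarray:
    """Implicit analysis mask: voxels whose cohort-mean intensity exceeds
    ``fraction`` times the global mean of the cohort-mean image."""
    mean_img = data4d.mean(axis=0)
    return mean_img > fraction * mean_img.mean()


def _p_from_t(t: np.ndarray, df: int, direction: str) -> np.ndarray:
    if direction == "positive":
        return stats.t.sf(t, df)
    if direction == "negative":
        return stats.t.cdf(t, df)
    if direction == "two-sided":
        return 2.0 * stats.t.sf(np.abs(t), df)
    raise ValueError(f"unknown direction {direction!r}")


def fit_voxelwise(
    volumes: Sequence[VolumeImage],
    design: DesignMatrix,
    mask: np.ndarray | None = None,
    direction: str = "positive",
) -> GLMResult:
    """Ordinary least squares at every in-mask voxel.

    Voxels with exactly zero residual variance get t = +/-inf (sign of the
    tested beta; 0 for a zero beta) with the corresponding degenerate p, and
    a warning is logged.
    """
    x = design.matrix
    n, k = x.shape
    if len(volumes) != n:
        raise ValueError(f"{len(volumes)} volumes but {n} design rows")
    df = n - k
    if df < 1:
        raise ValueError(f"non-positive degrees of freedom (n={n}, k={k})")

    data = stack_cohort(volumes)
    shape = data.shape[1:]
    if mask is None:
        mask = default_mask(data)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match volume grid")

    y = data.reshape(n, -1)[:, mask.ravel()]  # n x v
    pinv = np.linalg.pinv(x)
    beta = pinv @ y  # k x v
    resid = y - x @ beta
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(x.T @ x)
    j = design.tested_index
    se = np.sqrt(sigma2 * xtx_inv[j, j])

    bj = beta[j]
    # voxels whose residual variance vanishes (up to float rounding of an
    # exact fit) get t = +/-inf, or 0 when the tested beta itself vanishes
    scale = np.sqrt((y**2).mean(axis=0))
    zero_resid = np.sqrt(sigma2) <= 1e-10 * scale
    zero_beta = np.abs(bj) <= 1e-10 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = bj / np.where(se > 0, se, 1.0)
    t = np.where(zero_resid & ~zero_beta, np.sign(bj) * np.inf, t)
    t = np.where(zero_resid & zero_beta, 0.0, t)
    n_degenerate = int(zero_resid.sum())
    if n_degenerate:
        logger.warning(
            "fit_voxelwise: %d voxels with zero residual variance", n_degenerate
        )
    finite = np.isfinite(t)
    p = np.empty_like(t)
    p[finite] = _p_from_t(t[finite], df, direction)
    p[~finite] = np.where(t[~finite] > 0, 0.0, 1.0)
    if direction == "two-sided":
        p[~finite] = 0.0

    def _grid(vals, fill=np.nan):
        out = np.full(shape, fill, dtype=float)
        out[mask] = vals
        return out

    beta_maps = np.stack([_grid(beta[i]) for i in range(k)], axis=0)
    return GLMResult(
        beta=beta_maps,
        t=_grid(t),
        p=_grid(p),
        df=df,
        mask=mask,
        affine=volumes[0].affine.copy(),
        columns=list(design.columns),
        tested=design.tested,
        direction=direction,
        sigma2=_grid(sigma2),
    )


def _peak_index(t_map: np.ndarray, component: np.ndarray) -> tuple[int, int, int]:
    """Lexicographically-first voxel attaining the component maximum."""
    vals = t_map[component]
    peak_val = vals.max()
    where = np.argwhere(component & (t_map == peak_val))
    return tuple(int(v) for v in where[0])


def threshold_and_cluster(
    result: GLMResult,
    p_voxel: float = 0.001,
    k_min: int = 100,
    connectivity: int = 18,
) -> list[Cluster]:
    """Cluster-extent inference on the voxel-wise p map.

    Suprathreshold voxels (p < ``p_voxel`` within the analysis mask) are
    partitioned into connected components under the given connectivity
    (6 face, 18 face+edge, 26 face+edge+corner); components with at least
    ``k_min`` voxels are returned sorted by peak t descending, ties broken
    by voxel count then lexicographic peak index.  An empty suprathreshold
    set yields an empty list.
    """
    if not (0 < p_voxel < 1):
        raise ValueError("p_voxel must be in (0, 1)")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    supra = result.mask & (np.nan_to_num(result.p, nan=1.0) < p_voxel)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n_comp = ndimage.label(supra, structure=structure)
    clusters = []
    for comp_id in range(1, n_comp + 1):
        comp = labels == comp_id
        size = int(comp.sum())
        if size < k_min:
            continue
        peak = _peak_index(result.t, comp)
        clusters.append(
            Cluster(
                n_voxels=size,
                peak_t=float(result.t[peak]),
                peak_ijk=peak,
                peak_mm=tuple(voxel_to_world(result.affine, peak)),
            )
        )
    clusters.sort(key=lambda c: (-c.peak_t, -c.n_voxels, c.peak_ijk))
    return clusters


def fdr_correct(p: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over a flat vector of p-values.

    Returns (rejected boolean mask, adjusted p-values); empty input gives
    empty output.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def roi_analysis(
    result: GLMResult,
    rois: Sequence[ROIMask],
    p_voxel: float = 0.001,
    k_min: int = 100,
    connectivity: int = 18,
) -> pd.DataFrame:
    """Peak statistics restricted to each anatomical mask.

    Per ROI: peak t over in-mask voxels, its world coordinate and one-sided
    p, the largest suprathreshold connected component within the ROI, and a
    significance flag ``significant = peak p < p_voxel``.
    """
    rows = []
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    for roi in rois:
        joint = roi.mask & result.mask
        if not joint.any():
            raise ValueError(f"ROI {roi.name!r} has no voxels inside the analysis mask")
        peak = _peak_index(np.where(joint, result.t, -np.inf), joint)
        supra = joint & (np.nan_to_num(result.p, nan=1.0) < p_voxel)
        labels, n_comp = ndimage.label(supra, structure=structure)
        max_extent = 0
        if n_comp:
            max_extent = int(np.bincount(labels.ravel())[1:].max())
        peak_mm = voxel_to_world(result.affine, peak)
        rows.append(
            {
                "roi": roi.name,
                "label": roi.label,
                "n_voxels": int(joint.sum()),
                "peak_t": float(result.t[peak]),
                "peak_p": float(result.p[peak]),
                "x_mm": peak_mm[0],
                "y_mm": peak_mm[1],
                "z_mm": peak_mm[2],
                "max_cluster_extent": max_extent,
                "significant": bool(result.p[peak] < p_voxel),
                "extent_ok": bool(max_extent >= k_min),
            }
        )
    return pd.DataFrame(rows)


def group_difference_tmap(
    volumes: Sequence[VolumeImage],
    groups: Sequence[str],
    covariates: pd.DataFrame | None = None,
    mask: np.ndarray | None = None,
) -> GLMResult:
    """Two-group voxel-wise t contrast via a GLM group indicator column.

    ``groups`` holds two distinct labels; the indicator is 1 for the
    lexicographically-first group so the sign convention is deterministic.
    Two-sided p-values are reported.
    """
    groups = np.asarray([str(g) for g in groups])
    uniq = sorted(set(groups))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    if min((groups == g).sum() for g in uniq) < 2:
        raise ValueError("each group needs n >= 2")
    indicator = (groups == uniq[0]).astype(float)
    cols = ["intercept", "group"]
    mats = [np.ones(len(groups)), indicator]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(c)
            mats.append(covariates[c].to_numpy(dtype=float))
    x = np.column_stack(mats)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(f"rank-deficient design; collinear columns: {_find_collinear(x, cols)}")
    design = DesignMatrix(
        matrix=x,
        columns=cols,
        participant_ids=[str(i) for i in range(len(groups))],
        tested="group",
    )
    return fit_voxelwise(volumes, design, mask=mask, direction="two-sided")


def clusters_to_frame(
    clusters: Sequence[Cluster],
    atlas: VolumeImage | None = None,
    label_map: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Tabulate clusters; optionally name each peak by its atlas label."""
    rows = []
    for c in clusters:
        name = c.name
        if name is None and atlas is not None:
            label = int(atlas.data[c.peak_ijk])
            if label_map is not None:
                name = label_map.get(label, "unlabelled" if label == 0 else str(label))
            else:
                name = "unlabelled" if label == 0 else str(label)
        rows.append(
            {
                "name": name or "unlabelled",
                "n_voxels": c.n_voxels,
                "peak_t": c.peak_t,
                "x_mm": c.peak_mm[0],
                "y_mm": c.peak_mm[1],
                "z_mm": c.peak_mm[2],
            }
        )
    return pd.DataFrame(
        rows, columns=["name", "n_voxels", "peak_t", "x_mm", "y_mm", "z_mm"]
    )
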