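"""PCA of group-mean condition x voxel activation, with biplot data.

Each voxel is a variable and each experimental condition an observation.
After per-voxel centering across conditions (no variance scaling — values
share PSC units), a singular value decomposition yields condition scores,
voxel coefficients, and percent variance explained. Biplot data groups the
voxel coefficient vectors by ROI subregion, with condition scores scaled
into the coefficient range for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "PCAResult",
    "compute_group_mean_maps",
    "condition_voxel_pca",
    "biplot_data",
    "plot_biplots",
]


@dataclass
class PCAResult:
    condition_scores: pd.DataFrame      # conditions x components
    voxel_coefficients: pd.DataFrame    # voxels x components
    variance_explained: np.ndarray      # percent, over all components


def compute_group_mean_maps(table: pd.DataFrame) -> pd.DataFrame:
    """Condition x voxel matrix of across-subject mean activation.

    ``table`` is long format with columns subject_id, condition, voxel_id,
    value. Every subject must provide every (condition, voxel) cell.
    """
    pivot = table.pivot_table(
        index="condition", columns="voxel_id", values="value", aggfunc="mean"
    )
    counts = table.pivot_table(
        index="condition", columns="voxel_id", values="value", aggfunc="count"
    )
    if pivot.isna().any().any() or counts.nunique().nunique() > 1 or (
        counts.to_numpy().min() != counts.to_numpy().max()
    ):
        raise ValueError("inconsistent voxel sets across subjects/conditions")
    return pivot


def condition_voxel_pca(matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """SVD of the column-centered condition x voxel matrix.

    Sign convention: each component is oriented so the condition with the
    largest |score| has a positive score, making outputs deterministic.
    """
    M = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix must be finite")
    n_cond = M.shape[0]
    if n_cond < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} observations for {n_components} components"
        )
    centered = M - M.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("matrix is constant across conditions; no variance to decompose")

    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    var_pct = 100.0 * var / var.sum()
    scores = u * s                      # conditions x components
    coeffs = vt.T                       # voxels x components (orthonormal)

    for j in range(min(n_components, scores.shape[1])):
        i_star = int(np.argmax(np.abs(scores[:, j])))
        if scores[i_star, j] < 0:
            scores[:, j] *= -1
            coeffs[:, j] *= -1

    k = min(n_components, scores.shape[1])
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        condition_scores=pd.DataFrame(scores[:, :k], index=matrix.index, columns=comp_names),
        voxel_coefficients=pd.DataFrame(coeffs[:, :k], index=matrix.columns, columns=comp_names),
        variance_explained=var_pct,
    )


def biplot_data(
    result: PCAResult,
    voxel_subregions: Mapping | pd.Series,
    score_scale: float = 0.8,
) -> dict:
    """Per-subregion biplot geometry in the PC1 x PC2 plane.

    Returns {subregion: {"points": conditions x 2 DataFrame of scaled
    condition scores, "vectors": voxels x 2 DataFrame of coefficients}},
    plus an ``"axis_range"`` entry shared by all subregions.
    """
    if result.condition_scores.shape[1] < 2:
        raise ValueError("biplots need at least 2 components")
    lut = pd.Series(voxel_subregions)
    missing = [v for v in result.voxel_coefficients.index if v not in lut.index]
    if missing:
        raise ValueError(f"voxels missing subregion labels: {missing[:5]} ...")

    coeffs = result.voxel_coefficients[["PC1", "PC2"]]
    scores = result.condition_scores[["PC1", "PC2"]]
    axis_range = float(np.abs(coeffs.to_numpy()).max())
    if axis_range == 0:
        axis_range = 1.0
    max_score = float(np.abs(scores.to_numpy()).max())
    scale = score_scale * axis_range / max_score if max_score > 0 else 1.0
    points = scores * scale

    out: dict = {"axis_range": axis_range}
    for sr in pd.unique(lut.loc[coeffs.index]):
        vox = [v for v in coeffs.index if lut[v] == sr]
        out[sr] = {"points": points.copy(), "vectors": coeffs.loc[vox]}
    return out


def plot_biplots(data: dict, path: Optional[str] = None):
    """Render the biplot panels (condition points, voxel vectors)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    subregions = [k for k in data if k != "axis_range"]
    r = data["axis_range"] * 1.1
    fig, axes = plt.subplots(1, len(subregions), figsize=(4 * len(subregions), 4),
                             squeeze=False)
    for ax, sr in zip(axes.ravel(), subregions):
        vec = data[sr]["vectors"]
        pts = data[sr]["points"]
        for _, row in vec.iterrows():
            ax.annotate("", xy=(row["PC1"], row["PC2"]), xytext=(0, 0),
                        arrowprops=dict(arrowstyle="->", color="tab:blue", lw=0.8))
        ax.scatter(pts["PC1"], pts["PC2"], color="tab:orange", zorder=3)
        for cond, row in pts.iterrows():
            ax.annotate(str(cond), (row["PC1"], row["PC2"]), fontsize=8)
        ax.set_xlim(-r, r); ax.set_ylim(-r, r)
        ax.axhline(0, color="0.8", lw=0.5); ax.axvline(0, color="0.8", lw=0.5)
        ax.set_title(f"subregion {sr}")
        ax.set_xlabel("PC1"); ax.set_ylabel("PC2")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
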