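"""ROI machinery: probabilistic-map thresholding, equal-length partition
along the anterior-posterior axis, and centers of mass.

A probabilistic map holds, per voxel, the percentage of brains in which the
voxel belonged to the region. Thresholding at 30% (inclusive) produces a
binary mask, which is split into K subregions of equal spatial extent along
a world-coordinate axis (default the y axis, millimeters); labels are
numbered 1..K from anterior (larger y) to posterior.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "threshold_probmap",
    "split_equal_length",
    "centers_of_mass",
    "load_nifti",
    "save_nifti",
]


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI file, returning (data, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def threshold_probmap(prob_map: np.ndarray, threshold_pct: float = 30.0) -> np.ndarray:
    """Binary mask of voxels whose inclusion percentage is >= threshold.

    Voxels with zero inclusion are never part of the mask, so a threshold of
    0 returns the support of the map.
    """
    m = np.asarray(prob_map, dtype=float)
    if m.min() < 0 or m.max() > 100:
        raise ValueError("probabilistic map values must lie in [0, 100]")
    mask = (m >= threshold_pct) & (m > 0)
    if not mask.any():
        raise ValueError(f"thresholding at {threshold_pct}% leaves an empty mask")
    return mask


def _world_coords(idx: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map an (n, ndim) voxel-index array to world coordinates (mm)."""
    affine = np.asarray(affine, dtype=float)
    ndim = idx.shape[1]
    hom = np.column_stack([idx.astype(float), np.ones(len(idx))])
    return (hom @ affine[:ndim, list(range(ndim)) + [-1]].T)


def split_equal_length(
    mask: np.ndarray,
    affine: Optional[np.ndarray] = None,
    n_segments: int = 8,
    axis: int = 1,
) -> np.ndarray:
    """Partition a mask into equal-extent slabs along a world axis.

    The mask's world-coordinate extent along ``axis`` is divided into
    ``n_segments`` intervals of equal length; each voxel is labeled by the
    interval containing its coordinate. Intervals are half-open on the
    posterior side ([a, b) in ascending coordinate) with the final interval
    closed, and labels run 1 (anterior-most, largest coordinate) to
    ``n_segments`` (posterior-most). With ``affine=None``, voxel index
    space is used.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if affine is None:
        affine = np.eye(mask.ndim + 1)
    idx = np.column_stack(np.nonzero(mask))
    coords = _world_coords(idx, affine)[:, axis]
    cmin, cmax = coords.min(), coords.max()
    if cmax == cmin:
        raise ValueError("mask has zero extent along the chosen axis")
    if n_segments > len(np.unique(coords)):
        raise ValueError(
            f"{n_segments} segments exceed the {len(np.unique(coords))} distinct "
            "voxel coordinates along the axis"
        )
    seg_len = (cmax - cmin) / n_segments
    ascending_bin = np.minimum(
        ((coords - cmin) / seg_len).astype(int), n_segments - 1
    )
    labels_flat = n_segments - ascending_bin  # 1 = anterior-most (largest coord)
    labels = np.zeros(mask.shape, dtype=int)
    labels[tuple(idx.T)] = labels_flat
    return labels


def centers_of_mass(labels: np.ndarray, affine: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Unweighted mean world coordinate of each label's member voxels."""
    labels = np.asarray(labels)
    if affine is None:
        affine = np.eye(labels.ndim + 1)
    n = int(labels.max())
    if n < 1:
        raise ValueError("no labels present")
    coord_names = ["x", "y", "z"][: labels.ndim]
    rows = []
    for lab in range(1, n + 1):
        idx = np.column_stack(np.nonzero(labels == lab))
        if len(idx) == 0:
            raise ValueError(f"label {lab} is empty")
        com = _world_coords(idx, affine).mean(axis=0)
        rows.append({"label": lab, **dict(zip(coord_names, com))})
    return pd.DataFrame(rows)
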