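"""Anatomical axes and equal-volume sector rasterization.

The first axis is the rostrocaudal cutting direction (the slice axis of the
reconstructed volume).  The two in-plane axes are found by a principal
component analysis of the pooled 2D millimetre coordinates of all mask
voxels across slices — in real tissue these come out as the dominant
dorsolateral-to-ventromedial axis and its orthogonal.  Masked volumes are
then rasterized into ``k x k x k`` sectors of equal volume by splitting each
axis into k equal-count voxel bins (marginal quantiles), so every sector has
comparable support even inside an irregular lens-shaped mask; sector
intensity is the summed stained-pixel count of its voxels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .grid_io import IntensityVolume, SectorGrid


@dataclasses.dataclass
class AxisFrame:
    """Orthonormal in-plane PCA axes plus the slice axis.

    ``pca_axes`` is a (2, 2) array of row vectors in in-plane mm
    coordinates; ``origin`` is the mask centroid in mm.
    """

    pca_axes: np.ndarray
    origin: np.ndarray
    axis_labels: tuple[str, str, str] = (
        "rostrocaudal", "in-plane principal", "in-plane orthogonal")

    def __post_init__(self) -> None:
        self.pca_axes = np.asarray(self.pca_axes, float)
        gram = self.pca_axes @ self.pca_axes.T
        if not np.allclose(gram, np.eye(2), atol=1e-8):
            raise ValueError("pca_axes must be orthonormal")


def _voxel_coords_mm(vol: IntensityVolume) -> np.ndarray:
    """(n, 3) mm coordinates of mask voxel centers; axis order (inplane0,
    inplane1, slice)."""
    idx = np.argwhere(vol.mask).astype(float)
    return idx * np.asarray(vol.spacing)


def compute_axes(vol: IntensityVolume) -> AxisFrame:
    """PCA of pooled in-plane mask coordinates.

    The component with the larger variance becomes the dominant in-plane
    axis.  Signs are fixed deterministically: each component is oriented so
    that its largest-magnitude loading is positive.
    """
    xyz = _voxel_coords_mm(vol)
    if len(np.unique(np.argwhere(vol.mask)[:, 2])) < 2:
        raise ValueError("mask must span at least two slices")
    inplane = xyz[:, :2]
    center = inplane.mean(axis=0)
    cov = np.cov((inplane - center).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 1e-12 * max(evals[1], 1.0):
        raise ValueError("degenerate (collinear) in-plane mask")
    axes = evecs[:, ::-1].T  # rows, dominant first
    for r in range(2):
        lead = np.argmax(np.abs(axes[r]))
        if axes[r, lead] < 0:
            axes[r] = -axes[r]
    origin = np.array([center[0], center[1], xyz[:, 2].mean()])
    return AxisFrame(pca_axes=axes, origin=origin)


def _raw_axis_coords(vol: IntensityVolume, frame: AxisFrame) -> np.ndarray:
    """Per mask voxel, coordinates along (rostrocaudal, pca1, pca2) in mm."""
    xyz = _voxel_coords_mm(vol)
    inplane = xyz[:, :2] - frame.origin[:2]
    c2 = inplane @ frame.pca_axes[0]
    c3 = inplane @ frame.pca_axes[1]
    return np.column_stack([xyz[:, 2], c2, c3])


def normalize_coordinates(vol: IntensityVolume, frame: AxisFrame) -> np.ndarray:
    """Min-max scale each axis coordinate to [0, 1] over mask voxels."""
    c = _raw_axis_coords(vol, frame)
    lo = c.min(axis=0)
    hi = c.max(axis=0)
    if hi[0] == lo[0]:
        raise ValueError("single-slice mask: rostrocaudal coordinate undefined")
    if (hi == lo).any():
        raise ValueError("degenerate axis: zero extent")
    return (c - lo) / (hi - lo)


def _equal_count_bins(values: np.ndarray, k: int) -> np.ndarray:
    """Split values into k rank-based bins whose sizes differ by at most 1."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    bins = np.empty(n, int)
    bins[order] = (np.arange(n) * k) // n
    return bins


def rasterize(vol: IntensityVolume, frame: AxisFrame, k: int) -> SectorGrid:
    """Rasterize a masked volume into ``k**3`` equal-volume sectors.

    Binning is nested: mask voxels are split into k equal-count rank bins
    along the first axis; within each slab, into k bins along the second;
    within each column, into k along the third.  Conditional quantiles keep
    every one of the k^3 sectors populated with (nearly) ``n/k**3`` voxels
    even on a convex lens-shaped mask, where *marginal* quantile bins would
    leave the corner intersections geometrically empty.  Sector intensity
    is the sum of its voxels' values (count-like, matching the NB error
    model); sector coordinates are the bin centers ``(b + 0.5) / k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_vox = int(vol.mask.sum())
    if n_vox < k ** 3:
        raise ValueError(f"mask has {n_vox} voxels, fewer than k^3 = {k ** 3}")
    c = _raw_axis_coords(vol, frame)
    vals = vol.data[vol.mask]
    bins = np.empty((n_vox, 3), int)
    bins[:, 0] = _equal_count_bins(c[:, 0], k)
    for b1 in range(k):
        slab = bins[:, 0] == b1
        bins[slab, 1] = _equal_count_bins(c[slab, 1], k)
        for b2 in range(k):
            col = slab & (bins[:, 1] == b2)
            bins[col, 2] = _equal_count_bins(c[col, 2], k)
    df = pd.DataFrame({"i": bins[:, 0], "j": bins[:, 1], "k": bins[:, 2],
                       "y": vals})
    agg = df.groupby(["i", "j", "k"], sort=True)["y"].sum().reset_index()
    for ax, xc in zip("ijk", ("x1", "x2", "x3")):
        agg[xc] = (agg[ax] + 0.5) / k
    agg["included"] = True
    return SectorGrid(vol.specimen_id, vol.marker, (k, k, k), agg)
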