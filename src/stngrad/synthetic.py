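"""Synthetic nucleus masks and negative-binomial intensity data.

The generator emulates the structure of the seven-specimen, twelve-marker
immunoreactivity study: for each (specimen, marker) it draws overdispersed
sector counts whose log-mean follows one of the four spatial models
(homogeneous / linear gradient / three subdivisions / sigmoidal gradient),
with a per-specimen intercept jitter standing in for the substantial
inter-individual staining variability seen in real tissue.  Every generating
parameter is recorded in a truth record so recovery can be scored exactly.

Counts are drawn as a gamma–Poisson mixture: ``rate ~ Gamma(alpha, mu/alpha)``
then ``y ~ Poisson(rate)``, giving mean ``mu`` and variance
``mu + mu**2/alpha`` (Poisson limit as ``alpha -> inf``).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid_io import MARKERS, IntensityVolume, SectorGrid
from .models import ModelParams, predict_mean


@dataclasses.dataclass
class MaskSpec:
    """Geometry of a synthetic lens/ellipsoid nucleus mask.

    ``semi_axes`` are half-extents in mm; ``spacing`` is the voxel size in mm
    (the third axis is the inter-slice direction); ``orientation`` is an
    in-plane rotation angle in radians applied to the first two axes.
    """

    kind: str = "ellipsoid"
    semi_axes: tuple[float, float, float] = (2.0, 1.2, 1.5)
    spacing: tuple[float, float, float] = (0.1, 0.1, 0.3)
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("ellipsoid", "lens"):
            raise ValueError(f"unknown mask kind {self.kind!r}")
        if any(a <= 0 for a in self.semi_axes) or any(s <= 0 for s in self.spacing):
            raise ValueError("semi-axes and spacing must be positive")


def make_lens_mask(spec: MaskSpec) -> IntensityVolume:
    """Rasterize the mask: a voxel belongs iff its center lies inside the
    (rotated) body.  The bounding grid leaves a 2-voxel margin per side.

    ``kind='lens'`` builds a biconvex lens (intersection of two spheres)
    with half-width ``semi_axes[0]`` and half-thickness ``semi_axes[2]``;
    ``kind='ellipsoid'`` the plain ellipsoid.
    """
    a, b, c = spec.semi_axes
    dx, dy, dz = spec.spacing
    margin = 2
    # odd counts center the grid on a voxel, keeping the mask flip-symmetric
    n = [2 * (int(np.ceil(e / s)) + margin) + 1
         for e, s in zip(spec.semi_axes, spec.spacing)]
    # voxel-center coordinates in mm, origin at the grid center
    ax = [(np.arange(ni) - (ni - 1) / 2.0) * si for ni, si in zip(n, (dx, dy, dz))]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    th = spec.orientation
    Xr = np.cos(th) * X + np.sin(th) * Y
    Yr = -np.sin(th) * X + np.cos(th) * Y
    if spec.kind == "ellipsoid":
        inside = (Xr / a) ** 2 + (Yr / b) ** 2 + (Z / c) ** 2 <= 1.0
    else:
        # lens: two spheres of radius R centered at +/-(R - c) on the z axis
        r = max(a, b)
        R = (r * r + c * c) / (2.0 * c)
        off = R - c
        inside = ((Xr ** 2 + (Yr * (r / b)) ** 2 + (Z - off) ** 2 <= R * R)
                  & (Xr ** 2 + (Yr * (r / b)) ** 2 + (Z + off) ** 2 <= R * R))
    if not inside.any():
        raise ValueError("mask parameters yield an empty mask")
    return IntensityVolume("synthetic", "mask", np.zeros(inside.shape),
                           inside, spec.spacing)


def simulate_intensities(params: ModelParams, coords: np.ndarray,
                         rng: np.random.Generator | int) -> np.ndarray:
    """Draw independent NB counts with mean ``mu(x)`` from the model.

    ``coords`` is (n, 3) normalized locations; returns an (n,) count array.
    Reproducible for a given seed or Generator.
    """
    if not params.alpha > 0:
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mu = predict_mean(params, np.asarray(coords, float))
    rate = rng.gamma(shape=params.alpha, scale=mu / params.alpha)
    return rng.poisson(rate).astype(float)


def sector_center_coords(shape: tuple[int, int, int]) -> pd.DataFrame:
    """Full-grid sector index/coordinate frame with bin-center coordinates."""
    n1, n2, n3 = shape
    i, j, k = np.meshgrid(np.arange(n1), np.arange(n2), np.arange(n3),
                          indexing="ij")
    return pd.DataFrame({
        "i": i.ravel(), "j": j.ravel(), "k": k.ravel(),
        "x1": (i.ravel() + 0.5) / n1,
        "x2": (j.ravel() + 0.5) / n2,
        "x3": (k.ravel() + 0.5) / n3,
    })


def _default_truth() -> dict[str, ModelParams]:
    """Per-marker generating models mirroring the study's across-specimen
    preferences: mostly linear gradients, three sigmoidal-gradient markers,
    with effect magnitudes in the 0.5–1.5 range and dispersion alpha = 10."""
    grad = {"CALR": (1.0, -0.8, 0.5), "FER": (0.6, 0.9, -0.7),
            "GABRA3": (-1.2, 0.5, 0.6), "GAD6567": (0.8, -1.0, 0.5),
            "SERT": (1.1, 0.7, -0.5), "SMI32": (-0.9, -0.6, 0.8),
            "TH": (0.7, 1.2, 0.5), "TRANSF": (0.5, -0.7, 1.0),
            "VGLUT1": (-0.6, 0.8, 0.9)}
    sigm = {"MBP": (1.2, -1.0, 12.0), "PARV": (-1.0, 1.3, 18.0),
            "SYN": (1.4, -0.8, 10.0)}
    truth: dict[str, ModelParams] = {}
    for m, (l1, l2, l3) in grad.items():
        truth[m] = ModelParams("B", lambda0=3.0, alpha=10.0,
                               lambda1=l1, lambda2=l2, lambda3=l3)
    for m, (l1, l2, kap) in sigm.items():
        truth[m] = ModelParams("D", lambda0=3.0, alpha=10.0,
                               lambda1=l1, lambda2=l2,
                               beta1=0.5, beta2=0.6,
                               tau1=0.35, tau2=0.65, kappa=kap)
    return truth


@dataclasses.dataclass
class StudyDesign:
    """Layout and ground truth of a simulated study."""

    n_specimens: int = 7
    markers: Sequence[str] = tuple(MARKERS)
    grid_shape: tuple[int, int, int] = (10, 10, 10)
    params: Mapping[str, ModelParams] | None = None
    specimen_intercept_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 1:
            raise ValueError("need at least one specimen")
        if self.specimen_intercept_sd < 0:
            raise ValueError("specimen_intercept_sd must be >= 0")
        if self.params is None:
            defaults = _default_truth()
            self.params = {m: defaults[m] for m in self.markers} \
                if set(self.markers) <= set(defaults) else {
                    m: ModelParams("A", lambda0=3.0, alpha=10.0)
                    for m in self.markers}


def generate_study(design: StudyDesign) -> tuple[list[SectorGrid], dict]:
    """Simulate all (specimen, marker) sector grids plus the truth record.

    The study seed expands into independent per-(specimen, marker)
    substreams, so any single grid can be regenerated without the others.
    Per-specimen intercept offsets are drawn once per specimen and shared
    across markers, mimicking globally lighter/darker staining.
    """
    root = np.random.SeedSequence(design.seed)
    spec_ids = [f"S{s + 1:02d}" for s in range(design.n_specimens)]
    offset_rng = np.random.default_rng(root.spawn(1)[0])
    offsets = offset_rng.normal(0.0, design.specimen_intercept_sd,
                                design.n_specimens)
    coords = sector_center_coords(design.grid_shape)
    grids: list[SectorGrid] = []
    truth: dict = {"seed": design.seed, "grid_shape": list(design.grid_shape),
                   "specimen_intercept_sd": design.specimen_intercept_sd,
                   "specimen_offsets": dict(zip(spec_ids, offsets.tolist())),
                   "markers": {}, "grids": {}}
    for marker in design.markers:
        base = design.params[marker]
        truth["markers"][marker] = {"model_id": base.model_id,
                                    **{f: getattr(base, f)
                                       for f in ("lambda0", "lambda1", "lambda2",
                                                 "lambda3", "beta1", "beta2",
                                                 "tau1", "tau2", "kappa", "alpha")
                                       if getattr(base, f) is not None}}
    for s, sid in enumerate(spec_ids):
        for marker in design.markers:
            base = design.params[marker]
            shifted = dataclasses.replace(base, lambda0=base.lambda0 + offsets[s])
            sub = np.random.SeedSequence(
                design.seed,
                spawn_key=(1 + s, zlib.crc32(marker.encode()) % (2 ** 31)))
            y = simulate_intensities(shifted, coords[["x1", "x2", "x3"]].to_numpy(),
                                     np.random.default_rng(sub))
            rec = coords.copy()
            rec["y"] = y
            rec["included"] = True
            grids.append(SectorGrid(sid, marker, design.grid_shape, rec))
            truth["grids"][f"{sid}/{marker}"] = {
                "lambda0": float(shifted.lambda0), "model_id": base.model_id}
    return grids, truth


def aggregate_sectors(grid: SectorGrid, k: int) -> SectorGrid:
    """Block-sum a fine sector grid into a coarse ``k x k x k`` grid.

    Emulates rasterizing the same tissue at a coarser scale: each coarse
    sector is the sum of an equal-size block of fine sectors, so its counts
    carry the aggregated mean and dispersion of the tissue it covers.  Every
    fine axis division must be divisible by k.
    """
    if any(s % k for s in grid.shape):
        raise ValueError(f"fine shape {grid.shape} not divisible by k={k}")
    rec = grid.records.copy()
    for ax, n in zip("ijk", grid.shape):
        rec[ax] = rec[ax] * k // n
    agg = rec.groupby(["i", "j", "k"], sort=True)["y"].sum().reset_index()
    for ax, xc in zip("ijk", ("x1", "x2", "x3")):
        agg[xc] = (agg[ax] + 0.5) / k
    agg["included"] = True
    return SectorGrid(grid.specimen_id, grid.marker, (k, k, k), agg)


def save_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def load_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
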