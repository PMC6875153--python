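"""Sector tables and intensity volumes: the package's I/O layer.

A :class:`SectorGrid` holds the rasterized immunoreactivity of one nucleus
for one protein marker: ``y`` counts indexed by ``(i, j, k)`` sector indices
with normalized axis coordinates ``x1..x3`` in [0, 1].  An
:class:`IntensityVolume` holds the voxel-level representation: a 3D
stained-pixel count field, a binary nucleus mask, and the (anisotropic)
voxel spacing in mm.

The canonical on-disk form of sector data is a UTF-8 CSV with header
``specimen,marker,i,j,k,x1,x2,x3,y,included`` and 0-based indices; volumes
are stored as NIfTI (spacing in the header) with TIFF-stack import for
per-section images.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SECTOR_COLUMNS = [
    "specimen", "marker", "i", "j", "k",
    "x1", "x2", "x3", "y", "included",
]

#: The twelve protein markers of the seven-specimen study.
MARKERS = [
    "CALR", "FER", "GABRA3", "GAD6567", "MBP", "PARV",
    "SERT", "SMI32", "SYN", "TH", "TRANSF", "VGLUT1",
]


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable layout."""


class IntegrityError(ValueError):
    """A table or grid violates a structural invariant (duplicates, negatives)."""


@dataclasses.dataclass
class SectorGrid:
    """Rasterized sector intensities for one (specimen, marker).

    Parameters
    ----------
    specimen_id, marker
        Labels identifying the nucleus and the stain.
    shape
        ``(n1, n2, n3)`` sector divisions per axis.
    records
        DataFrame with columns ``i, j, k, x1, x2, x3, y, included``.
    """

    specimen_id: str
    marker: str
    shape: tuple[int, int, int]
    records: pd.DataFrame

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        rec = self.records.reset_index(drop=True)
        if all(c in rec.columns for c in ("i", "j", "k", "y", "included")):
            rec = rec.astype({"i": int, "j": int, "k": int,
                              "x1": float, "x2": float, "x3": float,
                              "y": float, "included": bool})
        self.records = rec
        self.validate()

    def validate(self) -> None:
        r = self.records
        missing = [c for c in ("i", "j", "k", "x1", "x2", "x3", "y", "included")
                   if c not in r.columns]
        if missing:
            raise SchemaError(f"sector records missing column(s): {missing}")
        if any(s < 1 for s in self.shape):
            raise IntegrityError(f"non-positive grid shape {self.shape}")
        idx = r[["i", "j", "k"]].to_numpy()
        if idx.size and (idx.min() < 0 or (idx >= np.array(self.shape)).any()):
            raise IntegrityError("sector index outside grid shape")
        if r.duplicated(subset=["i", "j", "k"]).any():
            raise IntegrityError(
                f"duplicate (i,j,k) in grid {self.specimen_id}/{self.marker}")
        if (r["y"].to_numpy() < 0).any():
            raise IntegrityError("negative intensity y")
        for ax, xc in zip("ijk", ("x1", "x2", "x3")):
            # x must be monotone (non-decreasing) with the index along its axis
            sub = r[[ax, xc]].drop_duplicates().sort_values(ax)
            if not sub[xc].is_monotonic_increasing:
                raise IntegrityError(f"{xc} not monotone with index {ax}")

    @property
    def included(self) -> pd.DataFrame:
        """Records currently flagged for analysis."""
        return self.records[self.records["included"].astype(bool)]

    @property
    def n_included(self) -> int:
        return int(self.records["included"].astype(bool).sum())

    def coords(self, only_included: bool = True) -> np.ndarray:
        """(n, 3) array of normalized coordinates."""
        r = self.included if only_included else self.records
        return r[["x1", "x2", "x3"]].to_numpy(float)

    def intensities(self, only_included: bool = True) -> np.ndarray:
        r = self.included if only_included else self.records
        return r["y"].to_numpy(float)

    def with_included(self, flags: Sequence[bool]) -> "SectorGrid":
        rec = self.records.copy()
        rec["included"] = np.asarray(flags, bool)
        return SectorGrid(self.specimen_id, self.marker, self.shape, rec)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SectorGrid):
            return NotImplemented
        if (self.specimen_id, self.marker, self.shape) != (
                other.specimen_id, other.marker, other.shape):
            return False
        cols = ["i", "j", "k", "x1", "x2", "x3", "y", "included"]
        a = self.records[cols].sort_values(["i", "j", "k"]).reset_index(drop=True)
        b = other.records[cols].sort_values(["i", "j", "k"]).reset_index(drop=True)
        return a.equals(b)


@dataclasses.dataclass
class IntensityVolume:
    """Voxel-level stained-pixel counts with a binary nucleus mask.

    ``spacing`` is (in-plane mm, in-plane mm, inter-slice mm); axis 2 is the
    rostrocaudal (slice) axis.
    """

    specimen_id: str
    marker: str
    data: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.mask = np.asarray(self.mask, bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.data.ndim != 3 or self.data.shape != self.mask.shape:
            raise IntegrityError("data and mask must be 3D with equal shapes")
        if any(s <= 0 for s in self.spacing):
            raise IntegrityError(f"non-positive spacing {self.spacing}")
        if not self.mask.any():
            raise IntegrityError("empty mask")
        if (self.data < 0).any():
            raise IntegrityError("negative voxel intensity")


# ---------------------------------------------------------------------------
# sector tables

def read_sector_table(path: str | Path) -> list[SectorGrid]:
    """Read the canonical CSV sector table into one grid per (specimen, marker).

    Raises
    ------
    SchemaError
        If a required column is absent.
    IntegrityError
        If a (specimen, marker, i, j, k) combination repeats or y < 0.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SECTOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sector table missing column(s): {missing}")
    if df.duplicated(subset=["specimen", "marker", "i", "j", "k"]).any():
        raise IntegrityError("duplicate (specimen, marker, i, j, k) rows")
    if len(df) and (df["y"].to_numpy() < 0).any():
        raise IntegrityError("negative intensity y in table")
    grids = []
    for (spec, marker), sub in df.groupby(["specimen", "marker"], sort=True):
        shape = tuple(int(sub[ax].max()) + 1 for ax in "ijk")
        grids.append(SectorGrid(str(spec), str(marker), shape,
                                sub.drop(columns=["specimen", "marker"])))
    return grids


def write_sector_table(grids: Iterable[SectorGrid], path: str | Path) -> None:
    """Write grids to the canonical CSV with stable (specimen, marker, i, j, k) order."""
    frames = []
    for g in grids:
        rec = g.records.copy()
        rec.insert(0, "specimen", g.specimen_id)
        rec.insert(1, "marker", g.marker)
        frames.append(rec[SECTOR_COLUMNS])
    if frames:
        out = pd.concat(frames, ignore_index=True)
        out = out.sort_values(["specimen", "marker", "i", "j", "k"])
    else:
        out = pd.DataFrame(columns=SECTOR_COLUMNS)
    # %.17g keeps doubles bit-exact across the roundtrip
    out.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# volumes

def save_volume(vol: IntensityVolume, data_path: str | Path,
                mask_path: str | Path) -> None:
    """Save data and mask as NIfTI images, spacing in the affine/header."""
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float64), affine), str(data_path))
    nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), affine), str(mask_path))


def load_volume(data_path: str | Path, mask_path: str | Path,
                specimen_id: str = "", marker: str = "") -> IntensityVolume:
    import nibabel as nib

    img = nib.load(str(data_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return IntensityVolume(specimen_id, marker,
                           np.asarray(img.dataobj, float),
                           np.asarray(msk.dataobj) > 0, spacing)


def load_tiff_stack(paths: Sequence[str | Path], spacing: tuple[float, float, float],
                    specimen_id: str = "", marker: str = "",
                    mask: np.ndarray | None = None) -> IntensityVolume:
    """Assemble an IntensityVolume from per-section TIFF images (slice axis last)."""
    import tifffile

    slices = [tifffile.imread(str(p)) for p in paths]
    data = np.stack(slices, axis=-1).astype(float)
    if mask is None:
        mask = np.ones(data.shape, bool)
    return IntensityVolume(specimen_id, marker, data, mask, spacing)
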