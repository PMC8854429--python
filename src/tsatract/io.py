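"""Voxel-grid data model and on-disk I/O.

All volumes participating in one tract analysis live on a single voxel grid
(dims + affine); world coordinates are mm at voxel centres, indices are
0-based.  NIfTI-1 is the only volume format; gradient tables use the FSL
bvec/bval text dialect; cohorts are TSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VoxelGrid",
    "ScalarVolume",
    "VectorVolume",
    "ROIMask",
    "GradientTable",
    "CohortTable",
    "read_volume",
    "write_volume",
    "read_gradient_table",
    "read_cohort",
    "write_cohort",
]


class FormatError(ValueError):
    """File could not be interpreted in the expected format."""


class GridMismatchError(ValueError):
    """Volumes expected to share a grid do not."""


@dataclasses.dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice: integer dims plus a 4x4 voxel-index -> world-mm affine."""

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if any(d < 1 for d in dims):
            raise ValueError("all dims must be >= 1")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length of a voxel along each axis, in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        arr = np.asarray(idx, dtype=float)
        out = np.atleast_2d(arr) @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if arr.ndim == 1 else out

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        arr = np.asarray(xyz, dtype=float)
        out = np.atleast_2d(arr) @ inv[:3, :3].T + inv[:3, 3]
        return out[0] if arr.ndim == 1 else out

    def voxel_centres(self) -> np.ndarray:
        """(N, 3) world-mm coordinates of every voxel centre, C-order."""
        ii, jj, kk = np.meshgrid(*[np.arange(d) for d in self.dims], indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def matches(self, other: "VoxelGrid", tol: float = 1e-4) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=tol
        )

    @classmethod
    def isotropic(cls, dims, voxel_size_mm: float = 2.0) -> "VoxelGrid":
        aff = np.diag([voxel_size_mm] * 3 + [1.0])
        return cls(tuple(dims), aff)


def _check_same_grid(*grids: VoxelGrid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.matches(g):
            raise GridMismatchError("volumes do not share a common grid")


@dataclasses.dataclass
class ScalarVolume:
    """One scalar value per voxel (probability fields, counts, diffusivity maps)."""

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.dims:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid dims {self.grid.dims}"
            )

    def copy_with(self, data: np.ndarray) -> "ScalarVolume":
        return ScalarVolume(self.grid, data)


@dataclasses.dataclass
class VectorVolume:
    """One 3-vector per voxel; nonzero vectors are unit, the zero vector means
    'no orientation defined here'."""

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.dims + (3,):
            raise ValueError(
                f"data shape {self.data.shape} does not match grid dims {self.grid.dims} + (3,)"
            )
        norms = np.linalg.norm(self.data, axis=-1)
        nonzero = norms > 0
        if nonzero.any() and not np.allclose(norms[nonzero], 1.0, atol=1e-6):
            raise ValueError("nonzero orientation vectors must be unit norm")

    @property
    def support(self) -> np.ndarray:
        """Boolean mask of voxels with a defined orientation."""
        return np.linalg.norm(self.data, axis=-1) > 0


@dataclasses.dataclass
class ROIMask:
    grid: VoxelGrid
    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.dims:
            raise ValueError("mask shape does not match grid dims")
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} has no member voxels")


@dataclasses.dataclass
class GradientTable:
    """Diffusion gradient scheme: M unit orientations at a single shell b-value.

    b=0 entries from the acquisition are counted (``n_b0``) but excluded from
    ``bvecs``, since they carry no orientation.
    """

    bvecs: np.ndarray
    b_value: float
    n_b0: int = 0

    def __post_init__(self) -> None:
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValueError("bvecs must be (M, 3)")
        norms = np.linalg.norm(self.bvecs, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("gradient orientations must be unit norm")
        if self.b_value <= 0:
            raise ValueError("b_value must be positive")

    @property
    def n_gradients(self) -> int:
        return self.bvecs.shape[0]


@dataclasses.dataclass
class CohortTable:
    """Participant covariates: id, age (years), sex coded 1 = male, 2 = female."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"participant_id", "age", "sex"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if len(t) == 0:
            raise ValueError("cohort table is empty")
        if t["participant_id"].duplicated().any():
            dup = t.loc[t["participant_id"].duplicated(), "participant_id"].iloc[0]
            raise ValueError(f"duplicate participant_id: {dup!r}")
        if (t["age"] <= 0).any():
            row = int(np.flatnonzero(t["age"].to_numpy() <= 0)[0])
            raise ValueError(f"non-positive age at row {row}")
        bad = ~t["sex"].isin([1, 2])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"sex value outside {{1, 2}} at row {row}")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def participant_ids(self) -> list[str]:
        return [str(p) for p in self.table["participant_id"]]

    @property
    def ages(self) -> np.ndarray:
        return self.table["age"].to_numpy(dtype=float)

    @property
    def sexes(self) -> np.ndarray:
        return self.table["sex"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers / writers


def read_volume(path, expect_vector: bool = False):
    """Read a NIfTI-1 volume as a ScalarVolume, or a VectorVolume when
    ``expect_vector`` is set (4D file with trailing dimension 3, the FSL dyads
    convention)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=float)
    grid = VoxelGrid(tuple(int(d) for d in data.shape[:3]), np.asarray(img.affine))
    if expect_vector:
        if data.ndim != 4 or data.shape[3] != 3:
            raise FormatError(
                f"{path}: expected a 4D volume with last dimension 3, got shape {data.shape}"
            )
        return VectorVolume(grid, data)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D scalar volume, got shape {data.shape}")
    return ScalarVolume(grid, data)


def write_volume(vol, path) -> None:
    """Write a Scalar/Vector volume (or raw ndarray + grid pair) to NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.data), vol.grid.affine)
    nib.save(img, str(path))


def read_gradient_table(bvec_path, bval_path) -> GradientTable:
    """Read FSL-style bvec (3 x M) and bval (1 x M) files.

    b=0 columns are dropped from the orientation set and counted separately;
    surviving orientations are renormalised to unit length.
    """
    bvecs = np.atleast_2d(np.loadtxt(bvec_path))
    bvals = np.atleast_1d(np.loadtxt(bval_path)).ravel()
    if bvecs.shape[0] != 3:
        raise FormatError(f"{bvec_path}: expected 3 rows, got {bvecs.shape[0]}")
    if bvecs.shape[1] != bvals.size:
        raise FormatError(
            f"bvec has {bvecs.shape[1]} columns but bval has {bvals.size} entries"
        )
    nonzero = bvals > 0
    n_b0 = int((~nonzero).sum())
    shells = np.unique(bvals[nonzero])
    if shells.size == 0:
        raise FormatError("gradient table contains no diffusion-weighted volumes")
    if shells.size > 1:
        raise FormatError(f"multiple nonzero b-values found: {shells}; single shell required")
    vecs = bvecs[:, nonzero].T
    norms = np.linalg.norm(vecs, axis=1)
    if (norms == 0).any():
        raise FormatError("zero-length orientation at nonzero b-value")
    vecs = vecs / norms[:, None]
    return GradientTable(vecs, float(shells[0]), n_b0=n_b0)


def read_cohort(path) -> CohortTable:
    """Read a TSV cohort table with participant_id, age and sex columns."""
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"cohort file {path} is empty") from exc
    return CohortTable(table)


def write_cohort(cohort: CohortTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(path, sep="\t", index=False)
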