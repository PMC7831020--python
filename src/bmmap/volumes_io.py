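"""Template-space volume I/O and grid bookkeeping.

All cohort volumes (lesion masks, atlases, statistical maps) live on one shared
grid, mirroring analyses performed after registration to a common brain
template.  :class:`GridSpec` carries the grid geometry, including the volume of
a single voxel used to convert voxel counts to mm^3.  Volumes are exchanged as
NIfTI-1 files via nibabel; region metadata travels in a tab-separated sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: Default volume of a single voxel in mm^3 used for lesion/region volumes.
DEFAULT_VOXEL_VOLUME = 0.08

LATERALITIES = ("left", "right", "midline")
COMPARTMENTS = ("supratentorial", "infratentorial")


class GridMismatchError(ValueError):
    """Raised when a volume does not live on the expected template grid."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the shared template grid.

    Parameters
    ----------
    shape
        Voxels per axis (i, j, k).
    voxel_volume
        Volume of a single voxel in mm^3.  Defaults to 0.08 mm^3.
    affine
        4x4 voxel-to-world transform.  Identity for toy grids.
    """

    shape: tuple[int, int, int]
    voxel_volume: float = DEFAULT_VOXEL_VOLUME
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be a positive integer triple, got {shape}")
        if not self.voxel_volume > 0:
            raise ValueError(f"voxel_volume must be > 0, got {self.voxel_volume}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        object.__setattr__(self, "affine", affine)

    def matches(self, other: "GridSpec", *, atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_match(self, other: "GridSpec") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"grid mismatch: shape {self.shape} vs {other.shape} "
                "(or differing affines)"
            )

    def voxel_to_world(self, coords: np.ndarray) -> np.ndarray:
        """Map voxel-index coordinates (…, 3) to world space via the affine."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        homog = np.c_[coords, np.ones(len(coords))]
        out = homog @ self.affine.T
        return np.squeeze(out[:, :3])


@dataclass(frozen=True)
class LesionMask:
    """One patient's binary lesion mask on the shared grid."""

    grid: GridSpec
    data: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {data.shape} does not match grid {self.grid.shape}"
            )
        data = (data > 0).astype(np.uint8)
        object.__setattr__(self, "data", data)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class Region:
    """Metadata for one atlas region."""

    region_id: int
    name: str
    laterality: str
    compartment: str
    volume: float = 0.0

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}")
        if self.region_id <= 0:
            raise ValueError("region_id must be positive (0 is background)")


@dataclass(frozen=True)
class RegionAtlas:
    """Integer-labeled parcellation (0 = background) with region metadata.

    Per-region volumes are derived from the label image: voxel count times
    ``grid.voxel_volume``.  Metadata volumes passed in are overwritten so the
    invariant always holds.
    """

    grid: GridSpec
    labels: np.ndarray
    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise GridMismatchError(
                f"label shape {labels.shape} does not match grid {self.grid.shape}"
            )
        labels = labels.astype(np.int32)
        object.__setattr__(self, "labels", labels)
        if len(self.regions) < 1:
            raise ValueError("atlas must define at least one region")
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region_id in atlas metadata")
        present = set(np.unique(labels)) - {0}
        missing = present - set(ids)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no region metadata")
        # recompute volumes from the label image
        counts = {rid: int((labels == rid).sum()) for rid in ids}
        regions = tuple(
            Region(
                region_id=r.region_id,
                name=r.name,
                laterality=r.laterality,
                compartment=r.compartment,
                volume=counts[r.region_id] * self.grid.voxel_volume,
            )
            for r in self.regions
        )
        object.__setattr__(self, "regions", regions)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0

    def region(self, region_id: int) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(f"unknown region_id {region_id}")

    def compartment_mask(self, compartment: str) -> np.ndarray:
        """Boolean mask of all voxels belonging to regions of a compartment."""
        ids = [r.region_id for r in self.regions if r.compartment == compartment]
        return np.isin(self.labels, ids)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _grid_from_nifti(img: nib.Nifti1Image, voxel_volume: float) -> GridSpec:
    return GridSpec(
        shape=tuple(int(s) for s in img.shape[:3]),
        voxel_volume=voxel_volume,
        affine=np.asarray(img.affine, dtype=float),
    )


def read_mask(
    path: str | Path,
    expected_grid: GridSpec | None = None,
    *,
    patient_id: str = "",
    voxel_volume: float = DEFAULT_VOXEL_VOLUME,
) -> LesionMask:
    """Read a binary lesion mask from a NIfTI file.

    Values are binarized at > 0.  If ``expected_grid`` is given, the file's
    grid must match (shape and affine), otherwise :class:`GridMismatchError`
    is raised naming both shapes.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    grid = _grid_from_nifti(img, voxel_volume)
    if expected_grid is not None:
        expected_grid.require_match(grid)
        grid = expected_grid
    if not patient_id:
        patient_id = Path(path).name.split(".")[0]
    return LesionMask(grid=grid, data=data, patient_id=patient_id)


def write_map(volume: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    """Write a scalar map (frequency, p-value, direction, …) as NIfTI."""
    volume = np.asarray(volume)
    if volume.shape != grid.shape:
        raise GridMismatchError(
            f"volume shape {volume.shape} does not match grid {grid.shape}"
        )
    img = nib.Nifti1Image(volume.astype(np.float32), grid.affine)
    nib.save(img, str(path))


def read_map(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read back a scalar map written by :func:`write_map`."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), _grid_from_nifti(
        img, DEFAULT_VOXEL_VOLUME
    )


def write_atlas(atlas: RegionAtlas, nifti_path: str | Path, meta_path: str | Path) -> None:
    """Write an atlas: label image as NIfTI plus a TSV region-metadata sidecar."""
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.grid.affine)
    nib.save(img, str(nifti_path))
    region_metadata_table(atlas).to_csv(meta_path, sep="\t", index=False)


def read_atlas(
    nifti_path: str | Path,
    meta_path: str | Path,
    *,
    voxel_volume: float = DEFAULT_VOXEL_VOLUME,
    expected_grid: GridSpec | None = None,
) -> RegionAtlas:
    """Read an atlas from a NIfTI label image plus its TSV sidecar."""
    img = nib.load(str(nifti_path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    grid = _grid_from_nifti(img, voxel_volume)
    if expected_grid is not None:
        expected_grid.require_match(grid)
        grid = expected_grid
    meta = pd.read_csv(meta_path, sep="\t")
    regions = tuple(
        Region(
            region_id=int(row.region_id),
            name=str(row.name_) if hasattr(row, "name_") else str(row.name),
            laterality=str(row.laterality),
            compartment=str(row.compartment),
        )
        for row in meta.rename(columns={"name": "name_"}).itertuples(index=False)
    )
    return RegionAtlas(grid=grid, labels=labels, regions=regions)


def region_metadata_table(atlas: RegionAtlas) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in atlas.regions],
            "name": [r.name for r in atlas.regions],
            "laterality": [r.laterality for r in atlas.regions],
            "compartment": [r.compartment for r in atlas.regions],
        }
    )


def atlas_region_volumes(atlas: RegionAtlas) -> pd.DataFrame:
    """Per-region volume in mm^3 (label voxel count x voxel_volume)."""
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in atlas.regions],
            "volume_mm3": [r.volume for r in atlas.regions],
        }
    )


def validate_cohort_grids(
    masks: Sequence[LesionMask], reference: GridSpec | None = None
) -> GridSpec:
    """Check all cohort masks share one grid; returns that grid."""
    if not masks:
        if reference is None:
            raise ValueError("empty mask list and no reference grid")
        return reference
    ref = reference if reference is not None else masks[0].grid
    for m in masks:
        ref.require_match(m.grid)
    return ref
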