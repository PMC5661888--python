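"""CT volumes, nodule masks, and the bounding-box conventions used everywhere.

Conventions (fixed for the whole package):

* axis order is ``(slice, row, col)``; the axial plane is ``(row, col)``;
* all coordinates are 0-based; all intervals are half-open ``[start, stop)``;
* ``spacing`` is millimetres per voxel along ``(slice, row, col)``.

Volumes and masks are stored on disk as NIfTI (``.nii`` / ``.nii.gz``) via
nibabel. NIfTI's natural data layout is (x, y, z) = (col, row, slice); the
reader/writer transpose so that in-memory arrays are always (slice, row, col).
Bounding boxes travel in small JSON sidecars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DimensionalityError, GeometryError


@dataclass
class CtVolume:
    """A 3-D CT intensity volume with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Intensity values (HU-like; no windowing is applied anywhere).
    spacing : tuple of 3 floats
        Millimetres per voxel along (slice, row, col); all positive.
    volume_id : str
        Free-text identifier carried through sampling and evaluation.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    volume_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DimensionalityError(
                f"expected 3-D voxel array, got ndim={self.voxels.ndim}"
            )
        if self.voxels.shape[0] < 1:
            raise GeometryError("volume must contain at least one slice")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive reals, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class NoduleMask:
    """A binary label volume aligned with a :class:`CtVolume`."""

    labels: np.ndarray
    rater_id: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionalityError(
                f"expected 3-D label array, got ndim={self.labels.ndim}"
            )
        uniq = np.unique(self.labels)
        if not np.isin(uniq, (0, 1)).all():
            raise GeometryError(f"mask values must be 0/1, found {uniq[:10]}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def volume_voxels(self) -> int:
        return int(self.labels.sum())


@dataclass(frozen=True)
class BoundingBox2D:
    """An axial, 0-based, half-open rectangle on one slice."""

    slice_index: int
    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_start >= self.row_stop or self.col_start >= self.col_stop:
            raise GeometryError(f"degenerate box {self}")

    @property
    def center(self) -> tuple[float, float]:
        """(row, col) centre of the box in continuous coordinates."""
        return (
            (self.row_start + self.row_stop - 1) / 2.0,
            (self.col_start + self.col_stop - 1) / 2.0,
        )

    def contains(self, row: int, col: int) -> bool:
        return (
            self.row_start <= row < self.row_stop
            and self.col_start <= col < self.col_stop
        )

    def to_json(self) -> dict:
        return {
            "slice": self.slice_index,
            "row": [self.row_start, self.row_stop],
            "col": [self.col_start, self.col_stop],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "BoundingBox2D":
        return cls(
            slice_index=int(obj["slice"]),
            row_start=int(obj["row"][0]),
            row_stop=int(obj["row"][1]),
            col_start=int(obj["col"][0]),
            col_stop=int(obj["col"][1]),
        )


def read_volume(path: str | Path) -> CtVolume:
    """Read a 3-D NIfTI file into a :class:`CtVolume`.

    The NIfTI (x, y, z) layout is transposed to (slice, row, col).
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"{path.name}: expected 3-D data, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise GeometryError(f"{path.name}: non-positive voxel spacing {zooms}")
    # nibabel layout (x=col, y=row, z=slice) -> (slice, row, col)
    voxels = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    vol_id = path.name
    for suffix in (".gz", ".nii"):
        if vol_id.endswith(suffix):
            vol_id = vol_id[: -len(suffix)]
    return CtVolume(voxels=voxels, spacing=spacing, volume_id=vol_id)


def write_volume(volume: CtVolume, path: str | Path, dtype=None) -> Path:
    """Write a :class:`CtVolume` as NIfTI; ``read_volume`` inverts it."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    data = np.transpose(volume.voxels, (2, 1, 0))
    if dtype is not None:
        data = data.astype(dtype)
    affine = np.diag(
        [volume.spacing[2], volume.spacing[1], volume.spacing[0], 1.0]
    )
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((volume.spacing[2], volume.spacing[1], volume.spacing[0]))
    nib.save(img, str(path))
    return path


def write_mask(mask: NoduleMask, spacing, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit NIfTI."""
    vol = CtVolume(voxels=mask.labels, spacing=spacing, volume_id="mask")
    return write_volume(vol, path, dtype=np.uint8)


def read_mask(path: str | Path, rater_id: str | None = None) -> NoduleMask:
    vol = read_volume(path)
    return NoduleMask(labels=(vol.voxels > 0).astype(np.uint8), rater_id=rater_id)


def clip_box(box: BoundingBox2D, shape: tuple[int, int, int]) -> BoundingBox2D:
    """Clamp a box to the image plane; a zero-overlap box is a geometry error."""
    n_slices, n_rows, n_cols = shape
    if not (0 <= box.slice_index < n_slices):
        raise GeometryError(f"slice {box.slice_index} outside volume of {n_slices}")
    r0, r1 = max(box.row_start, 0), min(box.row_stop, n_rows)
    c0, c1 = max(box.col_start, 0), min(box.col_stop, n_cols)
    if r0 >= r1 or c0 >= c1:
        raise GeometryError(f"box {box} does not overlap plane {(n_rows, n_cols)}")
    return BoundingBox2D(box.slice_index, r0, r1, c0, c1)


def save_box(box: BoundingBox2D, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(box.to_json(), indent=1))
    return path


def load_box(path: str | Path) -> BoundingBox2D:
    return BoundingBox2D.from_json(json.loads(Path(path).read_text()))
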