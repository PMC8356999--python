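"""Volume data model and NIfTI I/O shared by every pipeline stage.

All stages operate on 3-D volumes that live on a single common voxel grid
(the pipeline assumes spatial registration has already been done upstream).
A :class:`VoxelGrid` couples an array shape with a 4x4 voxel-to-world
affine in millimetres; scalar maps (diffusion metrics, streamline
densities, probability maps) are :class:`ScalarVolume` and categorical
maps (nucleus masks, parcellation atlases) are :class:`LabelVolume`.
Label 0 is reserved for background / unassigned voxels throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "ScalarVolume",
    "LabelVolume",
    "CountMapSet",
    "read_volume",
    "write_volume",
    "check_same_grid",
    "mask_indices",
]

#: Tolerance (mm) on affine entries when deciding two grids are the same.
GRID_ATOL_MM = 1e-4

#: Tolerance when checking that stored voxel sizes match the affine.
VOXEL_SIZE_ATOL = 1e-6


@dataclass(frozen=True)
class VoxelGrid:
    """Array shape plus voxel-to-world affine (mm) of a sampling lattice."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the 3x3 block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_coordinates(self, ijk: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoxelGrid):
            return NotImplemented
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=GRID_ATOL_MM, rtol=0.0
        )

    def __hash__(self) -> int:  # frozen dataclass with custom __eq__
        return hash(self.shape)


@dataclass
class ScalarVolume:
    """A real-valued 3-D map (diffusion metric, track density, probability)."""

    grid: VoxelGrid
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )


@dataclass
class LabelVolume:
    """An integer-labelled 3-D map; label 0 means background/unassigned."""

    grid: VoxelGrid
    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded, atol=1e-6):
                raise ValueError("labels must be integer-valued")
            labels = rounded.astype(np.int32)
        if labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if labels.shape != self.grid.shape:
            raise ValueError(
                f"labels shape {labels.shape} != grid shape {self.grid.shape}"
            )
        self.labels = labels.astype(np.int32, copy=False)
        self.label_names = {int(k): str(v) for k, v in self.label_names.items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.label_names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_names")

    def present_labels(self) -> list[int]:
        """Sorted nonzero labels that actually occur in the volume."""
        labs = np.unique(self.labels)
        return [int(l) for l in labs if l != 0]


@dataclass
class CountMapSet:
    """Per-target streamline-count (track-density) volumes on one grid.

    One nonnegative-integer volume per connectivity target; the target
    order is fixed and carried everywhere downstream (membership-vector
    components, winner-takes-all labels, summary rows).
    """

    grid: VoxelGrid
    target_names: list[str]
    counts: np.ndarray  # (n_targets, *shape)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.target_names), *self.grid.shape):
            raise ValueError("counts must be (n_targets, *grid.shape)")
        if counts.min() < 0:
            raise ValueError("streamline counts must be nonnegative")
        self.counts = counts.astype(np.int64, copy=False)
        self.target_names = [str(t) for t in self.target_names]

    @property
    def n_targets(self) -> int:
        return len(self.target_names)


Volume = Union[ScalarVolume, LabelVolume]


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, expected: str = "scalar") -> Volume:
    """Read a single 3-D NIfTI volume.

    Parameters
    ----------
    path:
        A ``.nii`` / ``.nii.gz`` file.
    expected:
        ``"scalar"`` or ``"label"``.  Label volumes must hold integer
        values (tolerance 1e-6 before rounding); a sidecar JSON with the
        same stem (``foo.labels.json``) supplies the label dictionary if
        present, otherwise labels are named after their integer value.

    Raises
    ------
    ValueError
        If the image is not a single 3-D volume, or non-integer data is
        read with ``expected="label"``.
    """
    if expected not in ("scalar", "label"):
        raise ValueError(f"expected must be 'scalar' or 'label', got {expected!r}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D in {path}")
    grid = VoxelGrid(shape=data.shape, affine=np.asarray(img.affine, dtype=float))
    if expected == "scalar":
        return ScalarVolume(grid=grid, values=data.astype(float))
    names = _read_sidecar_labels(Path(path))
    vol = LabelVolume(grid=grid, labels=data, label_names=names or {})
    if not vol.label_names:
        vol.label_names = {l: str(l) for l in vol.present_labels()}
    return vol


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; label dictionaries go to a JSON sidecar."""
    path = Path(path)
    if isinstance(volume, LabelVolume):
        img = nib.Nifti1Image(volume.labels.astype(np.int32), volume.grid.affine)
        img.to_filename(str(path))
        if volume.label_names:
            sidecar = _sidecar_path(path)
            sidecar.write_text(
                json.dumps({str(k): v for k, v in volume.label_names.items()}, indent=1)
            )
    else:
        img = nib.Nifti1Image(volume.values.astype(np.float64), volume.grid.affine)
        img.to_filename(str(path))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".labels.json")
    return path.with_suffix(".labels.json")


def _read_sidecar_labels(path: Path) -> dict[int, str] | None:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        return {int(k): str(v) for k, v in raw.items()}
    return None


# ---------------------------------------------------------------------------
# Grid consistency and masking
# ---------------------------------------------------------------------------

def check_same_grid(volumes: Sequence[Volume | CountMapSet]) -> bool:
    """True iff all volumes share one shape and affine (within 1e-4 mm)."""
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes to compare grids")
    ref = volumes[0].grid
    return all(v.grid == ref for v in volumes[1:])


def require_same_grid(volumes: Sequence[Volume | CountMapSet], what: str = "inputs") -> None:
    if not check_same_grid(volumes):
        raise ValueError(f"{what} are not on the same voxel grid")


def mask_indices(mask: LabelVolume, label: int = 1) -> np.ndarray:
    """Voxel indices carrying ``label``, in deterministic lexicographic order.

    Returns an (N, 3) integer array sorted lexicographically by (i, j, k);
    this ordering defines row order for membership fields and feature
    matrices, so it must be stable across calls and platforms
    (``np.argwhere`` scans in C order, which is exactly that ordering).
    """
    label = int(label)
    if label != 0 and label not in mask.label_names:
        raise KeyError(f"label {label} not in label dictionary")
    return np.argwhere(mask.labels == label)
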