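"""Standard-grid geometry: voxel grids, world/voxel coordinates, atlases, resampling.

All volumes are 3D scalar arrays paired with a 4x4 affine that maps 0-based
voxel indices to world coordinates in millimetres (RAS orientation for the
shipped fixtures).  The default working grid is 1.0-mm isotropic, matching the
standard-space template the analysis assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: The eleven anatomical segments lesions are assigned to, in display order.
CANONICAL_REGIONS: tuple[str, ...] = (
    "frontal lobe",
    "parietal lobe",
    "occipital lobe",
    "temporal lobe",
    "putamen",
    "caudate",
    "thalamus",
    "brainstem",
    "cerebellum",
    "pineal body",
    "pituitary gland",
)

UNASSIGNED = "unassigned"


class OutOfFieldOfViewError(ValueError):
    """A world coordinate maps outside the grid's field of view."""


class SingularTransformError(ValueError):
    """A supplied world-coordinate affine is not invertible."""


@dataclass
class VoxelGrid:
    """A 3D scalar volume plus a voxel-to-world(mm) affine.

    Parameters
    ----------
    data
        3D array of scalar values, one per voxel.
    affine
        4x4 matrix mapping 0-based voxel index (homogeneous) to world mm.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise SingularTransformError("grid affine is singular")
        if np.any(self.spacing <= 0):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """mm per voxel along each axis (column norms of the linear part)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_to_world(self, ijk: Sequence[float]) -> np.ndarray:
        """World-mm coordinates of (possibly fractional) voxel indices."""
        ijk = np.asarray(ijk, dtype=float)
        return self.affine[:3, :3] @ ijk + self.affine[:3, 3]

    def world_to_voxel(self, point_mm: Sequence[float]) -> tuple[int, int, int]:
        """Nearest voxel index for a world point; ties round toward the lower index."""
        return world_to_voxel(self, point_mm)

    def contains_voxel(self, ijk: Sequence[int]) -> bool:
        ijk = np.asarray(ijk)
        return bool(np.all(ijk >= 0) and np.all(ijk < self.shape))

    def like(self, data: np.ndarray) -> "VoxelGrid":
        """A new grid with the same geometry and different data."""
        return VoxelGrid(data=data, affine=self.affine.copy())


def world_to_voxel(grid: VoxelGrid, point_mm: Sequence[float]) -> tuple[int, int, int]:
    """Map a world-mm point to the nearest 0-based voxel index.

    Rounding is to the nearest integer with exact halves rounding toward the
    lower index, so each world point maps to exactly one voxel.

    Raises
    ------
    OutOfFieldOfViewError
        If the rounded index falls outside the grid.
    """
    point_mm = np.asarray(point_mm, dtype=float)
    inv = np.linalg.inv(grid.affine)
    cont = inv[:3, :3] @ point_mm + inv[:3, 3]
    # ceil(x - 1/2) = nearest integer with ties going down
    idx = np.ceil(cont - 0.5).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(grid.shape)):
        raise OutOfFieldOfViewError(
            f"point {tuple(point_mm)} mm maps to voxel {tuple(idx)}, "
            f"outside grid of shape {grid.shape}"
        )
    return tuple(int(v) for v in idx)


@dataclass
class RegionAtlas:
    """An integer-labelled :class:`VoxelGrid` plus a label table.

    Background voxels carry label 0; every other value present in the volume
    must appear in ``labels`` (label id -> region name).
    """

    grid: VoxelGrid
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = self.grid.data
        if not np.issubdtype(data.dtype, np.integer):
            if np.issubdtype(data.dtype, np.floating) and np.all(data == np.round(data)):
                self.grid = VoxelGrid(data.astype(np.int32), self.grid.affine)
                data = self.grid.data
            else:
                raise ValueError("atlas volume must be integer-valued")
        if np.any(data < 0):
            raise ValueError("atlas labels must be non-negative")
        ids = list(self.labels)
        if len(set(ids)) != len(ids):
            raise ValueError("label ids must be unique")
        names = list(self.labels.values())
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        if any(i < 1 for i in ids):
            raise ValueError("label ids must be >= 1 (0 is background)")
        present = set(np.unique(data)) - {0}
        orphans = sorted(int(v) for v in present if int(v) not in self.labels)
        if orphans:
            raise ValueError(f"voxel labels missing from label table: {orphans}")
        if not present:
            logger.warning("atlas volume contains no labelled voxels")

    @property
    def region_names(self) -> list[str]:
        return [self.labels[i] for i in sorted(self.labels)]

    def label_of(self, ijk: Sequence[int]) -> int:
        if not self.grid.contains_voxel(ijk):
            raise OutOfFieldOfViewError(
                f"voxel {tuple(ijk)} outside atlas grid {self.grid.shape}"
            )
        return int(self.grid.data[tuple(int(v) for v in ijk)])

    def bounding_box(self, label_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) inclusive-exclusive voxel bounding box of a label."""
        where = np.nonzero(self.grid.data == label_id)
        if where[0].size == 0:
            raise ValueError(f"label {label_id} has zero voxels")
        lo = np.array([w.min() for w in where])
        hi = np.array([w.max() + 1 for w in where])
        return lo, hi


# --- toy atlas -------------------------------------------------------------

DEFAULT_TOY_SHAPE = (144, 144, 144)


def _default_layout(shape: tuple[int, int, int]) -> dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]]:
    """Eleven disjoint 40-mm boxes on a 3x3x3 slot lattice, one per region."""
    size = 40
    starts = (6, 52, 98)
    slots = [(i, j, k) for i in starts for j in starts for k in starts]
    layout = {}
    for region, (i, j, k) in zip(CANONICAL_REGIONS, slots):
        layout[region] = ((i, j, k), (i + size, j + size, k + size))
    return layout


def build_toy_atlas(
    shape: tuple[int, int, int] = DEFAULT_TOY_SHAPE,
    layout: Mapping[str, tuple[Sequence[int], Sequence[int]]] | None = None,
    spacing_mm: float = 1.0,
) -> RegionAtlas:
    """Build a deterministic box atlas with the eleven canonical regions.

    Each region occupies an axis-aligned box (half-open voxel ranges); boxes
    must be disjoint and inside ``shape``.  The same input always yields a
    bit-identical atlas, so tests run without any downloaded template.
    """
    if layout is None:
        layout = _default_layout(shape)
    missing = set(CANONICAL_REGIONS) - set(layout)
    if missing:
        raise ValueError(f"layout missing canonical regions: {sorted(missing)}")
    extra = set(layout) - set(CANONICAL_REGIONS)
    if extra:
        raise ValueError(f"layout has unknown regions: {sorted(extra)}")

    data = np.zeros(shape, dtype=np.int16)
    labels: dict[int, str] = {}
    for label_id, region in enumerate(CANONICAL_REGIONS, start=1):
        lo, hi = (np.asarray(b, dtype=int) for b in layout[region])
        if np.any(lo < 0) or np.any(hi > np.array(shape)) or np.any(lo >= hi):
            raise ValueError(f"box for {region!r} ({tuple(lo)}..{tuple(hi)}) not inside shape {shape}")
        block = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        if np.any(block != 0):
            raise ValueError(f"box for {region!r} overlaps a previously placed region")
        block[...] = label_id
        labels[label_id] = region
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    return RegionAtlas(grid=VoxelGrid(data, affine), labels=labels)


# --- I/O -------------------------------------------------------------------

def load_volume(path: str | Path) -> VoxelGrid:
    """Load a NIfTI volume as a :class:`VoxelGrid`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return VoxelGrid(data=data, affine=np.asarray(img.affine))


def save_volume(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a :class:`VoxelGrid` as NIfTI (.nii or .nii.gz)."""
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, grid.affine)
    nib.save(img, str(path))
    return Path(path)


def read_label_table(path: str | Path) -> dict[int, str]:
    """Read a 2-column TSV (label_id, region_name), header optional."""
    labels: dict[int, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"label table line has fewer than 2 columns: {line!r}")
        try:
            label_id = int(parts[0])
        except ValueError:
            continue  # header line
        labels[label_id] = parts[1]
    return labels


def write_label_table(labels: Mapping[int, str], path: str | Path) -> Path:
    lines = ["label_id\tregion_name"]
    lines += [f"{i}\t{labels[i]}" for i in sorted(labels)]
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def load_atlas(volume_path: str | Path, label_table_path: str | Path) -> RegionAtlas:
    """Load and validate a labelled atlas (NIfTI volume + label TSV)."""
    grid = load_volume(volume_path)
    labels = read_label_table(label_table_path)
    return RegionAtlas(grid=grid, labels=labels)


def save_atlas(atlas: RegionAtlas, volume_path: str | Path, label_table_path: str | Path) -> None:
    save_volume(atlas.grid, volume_path)
    write_label_table(atlas.labels, label_table_path)


def read_affine(path: str | Path) -> np.ndarray:
    """Read a 4x4 whitespace-delimited world-coordinate affine."""
    mat = np.loadtxt(str(path))
    if mat.shape != (4, 4):
        raise ValueError(f"affine file must hold a 4x4 matrix, got {mat.shape}")
    return mat


def write_affine(mat: np.ndarray, path: str | Path) -> Path:
    np.savetxt(str(path), np.asarray(mat, dtype=float), fmt="%.17g")
    return Path(path)


# --- resampling ------------------------------------------------------------

def resample_affine(
    image: VoxelGrid,
    transform: np.ndarray,
    target: VoxelGrid,
    mode: str = "nearest",
) -> VoxelGrid:
    """Resample ``image`` onto ``target``'s grid under a world-coordinate affine.

    ``transform`` maps source-world mm to target-world mm (the direction a
    registration tool reports for moving an image into a template frame);
    estimation of such transforms is out of scope — only application is
    supported.  Voxels that pull back outside the source get 0.

    Parameters
    ----------
    mode
        ``"nearest"`` (required for label volumes) or ``"trilinear"``.
    """
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4):
        raise ValueError(f"transform must be 4x4, got {transform.shape}")
    if abs(np.linalg.det(transform)) < 1e-12:
        raise SingularTransformError("registration transform is singular")
    if mode not in ("nearest", "trilinear"):
        raise ValueError(f"mode must be 'nearest' or 'trilinear', got {mode!r}")

    # target voxel -> target world -> source world -> source voxel
    M = np.linalg.inv(image.affine) @ np.linalg.inv(transform) @ target.affine
    # snap numerically-integer mappings so identity / integer shifts are exact
    snapped = np.round(M)
    M = np.where(np.abs(M - snapped) < 1e-9, snapped, M)

    order = 0 if mode == "nearest" else 1
    out = ndimage.affine_transform(
        image.data.astype(float) if order == 1 else image.data,
        M[:3, :3],
        offset=M[:3, 3],
        output_shape=target.shape,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    if order == 0:
        out = out.astype(image.data.dtype)
    return VoxelGrid(data=out, affine=target.affine.copy())
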