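"""Lesion mapping: connected components, centers of gravity, sphere frequency
maps, and atlas region assignment.

The analysis chain mirrors a voxel-based lesion-mapping workflow: each lesion
in a standard-space binary mask is reduced to its center of gravity (COG),
which is taken as the primary site of occurrence; a site-centered sphere of
fixed diameter (default 20 mm) is rasterized per lesion to build an
occurrence-frequency heat map; and each COG voxel is assigned to one of the
eleven canonical atlas regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import (
    OutOfFieldOfViewError,
    RegionAtlas,
    UNASSIGNED,
    VoxelGrid,
    world_to_voxel,
)

logger = logging.getLogger(__name__)

#: Closed vocabulary of breast-cancer biological subtypes.
SUBTYPES: tuple[str, ...] = ("luminal A", "luminal B", "HER2", "TNBC")

_SUBTYPE_ALIASES = {
    "luminala": "luminal A",
    "luminal_a": "luminal A",
    "luminal a": "luminal A",
    "luminalb": "luminal B",
    "luminal_b": "luminal B",
    "luminal b": "luminal B",
    "her2": "HER2",
    "tnbc": "TNBC",
}


def normalize_subtype(value: str) -> str:
    """Map a subtype string onto the closed vocabulary, or raise."""
    key = str(value).strip().lower()
    if key in _SUBTYPE_ALIASES:
        return _SUBTYPE_ALIASES[key]
    raise ValueError(
        f"unknown subtype {value!r}; expected one of {list(SUBTYPES)}"
    )


@dataclass
class LesionComponent:
    """One connected lesion: its member voxels on a source grid."""

    voxels: np.ndarray  # (n, 3) integer voxel indices
    grid: VoxelGrid
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if self.voxels.size == 0:
            raise ValueError("lesion component must be non-empty")
        if np.any(self.voxels < 0) or np.any(self.voxels >= np.array(self.grid.shape)):
            raise ValueError("component voxels fall outside the grid")

    def __len__(self) -> int:
        return self.voxels.shape[0]


@dataclass
class LesionRecord:
    """One metastasis: who, what subtype, where (COG) and which region."""

    patient_id: str
    subtype: str
    cog_mm: tuple[float, float, float]
    cog_voxel: tuple[int, int, int]
    region: str

    def __post_init__(self) -> None:
        self.subtype = normalize_subtype(self.subtype)


@dataclass
class FrequencyMap:
    """Voxelwise count of lesion-centered spheres covering each voxel."""

    grid: VoxelGrid
    n_lesions: int
    sphere_diameter_mm: float = 20.0

    @property
    def total(self) -> int:
        return int(self.grid.data.sum())


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def extract_components(
    mask: VoxelGrid, connectivity: int = 26, patient_id: str | None = None
) -> list[LesionComponent]:
    """Maximal connected components of a binary mask.

    Components are ordered by their minimal flat voxel index, so the output
    is deterministic for a given mask.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    data = mask.data
    values = np.unique(data)
    if not np.all(np.isin(values, (0, 1))):
        raise ValueError(f"mask must be binary, found values {values[:10]}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labelled, n = ndimage.label(data, structure=structure)
    components = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labelled == lab)
        components.append(LesionComponent(voxels=vox, grid=mask, patient_id=patient_id))
    components.sort(key=lambda c: int(np.min(np.ravel_multi_index(c.voxels.T, mask.shape))))
    return components


def center_of_gravity(
    component: LesionComponent,
) -> tuple[tuple[float, float, float], tuple[int, int, int]]:
    """Unweighted (binary-mass) COG of a component, in mm and voxel indices.

    The voxel index follows the package-wide rounding rule: nearest integer,
    exact halves toward the lower index.
    """
    mean_idx = component.voxels.mean(axis=0)
    cog_mm = component.grid.voxel_to_world(mean_idx)
    cog_voxel = world_to_voxel(component.grid, cog_mm)
    return tuple(float(v) for v in cog_mm), cog_voxel


def rasterize_sphere(
    center_voxel: Sequence[int], diameter_mm: float, grid: VoxelGrid
) -> np.ndarray:
    """Voxel indices whose centers lie within ``diameter_mm/2`` of the center voxel.

    Distances are Euclidean in world mm; the sphere is clipped at the grid
    boundary without error.

    Returns
    -------
    (n, 3) integer array of voxel indices.
    """
    if diameter_mm <= 0:
        raise ValueError(f"sphere diameter must be positive, got {diameter_mm}")
    center = np.asarray(center_voxel, dtype=int)
    if not grid.contains_voxel(center):
        raise OutOfFieldOfViewError(
            f"sphere center {tuple(center)} outside grid {grid.shape}"
        )
    radius = diameter_mm / 2.0
    half = np.ceil(radius / grid.spacing).astype(int)
    lo = np.maximum(center - half, 0)
    hi = np.minimum(center + half + 1, np.array(grid.shape))
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    offsets = np.stack([ii - center[0], jj - center[1], kk - center[2]], axis=-1)
    disp_mm = offsets @ grid.affine[:3, :3].T
    inside = (disp_mm ** 2).sum(axis=-1) <= radius ** 2 + 1e-9
    return np.stack([ii[inside], jj[inside], kk[inside]], axis=-1)


def build_frequency_map(
    records: Iterable[LesionRecord], grid: VoxelGrid, diameter_mm: float = 20.0
) -> FrequencyMap:
    """Sum of per-lesion sphere indicators: the occurrence-frequency heat map.

    Overlapping spheres add, so a voxel's value counts how many lesions'
    spheres cover it (at most the number of lesions).
    """
    counts = np.zeros(grid.shape, dtype=np.int32)
    n = 0
    for rec in records:
        if not grid.contains_voxel(rec.cog_voxel):
            raise OutOfFieldOfViewError(
                f"record for patient {rec.patient_id!r} has COG voxel "
                f"{rec.cog_voxel} outside grid {grid.shape}"
            )
        sphere = rasterize_sphere(rec.cog_voxel, diameter_mm, grid)
        counts[sphere[:, 0], sphere[:, 1], sphere[:, 2]] += 1
        n += 1
    return FrequencyMap(grid=grid.like(counts), n_lesions=n, sphere_diameter_mm=diameter_mm)


def assign_region(
    atlas: RegionAtlas, cog_voxel: Sequence[int], max_dist_mm: float = 10.0
) -> str:
    """Atlas region of a COG voxel.

    If the voxel itself is background, the nearest labelled voxel within
    ``max_dist_mm`` is used (exact distance ties break toward the lower label
    id); beyond that the lesion is ``"unassigned"`` and a warning is logged.
    """
    label = atlas.label_of(cog_voxel)
    if label != 0:
        return atlas.labels[label]
    grid = atlas.grid
    center = np.asarray(cog_voxel, dtype=int)
    half = np.ceil(max_dist_mm / grid.spacing).astype(int)
    lo = np.maximum(center - half, 0)
    hi = np.minimum(center + half + 1, np.array(grid.shape))
    sub = grid.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    labelled = np.argwhere(sub != 0)
    if labelled.size:
        disp_mm = (labelled + lo - center) @ grid.affine[:3, :3].T
        d2 = (disp_mm ** 2).sum(axis=1)
        within = d2 <= max_dist_mm ** 2 + 1e-9
        if within.any():
            d2w = d2[within]
            cand = labelled[within]
            best = d2w.min()
            tied = cand[d2w <= best + 1e-9]
            ids = sub[tied[:, 0], tied[:, 1], tied[:, 2]]
            return atlas.labels[int(ids.min())]
    logger.warning(
        "COG voxel %s is more than %.1f mm from any atlas label; unassigned",
        tuple(int(v) for v in center),
        max_dist_mm,
    )
    return UNASSIGNED


def map_cohort(
    masks: Mapping[str, VoxelGrid],
    metadata: pd.DataFrame,
    atlas: RegionAtlas,
    connectivity: int = 26,
    max_dist_mm: float = 10.0,
) -> list[LesionRecord]:
    """Map every lesion of every patient to a record with subtype and region.

    Parameters
    ----------
    masks
        Per-patient binary lesion masks in standard space.
    metadata
        Table with columns ``patient_id`` and ``subtype`` covering every
        patient in ``masks``.
    """
    if not {"patient_id", "subtype"}.issubset(metadata.columns):
        raise ValueError("metadata must have columns 'patient_id' and 'subtype'")
    meta = metadata.astype({"patient_id": str}).set_index("patient_id")["subtype"]
    records: list[LesionRecord] = []
    for patient_id in sorted(masks, key=str):
        pid = str(patient_id)
        if pid not in meta.index:
            raise ValueError(f"patient {pid!r} has no subtype in metadata")
        subtype = normalize_subtype(meta.loc[pid])
        for comp in extract_components(masks[patient_id], connectivity, patient_id=pid):
            cog_mm, cog_voxel = center_of_gravity(comp)
            region = assign_region(atlas, cog_voxel, max_dist_mm=max_dist_mm)
            records.append(
                LesionRecord(
                    patient_id=pid,
                    subtype=subtype,
                    cog_mm=cog_mm,
                    cog_voxel=cog_voxel,
                    region=region,
                )
            )
    return records


# --- record table I/O ------------------------------------------------------

RECORD_COLUMNS = [
    "patient_id",
    "subtype",
    "cog_x_mm",
    "cog_y_mm",
    "cog_z_mm",
    "i",
    "j",
    "k",
    "region",
]


def records_to_frame(records: Iterable[LesionRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "subtype": r.subtype,
            "cog_x_mm": r.cog_mm[0],
            "cog_y_mm": r.cog_mm[1],
            "cog_z_mm": r.cog_mm[2],
            "i": r.cog_voxel[0],
            "j": r.cog_voxel[1],
            "k": r.cog_voxel[2],
            "region": r.region,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[LesionRecord]:
    return [
        LesionRecord(
            patient_id=str(row.patient_id),
            subtype=row.subtype,
            cog_mm=(float(row.cog_x_mm), float(row.cog_y_mm), float(row.cog_z_mm)),
            cog_voxel=(int(row.i), int(row.j), int(row.k)),
            region=row.region,
        )
        for row in frame.itertuples(index=False)
    ]


def write_records(records: Iterable[LesionRecord], path: str | Path) -> Path:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"patient_id": str})
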