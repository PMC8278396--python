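"""Synthetic cohort generation and Monte-Carlo power / type-I-error estimation.

A cohort is described by a :class:`CohortSpec`: patients per subtype, a
zero-truncated negative-binomial lesion-count law, a per-subtype multinomial
preference vector over the eleven atlas regions, and a lesion-radius law.
Lesion centers are drawn uniformly inside the sampled region of a box atlas
(with optional Gaussian jitter kept inside the region), and can be rendered
as spherical binary masks in standard space so the full mapping chain can be
exercised against known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.proportion import proportion_confint

from .grids import CANONICAL_REGIONS, RegionAtlas, VoxelGrid, build_toy_atlas
from .mapping import SUBTYPES, normalize_subtype, rasterize_sphere
from .stats import AnalysisConfig, ContingencyTable, chi_square_independence

logger = logging.getLogger(__name__)

#: Overall region frequencies of the example cohort (normalized 437-lesion
#: margin); used as the shared preference vector under the null.
OVERALL_PREFERENCE = np.array(
    [107, 69, 44, 38, 18, 6, 5, 4, 143, 2, 1], dtype=float
) / 437.0

_DEFAULT_PATIENTS = {"luminal A": 28, "luminal B": 9, "HER2": 14, "TNBC": 16}

# Per-subtype preference defaults: the example cohort's subtype columns.
_SUBTYPE_COLUMNS = {
    "luminal A": [33, 27, 17, 13, 4, 2, 0, 1, 64, 0, 1],
    "luminal B": [3, 4, 1, 2, 0, 1, 0, 0, 18, 1, 0],
    "HER2": [55, 32, 19, 17, 14, 3, 5, 3, 48, 0, 0],
    "TNBC": [16, 6, 7, 6, 0, 0, 0, 0, 13, 1, 0],
}


def _normalize_pref(vec: Sequence[float]) -> np.ndarray:
    arr = np.asarray(vec, dtype=float)
    if arr.shape != (len(CANONICAL_REGIONS),):
        raise ValueError(
            f"preference vector must have length {len(CANONICAL_REGIONS)}, got {arr.shape}"
        )
    if np.any(arr < 0):
        raise ValueError("preference vector entries must be non-negative")
    s = arr.sum()
    if s <= 0:
        raise ValueError("preference vector must have positive mass")
    return arr / s


@dataclass
class CohortSpec:
    """Generative parameters of a synthetic cohort.

    Lesion counts per patient follow a zero-truncated negative binomial with
    underlying mean ``count_mu`` and dispersion ``count_dispersion``; the
    defaults give a per-patient median of 2 lesions with strong
    over-dispersion, matching the cohort structure the analysis assumes.
    ``fixed_lesion_count`` overrides the law with a constant (useful for
    exact-count tests).
    """

    n_patients: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_PATIENTS))
    count_mu: float = 1.0
    count_dispersion: float = 0.1
    fixed_lesion_count: int | None = None
    region_preference: dict[str, np.ndarray] = field(
        default_factory=lambda: {
            s: _normalize_pref(v) for s, v in _SUBTYPE_COLUMNS.items()
        }
    )
    lesion_radius_range_mm: tuple[float, float] = (2.0, 8.0)
    jitter_mm: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.n_patients = {
            normalize_subtype(k): int(v) for k, v in self.n_patients.items()
        }
        if any(v < 1 for v in self.n_patients.values()):
            raise ValueError("each subtype needs at least one patient")
        self.region_preference = {
            normalize_subtype(k): _normalize_pref(v)
            for k, v in self.region_preference.items()
        }
        missing = set(self.n_patients) - set(self.region_preference)
        if missing:
            raise ValueError(f"no preference vector for subtypes: {sorted(missing)}")
        lo, hi = self.lesion_radius_range_mm
        if not 0 < lo <= hi:
            raise ValueError("lesion radius range must satisfy 0 < lo <= hi")
        if self.fixed_lesion_count is not None and self.fixed_lesion_count < 1:
            raise ValueError("fixed_lesion_count must be >= 1")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_patients": dict(self.n_patients),
            "count_mu": self.count_mu,
            "count_dispersion": self.count_dispersion,
            "fixed_lesion_count": self.fixed_lesion_count,
            "region_preference": {
                k: [float(x) for x in v] for k, v in self.region_preference.items()
            },
            "lesion_radius_range_mm": list(self.lesion_radius_range_mm),
            "jitter_mm": self.jitter_mm,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        if "lesion_radius_range_mm" in d:
            d["lesion_radius_range_mm"] = tuple(d["lesion_radius_range_mm"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def null_cohort_spec(seed: int | None = None, **kwargs) -> CohortSpec:
    """All subtypes share the overall preference vector (no spatial effect)."""
    pref = {s: OVERALL_PREFERENCE.copy() for s in SUBTYPES}
    return CohortSpec(region_preference=pref, seed=seed, **kwargs)


def shifted_cohort_spec(
    subtype: str = "HER2",
    source_region: str = "cerebellum",
    target_region: str = "putamen",
    mass: float = 0.3,
    seed: int | None = None,
    **kwargs,
) -> CohortSpec:
    """Null spec with one subtype's preference mass moved between two regions.

    The default moves 0.3 of the HER2 vector from cerebellum to putamen — a
    strong spatial effect used for power analysis.
    """
    pref = {s: OVERALL_PREFERENCE.copy() for s in SUBTYPES}
    subtype = normalize_subtype(subtype)
    i = CANONICAL_REGIONS.index(source_region)
    j = CANONICAL_REGIONS.index(target_region)
    moved = min(mass, pref[subtype][i])
    pref[subtype][i] -= moved
    pref[subtype][j] += moved
    return CohortSpec(region_preference=pref, seed=seed, **kwargs)


# --- sampling --------------------------------------------------------------

def _sample_ztnb(rng: np.random.Generator, mu: float, k: float, size: int) -> np.ndarray:
    """Zero-truncated negative binomial via rejection of zeros."""
    p = k / (k + mu)
    vals = rng.negative_binomial(k, p, size=size)
    while True:
        z = vals == 0
        if not z.any():
            return vals
        vals[z] = rng.negative_binomial(k, p, size=int(z.sum()))


def _lesion_counts(rng: np.random.Generator, spec: CohortSpec, n: int) -> np.ndarray:
    if spec.fixed_lesion_count is not None:
        return np.full(n, spec.fixed_lesion_count, dtype=int)
    return _sample_ztnb(rng, spec.count_mu, spec.count_dispersion, n)


@dataclass
class SimulationResult:
    truth: pd.DataFrame  # patient_id, subtype, region, x/y/z_mm, radius_mm
    masks: dict[str, VoxelGrid] | None = None


def simulate_cohort(
    spec: CohortSpec,
    atlas: RegionAtlas | None = None,
    render: bool = False,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Draw a synthetic cohort; optionally render lesions into binary masks.

    Each patient's lesion count comes from the spec's count law; each
    lesion's region is a multinomial draw from the subtype's preference
    vector; its center is uniform within the region's labelled voxels
    (continuous within-voxel offset), plus Gaussian jitter that is discarded
    if it would leave the region.  Rendering paints a sphere of the sampled
    radius into the patient's mask.  Fully reproducible from ``spec.seed``.
    """
    if atlas is None:
        atlas = build_toy_atlas()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    name_to_id = {v: k for k, v in atlas.labels.items()}
    region_voxels: dict[str, np.ndarray] = {}
    for region in CANONICAL_REGIONS:
        vox = np.argwhere(atlas.grid.data == name_to_id[region])
        region_voxels[region] = vox
    for subtype, pref in spec.region_preference.items():
        for i, p in enumerate(pref):
            if p > 0 and region_voxels[CANONICAL_REGIONS[i]].size == 0:
                raise ValueError(
                    f"region {CANONICAL_REGIONS[i]!r} has zero atlas volume but "
                    f"positive preference for {subtype}"
                )

    grid = atlas.grid
    rows = []
    masks: dict[str, VoxelGrid] | None = {} if render else None
    for subtype in SUBTYPES:
        if subtype not in spec.n_patients:
            continue
        n_pat = spec.n_patients[subtype]
        pref = spec.region_preference[subtype]
        counts = _lesion_counts(rng, spec, n_pat)
        for p_idx in range(n_pat):
            pid = f"sim-{subtype.replace(' ', '')}-{p_idx + 1:03d}"
            mask = np.zeros(grid.shape, dtype=bool) if render else None
            region_draws = rng.choice(len(CANONICAL_REGIONS), size=counts[p_idx], p=pref)
            for r_idx in region_draws:
                region = CANONICAL_REGIONS[int(r_idx)]
                vox_pool = region_voxels[region]
                vox = vox_pool[rng.integers(len(vox_pool))]
                center_idx = vox + rng.uniform(-0.5, 0.5, size=3)
                if spec.jitter_mm > 0:
                    jitter = rng.normal(0.0, spec.jitter_mm, size=3)
                    jittered = center_idx + jitter / grid.spacing
                    j_vox = np.round(jittered).astype(int)
                    if (
                        np.all(j_vox >= 0)
                        and np.all(j_vox < np.array(grid.shape))
                        and int(grid.data[tuple(j_vox)]) == name_to_id[region]
                    ):
                        center_idx = jittered
                center_mm = grid.voxel_to_world(center_idx)
                radius = rng.uniform(*spec.lesion_radius_range_mm)
                rows.append(
                    {
                        "patient_id": pid,
                        "subtype": subtype,
                        "region": region,
                        "x_mm": float(center_mm[0]),
                        "y_mm": float(center_mm[1]),
                        "z_mm": float(center_mm[2]),
                        "radius_mm": float(radius),
                    }
                )
                if render:
                    cvox = grid.world_to_voxel(center_mm)
                    sphere = rasterize_sphere(cvox, 2 * radius, grid)
                    mask[sphere[:, 0], sphere[:, 1], sphere[:, 2]] = True
            if render:
                masks[pid] = grid.like(mask)
    truth = pd.DataFrame(
        rows,
        columns=["patient_id", "subtype", "region", "x_mm", "y_mm", "z_mm", "radius_mm"],
    )
    return SimulationResult(truth=truth, masks=masks)


def truth_metadata(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-patient (patient_id, subtype) table from a truth table."""
    return (
        truth[["patient_id", "subtype"]].drop_duplicates().reset_index(drop=True)
    )


# --- power / type-I error --------------------------------------------------

@dataclass
class PowerEstimate:
    rejection_rate: float
    ci_low: float
    ci_high: float
    n_reps: int
    alpha: float
    n_degenerate: int = 0


def _simulate_counts_table(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    """Fast truth-level draw of the region x subtype counts table."""
    cols = []
    for subtype in SUBTYPES:
        if subtype not in spec.n_patients:
            continue
        total = int(_lesion_counts(rng, spec, spec.n_patients[subtype]).sum())
        cols.append(rng.multinomial(total, spec.region_preference[subtype]))
    return np.column_stack(cols)


def estimate_power(
    spec: CohortSpec,
    n_reps: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PowerEstimate:
    """Rejection rate of the chi-square test over simulated cohorts.

    Runs on truth-level counts tables (no mask rendering) for speed: each
    replicate draws per-patient lesion counts, allocates lesions to regions
    by the subtype preference vectors, and tests the resulting table at
    ``alpha``.  Degenerate tables (fewer than 2 non-empty rows or columns
    after dropping) count as non-rejections.  Returns the rate with a 95%
    Wilson confidence interval.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    groups = [s for s in SUBTYPES if s in spec.n_patients]
    config = AnalysisConfig(alpha=alpha)
    rejected = 0
    degenerate = 0
    # per-replicate empty-row / small-expected warnings would flood the log
    stats_logger = logging.getLogger("brainmets.stats")
    old_level = stats_logger.level
    stats_logger.setLevel(logging.ERROR)
    try:
        for _ in range(n_reps):
            O = _simulate_counts_table(rng, spec)
            frame = pd.DataFrame(O, index=list(CANONICAL_REGIONS), columns=groups)
            table = ContingencyTable(observed=frame)
            try:
                res = chi_square_independence(table, config)
            except ValueError:
                degenerate += 1
                continue
            if res.p < alpha:
                rejected += 1
    finally:
        stats_logger.setLevel(old_level)
    lo, hi = proportion_confint(rejected, n_reps, alpha=0.05, method="wilson")
    return PowerEstimate(
        rejection_rate=rejected / n_reps,
        ci_low=float(lo),
        ci_high=float(hi),
        n_reps=n_reps,
        alpha=alpha,
        n_degenerate=degenerate,
    )
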