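"""Packaged example dataset: region-by-subtype lesion counts from a published
67-patient breast-cancer brain-metastasis cohort (437 lesions total), plus the
cohort's reported presenting-symptom breakdown.

The counts table is the published region x subtype distribution; the records
expansion and the per-record coordinates are synthetic reconstructions (the
underlying per-patient lesion listing was never published), built so the full
pipeline can run end to end on a realistic table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grids import CANONICAL_REGIONS, RegionAtlas, build_toy_atlas
from .mapping import SUBTYPES

#: Number of patients per subtype in the example cohort.
PATIENT_COUNTS: dict[str, int] = {
    "luminal A": 28,
    "luminal B": 9,
    "HER2": 14,
    "TNBC": 16,
}

# Region x subtype lesion counts (rows follow CANONICAL_REGIONS order).
_COUNTS = np.array(
    [
        [33, 3, 55, 16],   # frontal lobe
        [27, 4, 32, 6],    # parietal lobe
        [17, 1, 19, 7],    # occipital lobe
        [13, 2, 17, 6],    # temporal lobe
        [4, 0, 14, 0],     # putamen
        [2, 1, 3, 0],      # caudate
        [0, 0, 5, 0],      # thalamus
        [1, 0, 3, 0],      # brainstem
        [64, 18, 48, 13],  # cerebellum
        [0, 1, 0, 1],      # pineal body
        [1, 0, 0, 0],      # pituitary gland
    ],
    dtype=int,
)

#: Presenting symptoms of the 67 patients.  Reconstructed from the published
#: percentages anchored on the seven asymptomatic patients; "other" is the
#: remainder after the four reported categories (synthetic reconstruction).
SYMPTOM_COUNTS: dict[str, int] = {
    "dizziness": 20,
    "headache": 19,
    "focal signs": 12,
    "asymptomatic": 7,
    "other": 9,
}


def example_counts() -> pd.DataFrame:
    """The 11x4 region-by-subtype lesion counts table."""
    frame = pd.DataFrame(
        _COUNTS.copy(), index=list(CANONICAL_REGIONS), columns=list(SUBTYPES)
    )
    frame.index.name = "region"
    frame.columns.name = "subtype"
    return frame


def example_records(atlas: RegionAtlas | None = None) -> pd.DataFrame:
    """A 437-row per-lesion records table expanding the counts matrix.

    Patient ids are synthetic, assigned round-robin within each subtype's
    patient pool; each record's COG is placed at the centroid of its region's
    box in the toy atlas (synthetic coordinates — the real per-lesion
    coordinates were never published).  Deterministic.
    """
    if atlas is None:
        atlas = build_toy_atlas()
    counts = example_counts()
    name_to_id = {v: k for k, v in atlas.labels.items()}
    centroids: dict[str, tuple] = {}
    for region in CANONICAL_REGIONS:
        lo, hi = atlas.bounding_box(name_to_id[region])
        center_idx = (lo + hi - 1) / 2.0
        mm = atlas.grid.voxel_to_world(center_idx)
        vox = atlas.grid.world_to_voxel(mm)
        centroids[region] = (mm, vox)

    rows = []
    for subtype in SUBTYPES:
        pool = [f"{subtype.replace(' ', '')}-{i + 1:02d}" for i in range(PATIENT_COUNTS[subtype])]
        cursor = 0
        for region in CANONICAL_REGIONS:
            for _ in range(int(counts.loc[region, subtype])):
                mm, vox = centroids[region]
                rows.append(
                    {
                        "patient_id": pool[cursor % len(pool)],
                        "subtype": subtype,
                        "cog_x_mm": float(mm[0]),
                        "cog_y_mm": float(mm[1]),
                        "cog_z_mm": float(mm[2]),
                        "i": int(vox[0]),
                        "j": int(vox[1]),
                        "k": int(vox[2]),
                        "region": region,
                    }
                )
                cursor += 1
    return pd.DataFrame(rows)


def symptom_table() -> pd.DataFrame:
    """Symptom counts with percentages of the 67 patients (one decimal)."""
    from .stats import _pct

    total = sum(SYMPTOM_COUNTS.values())
    return pd.DataFrame(
        {
            "count": list(SYMPTOM_COUNTS.values()),
            "percent": [_pct(v, total) for v in SYMPTOM_COUNTS.values()],
        },
        index=list(SYMPTOM_COUNTS),
    ).rename_axis("symptom")


def write_example_dataset(out_dir: str | Path) -> dict[str, Path]:
    """Write counts.tsv, records.tsv and symptoms.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "records": out / "records.tsv",
        "symptoms": out / "symptoms.tsv",
    }
    example_counts().to_csv(paths["counts"], sep="\t")
    example_records().to_csv(paths["records"], sep="\t", index=False)
    symptom_table().to_csv(paths["symptoms"], sep="\t")
    return paths
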