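"""End-to-end orchestration: configuration, the full analysis pipeline,
run manifests and human-readable reports.

A run takes lesion input in one of three forms — per-patient masks plus a
metadata TSV, a per-lesion records TSV, or a counts matrix TSV — and carries
it through tabulation, the chi-square test, adjusted-residual flagging and
group proportions, writing TSV/JSON outputs plus a manifest that captures the
configuration, input digests, seed and every warning the stages emitted.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grids import CANONICAL_REGIONS, RegionAtlas, build_toy_atlas, load_atlas, load_volume, save_volume
from .mapping import (
    SUBTYPES,
    frame_to_records,
    map_cohort,
    read_records,
    records_to_frame,
    write_records,
)
from .stats import (
    AnalysisConfig,
    ContingencyTable,
    adjusted_residuals,
    chi_square_independence,
    flag_significant,
    group_proportions,
    read_counts,
    tabulate,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class ConfigError(ValueError):
    """Configuration does not validate; the message lists offending keys."""


_SCHEMA: dict[str, type] = {
    "masks_dir": str,
    "metadata": str,
    "records": str,
    "counts": str,
    "atlas_volume": str,
    "atlas_labels": str,
    "use_toy_atlas": bool,
    "diameter_mm": (int, float),
    "connectivity": int,
    "z": (int, float),
    "alpha": (int, float),
    "mc_reps": int,
    "seed": int,
}

_DEFAULTS: dict[str, Any] = {
    "use_toy_atlas": False,
    "diameter_mm": 20.0,
    "connectivity": 26,
    "z": 1.96,
    "alpha": 0.05,
    "mc_reps": 0,
    "seed": 0,
}


@dataclass
class PipelineConfig:
    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        bad_keys = sorted(set(d) - set(_SCHEMA))
        bad_types = sorted(
            k for k, v in d.items()
            if k in _SCHEMA and v is not None and not isinstance(v, _SCHEMA[k])
        )
        problems = []
        if bad_keys:
            problems.append(f"unknown keys: {bad_keys}")
        if bad_types:
            problems.append(f"wrong types for keys: {bad_types}")
        merged = {**_DEFAULTS, **{k: v for k, v in d.items() if v is not None}}
        sources = [k for k in ("masks_dir", "records", "counts") if merged.get(k)]
        if len(sources) != 1:
            problems.append(
                f"exactly one of masks_dir / records / counts is required, got {sources}"
            )
        if merged.get("masks_dir") and not merged.get("metadata"):
            problems.append("masks_dir requires metadata")
        if not merged.get("use_toy_atlas") and not merged.get("counts"):
            if not (merged.get("atlas_volume") and merged.get("atlas_labels")):
                problems.append(
                    "atlas_volume and atlas_labels are required unless use_toy_atlas is true"
                )
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))
        return cls(raw=merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a key-value mapping")
        return cls.from_dict(data)

    def __getitem__(self, key: str) -> Any:
        return self.raw[key]

    def get(self, key: str, default: Any = None) -> Any:
        return self.raw.get(key, default)


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(f"{record.name}: {record.getMessage()}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_full_pipeline(config: PipelineConfig | Mapping[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run masks/records/counts through the full spatial-distribution analysis.

    Writes records.tsv (when per-lesion input is available), heatmap.nii.gz,
    counts.tsv, expected.tsv, residuals.tsv, flags.tsv, percentages.tsv,
    analysis.json, report.txt, residuals.png and manifest.json into
    ``out_dir``; returns the analysis summary dict.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(dict(config))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    collector = _WarningCollector()
    pkg_logger = logging.getLogger("brainmets")
    pkg_logger.addHandler(collector)
    input_digests: dict[str, str] = {}
    try:
        atlas: RegionAtlas | None = None
        with _stage("atlas"):
            if config.get("use_toy_atlas"):
                atlas = build_toy_atlas()
            elif config.get("atlas_volume"):
                atlas = load_atlas(config["atlas_volume"], config["atlas_labels"])
                input_digests["atlas_volume"] = _sha256(Path(config["atlas_volume"]))
                input_digests["atlas_labels"] = _sha256(Path(config["atlas_labels"]))

        records_frame: pd.DataFrame | None = None
        table: ContingencyTable
        if config.get("masks_dir"):
            with _stage("map"):
                masks_dir = Path(config["masks_dir"])
                masks = {}
                for p in sorted(masks_dir.glob("*.nii*")):
                    pid = p.name.split(".nii")[0]
                    masks[pid] = load_volume(p)
                    input_digests[f"mask:{p.name}"] = _sha256(p)
                metadata = pd.read_csv(config["metadata"], sep="\t", dtype={"patient_id": str})
                input_digests["metadata"] = _sha256(Path(config["metadata"]))
                records = map_cohort(masks, metadata, atlas, connectivity=config["connectivity"])
                records_frame = records_to_frame(records)
        elif config.get("records"):
            with _stage("load-records"):
                records_frame = read_records(config["records"])
                input_digests["records"] = _sha256(Path(config["records"]))

        if records_frame is not None:
            with _stage("tabulate"):
                table = tabulate(records_frame, list(CANONICAL_REGIONS), list(SUBTYPES))
                records_frame.to_csv(out / "records.tsv", sep="\t", index=False)
        else:
            with _stage("load-counts"):
                table = read_counts(config["counts"])
                input_digests["counts"] = _sha256(Path(config["counts"]))

        if records_frame is not None and atlas is not None:
            with _stage("heatmap"):
                from .mapping import build_frequency_map

                recs = frame_to_records(records_frame)
                fmap = build_frequency_map(recs, atlas.grid, diameter_mm=config["diameter_mm"])
                save_volume(fmap.grid, out / "heatmap.nii.gz")

        with _stage("analyze"):
            acfg = AnalysisConfig(
                z=config["z"],
                alpha=config["alpha"],
                mc_reps=config["mc_reps"],
                seed=config["seed"],
            )
            chi = chi_square_independence(table, acfg)
            resid = adjusted_residuals(table, acfg)
            flags = flag_significant(resid)
            pct = group_proportions(table)

        with _stage("write"):
            table.observed.to_csv(out / "counts.tsv", sep="\t")
            resid.expected.to_csv(out / "expected.tsv", sep="\t", float_format="%.6f")
            resid.adjusted.to_csv(out / "residuals.tsv", sep="\t", float_format="%.6f")
            pd.DataFrame(flags, columns=["region", "subtype", "direction"]).to_csv(
                out / "flags.tsv", sep="\t", index=False
            )
            pct.to_csv(out / "percentages.tsv", sep="\t", float_format="%.1f")
            summary = {
                "statistic": chi.statistic,
                "df": chi.df,
                "p": chi.p,
                "p_monte_carlo": chi.p_monte_carlo,
                "mc_reps": chi.mc_reps,
                "alpha": config["alpha"],
                "significant": chi.p < config["alpha"],
                "z": config["z"],
                "n_lesions": table.grand_total,
                "dropped_rows": chi.dropped_rows,
                "dropped_cols": chi.dropped_cols,
                "small_expected_fraction": chi.small_expected_fraction,
                "flags": [
                    {"region": r, "subtype": s, "direction": d} for r, s, d in flags
                ],
            }
            (out / "analysis.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

        with _stage("report"):
            render_report(out)

        with _stage("manifest"):
            manifest = {
                "command": "run",
                "config": dict(config.raw),
                "input_digests": input_digests,
                "seed": config["seed"],
                "version": __version__,
                "warnings": list(collector.messages),
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
            }
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    finally:
        pkg_logger.removeHandler(collector)
    return summary


# --- report ----------------------------------------------------------------

def format_counts_table(counts: pd.DataFrame, pct: pd.DataFrame) -> str:
    """Counts-with-percentages text table, one row per region."""
    groups = list(counts.columns)
    header = ["Location", f"All n={int(counts.to_numpy().sum())} (%)"] + [
        f"{g} n={int(counts[g].sum())} (%)" for g in groups
    ]
    lines = ["\t".join(header)]
    row_tot = counts.sum(axis=1)
    for region in counts.index:
        cells = [str(region).capitalize(), f"{int(row_tot[region])} ({pct.loc[region, 'all']:.1f})"]
        for g in groups:
            val = pct.loc[region, g]
            shown = "-" if pd.isna(val) else f"{val:.1f}"
            cells.append(f"{int(counts.loc[region, g])} ({shown})")
        lines.append("\t".join(cells))
    return "\n".join(lines)


def render_report(out_dir: str | Path) -> str:
    """Build report.txt and residuals.png from a pipeline output directory.

    The text report shows the counts-with-percentages table and the test
    summary; the chart plots each cell's adjusted residual per region with
    dashed reference lines at +/- z.
    """
    out = Path(out_dir)
    counts_path = out / "counts.tsv"
    analysis_path = out / "analysis.json"
    if not counts_path.exists() or not analysis_path.exists():
        raise FileNotFoundError(
            f"missing analysis outputs in {out} (need counts.tsv and analysis.json)"
        )
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    resid = pd.read_csv(out / "residuals.tsv", sep="\t", index_col=0)
    pct = pd.read_csv(out / "percentages.tsv", sep="\t", index_col=0)
    summary = json.loads(analysis_path.read_text())

    lines = ["Distribution of brain metastases", ""]
    lines.append(format_counts_table(counts, pct))
    lines.append("")
    lines.append(
        f"Chi-square test of independence: X2 = {summary['statistic']:.3f}, "
        f"df = {summary['df']}, P = {summary['p']:.4f}"
    )
    if summary.get("p_monte_carlo") is not None:
        lines.append(
            f"Monte-Carlo P = {summary['p_monte_carlo']:.4f} ({summary['mc_reps']} resamples)"
        )
    z = summary["z"]
    lines.append(f"Cells with |adjusted residual| > {z}:")
    for f in summary["flags"]:
        lines.append(f"  {f['region']} / {f['subtype']}: {f['direction']}-represented")
    if not summary["flags"]:
        lines.append("  none")
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4.5))
    x = np.arange(len(resid.index))
    markers = ["o", "s", "^", "D"]
    for m, group in zip(markers, resid.columns):
        ax.scatter(x, resid[group], marker=m, label=group)
    ax.axhline(z, linestyle=":", color="gray")
    ax.axhline(-z, linestyle=":", color="gray")
    ax.set_xticks(x)
    ax.set_xticklabels(resid.index, rotation=45, ha="right")
    ax.set_ylabel("adjusted residual")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "residuals.png", dpi=120)
    plt.close(fig)
    return text
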