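"""Contingency-table statistics for region-by-subtype lesion counts.

The core analysis is a Pearson chi-square test of independence on the
region x subtype table of lesion counts, followed by adjusted (standardized)
residual analysis:

    r_ij = (O_ij - E_ij) / sqrt(E_ij (1 - n_i./N) (1 - n_.j/N))

Under independence each r_ij is approximately standard normal, so cells with
|r_ij| > 1.96 mark regions where a subtype's metastases are over- or
under-represented at the 5% level.  A Kruskal-Wallis test is provided for
comparing cohort covariates (age, intervals, lesion counts) across subtypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the contingency analysis.

    z: flag threshold on adjusted residuals (1.96 ~ two-sided 5% level).
    alpha: significance level for the chi-square p-value.
    continuity: Yates correction for 2x2 tables (off by default; the
        headline analysis is a multi-df table).
    mc_reps: if > 0, also compute a Monte-Carlo p-value with this many
        resamples under the fitted independence model.
    """

    z: float = 1.96
    alpha: float = 0.05
    continuity: bool = False
    mc_reps: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.z <= 0:
            raise ValueError("z threshold must be positive")


@dataclass
class ContingencyTable:
    """Observed region x group counts with margins."""

    observed: pd.DataFrame  # rows: regions, columns: groups

    def __post_init__(self) -> None:
        obs = self.observed
        arr = obs.to_numpy()
        if np.any(arr < 0):
            raise ValueError("observed counts must be non-negative")
        if not np.all(arr == np.round(arr)):
            raise ValueError("observed counts must be integers")
        self.observed = obs.astype(int)

    @property
    def row_totals(self) -> pd.Series:
        return self.observed.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.observed.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.observed.to_numpy().sum())

    def expected(self) -> pd.DataFrame:
        N = self.grand_total
        if N == 0:
            raise ValueError("table is empty (grand total 0)")
        E = np.outer(self.row_totals, self.col_totals) / N
        return pd.DataFrame(E, index=self.observed.index, columns=self.observed.columns)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    p_monte_carlo: float | None = None
    mc_reps: int = 0
    dropped_rows: list[str] = field(default_factory=list)
    dropped_cols: list[str] = field(default_factory=list)
    small_expected_fraction: float = 0.0


@dataclass
class ResidualTable:
    expected: pd.DataFrame
    raw: pd.DataFrame
    adjusted: pd.DataFrame
    z: float

    @property
    def flags(self) -> pd.DataFrame:
        return self.adjusted.abs() > self.z


def tabulate(
    records: pd.DataFrame | Iterable,
    regions: Sequence[str],
    groups: Sequence[str],
) -> ContingencyTable:
    """Count records into a region x group table, keeping all-zero rows.

    ``"unassigned"`` records are excluded with a logged count; any other
    region outside ``regions`` is an error.
    """
    if len(regions) == 0 or len(groups) == 0:
        raise ValueError("region and group lists must be non-empty")
    if not isinstance(records, pd.DataFrame):
        from .mapping import records_to_frame

        records = records_to_frame(list(records))
    frame = records
    unassigned = int((frame["region"] == "unassigned").sum())
    if unassigned:
        logger.warning("excluding %d unassigned lesion(s) from the table", unassigned)
        frame = frame[frame["region"] != "unassigned"]
    unknown = sorted(set(frame["region"]) - set(regions))
    if unknown:
        raise ValueError(f"records contain regions outside the region list: {unknown}")
    unknown_g = sorted(set(frame["subtype"]) - set(groups))
    if unknown_g:
        raise ValueError(f"records contain groups outside the group list: {unknown_g}")
    counts = (
        pd.crosstab(frame["region"], frame["subtype"])
        .reindex(index=list(regions), columns=list(groups), fill_value=0)
        .fillna(0)
        .astype(int)
    )
    counts.index.name = "region"
    counts.columns.name = "subtype"
    return ContingencyTable(observed=counts)


def _drop_empty(table: ContingencyTable) -> tuple[pd.DataFrame, list[str], list[str]]:
    obs = table.observed
    empty_rows = [str(i) for i in obs.index[obs.sum(axis=1) == 0]]
    empty_cols = [str(c) for c in obs.columns[obs.sum(axis=0) == 0]]
    if empty_rows or empty_cols:
        logger.warning(
            "dropping empty rows %s and columns %s before chi-square test",
            empty_rows,
            empty_cols,
        )
    kept = obs.loc[obs.sum(axis=1) > 0, obs.sum(axis=0) > 0]
    return kept, empty_rows, empty_cols


def chi_square_independence(
    table: ContingencyTable, config: AnalysisConfig | None = None
) -> ChiSquareResult:
    """Pearson chi-square test of independence on the counts table.

    Empty rows/columns are dropped (with a warning) before testing; a table
    that degenerates to a single row or column is an error.  When more than
    20% of cells have expected counts below 5 a warning is logged and, if
    ``config.mc_reps > 0``, a Monte-Carlo p-value is computed alongside the
    analytic one by multinomial resampling of N cells from the fitted
    independence probabilities p_ij = (n_i./N)(n_.j/N).
    """
    config = config or AnalysisConfig()
    obs, dropped_rows, dropped_cols = _drop_empty(table)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError(
            f"degenerate table after dropping empties: shape {obs.shape}; "
            "need at least 2 rows and 2 columns"
        )
    O = obs.to_numpy(dtype=float)
    N = O.sum()
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / N
    if config.continuity and O.shape == (2, 2):
        X2 = float(((np.abs(O - E) - 0.5).clip(min=0) ** 2 / E).sum())
    else:
        X2 = float(((O - E) ** 2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(sps.chi2.sf(X2, df))

    small_frac = float((E < 5).mean())
    if small_frac > 0.2:
        logger.warning(
            "%.0f%% of cells have expected counts < 5; the analytic p-value "
            "relies on the chi-square approximation",
            100 * small_frac,
        )

    p_mc = None
    if config.mc_reps > 0:
        rng = np.random.default_rng(config.seed)
        probs = (E / N).ravel()
        ge = 0
        n_int = int(round(N))
        for _ in range(config.mc_reps):
            sim = rng.multinomial(n_int, probs).reshape(O.shape).astype(float)
            r = sim.sum(axis=1)
            c = sim.sum(axis=0)
            Es = np.outer(r, c) / N
            with np.errstate(divide="ignore", invalid="ignore"):
                cells = np.where(Es > 0, (sim - Es) ** 2 / Es, 0.0)
            if cells.sum() >= X2 - 1e-12:
                ge += 1
        p_mc = (ge + 1) / (config.mc_reps + 1)

    return ChiSquareResult(
        statistic=X2,
        df=df,
        p=p,
        p_monte_carlo=p_mc,
        mc_reps=config.mc_reps,
        dropped_rows=dropped_rows,
        dropped_cols=dropped_cols,
        small_expected_fraction=small_frac,
    )


def adjusted_residuals(
    table: ContingencyTable, config: AnalysisConfig | None = None
) -> ResidualTable:
    """Adjusted (standardized) residuals for every cell of the table.

    Cells with zero expected count get residual 0 with a warning; raw
    residual rows and columns sum to zero by construction.
    """
    config = config or AnalysisConfig()
    obs = table.observed
    O = obs.to_numpy(dtype=float)
    N = O.sum()
    if N == 0:
        raise ValueError("table is empty (grand total 0)")
    r = O.sum(axis=1, keepdims=True)
    c = O.sum(axis=0, keepdims=True)
    E = r * c / N
    raw = O - E
    var = E * (1 - r / N) * (1 - c / N)
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = np.where(var > 0, raw / np.sqrt(var), 0.0)
    if np.any(var <= 0):
        logger.warning(
            "%d cell(s) have zero expected count; their residuals are set to 0",
            int((var <= 0).sum()),
        )
    idx, cols = obs.index, obs.columns
    return ResidualTable(
        expected=pd.DataFrame(E, index=idx, columns=cols),
        raw=pd.DataFrame(raw, index=idx, columns=cols),
        adjusted=pd.DataFrame(adj, index=idx, columns=cols),
        z=config.z,
    )


def flag_significant(residuals: ResidualTable) -> list[tuple[str, str, str]]:
    """Cells whose |adjusted residual| exceeds the threshold, with direction."""
    out = []
    adj = residuals.adjusted
    for region in adj.index:
        for group in adj.columns:
            r = adj.loc[region, group]
            if abs(r) > residuals.z:
                out.append((str(region), str(group), "over" if r > 0 else "under"))
    return out


def _pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal, as printed tables do."""
    q = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


def group_proportions(table: ContingencyTable) -> pd.DataFrame:
    """Column-wise percentages (one decimal, half-up), plus an overall column.

    The ``all`` column is each region's share of the grand total; each group
    column is the region's share within that group.  Groups with zero total
    get blank (NaN) entries and a warning.
    """
    obs = table.observed
    N = table.grand_total
    out = pd.DataFrame(index=obs.index, dtype=float)
    if N == 0:
        logger.warning("empty table: all proportions blank")
        out["all"] = np.nan
        for g in obs.columns:
            out[g] = np.nan
        return out
    out["all"] = [_pct(int(v), N) for v in table.row_totals]
    for g in obs.columns:
        tot = int(table.col_totals[g])
        if tot == 0:
            logger.warning("group %r has zero total; proportions blank", str(g))
            out[g] = np.nan
        else:
            out[g] = [_pct(int(v), tot) for v in obs[g]]
    return out


def kruskal_wallis(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis rank test across groups (tie-corrected).

    All-identical values across all groups give (H=0, p=1) rather than an
    error; fewer than two groups, or an empty group, is an error.
    """
    if isinstance(groups, Mapping):
        samples = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        samples = [np.asarray(v, dtype=float) for v in groups]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for i, s in enumerate(samples):
        if s.size == 0:
            raise ValueError(f"group {i} is empty")
    allvals = np.concatenate(samples)
    if np.all(allvals == allvals[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*samples)
    return float(H), float(p)


# --- table I/O -------------------------------------------------------------

def read_counts(path) -> ContingencyTable:
    """Read a counts matrix TSV (first column = region names)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ContingencyTable(observed=frame)


def write_counts(table: ContingencyTable, path) -> None:
    table.observed.to_csv(path, sep="\t")
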