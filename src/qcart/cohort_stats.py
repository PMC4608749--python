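"""Cohort-level tables and regressions.

Assembles per-specimen ROI statistics into the study's summary tables,
computes the viable-vs-necrotic percent-difference statistic, and runs the
time-course and MRI-vs-histology regressions.

The percent difference used throughout is the symmetric form

    100 * (a - b) / ((a + b) / 2)

i.e. the difference relative to the mean of the two values, with ``a`` the
larger (the necrotic relaxation time, or the viable optical density).  This
definition — rather than percent-of-smaller or percent-of-larger — is the one
that reproduces the published difference columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datasets import PARAMETERS

__all__ = [
    "SpecimenRecord",
    "RegressionResult",
    "percent_difference",
    "build_relaxation_table",
    "build_difference_table",
    "fit_line",
    "od_time_regressions",
    "mri_vs_od_regression",
]


@dataclass
class SpecimenRecord:
    """Per-ROI summary statistics of one animal / harvest time point.

    ``stats`` maps (parameter, roi) -> (mean, sd); relaxation times in ms
    except T1, carried in seconds to mirror the published table.  ``od_stats``
    maps roi -> (mean, sd) of safranin-O optical density.  A specimen whose
    lesion showed no histologically evident chondronecrosis sets
    ``histological_necrosis=False`` and is excluded from the OD time
    regressions by default.
    """

    week: int
    lesion_class: str  # "LARGE" (5x5 mm incision) or "SMALL" (3x4 mm incision)
    stats: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    od_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    histological_necrosis: bool = True

    def __post_init__(self) -> None:
        if self.week <= 0:
            raise ValueError("week must be a positive integer")
        if self.lesion_class not in ("LARGE", "SMALL"):
            raise ValueError("lesion_class must be LARGE or SMALL")


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least-squares line fit."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def percent_difference(a: float, b: float) -> float:
    """Symmetric percent difference ``100*(a - b)/mean(a, b)``.

    Antisymmetric in its arguments and bounded in (-200, 200) for positive
    inputs.  The published tables report it with ``a`` the larger value.
    """
    if a <= 0 or b <= 0:
        raise ValueError("percent_difference requires positive inputs")
    return 100.0 * (a - b) / ((a + b) / 2.0)


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the printed-table convention)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


def build_relaxation_table(records: Iterable[SpecimenRecord]) -> pd.DataFrame:
    """Long-format relaxation table: week x parameter x ROI -> mean, sd.

    Missing (parameter, ROI) entries are simply absent rows; duplicate
    (week, parameter, roi) combinations raise.
    """
    rows = []
    for rec in records:
        for (param, roi), (mean, sd) in sorted(rec.stats.items()):
            rows.append(
                {"week": rec.week, "lesion_class": rec.lesion_class,
                 "parameter": param, "roi": roi, "mean": mean, "sd": sd}
            )
    table = pd.DataFrame(rows, columns=["week", "lesion_class", "parameter", "roi", "mean", "sd"])
    if len(table) and table.duplicated(["week", "parameter", "roi"]).any():
        dup = table[table.duplicated(["week", "parameter", "roi"], keep=False)]
        raise ValueError(f"duplicate (week, parameter, roi) entries:\n{dup}")
    return table


def relaxation_table_to_records(table: pd.DataFrame) -> list[SpecimenRecord]:
    """Inverse of :func:`build_relaxation_table` (round-trip identity)."""
    records = []
    for (week, lesion_class), grp in table.groupby(["week", "lesion_class"], sort=True):
        stats = {
            (row.parameter, row.roi): (row.mean, row.sd)
            for row in grp.itertuples()
        }
        records.append(SpecimenRecord(week=int(week), lesion_class=lesion_class, stats=stats))
    return records


def build_difference_table(
    relax_table: pd.DataFrame,
    parameters: Sequence[str] = PARAMETERS,
) -> pd.DataFrame:
    """Viable-vs-necrotic percent difference per week and parameter.

    Applies ``percent_difference(necrotic_mean, viable_mean)`` cell-wise;
    cells lacking either mean stay NaN (missing data never become zeros).
    Returns a week-indexed wide table with one column per parameter.
    """
    means = relax_table.pivot_table(
        index="week", columns=["parameter", "roi"], values="mean", aggfunc="first"
    )
    weeks = means.index
    out = pd.DataFrame(index=weeks, columns=list(parameters), dtype=float)
    for param in parameters:
        for week in weeks:
            try:
                viable = means.loc[week, (param, "viable")]
                necrotic = means.loc[week, (param, "necrotic")]
            except KeyError:
                continue
            if pd.notna(viable) and pd.notna(necrotic):
                out.loc[week, param] = percent_difference(necrotic, viable)
    out.index.name = "week"
    return out


def fit_line(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with ``R^2 = 1 - SS_res/SS_tot``.

    Constant x raises; constant y returns slope 0 with R^2 defined as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two paired points")
    if np.ptp(x) == 0:
        raise ValueError("x values are constant; the line is not identifiable")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0, int(x.size))
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(x.size),
    )


def od_time_regressions(
    records: Iterable[SpecimenRecord],
    include_no_necrosis: bool = False,
) -> dict[str, RegressionResult]:
    """OLS of viable OD, necrotic OD and their percent difference vs week.

    Specimens flagged ``histological_necrosis=False`` are excluded unless
    ``include_no_necrosis`` (their apparent OD drop has no histological
    lesion behind it, so they distort the necrosis time course).
    """
    recs = [
        r for r in records
        if (r.histological_necrosis or include_no_necrosis)
        and "viable" in r.od_stats and "necrotic" in r.od_stats
    ]
    if len(recs) < 3:
        raise ValueError("need at least 3 specimens with OD statistics")
    weeks = [r.week for r in recs]
    viable = [r.od_stats["viable"][0] for r in recs]
    necrotic = [r.od_stats["necrotic"][0] for r in recs]
    pct = [percent_difference(v, n) for v, n in zip(viable, necrotic)]
    return {
        "viable": fit_line(weeks, viable),
        "necrotic": fit_line(weeks, necrotic),
        "pct_diff": fit_line(weeks, pct),
    }


def mri_vs_od_regression(
    diff_table: pd.DataFrame,
    od_diff_by_week: Mapping[int, float],
    include_params: Sequence[str] | None = None,
    include_weeks: Sequence[int] | None = None,
) -> tuple[RegressionResult, pd.DataFrame]:
    """Pooled OLS of relaxation %-differences on the OD %-difference.

    Every non-null (week, parameter) relaxation percent difference becomes a
    point with x = that week's OD percent difference.  The inclusion set is
    configurable: restrict parameters (e.g. drop T1) or weeks.  Returns the
    fit and the paired points used.
    """
    params = list(include_params) if include_params is not None else list(diff_table.columns)
    weeks = list(include_weeks) if include_weeks is not None else list(diff_table.index)
    pts = []
    for week in weeks:
        if week not in od_diff_by_week:
            continue
        for param in params:
            y = diff_table.loc[week, param]
            if pd.notna(y):
                pts.append({"week": week, "parameter": param,
                            "od_pct_diff": float(od_diff_by_week[week]),
                            "relax_pct_diff": float(y)})
    points = pd.DataFrame(pts, columns=["week", "parameter", "od_pct_diff", "relax_pct_diff"])
    if len(points) < 3:
        raise ValueError("need at least 3 paired points")
    fit = fit_line(points["od_pct_diff"], points["relax_pct_diff"])
    return fit, points
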