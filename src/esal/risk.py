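"""Annual cyanobacterial-bloom risk statistic from daily condition records.

A bloom needs warm water and sufficient nutrients.  For each year ``i`` with
``n_i`` daily records, let ``n_Ti`` be the number of days with water
temperature strictly below the lowest temperature at which blooms have been
observed, and ``n_Pi`` / ``n_Ni`` the analogous counts for total phosphorus
and total nitrogen concentrations.  The annual statistic is

    x_i = 1 - [(n_i - n_Ti)/n_i] * [(n_i - n_Pi)/n_i] * [(n_i - n_Ni)/n_i]

Each bracket is the fraction of days on which one bloom precondition was met,
so the product shrinks as bloom-capable days accumulate.  ``x_i`` lies in
[0, 1] and, as defined, is *higher when conditions are safer*: a year in
which every day is cold (or nutrient-poor) gives ``x_i = 1``, while a year
in which every day satisfies all three bloom preconditions gives ``x_i = 0``.
It therefore enters the index pipeline as a benefit-direction indicator by
default; ``to_indicator_series`` accepts an explicit override for users who
prefer to treat it as a cost.

Counting uses strict inequality: a record exactly at a threshold is *not*
below it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataValidationError
from .panel import IndicatorSeries

DAILY_CSV_COLUMNS = ["year", "day_index", "temperature", "tp", "tn"]

RISK_INDICATOR_ID = "bloom_risk"


@dataclass(frozen=True)
class DailyConditionRecord:
    """One dated observation of temperature (°C), TP and TN (mg/L)."""

    year: int
    day_index: int
    temperature: float
    tp: float
    tn: float

    def __post_init__(self) -> None:
        if self.tp < 0 or self.tn < 0:
            raise DataValidationError(
                f"negative nutrient concentration in year {self.year}, "
                f"day {self.day_index}"
            )


@dataclass(frozen=True)
class BloomThresholds:
    """Lowest temperature / TP / TN recorded when blooms occur.

    Attributes
    ----------
    t_min : float
        Lowest water temperature (°C) at which a bloom has been observed.
    tp_min, tn_min : float
        Lowest total phosphorus / total nitrogen concentrations (mg/L) at
        which a bloom has been observed.
    """

    t_min: float
    tp_min: float
    tn_min: float

    def __post_init__(self) -> None:
        if self.tp_min < 0 or self.tn_min < 0:
            raise ConfigurationError("bloom nutrient thresholds must be >= 0")


class YearCounts(NamedTuple):
    """Per-year record counts entering the bloom-risk statistic."""

    n: int
    n_t: int
    n_p: int
    n_n: int


@dataclass
class RiskSeries:
    """Annual bloom-risk values with the underlying counts, for audit."""

    years: np.ndarray
    values: np.ndarray
    counts: list[YearCounts]

    def to_indicator_series(
        self, indicator_id: str = RISK_INDICATOR_ID, direction: str = "benefit"
    ) -> IndicatorSeries:
        """Package as a risk-category (R) indicator for the index pipeline."""
        return IndicatorSeries(
            id=indicator_id, category="R", direction=direction,
            values=self.values.copy(), name="cyanobacterial bloom risk statistic",
        )

    def to_json(self) -> str:
        payload = [
            {"year": int(y), "value": float(v),
             "n": c.n, "n_t": c.n_t, "n_p": c.n_p, "n_n": c.n_n}
            for y, v, c in zip(self.years, self.values, self.counts)
        ]
        return json.dumps(payload, indent=2)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def risk_from_counts(n: int, n_t: int, n_p: int, n_n: int) -> float:
    """Evaluate the bloom-risk formula from pre-tabulated counts."""
    if n <= 0:
        raise DataValidationError("bloom risk undefined for a year with no records")
    for label, c in (("n_t", n_t), ("n_p", n_p), ("n_n", n_n)):
        if not 0 <= c <= n:
            raise DataValidationError(f"count {label}={c} outside [0, {n}]")
    return 1.0 - ((n - n_t) / n) * ((n - n_p) / n) * ((n - n_n) / n)


def bloom_risk_year(
    records: pd.DataFrame, thresholds: BloomThresholds
) -> tuple[float, YearCounts]:
    """Annual bloom-risk value for one year of daily records.

    ``records`` needs columns ``temperature``, ``tp``, ``tn``; rows are the
    daily observations of a single year.
    """
    n = len(records)
    if n == 0:
        raise DataValidationError("bloom risk undefined for a year with no records")
    temperature = records["temperature"].to_numpy(dtype=float)
    tp = records["tp"].to_numpy(dtype=float)
    tn = records["tn"].to_numpy(dtype=float)
    if (tp < 0).any() or (tn < 0).any():
        raise DataValidationError("negative nutrient concentration in daily records")
    counts = YearCounts(
        n=n,
        n_t=int((temperature < thresholds.t_min).sum()),
        n_p=int((tp < thresholds.tp_min).sum()),
        n_n=int((tn < thresholds.tn_min).sum()),
    )
    return risk_from_counts(*counts), counts


def bloom_risk_series(
    daily: pd.DataFrame,
    thresholds: BloomThresholds,
    years: np.ndarray | None = None,
) -> RiskSeries:
    """Annual bloom-risk series over every year present in the records.

    Parameters
    ----------
    daily
        Daily records with columns ``year, temperature, tp, tn`` (extra
        columns are ignored).
    thresholds
        Bloom-occurrence thresholds.
    years
        Optional explicit year range the series must cover; a year in this
        range with no records raises an error naming the year.
    """
    if daily.empty:
        raise DataValidationError("no daily records supplied")
    present = np.sort(daily["year"].unique())
    if years is None:
        years = present
    else:
        years = np.asarray(years, dtype=int)
        missing = sorted(set(years.tolist()) - set(int(y) for y in present))
        if missing:
            raise DataValidationError(f"no daily records for year {missing[0]}")
    values = np.empty(len(years), dtype=float)
    counts: list[YearCounts] = []
    grouped = daily.groupby("year")
    for k, year in enumerate(years):
        values[k], c = bloom_risk_year(grouped.get_group(year), thresholds)
        counts.append(c)
    return RiskSeries(years=np.asarray(years, dtype=int), values=values, counts=counts)


def read_daily_csv(path: str | Path) -> pd.DataFrame:
    """Read daily condition records (``year,day_index,temperature,tp,tn``)."""
    frame = pd.read_csv(path)
    missing = [c for c in DAILY_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise DataValidationError(f"daily records missing columns: {missing}")
    return frame


def write_daily_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, columns=DAILY_CSV_COLUMNS)
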