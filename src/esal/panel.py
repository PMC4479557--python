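"""Annual indicator panels for DPSIR-style assessments.

An :class:`IndicatorPanel` holds one annual time series per indicator over a
contiguous range of calendar years, together with the DPSIR category
(driving force ``D``, pressure ``P``, status ``S``, impact ``I``, risk ``R``)
and the direction of each indicator.  A *benefit* indicator improves the
system as it rises (e.g. dissolved oxygen); a *cost* indicator worsens it
(e.g. a pollutant load).  The direction decides which baseline-ratio
normalization applies downstream.

The on-disk representation is a long-format CSV with header
``year,indicator_id,category,direction,value``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataValidationError

CATEGORIES = ("D", "P", "S", "I", "R")
DIRECTIONS = ("benefit", "cost")

PANEL_CSV_COLUMNS = ["year", "indicator_id", "category", "direction", "value"]


@dataclass
class IndicatorSeries:
    """One named annual series with its DPSIR category and direction."""

    id: str
    category: str
    direction: str
    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise DataValidationError(
                f"indicator {self.id!r}: category must be one of {CATEGORIES}, "
                f"got {self.category!r}"
            )
        if self.direction not in DIRECTIONS:
            raise DataValidationError(
                f"indicator {self.id!r}: direction must be one of {DIRECTIONS}, "
                f"got {self.direction!r}"
            )
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataValidationError(f"indicator {self.id!r}: values must be 1-D")
        if not self.name:
            self.name = self.id


@dataclass
class IndicatorPanel:
    """Aligned collection of indicator series over a contiguous year range.

    Parameters
    ----------
    years
        Contiguous, ordered calendar years.
    baseline_year
        Reference ("background") year used for ratio normalization; must lie
        within ``years``.
    series
        Mapping from indicator id to :class:`IndicatorSeries`; every series
        must have one value per year.
    """

    years: np.ndarray
    baseline_year: int
    series: dict[str, IndicatorSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if self.years.size == 0:
            raise DataValidationError("panel must cover at least one year")
        if not np.array_equal(self.years, np.arange(self.years[0], self.years[-1] + 1)):
            raise DataValidationError("panel years must be contiguous and ascending")
        if self.baseline_year not in self.years:
            raise DataValidationError(
                f"baseline year {self.baseline_year} outside panel range "
                f"{self.years[0]}..{self.years[-1]}"
            )
        for sid, s in self.series.items():
            if sid != s.id:
                raise DataValidationError(f"series key {sid!r} does not match id {s.id!r}")
            if len(s.values) != len(self.years):
                raise DataValidationError(
                    f"indicator {sid!r}: {len(s.values)} values for "
                    f"{len(self.years)} years"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def ids(self) -> list[str]:
        return list(self.series)

    def category_ids(self, category: str) -> list[str]:
        """Ids of all indicators in one DPSIR category, in panel order."""
        return [sid for sid, s in self.series.items() if s.category == category]

    def year_index(self, year: int) -> int:
        if year not in self.years:
            raise DataValidationError(f"year {year} outside panel range")
        return int(np.where(self.years == year)[0][0])

    def values_frame(self, ids: Iterable[str] | None = None) -> pd.DataFrame:
        """Wide DataFrame of values, indexed by year, one column per indicator."""
        ids = list(ids) if ids is not None else self.ids
        data = {sid: self.series[sid].values for sid in ids}
        return pd.DataFrame(data, index=pd.Index(self.years, name="year"))

    def subset(self, ids: Iterable[str]) -> "IndicatorPanel":
        """Panel restricted to the given indicator ids (metadata preserved)."""
        keep = [sid for sid in self.ids if sid in set(ids)]
        return IndicatorPanel(
            years=self.years.copy(),
            baseline_year=self.baseline_year,
            series={sid: replace(self.series[sid], values=self.series[sid].values.copy())
                    for sid in keep},
        )

    def add_series(self, s: IndicatorSeries) -> None:
        if s.id in self.series:
            raise DataValidationError(f"duplicate indicator id {s.id!r}")
        if len(s.values) != len(self.years):
            raise DataValidationError(
                f"indicator {s.id!r}: {len(s.values)} values for {len(self.years)} years"
            )
        self.series[s.id] = s

    def validate_positive(self) -> None:
        """Raise if any value is non-positive, naming indicator and year."""
        for sid, s in self.series.items():
            bad = np.where(s.values <= 0)[0]
            if bad.size:
                year = int(self.years[bad[0]])
                raise DataValidationError(
                    f"indicator {sid!r} has non-positive value "
                    f"{s.values[bad[0]]!r} in year {year}"
                )

    # -- CSV round trip ----------------------------------------------------

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for sid, s in self.series.items():
            for year, value in zip(self.years, s.values):
                rows.append((int(year), sid, s.category, s.direction, float(value)))
        return pd.DataFrame(rows, columns=PANEL_CSV_COLUMNS)

    def write_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame, baseline_year: int) -> "IndicatorPanel":
        missing = [c for c in PANEL_CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise DataValidationError(f"panel table missing columns: {missing}")
        years = np.sort(frame["year"].unique())
        series: dict[str, IndicatorSeries] = {}
        for sid, grp in frame.groupby("indicator_id", sort=False):
            grp = grp.sort_values("year")
            if not np.array_equal(grp["year"].to_numpy(), years):
                raise DataValidationError(
                    f"indicator {sid!r} does not cover every panel year"
                )
            cats = grp["category"].unique()
            dirs = grp["direction"].unique()
            if len(cats) != 1 or len(dirs) != 1:
                raise DataValidationError(
                    f"indicator {sid!r} has inconsistent category/direction tags"
                )
            series[str(sid)] = IndicatorSeries(
                id=str(sid), category=str(cats[0]), direction=str(dirs[0]),
                values=grp["value"].to_numpy(dtype=float),
            )
        return cls(years=years, baseline_year=baseline_year, series=series)

    @classmethod
    def read_csv(cls, path: str | Path, baseline_year: int) -> "IndicatorPanel":
        """Read a long-format panel CSV (``year,indicator_id,category,direction,value``)."""
        try:
            frame = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - message wrapping
            raise DataValidationError(f"cannot parse panel CSV {path}: {exc}") from exc
        return cls.from_long_frame(frame, baseline_year=baseline_year)
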