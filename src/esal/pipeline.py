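"""End-to-end assessment orchestration.

``run_assessment`` wires the stages together: read the indicator panel and
the daily condition records, fold the annual bloom-risk statistic into the
panel as the risk (R) indicator, screen the panel, normalize against the
baseline year, and aggregate into component indices and the ecological
security index — twice, once on the screened panel and once on the full
panel.  The unscreened index series (``ESINEW``) shows what multicollinear
inputs do to the aggregate; the report quantifies the agreement between the
two routes with per-component ordinary-least-squares fits (R², slope,
intercept), excluding the baseline year, where both series equal 1 by
construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .errors import ConfigurationError, DataValidationError
from .indices import ComponentWeights, NormalizedPanel, component_indices, esi, normalize
from .panel import CATEGORIES, IndicatorPanel
from .risk import (
    RISK_INDICATOR_ID,
    BloomThresholds,
    RiskSeries,
    bloom_risk_series,
    read_daily_csv,
)
from .screening import ScreeningConfig, ScreeningResult, screen_panel
from .synthetic_data import SyntheticConfig, generate_daily_conditions, generate_panel

logger = logging.getLogger(__name__)

#: Components whose screened-vs-unscreened comparison goes beyond the four
#: (D, P, S, ESI) usually examined in case studies of this design.
_SUPPLEMENTARY_COMPARISONS = {"I", "R"}


@dataclass(frozen=True)
class RunConfig:
    """Run configuration: baseline year, screening levels, thresholds, weights."""

    baseline_year: int
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    bloom_thresholds: BloomThresholds = field(
        default_factory=lambda: BloomThresholds(t_min=10.0, tp_min=0.05, tn_min=0.5)
    )
    risk_direction: str = "benefit"
    risk_normalized: bool = True
    exclude_baseline_from_comparison: bool = True
    weights: ComponentWeights | None = None

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "RunConfig":
        if "baseline_year" not in raw:
            raise ConfigurationError("run configuration must set baseline_year")
        screening = ScreeningConfig(**raw.get("screening", {}))
        threshold_kwargs = {"t_min": 10.0, "tp_min": 0.05, "tn_min": 0.5}
        threshold_kwargs.update(raw.get("bloom_thresholds", {}))
        thresholds = BloomThresholds(**threshold_kwargs)
        risk = raw.get("risk", {})
        weights = None
        if "weights" in raw:
            w = raw["weights"]
            kwargs = {}
            if "components" in w:
                kwargs["component_weights"] = {
                    str(k): float(v) for k, v in w["components"].items()
                }
            if "indicators" in w:
                kwargs["indicator_weights"] = {
                    str(c): {str(i): float(v) for i, v in d.items()}
                    for c, d in w["indicators"].items()
                }
            weights = ComponentWeights(**kwargs)
        return cls(
            baseline_year=int(raw["baseline_year"]),
            screening=screening,
            bloom_thresholds=thresholds,
            risk_direction=str(risk.get("direction", "benefit")),
            risk_normalized=bool(risk.get("normalized", True)),
            exclude_baseline_from_comparison=bool(
                raw.get("comparison", {}).get("exclude_baseline", True)
            ),
            weights=weights,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(raw)


@dataclass(frozen=True)
class ComparisonResult:
    """OLS fit of one index series on another over shared, non-excluded years.

    ``r_squared`` is ``None`` (undefined, not zero) when the predictor
    series is constant.
    """

    a_id: str
    b_id: str
    r_squared: float | None
    slope: float | None
    intercept: float | None
    n_years: int
    excluded_years: tuple[int, ...]


def compare_series(
    a: pd.Series,
    b: pd.Series,
    exclude_years: tuple[int, ...] = (),
    a_id: str = "a",
    b_id: str = "b",
) -> ComparisonResult:
    """Regress ``b`` on ``a`` over shared years, excluding ``exclude_years``.

    R² of a simple regression equals the squared Pearson correlation, so the
    direction of the regression does not change it; slope and intercept are
    reported so either reading is recoverable.
    """
    shared = a.index.intersection(b.index).difference(list(exclude_years))
    if len(shared) < 3:
        raise DataValidationError(
            f"need at least 3 shared years after exclusion, have {len(shared)}"
        )
    x = a.loc[shared].to_numpy(dtype=float)
    y = b.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        logger.warning("series %s is constant; R^2 undefined", a_id)
        return ComparisonResult(
            a_id=a_id, b_id=b_id, r_squared=None, slope=None, intercept=None,
            n_years=len(shared), excluded_years=tuple(int(y) for y in exclude_years),
        )
    fit = stats.linregress(x, y)
    return ComparisonResult(
        a_id=a_id,
        b_id=b_id,
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_years=len(shared),
        excluded_years=tuple(int(y) for y in exclude_years),
    )


def trend_slope(series: pd.Series, exclude_years: tuple[int, ...] = ()) -> float:
    """OLS slope of an index series against calendar year."""
    keep = series.index.difference(list(exclude_years))
    fit = stats.linregress(
        np.asarray(keep, dtype=float), series.loc[keep].to_numpy(dtype=float)
    )
    return float(fit.slope)


@dataclass
class AssessmentReport:
    """Everything one assessment run produced."""

    config: RunConfig
    screening: ScreeningResult
    risk: RiskSeries
    normalized_panel: NormalizedPanel
    indices_screened: pd.DataFrame  # year x (D, P, S, I, R, ESI)
    indices_unscreened: pd.DataFrame
    comparisons: dict[str, ComparisonResult]

    @property
    def esi_series(self) -> pd.Series:
        return self.indices_screened["ESI"]

    @property
    def worst_year(self) -> int:
        """Year of the lowest screened ESI."""
        return int(self.esi_series.idxmin())

    def esi_table(self) -> pd.DataFrame:
        """Tidy year x (D, P, S, I, R, ESI, ESINEW) table."""
        table = self.indices_screened.copy()
        table["ESINEW"] = self.indices_unscreened["ESI"]
        table.index.name = "year"
        return table

    def to_dict(self) -> dict:
        return {
            "metadata": {
                "package": "esal",
                "version": __version__,
                "baseline_year": self.config.baseline_year,
                "risk_direction": self.config.risk_direction,
                "risk_normalized": self.config.risk_normalized,
                "alpha": self.config.screening.alpha,
                "pc_variance_threshold": self.config.screening.pc_variance_threshold,
            },
            "selected_ids": self.screening.selected_ids,
            "worst_year": self.worst_year,
            "esi": {int(y): float(v) for y, v in self.esi_series.items()},
            "esi_unscreened": {
                int(y): float(v) for y, v in self.indices_unscreened["ESI"].items()
            },
            "comparisons": {
                key: {
                    "r_squared": c.r_squared,
                    "slope": c.slope,
                    "intercept": c.intercept,
                    "n_years": c.n_years,
                    "excluded_years": list(c.excluded_years),
                    "supplementary": key in _SUPPLEMENTARY_COMPARISONS,
                }
                for key, c in self.comparisons.items()
            },
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.esi_table().to_csv(out / "esi.csv", float_format="%.10g")
        self.screening.write_json(out / "screening.json")
        (out / "report.json").write_text(json.dumps(self.to_dict(), indent=2))
        self.normalized_panel.write_csv(out / "normalized_panel.csv")
        self.risk.write_json(out / "risk.json")
        (out / "screening.txt").write_text(self.screening.text_report())


def _indices_with_esi(
    panel: IndicatorPanel, config: RunConfig, weights: ComponentWeights | None
) -> tuple[NormalizedPanel, pd.DataFrame]:
    """Normalize a panel and compute its component indices plus the ESI."""
    norm = normalize(panel)
    table = component_indices(norm, weights)
    missing = [c for c in CATEGORIES if c not in table.columns]
    if missing:
        raise DataValidationError(f"panel lacks indicators for components: {missing}")
    if not config.risk_normalized:
        # use the bloom-risk statistic directly as the R component index
        table["R"] = panel.values_frame([RISK_INDICATOR_ID])[RISK_INDICATOR_ID]
    table["ESI"] = esi(table[list(CATEGORIES)], weights)
    return norm, table


def assess_panel(
    panel: IndicatorPanel, daily: pd.DataFrame, config: RunConfig
) -> AssessmentReport:
    """Run the full assessment on in-memory inputs.

    The bloom-risk statistic is computed from the daily records over the
    panel's year range and appended to the panel as the risk indicator,
    then the screened and unscreened index routes are evaluated and
    compared component by component.
    """
    risk = bloom_risk_series(daily, config.bloom_thresholds, years=panel.years)
    full = panel.subset(panel.ids)
    full.add_series(risk.to_indicator_series(direction=config.risk_direction))

    screening = screen_panel(full, config.screening)
    screened_panel = screening.selected_panel

    norm_screened, idx_screened = _indices_with_esi(
        screened_panel, config, config.weights
    )
    # custom indicator weights are defined against the screened set; the
    # unscreened route always uses uniform weights within components
    unscreened_weights = (
        ComponentWeights(component_weights=config.weights.component_weights)
        if config.weights is not None
        else None
    )
    _, idx_unscreened = _indices_with_esi(full, config, unscreened_weights)

    exclude = (
        (config.baseline_year,) if config.exclude_baseline_from_comparison else ()
    )
    comparisons = {}
    for key in list(CATEGORIES) + ["ESI"]:
        comparisons[key] = compare_series(
            idx_screened[key],
            idx_unscreened[key],
            exclude_years=exclude,
            a_id=f"{key}_screened",
            b_id=f"{key}_unscreened",
        )

    return AssessmentReport(
        config=config,
        screening=screening,
        risk=risk,
        normalized_panel=norm_screened,
        indices_screened=idx_screened,
        indices_unscreened=idx_unscreened,
        comparisons=comparisons,
    )


def run_assessment(
    panel_path: str | Path,
    daily_path: str | Path,
    config_path: str | Path,
    out_dir: str | Path | None = None,
) -> AssessmentReport:
    """File-based entry point: read inputs, assess, optionally write reports."""
    config = RunConfig.from_yaml(config_path)
    panel = IndicatorPanel.read_csv(panel_path, baseline_year=config.baseline_year)
    daily = read_daily_csv(daily_path)
    report = assess_panel(panel, daily, config)
    if out_dir is not None:
        report.write(out_dir)
    return report


def generate_fixture(
    config: SyntheticConfig | str | Path, out_dir: str | Path
) -> dict[str, Path]:
    """Write a synthetic panel CSV, daily CSV and planted-truth JSON.

    ``config`` is either a :class:`SyntheticConfig` or a path to a YAML file
    whose ``synthetic`` section (or top level) holds its fields.  Idempotent
    for a fixed seed.
    """
    if not isinstance(config, SyntheticConfig):
        raw = yaml.safe_load(Path(config).read_text()) or {}
        raw = raw.get("synthetic", raw)
        thresholds = raw.pop("bloom_thresholds", None)
        if thresholds is not None:
            raw["bloom_thresholds"] = BloomThresholds(**thresholds)
        config = SyntheticConfig(**raw)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, truth = generate_panel(config)
    daily = generate_daily_conditions(config)
    paths = {
        "panel": out / "panel.csv",
        "daily": out / "daily.csv",
        "truth": out / "truth.json",
    }
    panel.write_csv(paths["panel"])
    daily.to_csv(paths["daily"], index=False)
    truth.write_json(paths["truth"])
    return paths
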