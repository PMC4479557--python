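"""Baseline normalization and geometric-mean aggregation into indices.

Every indicator is expressed relative to its value in the baseline
(background) year, oriented so that *higher is better*:

    benefit indicators:  x'_{i,j} = x_{i,j} / x_{base,j}
    cost indicators:     x'_{i,j} = x_{base,j} / x_{i,j}

Both ratios require strictly positive data, and both equal 1 in the baseline
year.  The index of DPSIR component k in year i is the weighted geometric
mean of its normalized indicators,

    Index_{k,i} = prod_j (x'_{i,j}) ** w_{k,j},     sum_j w_{k,j} = 1,

and the ecological security index is the weighted geometric mean of the
five component indices,

    ESI_i = prod_k (Index_{k,i}) ** w_k,            sum_k w_k = 1,

with equal weights by default.  By construction every component index and
the ESI equal 1 in the baseline year; values below 1 indicate deterioration
relative to the background condition.

The direction flag is a property of the indicator, not of an individual
value: a cost indicator uses the reciprocal normalization in every year,
so normalized values may fall on either side of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataValidationError
from .panel import CATEGORIES, IndicatorPanel, IndicatorSeries

_WEIGHT_TOL = 1e-9


class NormalizedPanel(IndicatorPanel):
    """Indicator panel of dimensionless baseline-relative values.

    Shares the :class:`IndicatorPanel` structure; every series holds
    ``x'_{i,j}`` and equals 1 exactly in the baseline year.
    """


@dataclass
class ComponentWeights:
    """Weights within each DPSIR component and across components.

    ``indicator_weights`` maps category -> {indicator id -> weight}; weights
    within a category must be non-negative and sum to 1.  ``component_weights``
    maps category -> weight across components, also summing to 1.  Components
    absent from ``indicator_weights`` fall back to uniform weights when an
    index is computed.
    """

    component_weights: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 / len(CATEGORIES) for c in CATEGORIES}
    )
    indicator_weights: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_simplex(self.component_weights, "component weights")
        for cat, w in self.indicator_weights.items():
            _check_simplex(w, f"indicator weights for component {cat!r}")

    @classmethod
    def uniform(cls, panel: IndicatorPanel) -> "ComponentWeights":
        """Equal weights within each component present in the panel."""
        iw = {}
        for cat in CATEGORIES:
            ids = panel.category_ids(cat)
            if ids:
                iw[cat] = {sid: 1.0 / len(ids) for sid in ids}
        return cls(indicator_weights=iw)

    def for_category(self, category: str, ids: list[str]) -> dict[str, float]:
        """Weights covering exactly ``ids``; uniform if none were configured."""
        if category not in self.indicator_weights:
            return {sid: 1.0 / len(ids) for sid in ids}
        w = self.indicator_weights[category]
        extra = sorted(set(w) - set(ids))
        missing = sorted(set(ids) - set(w))
        if extra or missing:
            raise ConfigurationError(
                f"weights for component {category!r} do not match its indicators: "
                f"missing {missing}, extraneous {extra}"
            )
        return w


def _check_simplex(weights: dict[str, float], label: str) -> None:
    if not weights:
        raise ConfigurationError(f"{label}: empty weight set")
    if any(v < 0 for v in weights.values()):
        raise ConfigurationError(f"{label}: weights must be non-negative")
    total = sum(weights.values())
    if abs(total - 1.0) > _WEIGHT_TOL:
        raise ConfigurationError(f"{label}: weights sum to {total}, expected 1")


def normalize(panel: IndicatorPanel) -> NormalizedPanel:
    """Baseline-relative, direction-oriented normalization of a panel.

    Raises :class:`DataValidationError`, naming the indicator and year, if
    any value is zero or negative (both normalizations divide).
    """
    panel.validate_positive()
    base_idx = panel.year_index(panel.baseline_year)
    series = {}
    for sid, s in panel.series.items():
        base = s.values[base_idx]
        if s.direction == "benefit":
            norm = s.values / base
        else:
            norm = base / s.values
        norm[base_idx] = 1.0  # exact, not just to roundoff
        series[sid] = IndicatorSeries(
            id=sid, category=s.category, direction=s.direction,
            values=norm, name=s.name, units="dimensionless",
        )
    return NormalizedPanel(
        years=panel.years.copy(), baseline_year=panel.baseline_year, series=series
    )


def component_index(
    norm_panel: NormalizedPanel,
    category: str,
    weights: ComponentWeights | None = None,
) -> pd.Series:
    """Weighted geometric mean of a component's normalized indicators per year."""
    ids = norm_panel.category_ids(category)
    if not ids:
        raise DataValidationError(f"no indicators in component {category!r}")
    weights = weights or ComponentWeights()
    w = weights.for_category(category, ids)
    frame = norm_panel.values_frame(ids)
    if (frame.to_numpy() <= 0).any():
        raise DataValidationError(
            f"component {category!r}: normalized values must be positive"
        )
    result = np.ones(len(frame), dtype=float)
    for sid in ids:
        result = result * frame[sid].to_numpy() ** w[sid]
    return pd.Series(result, index=frame.index, name=category)


def component_indices(
    norm_panel: NormalizedPanel, weights: ComponentWeights | None = None
) -> pd.DataFrame:
    """Index series for every component present in the panel (year x category)."""
    cols = {}
    for cat in CATEGORIES:
        if norm_panel.category_ids(cat):
            cols[cat] = component_index(norm_panel, cat, weights)
    return pd.DataFrame(cols)


def esi(
    indices: pd.DataFrame, weights: ComponentWeights | None = None
) -> pd.Series:
    """Ecological security index: weighted geometric mean of component indices.

    ``indices`` is a year-by-component DataFrame covering all five DPSIR
    components; a missing component or a missing (component, year) value
    raises an error naming it.
    """
    weights = weights or ComponentWeights()
    missing_cols = [c for c in weights.component_weights if c not in indices.columns]
    if missing_cols:
        raise DataValidationError(f"missing component index series: {missing_cols}")
    result = np.ones(len(indices), dtype=float)
    for cat, w in weights.component_weights.items():
        col = indices[cat]
        if col.isna().any():
            year = int(col[col.isna()].index[0])
            raise DataValidationError(f"component {cat!r} has no index for year {year}")
        result = result * col.to_numpy() ** w
    return pd.Series(result, index=indices.index, name="ESI")
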