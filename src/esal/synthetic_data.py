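"""Synthetic watershed generator with planted, recoverable structure.

Real lake-assessment panels mix (i) blocks of near-duplicate socio-economic
driving-force series — population, GDP and friends move together, with
pairwise correlations well above 0.95 over a 20-year window — and (ii)
pressure/status/impact series that track the lake's actual ecological
trajectory, here a V-shaped deterioration-and-partial-recovery with a worst
year somewhere inside the record.  This module emulates exactly that
structure and records the ground truth it plants, so that screening and
index pipelines can be tested against known answers:

* The driving-force block follows a single-factor model,
  ``z_j = sqrt(c_j) * latent + sqrt(1 - c_j) * noise_j``, where the latent
  is a standardized monotone ramp and the communalities ``c_j`` are distinct
  with one clear maximum.  The member with the largest communality (hence
  the largest common-factor loading) is the planted "most representative"
  driver.  Communalities are calibrated so the expected pairwise correlation
  within the block equals ``driver_block_correlation``.  Trend amplitudes
  differ across members — the representative grows most slowly, the way a
  population series trails the economic series it drives — so an index that
  pools the whole block overstates the decline relative to one built on the
  representative alone.
* Pressure, status and impact series load moderately on a piecewise-linear
  V-shaped latent with its vertex at ``worst_year`` (cost series peak there,
  benefit series trough there), plus a per-series smooth component
  orthogonal to the V and to each other.  The orthogonal components keep
  within-category correlations below typical significance cutoffs, so these
  series survive screening, while the shared V makes the aggregate index
  bottom out at the planted worst year.
* Daily temperature/TP/TN records have a seasonal temperature cycle and
  nutrient levels that rise into the worst year and recede after it, so the
  annual below-threshold counts feeding the bloom-risk statistic trace the
  same trajectory.

All values are kept strictly positive via an exponential transform
(``value = base * exp(amplitude * z)``); the downstream normalizations and
geometric means divide and take logs, so zeros and negatives are disallowed
at the source.  Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .panel import IndicatorPanel, IndicatorSeries
from .risk import DAILY_CSV_COLUMNS, BloomThresholds

#: Communality ceiling for the representative block member.
_REP_COMMUNALITY = 0.9995

#: Log-scale trend amplitudes for the driver block: the representative grows
#: slowest, the bulk of the block sits just below the block mean, and one
#: fast-growing member pulls the mean up — the typical shape of a
#: population-plus-economy block, where GDP-type series outpace population.
def _driver_amplitudes(m: int) -> np.ndarray:
    return np.concatenate([[0.06], np.linspace(0.09, 0.15, m - 1)])

#: Loading of every non-block series on the V-shaped latent.  0.55 puts the
#: expected within-category correlation near 0.30, safely below the n=20
#: significance cutoff (|r| ~ 0.44 at alpha 0.05) while keeping the shared
#: dip dominant in the aggregate index.
_V_LOADING = 0.55

_DRIVER_IDS = [
    ("population", "resident population"),
    ("gdp", "gross domestic product"),
    ("industrial_output", "industrial output value"),
    ("urban_population", "urban resident population"),
    ("retail_sales", "total retail sales"),
    ("fixed_investment", "fixed-asset investment"),
]

#: (id, name, category, direction, orthogonal-shape index, amplitude, base level)
_NONBLOCK_SPECS = [
    ("nutrient_load", "nutrient load to the lake", "P", "cost", 0, 0.22, 3500.0),
    ("construction_land", "area of construction land", "P", "cost", 1, 0.15, 180.0),
    ("tp_concentration", "total phosphorus concentration", "S", "cost", 2, 0.25, 0.08),
    ("do_concentration", "dissolved oxygen concentration", "S", "benefit", 3, 0.15, 6.5),
    ("fish_production", "fishery production", "I", "benefit", 4, 0.20, 9000.0),
    ("tourism_income", "per capita tourism income", "I", "benefit", 5, 0.18, 850.0),
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic watershed.

    Defaults emulate a 20-year panel (1988–2007) with the baseline at the
    first year, the planted ecological minimum in 1998, and a three-member
    driving-force block with expected pairwise correlation 0.98.
    """

    year_start: int = 1988
    year_end: int = 2007
    baseline_year: int = 1988
    worst_year: int = 1998
    driver_block_size: int = 3
    driver_block_correlation: float = 0.98
    noise_sd: float = 0.1
    n_daily_per_year: int = 365
    bloom_thresholds: BloomThresholds = field(
        default_factory=lambda: BloomThresholds(t_min=10.0, tp_min=0.05, tn_min=0.5)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.year_start <= self.baseline_year < self.worst_year <= self.year_end):
            raise ConfigurationError(
                "need year_start <= baseline_year < worst_year <= year_end, got "
                f"{self.year_start}, {self.baseline_year}, {self.worst_year}, "
                f"{self.year_end}"
            )
        if self.driver_block_size < 2:
            raise ConfigurationError("driver_block_size must be at least 2")
        if not 0 < self.driver_block_correlation < 1:
            raise ConfigurationError("driver_block_correlation must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.n_daily_per_year < 1:
            raise ConfigurationError("n_daily_per_year must be at least 1")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted by :func:`generate_panel`."""

    representative_driver_id: str
    worst_year: int
    block_member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.representative_driver_id not in self.block_member_ids:
            raise ConfigurationError("representative driver must be a block member")

    def to_json(self) -> str:
        return json.dumps(
            {
                "representative_driver_id": self.representative_driver_id,
                "worst_year": self.worst_year,
                "block_member_ids": list(self.block_member_ids),
            },
            indent=2,
        )

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            representative_driver_id=d["representative_driver_id"],
            worst_year=int(d["worst_year"]),
            block_member_ids=tuple(d["block_member_ids"]),
        )


# ---------------------------------------------------------------------------
# latent structure
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def monotone_latent(config: SyntheticConfig) -> np.ndarray:
    """Standardized linear ramp driving the socio-economic block."""
    return _standardize(config.years.astype(float))


def v_latent(config: SyntheticConfig) -> np.ndarray:
    """Standardized piecewise-linear V with its minimum exactly at worst_year.

    Descends linearly from the start of the record to the vertex, then
    recovers at 60% of the descent depth by the final year — deterioration
    followed by partial recovery.  Benefit series follow this latent
    directly; cost series follow its negative.
    """
    years = config.years
    raw = np.empty(len(years), dtype=float)
    down = years <= config.worst_year
    raw[down] = 1.0 - (years[down] - config.year_start) / (
        config.worst_year - config.year_start
    )
    if config.worst_year < config.year_end:
        up = years > config.worst_year
        raw[up] = 0.6 * (years[up] - config.worst_year) / (
            config.year_end - config.worst_year
        )
    return _standardize(raw)


def _orthogonal_shapes(config: SyntheticConfig, count: int) -> np.ndarray:
    """Unit-variance smooth shapes orthogonal to the V latent and each other.

    Cosine waveforms Gram–Schmidt-orthogonalized against the constant and
    the V latent; they give each non-block series an idiosyncratic
    deterministic component that does not move its category-mates.
    """
    n = len(config.years)
    t = np.arange(n)
    basis = [np.ones(n), v_latent(config)]
    shapes = []
    k = 2
    while len(shapes) < count:
        u = np.cos(math.pi * k * (t + 0.5) / n)
        for b in basis:
            u = u - (u @ b) / (b @ b) * b
        norm = np.linalg.norm(u)
        k += 1
        if norm < 1e-8:  # collinear with existing basis, skip
            continue
        u = _standardize(u)
        basis.append(u)
        shapes.append(u)
    return np.asarray(shapes)


def _block_communalities(config: SyntheticConfig) -> np.ndarray:
    """Distinct communalities whose mean pairwise sqrt-product equals the target.

    The representative gets a near-unit communality; the remaining members
    share a common level solved in closed form from the target expected
    pairwise correlation, with tiny distinct offsets so every common-factor
    loading is unique.
    """
    m = config.driver_block_size
    r = config.driver_block_correlation
    c0 = max(_REP_COMMUNALITY, 1.0 - (1.0 - r) / 10.0)
    # mean over pairs of sqrt(c_a c_b) = r with c = (c0, x, ..., x):
    #   [(m-1) sqrt(c0 x) + C(m-1,2) x] / C(m,2) = r
    a_coef = (m - 1) * (m - 2) / 2.0
    b_coef = (m - 1) * math.sqrt(c0)
    t_coef = m * (m - 1) / 2.0 * r
    if a_coef == 0:  # two-member block
        t = t_coef / b_coef
    else:
        t = (-b_coef + math.sqrt(b_coef**2 + 4 * a_coef * t_coef)) / (2 * a_coef)
    x = t * t
    if not 0 < x < c0:
        raise ConfigurationError(
            f"driver_block_correlation {r} not attainable with a distinct "
            "representative member"
        )
    offsets = 1.0 - 5e-4 * np.arange(m - 1)
    others = np.minimum(x * offsets, c0 - 1e-6)
    return np.concatenate([[c0], others])


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_panel(config: SyntheticConfig) -> tuple[IndicatorPanel, PlantedTruth]:
    """Generate an indicator panel and the truth planted inside it.

    The panel holds the driving-force block (category D, cost direction) and
    six pressure/status/impact series tied to the V-shaped latent.  The risk
    category is left to the daily records and the bloom-risk statistic.
    """
    rng = np.random.default_rng([config.seed, 0])
    years = config.years
    n = len(years)
    m = config.driver_block_size

    series: dict[str, IndicatorSeries] = {}

    # driving-force block: single-factor model on the monotone ramp
    ramp = monotone_latent(config)
    comm = _block_communalities(config)
    amps = _driver_amplitudes(m)
    block_ids = []
    for j in range(m):
        if j < len(_DRIVER_IDS):
            sid, name = _DRIVER_IDS[j]
        else:
            sid, name = f"driver_{j + 1:02d}", f"auxiliary driver {j + 1}"
        z = math.sqrt(comm[j]) * ramp + math.sqrt(1.0 - comm[j]) * rng.standard_normal(n)
        base = 200.0 / (1 + j)
        series[sid] = IndicatorSeries(
            id=sid, category="D", direction="cost",
            values=base * np.exp(amps[j] * z), name=name,
        )
        block_ids.append(sid)

    # pressure / status / impact series on the V latent
    v = v_latent(config)
    shapes = _orthogonal_shapes(config, len(_NONBLOCK_SPECS))
    u_load = math.sqrt(1.0 - _V_LOADING**2)
    for sid, name, cat, direction, shape_idx, amp, base in _NONBLOCK_SPECS:
        sign = 1.0 if direction == "benefit" else -1.0
        z = (
            _V_LOADING * sign * v
            + u_load * shapes[shape_idx]
            + config.noise_sd * rng.standard_normal(n)
        )
        series[sid] = IndicatorSeries(
            id=sid, category=cat, direction=direction,
            values=base * np.exp(amp * z), name=name,
        )

    panel = IndicatorPanel(
        years=years, baseline_year=config.baseline_year, series=series
    )
    truth = PlantedTruth(
        representative_driver_id=block_ids[0],
        worst_year=config.worst_year,
        block_member_ids=tuple(block_ids),
    )
    return panel, truth


def generate_daily_conditions(config: SyntheticConfig) -> pd.DataFrame:
    """Daily temperature/TP/TN records for every year of the study window.

    Temperature follows a seasonal cosine (annual range roughly 7–25 °C)
    with day-to-day noise, identical in expectation across years, so the
    cold-day count is stable.  Nutrient levels are lognormal around a yearly
    median that rises into the worst year and falls after it, so the counts
    of days below the bloom thresholds shrink toward the worst year and
    recover afterwards.
    """
    rng = np.random.default_rng([config.seed, 1])
    years = config.years
    nd = config.n_daily_per_year
    v = v_latent(config)

    tp_year = 0.05 * np.exp(0.55 * (-v))
    tn_year = 0.50 * np.exp(0.45 * (-v))

    day = np.arange(nd)
    season = 16.0 + 9.0 * np.cos(2 * math.pi * (day - 200) / nd)

    frames = []
    for i, year in enumerate(years):
        temperature = season + 1.5 * rng.standard_normal(nd)
        tp = tp_year[i] * np.exp(0.35 * rng.standard_normal(nd))
        tn = tn_year[i] * np.exp(0.30 * rng.standard_normal(nd))
        frames.append(
            pd.DataFrame(
                {
                    "year": np.full(nd, year, dtype=int),
                    "day_index": day,
                    "temperature": temperature,
                    "tp": tp,
                    "tn": tn,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[DAILY_CSV_COLUMNS]


def replicate_driver_block(
    panel: IndicatorPanel,
    truth: PlantedTruth,
    copies: int = 2,
    copy_noise_sd: float = 0.1,
    seed: int = 0,
) -> IndicatorPanel:
    """Panel with extra noisy duplicates of every driving-force block member.

    Each copy multiplies the original series by lognormal jitter whose scale
    is ``copy_noise_sd`` times the series' own log-scale standard deviation,
    preserving its trend and its near-perfect correlation with the block
    regardless of how fast the member grows.  Used to study how redundant
    co-trending drivers bias an unscreened index.
    """
    if copies < 1:
        raise ConfigurationError("copies must be at least 1")
    rng = np.random.default_rng([seed, 2])
    out = panel.subset(panel.ids)
    for sid in truth.block_member_ids:
        src = panel.series[sid]
        log_sd = float(np.std(np.log(src.values)))
        for k in range(copies):
            jitter = np.exp(
                copy_noise_sd * log_sd * rng.standard_normal(len(panel.years))
            )
            out.add_series(
                IndicatorSeries(
                    id=f"{sid}_copy{k + 1}",
                    category=src.category,
                    direction=src.direction,
                    values=src.values * jitter,
                    name=f"{src.name} (duplicate {k + 1})",
                )
            )
    return out
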