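"""Statistical indicator screening within DPSIR categories.

Composite indices built from many co-trending indicators double-count
information: strongly correlated members of a category drag the aggregate in
the same direction and bias it (multicollinearity).  Screening enforces two
of the basic indicator criteria — independence and representativeness — in
two steps, applied separately within each DPSIR category:

1. *Correlation test.*  Pairwise Pearson correlations with two-sided
   p-values (t distribution, n - 2 degrees of freedom).  Pairs significant
   at level ``alpha`` are linked; connected components of the resulting
   graph form clusters of mutually redundant indicators.
2. *Representative selection.*  Within each multi-member cluster the member
   series are standardized and a principal component analysis is run on the
   correlation structure.  When the first component explains at least
   ``pc_variance_threshold`` of the variance, the single indicator with the
   largest absolute PC1 loading carries essentially all the cluster's
   information and is selected alone.  Otherwise the smallest set of leading
   components reaching the threshold each contribute their top-loading
   indicator.

Singleton clusters pass through unchanged.  The full audit trail (matrices,
clusters, loadings) is retained in the result so any selection can be
inspected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import ConfigurationError, DataValidationError
from .panel import CATEGORIES, IndicatorPanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreeningConfig:
    """Significance level for the correlation test and PCA dominance threshold."""

    alpha: float = 0.05
    pc_variance_threshold: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 < self.pc_variance_threshold <= 1:
            raise ConfigurationError(
                "pc_variance_threshold must lie in (0, 1], "
                f"got {self.pc_variance_threshold}"
            )


@dataclass
class ClusterSelection:
    """Audit record of one cluster's PCA and the ids selected from it."""

    members: list[str]
    selected: list[str]
    explained_variance_ratio: list[float] = field(default_factory=list)
    loadings: dict[str, list[float]] = field(default_factory=dict)  # id -> per-PC


@dataclass
class CategoryScreening:
    """Correlation/p-value matrices, clusters and selections for one category."""

    category: str
    ids: list[str]
    correlations: pd.DataFrame
    p_values: pd.DataFrame
    constant_ids: list[str]
    clusters: list[list[str]]
    selections: list[ClusterSelection]

    @property
    def selected(self) -> list[str]:
        out: list[str] = []
        for sel in self.selections:
            out.extend(sel.selected)
        return out


@dataclass
class ScreeningResult:
    """Per-category screening audit plus the screened panel."""

    config: ScreeningConfig
    categories: dict[str, CategoryScreening]
    selected_panel: IndicatorPanel

    @property
    def selected_ids(self) -> list[str]:
        return self.selected_panel.ids

    def to_dict(self) -> dict:
        payload: dict = {
            "config": {
                "alpha": self.config.alpha,
                "pc_variance_threshold": self.config.pc_variance_threshold,
            },
            "categories": {},
            "selected_ids": self.selected_ids,
        }
        for cat, cs in self.categories.items():
            payload["categories"][cat] = {
                "ids": cs.ids,
                "correlations": np.round(cs.correlations.to_numpy(), 10).tolist(),
                "p_values": cs.p_values.to_numpy().tolist(),
                "constant_ids": cs.constant_ids,
                "clusters": cs.clusters,
                "selections": [
                    {
                        "members": sel.members,
                        "selected": sel.selected,
                        "explained_variance_ratio": sel.explained_variance_ratio,
                        "loadings": sel.loadings,
                    }
                    for sel in cs.selections
                ],
            }
        return payload

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def text_report(self) -> str:
        lines = ["Indicator screening report", "=" * 26, ""]
        for cat, cs in self.categories.items():
            lines.append(f"Component {cat}: {len(cs.ids)} indicator(s)")
            for sel in cs.selections:
                if len(sel.members) == 1:
                    lines.append(f"  [{sel.members[0]}] independent, kept")
                else:
                    evr = ", ".join(f"{v:.3f}" for v in sel.explained_variance_ratio)
                    lines.append(
                        f"  cluster {{{', '.join(sel.members)}}} "
                        f"(explained variance: {evr}) -> kept {', '.join(sel.selected)}"
                    )
            lines.append("")
        lines.append(f"Selected: {', '.join(self.selected_ids)}")
        return "\n".join(lines)


def correlation_matrix(
    panel: IndicatorPanel, category: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations and two-sided p-values for one category.

    A constant (zero-variance) series has undefined correlation with every
    other series; those entries are reported as NaN and later treated as
    non-significant.  Diagonals are exactly 1 (r) and 0 (p).
    """
    ids = panel.category_ids(category)
    if not ids:
        raise DataValidationError(f"no indicators in category {category!r}")
    if panel.n_years < 3:
        raise DataValidationError(
            "correlation significance needs at least 3 years of data"
        )
    frame = panel.values_frame(ids)
    m = len(ids)
    r = np.eye(m)
    p = np.zeros((m, m))
    constant = [sid for sid in ids if np.std(frame[sid].to_numpy()) == 0.0]
    for a in range(m):
        for b in range(a + 1, m):
            if ids[a] in constant or ids[b] in constant:
                r[a, b] = r[b, a] = np.nan
                p[a, b] = p[b, a] = np.nan
                continue
            res = stats.pearsonr(frame[ids[a]], frame[ids[b]])
            r[a, b] = r[b, a] = res.statistic
            p[a, b] = p[b, a] = res.pvalue
    if constant:
        logger.warning(
            "category %s: constant series %s — correlations undefined, "
            "treated as non-significant", category, constant,
        )
    idx = pd.Index(ids, name="indicator_id")
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
    )


def cluster_correlated(
    correlations: pd.DataFrame,
    p_values: pd.DataFrame,
    config: ScreeningConfig | None = None,
) -> list[list[str]]:
    """Connected components of the significance graph (p <= alpha edges).

    Returns clusters as sorted id lists, ordered by their smallest member;
    indicators with no significant partner come back as singletons.
    Undefined (NaN) p-values contribute no edge.
    """
    config = config or ScreeningConfig()
    ids = list(correlations.columns)
    if list(p_values.columns) != ids or correlations.shape != p_values.shape:
        raise DataValidationError("correlation and p-value matrices do not match")
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    p = p_values.to_numpy()
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if np.isfinite(p[a, b]) and p[a, b] <= config.alpha:
                graph.add_edge(ids[a], ids[b])
    clusters = [sorted(c) for c in nx.connected_components(graph)]
    return sorted(clusters, key=lambda c: c[0])


def _standardized_matrix(panel: IndicatorPanel, ids: list[str]) -> np.ndarray:
    """Year-by-indicator matrix, each column scaled to zero mean, unit variance."""
    x = panel.values_frame(ids).to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0  # constant column -> all zeros after centering
    return (x - mu) / sd


def select_representative(
    panel: IndicatorPanel,
    cluster: list[str],
    config: ScreeningConfig | None = None,
) -> ClusterSelection:
    """Pick the most informative member(s) of one correlated cluster via PCA.

    With PC1 explaining at least ``pc_variance_threshold`` of the cluster
    variance, the single member with the largest absolute PC1 loading is
    returned.  Otherwise each of the smallest set of leading components
    whose cumulative explained variance reaches the threshold nominates the
    not-yet-chosen member with the largest absolute loading.  Loading ties
    are broken by lexicographic id order (and logged).
    """
    config = config or ScreeningConfig()
    members = sorted(cluster)
    if not members:
        raise DataValidationError("cannot select from an empty cluster")
    if len(members) == 1:
        return ClusterSelection(members=members, selected=list(members))

    z = _standardized_matrix(panel, members)
    pca = PCA(n_components=len(members))
    pca.fit(z)
    evr = pca.explained_variance_ratio_
    loadings = pca.components_  # (n_pc, n_members)

    n_keep = int(np.searchsorted(np.cumsum(evr), config.pc_variance_threshold - 1e-12) + 1)
    n_keep = min(n_keep, len(members))
    selected: list[str] = []
    for pc in range(n_keep):
        order = _by_loading(members, np.abs(loadings[pc]))
        pick = next((sid for sid in order if sid not in selected), None)
        if pick is not None:
            selected.append(pick)
    return ClusterSelection(
        members=members,
        selected=selected,
        explained_variance_ratio=[float(v) for v in evr],
        loadings={
            sid: [float(loadings[pc, j]) for pc in range(len(members))]
            for j, sid in enumerate(members)
        },
    )


def _by_loading(members: list[str], abs_loadings: np.ndarray) -> list[str]:
    """Members ordered by decreasing |loading|, ties lexicographic.

    Loadings are quantized to 9 decimals first so that numerically identical
    series (which differ only by SVD roundoff) tie deterministically.
    """
    quantized = np.round(abs_loadings, 9)
    order = sorted(zip(members, quantized), key=lambda t: (-t[1], t[0]))
    top = order[0]
    ties = [sid for sid, v in order if v == top[1]]
    if len(ties) > 1:
        logger.info("loading tie among %s; keeping %s (lexicographic)", ties, top[0])
    return [sid for sid, _ in order]


def screen_panel(
    panel: IndicatorPanel, config: ScreeningConfig | None = None
) -> ScreeningResult:
    """Run correlation clustering and PCA selection over every category.

    Categories with no indicators are skipped with a warning.  The returned
    ``selected_panel`` is the input panel restricted to the union of the
    selections, with category and direction metadata preserved.
    """
    config = config or ScreeningConfig()
    if not panel.series:
        raise DataValidationError("cannot screen an empty panel")
    categories: dict[str, CategoryScreening] = {}
    all_selected: list[str] = []
    for cat in CATEGORIES:
        ids = panel.category_ids(cat)
        if not ids:
            logger.warning("category %s has no indicators; skipped", cat)
            continue
        corr, pvals = correlation_matrix(panel, cat)
        clusters = cluster_correlated(corr, pvals, config)
        selections = [select_representative(panel, c, config) for c in clusters]
        cs = CategoryScreening(
            category=cat,
            ids=ids,
            correlations=corr,
            p_values=pvals,
            constant_ids=[sid for sid in ids
                          if np.std(panel.series[sid].values) == 0.0],
            clusters=clusters,
            selections=selections,
        )
        categories[cat] = cs
        all_selected.extend(cs.selected)
    return ScreeningResult(
        config=config,
        categories=categories,
        selected_panel=panel.subset(all_selected),
    )
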