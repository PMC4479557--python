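"""Correlation screening and PCA representative selection."""

import numpy as np
import pandas as pd
import pytest

from esal import (
    DataValidationError,
    IndicatorPanel,
    IndicatorSeries,
    ScreeningConfig,
    cluster_correlated,
    correlation_matrix,
    screen_panel,
    select_representative,
)
from conftest import brute_force_pearson


def panel_of(arrays, category="D", years_start=2000, baseline=None, direction="cost"):
    n = len(next(iter(arrays.values())))
    years = np.arange(years_start, years_start + n)
    series = {
        sid: IndicatorSeries(
            id=sid, category=category, direction=direction,
            values=np.asarray(vals, dtype=float),
        )
        for sid, vals in arrays.items()
    }
    return IndicatorPanel(
        years=years, baseline_year=baseline or years_start, series=series
    )


def matrices(ids, p):
    idx = pd.Index(ids)
    r = pd.DataFrame(np.eye(len(ids)), index=idx, columns=idx)
    return r, pd.DataFrame(p, index=idx, columns=idx)


class TestCorrelationMatrix:
    def test_diagonal_and_perfect_negative(self):
        panel = panel_of({"a": [1, 2, 3], "b": [3, 2, 1]})
        r, p = correlation_matrix(panel, "D")
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert np.allclose(r, r.T, equal_nan=True)

    def test_matches_sum_of_products_oracle(self):
        x, y = [1, 2, 4, 8], [1, 3, 2, 7]
        panel = panel_of({"x": x, "y": y})
        r, _ = correlation_matrix(panel, "D")
        assert r.loc["x", "y"] == pytest.approx(0.9109657318986027, abs=1e-12)
        assert r.loc["x", "y"] == pytest.approx(brute_force_pearson(x, y), abs=1e-12)

    def test_p_values_from_t_distribution(self):
        # two-sided p for r on n points, df = n - 2, cross-checked against
        # the closed-form t transform
        from scipy import stats

        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        y = x + rng.normal(size=10)
        panel = panel_of({"x": x, "y": y})
        r, p = correlation_matrix(panel, "D")
        rv = r.loc["x", "y"]
        t = rv * np.sqrt(8 / (1 - rv**2))
        assert p.loc["x", "y"] == pytest.approx(2 * stats.t.sf(abs(t), df=8), rel=1e-9)

    def test_constant_series_reported_undefined(self):
        panel = panel_of({"a": [1, 2, 3], "c": [5, 5, 5]})
        r, p = correlation_matrix(panel, "D")
        assert np.isnan(r.loc["a", "c"]) and np.isnan(p.loc["a", "c"])
        assert r.loc["c", "c"] == 1.0

    def test_too_few_years_rejected(self):
        panel = panel_of({"a": [1, 2], "b": [2, 1]})
        with pytest.raises(DataValidationError):
            correlation_matrix(panel, "D")


class TestClusterCorrelated:
    def test_no_significant_pairs_gives_singletons(self):
        r, p = matrices(["a", "b", "c"], np.full((3, 3), 0.9))
        assert cluster_correlated(r, p) == [["a"], ["b"], ["c"]]

    def test_all_significant_gives_one_cluster(self):
        r, p = matrices(["a", "b", "c"], np.full((3, 3), 0.001))
        assert cluster_correlated(r, p) == [["a", "b", "c"]]

    def test_path_edges_merge_transitively(self):
        # significant only a-b and b-c: one component by transitivity
        p = np.full((3, 3), 0.9)
        p[0, 1] = p[1, 0] = 0.01
        p[1, 2] = p[2, 1] = 0.01
        r, p = matrices(["a", "b", "c"], p)
        assert cluster_correlated(r, p) == [["a", "b", "c"]]

    def test_nan_p_values_contribute_no_edge(self):
        p = np.full((2, 2), np.nan)
        r, p = matrices(["a", "c"], p)
        assert cluster_correlated(r, p) == [["a"], ["c"]]


class TestSelectRepresentative:
    def test_singleton_passes_through(self, panel_and_truth):
        panel, _ = panel_and_truth
        sel = select_representative(panel, ["population"])
        assert sel.selected == ["population"]

    def test_matches_eigendecomposition_oracle(self):
        # three series loading 1.0/0.9/0.8 on one latent plus small noise
        rng = np.random.default_rng(7)
        latent = rng.normal(size=12)
        arrays = {
            "a": 10 + 1.0 * latent + 0.1 * rng.normal(size=12),
            "b": 10 + 0.9 * latent + 0.1 * rng.normal(size=12),
            "c": 10 + 0.8 * latent + 0.1 * rng.normal(size=12),
        }
        panel = panel_of(arrays)
        sel = select_representative(panel, ["a", "b", "c"])
        # oracle: PC1 of the correlation matrix via eigen-decomposition
        frame = panel.values_frame(["a", "b", "c"]).to_numpy()
        corr = np.corrcoef(frame.T)
        w, v = np.linalg.eigh(corr)
        pc1 = np.abs(v[:, -1])
        expected = ["a", "b", "c"][int(np.argmax(pc1))]
        assert sel.selected == [expected]
        impl = np.abs([sel.loadings[sid][0] for sid in ["a", "b", "c"]])
        impl = impl / np.linalg.norm(impl)
        np.testing.assert_allclose(impl, pc1 / np.linalg.norm(pc1), atol=1e-6)

    def test_recovers_planted_driver(self, panel_and_truth):
        panel, truth = panel_and_truth
        sel = select_representative(panel, list(truth.block_member_ids))
        assert sel.selected == [truth.representative_driver_id]

    def test_identical_series_tie_breaks_lexicographically(self):
        vals = [1.0, 2.0, 3.0, 5.0]
        panel = panel_of({"b": vals, "a": vals})
        sel = select_representative(panel, ["b", "a"])
        assert sel.selected == ["a"]

    def test_low_pc1_dominance_selects_one_per_leading_pc(self):
        # two nearly orthogonal shapes: PC1 alone cannot reach 80%
        t = np.arange(10, dtype=float)
        panel = panel_of({"lin": 5 + t, "osc": 10 + np.cos(np.pi * t / 2)})
        cfg = ScreeningConfig(pc_variance_threshold=0.95)
        sel = select_representative(panel, ["lin", "osc"], cfg)
        assert len(sel.selected) == 2
        assert set(sel.selected) == {"lin", "osc"}


class TestScreenPanel:
    def test_independent_series_pass_unchanged(self):
        rng = np.random.default_rng(11)
        arrays = {f"s{i}": np.exp(rng.normal(size=15)) for i in range(4)}
        panel = panel_of(arrays, category="S")
        result = screen_panel(panel)
        assert result.selected_ids == panel.ids
        assert result.selected_panel.values_frame().equals(panel.values_frame())

    def test_correlated_block_reduced_to_one_driver(self, panel_and_truth):
        panel, truth = panel_and_truth
        result = screen_panel(panel)
        d_selected = [
            sid for sid in result.selected_ids
            if result.selected_panel.series[sid].category == "D"
        ]
        assert len(d_selected) == 1

    def test_planted_recovery_of_full_selection(self, panel_and_truth):
        panel, truth = panel_and_truth
        result = screen_panel(panel)
        non_block = [s for s in panel.ids if s not in truth.block_member_ids]
        assert set(result.selected_ids) == {truth.representative_driver_id, *non_block}

    def test_metadata_preserved_in_selected_panel(self, panel_and_truth):
        panel, _ = panel_and_truth
        result = screen_panel(panel)
        for sid in result.selected_ids:
            assert result.selected_panel.series[sid].category == panel.series[sid].category
            assert result.selected_panel.series[sid].direction == panel.series[sid].direction

    def test_every_cluster_contributes_and_pc1_dominant_ones_give_one(
        self, panel_and_truth
    ):
        panel, _ = panel_and_truth
        result = screen_panel(panel)
        for cs in result.categories.values():
            assert sorted(sum(cs.clusters, [])) == sorted(cs.ids)
            for sel in cs.selections:
                assert len(sel.selected) >= 1
                pc1_dominant = (
                    len(sel.members) == 1
                    or sel.explained_variance_ratio[0] >= 0.8
                )
                if pc1_dominant:
                    assert len(sel.selected) == 1

    def test_idempotent_on_screened_panel(self, panel_and_truth):
        panel, _ = panel_and_truth
        first = screen_panel(panel)
        second = screen_panel(first.selected_panel)
        assert second.selected_ids == first.selected_ids
        assert second.selected_panel.values_frame().equals(
            first.selected_panel.values_frame()
        )

    def test_empty_panel_rejected(self):
        panel = IndicatorPanel(years=np.arange(2000, 2005), baseline_year=2000, series={})
        with pytest.raises(DataValidationError):
            screen_panel(panel)

    def test_audit_trail_serializes(self, panel_and_truth, tmp_path):
        panel, _ = panel_and_truth
        result = screen_panel(panel)
        out = tmp_path / "screening.json"
        result.write_json(out)
        import json

        payload = json.loads(out.read_text())
        assert payload["selected_ids"] == result.selected_ids
        assert set(payload["categories"]) == {"D", "P", "S", "I"}
        assert "kept" in result.text_report()
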