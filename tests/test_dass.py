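"""DASS-21 scoring, prevalence, panel reading and attrition comparisons."""

import numpy as np
import pandas as pd
import pytest

from clpnet import (PanelDataset, attrition_ttest, prevalence, read_panel,
                    score_dass)
from clpnet.dass import PanelValidationError, SchemaError, subscale_totals
from clpnet.panel import N_NODES, WAVE1_COLUMNS, WAVE2_COLUMNS


def _panel(wave1, wave2=None, status=None, age=None, gender=None):
    n = len(wave1)
    return PanelDataset(
        ids=np.arange(n),
        wave1_items=np.asarray(wave1, dtype=float),
        wave2_items=np.full((n, N_NODES), np.nan) if wave2 is None else np.asarray(wave2, dtype=float),
        age=np.full(n, 20.0) if age is None else np.asarray(age, dtype=float),
        gender=np.zeros(n, dtype=int) if gender is None else np.asarray(gender),
        status=status,
    )


class TestScoring:
    def test_all_zero_items_score_zero_and_normal(self):
        s = score_dass(np.zeros(7), "depression")
        assert s.depression_total == 0
        assert s.depression_flag == "normal"

    def test_depression_cutoff_at_ten(self):
        # all items 1 -> total 14, above the mild cutoff of 10
        s = score_dass(np.ones(7), "depression")
        assert s.depression_total == 14
        assert s.depression_flag == "mild_or_above"
        # total 8 stays normal
        assert score_dass([1, 1, 1, 1, 0, 0, 0], "depression").depression_flag == "normal"

    def test_anxiety_cutoff_at_eight(self):
        s = score_dass([1, 1, 1, 1, 0, 0, 0], "anxiety")
        assert s.anxiety_total == 8
        assert s.anxiety_flag == "mild_or_above"
        assert score_dass([1, 1, 1, 0, 0, 0, 0], "anxiety").anxiety_flag == "normal"

    @pytest.mark.parametrize("items", [
        [3, 3, 3, 3, 3, 3, 3], [0, 1, 2, 3, 0, 1, 2], [2, 2, 2, 2, 2, 2, 2]])
    def test_totals_are_even_and_bounded(self, items):
        s = score_dass(items, "depression")
        assert s.depression_total % 2 == 0
        assert 0 <= s.depression_total <= 42

    def test_missing_item_is_an_error(self):
        with pytest.raises(ValueError, match="missing"):
            score_dass([np.nan, 1, 1, 1, 1, 1, 1], "depression")

    def test_out_of_range_item_is_an_error(self):
        with pytest.raises(ValueError):
            score_dass([4, 0, 0, 0, 0, 0, 0], "depression")


class TestScoringProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.integers(0, 3), min_size=7, max_size=7))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_total_is_double_the_item_sum(self, items):
        s = score_dass(items, "anxiety")
        assert s.anxiety_total == 2 * sum(items)
        assert s.anxiety_total % 2 == 0
        assert (s.anxiety_flag == "mild_or_above") == (s.anxiety_total >= 8)


class TestPrevalence:
    def test_all_zero_matrix_gives_zero(self):
        panel = _panel(np.zeros((5, N_NODES)))
        assert prevalence(panel, 1, "depression") == 0.0

    def test_hand_counted_toy_case(self):
        # depression totals 0, 10, 12, 8 -> 2 of 4 at or above cutoff 10
        w1 = np.zeros((4, N_NODES))
        w1[1, :5] = 1; w1[1, 5] = 0  # noqa: E702  sum 5 -> 10
        w1[2, :6] = 1                 # sum 6 -> 12
        w1[3, :4] = 1                 # sum 4 -> 8
        panel = _panel(w1)
        assert prevalence(panel, 1, "depression") == pytest.approx(0.5)

    def test_wave2_excludes_deceased(self):
        w1 = np.zeros((4, N_NODES))
        w2 = np.zeros((4, N_NODES))
        w2[0, 7:] = 2  # anxiety total 28 for the one deceased participant
        status = np.array(["complete"] * 4, dtype=object)
        w2_masked = w2.copy()
        status[0] = "deceased"
        w2_masked[0] = np.nan
        panel = _panel(w1, w2_masked, status=status)
        assert prevalence(panel, 2, "anxiety") == 0.0

    def test_invariant_to_row_order(self, rng):
        w1 = rng.integers(0, 4, size=(50, N_NODES)).astype(float)
        panel = _panel(w1)
        perm = rng.permutation(50)
        shuffled = _panel(w1[perm])
        assert prevalence(panel, 1, "anxiety") == prevalence(shuffled, 1, "anxiety")

    def test_empty_denominator_is_an_error(self):
        panel = _panel(np.full((3, N_NODES), np.nan))
        with pytest.raises(ValueError, match="denominator"):
            prevalence(panel, 1, "depression")


class TestReadPanel:
    def test_schema_error_on_missing_column(self, tmp_path, clean_panel):
        df = clean_panel.to_frame().drop(columns=["d3_t1"])
        path = tmp_path / "broken.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="d3_t1"):
            read_panel(path)

    def test_out_of_range_cell_named_in_error(self, tmp_path, clean_panel):
        df = clean_panel.to_frame()
        df.loc[2, "a1_t1"] = 5
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(PanelValidationError, match="a1_t1"):
            read_panel(path)

    def test_empty_cells_parse_as_missing_patterns(self, tmp_path):
        header = ["id", "age", "gender", "status"] + WAVE1_COLUMNS + WAVE2_COLUMNS
        rows = []
        complete = ["1", "20", "male", "complete"] + ["1"] * 28
        gap = ["2", "21", "female", "complete"] + ["1"] * 27 + [""]
        gap2 = ["3", "22", "male", "complete"] + ["1"] * 27 + [""]
        rows = [complete, gap, gap2]
        path = tmp_path / "toy.csv"
        path.write_text("\n".join(",".join(r) for r in [header] + rows) + "\n")
        panel = read_panel(path)
        assert np.isnan(panel.wave2_items).sum() == 2
        from clpnet import little_mcar_test
        report = little_mcar_test(panel, include_age=False)
        assert report.n_patterns == 2

    def test_custom_schema_mapping(self, tmp_path, clean_panel):
        df = clean_panel.to_frame().rename(columns={"age": "age_years"})
        path = tmp_path / "renamed.csv"
        df.to_csv(path, index=False)
        panel = read_panel(path, {"age": "age_years"})
        assert np.allclose(panel.age, clean_panel.age)


class TestAttrition:
    def test_identical_groups_give_t_zero(self):
        # completers (even rows) and dropouts (odd rows) carry identical
        # baseline values, so every Welch t is exactly 0
        w1 = np.repeat(np.arange(5)[:, None], 2, axis=0).repeat(N_NODES, axis=1).astype(float) % 4
        status = np.array(["complete", "dropout"] * 5, dtype=object)
        age = np.repeat([20.0, 22.0, 24.0, 26.0, 28.0], 2)
        panel = _panel(w1, np.zeros((10, N_NODES)), status=status, age=age)
        for res in attrition_ttest(panel):
            assert res.t_statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_welch_formula(self, rng):
        n = 50
        a = rng.normal(10, 2, n)
        b = rng.normal(12, 2, n)
        w1 = np.zeros((2 * n, N_NODES))
        # encode ages as the variable of interest
        status = np.array(["complete"] * n + ["dropout"] * n, dtype=object)
        w2 = np.zeros((2 * n, N_NODES))
        w2[n:] = np.nan
        panel = _panel(w1, w2, status=status, age=np.concatenate([a, b]))
        res = {r.variable: r for r in attrition_ttest(panel)}["age"]
        se = np.sqrt(a.var(ddof=1) / n + b.var(ddof=1) / n)
        t_hand = (a.mean() - b.mean()) / se
        assert res.t_statistic == pytest.approx(t_hand, rel=1e-10)
        assert res.group_means == pytest.approx((a.mean(), b.mean()))

    def test_small_group_is_an_error(self):
        w1 = np.zeros((4, N_NODES))
        status = np.array(["complete", "complete", "complete", "dropout"], dtype=object)
        w2 = np.zeros((4, N_NODES)); w2[3] = np.nan  # noqa: E702
        panel = _panel(w1, w2, status=status)
        with pytest.raises(ValueError):
            attrition_ttest(panel)

    def test_mcar_dropout_rarely_significant(self):
        """Random (MCAR) attrition should not create baseline differences."""
        from clpnet import SimulationConfig, TrueNetworkSpec, simulate_panel
        spec = TrueNetworkSpec()
        nonsig = 0
        n_seeds = 40
        for seed in range(n_seeds):
            panel = simulate_panel(spec, SimulationConfig(
                n_participants=300, attrition_rate=0.2, seed=seed))
            results = attrition_ttest(panel)
            nonsig += all(r.p_value >= 0.05 for r in results)
        # three tests per seed; joint non-significance ~0.86 under the null
        assert nonsig >= 0.7 * n_seeds
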