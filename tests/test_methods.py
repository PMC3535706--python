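import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rnaiscreen.methods import (
    DEFAULT_METHODS,
    fold_change,
    lm_interaction_test,
    score_all,
    sensitivity_index,
    summarize_cells,
    t_statistic,
    wilcoxon_test,
)
from rnaiscreen.simulate import ScenarioConfig, ScreenDesign, simulate_screen

from conftest import make_toy_screen


def lstsq_lm_oracle(screen, sirna_id):
    """Brute-force least-squares version of the deviance-difference statistic."""
    w = screen.wells
    act = w[(w["kind"] == "active") & (w["sirna_id"] == sirna_id)]
    plates = act["plate"].unique()
    ctl = w[(w["kind"] == "control") & w["plate"].isin(plates)]
    sub = pd.concat([act, ctl])
    y = sub["viability"].to_numpy(float)
    x1 = (sub["condition"] == "treated").to_numpy(float)
    x2 = (sub["kind"] == "active").to_numpy(float)
    n = len(y)
    x_full = np.column_stack([np.ones(n), x1, x2, x1 * x2])
    x_red = np.column_stack([np.ones(n), x1])
    rss = lambda X: float(((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2).sum())
    rss_full, rss_red = rss(x_full), rss(x_red)
    beta3 = np.linalg.lstsq(x_full, y, rcond=None)[0][3]
    return (rss_red - rss_full) / (rss_full / (n - 4)), beta3


class TestSummarizeCells:
    def test_all_equal_wells(self):
        screen = make_toy_screen({"a": ([1, 1], [1, 1])}, ([1, 1], [1, 1]))
        cells = summarize_cells(screen, "a")
        assert (cells.rc, cells.rd, cells.cc, cells.cd) == (1, 1, 1, 1)

    def test_hand_arithmetic(self):
        screen = make_toy_screen(
            {"a": ([0.9, 1.1], [0.2, 0.4])}, ([1.0, 1.0], [0.5, 0.5])
        )
        cells = summarize_cells(screen, "a")
        assert (cells.rc, cells.rd, cells.cc, cells.cd) == pytest.approx((1.0, 0.3, 1.0, 0.5))

    def test_zero_noise_simulation_recovers_cell_mean_formulas(self):
        cfg = ScenarioConfig(sigma=1e-12, d=0.3, k=1.1, n_hit_low=0, n_hit_high=0, seed=2)
        ds = simulate_screen(cfg, ScreenDesign(replicates_per_condition=3))
        cells = summarize_cells(ds, "s0001")
        assert (cells.rc, cells.rd, cells.cc, cells.cd) == pytest.approx(
            (1.0, 0.3, 1.1, 0.33), abs=1e-6
        )

    def test_missing_sirna_errors(self):
        screen = make_toy_screen({"a": ([1], [1])}, ([1], [1]))
        with pytest.raises(KeyError, match="zzz"):
            summarize_cells(screen, "zzz")


class TestFoldChange:
    def test_equal_means_give_zero(self):
        screen = make_toy_screen({"a": ([1.0, 1.2], [0.9, 1.3])}, ([1], [1]))
        assert fold_change(screen, "a").statistic == pytest.approx(0.0)

    def test_hand_value(self):
        screen = make_toy_screen({"a": ([1.0, 1.0], [0.3, 0.3])}, ([1], [1]))
        sc = fold_change(screen, "a")
        assert sc.statistic == pytest.approx(math.log2(0.3))
        assert sc.direction == "sensitizing"

    def test_zero_noise_non_hit_sits_at_log2_d(self):
        """Every siRNA lands at log2(D) regardless of hit status: the drug
        multiplies both arms' means, so the ratio carries no RNAi signal."""
        cfg = ScenarioConfig(sigma=1e-12, d=0.3, seed=0, floor_epsilon=None)
        ds = simulate_screen(cfg, ScreenDesign(replicates_per_condition=3))
        for sid in ("s0001", "s0500"):
            assert fold_change(ds, sid).statistic == pytest.approx(math.log2(0.3), abs=1e-5)

    def test_non_positive_untreated_mean_flagged_invalid(self):
        screen = make_toy_screen({"a": ([0.0, 0.0], [0.5, 0.5])}, ([1], [1]))
        assert not fold_change(screen, "a").valid


class TestTStatistic:
    def test_identical_groups(self):
        screen = make_toy_screen({"a": ([1, 2, 3], [1, 2, 3])}, ([1], [1]))
        sc = t_statistic(screen, "a")
        assert sc.statistic == 0.0 and sc.p_value == 1.0

    def test_pooled_t_hand_computation(self):
        screen = make_toy_screen({"a": ([2, 3, 4], [1, 2, 3])}, ([1], [1]))
        sc = t_statistic(screen, "a")
        assert sc.statistic == pytest.approx(-1.224744871)
        assert sc.extras["df"] == 4

    def test_swapping_groups_negates_t(self):
        s1 = make_toy_screen({"a": ([2, 3, 4], [1, 2, 3])}, ([1], [1]))
        s2 = make_toy_screen({"a": ([1, 2, 3], [2, 3, 4])}, ([1], [1]))
        a, b = t_statistic(s1, "a"), t_statistic(s2, "a")
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_variance_different_means(self):
        screen = make_toy_screen({"a": ([1, 1], [2, 2])}, ([1], [1]))
        sc = t_statistic(screen, "a")
        assert sc.statistic == math.inf and sc.p_value == 0.0

    def test_single_well_per_arm_rejected(self):
        screen = make_toy_screen({"a": ([1], [1, 2])}, ([1], [1]))
        with pytest.raises(ValueError):
            t_statistic(screen, "a")


class TestSensitivityIndex:
    def test_all_ones_give_zero(self):
        screen = make_toy_screen({"a": ([1, 1], [1, 1])}, ([1, 1], [1, 1]))
        assert sensitivity_index(screen, "a").statistic == 0.0

    def test_multiplicative_null_forces_zero(self):
        # Rc=0.8, Cc=1, Cd=0.5, Rd=0.4: observed equals expected combination
        screen = make_toy_screen({"a": ([0.8, 0.8], [0.4, 0.4])}, ([1, 1], [0.5, 0.5]))
        assert sensitivity_index(screen, "a").statistic == pytest.approx(0.0)

    def test_hand_value_sensitizing(self):
        screen = make_toy_screen({"a": ([0.9, 0.9], [0.2, 0.2])}, ([1, 1], [0.5, 0.5]))
        sc = sensitivity_index(screen, "a")
        assert sc.statistic == pytest.approx(0.25)
        assert sc.direction == "sensitizing"
        assert sc.p_value is None


class TestLinearModel:
    def test_equal_cell_structure_gives_null_statistic(self):
        # active means equal control means per condition -> nested models agree
        screen = make_toy_screen(
            {"a": ([1.0, 1.2], [0.5, 0.7])}, ([1.0, 1.2], [0.5, 0.7])
        )
        sc = lm_interaction_test(screen, "a")
        assert sc.statistic == pytest.approx(0.0, abs=1e-9)
        assert sc.p_value == pytest.approx(1.0)

    def test_matches_lstsq_oracle_on_toy_wells(self):
        screen = make_toy_screen(
            {"a": ([1.0, 1.2], [0.1, 0.3])}, ([1.0, 1.2], [0.5, 0.7])
        )
        sc = lm_interaction_test(screen, "a")
        stat, beta3 = lstsq_lm_oracle(screen, "a")
        assert sc.statistic == pytest.approx(stat, rel=1e-8)
        assert sc.extras["beta3"] == pytest.approx(beta3, rel=1e-8)
        assert sc.direction == "sensitizing"

    def test_vectorized_scores_match_oracle_across_screen(self, small_screen):
        table = score_all(small_screen, ("lm",)).set_index("sirna_id")
        for sid in table.index:
            stat, beta3 = lstsq_lm_oracle(small_screen, sid)
            assert table.loc[sid, "statistic"] == pytest.approx(stat, rel=1e-8, abs=1e-10)
            assert table.loc[sid, "beta3"] == pytest.approx(beta3, rel=1e-8, abs=1e-12)

    def test_f_variant_is_monotone_transform_of_chi2(self, small_screen):
        chi = score_all(small_screen, ("lm",), lm_test="chi2")
        f = score_all(small_screen, ("lm",), lm_test="f")
        assert (chi["statistic"].rank() == f["statistic"].rank()).all()

    def test_perfect_fit_degenerate_case(self):
        screen = make_toy_screen({"a": ([1.0, 1.0], [0.5, 0.5])}, ([2.0, 2.0], [1.5, 1.5]))
        sc = lm_interaction_test(screen, "a")
        assert sc.statistic == math.inf and sc.p_value == 0.0


class TestWilcoxon:
    def test_identical_samples(self):
        screen = make_toy_screen({"a": ([1, 2], [1, 2])}, ([1], [1]))
        assert wilcoxon_test(screen, "a").p_value == pytest.approx(1.0)

    def test_exact_p_from_enumeration(self):
        # no overlap, n=2 per arm: one-sided p = 1/6, two-sided = 1/3
        screen = make_toy_screen({"a": ([3, 4], [1, 2])}, ([1], [1]))
        sc = wilcoxon_test(screen, "a")
        assert sc.p_value == pytest.approx(2 / 6)
        assert sc.direction == "sensitizing"

    def test_swapped_labels_mirror(self):
        s1 = make_toy_screen({"a": ([3, 4], [1, 2])}, ([1], [1]))
        s2 = make_toy_screen({"a": ([1, 2], [3, 4])}, ([1], [1]))
        a, b = wilcoxon_test(s1, "a"), wilcoxon_test(s2, "a")
        assert a.statistic == -b.statistic
        assert a.p_value == b.p_value


class TestScoreAll:
    def test_default_methods_give_3600_rows(self, default_screen):
        table = score_all(default_screen)
        assert len(table) == 900 * 4
        assert set(table["method"]) == set(DEFAULT_METHODS)

    def test_empty_method_list_gives_empty_table(self, default_screen):
        assert score_all(default_screen, ()).empty

    def test_deterministic(self, small_screen):
        pd.testing.assert_frame_equal(score_all(small_screen), score_all(small_screen))

    def test_vectorized_matches_per_sirna_reference(self, small_screen):
        table = score_all(small_screen, DEFAULT_METHODS + ("wilcoxon",))
        ref_fns = {
            "fold_change": fold_change,
            "t_test": t_statistic,
            "si": sensitivity_index,
            "lm": lm_interaction_test,
            "wilcoxon": wilcoxon_test,
        }
        for _, row in table.iterrows():
            ref = ref_fns[row["method"]](small_screen, row["sirna_id"])
            assert row["statistic"] == pytest.approx(ref.statistic, rel=1e-9, abs=1e-12)
            if ref.p_value is not None:
                assert row["p_value"] == pytest.approx(ref.p_value, rel=1e-9, abs=1e-12)
            assert row["direction"] == ref.direction

    def test_unknown_method_rejected(self, small_screen):
        with pytest.raises(ValueError):
            score_all(small_screen, ("ssmd",))

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        """Multiplying every viability by c > 0 changes no statistic."""
        cfg = ScenarioConfig(sigma=0.4, n_hit_low=2, n_hit_high=4, seed=99)
        design = ScreenDesign(n_plates=2, wells_per_plate=12, sirna_wells_per_plate=10,
                              control_wells_per_plate=2, replicates_per_condition=3)
        screen = simulate_screen(cfg, design)
        base = score_all(screen, DEFAULT_METHODS)
        scaled_screen = simulate_screen(cfg, design)
        scaled_screen.wells["viability"] *= scale
        scaled = score_all(scaled_screen, DEFAULT_METHODS)
        np.testing.assert_allclose(base["statistic"], scaled["statistic"], rtol=1e-7)
        np.testing.assert_allclose(base["p_value"], scaled["p_value"], rtol=1e-7)
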