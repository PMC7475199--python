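"""Tests for summary tables, Welch t tests, and trajectory aggregates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ffvpsim.cohort import AgentRecord
from ffvpsim.report import (
    effect_table,
    pattern_summary,
    trajectory_panel,
    welch_t,
)
from ffvpsim.simulate import SimulationConfig, simulate_cohort

from conftest import make_pattern_cohort

# Published n / mean / SD cells for end-of-study servings by food-desert
# exposure (never-exposed vs ever-exposed to FFVP) and the t statistics
# printed alongside them.
PRINTED_CELLS = {
    "never_desert": ((7942, 2.493, 0.500), (2591, 2.924, 0.269), -55.928),
    "desert": ((17598, 2.079, 0.472), (7850, 2.716, 0.461), -100.97),
    "total": ((25540, 2.208, 0.518), (10441, 2.767, 0.431), -105.200),
}


class TestWelchT:
    def test_equal_groups_give_zero(self):
        res = welch_t(50, 1.0, 0.3, 50, 1.0, 0.3)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("row", PRINTED_CELLS.values(), ids=PRINTED_CELLS.keys())
    def test_reproduces_printed_statistics(self, row):
        """Recomputing t from the published (rounded) cells lands within 0.5
        of each printed t statistic."""
        (n1, m1, s1), (n2, m2, s2), t_printed = row
        res = welch_t(n1, m1, s1, n2, m2, s2)
        assert res.t == pytest.approx(t_printed, abs=0.5)
        assert res.df > 0
        assert res.p < 0.0005  # printed as (0.000)

    def test_matches_scipy_from_stats(self):
        """Cross-check formulae against scipy's unequal-variance t test."""
        n1, m1, s1, n2, m2, s2 = 23, 1.7, 0.8, 41, 1.2, 1.1
        res = welch_t(n1, m1, s1, n2, m2, s2)
        ref = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    @pytest.mark.parametrize(
        "args",
        [
            (1, 1.0, 0.5, 10, 1.0, 0.5),
            (10, 1.0, 0.0, 10, 1.0, 0.0),
            (10, 1.0, -0.1, 10, 1.0, 0.5),
        ],
    )
    def test_degenerate_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            welch_t(*args)


def toy_final(rows):
    return pd.DataFrame(
        rows,
        columns=["agent_id", "exposure_pattern", "desert_history", "mean_servings"],
    )


class TestEffectTable:
    def test_printed_means_reproduce_published_effects(self):
        """Using the published cell means directly, the FFVP effect is 0.43
        servings outside food deserts and 0.64 inside."""
        non_desert = 2.924 - 2.493
        desert = 2.716 - 2.079
        assert round(non_desert, 2) == 0.43
        assert round(desert, 2) == 0.64

    def test_cells_partition_cohort(self):
        final = toy_final(
            [
                (0, "0000000", "0000000", 1.0),
                (1, "0000000", "0000000", 2.0),
                (2, "1000000", "0000000", 3.0),
                (3, "1000000", "0000000", 3.5),
                (4, "0000000", "1000000", 0.5),
                (5, "0000000", "0100000", 1.5),
                (6, "1100000", "1110000", 2.5),
                (7, "1100000", "1110000", 3.0),
            ]
        )
        table = effect_table(final)
        nd, des, tot = table.iloc[0], table.iloc[1], table.iloc[2]
        assert nd["n_unexposed"] + nd["n_exposed"] + des["n_unexposed"] + des["n_exposed"] == 8
        assert tot["n_unexposed"] + tot["n_exposed"] == 8
        assert nd["ffvp_effect"] == pytest.approx(3.25 - 1.5)
        assert des["ffvp_effect"] == pytest.approx(2.75 - 1.0)

    def test_empty_cells_yield_nan_not_crash(self):
        final = toy_final([(0, "0000000", "0000000", 1.0), (1, "0000000", "0000000", 2.0)])
        table = effect_table(final)
        assert table.loc[1, "n_unexposed"] == 0
        assert np.isnan(table.loc[0, "ffvp_effect"])
        assert np.isnan(table.loc[1, "t"])

    def test_joins_cohort_attributes_when_missing(self):
        cohort = [
            AgentRecord(0, "0000000", "1111111", 0.01),
            AgentRecord(1, "1111111", "1111111", 0.01),
        ]
        final = pd.DataFrame({"agent_id": [0, 1], "mean_servings": [1.0, 2.0]})
        table = effect_table(final, cohort)
        assert table.loc[1, "n_unexposed"] == 1
        assert table.loc[1, "n_exposed"] == 1


class TestPatternSummary:
    def test_single_pattern_single_row(self):
        final = toy_final([(0, "0000000", "0000000", 1.0), (1, "0000000", "0000000", 3.0)])
        out = pattern_summary(final)
        assert len(out) == 1
        assert out.loc[0, "n"] == 2
        assert out.loc[0, "mean_servings"] == pytest.approx(2.0)

    def test_sorted_by_exposure_years_then_pattern(self):
        final = toy_final(
            [
                (0, "1111111", "0000000", 3.0),
                (1, "0000001", "0000000", 1.0),
                (2, "1000000", "0000000", 1.5),
                (3, "0110000", "0000000", 2.0),
            ]
        )
        out = pattern_summary(final)
        assert list(out["exposure_pattern"]) == ["0000001", "1000000", "0110000", "1111111"]
        assert list(out["exposure_years"]) == [1, 1, 2, 7]

    def test_observed_patterns_bounded_by_possible(self):
        rows = [(i, f"{i % 4:07b}"[-7:], "0000000", 1.0) for i in range(40)]
        out = pattern_summary(toy_final(rows))
        assert out["n"].sum() == 40
        assert len(out) <= 128


class TestTrajectoryPanel:
    def test_single_agent_curve_equals_its_trajectory(self, fast_cfg):
        cohort = make_pattern_cohort("0011000", "0000000", 1)
        trajs, _ = simulate_cohort(cohort, fast_cfg)
        panel = trajectory_panel(trajs, cohort, ["0011000"])
        sub = panel[panel["exposure_pattern"] == "0011000"]
        np.testing.assert_allclose(sub["mean_v_hat_H"].to_numpy(), trajs[0].v_hat_H)

    def test_includes_reference_patterns_when_present(self, fast_cfg):
        cohort = (
            make_pattern_cohort("0011000", "0000000", 2)
            + make_pattern_cohort("0000000", "0000000", 2, start_id=10)
            + make_pattern_cohort("1111111", "0000000", 2, start_id=20)
        )
        trajs, _ = simulate_cohort(cohort, fast_cfg)
        panel = trajectory_panel(trajs, cohort, ["0011000"])
        assert set(panel["exposure_pattern"]) == {"0011000", "0000000", "1111111"}

    def test_full_exposure_dominates_no_exposure_everywhere(self):
        cfg = SimulationConfig(seed=23, record_every=60)
        cohort = make_pattern_cohort("1111111", "1111111", 200) + make_pattern_cohort(
            "0000000", "1111111", 200, start_id=500
        )
        trajs, _ = simulate_cohort(cohort, cfg)
        panel = trajectory_panel(trajs, cohort, ["1111111", "0000000"])
        wide = panel.pivot(index="step", columns="exposure_pattern", values="mean_v_hat_H")
        assert (wide["1111111"] >= wide["0000000"]).all()

    def test_missing_pattern_is_explicit_error(self, fast_cfg):
        cohort = make_pattern_cohort("0011000", "0000000", 1)
        trajs, _ = simulate_cohort(cohort, fast_cfg)
        with pytest.raises(ValueError, match="not present"):
            trajectory_panel(trajs, cohort, ["1111111"])
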