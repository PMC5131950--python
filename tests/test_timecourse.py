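import math

import numpy as np
import pytest

from eaeox import (
    BehaviorBins,
    CallLabel,
    WindowSpec,
    anova_games_howell,
    behavior_absolute_po2_tests,
    call_study,
    group_abs_delta_by_behavior,
    pair_score,
    regression_ftest,
    window_probabilities,
)
from eaeox import Group, Region, StudyDataset
from eaeox.calling import DayCall

from conftest import make_mouse
from oracles import ols_line, tukey_hsd_p, welch_t


def _call(mouse_id="E1", day=3, delta=0.0, label=CallLabel.NORMOXIC):
    return DayCall(
        mouse_id=mouse_id, day=day, mean_delta_eae=delta, mean_delta_control=0.0,
        t_stat=0.0, p_raw=1.0, alpha_corrected=0.005, n_eae=60, n_control=300,
        label=label,
    )


class TestWindowProbabilities:
    def test_forced_counting(self):
        calls = [_call(day=d, label=CallLabel.HYPOXIC) for d in (0, 1, 2)]
        calls += [_call(day=3), _call(day=3, label=CallLabel.HYPEROXIC)]
        df = window_probabilities(calls, WindowSpec(width=4))
        row = df.iloc[0]
        assert row["n_measurements"] == 5
        assert row["p_hypoxia"] == pytest.approx(0.6)
        assert row["p_hyperoxia"] == pytest.approx(0.2)

    def test_empty_window_reported_absent(self):
        calls = [_call(day=1, label=CallLabel.HYPOXIC), _call(day=9)]
        df = window_probabilities(calls, WindowSpec(width=4))
        middle = df[df.window_start == 4].iloc[0]
        assert middle["n_measurements"] == 0
        assert math.isnan(middle["p_hypoxia"])

    def test_windows_tile_all_calls(self, cereb_sim):
        ds, _ = cereb_sim
        calls, _, _ = call_study(ds)
        df = window_probabilities(calls, WindowSpec(width=4))
        assert int(df["n_measurements"].sum()) == len(calls)
        occupied = df[df.n_measurements > 0]
        assert ((occupied.p_hypoxia + occupied.p_hyperoxia) <= 1 + 1e-12).all()
        assert ((occupied.p_hypoxia >= 0) & (occupied.p_hypoxia <= 1)).all()

    def test_no_calls_rejected(self):
        with pytest.raises(ValueError):
            window_probabilities([], WindowSpec())


class TestBehaviorBinning:
    def test_bin_assignment_and_boundaries(self):
        bins = BehaviorBins()
        assert bins.bin_of(0.0) == "low"
        assert bins.bin_of(3.5) == "low"
        assert bins.bin_of(4.0) == "medium"  # half-open boundary
        assert bins.bin_of(8.0) == "high"
        assert bins.bin_of(12.0) == "high"  # closed top edge

    def test_above_top_edge_warns_into_top_bin(self):
        with pytest.warns(UserWarning, match="top bin"):
            assert BehaviorBins().bin_of(12.5) == "high"

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            BehaviorBins(edges=(0.0, 8.0, 4.0), labels=("a", "b"))

    def test_pairing_rule(self):
        behavior = [(10, 2.0), (14, 5.0)]
        assert pair_score(behavior, 10) == 2.0  # exact
        assert pair_score(behavior, 12) == 2.0  # tie -> earlier day
        assert pair_score(behavior, 13) == 5.0  # nearest
        assert pair_score(behavior, 20) is None  # beyond tolerance
        assert pair_score([], 5) is None

    def test_grouping_by_score_bin(self):
        calls = [
            _call("E1", day=3, delta=-2.0),
            _call("E2", day=3, delta=6.0),
            _call("E3", day=3, delta=-11.0),
            _call("E4", day=30, delta=5.0),  # no score within 2 days
        ]
        behavior = {"E1": [(3, 0.0)], "E2": [(3, 5.0)], "E3": [(3, 9.0)],
                    "E4": [(10, 1.0)]}
        groups, unpaired = group_abs_delta_by_behavior(calls, behavior)
        assert groups == {"low": [2.0], "medium": [6.0], "high": [11.0]}
        assert [c.mouse_id for c in unpaired] == ["E4"]

    def test_no_pairable_call_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            group_abs_delta_by_behavior([_call("E9", day=3)], {"E9": []})


class TestGamesHowell:
    def test_constant_groups_flagged(self):
        groups = {"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0], "c": [5.0, 5.0]}
        with pytest.warns(UserWarning, match="ANOVA F undefined"):
            f, p, pairwise = anova_games_howell(groups)
        assert math.isnan(f)
        by_pair = {c.pair: c for c in pairwise}
        assert by_pair[("a", "b")].q_stat == 0.0
        assert by_pair[("a", "b")].p_value == 1.0
        assert by_pair[("a", "c")].p_value == 0.0  # zero variance, unequal means

    def test_two_groups_reduce_to_welch_t(self):
        """With k = 2 the studentized-range p equals the Welch p (q = t*sqrt(2))."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(5, 30))
            y = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(5, 30))
            _, _, pairwise = anova_games_howell({"x": x, "y": y})
            t_ref, _, p_ref = welch_t(x, y)
            assert pairwise[0].q_stat == pytest.approx(abs(t_ref) * math.sqrt(2), rel=1e-9)
            assert pairwise[0].p_value == pytest.approx(p_ref, abs=1e-6)

    def test_equal_variance_equal_n_approaches_tukey(self):
        """Games-Howell collapses toward Tukey HSD when its unequal-variance
        allowance is not needed (sample variances standardized to equality)."""
        rng = np.random.default_rng(6)
        k, n = 3, 50
        for _ in range(50):
            arrays = []
            for _ in range(k):
                g = rng.normal(rng.uniform(-0.5, 0.5), 1.0, n)
                g = (g - g.mean()) / g.std(ddof=1)  # unit sample variance
                g = g + rng.uniform(-1, 1)
                arrays.append(g)
            _, _, pairwise = anova_games_howell(
                {f"g{i}": a for i, a in enumerate(arrays)}
            )
            ref = tukey_hsd_p([list(a) for a in arrays])
            for c in pairwise:
                i, j = int(c.pair[0][1]), int(c.pair[1][1])
                assert c.p_value == pytest.approx(ref[(i, j)], abs=0.01)

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        groups = {
            "a": rng.normal(0, 1.0, 12),
            "b": rng.normal(0.8, 2.0, 18),
            "c": rng.normal(-0.5, 0.5, 8),
        }
        _, _, pairwise = anova_games_howell(groups)
        df = pd.DataFrame(
            [(k, v) for k, vals in groups.items() for v in vals],
            columns=["grp", "val"],
        )
        ref = pingouin.pairwise_gameshowell(data=df, dv="val", between="grp")
        ours = {tuple(sorted(c.pair)): c.p_value for c in pairwise}
        for row in ref.itertuples(index=False):
            assert ours[tuple(sorted((row.A, row.B)))] == pytest.approx(
                row.pval, abs=1e-6
            )

    def test_relabelling_does_not_change_pair_p(self):
        rng = np.random.default_rng(8)
        g = {n: rng.normal(i, 1 + i, 10) for i, n in enumerate("abc")}
        _, _, p1 = anova_games_howell(g)
        _, _, p2 = anova_games_howell(dict(reversed(list(g.items()))))
        ours1 = {frozenset(c.pair): c.p_value for c in p1}
        ours2 = {frozenset(c.pair): c.p_value for c in p2}
        assert ours1.keys() == ours2.keys()
        for k in ours1:
            assert ours1[k] == pytest.approx(ours2[k], rel=1e-12)

    def test_small_group_excluded_with_warning(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [9.0]}
        with pytest.warns(UserWarning, match="excluding"):
            _, _, pairwise = anova_games_howell(groups)
        assert {c.pair for c in pairwise} == {("a", "b")}

    def test_fewer_than_two_usable_groups_rejected(self):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                anova_games_howell({"a": [1.0, 2.0], "b": [3.0]})


class TestRegressionFtest:
    def test_hand_least_squares_example(self):
        xs, ys = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 5.0, 6.0]
        slope, intercept, r2, f, p = regression_ftest(xs, ys)
        o_slope, o_intercept, o_r2 = ols_line(xs, ys)
        assert slope == pytest.approx(o_slope) == pytest.approx(1.4)
        assert intercept == pytest.approx(o_intercept)
        assert r2 == pytest.approx(o_r2) == pytest.approx(0.98)
        assert f == pytest.approx((4 - 2) * 0.98 / 0.02)  # = 98

    def test_collinear_limit(self):
        _, _, r2, f, p = regression_ftest([1, 2, 3, 4], [2, 4, 6, 8])
        assert r2 == 1.0 and math.isinf(f) and p == 0.0

    def test_flat_response(self):
        slope, _, r2, f, p = regression_ftest([1, 2, 3], [5.0, 5.0, 5.0])
        assert (slope, r2, f, p) == (0.0, 0.0, 0.0, 1.0)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="degenerate predictor"):
            regression_ftest([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_f_identity_on_random_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(3, 40))
            x = rng.normal(0, 1, n)
            y = 0.5 * x + rng.normal(0, rng.uniform(0.1, 2), n)
            _, _, r2, f, _ = regression_ftest(x, y)
            assert f == pytest.approx((n - 2) * r2 / (1 - r2), rel=1e-12)


class TestBehaviorAbsolutePo2:
    def test_shifted_bins_detected_as_lower(self, cereb_sim):
        ds, _ = cereb_sim
        results = behavior_absolute_po2_tests(ds)
        assert results
        m = len(results)
        for r in results:
            assert r.alpha_corrected == pytest.approx(0.05 / m)
            assert r.n_control_sessions >= 2

    def test_single_bin_family_is_one(self):
        controls = [
            make_mouse(f"C{i}", Group.CONTROL,
                       sessions=[(-1, [20.0] * 4), (14, [20.0 + 0.1 * i] * 6)])
            for i in (1, 2)
        ]
        eae = make_mouse(
            "E1", Group.EAE,
            sessions=[(-1, [25.0] * 4), (14, [15.0, 15.5] * 3),
                      (16, [14.0, 14.5] * 3)],
            behavior=[(14, 3.0), (16, 3.5)],
        )
        ds = StudyDataset(mice=controls + [eae], region=Region.CEREBELLUM)
        res = behavior_absolute_po2_tests(ds)
        assert len(res) == 1  # only the low-deficit bin is occupied
        assert res[0].alpha_corrected == pytest.approx(0.05)
        assert res[0].direction == "lower"  # EAE traces sit ~5 mmHg below

    def test_null_bins_match_nominal_size_with_independent_sessions(self):
        """With one post-induction session per animal the binned session
        means are independent, and under the null the significant-bin
        fraction stays at (below, after Bonferroni) the nominal alpha.
        With the full repeated-measures schedule this does not hold:
        sessions of one mouse share its baseline, which inflates the
        test's realized size (see the methods note)."""
        import dataclasses

        from eaeox.simulate import null_config, simulate_study

        base = dataclasses.replace(
            null_config("cerebellum"), n_eae=40, n_control=20,
            post_schedule=(14,),
        )
        n_sig = n_tests = 0
        for seed in range(30):
            ds, _ = simulate_study(dataclasses.replace(base, seed=40 + seed))
            for r in behavior_absolute_po2_tests(ds):
                n_tests += 1
                n_sig += r.significant
        assert n_tests >= 30
        rate = n_sig / n_tests
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_tests)

    def test_empty_control_pool_rejected(self, toy_dataset):
        ds = toy_dataset
        ds.mice = [m for m in ds.mice if m.mouse_id == "E1"]
        with pytest.raises(ValueError, match="control"):
            behavior_absolute_po2_tests(ds)
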