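"""Concentration-reduction metrics, thresholds, contours and Pareto fronts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from legacylag import (
    ExponentialTTD,
    OutletModel,
    ScenarioSpec,
    StepSourceParams,
    TabulatedTTD,
    UnreachableTargetError,
    benefit_threshold,
    contour_grid,
    cr_inf,
    cr_t,
    pareto_front,
    time_to_cr,
)
from conftest import make_model


class TestCrT:
    @pytest.mark.parametrize("pattern", ["frontal", "distal", "random"])
    def test_zero_at_t0_and_p0(self, scenario_source, pattern):
        assert cr_t(0.0, make_model(scenario_source, pattern=pattern)) == pytest.approx(
            0.0, abs=1e-12
        )
        assert cr_t(30.0, make_model(scenario_source, pattern=pattern, p=0.0)) == 0.0

    def test_random_worked_value_at_16y(self, scenario_source):
        model = make_model(scenario_source, pattern="random", p=0.5, mu=21.6, k=0.18)
        assert cr_t(16.0, model) == pytest.approx(0.43, abs=0.03)

    def test_frontal_worked_value_at_16y(self, scenario_source):
        model = make_model(scenario_source, pattern="frontal", p=0.5, mu=21.6, k=0.18)
        assert cr_t(16.0, model) == pytest.approx(0.85, abs=0.03)

    def test_monotone_in_t_and_p(self, walnut_source):
        for pattern in ("frontal", "distal", "random"):
            t = np.linspace(0, 60, 31)
            vals = cr_t(t, make_model(walnut_source, pattern=pattern, k=0.06))
            assert np.all(np.diff(vals) >= -1e-10)
            ps = np.linspace(0.0, 1.0, 11)
            at_t = [
                cr_t(20.0, make_model(walnut_source, pattern=pattern, p=p, k=0.06))
                for p in ps
            ]
            assert np.all(np.diff(at_t) >= -1e-10)


class TestCrInf:
    def test_random_one_to_one_rule(self, walnut_source):
        model = make_model(walnut_source, pattern="random", p=0.2, k=0.24)
        assert cr_inf(model) == 0.2

    @given(p=st.floats(0.0, 1.0), mu=st.floats(1.0, 80.0), k=st.floats(0.0, 0.6))
    def test_random_rule_independent_of_mu_and_k(self, walnut_source, p, mu, k):
        model = make_model(walnut_source, pattern="random", p=p, mu=mu, k=k)
        assert cr_inf(model) == p

    def test_frontal_distal_closed_forms(self, walnut_source):
        # 1 + mu k = 2.296 at mu=21.6, k=0.06
        frontal = make_model(walnut_source, pattern="frontal", p=0.5, k=0.06)
        distal = make_model(walnut_source, pattern="distal", p=0.5, k=0.06)
        assert cr_inf(frontal) == pytest.approx(1 - 0.5**2.296, rel=1e-12)
        assert cr_inf(frontal) == pytest.approx(0.796, abs=1e-3)
        assert cr_inf(distal) == pytest.approx(0.5**2.296, rel=1e-12)
        assert cr_inf(distal) == pytest.approx(0.204, abs=1e-3)

    @pytest.mark.parametrize("pattern", ["frontal", "distal", "random"])
    def test_no_decay_collapses_to_p(self, walnut_source, pattern):
        model = make_model(walnut_source, pattern=pattern, p=0.37, k=0.0)
        assert cr_inf(model) == pytest.approx(0.37, rel=1e-12)

    def test_matches_long_time_cr_t(self, walnut_source):
        """Closed-form limits equal the trajectory at t = 50*mu."""
        for pattern in ("frontal", "distal", "random"):
            model = make_model(walnut_source, pattern=pattern, p=0.4, mu=10.0, k=0.1)
            assert cr_t(500.0, model) == pytest.approx(cr_inf(model), abs=1e-5)

    def test_general_ttd_quadrature_route(self, walnut_source):
        taus = np.linspace(0.0, 400.0, 4001)
        tab = TabulatedTTD(taus, np.exp(-taus / 21.6) / 21.6)
        for pattern in ("frontal", "distal"):
            tab_model = OutletModel(walnut_source, tab, 0.06, ScenarioSpec(pattern, 0.5))
            exp_model = make_model(walnut_source, pattern=pattern, p=0.5, k=0.06)
            assert cr_inf(tab_model) == pytest.approx(cr_inf(exp_model), abs=2e-3)

    def test_non_decaying_source_rejected(self):
        model = OutletModel(
            StepSourceParams(15.0, post=5.0), ExponentialTTD(21.6), 0.1,
            ScenarioSpec("random", 0.5),
        )
        with pytest.raises(ValueError):
            cr_inf(model)

    @given(p=st.floats(0.01, 0.99), mu=st.floats(2.0, 60.0), k=st.floats(1e-3, 0.5))
    def test_scenario_ordering_for_positive_k(self, walnut_source, p, mu, k):
        frontal = cr_inf(make_model(walnut_source, pattern="frontal", p=p, mu=mu, k=k))
        random_ = cr_inf(make_model(walnut_source, pattern="random", p=p, mu=mu, k=k))
        distal = cr_inf(make_model(walnut_source, pattern="distal", p=p, mu=mu, k=k))
        assert frontal >= random_ >= distal
        assert frontal >= p >= distal


class TestTimeToCr:
    def test_distal_onset_lag(self, walnut_source):
        """Any distal benefit waits for the shortest converted travel time."""
        model = make_model(walnut_source, pattern="distal", p=0.5, mu=21.6, k=0.06)
        onset = 21.6 * np.log(2)
        t = time_to_cr(0.001, model)
        assert t >= onset - 1e-6
        assert onset == pytest.approx(15.0, abs=0.03)

    def test_unreachable_target_names_cr_inf(self, walnut_source):
        model = make_model(walnut_source, pattern="random", p=0.3, k=0.1)
        with pytest.raises(UnreachableTargetError, match="0.3"):
            time_to_cr(0.5, model)

    def test_small_target_immediate_for_random(self, walnut_source):
        model = make_model(walnut_source, pattern="random", p=0.5, k=0.1)
        assert time_to_cr(1e-6, model) < 0.5

    def test_crossing_is_consistent(self, walnut_source):
        model = make_model(walnut_source, pattern="frontal", p=0.6, mu=15.0, k=0.1)
        t = time_to_cr(0.4, model)
        assert cr_t(t, model) == pytest.approx(0.4, abs=1e-6)


class TestBenefitThreshold:
    def test_exponential_closed_form(self):
        pstar = benefit_threshold(5.0, ExponentialTTD(15.0))
        assert pstar == pytest.approx(1 - np.exp(-1 / 3), rel=1e-12)
        assert pstar == pytest.approx(0.2835, abs=1e-4)

    def test_long_deadline_approaches_one(self):
        assert benefit_threshold(1e4, ExponentialTTD(15.0)) == pytest.approx(1.0)

    def test_frontal_cr_flat_beyond_threshold(self, walnut_source):
        """Converting past p* = F(t_d) adds nothing by the deadline."""
        t_d, mu = 5.0, 15.0
        pstar = benefit_threshold(t_d, ExponentialTTD(mu))
        base = cr_t(t_d, make_model(walnut_source, pattern="frontal", p=pstar, mu=mu,
                                    k=0.06))
        for p in (pstar + 0.1, 0.9, 1.0):
            val = cr_t(t_d, make_model(walnut_source, pattern="frontal", p=p, mu=mu,
                                       k=0.06))
            assert abs(val - base) < 1e-9

    def test_invalid_deadline(self):
        with pytest.raises(ValueError):
            benefit_threshold(0.0, ExponentialTTD(15.0))


class TestContourGrid:
    def test_random_inf_columns_equal_p(self, walnut_source):
        p = np.linspace(0.1, 0.9, 9)
        mu = np.array([5.0, 20.0, 50.0])
        grid = contour_grid(p, mu, "inf", "random", 0.06, walnut_source)
        for j in range(mu.size):
            assert grid.cr[:, j] == pytest.approx(p, rel=1e-12)

    def test_frontal_inf_increases_with_mu(self, walnut_source):
        p = np.array([0.3, 0.6])
        mu = np.array([5.0, 20.0, 50.0])
        grid = contour_grid(p, mu, "inf", "frontal", 0.06, walnut_source)
        assert np.all(np.diff(grid.cr, axis=1) > 0)
        distal = contour_grid(p, mu, "inf", "distal", 0.06, walnut_source)
        assert np.all(np.diff(distal.cr, axis=1) < 0)

    def test_elementwise_scenario_ordering(self, walnut_source):
        p = np.linspace(0.1, 0.9, 5)
        mu = np.array([10.0, 30.0])
        grids = {
            pat: contour_grid(p, mu, 5.0, pat, 0.06, walnut_source).cr
            for pat in ("frontal", "random", "distal")
        }
        assert np.all(grids["frontal"] >= grids["random"] - 1e-10)
        assert np.all(grids["random"] >= grids["distal"] - 1e-10)

    def test_single_cell_reduces_to_scalar_metric(self, walnut_source):
        grid = contour_grid([0.5], [21.6], 16.0, "random", 0.18, walnut_source)
        model = make_model(walnut_source, pattern="random", p=0.5, mu=21.6, k=0.18)
        assert grid.cr[0, 0] == pytest.approx(cr_t(16.0, model), rel=1e-12)

    def test_long_frame_shape(self, walnut_source):
        grid = contour_grid([0.2, 0.5], [10.0, 20.0, 30.0], "inf", "random", 0.06,
                            walnut_source)
        frame = grid.to_long_frame()
        assert len(frame) == 6
        assert set(frame.columns) == {"p", "mu_years", "cr"}


class TestParetoFront:
    def test_largest_p_has_minimal_time(self, walnut_source):
        front = pareto_front(0.3, 15.0, "random", 0.06, walnut_source,
                             np.linspace(0.35, 1.0, 14))
        times = [pt.time_to_target for pt in front]
        ps = [pt.p for pt in front]
        assert times == sorted(times, reverse=True)
        assert ps == sorted(ps)
        assert min(times) == times[-1]

    def test_random_feasibility_bound(self, walnut_source):
        """CR_inf = p for random, so a 50% goal needs p > 0.5."""
        front = pareto_front(0.5, 10.0, "random", 0.06, walnut_source,
                             np.linspace(0.1, 1.0, 19))
        assert all(pt.p > 0.5 for pt in front)

    def test_frontal_dominates_random(self, walnut_source):
        grid = np.linspace(0.55, 1.0, 10)
        frontal = {pt.p: pt.time_to_target
                   for pt in pareto_front(0.5, 15.0, "frontal", 0.06, walnut_source, grid)}
        random_ = {pt.p: pt.time_to_target
                   for pt in pareto_front(0.5, 15.0, "random", 0.06, walnut_source, grid)}
        common = set(frontal) & set(random_)
        assert common
        for p in common:
            assert frontal[p] <= random_[p] + 1e-9

    def test_infeasible_everywhere_raises(self, walnut_source):
        with pytest.raises(UnreachableTargetError, match="max achievable"):
            pareto_front(0.9, 10.0, "random", 0.06, walnut_source,
                         np.linspace(0.1, 0.5, 5))
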