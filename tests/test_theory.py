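"""Closed-form machinery: conditional probabilities, path counts, tree laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sictf.epidemics import EpidemicParams
from sictf.networks import rb_level_count
from sictf.theory import (
    PathLengthDistribution,
    TheoryParams,
    det_stopped_path_dist,
    effective_params,
    ls_plus_success_lower_bound,
    ls_success_probability,
    p_asym_given_not_hosp,
    predict_success,
    rb_level_count_closed_form,
    ret_expected_profile,
    ret_expected_size,
    ret_profile_array,
    ret_stopped_path_dist,
    simulate_ret_stopped,
    valid_k_set,
)


class TestConditionalAsymptomatic:
    def test_degenerate_cases(self):
        assert p_asym_given_not_hosp(0.0, 0.5) == 0.0
        assert p_asym_given_not_hosp(0.3, 0.0) == pytest.approx(0.3)
        with pytest.raises(ValueError):
            p_asym_given_not_hosp(0.0, 1.0)

    def test_against_monte_carlo_course_oracle(self, rng):
        p_a, p_h = 0.4, 0.083
        n = 200_000
        asym = rng.random(n) < p_a
        hosp = (~asym) & (rng.random(n) < p_h)
        kept = ~hosp
        est = asym[kept].mean()
        se = np.sqrt(est * (1 - est) / kept.sum())
        assert abs(p_asym_given_not_hosp(p_a, p_h) - est) < 3 * se
        assert p_asym_given_not_hosp(p_a, p_h) == pytest.approx(0.4210, abs=5e-4)


class TestValidKSet:
    def test_enumerated_examples(self):
        assert valid_k_set(2, 0, 0) == [3]
        assert valid_k_set(2, 1, 0) == [1]
        assert valid_k_set(2, 0, 1) == [1]
        assert valid_k_set(2, 1, 1) == []

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(2, 15), alpha=st.integers(0, 1), beta=st.integers(0, 1))
    def test_parity_and_bounds(self, n, alpha, beta):
        ks = valid_k_set(n, alpha, beta)
        for k in ks:
            assert (k - n) % 2 == 1
            assert 2 - (alpha + beta) <= k <= n + 1 - 2 * (alpha + beta)


class TestDenominatorIdentity:
    @pytest.mark.parametrize("d_c,d_h", [(3, 2), (2, 1), (4, 3), (2, 4)])
    def test_closed_form_matches_tree_counts(self, d_c, d_h):
        for n in range(1, 13):
            exact = rb_level_count(d_c, d_h, n)
            closed = rb_level_count_closed_form(d_c, d_h, n)
            assert abs(closed - exact) / exact < 1e-6


class TestLsSuccess:
    def test_zero_p_gives_total_mass(self):
        dist = PathLengthDistribution(np.array([0.1, 0.3, 0.4]))
        assert ls_success_probability(dist, 0.0) == pytest.approx(0.8)

    def test_point_mass(self):
        dist = PathLengthDistribution.point_mass(2, n_max=5)
        assert ls_success_probability(dist, 0.5) == pytest.approx(0.25)


class TestLsPlusBound:
    def test_point_mass_boundary_terms(self):
        p = p_asym_given_not_hosp(0.4, 0.083)
        assert ls_plus_success_lower_bound(
            PathLengthDistribution.point_mass(0, 5), p, 3, 2) == pytest.approx(1.0)
        assert ls_plus_success_lower_bound(
            PathLengthDistribution.point_mass(1, 5), p, 3, 2) == pytest.approx(1 - p)

    def test_point_mass_n2_hand_count(self):
        """Hand enumeration of the 18 length-2 paths: 6 all-lone paths need
        the source and the middle node symptomatic; 12 paths sharing a
        household with the source or the endpoint need only the source, so
        the bound is (6 (1-p)^2 + 12 (1-p)) / 18."""
        p = p_asym_given_not_hosp(0.4, 0.083)
        expected = (6 * (1 - p) ** 2 + 12 * (1 - p)) / 18
        got = ls_plus_success_lower_bound(
            PathLengthDistribution.point_mass(2, 5), p, 3, 2)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.49778, abs=1e-5)

    @pytest.mark.parametrize("d_c,d_h", [(3, 2), (2, 1), (4, 3), (2, 4), (5, 0)])
    def test_weighted_counts_exhaust_level_population_at_p_zero(self, d_c, d_h):
        # at p = 0 every embedding succeeds, so the bound must hit the total mass
        dist = PathLengthDistribution(np.full(13, 1 / 13))
        assert ls_plus_success_lower_bound(dist, 0.0, d_c, d_h) == pytest.approx(
            dist.mass.sum(), rel=1e-9)

    def test_dominates_ls_success(self):
        for p_a in (0.1, 0.4, 0.7):
            p = p_asym_given_not_hosp(p_a, 0.083)
            dist = ret_stopped_path_dist(
                TheoryParams.from_epidemic(EpidemicParams(p_a=p_a), 3, 2))
            assert ls_plus_success_lower_bound(dist, p, 3, 2) >= \
                ls_success_probability(dist, p) - 1e-12

    def test_dc_one_falls_back_to_ls(self):
        dist = PathLengthDistribution.point_mass(3, 5)
        assert ls_plus_success_lower_bound(dist, 0.3, 1, 2) == \
            ls_success_probability(dist, 0.3)


class TestRetProfile:
    def test_boundary_cases(self):
        assert ret_expected_profile(3, 5, 5, 4.6, 0.3) == 0.0  # l > t
        assert ret_expected_profile(7, 0, 5, 4.6, 0.3) == 1.0
        assert ret_expected_profile(1, 1, 5, 4.6, 0.27) == pytest.approx(5 * 0.27)

    def test_size_identity_across_grid(self):
        """Row sums of the expected profile reproduce the closed-form size."""
        for d_r, d, p_i in [(5, 4.645751311064591, 0.271), (5, 5, 0.271),
                            (4, 3.0, 0.5), (6, 2.5, 0.1)]:
            for t in range(21):
                total = sum(ret_expected_profile(t, l, d_r, d, p_i)
                            for l in range(t + 1))
                assert total == pytest.approx(ret_expected_size(t, d_r, d, p_i),
                                              rel=1e-9)

    def test_reference_value(self):
        assert ret_expected_size(2, 5, 4.645751311064591, 0.271) == pytest.approx(
            5.0489, abs=2e-4)

    def test_degenerate_degree_rejected(self):
        with pytest.raises(ValueError):
            ret_expected_size(3, 5, 1.0, 0.2)


class TestEffectiveParams:
    def test_time_rescaling(self):
        p_i_eff, d_r, d = effective_params(0.1, 3, 3, 2)
        assert p_i_eff == pytest.approx(0.271)
        assert d_r == 5
        assert d == pytest.approx(4.6458, abs=2e-4)

    def test_degenerate_household_free(self):
        p_i_eff, d_r, d = effective_params(0.2, 2, 4, 0)
        assert d == 4.0 and d_r == 4

    def test_level_weighted_tree_average_agrees(self):
        """Cross-check the stationary mean degree against an explicit tree."""
        from sictf.networks import build_rb_tree

        tree = build_rb_tree(3, 2, 9)
        weights = {"red": 3 + 2, "blue": 3 + 1}
        levels = [v for v in tree.nodes if 7 <= tree.level(v) <= 9]
        avg = np.mean([weights[tree.color(v)] for v in levels])
        _, _, d = effective_params(0.1, 3, 3, 2)
        assert d == pytest.approx(avg, abs=5e-3)


class TestStoppedDet:
    def test_certain_hospitalization_stops_at_root(self):
        c = np.zeros((4, 3))
        c[:, 0] = 1
        c[1:, 1] = [2, 4, 8]
        dist = det_stopped_path_dist(c, 0.0, 1.0)
        assert dist.mass[0] == pytest.approx(1.0)

    def test_geometric_profile_splits_evenly(self):
        T = 80
        c = np.zeros((T, 2))
        c[:, 0] = 1
        c[:, 1] = np.arange(T)
        dist = det_stopped_path_dist(c, 0.0, 0.5)
        assert dist.mass[0] == pytest.approx(0.5, abs=1e-12)
        assert dist.mass[1] == pytest.approx(0.5, abs=1e-12)

    def test_mass_sums_to_one(self):
        tp = TheoryParams.from_epidemic(EpidemicParams(), 3, 2, n_max=20, t_max=60)
        prof = ret_profile_array(tp, t_max=60, l_max=20)
        dist = det_stopped_path_dist(prof, tp.p_a, tp.p_h)
        assert dist.truncation_deficit < 1e-6

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            det_stopped_path_dist(np.array([[2.0, 0.0], [3.0, 1.0]]), 0.4, 0.1)
        shrinking = np.array([[1.0, 0.0], [1.0, 3.0], [1.0, 2.0]])
        with pytest.raises(ValueError):
            det_stopped_path_dist(shrinking, 0.4, 0.1)
        stalled = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            det_stopped_path_dist(stalled, 0.4, 0.1)

    def test_against_brute_force_stopped_simulation(self, rng):
        """Integer DET profile: the law matches direct stopping simulation."""
        c = np.array([[1, 0, 0], [1, 2, 0], [1, 4, 3], [1, 4, 9]], dtype=float)
        p_a, p_h = 0.2, 0.5
        dist = det_stopped_path_dist(c, p_a, p_h)
        q_hosp = (1 - p_a) * p_h
        hits = np.zeros(3)
        n = 20_000
        for _ in range(n):
            prev = np.zeros(3)
            for t in range(4):
                new = c[t] - prev
                arrivals = np.repeat(np.arange(3), new.astype(int))
                rng.shuffle(arrivals)
                flags = rng.random(len(arrivals)) < q_hosp
                if flags.any():
                    hits[arrivals[np.argmax(flags)]] += 1
                    break
                prev = c[t]
        emp = hits / n
        for l in range(3):
            se = np.sqrt(max(emp[l] * (1 - emp[l]), 1e-6) / n)
            assert abs(emp[l] - dist.mass[l] / dist.mass.sum()) < 4 * se


class TestStoppedRet:
    def test_equals_det_on_expected_profile(self):
        tp = TheoryParams.from_epidemic(EpidemicParams(), 3, 2, n_max=12, t_max=60)
        direct = ret_stopped_path_dist(tp)
        via_det = det_stopped_path_dist(
            ret_profile_array(tp, t_max=60, l_max=12), tp.p_a, tp.p_h)
        assert np.max(np.abs(direct.mass - via_det.mass[:13])) < 1e-9

    def test_certain_hospitalization(self):
        tp = TheoryParams(p=0.0, p_a=0.0, p_h=1.0, d_c=3, d_h=2, d_r=5,
                          d=4.6458, p_i_eff=0.271, n_max=6, t_max=40)
        dist = ret_stopped_path_dist(tp)
        assert dist.mass[0] == pytest.approx(1.0)

    def test_simulator_degenerate_cases(self):
        _, level = simulate_ret_stopped(5, 4.6458, 0.271, 0.0, 1.0, seed=0)
        assert level == 0
        profile, level = simulate_ret_stopped(5, 4.6458, 0.0, 0.4, 0.083, seed=1,
                                              t_max=20)
        assert profile.sum() == 1  # only the root ever exists

    def test_simulated_size_matches_expectation(self):
        rng = np.random.default_rng(5)
        sizes = []
        for _ in range(3000):
            profile, _ = simulate_ret_stopped(5, 5, 0.271, 0.0, 0.0, rng, t_max=4)
            sizes.append(profile.sum())
        mean, se = np.mean(sizes), np.std(sizes, ddof=1) / np.sqrt(len(sizes))
        assert abs(mean - ret_expected_size(4, 5, 5, 0.271)) < 3 * se


class TestPredictSuccess:
    def test_no_asymptomatics_means_certain_ls(self):
        val = predict_success("LS", EpidemicParams(p_a=0.0), 3, 2)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_ls_plus_at_least_ls(self):
        for p_a in (0.2, 0.4, 0.6):
            params = EpidemicParams(p_a=p_a)
            assert predict_success("LS+", params, 3, 2) >= \
                predict_success("LS", params, 3, 2) - 1e-12

    def test_monotone_decreasing_in_asymptomatic_share(self):
        grid = [0.0, 0.2, 0.4, 0.6, 0.8]
        for kind in ("LS", "LS+"):
            vals = [predict_success(kind, EpidemicParams(p_a=a), 3, 2) for a in grid]
            assert all(x >= y - 1e-12 for x, y in zip(vals, vals[1:]))

    def test_probabilities_in_unit_interval(self):
        for p_i in (0.05, 0.1, 0.3):
            for kind in ("LS", "LS+"):
                v = predict_success(kind, EpidemicParams(p_i=p_i), 3, 2)
                assert 0.0 <= v <= 1.0


@settings(max_examples=25, deadline=None)
@given(
    mass=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10),
    p=st.floats(0.0, 1.0),
)
def test_success_functionals_are_probabilities(mass, p):
    total = sum(mass)
    if total > 0:
        mass = [m / total for m in mass]
    dist = PathLengthDistribution(np.array(mass))
    ls = ls_success_probability(dist, p)
    lsp = ls_plus_success_lower_bound(dist, p, 3, 2)
    assert -1e-9 <= ls <= 1.0 + 1e-9
    assert -1e-9 <= lsp <= 1.0 + 1e-9
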