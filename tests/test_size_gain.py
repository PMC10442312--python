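"""Size-Gain baseline: feasibility rule, sensor choice, run semantics."""

import networkx as nx
import numpy as np
import pytest

from sictf.epidemics import EpidemicParams, simulate_dde
from sictf.networks import HouseholdNetwork, generate_hnm
from sictf.oracle import SictfOracle
from sictf.size_gain import (
    ASYM,
    NEG,
    SYM,
    Observation,
    SGConfig,
    SGState,
    _filter,
    run_size_gain,
    sg_feasible,
    sg_select_sensor,
)


def _line_net(n):
    g = nx.path_graph(n)
    for u, v in g.edges():
        g[u][v]["kind"] = "external"
    return HouseholdNetwork(N=n, d_h=0, d_c=2,
                            households=[(i,) for i in range(n)], graph=g)


def _star_net(n_leaves):
    g = nx.star_graph(n_leaves)
    for u, v in g.edges():
        g[u][v]["kind"] = "external"
    return HouseholdNetwork(N=n_leaves + 1, d_h=0, d_c=n_leaves,
                            households=[(i,) for i in range(n_leaves + 1)], graph=g)


class TestFeasibility:
    def test_same_node_pair_always_feasible(self):
        o = Observation(3, SYM, 5.0)
        dist = lambda obs_node, c: 2
        assert sg_feasible(0, o, o, dist, sigma=0.5)

    def test_symptomatic_pair_exclusion_arithmetic(self):
        # |(10-5) - (2-1)| = 4, bound sigma*(1+2) = 3: excluded
        d = {1: 1, 2: 2}
        dist = lambda obs_node, c: d[obs_node]
        o1, o2 = Observation(1, SYM, 5.0), Observation(2, SYM, 10.0)
        assert not sg_feasible(0, o1, o2, dist, sigma=1.0)
        assert sg_feasible(0, o1, o2, dist, sigma=1.5)

    def test_huge_sigma_accepts_everything(self, rng):
        for _ in range(20):
            d = dict(enumerate(rng.integers(1, 10, size=2)))
            t = rng.normal(scale=20, size=2)
            o1 = Observation(0, SYM, t[0])
            o2 = Observation(1, rng.choice([SYM, NEG, ASYM]), t[1])
            assert sg_feasible(9, o1, o2, lambda o, c: d[o], sigma=1e6)

    def test_unreachable_candidate_infeasible(self):
        o1, o2 = Observation(0, SYM, 1.0), Observation(1, SYM, 2.0)
        dist = lambda o, c: None
        assert not sg_feasible(5, o1, o2, dist, sigma=10.0)

    def test_bound_kinds_drop_one_side(self):
        # negative at small time would violate the two-sided rule but is fine
        # one-sided (the true time can only be larger)
        d = {1: 1, 2: 1}
        dist = lambda o, c: d[o]
        sym = Observation(1, SYM, 10.0)
        neg_early = Observation(2, NEG, 0.0)
        assert sg_feasible(0, sym, neg_early, dist, sigma=0.5)
        # ...but a negative far in the future stays a violation
        neg_late = Observation(2, NEG, 30.0)
        assert not sg_feasible(0, sym, neg_late, dist, sigma=0.5)
        # asymptomatic mirrors it: an early upper bound violates, a late one is fine
        asym_late = Observation(2, ASYM, 30.0)
        assert sg_feasible(0, sym, asym_late, dist, sigma=0.5)
        asym_early = Observation(2, ASYM, -30.0)
        assert not sg_feasible(0, asym_early, sym, dist, sigma=0.5)

    def test_filter_monotone(self, rng):
        net = _line_net(12)
        dist_maps = {
            v: dict(nx.single_source_shortest_path_length(net.graph, v))
            for v in net.nodes()
        }
        dist = lambda o, c: dist_maps[o].get(c)
        cands = set(net.nodes())
        obs = [Observation(0, SYM, 0.0)]
        for v, t in [(4, 4.2), (9, 8.7), (2, 2.5)]:
            new = Observation(v, SYM, t)
            filtered = _filter(cands, new, obs, dist, sigma=0.4)
            assert filtered <= cands
            cands = filtered
            obs.append(new)


class TestSensorSelection:
    def test_minimal_candidate_set_needs_no_sensor(self):
        state = SGState({3}, [], sigma=1.0, deadline_day=10)
        with pytest.raises(ValueError):
            sg_select_sensor(state, None, {1, 2}, lambda o, c: 1, 0.0,
                             np.random.default_rng(0), SGConfig())

    def test_star_matches_brute_force(self):
        """Uncapped selection equals exhaustive hypothesis enumeration."""
        net = _star_net(6)
        dist_maps = {
            v: dict(nx.single_source_shortest_path_length(net.graph, v))
            for v in net.nodes()
        }
        dist = lambda o, c: dist_maps[o].get(c)
        cfg = SGConfig(day_grid_step=1, max_untested=10**6, max_hypotheses=10**6)
        obs = [Observation(1, SYM, 3.0)]
        state = SGState(set(net.nodes()), obs, sigma=0.3, deadline_day=99)
        untested = set(net.nodes()) - {1}
        pick = sg_select_sensor(state, net, untested, dist, current_day_hops=4.0,
                                rng=np.random.default_rng(0), config=cfg)

        # independent brute force over every (source, day) hypothesis
        import math
        days = np.arange(math.floor(0.0), math.ceil(4.0) + 1, 1, dtype=float)
        best = None
        for u in sorted(untested):
            sizes = []
            for s0 in sorted(state.candidate_set):
                for t0 in days:
                    pred = Observation(u, SYM, t0 + dist(u, s0))
                    kept = sum(
                        1 for c in state.candidate_set
                        if all(sg_feasible(c, pred, o, dist, state.sigma)
                               for o in obs)
                    )
                    sizes.append(kept)
            score = np.mean(sizes)
            if best is None or score < best[1]:
                best = (u, score)
        assert pick == best[0]


class TestRun:
    def _conditioned(self, net, params, seed):
        rng = np.random.default_rng(seed)
        for s in range(200):
            src = int(rng.integers(net.N))
            trace = simulate_dde(net, src, params, seed=seed + 100 + s, horizon=80)
            if trace.first_hospitalized is not None:
                return trace
        raise RuntimeError("no conditioned run")

    def test_deterministic_spread_on_line_finds_source(self):
        net = _line_net(15)
        params = EpidemicParams(p_i=1.0, p_a=0.0, p_h=0.3)
        for seed in (0, 1, 2):
            trace = self._conditioned(net, params, seed)
            oracle = SictfOracle(trace, net, budget=2)
            res = run_size_gain(oracle, net,
                                deadline_day=trace.first_hospitalized[1] + 25,
                                seed=seed, config=SGConfig(sigma=0.1))
            assert res.found_source

    def test_immediate_deadline_falls_back_uniformly(self):
        net = _line_net(15)
        params = EpidemicParams(p_i=1.0, p_a=0.0, p_h=0.3)
        trace = self._conditioned(net, params, 0)
        oracle = SictfOracle(trace, net)
        res = run_size_gain(oracle, net, deadline_day=trace.first_hospitalized[1],
                            seed=5)
        assert res.tests_used == 0
        assert res.estimate in set(net.nodes())

    def test_zero_sigma_conflict_empties_candidate_set(self):
        net = _line_net(15)
        params = EpidemicParams(p_i=0.5, p_a=0.0, p_h=0.3)
        trace = self._conditioned(net, params, 3)
        oracle = SictfOracle(trace, net, budget=4)
        res = run_size_gain(oracle, net,
                            deadline_day=trace.first_hospitalized[1] + 20,
                            seed=3, config=SGConfig(sigma=0.0))
        assert res.candidate_set_empty and res.estimate is None

    def test_seeded_reproducibility_including_fallback(self):
        net = generate_hnm(48, 2, 3, seed=2)
        params = EpidemicParams()
        trace = self._conditioned(net, params, 8)
        deadline = trace.first_hospitalized[1] + 3  # early: forces the fallback
        a = run_size_gain(SictfOracle(trace, net), net, deadline, seed=42)
        b = run_size_gain(SictfOracle(trace, net), net, deadline, seed=42)
        assert a.estimate == b.estimate and a.tests_used == b.tests_used

    def test_generous_sigma_keeps_true_source(self):
        net = generate_hnm(48, 2, 3, seed=4)
        params = EpidemicParams()
        trace = self._conditioned(net, params, 21)
        oracle = SictfOracle(trace, net)
        res = run_size_gain(oracle, net,
                            deadline_day=trace.first_hospitalized[1] + 6,
                            seed=1, config=SGConfig(sigma=5.0))
        assert trace.source in res.extra["final_candidate_set"]
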