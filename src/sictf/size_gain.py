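"""Adaptive Size-Gain (SG) baseline, adapted to the contact-tracing setting.

SG was designed for epidemics that spread (nearly) deterministically: if two
sensors report times ``t_1, t_2`` and a candidate source sits at hop
distances ``d_1, d_2`` from them, then under unit per-hop delay the
candidate is kept only while

    |(t_2 - t_1) - (d_2 - d_1)| < sigma * (d_1 + d_2),

with ``sigma`` the per-hop delay spread. A negative observation only lower
bounds the true onset, and a positive-without-onset (asymptomatic or
presymptomatic) observation only upper bounds it; in either case the
corresponding side of the absolute value is dropped.

Because our epidemic takes ``mu = T_E + (1-p_i)/p_i`` days per hop on
average, observation times are first converted to per-hop units (the
infection-time estimate divided by ``mu``); ``sigma`` defaults to the
geometric per-edge delay spread ``sqrt(1-p_i)/p_i`` days, likewise in hop
units. The feasibility predicate itself is the literal unit-delay rule
above.

Unlike the local-search algorithms, SG is granted the full contact network
(the baseline's home-field advantage); only test placement goes through the
oracle's budgeted, next-day query channel. Sensors are placed to maximize
the expected shrinkage of the candidate set over a uniform prior of
(source, infection-day) hypotheses; the scan is capped by config knobs to
stay tractable on few-hundred-node networks. If the candidate set has not
shrunk to a single node by the deadline, the estimate is a uniformly random
member of the current set; an emptied set (inconsistent constraints) is an
SG failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import networkx as nx
import numpy as np

from .local_search import IdentificationResult
from .oracle import NEGATIVE, ONSET_REVEALED, POSITIVE_NO_TIME, HorizonExceeded, SictfOracle

SYM = "sym"    # exact onset-derived time
NEG = "neg"    # lower bound on the true time
ASYM = "asym"  # upper bound on the true time


@dataclass(frozen=True)
class Observation:
    node: int
    kind: str  # SYM | NEG | ASYM
    time: float  # in per-hop units


@dataclass
class SGConfig:
    sigma: Optional[float] = None  # per-hop units; None -> sqrt(1-p_i)/p_i days / mu
    day_grid_step: int = 2         # coarsening of hypothesis infection days
    max_untested: int = 30         # sensor candidates scanned per placement day
    max_hypotheses: int = 40       # (source, day) hypotheses sampled per scan


@dataclass
class SGState:
    candidate_set: set[int]
    observations: list[Observation]
    sigma: float
    deadline_day: int


def _pair_constraints(o1: Observation, o2: Observation):
    """Yield (upper_obs, lower_obs) orderings with a testable one-sided rule."""
    for u, w in ((o1, o2), (o2, o1)):
        if u.kind in (SYM, ASYM) and w.kind in (SYM, NEG):
            yield u, w


def sg_feasible(candidate: int, obs1: Observation, obs2: Observation,
                dist: Callable[[int, int], Optional[int]], sigma: float) -> bool:
    """Deterministic-delay consistency of a candidate with one observation pair.

    ``dist`` maps (observation node, candidate) to hop distance (``None`` if
    unreachable, which is infeasible). Exact-exact pairs apply the two-sided
    rule; pairs involving a bound apply the one-sided rule(s) in the
    testable direction(s).
    """
    d1 = dist(obs1.node, candidate)
    d2 = dist(obs2.node, candidate)
    if d1 is None or d2 is None:
        return False
    dd = {obs1: d1, obs2: d2}
    for u, w in _pair_constraints(obs1, obs2):
        if not (w.time - u.time) - (dd[w] - dd[u]) < sigma * (dd[u] + dd[w]):
            return False
    return True


def _filter(cands: set[int], new_obs: Observation, old_obs: list[Observation],
            dist: Callable[[int, int], Optional[int]], sigma: float) -> set[int]:
    out = set()
    for c in cands:
        if all(sg_feasible(c, new_obs, o, dist, sigma) for o in old_obs):
            out.add(c)
    return out


def sg_select_sensor(state: SGState, net, untested: set[int],
                     dist: Callable[[int, int], Optional[int]],
                     current_day_hops: float,
                     rng: np.random.Generator,
                     config: SGConfig) -> int:
    """The untested node whose observation shrinks the candidate set most.

    For each scanned node ``u`` and each sampled hypothesis (source ``s0``,
    infection time ``t0``), the deterministic expected observation at ``u``
    is an exact report at ``t0 + d(s0, u)`` hop units; the post-observation
    candidate-set size is averaged over hypotheses and minimized (ties to
    the smallest node id).
    """
    if len(state.candidate_set) <= 1:
        raise ValueError("no sensor needed: candidate set already minimal")
    pool = sorted(untested)
    if len(pool) > config.max_untested:
        pool = sorted(rng.choice(pool, size=config.max_untested, replace=False))
    sources = sorted(state.candidate_set)
    day_lo = current_day_hops - max(2.0, current_day_hops)
    days = np.arange(math.floor(day_lo), math.ceil(current_day_hops) + 1,
                     max(1, config.day_grid_step), dtype=float)
    hypotheses = [(s0, t0) for s0 in sources for t0 in days]
    if len(hypotheses) > config.max_hypotheses:
        idx = rng.choice(len(hypotheses), size=config.max_hypotheses, replace=False)
        hypotheses = [hypotheses[i] for i in sorted(idx)]
    best_u, best_score = None, None
    for u in pool:
        total = 0.0
        for s0, t0 in hypotheses:
            d0 = dist(u, s0)
            if d0 is None:
                total += len(state.candidate_set)
                continue
            pred = Observation(u, SYM, t0 + d0)
            kept = _filter(state.candidate_set, pred, state.observations,
                           dist, state.sigma)
            total += len(kept)
        score = total / len(hypotheses)
        if best_score is None or score < best_score:
            best_u, best_score = u, score
    return best_u


def run_size_gain(oracle: SictfOracle, net, deadline_day: int, seed: int,
                  config: Optional[SGConfig] = None) -> IdentificationResult:
    """Run the SG baseline against a detected outbreak.

    ``deadline_day`` is an absolute day (conventionally the day LS and LS+
    both finished on the same trace); past it the estimate is a uniformly
    random member of the surviving candidate set.
    """
    config = config or SGConfig()
    rng = np.random.default_rng(seed)
    if not oracle.active:
        oracle.detect_outbreak()
    p = oracle.params
    mu = p.T_E + (1.0 - p.p_i) / p.p_i if p.p_i > 0 else float("inf")
    sigma = config.sigma
    if sigma is None:
        sigma = (math.sqrt(1.0 - p.p_i) / p.p_i) / mu if p.p_i > 0 else 1.0

    spl_cache: dict[int, dict[int, int]] = {}

    def dist(obs_node: int, cand: int) -> Optional[int]:
        if obs_node not in spl_cache:
            spl_cache[obs_node] = dict(
                nx.single_source_shortest_path_length(net.graph, obs_node)
            )
        return spl_cache[obs_node].get(cand)

    def to_obs(node: int, kind: str, day: float) -> Observation:
        if kind == SYM:
            t = (day - p.T_E - p.T_P) / mu  # onset back to infection estimate
        elif kind == NEG:
            t = (day - p.T_E) / mu
        else:
            t = day / mu
        return Observation(node, kind, t)

    h = oracle.initial_case
    state = SGState(
        candidate_set=set(net.nodes()),
        observations=[to_obs(h, SYM, oracle.initial_onset)],
        sigma=sigma,
        deadline_day=deadline_day,
    )
    tested: set[int] = {h}
    partial = False
    try:
        while len(state.candidate_set) > 1 and oracle.current_day < deadline_day:
            untested = set(net.nodes()) - tested
            placed = []
            while untested and oracle.capacity_today() > 0 and len(state.candidate_set) > 1:
                u = sg_select_sensor(
                    state, net, untested, dist,
                    current_day_hops=oracle.current_day / mu,
                    rng=rng, config=config,
                )
                untested.discard(u)
                tested.add(u)
                if oracle.submit_test(u):
                    placed.append(u)
            oracle.advance_day()
            for r in oracle.collect_results():
                if r.kind == ONSET_REVEALED:
                    obs = to_obs(r.node, SYM, r.onset)
                elif r.kind == NEGATIVE:
                    obs = to_obs(r.node, NEG, r.result_day - 1)
                else:
                    obs = to_obs(r.node, ASYM, r.result_day - 1)
                state.candidate_set = _filter(
                    state.candidate_set, obs, state.observations, dist, state.sigma
                )
                state.observations.append(obs)
            if not state.candidate_set:
                break
            if not (set(net.nodes()) - tested) and len(state.candidate_set) > 1:
                break  # nothing left to test: fall back at once
    except HorizonExceeded:
        partial = True

    empty = len(state.candidate_set) == 0
    if empty:
        estimate = None
    elif len(state.candidate_set) == 1:
        estimate = next(iter(state.candidate_set))
    else:
        pool = sorted(state.candidate_set)
        estimate = int(pool[int(rng.integers(len(pool)))])

    led = oracle.ledger
    found_source, found_fs = oracle.score(estimate)
    return IdentificationResult(
        algorithm="SG",
        estimate=estimate,
        candidate_history=[estimate] if estimate is not None else [],
        candidate_onsets=[],
        found_source=found_source,
        found_first_symptomatic=found_fs,
        tests_used=led.tests_submitted,
        edges_revealed=led.edges_revealed,
        household_queries=led.household_queries,
        days_elapsed=led.days_elapsed,
        partial=partial,
        candidate_set_empty=empty,
        extra={"final_candidate_set": sorted(state.candidate_set)},
    )
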