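"""Discrete-time epidemic dynamics.

Two engines share one trace interface:

* :class:`DdeTrace` runs the Deterministically Developing Epidemic (DDE) on a
  :class:`~sictf.networks.HouseholdNetwork`, day-synchronously. A node
  infected on day ``t`` is exposed on days ``t .. t+T_E-1`` and infectious
  from ``t+T_E``; with probability ``p_a`` its course is asymptomatic
  (infectious ``T_I`` days, then recovered), otherwise presymptomatic for
  ``T_P`` days, then symptomatic with onset ``t+T_E+T_P``, hospitalized at
  ``onset+T_H`` with probability ``p_h`` or recovered at ``onset+T_I-T_P``.
  Presymptomatic nodes are infectious; hospitalized and recovered nodes are
  not. Every infectious node attacks each susceptible neighbor independently
  with probability ``p_i`` per day; same-day infections take effect
  simultaneously, the infector drawn uniformly among that day's successful
  attackers.

* :class:`DdeNrTreeTrace` runs the no-presymptomatic / no-recovery variant
  (``T_P = 0``, ``T_I = infinity``) on a lazily materialized RB tree. On a
  tree every node has a unique potential infector, so the day-synchronous
  Bernoulli dynamics are equivalent to independent per-edge geometric delays
  (child infected at ``parent + T_E + (G-1)``, ``G ~ Geometric(p_i)``,
  truncated at the parent's hospitalization day). This lets the first
  hospitalized node be located by an exact best-first exploration in
  infection order, without stepping an exponentially growing cluster day by
  day. Per-node randomness is keyed by node id, so lazy queries after
  detection are consistent regardless of query order.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .networks import HouseholdNetwork, RBTree

# Per-day node states
SUSCEPTIBLE = "susceptible"
EXPOSED = "exposed"
PRESYMPTOMATIC = "presymptomatic"
ASYMPTOMATIC_INFECTIOUS = "asymptomatic_infectious"
SYMPTOMATIC_INFECTIOUS = "symptomatic_infectious"
HOSPITALIZED = "hospitalized"
RECOVERED = "recovered"

INFECTIOUS_STATES = frozenset(
    {PRESYMPTOMATIC, ASYMPTOMATIC_INFECTIOUS, SYMPTOMATIC_INFECTIOUS}
)


@dataclass(frozen=True)
class EpidemicParams:
    """DDE parameters (defaults: the fitted synthetic-model values).

    ``p_i``: per-day per-edge infection probability; ``p_a``: asymptomatic
    probability; ``p_h``: hospitalization probability given symptomatic;
    ``T_E/T_P/T_I/T_H``: exposed / presymptomatic / infectious /
    onset-to-hospitalization durations in days; ``sigma_E/sigma_P``: slack
    days for backward-contact windows (0 for the deterministic model).
    ``T_I=None`` means no recovery.
    """

    p_i: float = 0.1
    p_a: float = 0.4
    p_h: float = 0.083
    T_E: int = 3
    T_P: int = 2
    T_I: Optional[int] = 14
    T_H: int = 7
    sigma_E: int = 0
    sigma_P: int = 0

    def __post_init__(self) -> None:
        for name in ("p_i", "p_a", "p_h"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name}={x} must be in [0, 1]")
        for name in ("T_E", "T_P", "T_H", "sigma_E", "sigma_P"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.T_I is not None and self.T_I < 0:
            raise ValueError("T_I must be >= 0 (or None for no recovery)")
        if not self.T_P < self.T_E + self.T_H:
            raise ValueError("require T_P < T_E + T_H")

    def without_presymptomatic_and_recovery(self) -> "EpidemicParams":
        """The no-presymptomatic / no-recovery variant of these parameters."""
        return EpidemicParams(
            p_i=self.p_i, p_a=self.p_a, p_h=self.p_h,
            T_E=self.T_E, T_P=0, T_I=None, T_H=self.T_H,
            sigma_E=self.sigma_E, sigma_P=self.sigma_P,
        )


DEFAULT_PARAMS = EpidemicParams()


class _TraceBase:
    """Shared derived-state logic over (infection_time, course) records."""

    params: EpidemicParams
    source: int

    def infection_time(self, v) -> Optional[int]:
        raise NotImplementedError

    def infector(self, v) -> Optional[int]:
        raise NotImplementedError

    def is_asymptomatic(self, v) -> bool:
        raise NotImplementedError

    def is_hospitalized_course(self, v) -> bool:
        raise NotImplementedError

    def onset_time(self, v) -> Optional[int]:
        """Symptom onset day (symptomatic courses only)."""
        t = self.infection_time(v)
        if t is None or self.is_asymptomatic(v):
            return None
        return t + self.params.T_E + self.params.T_P

    def hospitalization_time(self, v) -> Optional[int]:
        o = self.onset_time(v)
        if o is None or not self.is_hospitalized_course(v):
            return None
        return o + self.params.T_H

    def recovery_time(self, v) -> Optional[int]:
        t = self.infection_time(v)
        if t is None or self.params.T_I is None or self.is_hospitalized_course(v):
            return None
        return t + self.params.T_E + self.params.T_I

    def state(self, v, day: int) -> str:
        p = self.params
        t = self.infection_time(v)
        if t is None or day < t:
            return SUSCEPTIBLE
        if day < t + p.T_E:
            return EXPOSED
        if self.is_asymptomatic(v):
            rec = self.recovery_time(v)
            return ASYMPTOMATIC_INFECTIOUS if rec is None or day < rec else RECOVERED
        onset = self.onset_time(v)
        if day < onset:
            return PRESYMPTOMATIC
        if self.is_hospitalized_course(v):
            return SYMPTOMATIC_INFECTIOUS if day < self.hospitalization_time(v) else HOSPITALIZED
        rec = self.recovery_time(v)
        return SYMPTOMATIC_INFECTIOUS if rec is None or day < rec else RECOVERED


class DdeTrace(_TraceBase):
    """Live day-synchronous DDE simulation on a HouseholdNetwork."""

    def __init__(self, net: HouseholdNetwork, source: int, params: EpidemicParams,
                 seed: int):
        net._check_node(source)
        self.net = net
        self.source = source
        self.params = params
        self._rng = np.random.default_rng(seed)
        self.day = 0  # last simulated day
        self._infection_time: dict[int, int] = {}
        self._infector: dict[int, Optional[int]] = {}
        self._asym: dict[int, bool] = {}
        self._hosp_course: dict[int, bool] = {}
        self.first_hospitalized: Optional[tuple[int, int]] = None
        self._infect(source, 0, None)

    # -- dynamics ----------------------------------------------------------

    def _infect(self, v: int, day: int, infector: Optional[int]) -> None:
        self._infection_time[v] = day
        self._infector[v] = infector
        asym = bool(self._rng.random() < self.params.p_a)
        self._asym[v] = asym
        hosp = (not asym) and bool(self._rng.random() < self.params.p_h)
        self._hosp_course[v] = hosp
        if hosp:
            h_day = day + self.params.T_E + self.params.T_P + self.params.T_H
            cur = self.first_hospitalized
            if cur is None or (h_day, v) < cur[::-1]:
                self.first_hospitalized = (v, h_day)

    def step(self) -> None:
        """Advance the epidemic by one day (infections land on the new day)."""
        day = self.day + 1
        infectious = {
            v for v in self._infection_time if self.state(v, day) in INFECTIOUS_STATES
        }
        new: list[tuple[int, int]] = []  # (target, infector)
        seen_targets = set()
        for v in sorted(self._infection_time):
            if v not in infectious:
                continue
            for u in sorted(self.net.neighbors(v)):
                if u in self._infection_time or u in seen_targets:
                    continue
                # resolve all of u's attackers at once, in attacker-id order
                attackers = [
                    w for w in sorted(self.net.neighbors(u)) if w in infectious
                ]
                hits = [w for w in attackers if self._rng.random() < self.params.p_i]
                if hits:
                    winner = hits[int(self._rng.integers(len(hits)))]
                    new.append((u, winner))
                seen_targets.add(u)
        for u, w in new:
            self._infect(u, day, w)
        self.day = day

    def advance_to(self, day: int) -> None:
        while self.day < day:
            self.step()

    # -- record access -----------------------------------------------------

    def infection_time(self, v) -> Optional[int]:
        return self._infection_time.get(v)

    def infector(self, v) -> Optional[int]:
        return self._infector.get(v)

    def is_asymptomatic(self, v) -> bool:
        return self._asym.get(v, False)

    def is_hospitalized_course(self, v) -> bool:
        return self._hosp_course.get(v, False)

    def infected_nodes(self) -> list[int]:
        return sorted(self._infection_time)

    def hospitalizations_on(self, day: int) -> list[int]:
        return sorted(
            v for v in self._infection_time if self.hospitalization_time(v) == day
        )

    def state_counts(self, day: int) -> dict[str, int]:
        counts = {
            s: 0
            for s in (SUSCEPTIBLE, EXPOSED, PRESYMPTOMATIC, ASYMPTOMATIC_INFECTIOUS,
                      SYMPTOMATIC_INFECTIOUS, HOSPITALIZED, RECOVERED)
        }
        for v in self.net.nodes():
            counts[self.state(v, day)] += 1
        return counts


def simulate_dde(net: HouseholdNetwork, source: int, params: EpidemicParams,
                 seed: int, horizon: int = 100,
                 stop: str = "first_hospitalization") -> DdeTrace:
    """Simulate the DDE; returns a live trace that can be advanced further.

    With ``stop="first_hospitalization"`` the simulation halts on the day the
    first hospitalization occurs (the trace can still be advanced lazily
    afterwards — identification runs in real time). If no hospitalization
    happens within ``horizon`` days, ``trace.first_hospitalized`` is ``None``
    and the caller decides whether to discard the run.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if stop not in ("first_hospitalization", "horizon"):
        raise ValueError(f"unknown stop condition {stop!r}")
    trace = DdeTrace(net, source, params, seed)
    while trace.day < horizon:
        fh = trace.first_hospitalized
        if stop == "first_hospitalization" and fh is not None and trace.day >= fh[1]:
            break
        trace.step()
    if stop == "first_hospitalization" and trace.first_hospitalized is not None:
        if trace.first_hospitalized[1] > trace.day:
            # scheduled beyond the horizon: not yet observed
            trace.first_hospitalized = None
    return trace


class DdeNrTreeTrace(_TraceBase):
    """No-presymptomatic / no-recovery epidemic on a lazy RB tree.

    All infection times and courses are determined lazily from per-node RNG
    streams; ``first_hospitalized`` is found by best-first exploration in
    infection order (exact: hospitalization lags infection by the constant
    ``T_E + T_H``, so the first hospitalized node is the hospitalized-course
    node with minimal infection time, ties to the smaller node id).
    """

    def __init__(self, tree: RBTree, params: EpidemicParams, seed: int,
                 horizon: int = 200, max_nodes: int = 500_000):
        self.tree = tree
        self.params = params.without_presymptomatic_and_recovery()
        self.seed = seed
        self.source = tree.root
        self.horizon = horizon
        self.max_nodes = max_nodes
        self._infection_time: dict[int, Optional[int]] = {tree.root: 0}
        self._course: dict[int, tuple[bool, bool]] = {}  # v -> (asym, hosp)
        self._children_sampled: set[int] = set()
        self.first_hospitalized: Optional[tuple[int, int]] = None
        self._explored_upto: float = -1.0  # all nodes with inf <= this are popped
        self._heap: list[tuple[int, int]] = [(0, tree.root)]
        self._popped: list[int] = []
        self._find_first_hospitalization()

    def _node_rng(self, v: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, v])

    def _course_of(self, v: int) -> tuple[bool, bool]:
        if v not in self._course:
            rng = self._node_rng(v)
            asym = bool(rng.random() < self.params.p_a)
            hosp = (not asym) and bool(rng.random() < self.params.p_h)
            self._course[v] = (asym, hosp)
        return self._course[v]

    def _sample_children(self, v: int) -> None:
        """Sample infection times of v's children (once), given v infected."""
        if v in self._children_sampled:
            return
        self._children_sampled.add(v)
        t_v = self._infection_time[v]
        asym, hosp = self._course_of(v)
        stop_day = (
            t_v + self.params.T_E + self.params.T_H if hosp else None
        )  # hospitalized nodes stop infecting at their hospitalization day
        rng = self._node_rng(v)
        rng.random(2)  # skip the course draws to keep one stream per node
        for c in self.tree.ensure_children(v):
            if self.params.p_i <= 0.0:
                self._infection_time[c] = None
                continue
            g = int(rng.geometric(self.params.p_i))  # support 1, 2, ...
            t_c = t_v + self.params.T_E + (g - 1)
            if (stop_day is not None and t_c >= stop_day) or t_c > self.horizon:
                self._infection_time[c] = None
            else:
                self._infection_time[c] = t_c

    def _explore_next(self) -> Optional[int]:
        """Pop the next node in (infection_time, id) order; push its children."""
        if not self._heap:
            return None
        t, v = heapq.heappop(self._heap)
        self._explored_upto = t
        self._popped.append(v)
        self._sample_children(v)
        for c in self.tree.ensure_children(v):
            t_c = self._infection_time[c]
            if t_c is not None:
                heapq.heappush(self._heap, (t_c, c))
        return v

    def _find_first_hospitalization(self) -> None:
        best: Optional[tuple[int, int]] = None  # (hosp_day, node)
        lag = self.params.T_E + self.params.T_H
        while self._heap:
            if best is not None and self._heap[0][0] + lag > best[0]:
                break
            if len(self._popped) > self.max_nodes:
                break
            v = self._explore_next()
            asym, hosp = self._course_of(v)
            if hosp:
                h_day = self._infection_time[v] + lag
                if best is None or (h_day, v) < best:
                    best = (h_day, v)
        if best is not None:
            self.first_hospitalized = (best[1], best[0])

    # -- record access (lazy) ----------------------------------------------

    def _materialize(self, v: int) -> None:
        """Ensure v's infection status is decided (sampling ancestors as needed)."""
        if v in self._infection_time:
            return
        p = self.tree.parent(v)
        if p is None:
            return
        self._materialize(p)
        if self._infection_time.get(p) is None:
            self._infection_time[v] = None
        else:
            self._sample_children(p)

    def infection_time(self, v) -> Optional[int]:
        self._materialize(v)
        return self._infection_time.get(v)

    def infector(self, v) -> Optional[int]:
        if v == self.source or self.infection_time(v) is None:
            return None
        return self.tree.parent(v)

    def is_asymptomatic(self, v) -> bool:
        if self.infection_time(v) is None:
            return False
        return self._course_of(v)[0]

    def is_hospitalized_course(self, v) -> bool:
        if self.infection_time(v) is None:
            return False
        return self._course_of(v)[1]

    def advance_to(self, day: int) -> None:
        """No-op: all state is a deterministic function of cached samples."""

    def infected_nodes(self) -> list[int]:
        """Nodes known infected so far (complete up to the explored frontier)."""
        return sorted(v for v, t in self._infection_time.items() if t is not None)

    def explore_until(self, day: int, max_nodes: Optional[int] = None) -> None:
        """Extend the exploration to cover every infection up to ``day``."""
        cap = max_nodes or self.max_nodes
        while self._heap and self._heap[0][0] <= day and len(self._popped) <= cap:
            self._explore_next()


def simulate_dde_nr(tree: RBTree, params: EpidemicParams, seed: int,
                    horizon: int = 200) -> DdeNrTreeTrace:
    """Simulate the no-presymptomatic / no-recovery DDE from the RB-tree root.

    ``params.T_P`` and ``params.T_I`` are ignored (treated as 0 and infinity).
    If no hospitalization occurs within ``horizon`` days the trace has
    ``first_hospitalized = None`` (caller discards).
    """
    return DdeNrTreeTrace(tree, params, seed, horizon=horizon)


# ---------------------------------------------------------------------------
# Ground-truth inspection
# ---------------------------------------------------------------------------


def transmission_path(trace: _TraceBase, v) -> list:
    """The infector chain ``(source, ..., v)``; length = hops."""
    if trace.infection_time(v) is None:
        raise ValueError(f"node {v!r} was never infected")
    path = [v]
    while trace.infector(path[-1]) is not None:
        path.append(trace.infector(path[-1]))
    return path[::-1]


def first_symptomatic(trace: _TraceBase):
    """The symptomatic-course node with minimal infection time (ties: min id).

    Returns ``None`` if no symptomatic node exists among the infected.
    """
    if isinstance(trace, DdeNrTreeTrace):
        # ensure exploration covers every node infected no later than the
        # earliest symptomatic seen so far
        while True:
            cands = [
                (trace.infection_time(v), v)
                for v in trace._popped
                if not trace.is_asymptomatic(v)
            ]
            if cands:
                t_best, v_best = min(cands)
                if not trace._heap or trace._heap[0][0] > t_best:
                    return v_best
            if not trace._heap or len(trace._popped) > trace.max_nodes:
                return min(cands)[1] if cands else None
            trace._explore_next()
    cands = [
        (trace.infection_time(v), v)
        for v in trace.infected_nodes()
        if not trace.is_asymptomatic(v)
    ]
    return min(cands)[1] if cands else None


def write_trace(trace: _TraceBase, path: str) -> None:
    """CSV: node, infection_time, infector, course, onset, hospitalization, recovery."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["node", "infection_time", "infector", "course", "onset_time",
             "hospitalization_time", "recovery_time"]
        )
        for v in trace.infected_nodes():
            course = (
                "asymptomatic" if trace.is_asymptomatic(v)
                else "symptomatic_hospitalized" if trace.is_hospitalized_course(v)
                else "symptomatic"
            )
            w.writerow([
                v, trace.infection_time(v),
                "" if trace.infector(v) is None else trace.infector(v),
                course,
                "" if trace.onset_time(v) is None else trace.onset_time(v),
                "" if trace.hospitalization_time(v) is None else trace.hospitalization_time(v),
                "" if trace.recovery_time(v) is None else trace.recovery_time(v),
            ])
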