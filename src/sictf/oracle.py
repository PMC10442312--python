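"""The contact-tracing query contract.

Identification algorithms never touch a ground-truth trace directly: they
receive a :class:`SictfOracle`, whose only information channels are

* outbreak detection — the identity, hospitalization day, and symptom onset
  of the first hospitalized agent (hospital cases are diagnosed, so no test
  is spent on them);
* household queries (free, unlimited, instant, but counted);
* contact queries (instant; the ledger counts each revealed edge once);
* test queries — processed against the agent's state on the submission day,
  answered the next day, at most ``budget`` per day (submissions beyond the
  budget spill to the next day rather than erroring);
* the daily stream of new hospitalization announcements (finite networks).

The epidemic keeps propagating in real time: a day passes only through
:meth:`SictfOracle.advance_day`, whether or not queries were made.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Union

from .epidemics import (
    ASYMPTOMATIC_INFECTIOUS,
    EXPOSED,
    HOSPITALIZED,
    PRESYMPTOMATIC,
    RECOVERED,
    SUSCEPTIBLE,
    SYMPTOMATIC_INFECTIOUS,
    DdeNrTreeTrace,
    DdeTrace,
    first_symptomatic,
)
from .networks import HouseholdNetwork, RBTree

NEGATIVE = "negative"
POSITIVE_NO_TIME = "positive_no_time"
ONSET_REVEALED = "onset_revealed"


class HorizonExceeded(RuntimeError):
    """Raised when the identification run outlives the oracle's day guard."""


@dataclass(frozen=True)
class TestResult:
    node: int
    kind: str
    onset: Optional[int]
    result_day: int


@dataclass
class QueryLedger:
    tests_submitted: int = 0
    edges_revealed: int = 0
    household_queries: int = 0
    contact_queries: int = 0
    days_elapsed: int = 0


def default_budget(N: int) -> int:
    """Daily test budget: at most 1% of the population, at least one test."""
    return max(1, int(0.01 * N))


class SictfOracle:
    """Sealed access to one epidemic run.

    Parameters
    ----------
    trace
        A live epidemic trace (:class:`DdeTrace` or :class:`DdeNrTreeTrace`).
    substrate
        The contact structure the trace runs on (HouseholdNetwork or RBTree).
    budget
        Tests per day; defaults to ``floor(0.01 N)`` (min 1) on finite
        networks and to 4 (the N=400 equivalent) on infinite trees.
    horizon_days
        Guard on days elapsed after detection; exceeding it raises
        :class:`HorizonExceeded` so callers can return a partial result.
    """

    def __init__(self, trace: Union[DdeTrace, DdeNrTreeTrace],
                 substrate: Union[HouseholdNetwork, RBTree],
                 budget: Optional[int] = None, horizon_days: int = 365):
        self._trace = trace
        self._substrate = substrate
        if budget is None:
            budget = (
                default_budget(substrate.N)
                if isinstance(substrate, HouseholdNetwork)
                else 4
            )
        self.budget = budget
        self.horizon_days = horizon_days
        self.params = trace.params  # epidemic parameters are public knowledge
        self.ledger = QueryLedger()
        self.active = False
        self.current_day: Optional[int] = None
        self.detection_day: Optional[int] = None
        self.initial_case: Optional[int] = None
        self.initial_onset: Optional[int] = None
        self._revealed_edges: set[frozenset] = set()
        self._tested: set[int] = set()
        self._processed_today = 0
        self._spill: deque[int] = deque()
        self._scheduled: list[TestResult] = []  # awaiting delivery
        self._ready: list[TestResult] = []
        self.announced_hospitalizations: list[tuple[int, int]] = []  # (node, day)
        self.query_log: list[tuple] = []

    # -- lifecycle ---------------------------------------------------------

    def detect_outbreak(self) -> tuple[int, int]:
        """Start the clock at the first hospitalization; reveal its onset."""
        fh = self._trace.first_hospitalized
        if fh is None:
            raise ValueError("trace has no hospitalization; run must be discarded")
        node, day = fh
        self.active = True
        self.current_day = day
        self.detection_day = day
        self.initial_case = node
        self.initial_onset = self._trace.onset_time(node)
        self._tested.add(node)  # diagnosed at the hospital, never re-tested
        self.announced_hospitalizations.append((node, day))
        self.query_log.append((day, "detect", node, self.initial_onset))
        return node, day

    def _require_active(self) -> None:
        if not self.active:
            raise RuntimeError("oracle not active: call detect_outbreak() first")

    # -- queries -----------------------------------------------------------

    def household_query(self, v: int) -> set[int]:
        self._require_active()
        members = self._substrate.household_of(v)
        self.ledger.household_queries += 1
        self.query_log.append(
            (self.current_day, "household", v, ";".join(map(str, sorted(members))))
        )
        return members

    def contact_query(self, v: int, window: Optional[tuple[int, int]] = None) -> set[int]:
        """All graph neighbors of v (the window only matters on temporal data)."""
        self._require_active()
        nbrs = self._substrate.neighbors(v)
        for u in nbrs:
            self._revealed_edges.add(frozenset((v, u)))
        self.ledger.contact_queries += 1
        self.ledger.edges_revealed = len(self._revealed_edges)
        self.query_log.append(
            (self.current_day, "contact", v, ";".join(map(str, sorted(nbrs))))
        )
        return nbrs

    def submit_test(self, v: int) -> bool:
        """Queue a test for v. Returns False (rejected) for duplicate tests."""
        self._require_active()
        if v in self._tested:
            return False
        self._tested.add(v)
        self.ledger.tests_submitted += 1
        self.query_log.append((self.current_day, "test_submitted", v, ""))
        if self._processed_today < self.budget:
            self._process_test(v)
        else:
            self._spill.append(v)
        return True

    def _process_test(self, v: int) -> None:
        """Evaluate v's state on the current (submission) day; deliver tomorrow."""
        day = self.current_day
        state = self._trace.state(v, day)
        if state in (SUSCEPTIBLE, EXPOSED):
            kind, onset = NEGATIVE, None
        elif state in (PRESYMPTOMATIC, ASYMPTOMATIC_INFECTIOUS):
            kind, onset = POSITIVE_NO_TIME, None
        elif state == RECOVERED and self._trace.is_asymptomatic(v):
            kind, onset = POSITIVE_NO_TIME, None
        elif state in (SYMPTOMATIC_INFECTIOUS, HOSPITALIZED, RECOVERED):
            kind, onset = ONSET_REVEALED, self._trace.onset_time(v)
        else:  # pragma: no cover
            raise AssertionError(f"unhandled state {state}")
        self._processed_today += 1
        self._scheduled.append(TestResult(v, kind, onset, day + 1))
        self.query_log.append((day, "test", v, kind))

    def advance_day(self) -> int:
        """One real-time day: epidemic advances, results mature, spill drains."""
        self._require_active()
        self.current_day += 1
        self.ledger.days_elapsed = self.current_day - self.detection_day
        if self.ledger.days_elapsed > self.horizon_days:
            raise HorizonExceeded(
                f"{self.ledger.days_elapsed} days since detection"
            )
        self.query_log.append((self.current_day, "advance", "", ""))
        self._trace.advance_to(self.current_day)
        if isinstance(self._trace, DdeTrace):
            for v in self._trace.hospitalizations_on(self.current_day):
                self.announced_hospitalizations.append((v, self.current_day))
        still = []
        for r in self._scheduled:
            (self._ready if r.result_day <= self.current_day else still).append(r)
        self._scheduled = still
        self._processed_today = 0
        while self._spill and self._processed_today < self.budget:
            self._process_test(self._spill.popleft())
        return self.current_day

    def collect_results(self) -> list[TestResult]:
        """Matured results (submission day strictly before today); clears them."""
        self._require_active()
        out, self._ready = sorted(self._ready, key=lambda r: r.node), []
        return out

    def capacity_today(self) -> int:
        """Tests that can still be processed (not just queued) today."""
        return max(0, self.budget - self._processed_today)

    def tests_pending(self) -> int:
        return len(self._spill) + len(self._scheduled)

    # -- post-hoc scoring (ground truth; not available during the search) ---

    def score(self, estimate) -> tuple[bool, bool]:
        """(found_source, found_first_symptomatic) for a final estimate."""
        fs = first_symptomatic(self._trace)
        return estimate == self._trace.source, estimate == fs


def write_query_log(oracle: SictfOracle, path: str) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["day", "type", "argument", "response"])
        for row in oracle.query_log:
            w.writerow(row)


def audit_ledger(log_rows: list[tuple]) -> QueryLedger:
    """Recompute ledger counters independently from a query log."""
    led = QueryLedger()
    edges: set[frozenset] = set()
    days = [r[0] for r in log_rows]
    detection = min((r[0] for r in log_rows if r[1] == "detect"), default=0)
    for day, kind, arg, resp in log_rows:
        if kind == "household":
            led.household_queries += 1
        elif kind == "contact":
            led.contact_queries += 1
            for u in str(resp).split(";"):
                if u != "":
                    edges.add(frozenset((int(arg), int(u))))
        elif kind == "test_submitted":
            led.tests_submitted += 1
    led.edges_revealed = len(edges)
    led.days_elapsed = max(days, default=detection) - detection
    return led
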