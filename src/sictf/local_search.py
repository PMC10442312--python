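"""Greedy backward tracing of the transmission path: LS, LS+, and v2 cuts.

LS keeps a candidate — always the node with the earliest revealed symptom
onset — and repeatedly tests the candidate's household members and backward
contacts. An iteration ends only when the test queue has fully drained; the
next candidate is the earliest onset revealed so far. The algorithm stops
when an iteration produces no earlier onset than the incumbent candidate.

LS+ additionally reacts to positives without an onset time (asymptomatic or
presymptomatic agents): their whole household enters the queue, and if such
a node shares the incumbent's household, so do its backward contacts (with
the wider window appropriate for an unknown onset). This lets the search hop
over an asymptomatic link in the transmission path whenever some household
member of that link is symptomatic.

The v2 variants cut an iteration the first time the candidate improves,
discarding the remaining queue — cheaper in tests, but without the
guarantees the full drain provides.

On static networks all neighbors count as backward contacts; the day windows
are still computed and logged for interface parity with temporal data.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional

from .epidemics import EpidemicParams
from .oracle import ONSET_REVEALED, POSITIVE_NO_TIME, HorizonExceeded, SictfOracle

VARIANTS = ("LS", "LS+", "LSv2", "LS+v2")


@dataclass
class IdentificationResult:
    """Outcome of one identification run, counters read from the oracle ledger."""

    algorithm: str
    estimate: Optional[int]
    candidate_history: list[int]
    candidate_onsets: list[int]
    found_source: bool = False
    found_first_symptomatic: bool = False
    tests_used: int = 0
    edges_revealed: int = 0
    household_queries: int = 0
    days_elapsed: int = 0
    partial: bool = False
    candidate_set_empty: bool = False
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "estimate": self.estimate,
            "candidate_history": list(self.candidate_history),
            "candidate_onsets": list(self.candidate_onsets),
            "found_source": self.found_source,
            "found_first_symptomatic": self.found_first_symptomatic,
            "tests_used": self.tests_used,
            "edges_revealed": self.edges_revealed,
            "household_queries": self.household_queries,
            "days_elapsed": self.days_elapsed,
            "partial": self.partial,
            "candidate_set_empty": self.candidate_set_empty,
        }


def backward_window(t_candidate: int, params: EpidemicParams,
                    target: str = "symptomatic_candidate") -> tuple[Optional[int], int]:
    """Day interval in which the candidate's infector must have been in contact.

    For a symptomatic candidate with onset ``t``, the infection happened
    ``T_E + T_P`` days before ``t`` (give or take the slack days). For an
    asymptomatic household member whose own onset is unknown, the infector
    must have been infectious while infecting them, pushing the window back a
    further exposed period and widening it by the infectious duration.
    A ``None`` lower bound means unbounded (no recovery, ``T_I = None``).
    """
    p = params
    if target == "symptomatic_candidate":
        center = t_candidate - (p.T_E + p.T_P)
        slack = p.sigma_E + p.sigma_P
        return center - slack, center + slack
    if target == "asymptomatic_member":
        hi = t_candidate - (p.T_P + 2 * p.T_E)
        lo = None if p.T_I is None else hi - p.T_I
        return lo, hi
    raise ValueError(f"unknown target {target!r}")


def run_local_search(oracle: SictfOracle, variant: str = "LS") -> IdentificationResult:
    """Run LS / LS+ / LSv2 / LS+v2 against a detected outbreak."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    plus = variant.startswith("LS+")
    v2 = variant.endswith("v2")
    if not oracle.active:
        oracle.detect_outbreak()

    candidate = oracle.initial_case
    candidate_onset = oracle.initial_onset
    history = [candidate]
    onsets = [candidate_onset]
    seen: set[int] = {candidate}  # ever enqueued or tested
    partial = False

    def fresh(nodes) -> list[int]:
        out = [u for u in sorted(nodes) if u not in seen]
        seen.update(out)
        return out

    try:
        while True:
            # one iteration: drain the test queue built around the candidate
            hh = oracle.household_query(candidate)
            win = backward_window(candidate_onset, oracle.params)
            contacts = oracle.contact_query(candidate, window=win)
            queue = deque(fresh(hh))
            queue.extend(fresh(contacts))
            best_node, best_onset = candidate, candidate_onset
            pending = 0
            cut = False
            while queue or pending:
                while queue and oracle.capacity_today() > 0:
                    if oracle.submit_test(queue.popleft()):
                        pending += 1
                oracle.advance_day()
                for r in oracle.collect_results():
                    pending -= 1
                    if r.kind == ONSET_REVEALED and r.onset < best_onset:
                        best_node, best_onset = r.node, r.onset
                        if v2:
                            cut = True
                            break
                    elif plus and r.kind == POSITIVE_NO_TIME:
                        queue.extend(fresh(oracle.household_query(r.node)))
                        if r.node in hh:
                            awin = backward_window(
                                candidate_onset, oracle.params, "asymptomatic_member"
                            )
                            queue.extend(fresh(oracle.contact_query(r.node, window=awin)))
                if cut:
                    queue.clear()
                    while oracle.tests_pending():
                        oracle.advance_day()
                        oracle.collect_results()
                    break
            if best_node == candidate:
                break
            candidate, candidate_onset = best_node, best_onset
            history.append(candidate)
            onsets.append(candidate_onset)
    except HorizonExceeded:
        partial = True

    led = oracle.ledger
    found_source, found_fs = oracle.score(candidate)
    return IdentificationResult(
        algorithm=variant,
        estimate=candidate,
        candidate_history=history,
        candidate_onsets=onsets,
        found_source=found_source,
        found_first_symptomatic=found_fs,
        tests_used=led.tests_submitted,
        edges_revealed=led.edges_revealed,
        household_queries=led.household_queries,
        days_elapsed=led.days_elapsed,
        partial=partial,
    )
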