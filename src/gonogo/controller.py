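"""Trial-control state machine.

Implements the closed-loop trial logic of an automated home-cage operant
conditioning rig: door access gating from infra-red beam sensors, RFID-gated
trial initiation, lick-quarter response classification, outcome resolution
against the go/no-go response/reward table, and inter-trial-interval
bookkeeping.  Hardware is abstracted behind a small interface that the
cohort simulator satisfies.

Response rule: the stimulus/response window is divided into four equal
quarters (Q1-Q4); a lick in three or more quarters is a positive response,
two or fewer (including no licking) a negative response.  Crossing response
with stimulus valence yields the four outcomes hit (H), miss (M), correct
rejection (CR) and false alarm (FA).  Only hits are rewarded; false alarms
draw a lengthened "timeout" ITI.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Iterator, Protocol, Sequence, runtime_checkable

import numpy as np

from .scheduler import TrialPlan

__all__ = [
    "PortState",
    "TrialRecord",
    "Visit",
    "HardwareInterface",
    "update_access",
    "debounce_licks",
    "classify_response",
    "resolve_outcome",
    "run_session",
    "OUTCOMES",
]

logger = logging.getLogger(__name__)

OUTCOMES = ("H", "M", "CR", "FA")
#: minimum number of licked quarters for a positive response
RESPONSE_QUARTERS = 3
#: lick events closer than this merge into one (seconds)
LICK_DEBOUNCE_S = 0.020


@dataclass(frozen=True)
class PortState:
    """Sensor snapshot of the staging area and behaviour port."""

    tunnel_beams: tuple[bool, ...]  # True = blocked
    port_beam: bool
    rfid: str | None
    door: str  # "open" | "closed"


def update_access(beams: Iterable[bool]) -> str:
    """Door command from beam states: close while any beam is blocked,
    spring-open when all are clear — so only one animal can occupy the port
    at a time."""
    return "closed" if any(beams) else "open"


@dataclass(frozen=True)
class TrialRecord:
    """One executed trial."""

    animal_id: str
    task_id: str
    trial_idx: int
    valence: str
    combo_index: int
    t_start: float  # seconds since experiment epoch
    lick_quarters: tuple[int, ...]  # presence mask, Q1 leftmost
    response: bool  # True = positive
    outcome: str  # H / M / CR / FA
    reward_ul: float
    iti_s: float

    @property
    def lick_mask(self) -> str:
        return "".join(str(q) for q in self.lick_quarters)

    @property
    def correct(self) -> bool:
        return self.outcome in ("H", "CR")


def debounce_licks(
    lick_times: Sequence[float], min_interval: float = LICK_DEBOUNCE_S
) -> list[float]:
    """Merge lick contacts closer than the lickometer debounce interval."""
    out: list[float] = []
    for t in sorted(lick_times):
        if not out or t - out[-1] >= min_interval:
            out.append(t)
    return out


def classify_response(
    lick_times: Sequence[float],
    onset: float,
    window: float = 2.0,
    n_quarters: int = 4,
    threshold: int = RESPONSE_QUARTERS,
) -> tuple[tuple[int, ...], bool]:
    """Classify licking into a quarter-presence mask and a response.

    Quarter i covers the half-open interval
    [onset + i*window/n, onset + (i+1)*window/n); licks outside the window
    are ignored.  The response is positive iff at least ``threshold``
    (default 3) quarters contain a lick.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if n_quarters < 1:
        raise ValueError("n_quarters must be >= 1")
    # absolute interval boundaries, so a lick exactly on an internal
    # boundary belongs to the later quarter with no float drift
    edges = [onset + i * window / n_quarters for i in range(n_quarters + 1)]
    mask = [0] * n_quarters
    for t in lick_times:
        for q in range(n_quarters):
            if edges[q] <= t < edges[q + 1]:
                mask[q] = 1
                break
    return tuple(mask), sum(mask) >= threshold


def resolve_outcome(
    valence: str,
    response: bool,
    spec,
    rng: np.random.Generator | int | None = None,
) -> tuple[str, float, float]:
    """Resolve (outcome, reward_ul, iti_s) from the response/reward table.

    (S+, pos) -> hit, rewarded, normal ITI; (S+, neg) -> miss; (S-, neg) ->
    correct rejection; (S-, pos) -> false alarm with a timeout ITI drawn
    uniformly from the configured range (default 8-12 s).  ``spec`` is any
    object with reward_volume/iti_normal/iti_timeout_range attributes (a
    TaskSpec) or reward_ul (a TrialPlan).
    """
    reward_volume = getattr(spec, "reward_volume", None)
    if reward_volume is None:
        reward_volume = spec.reward_ul
    if valence == "+":
        if response:
            return "H", reward_volume, spec.iti_normal
        return "M", 0.0, spec.iti_normal
    if response:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        lo, hi = spec.iti_timeout_range
        return "FA", 0.0, float(rng.uniform(lo, hi))
    return "CR", 0.0, spec.iti_normal


@dataclass(frozen=True)
class Visit:
    """One occupancy of the behaviour port (door closed behind the animal).

    ``rfid`` is None when the tag could not be decoded; such visits abort
    without a trial.
    """

    t_enter: float
    t_exit: float
    rfid: str | None


@runtime_checkable
class HardwareInterface(Protocol):
    """What the controller needs from the rig (or its simulation)."""

    def visits(self) -> Iterator[Visit]:
        """Time-ordered port occupancies."""
        ...

    def lick_times(self, animal_id: str, plan: TrialPlan, onset: float) -> Sequence[float]:
        """Lick contact times observed during one trial."""
        ...

    def notify_outcome(self, animal_id: str, plan: TrialPlan, record: TrialRecord) -> None:
        """Fire-and-forget completion event (reward delivery, learning)."""
        ...


def run_session(
    plans: dict[str, Sequence[TrialPlan]],
    hardware: HardwareInterface,
    log_sink=None,
    seed: int | None = None,
) -> list[TrialRecord]:
    """Run queued trial plans against a hardware interface.

    Each decoded visit delivers trials from that animal's queue back to back
    while the animal remains in the port, honouring each trial's imposed ITI
    before the next can start.  Every completed trial appends exactly one
    TrialRecord; per-animal records are strictly time-ordered.  RFID read
    failures abort the visit with a logged warning; an animal with an
    exhausted queue produces an idle event only.

    ``log_sink``, if given, is a callable receiving each TrialRecord (e.g. a
    CSV writer).
    """
    queues = {a: deque(p) for a, p in plans.items()}
    next_ok = {a: float("-inf") for a in plans}  # end of the imposed ITI
    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    for visit in hardware.visits():
        if visit.rfid is None:
            logger.warning("RFID read failure at t=%.3f; trial aborted", visit.t_enter)
            continue
        queue = queues.get(visit.rfid)
        if queue is None or not queue:
            logger.info("animal %s idle at t=%.3f (no queued trials)", visit.rfid, visit.t_enter)
            continue
        t = max(visit.t_enter, next_ok[visit.rfid])
        while queue and t + queue[0].response_window_s <= visit.t_exit:
            plan = queue.popleft()
            licks = debounce_licks(hardware.lick_times(visit.rfid, plan, t))
            mask, response = classify_response(
                licks, t, plan.response_window_s, plan.n_quarters
            )
            outcome, reward, iti = resolve_outcome(plan.valence, response, plan, rng)
            record = TrialRecord(
                animal_id=visit.rfid,
                task_id=plan.task_id,
                trial_idx=plan.trial_idx,
                valence=plan.valence,
                combo_index=plan.combo_index,
                t_start=t,
                lick_quarters=mask,
                response=response,
                outcome=outcome,
                reward_ul=reward,
                iti_s=iti,
            )
            records.append(record)
            if log_sink is not None:
                log_sink(record)
            hardware.notify_outcome(visit.rfid, plan, record)
            t += plan.response_window_s + iti
            next_ok[visit.rfid] = t
    return records
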