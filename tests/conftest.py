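"""Shared fixtures: olfactometer configs, synthetic logs, scripted hardware."""

from __future__ import annotations

import numpy as np
import pytest

from gonogo.controller import TrialRecord, Visit
from gonogo.olfactometer import default_config


@pytest.fixture
def paper_default_config():
    """Two parallel lines, each with two S+ and two S- sources."""
    return default_config()


def make_records(
    outcomes,
    times=None,
    animal_id="A1",
    task_id="task",
    iti=4.0,
    reward_ul=15.0,
):
    """Build TrialRecords from an outcome string sequence (H/M/CR/FA).

    Valence, response, lick mask and reward follow from the outcome so the
    records are internally consistent.
    """
    records = []
    t = 0.0
    for i, o in enumerate(outcomes):
        if times is not None:
            t = times[i]
        valence = "+" if o in ("H", "M") else "-"
        response = o in ("H", "FA")
        mask = (1, 1, 1, 1) if response else (0, 1, 0, 0)
        records.append(
            TrialRecord(
                animal_id=animal_id,
                task_id=task_id,
                trial_idx=i,
                valence=valence,
                combo_index=0,
                t_start=t,
                lick_quarters=mask,
                response=response,
                outcome=o,
                reward_ul=reward_ul if o == "H" else 0.0,
                iti_s=iti,
            )
        )
        if times is None:
            t += 2.0 + iti
    return records


class ScriptedHardware:
    """Hardware stub: fixed visit list plus a per-trial lick policy."""

    def __init__(self, visits, policy):
        self._visits = visits
        self._policy = policy  # (animal_id, plan, onset) -> lick times
        self.outcomes = []

    def visits(self):
        yield from self._visits

    def lick_times(self, animal_id, plan, onset):
        return self._policy(animal_id, plan, onset)

    def notify_outcome(self, animal_id, plan, record):
        self.outcomes.append(record)


def always_lick(animal_id, plan, onset):
    """Lick in every quarter (positive response)."""
    q = plan.response_window_s / plan.n_quarters
    return [onset + (i + 0.5) * q for i in range(plan.n_quarters)]


def never_lick(animal_id, plan, onset):
    return []


def perfect_policy(animal_id, plan, onset):
    """Lick on S+, withhold on S- (all hits and correct rejections)."""
    return always_lick(animal_id, plan, onset) if plan.valence == "+" else []
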