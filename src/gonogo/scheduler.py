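"""Task-schedule generation for go/no-go conditioning.

Valence sequences obey two constraints: no more than ``max_run`` identical
valences in a row, and an exact 1:1 S+:S- ratio in every complete block of
``block_size`` (default 100) trials.  Stimuli are delivered through valve
combinations drawn at random from the set of combinations that produce the
intended odour, so that valve noise and flow idiosyncrasies are never
informative about the reward condition.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Sequence

import numpy as np

from .olfactometer import InputLine, OlfactometerConfig, SourceValve

__all__ = [
    "TaskSpec",
    "ValenceSequence",
    "ValveCombo",
    "CohortAssignment",
    "TrialPlan",
    "InfeasibleScheduleError",
    "MissingOdourError",
    "TASK_TYPES",
    "MIXTURE_TASKS",
    "generate_valence_sequence",
    "enumerate_valve_combinations",
    "assign_valve_combination",
    "build_task_schedule",
    "pretraining_schedule",
    "introduce_new_valves",
    "bottle_switch_remap",
]

TASK_TYPES = frozenset(
    {
        "initial",
        "novel",
        "familiar",
        "NTS",
        "mixture",
        "NTM",
        "auditory",
        "s_plus_detection",
        "s_minus_detection",
        "pretraining",
    }
)
MIXTURE_TASKS = frozenset({"mixture", "NTM"})
OLFACTORY_TASKS = TASK_TYPES - {"auditory", "pretraining"}


class InfeasibleScheduleError(ValueError):
    """Raised when no valence sequence can satisfy the constraints."""


class MissingOdourError(LookupError):
    """Raised when the config cannot produce the requested stimulus."""


@dataclass(frozen=True)
class TaskSpec:
    """Parameters of one task in a training battery."""

    task_id: str
    task_type: str
    odour_pair: tuple[str, str] = ("odour_a", "odour_b")
    mixture_ratios: tuple[tuple[float, float], tuple[float, float]] | None = None
    n_trials: int = 500
    reward_volume: float = 15.0  # microlitres
    criterion: float = 0.8
    response_window: float = 2.0  # seconds
    n_quarters: int = 4
    iti_normal: float = 4.0  # seconds
    iti_timeout_range: tuple[float, float] = (8.0, 12.0)

    def __post_init__(self) -> None:
        if self.task_type not in TASK_TYPES:
            raise ValueError(f"unknown task_type {self.task_type!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.reward_volume <= 0:
            raise ValueError("reward_volume must be positive")
        if not 0 < self.criterion <= 1:
            raise ValueError("criterion must lie in (0, 1]")
        if self.iti_timeout_range[0] < self.iti_normal:
            raise ValueError("timeout ITI lower bound must be >= iti_normal")
        is_mix = self.task_type in MIXTURE_TASKS
        if is_mix and self.mixture_ratios is None:
            object.__setattr__(self, "mixture_ratios", ((60.0, 40.0), (40.0, 60.0)))
        if (self.mixture_ratios is not None) != is_mix:
            raise ValueError("mixture_ratios present iff task is mixture/NTM")
        if is_mix:
            for a, b in self.mixture_ratios:
                if abs(a + b - 100.0) > 1e-9:
                    raise ValueError("mixture ratios must sum to 100 per stimulus")


@dataclass(frozen=True)
class ValenceSequence:
    """An ordered S+/S- ('+'/'-') sequence with its generating parameters."""

    trials: tuple[str, ...]
    block_size: int = 100
    max_run: int = 3
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class ValveCombo:
    """One way of opening exactly one source valve per parallel line.

    ``line_assignments`` maps each participating line to the chosen valve and
    the odour it carries (None for a blank source).
    """

    line_assignments: tuple[tuple[str, str, str | None], ...]
    combo_index: int

    @property
    def valve_ids(self) -> tuple[str, ...]:
        return tuple(v for _, v, _ in self.line_assignments)

    @property
    def odours(self) -> tuple[str | None, ...]:
        return tuple(o for _, _, o in self.line_assignments)


@dataclass(frozen=True)
class CohortAssignment:
    """Animal list with per-animal reward mapping (which odour is S+)."""

    animal_ids: tuple[str, ...]
    reward_mapping: dict[str, str]

    @classmethod
    def balanced(
        cls, animal_ids: Sequence[str], odour_pair: tuple[str, str], seed: int = 0
    ) -> "CohortAssignment":
        """Split the cohort in half (sizes differ by at most 1) after a
        seeded shuffle; each half has the opposite odour as S+."""
        ids = list(animal_ids)
        random.Random(seed).shuffle(ids)
        half = math.ceil(len(ids) / 2)
        mapping = {a: odour_pair[0] for a in ids[:half]}
        mapping.update({a: odour_pair[1] for a in ids[half:]})
        return cls(tuple(animal_ids), mapping)


@dataclass(frozen=True)
class TrialPlan:
    """One scheduled trial for one animal."""

    animal_id: str
    task_id: str
    trial_idx: int
    valence: str  # '+' or '-'
    odour_labels: tuple[str | None, ...]
    mixture_ratio: tuple[float, float] | None
    combo_index: int
    valve_ids: tuple[str, ...]
    reward_ul: float
    lick_fraction: float = 0.0  # required licking, fraction of trial length
    min_licks: int = 0
    response_window_s: float = 2.0
    n_quarters: int = 4
    iti_normal: float = 4.0
    iti_timeout_range: tuple[float, float] = (8.0, 12.0)
    task_type: str = "novel"
    stage: int | None = None  # pre-training stage, if any
    #: the task's odour (or tone) pair — the identity of the discrimination,
    #: invariant to per-animal reward reversal
    odour_pair: tuple[str, str] = ("odour_a", "odour_b")


# ---------------------------------------------------------------------------
# valence sequences
# ---------------------------------------------------------------------------


def _arrangeable(p: int, q: int, max_run: int, trailing: int) -> bool:
    """Can p trials of the current run's valence and q of the other still be
    arranged with no run exceeding max_run, given ``trailing`` identical
    trials already emitted?  Standard gap-capacity argument: the q other
    trials carve q+1 slots for the run valence, the first of which is
    contiguous with the trailing run."""
    if p < 0 or q < 0:
        return False
    if p == 0 and q == 0:
        return True
    if p > (max_run - trailing) + max_run * q:
        return False
    if q > max_run * (p + 1):
        return False
    return True


def generate_valence_sequence(
    n: int,
    block_size: int = 100,
    max_run: int = 3,
    seed: int | None = None,
) -> ValenceSequence:
    """Generate a constrained S+/S- sequence.

    Rejection-free constructive sampler: trials are drawn one at a time with
    a feasibility lookahead on the remaining block budget and the current
    run length, so generation always terminates and every sequence
    satisfying the constraints has nonzero probability.  Complete blocks are
    exactly balanced; a partial final block is balanced to within one trial.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if max_run < 1:
        raise InfeasibleScheduleError("max_run must be >= 1")
    if block_size < 2 or block_size % 2:
        raise InfeasibleScheduleError("block_size must be even and >= 2")

    rng = random.Random(seed)
    trials: list[str] = []
    run_val = ""
    run_len = 0
    for start in range(0, n, block_size):
        k = min(block_size, n - start)
        budget = {"+": k // 2, "-": k // 2}
        if k % 2:
            budget[rng.choice("+-")] += 1
        for _ in range(k):
            feasible = []
            for v in "+-":
                if budget[v] == 0:
                    continue
                new_run = run_len + 1 if v == run_val else 1
                if new_run > max_run:
                    continue
                other = "-" if v == "+" else "+"
                if _arrangeable(budget[v] - 1, budget[other], max_run, new_run):
                    feasible.append(v)
            if not feasible:
                raise InfeasibleScheduleError(
                    f"no feasible valence at trial {len(trials)} "
                    f"(block_size={block_size}, max_run={max_run})"
                )
            v = feasible[0] if len(feasible) == 1 else rng.choice(feasible)
            budget[v] -= 1
            run_len = run_len + 1 if v == run_val else 1
            run_val = v
            trials.append(v)
    return ValenceSequence(tuple(trials), block_size, max_run, seed)


# ---------------------------------------------------------------------------
# valve combinatorics
# ---------------------------------------------------------------------------


def _pure_combos(config: OlfactometerConfig, odour: str | None) -> list[tuple]:
    per_line = []
    for line in config.lines:
        matches = line.sources_with(odour)
        if not matches:
            raise MissingOdourError(
                f"line {line.line_id!r} has no source for odour {odour!r}"
            )
        per_line.append([(line.line_id, s.valve_id, s.odour) for s in matches])
    return [tuple(choice) for choice in product(*per_line)]


def _mixture_combos(config: OlfactometerConfig, odours: tuple[str, str]) -> list[tuple]:
    if len(config.lines) != 2:
        raise MissingOdourError(
            "binary mixtures need exactly two parallel input lines"
        )
    combos: list[tuple] = []
    # both line-to-odour assignments count as distinct combinations
    for assignment in (odours, odours[::-1]):
        per_line = []
        for line, odour in zip(config.lines, assignment):
            matches = line.sources_with(odour)
            if not matches:
                raise MissingOdourError(
                    f"line {line.line_id!r} has no source for odour {odour!r}"
                )
            per_line.append([(line.line_id, s.valve_id, s.odour) for s in matches])
        combos.extend(tuple(choice) for choice in product(*per_line))
    return combos


def enumerate_valve_combinations(
    valence: str,
    task_type: str,
    config: OlfactometerConfig,
    odour_pair: tuple[str, str] | None = None,
) -> list[ValveCombo]:
    """Exhaustively enumerate the valid valve combinations for a stimulus.

    Pure stimuli pair same-odour sources across lines (4 combinations in the
    default two-line, two-sources-per-odour config); binary mixtures put the
    two components on distinct lines and count both line-to-odour
    assignments (8 combinations).  Detection tasks contrast one odour with
    blank (clean air) sources; auditory tasks involve no odour valves and
    return a single empty combination.
    """
    if valence not in "+-":
        raise ValueError("valence must be '+' or '-'")
    if task_type not in TASK_TYPES:
        raise ValueError(f"unknown task_type {task_type!r}")
    splus, sminus = odour_pair or config.odour_pair

    if task_type == "auditory":
        raw = [()]
    elif task_type in MIXTURE_TASKS:
        raw = _mixture_combos(config, (splus, sminus))
    elif task_type == "s_plus_detection":
        raw = _pure_combos(config, splus if valence == "+" else None)
    elif task_type == "s_minus_detection":
        raw = _pure_combos(config, None if valence == "+" else splus)
    elif task_type == "pretraining":
        raw = [()]
    else:  # initial / novel / familiar / NTS: pure odour per valence
        raw = _pure_combos(config, splus if valence == "+" else sminus)

    seen = set()
    combos = []
    for assignment in raw:
        if assignment in seen:
            continue
        seen.add(assignment)
        combos.append(ValveCombo(assignment, len(combos)))
    return combos


def assign_valve_combination(
    valence: str,
    task_type: str,
    config: OlfactometerConfig,
    seed: int | np.random.Generator | None = None,
    odour_pair: tuple[str, str] | None = None,
) -> ValveCombo:
    """Draw one combination uniformly from the enumerated valid set."""
    combos = enumerate_valve_combinations(valence, task_type, config, odour_pair)
    if len(combos) == 1:
        return combos[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return combos[int(rng.integers(len(combos)))]


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------


def _trial_odours(
    spec: TaskSpec, valence: str, animal_splus: str
) -> tuple[tuple[str | None, ...], tuple[float, float] | None]:
    """Odour labels (and mixture ratio) actually delivered to this animal on
    this trial, honouring the per-animal reward reversal."""
    pair = spec.odour_pair
    swapped = animal_splus != pair[0]
    if spec.task_type == "auditory":
        tone = pair[0] if (valence == "+") != swapped else pair[1]
        return (tone,), None
    if spec.task_type in MIXTURE_TASKS:
        ratios = spec.mixture_ratios
        ratio = ratios[0] if (valence == "+") != swapped else ratios[1]
        return pair, ratio
    if spec.task_type in ("s_plus_detection", "s_minus_detection"):
        odour_trial = (valence == "+") == (spec.task_type == "s_plus_detection")
        return ((pair[0],) if odour_trial else (None,)), None
    odour = pair[0] if (valence == "+") != swapped else pair[1]
    return (odour, odour), None


def build_task_schedule(
    spec: TaskSpec,
    cohort: CohortAssignment,
    config: OlfactometerConfig,
    seed: int | None = None,
) -> dict[str, list[TrialPlan]]:
    """Build per-animal trial plans for one task.

    All animals share the same valence sequence; the physical odour
    delivered on S+ trials differs between the two cohort halves per the
    reward mapping.  Valve combinations are drawn per animal per trial.
    """
    seq = generate_valence_sequence(spec.n_trials, seed=seed)
    ss = np.random.SeedSequence(0 if seed is None else seed)
    plans: dict[str, list[TrialPlan]] = {}
    for child, animal in zip(ss.spawn(len(cohort.animal_ids)), cohort.animal_ids):
        rng = np.random.default_rng(child)
        animal_splus = cohort.reward_mapping[animal]
        # flip the stimulus mapping for reversed animals so the *delivered*
        # odour matches their S+ assignment
        pair = spec.odour_pair if animal_splus == spec.odour_pair[0] else spec.odour_pair[::-1]
        animal_plans = []
        for idx, valence in enumerate(seq.trials):
            combo = assign_valve_combination(
                valence, spec.task_type, config, rng, odour_pair=pair
            )
            odours, ratio = _trial_odours(spec, valence, animal_splus)
            animal_plans.append(
                TrialPlan(
                    animal_id=animal,
                    task_id=spec.task_id,
                    trial_idx=idx,
                    valence=valence,
                    odour_labels=odours,
                    mixture_ratio=ratio,
                    combo_index=combo.combo_index,
                    valve_ids=combo.valve_ids,
                    reward_ul=spec.reward_volume,
                    response_window_s=spec.response_window,
                    n_quarters=spec.n_quarters,
                    iti_normal=spec.iti_normal,
                    iti_timeout_range=spec.iti_timeout_range,
                    task_type=spec.task_type,
                    odour_pair=spec.odour_pair,
                )
            )
        plans[animal] = animal_plans
    return plans


# pre-training stage lengths: free water, lick-once, ramped lick requirement
PRETRAIN_STAGES = (10, 50, 100)
PRETRAIN_TRIAL_S = 2.0
PRETRAIN_MAX_FRACTION = 0.10


def pretraining_schedule(
    seed: int | None = None, animal_id: str = "", reward_ul: float = 15.0
) -> list[TrialPlan]:
    """The three-stage pre-training protocol (160 trials total).

    Stage 1 (10 trials): water delivered on port entry, no lick required.
    Stage 2 (50 trials): at least one lick anywhere in the window.
    Stage 3 (100 trials): required licking ramps linearly up to 10% of the
    2 s trial length.
    """
    plans: list[TrialPlan] = []
    idx = 0
    for stage, length in enumerate(PRETRAIN_STAGES, start=1):
        for j in range(length):
            if stage == 1:
                frac, min_licks = 0.0, 0
            elif stage == 2:
                frac, min_licks = 0.0, 1
            else:
                frac = PRETRAIN_MAX_FRACTION * (j + 1) / length
                min_licks = 1
            plans.append(
                TrialPlan(
                    animal_id=animal_id,
                    task_id="pretraining",
                    trial_idx=idx,
                    valence="+",
                    odour_labels=(),
                    mixture_ratio=None,
                    combo_index=0,
                    valve_ids=(),
                    reward_ul=reward_ul,
                    lick_fraction=frac,
                    min_licks=min_licks,
                    response_window_s=PRETRAIN_TRIAL_S,
                    task_type="pretraining",
                    stage=stage,
                )
            )
            idx += 1
    return plans


def introduce_new_valves(
    plans: Sequence[TrialPlan],
    at_trial: int,
    config: OlfactometerConfig,
    added_sources: dict[str, list[tuple[str, str | None]]],
    seed: int | None = None,
) -> list[TrialPlan]:
    """Valve-introduction control: from ``at_trial`` on, draw combinations
    from the configuration enlarged by ``added_sources``; earlier trials and
    every other plan field are untouched."""
    if not 0 <= at_trial <= len(plans):
        raise IndexError(f"at_trial {at_trial} outside [0, {len(plans)}]")
    if not added_sources or all(not v for v in added_sources.values()):
        return list(plans)
    enlarged = config.with_added_sources(added_sources)
    rng = np.random.default_rng(seed)
    out = list(plans[:at_trial])
    for plan in plans[at_trial:]:
        combo = assign_valve_combination(plan.valence, plan.task_type, enlarged, rng)
        out.append(replace(plan, combo_index=combo.combo_index, valve_ids=combo.valve_ids))
    return out


def bottle_switch_remap(
    config: OlfactometerConfig, permutation: dict[int, int]
) -> OlfactometerConfig:
    """Full bottle switch with software remap.

    Bottles are physically permuted across positions, but the odour input is
    remapped at the software level so each valve still delivers the same
    logical stimulus: positions change, odour labels per valve do not, and
    the enumerated combination sets are stimulus-equivalent before and
    after."""
    positions = sorted({s.position for ln in config.lines for s in ln.sources})
    if sorted(permutation) != positions or sorted(permutation.values()) != positions:
        raise ValueError("permutation must be a bijection over bottle positions")
    new_lines = tuple(
        replace(
            ln,
            sources=tuple(
                replace(s, position=permutation[s.position]) for s in ln.sources
            ),
        )
        for ln in config.lines
    )
    return replace(config, lines=new_lines)
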