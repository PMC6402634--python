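"""Agent-based simulated mouse cohort.

Stands in for live animals so the full conditioning loop and every analysis
can be exercised without hardware: a circadian visit process (crepuscular,
night-biased), water-budget self-regulation (animals perform only the
trials needed for their daily intake), a delta-rule associative learning
policy mapped to lick behaviour, and graded olfactory-bulb lesion
phenotypes (anosmia, recognition loss, slowed learning, non-trigeminal
deficits) with auditory learning spared throughout.

The learning model — a scalar association strength per odour pair updated
by a delta rule and mapped linearly to response probability — is this
module's central modelling invention; the source experiments report
learning curves but prescribe no model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np

from . import controller
from .controller import TrialRecord, Visit
from .scheduler import (
    MIXTURE_TASKS,
    CohortAssignment,
    TaskSpec,
    TrialPlan,
    build_task_schedule,
)
from .olfactometer import OlfactometerConfig, default_config

__all__ = [
    "AnimalAgent",
    "LesionSpec",
    "LesionEvent",
    "LESION_PRESETS",
    "default_circadian_profile",
    "make_cohort",
    "visit_process",
    "water_budget",
    "decide_licks",
    "response_probability",
    "update_learning",
    "apply_lesion",
    "run_agent_task",
    "simulate_experiment",
    "SimulatedHardware",
]

# --- stated-world defaults -------------------------------------------------
#: fraction of daily trials in the dark phase (21:00-09:00)
NIGHT_FRACTION = 0.61
#: clock-hour bin of peak activity (10th hour of the dark phase)
PEAK_HOUR = 6
#: clock-hour bin of minimum activity (7th hour of the light phase)
TROUGH_HOUR = 15
#: reward volume (ul) below which extra activity no longer compensates
MIN_COMPENSATED_REWARD_UL = 12.0
#: cap on trials/day relative to the 12 ul baseline when rewards are small
COMPENSATION_CAP = 1.5
#: daily water target (ul) = WATER_C0 + WATER_C1 * weight_g; chosen so a
#: 25 g mouse at a 12 ul reward performs ~340 trials/day (cohort mean 333,
#: observed range 150-560 across weights and 10-30 ul rewards)
WATER_C0 = 300.0
WATER_C1 = 70.0
#: mean trials per continuous session/burst (printed mean session length 38)
MEAN_SESSION_LENGTH = 38.0
#: mixture discriminations are acquired more slowly than pure-odour ones;
#: their associations learn at this fraction of the base rate
MIXTURE_LEARN_FACTOR = 0.5


@dataclass(frozen=True)
class LesionSpec:
    """Olfactory-bulb lesion phenotype parameters.

    ``nmda_ng`` is the injected excitotoxin amount (0 = sham).  The
    phenotype mapping (which booleans/multipliers a given amount switches
    on) is a modelling choice calibrated to the observed group orderings,
    not a measured dose-response curve.
    """

    nmda_ng: float = 0.0
    effect_anosmia: bool = False
    effect_recognition_loss: bool = False
    learn_rate_multiplier: float = 1.0
    asymptote_penalty_nts_ntm: float = 0.0
    trigeminal_bypass: float = 0.0

    def __post_init__(self) -> None:
        if self.nmda_ng < 0:
            raise ValueError("nmda_ng must be >= 0")
        if not 0 < self.learn_rate_multiplier <= 1:
            raise ValueError("learn_rate_multiplier must lie in (0, 1]")
        if self.nmda_ng == 0 and (
            self.effect_anosmia
            or self.effect_recognition_loss
            or self.learn_rate_multiplier != 1.0
            or self.asymptote_penalty_nts_ntm != 0.0
            or self.trigeminal_bypass != 0.0
        ):
            raise ValueError("sham (0 ng) lesion must have all effects null")

    @property
    def is_sham(self) -> bool:
        return self.nmda_ng == 0


#: presets keyed by the experimental group labels (injected NMDA in ng)
LESION_PRESETS: dict[str, LesionSpec] = {
    "sham": LesionSpec(0.0),
    "S": LesionSpec(303.6, effect_recognition_loss=True),
    "M": LesionSpec(607.2, effect_recognition_loss=True),
    "L": LesionSpec(
        1214.0,
        effect_recognition_loss=True,
        learn_rate_multiplier=0.4,
        asymptote_penalty_nts_ntm=0.15,
        trigeminal_bypass=0.25,
    ),
    "XL": LesionSpec(
        1669.8,
        effect_recognition_loss=True,
        learn_rate_multiplier=0.3,
        asymptote_penalty_nts_ntm=0.2,
        trigeminal_bypass=0.2,
    ),
    "XXL": LesionSpec(2125.0, effect_anosmia=True, effect_recognition_loss=True),
}


@lru_cache(maxsize=None)
def _circadian_coefficients() -> tuple[float, float, float, float]:
    """Fit the two-term cosine density
    p(h) = 1/24 + A cos(pi (h-phi1)/12) + B cos(pi (h-phi2)/6)
    constrained to a stationary peak at 06:30, a stationary trough at 15:30
    and dark-phase (21:00-09:00) mass 0.61."""
    from scipy.optimize import least_squares

    peak, trough = PEAK_HOUR + 0.5, TROUGH_HOUR + 0.5

    def dp(h, x):
        a, b, p1, p2 = x
        return (
            -a * math.pi / 12 * math.sin(math.pi * (h - p1) / 12)
            - b * math.pi / 6 * math.sin(math.pi * (h - p2) / 6)
        )

    def night(x):
        a, _, p1, _ = x
        return 0.5 - 24 * a / math.pi * math.sin(math.pi * (21 - p1) / 12)

    sol = least_squares(
        lambda x: [dp(peak, x), dp(trough, x), night(x) - NIGHT_FRACTION, 0.02 * x[1]],
        x0=[0.02, 0.008, 4.0, 0.0],
    )
    return tuple(float(v) for v in sol.x)


@lru_cache(maxsize=None)
def default_circadian_profile() -> tuple[float, ...]:
    """24 hourly visit-intensity fractions (sum 1) from the calibrated
    two-term cosine: minimum in the 7th light-phase hour (15:00-16:00 bin),
    maximum 15 hours later, night mass 0.61 by construction."""
    a, b, p1, p2 = _circadian_coefficients()

    def antideriv(h: float) -> float:
        return (
            h / 24
            + a * 12 / math.pi * math.sin(math.pi * (h - p1) / 12)
            + b * 6 / math.pi * math.sin(math.pi * (h - p2) / 6)
        )

    bins = tuple(antideriv(h + 1.0) - antideriv(h) for h in range(24))
    total = sum(bins)
    return tuple(v / total for v in bins)


@dataclass
class AnimalAgent:
    """A simulated mouse."""

    animal_id: str
    weight_g: float = 25.0
    daily_water_target_ul: float | None = None
    circadian_profile: tuple[float, ...] = field(default_factory=default_circadian_profile)
    learning_state: dict = field(default_factory=dict)  # pair key -> a in [0,1]
    learn_rate: float = 0.01
    asymptote: float = 0.95
    lapse_rate: float = 0.02
    base_lick_rate: float = 0.5  # valence-blind positive-pattern rate pre-learning
    lesion: LesionSpec | None = None

    def __post_init__(self) -> None:
        if self.daily_water_target_ul is None:
            self.daily_water_target_ul = WATER_C0 + WATER_C1 * self.weight_g
        if not 0.5 <= self.asymptote <= 1.0:
            raise ValueError("asymptote must lie in [0.5, 1]")
        total = sum(self.circadian_profile)
        if len(self.circadian_profile) != 24 or (
            total > 0 and abs(total - 1.0) > 1e-9
        ):
            raise ValueError("circadian_profile needs 24 intensities summing to 1 (or all-zero)")


def make_cohort(
    n: int,
    seed: int | None = None,
    prefix: str = "RFID",
    weight_mean_g: float = 25.0,
    weight_sd_g: float = 3.0,
    **agent_kwargs,
) -> list[AnimalAgent]:
    """A cohort of agents with weights drawn from a normal distribution."""
    rng = np.random.default_rng(seed)
    weights = np.clip(rng.normal(weight_mean_g, weight_sd_g, size=n), 16.0, 40.0)
    return [
        AnimalAgent(animal_id=f"{prefix}{i + 1:03d}", weight_g=float(w), **agent_kwargs)
        for i, w in enumerate(weights)
    ]


# ---------------------------------------------------------------------------
# water budget and visit process
# ---------------------------------------------------------------------------


def water_budget(
    agent: AnimalAgent,
    reward_ul: float,
    expected_hit_fraction: float = 0.5,
) -> float:
    """Expected daily trial count from self-regulated water intake.

    Trials x reward ~= constant: the animal performs
    daily_water_target / (reward x expected hit fraction) trials per day for
    rewards of 12 ul and above.  Below 12 ul a compensation ceiling binds —
    animals do not fully make up very small rewards with extra activity.
    """
    if reward_ul <= 0:
        raise ValueError("reward_ul must be positive")
    if not 0 < expected_hit_fraction <= 1:
        raise ValueError("expected_hit_fraction must lie in (0, 1]")
    target = agent.daily_water_target_ul
    trials = target / (reward_ul * expected_hit_fraction)
    ceiling = COMPENSATION_CAP * target / (
        MIN_COMPENSATED_REWARD_UL * expected_hit_fraction
    )
    return min(trials, ceiling)


def visit_process(
    agent: AnimalAgent,
    seed: int | np.random.Generator | None = None,
    reward_ul: float = 15.0,
    day_length_h: float = 24.0,
    expected_trials: float | None = None,
) -> np.ndarray:
    """Trial-initiation times (hours within one day), an inhomogeneous
    Poisson process with hourly rates proportional to the circadian profile
    and total intensity matching the water budget."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if expected_trials is None:
        expected_trials = water_budget(agent, reward_ul)
    profile = np.asarray(agent.circadian_profile, dtype=float)
    n_hours = int(math.ceil(day_length_h))
    rates = expected_trials * profile[:n_hours]
    counts = rng.poisson(rates)
    times = np.concatenate(
        [h + rng.uniform(0.0, 1.0, size=c) for h, c in enumerate(counts)]
    ) if counts.sum() else np.empty(0)
    times = times[times < day_length_h]
    return np.sort(times)


# ---------------------------------------------------------------------------
# behaviour policy and learning
# ---------------------------------------------------------------------------


def pair_key(plan: TrialPlan) -> tuple:
    """Associative-memory key: one association per odour pair, kept separate
    for mixture versions of a pair (mixture discrimination must be learned
    anew) and for auditory stimuli."""
    labels = tuple(sorted(plan.odour_pair))
    if plan.task_type == "auditory":
        return ("auditory", labels)
    if plan.task_type in MIXTURE_TASKS:
        return ("mixture", labels)
    return ("odour", labels)


def _is_olfactory(plan: TrialPlan) -> bool:
    return plan.task_type not in ("auditory", "pretraining")


def _effective_params(agent: AnimalAgent, plan: TrialPlan) -> tuple[float, float]:
    """(association strength a, effective asymptote) after lesion effects."""
    key = pair_key(plan)
    a = agent.learning_state.get(key, 0.0)
    asym = agent.asymptote
    lesion = agent.lesion
    if lesion is not None and not lesion.is_sham and _is_olfactory(plan):
        if lesion.effect_anosmia:
            return 0.0, 0.5
        if plan.task_type in ("NTS", "NTM"):
            asym = max(0.5, asym - lesion.asymptote_penalty_nts_ntm)
        elif lesion.trigeminal_bypass > 0:
            # trigeminally active odours provide a residual non-olfactory cue
            asym = max(asym, 0.5 + lesion.trigeminal_bypass)
    return a, asym


def response_probability(agent: AnimalAgent, plan: TrialPlan) -> float:
    """Probability of a positive-response lick pattern on this trial.

    With discriminability d = 2 a (asymptote - 0.5):
    P(pos|S+) = base + (1-base) d, P(pos|S-) = base (1-d), each mixed with
    a lapse-rate fraction of coin-flip responding.  At a=0 the policy is
    valence-blind at the base rate; at a=1 expected performance equals the
    asymptote."""
    a, asym = _effective_params(agent, plan)
    d = max(0.0, min(1.0, 2.0 * a * (asym - 0.5)))
    base = agent.base_lick_rate
    core = base + (1.0 - base) * d if plan.valence == "+" else base * (1.0 - d)
    return (1.0 - agent.lapse_rate) * core + agent.lapse_rate * 0.5


def decide_licks(
    agent: AnimalAgent,
    plan: TrialPlan,
    onset: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> list[float]:
    """Emit lick times for one trial.

    Positive patterns occupy at least 3 response quarters, negative patterns
    at most 2 (possibly none).  An anosmic agent has a pinned at 0 on odour
    tasks and so licks valence-blindly there, while learning and responding
    normally on auditory tasks.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positive = rng.random() < response_probability(agent, plan)
    nq = plan.n_quarters
    qlen = plan.response_window_s / nq
    if positive:
        k = nq if rng.random() < 0.6 else max(1, nq - 1)
    else:
        k = int(rng.integers(0, min(3, nq)))  # 0-2 quarters
    quarters = rng.choice(nq, size=k, replace=False)
    return sorted(onset + (q + 0.5) * qlen for q in quarters)


def update_learning(agent: AnimalAgent, plan: TrialPlan, record: TrialRecord | None = None) -> None:
    """Delta-rule update after one completed trial: a <- a + lr (1 - a).

    Every stimulus presentation is informative (the outcome reveals the
    contingency through reward or timeout).  Anosmic agents receive no
    odour-task updates; lesioned agents learn olfactory tasks at a reduced
    rate but auditory tasks at the full rate.
    """
    if plan.task_type == "pretraining":
        return
    lr = agent.learn_rate
    if plan.task_type in MIXTURE_TASKS:
        lr *= MIXTURE_LEARN_FACTOR
    lesion = agent.lesion
    if lesion is not None and not lesion.is_sham and _is_olfactory(plan):
        if lesion.effect_anosmia:
            return
        lr *= lesion.learn_rate_multiplier
    key = pair_key(plan)
    a = agent.learning_state.get(key, 0.0)
    agent.learning_state[key] = min(1.0, a + lr * (1.0 - a))


def apply_lesion(agent: AnimalAgent, spec: LesionSpec) -> AnimalAgent:
    """Apply a lesion phenotype; sham (0 ng) is the identity.

    Recognition loss resets stored odour-pair associations to 0 (auditory
    associations are spared); anosmia pins odour-task behaviour at chance;
    learning-rate and asymptote effects are carried on the stored spec and
    applied at decision time."""
    if spec.is_sham:
        return agent
    if spec.effect_recognition_loss:
        agent.learning_state = {
            k: v for k, v in agent.learning_state.items() if k[0] == "auditory"
        }
    agent.lesion = spec
    return agent


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------


def run_agent_task(
    agent: AnimalAgent,
    plans: Sequence[TrialPlan],
    seed: int | np.random.Generator | None = None,
    t_start: float = 0.0,
    iti_rng: np.random.Generator | None = None,
) -> list[TrialRecord]:
    """Run one agent through a plan list with the controller's trial logic
    (classification, outcome table, learning updates) but trivial timing —
    the desk-scale path for learning-curve and lesion studies."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if iti_rng is None:
        iti_rng = rng
    records = []
    t = t_start
    for plan in plans:
        licks = controller.debounce_licks(decide_licks(agent, plan, t, rng))
        mask, response = controller.classify_response(
            licks, t, plan.response_window_s, plan.n_quarters
        )
        outcome, reward, iti = controller.resolve_outcome(
            plan.valence, response, plan, iti_rng
        )
        records.append(
            TrialRecord(
                animal_id=agent.animal_id,
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
        )
        update_learning(agent, plan)
        t += plan.response_window_s + iti
    return records


@dataclass(frozen=True)
class LesionEvent:
    """A battery item: apply per-animal lesion specs between tasks."""

    specs: dict[str, LesionSpec]


class SimulatedHardware:
    """Hardware interface backed by the agent cohort.

    Generates the merged visit stream (bursts of back-to-back trials whose
    start times follow each agent's circadian profile and water budget) and
    answers lick queries from the agents' behaviour policy.  Lesion events
    are applied when an animal's queue position crosses the event marker.
    """

    def __init__(
        self,
        agents: dict[str, AnimalAgent],
        days: int,
        reward_ul: float,
        seed: int | None,
        rfid_failure_rate: float = 0.0,
        lesion_at: dict[str, tuple[int, LesionSpec]] | None = None,
        mean_session_length: float = MEAN_SESSION_LENGTH,
    ) -> None:
        self.agents = agents
        self.days = days
        self.reward_ul = reward_ul
        self.rfid_failure_rate = rfid_failure_rate
        self.lesion_at = lesion_at or {}
        self.mean_session_length = max(1.0, mean_session_length)
        ss = np.random.SeedSequence(0 if seed is None else seed)
        children = ss.spawn(len(agents) + 1)
        self.visit_rng = np.random.default_rng(children[0])
        self.agent_rngs = {
            a: np.random.default_rng(c) for a, c in zip(agents, children[1:])
        }
        self.trials_done: dict[str, int] = {a: 0 for a in agents}
        self.water_earned_ul: dict[str, float] = {a: 0.0 for a in agents}

    def visits(self) -> Iterator[Visit]:
        all_visits: list[Visit] = []
        for animal_id, agent in self.agents.items():
            rng = self.agent_rngs[animal_id]
            daily = water_budget(agent, self.reward_ul)
            n_sessions = max(daily / self.mean_session_length, 1e-9)
            for day in range(self.days):
                starts = visit_process(
                    agent, rng, expected_trials=n_sessions
                )
                for h in starts:
                    length = rng.geometric(1.0 / self.mean_session_length)
                    # dwell sized to the nominal trial duration (2 s window
                    # + 4 s ITI, small allowance for occasional timeouts)
                    t0 = day * 86400.0 + h * 3600.0
                    rfid = animal_id
                    if self.rfid_failure_rate and rng.random() < self.rfid_failure_rate:
                        rfid = None
                    all_visits.append(Visit(t0, t0 + 6.2 * length + 2.0, rfid))
        all_visits.sort(key=lambda v: v.t_enter)
        yield from all_visits

    def lick_times(self, animal_id: str, plan: TrialPlan, onset: float):
        agent = self.agents[animal_id]
        marker = self.lesion_at.get(animal_id)
        if marker is not None and self.trials_done[animal_id] >= marker[0]:
            apply_lesion(agent, marker[1])
            del self.lesion_at[animal_id]
        return decide_licks(agent, plan, onset, self.agent_rngs[animal_id])

    def notify_outcome(self, animal_id: str, plan: TrialPlan, record: TrialRecord) -> None:
        agent = self.agents[animal_id]
        update_learning(agent, plan)
        self.trials_done[animal_id] += 1
        self.water_earned_ul[animal_id] += record.reward_ul


def simulate_experiment(
    cohort: Sequence[AnimalAgent],
    battery: Sequence[TaskSpec | LesionEvent],
    days: int = 30,
    seed: int | None = None,
    config: OlfactometerConfig | None = None,
    rfid_failure_rate: float = 0.0,
) -> list[TrialRecord]:
    """Drive the controller over a task battery with simulated hardware.

    Each animal works through the battery in order at its own pace; a
    LesionEvent item applies the per-animal lesion when the animal reaches
    that point in its queue.  Fully reproducible from ``seed``; returns the
    time-ordered trial records (write them with io.write_event_log).
    """
    agents = {a.animal_id: a for a in cohort}
    if len(agents) != len(cohort):
        raise ValueError("duplicate animal ids in cohort")
    ss = np.random.SeedSequence(0 if seed is None else seed)
    sched_seed, hw_seed, sess_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )

    queues: dict[str, list[TrialPlan]] = {a: [] for a in agents}
    lesion_at: dict[str, tuple[int, LesionSpec]] = {}
    tasks = [b for b in battery if isinstance(b, TaskSpec)]
    first_spec = tasks[0] if tasks else None
    reward_ul = first_spec.reward_volume if first_spec else 15.0
    for item_idx, item in enumerate(battery):
        if isinstance(item, LesionEvent):
            for animal_id, spec in item.specs.items():
                if animal_id not in agents:
                    raise KeyError(f"lesion event names unknown animal {animal_id!r}")
                lesion_at[animal_id] = (len(queues[animal_id]), spec)
            continue
        assignment = CohortAssignment.balanced(
            list(agents), item.odour_pair, seed=sched_seed + item_idx
        )
        plans = build_task_schedule(
            item, assignment, config or default_config(*item.odour_pair),
            seed=sched_seed + item_idx,
        )
        for animal_id, animal_plans in plans.items():
            queues[animal_id].extend(animal_plans)

    hardware = SimulatedHardware(
        agents,
        days=days,
        reward_ul=reward_ul,
        seed=hw_seed,
        rfid_failure_rate=rfid_failure_rate,
        lesion_at=lesion_at,
    )
    records = controller.run_session(queues, hardware, seed=sess_seed)
    records.sort(key=lambda r: (r.t_start, r.animal_id))
    return records
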