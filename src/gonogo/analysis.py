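"""Behavioural analysis of go/no-go event logs.

Performance is always the class-balanced score
``((S+ correct / total S+) + (S- correct / total S-)) / 2`` so that the
S+:S- mix inside an analysis window cannot bias the estimate.  On top of it
sit the sliding-window learning curves (windows 10/20/100), trials to
criterion, session segmentation (gaps < 20 s), circadian activity/accuracy
profiles, fast/slow learner stratification, the water-budget
trials-vs-reward curve, and task-context pooling with one-way ANOVA and
Tukey-Kramer post-hoc comparisons.

Most functions accept either a list of ``TrialRecord`` or the DataFrame
returned by ``gonogo.io.records_to_frame`` / ``read_event_log``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PerformanceSeries",
    "Session",
    "SessionSet",
    "performance",
    "sliding_performance",
    "trials_to_criterion",
    "segment_sessions",
    "hourly_profiles",
    "fast_slow_split",
    "reward_trials_curve",
    "task_context_pooling",
    "GAP_THRESHOLD_S",
    "NIGHT_HOURS",
]

#: inter-trial gap (s) above which a new session starts
GAP_THRESHOLD_S = 20.0
#: clock hours counted as night (dark phase 21:00-09:00); a trial at
#: exactly 21:00:00.000 counts as night
NIGHT_HOURS = frozenset(list(range(21, 24)) + list(range(0, 9)))

_CORRECT = {"H", "CR"}
_SPLUS = {"H", "M"}


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    from .io import records_to_frame

    return records_to_frame(records)


def performance(outcomes: Sequence[str]) -> float:
    """Class-balanced fraction correct: (H/(H+M) + CR/(CR+FA)) / 2.

    Returns NaN (the undefined marker) when either valence class is absent,
    rather than a biased number.
    """
    h = m = cr = fa = 0
    for o in outcomes:
        if o == "H":
            h += 1
        elif o == "M":
            m += 1
        elif o == "CR":
            cr += 1
        elif o == "FA":
            fa += 1
        else:
            raise ValueError(f"unknown outcome {o!r}")
    if h + m == 0 or cr + fa == 0:
        return float("nan")
    return 0.5 * (h / (h + m) + cr / (cr + fa))


@dataclass
class PerformanceSeries:
    """Per-trial trailing-window performance scores.

    ``scores[i]`` is the balanced performance over trials (i-window, i]
    (1-based trial counting: defined from trial index window-1 onward), NaN
    where the window is incomplete or lacks a valence class.
    """

    trial_idx: np.ndarray
    outcomes: np.ndarray
    scores: np.ndarray
    window: int

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.scores)


def sliding_performance(records, window: int = 20) -> PerformanceSeries:
    """Trailing-window performance per trial for one animal/task log."""
    if window < 1:
        raise ValueError("window must be >= 1")
    df = _as_frame(records)
    outcomes = df["outcome"].to_numpy()
    n = len(outcomes)
    is_splus = np.isin(outcomes, list(_SPLUS)).astype(float)
    is_correct = np.isin(outcomes, list(_CORRECT)).astype(float)
    scores = np.full(n, np.nan)
    if n >= window:
        ser_sp = pd.Series(is_splus)
        ser_sp_corr = pd.Series(is_splus * is_correct)
        ser_sm = 1.0 - ser_sp
        ser_sm_corr = pd.Series((1.0 - is_splus) * is_correct)
        n_sp = ser_sp.rolling(window).sum().to_numpy()
        n_sm = ser_sm.rolling(window).sum().to_numpy()
        c_sp = ser_sp_corr.rolling(window).sum().to_numpy()
        c_sm = ser_sm_corr.rolling(window).sum().to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            s = 0.5 * (c_sp / n_sp + c_sm / n_sm)
        ok = (n_sp > 0) & (n_sm > 0) & ~np.isnan(n_sp)
        scores[ok] = s[ok]
    idx = df["trial_idx"].to_numpy() if "trial_idx" in df else np.arange(n)
    return PerformanceSeries(idx, outcomes, scores, window)


NOT_REACHED = None


def trials_to_criterion(
    series: PerformanceSeries, criterion: float = 0.8
) -> int | None:
    """First trial count at which the trailing-window score reaches the
    criterion: the smallest i >= window with score(i) >= criterion (1-based
    trial counting, so a perfect responder returns exactly ``window``).
    Returns None when the criterion is never reached."""
    if not 0 < criterion <= 1:
        raise ValueError("criterion must lie in (0, 1]")
    hit = np.nonzero(series.scores >= criterion)[0]
    if hit.size == 0:
        return NOT_REACHED
    return int(hit[0]) + 1


@dataclass(frozen=True)
class Session:
    start_idx: int  # positional index of first trial in the log
    length: int
    mean_performance: float  # NaN when undefined (single-class session)


@dataclass
class SessionSet:
    sessions: list[Session]
    gap_threshold: float

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.sessions])

    def length_performance_pairs(self) -> list[tuple[int, float]]:
        """(session length, session performance) pairs with defined
        performance — the inputs to the session-length correlation."""
        return [
            (s.length, s.mean_performance)
            for s in self.sessions
            if not math.isnan(s.mean_performance)
        ]


def segment_sessions(records, gap_threshold: float = GAP_THRESHOLD_S) -> SessionSet:
    """Partition one animal's time-ordered trials into maximal runs with
    inter-trial start gaps below ``gap_threshold`` (default 20 s)."""
    df = _as_frame(records)
    times = df["timestamp_s"].to_numpy() if "timestamp_s" in df else df["t_start"].to_numpy()
    if np.any(np.diff(times) < 0):
        raise ValueError("records must be time-ordered")
    outcomes = df["outcome"].to_numpy()
    sessions: list[Session] = []
    if len(times) == 0:
        return SessionSet(sessions, gap_threshold)
    start = 0
    for i in range(1, len(times) + 1):
        if i == len(times) or times[i] - times[i - 1] >= gap_threshold:
            sessions.append(
                Session(start, i - start, performance(outcomes[start:i]))
            )
            start = i
    return SessionSet(sessions, gap_threshold)


def hourly_profiles(records) -> dict:
    """Circadian activity and accuracy profiles over all animals.

    Returns per-animal 24-bin activity fractions (each summing to 1),
    per-hour accuracy via the balanced performance score, per-animal
    night/day trial fractions with a two-sample two-tailed t-test, and the
    Pearson correlation between an hour's activity fraction and its
    accuracy.
    """
    df = _as_frame(records).copy()
    tcol = "timestamp_s" if "timestamp_s" in df else "t_start"
    df["hour"] = (df[tcol] // 3600).astype(int) % 24
    animals = sorted(df["animal_id"].unique())
    frac = pd.DataFrame(0.0, index=animals, columns=range(24))
    for animal, sub in df.groupby("animal_id"):
        counts = sub["hour"].value_counts()
        frac.loc[animal, counts.index] = counts.to_numpy() / len(sub)
    acc = pd.Series(
        {h: performance(df.loc[df["hour"] == h, "outcome"]) for h in range(24)}
    )
    night_cols = sorted(NIGHT_HOURS)
    day_cols = [h for h in range(24) if h not in NIGHT_HOURS]
    night_frac = frac[night_cols].sum(axis=1)
    day_frac = frac[day_cols].sum(axis=1)
    tt = stats.ttest_ind(night_frac, day_frac)
    # per animal-hour: fraction of the animal's trials in the hour vs its
    # accuracy in that hour
    pair_rows = []
    for animal, sub in df.groupby("animal_id"):
        for h, hsub in sub.groupby("hour"):
            a = performance(hsub["outcome"])
            if not math.isnan(a):
                pair_rows.append((frac.loc[animal, h], a))
    corr = (
        stats.pearsonr(*zip(*pair_rows)) if len(pair_rows) >= 3 else None
    )
    return {
        "fractions": frac,
        "hourly_accuracy": acc,
        "night_fraction": night_frac,
        "day_fraction": day_frac,
        "night_day_ttest": tt,
        "fraction_accuracy_pearson": corr,
    }


def fast_slow_split(
    cohort_series: dict[str, "PerformanceSeries | pd.DataFrame"],
    n_early: int = 200,
    window: int = 20,
) -> dict:
    """Stratify a cohort into fast and slow learners on one task.

    Each animal is scored by its balanced performance over the first
    ``n_early`` trials; animals below the cohort mean are "slow", the rest
    "fast".  Returns the groups, their mean +/- sem learning curves, and
    each group's per-animal maximum windowed performance.  Animals with
    fewer than ``n_early`` trials are excluded with a warning; a degenerate
    one-group split is flagged rather than an error.
    """
    early: dict[str, float] = {}
    series: dict[str, PerformanceSeries] = {}
    for animal, s in cohort_series.items():
        if not isinstance(s, PerformanceSeries):
            s = sliding_performance(s, window)
        if len(s.outcomes) < n_early:
            warnings.warn(
                f"animal {animal} has {len(s.outcomes)} < {n_early} trials; excluded"
            )
            continue
        early[animal] = performance(s.outcomes[:n_early])
        series[animal] = s
    if len(early) < 2:
        raise ValueError("need >= 2 animals with enough trials")
    mean_early = float(np.mean(list(early.values())))
    groups = {
        "fast": sorted(a for a, p in early.items() if p >= mean_early),
        "slow": sorted(a for a, p in early.items() if p < mean_early),
    }

    def group_curve(names):
        if not names:
            return None
        length = max(len(series[a]) for a in names)
        mat = np.full((len(names), length), np.nan)
        for i, a in enumerate(names):
            mat[i, : len(series[a])] = series[a].scores
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(mat, axis=0)
            n = np.sum(~np.isnan(mat), axis=0)
            sem = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
        return {"mean": mean, "sem": sem, "n": n}

    max_perf = {
        g: {a: float(np.nanmax(series[a].scores)) for a in names}
        for g, names in groups.items()
    }
    result = {
        "split_threshold": mean_early,
        "early_performance": early,
        "groups": groups,
        "curves": {g: group_curve(names) for g, names in groups.items()},
        "max_performance": max_perf,
        "degenerate": not (groups["fast"] and groups["slow"]),
    }
    if result["degenerate"]:
        warnings.warn("degenerate fast/slow split: all animals in one group")
    if groups["fast"] and groups["slow"]:
        f = list(max_perf["fast"].values())
        s = list(max_perf["slow"].values())
        if len(f) >= 2 and len(s) >= 2:
            result["max_performance_ttest"] = stats.ttest_ind(f, s)
    return result


def reward_trials_curve(
    daily_trials_by_reward: dict[float, Sequence[float]],
    baseline_reward_ul: float = 12.0,
) -> pd.DataFrame:
    """Normalized trials/day against reward size with the constant-intake
    reference.

    ``daily_trials_by_reward`` maps reward volume (ul) to per-animal (or
    per-day) trial counts.  Counts are normalized to the mean at the
    baseline (12 ul = 100%) condition; the reference curve is
    baseline/reward (trials x reward = constant).  ``deviation`` is the
    shortfall below the reference (positive = under-compensation, expected
    for rewards below the baseline)."""
    if len(daily_trials_by_reward) < 2:
        raise ValueError("need trial counts at >= 2 reward levels")
    if baseline_reward_ul not in daily_trials_by_reward:
        raise ValueError(f"missing baseline condition ({baseline_reward_ul} ul)")
    base = float(np.mean(daily_trials_by_reward[baseline_reward_ul]))
    rows = []
    for reward in sorted(daily_trials_by_reward):
        counts = np.asarray(daily_trials_by_reward[reward], dtype=float)
        norm = counts.mean() / base
        ref = baseline_reward_ul / reward
        rows.append(
            {
                "reward_ul": reward,
                "reward_fraction": reward / baseline_reward_ul,
                "mean_trials": counts.mean(),
                "normalized_trials": norm,
                "reference": ref,
                "deviation": ref - norm,
            }
        )
    return pd.DataFrame(rows)


def task_context_pooling(
    series_by_context: dict[str, Sequence["PerformanceSeries | pd.DataFrame"]],
    n_trials: int = 100,
    window: int = 20,
) -> dict:
    """Pool first-``n_trials`` performance by task context and compare.

    Per series, the summary statistic is the mean defined 20-trial-window
    score within the first ``n_trials`` trials.  Contexts are compared with
    a one-way ANOVA and Tukey-Kramer-corrected pairwise comparisons.
    """
    if len(series_by_context) < 2:
        raise ValueError("need >= 2 task contexts")
    values: dict[str, list[float]] = {}
    curves: dict[str, dict] = {}
    for context, many in series_by_context.items():
        if len(many) < 2:
            raise ValueError(f"context {context!r} needs >= 2 series")
        vals = []
        mat = np.full((len(many), n_trials), np.nan)
        for i, s in enumerate(many):
            if not isinstance(s, PerformanceSeries):
                s = sliding_performance(s, window)
            scores = s.scores[:n_trials]
            mat[i, : len(scores)] = scores
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                v = np.nanmean(scores)
            if not math.isnan(v):
                vals.append(float(v))
        values[context] = vals
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            curves[context] = {
                "mean": np.nanmean(mat, axis=0),
                "sem": np.nanstd(mat, axis=0, ddof=1)
                / np.sqrt(np.maximum(np.sum(~np.isnan(mat), axis=0), 1)),
            }
    f_stat, p_value = stats.f_oneway(*values.values())
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    flat = np.concatenate([np.asarray(v) for v in values.values()])
    labels = np.concatenate(
        [np.repeat(c, len(v)) for c, v in values.items()]
    )
    tukey = pairwise_tukeyhsd(flat, labels)
    return {
        "values": values,
        "curves": curves,
        "anova_F": float(f_stat),
        "anova_p": float(p_value),
        "tukey": tukey,
    }
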