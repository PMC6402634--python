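"""Shared plumbing: the canonical event-log CSV and experiment configs.

The event log is the repository's lingua franca — every executed trial is
one CSV row with header::

    timestamp_s,animal_id,task_id,trial_idx,valence,combo_index,lick_mask,response,outcome,reward_ul,iti_s

lick_mask is a binary string (Q1 leftmost), valence is ``+``/``-``,
response is ``1``/``0`` and outcome one of H/M/CR/FA.  Writing is
deterministic (fixed float formats), so write -> read -> write is
bit-identical.

Experiment configs are YAML; validation returns either a fully typed
``ExperimentConfig`` or the complete list of diagnostics (never just the
first error).
"""

from __future__ import annotations

import csv
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .controller import OUTCOMES, TrialRecord

__all__ = [
    "LOG_COLUMNS",
    "FORMAT_VERSION",
    "MalformedLogError",
    "ConfigError",
    "ExperimentConfig",
    "write_event_log",
    "read_event_log",
    "read_event_log_frame",
    "records_to_frame",
    "validate_config",
    "load_config",
]

FORMAT_VERSION = "1"

LOG_COLUMNS = (
    "timestamp_s",
    "animal_id",
    "task_id",
    "trial_idx",
    "valence",
    "combo_index",
    "lick_mask",
    "response",
    "outcome",
    "reward_ul",
    "iti_s",
)


class MalformedLogError(ValueError):
    """Event-log parse failure; ``diagnostics`` lists every problem found."""

    def __init__(self, diagnostics: list[str]):
        self.diagnostics = diagnostics
        super().__init__("; ".join(diagnostics))


class ConfigError(ValueError):
    """Config validation failure with the full diagnostic list."""

    def __init__(self, diagnostics: list[str]):
        self.diagnostics = diagnostics
        super().__init__("\n".join(diagnostics))


def _format_row(r: TrialRecord) -> list[str]:
    return [
        f"{r.t_start:.3f}",
        r.animal_id,
        r.task_id,
        str(r.trial_idx),
        r.valence,
        str(r.combo_index),
        r.lick_mask,
        "1" if r.response else "0",
        r.outcome,
        f"{r.reward_ul:.2f}",
        f"{r.iti_s:.3f}",
    ]


def write_event_log(records: Sequence[TrialRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LOG_COLUMNS)
        for r in records:
            writer.writerow(_format_row(r))


def read_event_log(path, fail_fast: bool = False) -> list[TrialRecord]:
    """Parse an event log back into TrialRecords.

    Parsing is header-keyed, so column order is free as long as the header
    names match the canonical set.  Malformed rows are reported with their
    line number and offending field; with ``fail_fast`` the first problem
    raises immediately, otherwise all diagnostics are collected first.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if sorted(header) != sorted(LOG_COLUMNS):
            raise MalformedLogError(
                [
                    f"{path.name}: header mismatch (format version {FORMAT_VERSION}): "
                    f"expected columns {sorted(LOG_COLUMNS)}, got {sorted(header)}"
                ]
            )
        records: list[TrialRecord] = []
        diagnostics: list[str] = []

        def problem(lineno: int, fieldname: str, msg: str) -> None:
            diagnostics.append(f"{path.name}:{lineno}: field {fieldname!r}: {msg}")
            if fail_fast:
                raise MalformedLogError(diagnostics)

        for lineno, row in enumerate(reader, start=2):
            ok = True
            parsed = {}
            for name, conv in (
                ("timestamp_s", float),
                ("trial_idx", int),
                ("combo_index", int),
                ("reward_ul", float),
                ("iti_s", float),
            ):
                try:
                    parsed[name] = conv(row[name])
                except (TypeError, ValueError):
                    problem(lineno, name, f"cannot parse {row.get(name)!r}")
                    ok = False
            if row.get("valence") not in ("+", "-"):
                problem(lineno, "valence", f"must be '+' or '-', got {row.get('valence')!r}")
                ok = False
            if row.get("outcome") not in OUTCOMES:
                problem(lineno, "outcome", f"must be one of {OUTCOMES}, got {row.get('outcome')!r}")
                ok = False
            mask = row.get("lick_mask") or ""
            if len(mask) != 4 or set(mask) - {"0", "1"}:
                problem(
                    lineno,
                    "lick_mask",
                    f"must be a 4-character binary string, got {mask!r}",
                )
                ok = False
            if row.get("response") not in ("0", "1"):
                problem(lineno, "response", f"must be '0' or '1', got {row.get('response')!r}")
                ok = False
            if not ok:
                continue
            records.append(
                TrialRecord(
                    animal_id=row["animal_id"],
                    task_id=row["task_id"],
                    trial_idx=parsed["trial_idx"],
                    valence=row["valence"],
                    combo_index=parsed["combo_index"],
                    t_start=parsed["timestamp_s"],
                    lick_quarters=tuple(int(c) for c in mask),
                    response=row["response"] == "1",
                    outcome=row["outcome"],
                    reward_ul=parsed["reward_ul"],
                    iti_s=parsed["iti_s"],
                )
            )
    if diagnostics:
        raise MalformedLogError(diagnostics)
    return records


SCHEDULE_COLUMNS = (
    "animal_id",
    "task_id",
    "trial_idx",
    "valence",
    "odour_labels",
    "mixture_ratio",
    "combo_index",
    "valve_ids",
    "reward_ul",
    "lick_requirement",
    "response_window_s",
)


def write_schedule(plans: dict[str, Sequence], path) -> None:
    """Emit per-animal trial plans as the schedule CSV (one row per trial)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCHEDULE_COLUMNS)
        for animal in plans:
            for p in plans[animal]:
                writer.writerow(
                    [
                        p.animal_id,
                        p.task_id,
                        p.trial_idx,
                        p.valence,
                        "|".join(str(o) for o in p.odour_labels),
                        "" if p.mixture_ratio is None else f"{p.mixture_ratio[0]:g}:{p.mixture_ratio[1]:g}",
                        p.combo_index,
                        "|".join(p.valve_ids),
                        f"{p.reward_ul:.2f}",
                        f"{p.lick_fraction:.4f}",
                        f"{p.response_window_s:.2f}",
                    ]
                )


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Records as a tidy DataFrame with the canonical column names."""
    return pd.DataFrame(
        {
            "timestamp_s": [r.t_start for r in records],
            "animal_id": [r.animal_id for r in records],
            "task_id": [r.task_id for r in records],
            "trial_idx": [r.trial_idx for r in records],
            "valence": [r.valence for r in records],
            "combo_index": [r.combo_index for r in records],
            "lick_mask": [r.lick_mask for r in records],
            "response": [r.response for r in records],
            "outcome": [r.outcome for r in records],
            "reward_ul": [r.reward_ul for r in records],
            "iti_s": [r.iti_s for r in records],
        }
    )


def read_event_log_frame(path, fail_fast: bool = False) -> pd.DataFrame:
    return records_to_frame(read_event_log(path, fail_fast=fail_fast))


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

_TOP_KEYS = {"version", "seed", "days", "odours", "cohort", "olfactometer", "battery"}
_COHORT_KEYS = {
    "n_animals",
    "prefix",
    "weight_mean_g",
    "weight_sd_g",
    "learn_rate",
    "asymptote",
    "lapse_rate",
    "animals",
}
_OLF_KEYS = {"splus_odour", "sminus_odour", "n_sources_per_odour", "n_lines", "mfc_fraction"}
_TASK_KEYS = {
    "task_id",
    "task_type",
    "odour_pair",
    "mixture_ratios",
    "n_trials",
    "reward_volume",
    "criterion",
    "response_window",
    "n_quarters",
    "iti_normal",
    "iti_timeout_range",
}


@dataclass
class ExperimentConfig:
    """Validated experiment description (cohort + olfactometer + battery)."""

    version: str
    seed: int = 0
    days: int = 30
    odours: list[str] = field(default_factory=list)
    cohort: dict = field(default_factory=dict)
    olfactometer: dict = field(default_factory=dict)
    battery: list = field(default_factory=list)

    def build_cohort(self):
        from .cohort import make_cohort

        c = dict(self.cohort)
        animals = c.pop("animals", None)
        if animals is not None:
            from .cohort import AnimalAgent

            return [AnimalAgent(**a) for a in animals]
        n = c.pop("n_animals", 8)
        return make_cohort(n, seed=self.seed, **c)

    def build_olfactometer(self):
        """The configured olfactometer, or None when the config leaves it
        implicit (bottles are then installed per task's odour pair)."""
        if not self.olfactometer:
            return None
        from .olfactometer import default_config

        olf = {k: v for k, v in self.olfactometer.items() if k != "mfc_fraction"}
        cfg = default_config(**olf)
        if "mfc_fraction" in self.olfactometer:
            from dataclasses import replace

            cfg = replace(cfg, mfc_fraction=self.olfactometer["mfc_fraction"])
        return cfg

    def build_battery(self):
        from .cohort import LESION_PRESETS, LesionEvent
        from .scheduler import TaskSpec

        items = []
        cohort_ids = [a.animal_id for a in self.build_cohort()]
        for raw in self.battery:
            if "lesion" in raw:
                specs = {}
                for animal, preset in raw["lesion"].items():
                    targets = cohort_ids if animal == "all" else [animal]
                    for t in targets:
                        specs[t] = LESION_PRESETS[preset]
                items.append(LesionEvent(specs))
            else:
                kw = dict(raw)
                if "odour_pair" in kw:
                    kw["odour_pair"] = tuple(kw["odour_pair"])
                if kw.get("mixture_ratios"):
                    kw["mixture_ratios"] = tuple(tuple(r) for r in kw["mixture_ratios"])
                if "iti_timeout_range" in kw:
                    kw["iti_timeout_range"] = tuple(kw["iti_timeout_range"])
                items.append(TaskSpec(**kw))
        return items


def validate_config(text: str) -> ExperimentConfig:
    """Validate YAML config text; raise ConfigError with *all* diagnostics.

    Unknown keys are rejected by name; invariant violations cite the
    invariant; battery entries referencing odours absent from the declared
    ``odours`` list are named.
    """
    diagnostics: list[str] = []
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError([f"not valid YAML: {exc}"]) from exc
    if not isinstance(data, dict):
        raise ConfigError(["config must be a mapping"])

    for key in sorted(set(data) - _TOP_KEYS):
        diagnostics.append(f"unknown top-level key {key!r}")
    if "version" not in data:
        diagnostics.append("missing mandatory key 'version'")

    cohort = data.get("cohort") or {}
    for key in sorted(set(cohort) - _COHORT_KEYS):
        diagnostics.append(f"cohort: unknown key {key!r}")

    olf = data.get("olfactometer") or {}
    for key in sorted(set(olf) - _OLF_KEYS):
        diagnostics.append(f"olfactometer: unknown key {key!r}")
    mfc = olf.get("mfc_fraction")
    if mfc is not None and not 0 <= mfc <= 1:
        diagnostics.append(
            f"olfactometer.mfc_fraction: {mfc} violates invariant mfc_fraction in [0, 1]"
        )

    declared = set(data.get("odours") or [])
    if olf:
        declared |= {olf.get("splus_odour"), olf.get("sminus_odour")} - {None}

    battery = data.get("battery") or []
    if not isinstance(battery, list):
        diagnostics.append("battery must be a list")
        battery = []
    from .cohort import LESION_PRESETS
    from .scheduler import TASK_TYPES

    for i, item in enumerate(battery):
        where = f"battery[{i}]"
        if not isinstance(item, dict):
            diagnostics.append(f"{where}: must be a mapping")
            continue
        if "lesion" in item:
            for preset in item["lesion"].values():
                if preset not in LESION_PRESETS:
                    diagnostics.append(
                        f"{where}: unknown lesion preset {preset!r} "
                        f"(known: {sorted(LESION_PRESETS)})"
                    )
            continue
        for key in sorted(set(item) - _TASK_KEYS):
            diagnostics.append(f"{where}: unknown key {key!r}")
        ttype = item.get("task_type")
        if ttype is not None and ttype not in TASK_TYPES:
            diagnostics.append(f"{where}: unknown task_type {ttype!r}")
        n_trials = item.get("n_trials")
        if n_trials is not None and n_trials < 1:
            diagnostics.append(f"{where}: n_trials={n_trials} violates invariant n_trials >= 1")
        reward = item.get("reward_volume")
        if reward is not None and reward <= 0:
            diagnostics.append(
                f"{where}: reward_volume={reward} violates invariant reward_volume > 0"
            )
        crit = item.get("criterion")
        if crit is not None and not 0 < crit <= 1:
            diagnostics.append(
                f"{where}: criterion={crit} violates invariant 0 < criterion <= 1"
            )
        if declared:
            for odour in item.get("odour_pair") or []:
                if odour not in declared:
                    diagnostics.append(
                        f"{where}: odour {odour!r} is not declared in the config"
                    )

    if diagnostics:
        raise ConfigError(diagnostics)
    return ExperimentConfig(
        version=str(data["version"]),
        seed=int(data.get("seed", 0)),
        days=int(data.get("days", 30)),
        odours=sorted(declared),
        cohort=cohort,
        olfactometer=olf,
        battery=battery,
    )


def load_config(path) -> ExperimentConfig:
    return validate_config(Path(path).read_text())
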