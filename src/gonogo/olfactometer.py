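"""Air-dilution olfactometer model.

Models the dual-line olfactometer used for odour delivery in automated
go/no-go conditioning: a carrier air stream into which one source valve per
parallel input line injects odourised air.  Delivered concentration is set
by the commanded mass-flow-controller (MFC) fraction — the flow-to-output
relation is linear — and the final valve either delivers the stream to the
animal or diverts it to exhaust.

Concentrations are relative units normalised so that a full-strength pulse
has plateau 1; the absolute vapour concentration is never modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SourceValve",
    "InputLine",
    "OlfactometerConfig",
    "StimulusTrace",
    "default_config",
    "concentration_from_flow",
    "synthesize_trace",
]

#: time for the pulse to rise from baseline to 90% of plateau (seconds)
DEFAULT_RISE_TIME_90 = 0.020
#: sampling grid step (seconds); 1 kHz resolves a 20 ms rise comfortably
DEFAULT_DT = 0.001


@dataclass(frozen=True)
class SourceValve:
    """One odour source: a valve drawing from a bottle at a physical position.

    ``odour`` is the label of the odorant in the bottle, or ``None`` for a
    blank (clean-air) source.
    """

    valve_id: str
    odour: str | None
    position: int = 0


@dataclass(frozen=True)
class InputLine:
    line_id: str
    sources: tuple[SourceValve, ...]

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError(f"line {self.line_id!r} has no source valves")

    def sources_with(self, odour: str | None) -> tuple[SourceValve, ...]:
        return tuple(s for s in self.sources if s.odour == odour)


@dataclass(frozen=True)
class OlfactometerConfig:
    """Valve/line topology plus flow settings.

    ``odour_pair`` is the canonical (S+ odour, S- odour) mapping for the
    currently installed task; per-animal reward reversal swaps the labels at
    schedule-build time, not here.
    """

    lines: tuple[InputLine, ...]
    odour_pair: tuple[str, str] = ("odour_a", "odour_b")
    carrier_flow: float = 2000.0  # cc/min
    line_flows: tuple[float, ...] = ()
    mfc_fraction: float = 1.0
    final_valve_mode: str = "deliver"  # "deliver" | "divert"

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError("config needs at least one input line")
        if self.carrier_flow < 0 or any(f < 0 for f in self.line_flows):
            raise ValueError("flows must be non-negative")
        if not 0.0 <= self.mfc_fraction <= 1.0:
            raise ValueError("mfc_fraction must lie in [0, 1]")
        if self.final_valve_mode not in ("deliver", "divert"):
            raise ValueError(f"unknown final_valve_mode {self.final_valve_mode!r}")

    def with_added_sources(
        self, added: dict[str, list[tuple[str, str | None]]]
    ) -> "OlfactometerConfig":
        """Return a config with extra source valves appended to named lines."""
        new_lines = []
        next_pos = 1 + max(
            (s.position for ln in self.lines for s in ln.sources), default=-1
        )
        for line in self.lines:
            extra = added.get(line.line_id, [])
            new = []
            for vid, od in extra:
                new.append(SourceValve(vid, od, next_pos))
                next_pos += 1
            new_lines.append(replace(line, sources=line.sources + tuple(new)))
        unknown = set(added) - {ln.line_id for ln in self.lines}
        if unknown:
            raise KeyError(f"unknown line id(s): {sorted(unknown)}")
        return replace(self, lines=tuple(new_lines))


def default_config(
    splus_odour: str = "odour_a",
    sminus_odour: str = "odour_b",
    n_sources_per_odour: int = 2,
    n_lines: int = 2,
) -> OlfactometerConfig:
    """The standard dual-line configuration.

    Each parallel input line holds ``n_sources_per_odour`` sources of the S+
    odour and the same number of the S- odour (default two of each), so a
    pure stimulus can be produced by 2x2 = 4 valve combinations and a binary
    mixture by 8.
    """
    lines = []
    pos = 0  # bottle positions are globally unique across lines
    for li in range(n_lines):
        sources = []
        for odour in (splus_odour, sminus_odour):
            for k in range(n_sources_per_odour):
                sources.append(SourceValve(f"L{li + 1}V{len(sources) + 1}", odour, pos))
                pos += 1
        lines.append(InputLine(f"L{li + 1}", tuple(sources)))
    return OlfactometerConfig(
        lines=tuple(lines),
        odour_pair=(splus_odour, sminus_odour),
        line_flows=tuple(100.0 for _ in range(n_lines)),
    )


@dataclass
class StimulusTrace:
    """A synthetic PID-like concentration trace on a uniform time grid."""

    times: np.ndarray
    concentration: np.ndarray
    onset: float
    duration: float
    rise_time_90: float = DEFAULT_RISE_TIME_90

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"time_s": self.times, "concentration": self.concentration}
        ).to_csv(path, index=False)


def concentration_from_flow(mfc_fraction: float) -> float:
    """Relative plateau concentration for a commanded MFC fraction.

    Output odour level is linear in input flow, normalised so full flow
    gives 1; e.g. 60% and 40% MFC input give plateaus 0.6 and 0.4.
    """
    if not 0.0 <= mfc_fraction <= 1.0:
        raise ValueError(f"mfc_fraction {mfc_fraction} outside [0, 1]")
    return float(mfc_fraction)


def synthesize_trace(
    config: OlfactometerConfig,
    onset: float,
    duration: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dt: float = DEFAULT_DT,
    rise_time_90: float = DEFAULT_RISE_TIME_90,
    tail: float = 0.1,
) -> StimulusTrace:
    """Synthesize a square-pulse stimulus trace.

    The rise is single-exponential with time constant tau = rise_time_90 /
    ln(10), so the noiseless trace crosses 90% of plateau exactly
    ``rise_time_90`` after onset.  In divert mode the odour stream goes to
    exhaust and the mean trace is identically zero regardless of the
    configured stimulus — the property that makes final-valve diversion a
    chance-performance control.

    Additive Gaussian measurement noise (sd ``noise_sd``) is symmetric about
    the signal; only the upper physical bound (1.05) is clipped, so a zero
    signal keeps zero mean.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n = int(round((onset + duration + tail) / dt)) + 1
    times = np.arange(n) * dt
    plateau = concentration_from_flow(config.mfc_fraction)
    tau = rise_time_90 / math.log(10.0)
    conc = np.zeros(n)
    if config.final_valve_mode == "deliver":
        on = times >= onset
        rising = on & (times < onset + duration)
        conc[rising] = plateau * (1.0 - np.exp(-(times[rising] - onset) / tau))
        after = times >= onset + duration
        # decay back to baseline with the same kinetics
        level = plateau * (1.0 - math.exp(-duration / tau))
        conc[after] = level * np.exp(-(times[after] - onset - duration) / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        conc = conc + rng.normal(0.0, noise_sd, size=n)
    np.clip(conc, None, 1.05, out=conc)
    return StimulusTrace(times, conc, onset, duration, rise_time_90)
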