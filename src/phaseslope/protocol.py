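"""Environmental schedules and Zeitgeber time.

An experiment is an ordered, contiguous list of :class:`EnvironmentSegment`
objects.  Within a segment at most one modality cycles as a 12h:12h square
wave: light under LD, temperature under LLTC/DDTC.  ZT0 is defined as
lights-on when light cycles and as thermophase onset when temperature
cycles; in fully constant segments ZT is projected from the segment's
anchor (the subjective day grid).

The standard protocol modeled here entrains flies in LD 25 degC, releases
them into constant conditions at 25 degC, then applies 25:16 degC
temperature cycles whose thermophase onset is delayed by a configurable
number of hours relative to the old lights-on time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .errors import ProtocolError

MIN_PER_DAY = 1440
HALF_DAY = 720
_DAY = pd.Timedelta(days=1)

LightState = Literal["ON", "OFF"]


@dataclass(frozen=True)
class LightSpec:
    mode: Literal["constant", "cycle"]
    state: LightState = "ON"          # constant mode only


@dataclass(frozen=True)
class TemperatureSpec:
    mode: Literal["constant", "cycle"]
    level: float = 25.0               # constant mode
    warm: float = 25.0                # cycle mode: thermophase level
    cold: float = 16.0                # cycle mode: cryophase level


@dataclass(frozen=True)
class EnvironmentSegment:
    """One homogeneous stretch of the schedule.

    ``zt0_anchor`` is any absolute occurrence of ZT0 for this segment
    (lights-on or thermophase onset for cyclic segments, the projected
    subjective ZT0 for constant ones); ZT is computed modulo 24 h from it.
    """

    label: str
    start: pd.Timestamp
    end: pd.Timestamp
    light: LightSpec
    temperature: TemperatureSpec
    zt0_anchor: pd.Timestamp

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ProtocolError(f"segment {self.label}: start must precede end")
        if self.light.mode == "cycle" and self.temperature.mode == "cycle":
            raise ProtocolError(
                f"segment {self.label}: at most one cyclic modality is supported"
            )

    @property
    def cyclic(self) -> bool:
        return self.light.mode == "cycle" or self.temperature.mode == "cycle"


@dataclass(frozen=True)
class Protocol:
    segments: tuple[EnvironmentSegment, ...]

    def __post_init__(self) -> None:
        segs = self.segments
        if not segs:
            raise ProtocolError("protocol needs at least one segment")
        for a, b in zip(segs, segs[1:]):
            if a.end != b.start:
                raise ProtocolError(
                    f"segments {a.label} and {b.label} are not contiguous"
                )

    @property
    def start(self) -> pd.Timestamp:
        return self.segments[0].start

    @property
    def end(self) -> pd.Timestamp:
        return self.segments[-1].end

    def segment_at(self, t: pd.Timestamp) -> EnvironmentSegment:
        for seg in self.segments:
            if seg.start <= t < seg.end:
                return seg
        raise ProtocolError(f"{t} lies outside the protocol span "
                            f"[{self.start}, {self.end})")

    def segment(self, label: str) -> EnvironmentSegment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise ProtocolError(f"no segment labelled {label!r}")


def zt_of(t: pd.Timestamp, protocol: Protocol) -> float:
    """Zeitgeber time of ``t`` in minutes, in [0, 1440)."""
    seg = protocol.segment_at(t)
    delta = (t - seg.zt0_anchor).total_seconds() / 60.0
    return delta % MIN_PER_DAY


def environment_at(t: pd.Timestamp, protocol: Protocol) -> tuple[LightState, float]:
    """(light state, temperature in degC) at absolute time ``t``."""
    seg = protocol.segment_at(t)
    zt = zt_of(t, protocol)
    if seg.light.mode == "cycle":
        light: LightState = "ON" if zt < HALF_DAY else "OFF"
    else:
        light = seg.light.state
    if seg.temperature.mode == "cycle":
        temp = seg.temperature.warm if zt < HALF_DAY else seg.temperature.cold
    else:
        temp = seg.temperature.level
    return light, temp


def segment_transitions(segment: EnvironmentSegment) -> list[tuple[int, str]]:
    """The segment's daily Zeitgeber transitions as (ZT minute, kind)."""
    if segment.light.mode == "cycle":
        return [(0, "lights-on"), (HALF_DAY, "lights-off")]
    if segment.temperature.mode == "cycle":
        return [(0, "warm-onset"), (HALF_DAY, "cold-onset")]
    return []


def transitions(protocol: Protocol, day: int) -> list[tuple[int, str]]:
    """Transitions of protocol day ``day`` (0-based, counted from start)."""
    mid = protocol.start + pd.Timedelta(hours=12) + day * _DAY
    if not (protocol.start <= mid < protocol.end):
        raise ProtocolError(f"day {day} is outside the protocol")
    return segment_transitions(protocol.segment_at(mid))


def standard_protocol(
    name: Literal["LLTC", "DDTC"],
    days_ld: int = 2,
    days_constant: int = 3,
    days_tc: int = 6,
    shift_h: float = 5.0,
    days_after: int = 0,
    start: pd.Timestamp | str = "2022-01-03 08:00",
) -> Protocol:
    """Build the LD -> constant -> temperature-cycle protocol.

    ``shift_h`` delays the thermophase onset relative to the old lights-on
    clock time; the TC segment's first full Zeitgeber day starts at the
    first thermophase onset, so "TC day k" indexes full TC days only.
    ``days_after`` appends a final constant segment (free run) whose
    subjective-day grid is projected from the TC anchor.
    """
    if name not in ("LLTC", "DDTC"):
        raise ProtocolError(f"unknown protocol {name!r}")
    if min(days_ld, days_constant, days_tc) < 1:
        raise ProtocolError("each phase needs at least one day")
    if not 0 <= shift_h < 24:
        raise ProtocolError("shift_h must lie in [0, 24)")
    t0 = pd.Timestamp(start)
    light_const: LightState = "ON" if name == "LLTC" else "OFF"
    ld_end = t0 + days_ld * _DAY
    const_end = ld_end + days_constant * _DAY
    tc_anchor = const_end + pd.Timedelta(hours=shift_h)
    tc_end = tc_anchor + days_tc * _DAY
    segs = [
        EnvironmentSegment("LD", t0, ld_end,
                           LightSpec("cycle"), TemperatureSpec("constant", 25.0), t0),
        EnvironmentSegment("LL" if name == "LLTC" else "DD", ld_end, const_end,
                           LightSpec("constant", light_const),
                           TemperatureSpec("constant", 25.0), t0),
        EnvironmentSegment(name, const_end, tc_end,
                           LightSpec("constant", light_const),
                           TemperatureSpec("cycle", warm=25.0, cold=16.0),
                           tc_anchor),
    ]
    if days_after > 0:
        segs.append(EnvironmentSegment(
            "free", tc_end, tc_end + days_after * _DAY,
            LightSpec("constant", light_const),
            TemperatureSpec("constant", 25.0), tc_anchor))
    return Protocol(tuple(segs))


def from_dict(spec: dict) -> Protocol:
    """Build a protocol from a config mapping (the YAML surface).

    Expected keys: ``name`` plus the optional ``standard_protocol``
    arguments (``days_ld``, ``days_constant``, ``days_tc``, ``shift_h``,
    ``days_after``, ``start``).
    """
    allowed = {"name", "days_ld", "days_constant", "days_tc",
               "shift_h", "days_after", "start"}
    unknown = set(spec) - allowed
    if unknown:
        raise ProtocolError(f"unknown protocol keys: {sorted(unknown)}")
    if "name" not in spec:
        raise ProtocolError("protocol spec needs a 'name' (LLTC or DDTC)")
    return standard_protocol(**spec)


def describe(protocol: Protocol) -> str:
    """Human-readable schedule, one line per segment."""
    lines = []
    for seg in protocol.segments:
        if seg.light.mode == "cycle":
            env = "light 12h:12h, 25degC"
        elif seg.temperature.mode == "cycle":
            env = (f"light {seg.light.state}, temperature "
                   f"{seg.temperature.warm:g}:{seg.temperature.cold:g}degC")
        else:
            env = f"light {seg.light.state}, {seg.temperature.level:g}degC"
        lines.append(f"{seg.label:>6}  {seg.start} -> {seg.end}  {env}  "
                     f"ZT0 anchor {seg.zt0_anchor}")
    return "\n".join(lines)
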