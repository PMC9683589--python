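"""Labeled synthetic activity-monitor data.

The generator emulates the features of fly locomotor recordings that the
slope pipeline consumes: a piecewise-linear anticipatory ramp rising
toward each Zeitgeber transition, an exponentially decaying startle burst
*at* the transition (which a correct peak search must exclude), a midday
siesta trough, and Poisson counting noise at the monitor's one-minute
resolution.  Each fly belongs to one of three labeled classes:

* ``synchronized`` — ramps at the template phase (plus any population-wide
  delay), the anticipating ground truth;
* ``desynchronized`` — the ramp phase redrawn uniformly over the cycle
  (clock running, not entrained);
* ``flat`` — no clock-driven component at all (clock-disrupted): neither
  anticipation ramps nor the clock-gated siesta trough, only a constant
  baseline (optionally elevated — clock mutants are typically
  hyperactive around the clock) plus the startle, which is a direct
  environmental response and therefore survives clock disruption.

In constant segments the ramp phase free-runs with a configurable period.
Linear ramps keep the analyzed statistic analytically tractable:
``expected_rate`` returns the exact rate function of a synchronized fly,
which tests compare against empirical bin means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dam_io import ActivityMatrix
from .protocol import (MIN_PER_DAY, HALF_DAY, Protocol, segment_transitions,
                       standard_protocol)


@dataclass(frozen=True)
class RampSpec:
    """Linear anticipation ramp: 0 at onset, peaking near a transition.

    The rate rises linearly from ``onset_zt`` to ``peak_zt`` (counts/min),
    holds at the peak level until the transition the ramp anticipates
    (or ``end_zt`` when given — e.g. activity that persists into the
    early thermophase), then drops to zero.  Times wrap modulo 24 h, so a
    ramp may straddle ZT0.
    """

    amplitude: float          # counts/min at the peak
    onset_zt: float           # minutes
    peak_zt: float            # minutes
    end_zt: float | None = None


@dataclass(frozen=True)
class StartleSpec:
    """Acute burst at each transition, decaying exponentially."""

    amplitude: float          # counts/min at the transition instant
    half_life_min: float = 10.0


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of one simulated population."""

    n_flies: int = 60
    baseline_rate: float = 0.2                      # counts/min
    evening: RampSpec = RampSpec(2.0, 510.0, 690.0)  # anticipates ZT720
    morning: RampSpec = RampSpec(0.8, 1290.0, 1430.0)  # anticipates ZT0
    startle: StartleSpec = StartleSpec(3.0, 10.0)
    siesta_depth: float = 0.3                       # multiplicative midday trough
    p_desync: float = 0.0
    p_flat: float = 0.0
    flat_activity_rate: float | None = None         # counts/min for flat flies
    phase_delay_min: float = 0.0                    # population-wide delay
    freerun_period_min: float = 1440.0
    overdispersion: float = 0.0                     # gamma-mixed rates if > 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_flies < 1:
            raise ValueError("need at least one fly")
        for p in (self.p_desync, self.p_flat):
            if not 0.0 <= p <= 1.0:
                raise ValueError("class probabilities must lie in [0, 1]")
        if self.p_desync + self.p_flat > 1.0 + 1e-12:
            raise ValueError("p_desync + p_flat must not exceed 1")
        if min(self.baseline_rate, self.evening.amplitude,
               self.morning.amplitude, self.startle.amplitude) < 0:
            raise ValueError("rates must be non-negative")
        if self.flat_activity_rate is not None and self.flat_activity_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.siesta_depth <= 1.0:
            raise ValueError("siesta_depth must lie in [0, 1]")
        if self.freerun_period_min <= 0:
            raise ValueError("free-running period must be positive")


# ---------------------------------------------------------------------------
# deterministic rate machinery

def circadian_phase(protocol: Protocol, timestamps: pd.DatetimeIndex,
                    freerun_period_min: float = 1440.0) -> np.ndarray:
    """Internal clock phase (minutes, [0, 1440)) per timestamp.

    In cyclic segments the phase equals ZT (instant re-entrainment); in
    constant segments it advances from its value at segment entry at
    1440 / freerun_period minutes of phase per minute of real time.
    """
    phase = np.empty(len(timestamps), dtype=float)
    carry: float | None = None
    for seg in protocol.segments:
        mask = (timestamps >= seg.start) & (timestamps < seg.end)
        entry = seg.start
        if seg.cyclic:
            if mask.any():
                delta = (timestamps[mask] - seg.zt0_anchor).total_seconds() / 60.0
                phase[mask] = np.mod(delta, MIN_PER_DAY)
            carry = float(np.mod(
                (seg.end - seg.zt0_anchor).total_seconds() / 60.0, MIN_PER_DAY))
        else:
            if carry is None:
                carry = float(np.mod(
                    (entry - seg.zt0_anchor).total_seconds() / 60.0, MIN_PER_DAY))
            if mask.any():
                elapsed = (timestamps[mask] - entry).total_seconds() / 60.0
                phase[mask] = np.mod(
                    carry + elapsed * MIN_PER_DAY / freerun_period_min,
                    MIN_PER_DAY)
            span = (seg.end - entry).total_seconds() / 60.0
            carry = float(np.mod(
                carry + span * MIN_PER_DAY / freerun_period_min, MIN_PER_DAY))
    return phase


def ramp_value(phase: np.ndarray, ramp: RampSpec, transition_zt: float) -> np.ndarray:
    """Evaluate a ramp (possibly phase-shifted elsewhere) at clock phases."""
    if ramp.amplitude == 0:
        return np.zeros_like(phase)
    dur = np.mod(ramp.peak_zt - ramp.onset_zt, MIN_PER_DAY)
    if dur <= 0:
        raise ValueError("ramp onset must precede its peak")
    end = transition_zt if ramp.end_zt is None else ramp.end_zt
    hold = np.mod(end - ramp.onset_zt, MIN_PER_DAY)
    if hold == 0:
        hold = MIN_PER_DAY
    rel = np.mod(phase - ramp.onset_zt, MIN_PER_DAY)
    out = np.zeros_like(phase)
    rising = rel < dur
    out[rising] = ramp.amplitude * rel[rising] / dur
    out[(rel >= dur) & (rel < hold)] = ramp.amplitude
    return out


def _siesta_factor(phase: np.ndarray, depth: float) -> np.ndarray:
    trough = (phase >= 240.0) & (phase < 480.0)       # ZT4-ZT8
    return 1.0 - depth * trough


def startle_trace(protocol: Protocol, timestamps: pd.DatetimeIndex,
                  spec: StartleSpec, cutoff_min: float = 120.0) -> np.ndarray:
    """Summed startle rate (counts/min) at each timestamp."""
    out = np.zeros(len(timestamps))
    if spec.amplitude == 0:
        return out
    t_min = timestamps.asi8 / 60_000_000_000.0        # epoch minutes
    for seg in protocol.segments:
        for zt, _kind in segment_transitions(seg):
            first = seg.zt0_anchor + pd.Timedelta(minutes=zt)
            while first < seg.start:
                first += pd.Timedelta(days=1)
            tr = first
            while tr < seg.end:
                dt = t_min - tr.value / 60_000_000_000.0
                hit = (dt >= 0) & (dt <= cutoff_min)
                out[hit] += spec.amplitude * 0.5 ** (dt[hit] / spec.half_life_min)
                tr += pd.Timedelta(days=1)
    return out


def _fly_rate(cfg: SimConfig, phase: np.ndarray, startle: np.ndarray,
              shift: float | None) -> np.ndarray:
    """Rate function of one fly; ``shift=None`` marks a flat (clock-less) fly.

    Ramps and the siesta trough are clock outputs and follow the fly's
    own phase; flat flies have neither, just a constant rate plus the
    environmentally driven startle.
    """
    if shift is None:
        rate = (cfg.baseline_rate if cfg.flat_activity_rate is None
                else cfg.flat_activity_rate)
        return np.full_like(phase, rate) + startle
    p = np.mod(phase - shift, MIN_PER_DAY)
    lam = np.full_like(phase, cfg.baseline_rate)
    lam = lam + ramp_value(p, cfg.evening, HALF_DAY)
    lam = lam + ramp_value(p, cfg.morning, MIN_PER_DAY)
    lam = lam * _siesta_factor(p, cfg.siesta_depth)
    return lam + startle


def expected_rate(cfg: SimConfig, protocol: Protocol) -> pd.Series:
    """Exact per-minute rate of a synchronized fly under the protocol."""
    cfg.validate()
    timestamps = pd.date_range(protocol.start, protocol.end,
                               freq="1min", inclusive="left")
    phase = circadian_phase(protocol, timestamps, cfg.freerun_period_min)
    startle = startle_trace(protocol, timestamps, cfg.startle)
    return pd.Series(_fly_rate(cfg, phase, startle, cfg.phase_delay_min),
                     index=timestamps)


def expected_day_profile(cfg: SimConfig, protocol: Protocol,
                         which: str = "TC_day_6",
                         bin_minutes: int = 30) -> pd.Series:
    """Noise-free normalized profile of the synchronized archetype.

    The exact rate is integrated per bin over the whole protocol,
    normalized to its maximum bin (the same percent-of-max convention the
    pipeline applies to each fly), and sliced to one analysis day on the
    ZT grid.  Its slope between the true ramp landmarks is the
    theoretical slope of a perfectly synchronized fly — the natural
    anchor for ground-truth recovery experiments.
    """
    from .preprocess import day_window   # local import; avoids a cycle

    lam = expected_rate(cfg, protocol)
    n = len(lam) // bin_minutes
    sums = lam.to_numpy()[: n * bin_minutes].reshape(n, bin_minutes).sum(axis=1)
    series = pd.Series(sums / sums.max() * 100.0, index=lam.index[::bin_minutes][:n])
    start, end = day_window(protocol, which)
    day = series[(series.index >= start) & (series.index < end)]
    zt = ((day.index - start).total_seconds() / 60.0).astype(int)
    return pd.Series(day.to_numpy(), index=pd.Index(zt, name="zt_min"))


# ---------------------------------------------------------------------------
# population simulation

def simulate_population(cfg: SimConfig, protocol: Protocol,
                        seed: int | None = None
                        ) -> tuple[ActivityMatrix, pd.DataFrame]:
    """Draw a labeled population of per-minute Poisson count series.

    Class sizes are deterministic (rounded from the configured fractions)
    so ground-truth fractions are exact; class membership is shuffled
    across fly indices.  Returns the activity matrix and a per-fly label
    table (class, phase shift, true evening onset, anticipating truth).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    timestamps = pd.date_range(protocol.start, protocol.end,
                               freq="1min", inclusive="left")
    phase = circadian_phase(protocol, timestamps, cfg.freerun_period_min)
    startle = startle_trace(protocol, timestamps, cfg.startle)

    n = cfg.n_flies
    n_flat = int(round(cfg.p_flat * n))
    n_desync = int(round(cfg.p_desync * n))
    n_desync = min(n_desync, n - n_flat)
    classes = (["flat"] * n_flat + ["desynchronized"] * n_desync
               + ["synchronized"] * (n - n_flat - n_desync))
    order = rng.permutation(n)
    classes = [classes[i] for i in order]

    width = max(2, len(str(n)))
    fly_ids = [f"sim:{i + 1:0{width}d}" for i in range(n)]
    counts = np.empty((len(timestamps), n), dtype=np.int64)
    shifts: list[float] = []
    for j, cls in enumerate(classes):
        if cls == "flat":
            shift: float | None = None
        elif cls == "desynchronized":
            shift = float(rng.uniform(0.0, MIN_PER_DAY))
        else:
            shift = cfg.phase_delay_min
        shifts.append(np.nan if shift is None else shift)
        lam = _fly_rate(cfg, phase, startle, shift)
        if cfg.overdispersion > 0:
            k = 1.0 / cfg.overdispersion
            lam = lam * rng.gamma(k, 1.0 / k, size=lam.shape)
        counts[:, j] = rng.poisson(lam)

    frame = pd.DataFrame(counts, index=timestamps, columns=fly_ids)
    valid = pd.Series(True, index=timestamps)
    labels = pd.DataFrame({
        "fly_id": fly_ids,
        "label": classes,
        "shift_min": shifts,
        "evening_onset_zt": [np.nan if np.isnan(s)
                             else float(np.mod(cfg.evening.onset_zt + s,
                                               MIN_PER_DAY))
                             for s in shifts],
        "anticipating_truth": [c == "synchronized" for c in classes],
    })
    return ActivityMatrix(frame, valid), labels


# ---------------------------------------------------------------------------
# presets

_CONTROL = SimConfig()


def preset(name: str) -> SimConfig:
    """Named configurations mirroring the qualitative study phenotypes.

    * ``control_LLTC`` — fully synchronized population, evening ramp
      peaking late in the thermophase (before the ZT720 warm-to-cold
      transition) under constant light.
    * ``cycDN_like`` — half the population clock-disrupted, mostly
      constitutively active around the clock (clock mutants lose the
      siesta and show elevated off-peak activity) plus a small contingent
      with uniformly redrawn ramp phase.  Flat-active flies hold the
      population median up at the evening peak while contributing no
      individual slope, which is what drives the synchronization ratio
      toward one half.
    * ``delayed_EO`` — synchronized but with a 2 h population-wide delay.
    * ``control_DDTC`` — main ramp anticipating the cold-to-warm
      transition, so activity peaks in the first half of the warm phase
      (constant darkness).
    * ``arrhythmic`` — no fly carries an anticipation component.
    """
    presets = {
        "control_LLTC": _CONTROL,
        "cycDN_like": replace(_CONTROL, p_desync=0.05, p_flat=0.45,
                              flat_activity_rate=5.0),
        "delayed_EO": replace(_CONTROL, phase_delay_min=120.0),
        "control_DDTC": replace(
            _CONTROL,
            evening=RampSpec(0.3, 510.0, 690.0),
            # rises before the cold-to-warm transition and persists into
            # the early thermophase, peaking in its first half
            morning=RampSpec(2.0, 1290.0, 90.0, end_zt=360.0)),
        "arrhythmic": replace(_CONTROL, p_flat=1.0),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return presets[name]


def default_protocol(preset_name: str) -> Protocol:
    """The entrainment schedule each preset is meant to run under."""
    name = "DDTC" if "DDTC" in preset_name else "LLTC"
    return standard_protocol(name, days_ld=2, days_constant=3, days_tc=6,
                             shift_h=5.0)
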