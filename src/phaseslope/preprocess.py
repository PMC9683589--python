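"""From raw counts to the analysis substrate.

The slope statistics operate on 30-minute binned activity, normalized per
fly to that fly's own maximum bin (percent of max, 0-100), summarized as
the per-bin median across flies.  Binning sums valid minutes; a bin with
more than half of its minutes invalid is treated as missing.  The
normalization window defaults to the fly's entire binned recording so that
days stay mutually comparable; a per-day window can be passed explicitly.

Bin timestamps refer to the bin start: the value reported at ZT 690 covers
minutes 690-719 of the Zeitgeber day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import re

import numpy as np
import pandas as pd

from .dam_io import ActivityMatrix
from .errors import ProtocolError
from .protocol import MIN_PER_DAY, Protocol

_DAY = pd.Timedelta(days=1)


@dataclass
class NormalizedActivity:
    """Per-fly binned activity as percent of each fly's maximum bin."""

    values: pd.DataFrame          # index: bin-start timestamps; columns: flies
    bin_minutes: int
    excluded: list[str] = field(default_factory=list)   # flies with zero max


@dataclass
class PopulationProfile:
    """Median normalized activity per ZT bin over one analysis day."""

    zt: np.ndarray                # bin-start minutes on the ZT grid
    median: np.ndarray            # percent of max, [0, 100]
    n_flies: np.ndarray           # flies with valid data per bin
    bin_minutes: int
    day_label: str = ""

    def value_at(self, zt_min: float) -> float:
        i = np.nonzero(self.zt == zt_min)[0]
        if i.size == 0:
            raise KeyError(f"no bin starts at ZT {zt_min} min")
        return float(self.median[i[0]])


def bin_counts(matrix: ActivityMatrix, bin_minutes: int = 30,
               max_invalid_frac: float = 0.5) -> pd.DataFrame:
    """Sum valid per-minute counts into fixed-width bins.

    Bins start at the matrix's first timestamp (which analysis-day
    selection aligns to ZT0).  Bins whose invalid-minute fraction exceeds
    ``max_invalid_frac`` are missing (NaN); a trailing partial bin is
    dropped.
    """
    if MIN_PER_DAY % bin_minutes != 0:
        raise ValueError(f"bin width {bin_minutes} must divide {MIN_PER_DAY}")
    step = bin_minutes // matrix.acquisition_interval
    n_rows = len(matrix)
    n_bins = n_rows // step
    if n_bins == 0:
        raise ValueError("recording shorter than one bin")
    vals = matrix.counts.to_numpy(dtype=float)[: n_bins * step]
    valid = matrix.valid.to_numpy()[: n_bins * step]
    vals[~valid] = 0.0
    sums = vals.reshape(n_bins, step, -1).sum(axis=1)
    invalid_frac = 1.0 - valid.reshape(n_bins, step).mean(axis=1)
    sums[invalid_frac > max_invalid_frac] = np.nan
    idx = matrix.timestamps[::step][:n_bins]
    return pd.DataFrame(sums, index=idx, columns=matrix.fly_ids)


def normalize_per_fly(binned: pd.DataFrame,
                      window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
                      bin_minutes: int = 30) -> NormalizedActivity:
    """Express each fly's bins as percent of its maximum bin.

    ``window`` restricts where the maximum is taken (default: the whole
    recording).  Flies whose maximum is zero (or all-missing) cannot be
    normalized; they are dropped and listed in ``excluded``.
    """
    if window is not None:
        lo, hi = window
        ref = binned.loc[(binned.index >= lo) & (binned.index < hi)]
        if ref.empty:
            raise ValueError("normalization window contains no bins")
    else:
        ref = binned
    maxima = ref.max(axis=0, skipna=True)
    dead = maxima.isna() | (maxima <= 0)
    excluded = list(binned.columns[dead])
    kept = binned.loc[:, ~dead.to_numpy()]
    values = kept.div(maxima[~dead], axis=1) * 100.0
    return NormalizedActivity(values, bin_minutes, excluded)


_DAY_RE = re.compile(r"^(TC|DD)_day_(\d+)$")


def day_window(protocol: Protocol, which: str) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Absolute [start, end) of one Zeitgeber analysis day.

    ``which`` is ``last_LD``, ``TC_day_k`` or ``DD_day_k``; TC days count
    full days from the first thermophase onset, and DD days index the
    post-TC constant segment on the subjective grid projected from the TC
    anchor.
    """
    if which == "last_LD":
        seg = protocol.segment("LD")
        n_days = int((seg.end - seg.start) / _DAY)
        start = seg.zt0_anchor + (n_days - 1) * _DAY
    else:
        m = _DAY_RE.match(which)
        if not m:
            raise ProtocolError(
                f"unknown analysis day {which!r}; use last_LD, TC_day_k or DD_day_k"
            )
        kind, k = m.group(1), int(m.group(2))
        if k < 1:
            raise ProtocolError("day index must be >= 1")
        if kind == "TC":
            seg = next((s for s in protocol.segments
                        if s.temperature.mode == "cycle"), None)
            if seg is None:
                raise ProtocolError("protocol has no temperature-cycle segment")
        else:
            seg = next((s for s in protocol.segments if s.label == "free"), None)
            if seg is None:
                raise ProtocolError("protocol has no post-TC constant segment")
        first_zt0 = seg.zt0_anchor
        while first_zt0 < seg.start:
            first_zt0 += _DAY
        start = first_zt0 + (k - 1) * _DAY
        if start + _DAY > seg.end:
            raise ProtocolError(f"{which} exceeds the {seg.label} segment")
    if start < protocol.start or start + _DAY > protocol.end:
        raise ProtocolError(f"{which} is not covered by the protocol")
    return start, start + _DAY


def select_analysis_day(matrix: ActivityMatrix, protocol: Protocol,
                        which: str) -> ActivityMatrix:
    """Rows spanning exactly ZT0 -> ZT0 + 24 h of the requested day."""
    start, end = day_window(protocol, which)
    out = matrix.between(start, end)
    if len(out) == 0:
        raise ProtocolError(f"recording does not cover {which}")
    return out


def day_view(norm: NormalizedActivity, protocol: Protocol,
             which: str) -> pd.DataFrame:
    """One analysis day of normalized activity, indexed by ZT bin-start minutes."""
    start, end = day_window(protocol, which)
    idx = norm.values.index
    sel = norm.values.loc[(idx >= start) & (idx < end)]
    if sel.empty:
        raise ProtocolError(f"no bins fall inside {which}")
    minutes = ((sel.index - start).total_seconds() / 60.0).astype(int)
    out = sel.copy()
    out.index = pd.Index(minutes, name="zt_min")
    return out.sort_index()


def median_profile(day_frame: pd.DataFrame, bin_minutes: int = 30,
                   day_label: str = "") -> PopulationProfile:
    """Per-bin median across flies; bins with no valid fly are dropped."""
    n = day_frame.notna().sum(axis=1).to_numpy()
    keep = n > 0
    med = day_frame.median(axis=1, skipna=True).to_numpy()[keep]
    zt = day_frame.index.to_numpy()[keep]
    return PopulationProfile(zt, med, n[keep], bin_minutes, day_label)


def exclude_dead_flies(matrix: ActivityMatrix,
                       window: tuple[pd.Timestamp, pd.Timestamp] | None = None
                       ) -> tuple[ActivityMatrix, list[str]]:
    """Drop flies with zero total valid counts in the window; report them."""
    m = matrix if window is None else matrix.between(*window)
    totals = m.counts.loc[m.valid.to_numpy()].sum(axis=0)
    dead = list(totals.index[totals <= 0])
    keep = [f for f in matrix.fly_ids if f not in dead]
    out = ActivityMatrix(matrix.counts.loc[:, keep], matrix.valid,
                         matrix.acquisition_interval)
    return out, dead


def normalized_day(matrix: ActivityMatrix, protocol: Protocol, which: str,
                   bin_minutes: int = 30,
                   normalization: str = "recording") -> tuple[pd.DataFrame, NormalizedActivity]:
    """Convenience: bin the whole recording, normalize, slice one ZT day.

    ``normalization`` is ``"recording"`` (default: per-fly max over the
    whole recording) or ``"day"`` (max over the analysis day only).
    """
    binned = bin_counts(matrix, bin_minutes)
    window = day_window(protocol, which) if normalization == "day" else None
    norm = normalize_per_fly(binned, window=window, bin_minutes=bin_minutes)
    return day_view(norm, protocol, which), norm
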