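"""Anticipation slopes, the synchronization ratio, and the classifier.

The central statistic is the slope of the line joining two landmarks of
the population median profile before a Zeitgeber transition:

    slope = (Act_max - Act_ZTmin) / (t_ZTmax - t_ZTmin)

with activity in percent of each fly's maximum and time in minutes.
ZT_min is the *last* bin attaining the window minimum of the median,
ZT_max the *first* bin attaining the maximum after it, and the transition
bin itself is excluded so the startle response never counts as the peak.

Slo_the applies the formula to the median profile, Slo_exp is the median
of the per-fly slopes over the same (shared) landmarks, and the ratio
Slo_exp/Slo_the indexes population synchronization: near 1 when most
individuals track the median, smaller when the population is
desynchronized.  A fly "anticipates" the transition if its own slope
exceeds half of Slo_the; for the downhill variant (activity decline after
a morning peak in constant conditions) the mirror rule applies: steeper
than half the theoretical (negative) slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import LandmarkError
from .preprocess import PopulationProfile, median_profile

Mode = Literal["uphill", "downhill"]


def slope_between(act_first: float, act_second: float,
                  t_first: float, t_second: float) -> float:
    """Slope of the line between two (time, activity) points, per minute."""
    if t_second == t_first:
        raise ValueError("landmarks must be distinct time points")
    return (act_second - act_first) / (t_second - t_first)


@dataclass(frozen=True)
class Landmarks:
    zt_min: int
    zt_max: int
    act_at_min: float
    act_at_max: float
    source: str = "detected"      # or "manual"


def detect_landmarks(profile: PopulationProfile, transition_zt: int,
                     window: tuple[int, int] | None = None) -> Landmarks:
    """Find (ZT_min, ZT_max) of the median profile before a transition.

    The search covers bins with start in [window_start, transition); the
    bin starting at the transition (the startle bin) is never a candidate.
    ZT_min is the last bin attaining the window minimum; ZT_max the first
    bin after ZT_min attaining the maximum of the remaining bins.
    """
    if window is None:
        window = (transition_zt - 360, transition_zt)
    lo, hi = window
    if hi != transition_zt:
        raise ValueError("search window must end at the transition")
    mask = (profile.zt >= lo) & (profile.zt < transition_zt)
    zt = profile.zt[mask]
    med = profile.median[mask]
    if zt.size < 3:
        raise LandmarkError("window holds fewer than 3 bins")
    if np.isclose(med.min(), med.max()):
        raise LandmarkError("no anticipation structure: flat median in window")
    i_min = int(np.flatnonzero(med == med.min())[-1])   # last of tied minima
    if i_min == zt.size - 1:
        raise LandmarkError(
            "minimum falls on the last pre-transition bin; the maximum would "
            "coincide with the transition bin — use a narrower window"
        )
    after = med[i_min + 1:]
    i_max = i_min + 1 + int(np.flatnonzero(after == after.max())[0])  # first max
    return Landmarks(int(zt[i_min]), int(zt[i_max]),
                     float(med[i_min]), float(med[i_max]))


def detect_downhill_landmarks(profile: PopulationProfile,
                              window: tuple[int, int]) -> Landmarks:
    """Mirror rule for a declining phase: first peak bin, then last minimum.

    ``zt_max`` (the morning peak) precedes ``zt_min`` here, so slopes come
    out negative.
    """
    lo, hi = window
    mask = (profile.zt >= lo) & (profile.zt < hi)
    zt = profile.zt[mask]
    med = profile.median[mask]
    if zt.size < 3:
        raise LandmarkError("window holds fewer than 3 bins")
    if np.isclose(med.min(), med.max()):
        raise LandmarkError("no anticipation structure: flat median in window")
    i_max = int(np.flatnonzero(med == med.max())[0])    # first of tied maxima
    if i_max == zt.size - 1:
        raise LandmarkError("peak falls on the last window bin; widen the window")
    after = med[i_max + 1:]
    i_min = i_max + 1 + int(np.flatnonzero(after == after.min())[-1])  # last min
    return Landmarks(int(zt[i_min]), int(zt[i_max]),
                     float(med[i_min]), float(med[i_max]))


def fly_slopes(day_frame: pd.DataFrame, zt_min: int, zt_max: int
               ) -> tuple[pd.Series, list[str]]:
    """Per-fly slope between the shared landmarks.

    Landmarks come from the population profile and are common to all
    flies.  Flies missing a bin at either landmark are excluded and
    listed.  Works for both orientations (zt_max before or after zt_min).
    """
    for zt in (zt_min, zt_max):
        if zt not in day_frame.index:
            raise KeyError(f"no bin starts at ZT {zt} min")
    t1, t2 = sorted((zt_min, zt_max))
    a1 = day_frame.loc[t1]
    a2 = day_frame.loc[t2]
    ok = a1.notna() & a2.notna()
    slopes = (a2[ok] - a1[ok]) / (t2 - t1)
    return slopes.astype(float), list(day_frame.columns[~ok])


def slo_the(profile: PopulationProfile, zt_min: int, zt_max: int) -> float:
    """The slope formula applied to the median profile itself."""
    t1, t2 = sorted((zt_min, zt_max))
    return slope_between(profile.value_at(t1), profile.value_at(t2), t1, t2)


def slo_exp(slopes: Sequence[float] | pd.Series) -> float:
    """Median of the individual fly slopes."""
    arr = np.asarray(slopes, dtype=float)
    if arr.size == 0:
        raise ValueError("no fly slopes")
    return float(np.median(arr))


def sync_ratio(slo_exp_value: float, slo_the_value: float,
               mode: Mode = "uphill") -> float:
    """Slo_exp / Slo_the, the population-synchronization index."""
    if mode == "uphill" and slo_the_value <= 0:
        raise ValueError("theoretical slope non-positive; ratio undefined")
    if mode == "downhill" and slo_the_value >= 0:
        raise ValueError("theoretical slope non-negative; ratio undefined")
    return slo_exp_value / slo_the_value


def classify_anticipation(slopes: pd.Series | Sequence[float],
                          slo_the_value: float,
                          mode: Mode = "uphill") -> tuple[pd.Series, float]:
    """Flag each fly whose slope beats half the theoretical slope.

    Uphill: slope > 0.5 * Slo_the.  Downhill: slope < 0.5 * Slo_the
    (steeper decline).  Returns the per-fly flags and the anticipating
    fraction in percent.
    """
    s = pd.Series(slopes, dtype=float)
    threshold = 0.5 * slo_the_value
    flags = s > threshold if mode == "uphill" else s < threshold
    return flags, float(100.0 * flags.mean())


@dataclass
class SlopeAnalysis:
    """Full result bundle of one slope analysis."""

    mode: Mode
    zt_min: int
    zt_max: int
    act_at_min: float
    act_at_max: float
    landmark_source: str
    fly_slopes: pd.Series
    excluded: list[str]
    slo_the: float
    slo_exp: float
    ratio: float
    anticipating: pd.Series
    fraction_anticipating: float

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "zt_min": self.zt_min,
            "zt_max": self.zt_max,
            "act_at_min": self.act_at_min,
            "act_at_max": self.act_at_max,
            "landmark_source": self.landmark_source,
            "slo_the": self.slo_the,
            "slo_exp": self.slo_exp,
            "ratio": self.ratio,
            "fraction_anticipating": self.fraction_anticipating,
            "n_flies": int(self.fly_slopes.size),
            "excluded": self.excluded,
            "fly_slopes": {k: float(v) for k, v in self.fly_slopes.items()},
            "anticipating": {k: bool(v) for k, v in self.anticipating.items()},
        }


def _assemble(day_frame: pd.DataFrame, lm: Landmarks, mode: Mode) -> SlopeAnalysis:
    slopes, excluded = fly_slopes(day_frame, lm.zt_min, lm.zt_max)
    t1, t2 = sorted((lm.zt_min, lm.zt_max))
    a1 = lm.act_at_min if lm.zt_min == t1 else lm.act_at_max
    a2 = lm.act_at_max if lm.zt_max == t2 else lm.act_at_min
    the = slope_between(a1, a2, t1, t2)
    exp = slo_exp(slopes)
    ratio = sync_ratio(exp, the, mode)
    flags, frac = classify_anticipation(slopes, the, mode)
    return SlopeAnalysis(mode, lm.zt_min, lm.zt_max, lm.act_at_min,
                         lm.act_at_max, lm.source, slopes, excluded,
                         the, exp, ratio, flags, frac)


def evening_analysis(day_frame: pd.DataFrame, transition_zt: int = 720,
                     window: tuple[int, int] | None = None,
                     zt_min: int | None = None, zt_max: int | None = None,
                     bin_minutes: int = 30) -> SlopeAnalysis:
    """Uphill anticipation analysis before a Zeitgeber transition.

    Landmarks are detected on the population median unless both manual
    overrides are given (recorded as such in the result).
    """
    profile = median_profile(day_frame, bin_minutes)
    if zt_min is not None and zt_max is not None:
        lm = Landmarks(zt_min, zt_max, profile.value_at(zt_min),
                       profile.value_at(zt_max), source="manual")
    else:
        lm = detect_landmarks(profile, transition_zt, window)
    return _assemble(day_frame, lm, "uphill")


def downhill_analysis(day_frame: pd.DataFrame, window: tuple[int, int],
                      zt_min: int | None = None, zt_max: int | None = None,
                      bin_minutes: int = 30) -> SlopeAnalysis:
    """Downhill analysis of the activity decline after a (subjective) peak."""
    profile = median_profile(day_frame, bin_minutes)
    if zt_min is not None and zt_max is not None:
        lm = Landmarks(zt_min, zt_max, profile.value_at(zt_min),
                       profile.value_at(zt_max), source="manual")
    else:
        lm = detect_downhill_landmarks(profile, window)
    return _assemble(day_frame, lm, "downhill")


# ---------------------------------------------------------------------------
# group comparison plumbing

@dataclass
class GroupComparison:
    h: float
    p: float
    method: str
    pairwise: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"kruskal_h": self.h, "p_value": self.p,
                "method": self.method, "pairwise": self.pairwise}


def group_compare(groups: Mapping[str, Sequence[float]],
                  n_boot: int = 5000, seed: int = 0,
                  method: Literal["chi2", "permutation"] = "chi2",
                  n_perm: int = 9999) -> GroupComparison:
    """Kruskal-Wallis rank test plus bootstrap mean-difference estimation.

    The H statistic (tie-corrected) uses the chi-squared approximation by
    default; ``method="permutation"`` replaces the p-value by a seeded
    label-permutation test, appropriate for very small groups.  Pairwise
    mean differences carry 95% percentile-bootstrap confidence intervals
    (``n_boot`` seeded resamples).
    """
    names = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in names]
    for k, d in zip(names, data):
        if d.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    h, p = stats.kruskal(*data)
    h = float(h)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(data)
        sizes = [d.size for d in data]
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            hp, _ = stats.kruskal(*parts)
            if hp >= h:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
    rng = np.random.default_rng(seed)
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = data[i], data[j]
            diffs = np.empty(n_boot)
            for k in range(n_boot):
                diffs[k] = (rng.choice(b, b.size).mean()
                            - rng.choice(a, a.size).mean())
            lo, hi = np.percentile(diffs, [2.5, 97.5])
            pairwise.append({
                "a": names[i], "b": names[j],
                "mean_diff": float(b.mean() - a.mean()),
                "ci_low": float(lo), "ci_high": float(hi),
            })
    return GroupComparison(h, float(p), method, pairwise)


def box_summary(values: Sequence[float]) -> dict:
    """Box-plot statistics: quartiles, mean, Tukey 1.5*IQR whiskers.

    The whiskers reach the most extreme observations within 1.5 IQR of
    the quartiles; anything beyond is an outlier.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("empty group")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    in_fence = arr[(arr >= q1 - 1.5 * iqr) & (arr <= q3 + 1.5 * iqr)]
    return {
        "q1": float(q1), "median": float(med), "q3": float(q3),
        "mean": float(arr.mean()),
        "whisker_low": float(in_fence.min()),
        "whisker_high": float(in_fence.max()),
        "outliers": [float(v) for v in arr[(arr < q1 - 1.5 * iqr)
                                           | (arr > q3 + 1.5 * iqr)]],
    }
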