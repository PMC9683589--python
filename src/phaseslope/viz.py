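"""Figure rendering: double-plotted actograms, daily profiles, slope boxes.

viz only draws; every displayed statistic (medians, quartiles, whisker
ends) comes out of :mod:`preprocess` / :mod:`slope_stats`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .preprocess import NormalizedActivity, PopulationProfile  # noqa: E402
from .protocol import Protocol, environment_at  # noqa: E402
from .slope_stats import SlopeAnalysis, box_summary  # noqa: E402

_DAY = pd.Timedelta(days=1)


def _shade_color(light: str, temp: float) -> str:
    # white: lights-on 25C; grey: dark 25C; yellow/blue: thermo/cryophase
    if temp <= 20.0:
        return "#cfe3f5" if light == "ON" else "#9db8d9"
    if light == "OFF":
        return "#d9d9d9"
    return "white"


def _shade_day(ax, protocol: Protocol, day_start: pd.Timestamp,
               x0: float, scale: float = 1.0) -> None:
    """Underlay environmental shading for one 24 h stretch starting x0."""
    step = pd.Timedelta(minutes=30)
    t = day_start
    while t < day_start + _DAY:
        try:
            light, temp = environment_at(t, protocol)
        except Exception:
            t += step
            continue
        x = x0 + (t - day_start).total_seconds() / 3600.0 * scale
        ax.axvspan(x, x + 0.5 * scale, color=_shade_color(light, temp),
                   lw=0, zorder=0)
        t += step


def double_actogram(norm: NormalizedActivity, protocol: Protocol,
                    path: str | Path) -> Path:
    """Double-plotted average actogram: row d shows days d and d+1.

    Bar height is the population mean of per-fly normalized activity per
    bin (profiles use the median; actograms traditionally average).
    """
    start = protocol.start
    n_days = int(np.ceil((norm.values.index[-1] - start) / _DAY))
    if n_days < 2:
        raise ValueError("an actogram needs at least 2 days of data")
    mean = norm.values.mean(axis=1)
    fig, axes = plt.subplots(n_days, 1, figsize=(8, 1.0 * n_days),
                             sharex=True, squeeze=False)
    for d in range(n_days):
        ax = axes[d, 0]
        for half, day in enumerate((d, d + 1)):
            day_start = start + day * _DAY
            if day_start >= protocol.end:
                continue
            _shade_day(ax, protocol, day_start, x0=24.0 * half)
            sel = mean[(mean.index >= day_start) & (mean.index < day_start + _DAY)]
            if len(sel):
                hours = ((sel.index - day_start).total_seconds() / 3600.0
                         + 24.0 * half)
                ax.bar(hours, sel.to_numpy(), width=norm.bin_minutes / 60.0,
                       align="edge", color="black", zorder=2)
        ax.set_xlim(0, 48)
        ax.set_ylim(bottom=0)
        ax.set_yticks([])
        ax.set_ylabel(f"d{d + 1}", rotation=0, ha="right", va="center")
    axes[-1, 0].set_xlabel("time (h, double plotted)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def daily_profile_plot(profile: PopulationProfile, protocol: Protocol,
                       day_start: pd.Timestamp, path: str | Path,
                       analysis: SlopeAnalysis | None = None) -> Path:
    """Median normalized activity over one Zeitgeber day with shading."""
    fig, ax = plt.subplots(figsize=(7, 3))
    _shade_day(ax, protocol, day_start, x0=0.0)
    hours = profile.zt / 60.0
    ax.plot(hours, profile.median, color="black", drawstyle="steps-post")
    if analysis is not None:
        ax.plot(analysis.zt_min / 60.0, analysis.act_at_min, "v",
                color="tab:red", label="ZT_min")
        ax.plot(analysis.zt_max / 60.0, analysis.act_at_max, "^",
                color="tab:blue", label="ZT_max")
        ax.legend(frameon=False)
    ax.set_xlim(0, 24)
    ax.set_ylim(0, 105)
    ax.set_xlabel("ZT (h)")
    ax.set_ylabel("median activity\n(% of max)")
    if profile.day_label:
        ax.set_title(profile.day_label)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def slope_boxplot(groups: Mapping[str, Sequence[float]],
                  path: str | Path) -> Path:
    """Box = quartiles, cross = mean, Tukey whiskers, outliers as dots."""
    stats = []
    for name, values in groups.items():
        s = box_summary(values)
        stats.append({"label": name, "med": s["median"], "q1": s["q1"],
                      "q3": s["q3"], "whislo": s["whisker_low"],
                      "whishi": s["whisker_high"], "mean": s["mean"],
                      "fliers": s["outliers"]})
    fig, ax = plt.subplots(figsize=(1.2 + 1.2 * len(stats), 3.5))
    ax.bxp(stats, showmeans=True,
           meanprops={"marker": "x", "markeredgecolor": "black"})
    ax.set_ylabel("slope (% of max / min)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
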