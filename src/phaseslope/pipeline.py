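"""One-command orchestration: ingest/simulate -> preprocess -> slopes -> figures.

A run is described by a config mapping (usually loaded from YAML):

.. code-block:: yaml

    simulate:               # or: inputs: [monitor1.txt, ...]
      preset: control_LLTC
      seed: 42
    protocol:
      name: LLTC
      days_ld: 2
      days_constant: 3
      days_tc: 6
      shift_h: 5
    analysis:
      day: TC_day_6
      transition_zt: 720
      window_h: 6
    bin_minutes: 30
    outdir: results/run1

Outputs: normalized activity and population-profile CSVs, a slope-analysis
JSON, figures, and ``run.json`` with the echoed config, package version and
a hash of the statistics.  Re-running with the same config and seed
reproduces the statistics byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import dam_io, preprocess, protocol as proto, slope_stats, synthetic, viz
from .errors import ConfigError, PhaseslopeError

log = logging.getLogger("phaseslope")


@dataclasses.dataclass
class RunConfig:
    protocol: dict
    analysis: dict
    outdir: str
    simulate: dict | None = None
    inputs: list[str] | None = None
    bin_minutes: int = 30
    normalization: str = "recording"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"protocol", "analysis", "outdir"} - set(raw)
        if missing:
            raise ConfigError(f"missing config keys: {sorted(missing)}")
        cfg = cls(**raw)
        if (cfg.simulate is None) == (cfg.inputs is None):
            raise ConfigError("exactly one of 'simulate' or 'inputs' is required")
        if "day" not in cfg.analysis:
            raise ConfigError("analysis section needs a 'day'")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PhaseslopeError as exc:
                raise PhaseslopeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("ingest")
def _load_matrix(cfg: RunConfig, protocol: proto.Protocol) -> tuple[dam_io.ActivityMatrix, pd.DataFrame | None]:
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        name = sim.pop("preset", "control_LLTC")
        seed = sim.pop("seed", None)
        base = synthetic.preset(name)
        if sim:
            base = dataclasses.replace(base, **sim)
        matrix, labels = synthetic.simulate_population(base, protocol, seed=seed)
        return matrix, labels
    matrices = [dam_io.read_dam2(p) for p in cfg.inputs or []]
    return dam_io.merge_monitors(matrices), None


def run(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and write the report bundle to ``outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    protocol = proto.from_dict(cfg.protocol)
    matrix, labels = _load_matrix(cfg, protocol)
    matrix, dead = preprocess.exclude_dead_flies(matrix)
    if dead:
        log.info("excluded %d silent flies: %s", len(dead), dead)

    which = cfg.analysis["day"]
    day_frame, norm = preprocess.normalized_day(
        matrix, protocol, which, cfg.bin_minutes, cfg.normalization)
    profile = preprocess.median_profile(day_frame, cfg.bin_minutes, which)

    mode = cfg.analysis.get("mode", "uphill")
    zt_min = cfg.analysis.get("zt_min")
    zt_max = cfg.analysis.get("zt_max")
    if mode == "downhill":
        window = tuple(cfg.analysis.get("window", (0, 720)))
        analysis = slope_stats.downhill_analysis(
            day_frame, window, zt_min=zt_min, zt_max=zt_max,
            bin_minutes=cfg.bin_minutes)
    else:
        transition = int(cfg.analysis.get("transition_zt", 720))
        window_h = cfg.analysis.get("window_h", 6)
        window = (transition - int(window_h * 60), transition)
        analysis = slope_stats.evening_analysis(
            day_frame, transition, window, zt_min=zt_min, zt_max=zt_max,
            bin_minutes=cfg.bin_minutes)

    # ---- report bundle ---------------------------------------------------
    norm.values.to_csv(outdir / "normalized_activity.csv")
    pd.DataFrame({"zt_min": profile.zt, "median": profile.median,
                  "n_flies": profile.n_flies}).to_csv(
        outdir / "population_profile.csv", index=False)
    if labels is not None:
        labels.to_csv(outdir / "labels.csv", index=False)
    stats_json = json.dumps(analysis.to_dict(), indent=2, sort_keys=True)
    (outdir / "slope_analysis.json").write_text(stats_json + "\n")

    day_start, _ = preprocess.day_window(protocol, which)
    viz.daily_profile_plot(profile, protocol, day_start,
                           outdir / "daily_profile.png", analysis)
    viz.double_actogram(norm, protocol, outdir / "actogram.png")
    viz.slope_boxplot({which: analysis.fly_slopes.to_numpy()},
                      outdir / "slope_box.png")

    run_meta = {
        "version": __version__,
        "config": cfg.to_dict(),
        "excluded_dead": dead,
        "excluded_unnormalizable": norm.excluded,
        "stats_sha256": hashlib.sha256(stats_json.encode()).hexdigest(),
    }
    (outdir / "run.json").write_text(
        json.dumps(run_meta, indent=2, sort_keys=True) + "\n")
    return {"analysis": analysis, "profile": profile, "labels": labels,
            "excluded_dead": dead, "outdir": outdir}
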