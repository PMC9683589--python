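"""Reading and writing Trikinetics DAM2 monitor files.

A DAM2 file is tab-separated text with 42 fields per row: reading index,
date (``d mmm yy``, English month abbreviations), time (``HH:MM:SS``), a
status code, six device-metadata fields, and 32 per-channel beam-crossing
counts at one-minute resolution.  One channel holds one fly.

Only status code 1 marks a usable reading.  Rows with any other status, and
minutes missing from the file, are kept on the time grid but flagged
invalid, so downstream binning never has to re-align timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DamFormatError

N_CHANNELS = 32
N_FIELDS = 42
VALID_STATUS = 1
INVALID_STATUS = 0

_MONTHS = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
           "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")
_MONTH_NUM = {m.lower(): i + 1 for i, m in enumerate(_MONTHS)}


@dataclass
class ActivityMatrix:
    """Per-minute activity counts for a set of flies on a uniform time grid.

    Parameters
    ----------
    counts
        Integer DataFrame, rows indexed by a strictly increasing
        ``DatetimeIndex`` with constant spacing, one column per fly.
    valid
        Boolean Series on the same index; ``False`` rows carry no usable
        counts (monitor error or gap in the recording).
    acquisition_interval
        Row spacing in minutes (DAM2 records every minute).
    """

    counts: pd.DataFrame
    valid: pd.Series
    acquisition_interval: int = 1

    def __post_init__(self) -> None:
        idx = self.counts.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValueError("counts must be indexed by timestamps")
        if len(idx) > 1:
            deltas = np.diff(idx.asi8)
            step = self.acquisition_interval * 60_000_000_000
            if not (deltas == step).all():
                raise ValueError(
                    "timestamps must be strictly increasing with "
                    f"{self.acquisition_interval}-minute spacing"
                )
        if not self.valid.index.equals(idx):
            raise ValueError("valid flags must share the counts index")
        vals = self.counts.to_numpy()
        if vals.size and vals.min() < 0:
            raise ValueError("activity counts must be non-negative")

    # -- convenience accessors -------------------------------------------
    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.counts.index

    @property
    def fly_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_flies(self) -> int:
        return self.counts.shape[1]

    def __len__(self) -> int:
        return len(self.counts)

    def between(self, start: pd.Timestamp, end: pd.Timestamp) -> "ActivityMatrix":
        """Rows with ``start <= t < end``."""
        mask = (self.counts.index >= start) & (self.counts.index < end)
        return ActivityMatrix(self.counts.loc[mask], self.valid.loc[mask],
                              self.acquisition_interval)


def _parse_timestamp(date_field: str, time_field: str, row: int, path: str) -> pd.Timestamp:
    toks = date_field.strip().split()
    try:
        day, mon, year = toks
        month = _MONTH_NUM[mon.lower()]
        hh, mm, ss = time_field.strip().split(":")
        return pd.Timestamp(2000 + int(year), month, int(day),
                            int(hh), int(mm), int(ss))
    except (ValueError, KeyError) as exc:
        raise DamFormatError(
            f"{path}: row {row}: unparseable date/time "
            f"{date_field!r} {time_field!r}"
        ) from exc


def read_dam2(path: str | Path, monitor: str | None = None) -> ActivityMatrix:
    """Parse one DAM2 monitor file into an :class:`ActivityMatrix`.

    Rows whose status field differs from 1 are marked invalid; minutes
    missing from the file are inserted as invalid rows so spacing stays
    uniform.  Fly identifiers are ``"<monitor>:<channel>"`` with channels
    numbered 1-32; ``monitor`` defaults to the file stem.
    """
    path = Path(path)
    monitor = monitor if monitor is not None else path.stem
    times: list[pd.Timestamp] = []
    status: list[int] = []
    counts: list[list[int]] = []
    for row, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != N_FIELDS:
            raise DamFormatError(
                f"{path}: row {row}: expected {N_FIELDS} tab-separated "
                f"fields, got {len(fields)}"
            )
        ts = _parse_timestamp(fields[1], fields[2], row, str(path))
        try:
            st = int(fields[3])
            ch = [int(v) for v in fields[10:42]]
        except ValueError as exc:
            raise DamFormatError(
                f"{path}: row {row}: non-integer status or count field"
            ) from exc
        if any(c < 0 for c in ch):
            raise DamFormatError(f"{path}: row {row}: negative count")
        if times and ts <= times[-1]:
            raise DamFormatError(
                f"{path}: row {row}: timestamp {ts} not after previous "
                f"row ({times[-1]})"
            )
        times.append(ts)
        status.append(st)
        counts.append(ch)
    cols = [f"{monitor}:{c:02d}" for c in range(1, N_CHANNELS + 1)]
    if not times:
        idx = pd.DatetimeIndex([])
        frame = pd.DataFrame(np.empty((0, N_CHANNELS), dtype=np.int64),
                             index=idx, columns=cols)
        return ActivityMatrix(frame, pd.Series(np.bool_([]), index=idx))
    idx = pd.DatetimeIndex(times)
    frame = pd.DataFrame(np.asarray(counts, dtype=np.int64), index=idx, columns=cols)
    valid = pd.Series(np.asarray(status) == VALID_STATUS, index=idx)
    # gap-fill to a uniform one-minute grid
    full = pd.date_range(idx[0], idx[-1], freq="1min")
    if len(full) != len(idx):
        frame = frame.reindex(full, fill_value=0)
        valid = valid.reindex(full, fill_value=False)
    # invalid rows carry no usable counts
    frame.loc[~valid.to_numpy(), :] = 0
    return ActivityMatrix(frame, valid)


def write_dam2(matrix: ActivityMatrix, path: str | Path) -> None:
    """Write an :class:`ActivityMatrix` as a 42-field DAM2 dialect file.

    Channels beyond the matrix's flies are zero-padded up to 32; invalid
    rows are written with status 0 and zero counts.  ``read_dam2`` of the
    result reproduces counts, timestamps and validity exactly, and a
    second write is byte-identical.
    """
    if matrix.n_flies > N_CHANNELS:
        raise ValueError(
            f"matrix has {matrix.n_flies} channels; a DAM2 monitor holds "
            f"{N_CHANNELS} — split flies across monitor files"
        )
    lines = []
    vals = matrix.counts.to_numpy()
    valid = matrix.valid.to_numpy()
    for i, ts in enumerate(matrix.timestamps):
        date = f"{ts.day} {_MONTHS[ts.month - 1]} {ts.year % 100:02d}"
        row = vals[i] if valid[i] else np.zeros(matrix.n_flies, dtype=np.int64)
        padded = list(row) + [0] * (N_CHANNELS - matrix.n_flies)
        fields = [str(i + 1), date, f"{ts:%H:%M:%S}",
                  str(VALID_STATUS if valid[i] else INVALID_STATUS),
                  "1", "0", "0", "0", "0", "0"] + [str(v) for v in padded]
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def select_flies(matrix: ActivityMatrix, ids: Sequence[str]) -> ActivityMatrix:
    """Column subset in the order of ``ids`` (which must all exist)."""
    unknown = [i for i in ids if i not in matrix.counts.columns]
    if unknown:
        raise KeyError(f"unknown fly ids: {unknown}")
    return ActivityMatrix(matrix.counts.loc[:, list(ids)], matrix.valid,
                          matrix.acquisition_interval)


def merge_monitors(matrices: Iterable[ActivityMatrix]) -> ActivityMatrix:
    """Merge monitors recorded in parallel by exact timestamp intersection.

    A row of the merged matrix is valid only where every monitor's row was
    valid.  Disjoint recordings are an error rather than a truncation.
    """
    ms = list(matrices)
    if not ms:
        raise ValueError("no matrices to merge")
    if len(ms) == 1:
        return ms[0]
    common = ms[0].timestamps
    for m in ms[1:]:
        common = common.intersection(m.timestamps)
    if len(common) == 0:
        raise DamFormatError("monitors share no timestamps; cannot merge")
    counts = pd.concat([m.counts.loc[common] for m in ms], axis=1)
    if counts.columns.duplicated().any():
        raise DamFormatError("duplicate fly ids across monitors")
    valid = pd.concat([m.valid.loc[common] for m in ms], axis=1).all(axis=1)
    return ActivityMatrix(counts, valid, ms[0].acquisition_interval)


def to_csv(matrix: ActivityMatrix, path: str | Path) -> None:
    """Lossless tabular container: timestamp, validity flag, per-fly counts."""
    out = matrix.counts.copy()
    out.insert(0, "valid", matrix.valid.astype(int))
    out.index.name = "timestamp"
    out.to_csv(path)


def from_csv(path: str | Path) -> ActivityMatrix:
    frame = pd.read_csv(path, index_col="timestamp", parse_dates=True)
    frame.index.name = None
    valid = frame.pop("valid").astype(bool)
    return ActivityMatrix(frame.astype(np.int64), valid)
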