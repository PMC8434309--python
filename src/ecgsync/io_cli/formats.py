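"""Readers/writers for the delimited-text signal and annotation formats.

Signals are two-column CSV files with a ``time,amplitude`` header (seconds,
arbitrary units).  TTL traces use ``time,level`` with level in {0, 1} and
are written sparsely by default: the first sample, every level change and
the last sample, which is lossless on a known tick grid.  Annotations use
``time,kind``.
"""

from __future__ import annotations

import csv
from typing import List, Optional, Tuple

import numpy as np

from ..detector_core import EventSeries, InputError, UniformSignal

__all__ = [
    "FormatError",
    "read_signal",
    "write_signal",
    "read_ttl",
    "write_ttl",
    "read_events",
    "write_events",
]

_TIME_TOLERANCE = 1e-6


class FormatError(InputError):
    """Malformed file content; the message names the offending line."""


def _parse_rows(path: str, expected_header: Tuple[str, str]) -> List[Tuple[float, float]]:
    rows: List[Tuple[float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and not _is_number(row[0]):
                header = tuple(c.strip().lower() for c in row[:2])
                if header != expected_header:
                    raise FormatError(
                        f"{path}:1: expected header {','.join(expected_header)!r}, "
                        f"got {','.join(row)!r}"
                    )
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            try:
                rows.append((float(row[0]), float(row[1])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
    return rows


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_signal(path: str, format: str = "delimited", channel: int = 0) -> UniformSignal:
    """Load a signal from a delimited file or a PhysioNet (WFDB) record.

    Delimited files must have a monotone, uniform time column (tolerance
    1e-6 s).  For WFDB records, ``path`` is the record name (no extension)
    and ``channel`` selects the signal column; the ``wfdb`` package must be
    installed for this path.
    """
    if format == "physionet":
        try:
            import wfdb  # optional dependency
        except ImportError as exc:  # pragma: no cover - depends on env
            raise InputError(
                "reading PhysioNet records requires the optional 'wfdb' package"
            ) from exc
        record = wfdb.rdrecord(path)
        samples = np.asarray(record.p_signal)[:, channel]
        return UniformSignal(0.0, 1.0 / float(record.fs), samples)
    if format != "delimited":
        raise InputError(f"unknown signal format {format!r}")

    rows = _parse_rows(path, ("time", "amplitude"))
    if len(rows) < 2:
        raise FormatError(f"{path}: a signal needs at least 2 samples")
    times = np.array([r[0] for r in rows])
    values = np.array([r[1] for r in rows])
    dt = np.diff(times)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        # +2: one for the header line, one for 0- vs 1-based row numbers
        raise FormatError(
            f"{path}:{int(bad[0]) + 3}: time column is not strictly increasing"
        )
    interval = float(dt[0])
    off = np.flatnonzero(np.abs(dt - interval) > _TIME_TOLERANCE)
    if off.size:
        raise FormatError(
            f"{path}:{int(off[0]) + 3}: non-uniform sampling "
            f"(expected interval {interval:.9g} s)"
        )
    return UniformSignal(float(times[0]), interval, values)


def write_signal(path: str, sig: UniformSignal, fmt: str = "%.9g") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "amplitude"])
        for t, v in zip(sig.times(), sig.samples):
            writer.writerow([fmt % t, fmt % v])


def write_ttl(path: str, ttl: UniformSignal, sparse: bool = True, fmt: str = "%.9g") -> None:
    """Write a TTL trace as ``time,level`` rows.

    Sparse output keeps the first sample, every level change and the last
    sample; dense output keeps every tick.
    """
    if not ttl.is_ttl():
        raise InputError("signal does not hold TTL logic levels")
    levels = ttl.samples.astype(int)
    times = ttl.times()
    if sparse:
        keep = np.zeros(len(ttl), dtype=bool)
        keep[0] = keep[-1] = True
        keep[1:] |= levels[1:] != levels[:-1]
        idx = np.flatnonzero(keep)
    else:
        idx = np.arange(len(ttl))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "level"])
        for k in idx:
            writer.writerow([fmt % times[k], levels[k]])


def read_ttl(path: str, tick: Optional[float] = None) -> UniformSignal:
    """Load a TTL trace, reconstructing the dense grid from sparse files.

    Dense files are used as-is; sparse files need ``tick`` to rebuild the
    grid (levels are held constant between recorded changes).
    """
    rows = _parse_rows(path, ("time", "level"))
    if len(rows) < 2:
        raise FormatError(f"{path}: a TTL trace needs at least 2 rows")
    times = np.array([r[0] for r in rows])
    levels = np.array([r[1] for r in rows])
    if not np.isin(levels, (0.0, 1.0)).all():
        raise FormatError(f"{path}: TTL levels must be 0 or 1")
    if np.any(np.diff(times) <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    dt = np.diff(times)
    if np.all(np.abs(dt - dt[0]) <= _TIME_TOLERANCE):
        return UniformSignal(float(times[0]), float(dt[0]), levels)
    if tick is None:
        raise InputError("sparse TTL file: pass the tick to rebuild the grid")
    n = int(round((times[-1] - times[0]) / tick)) + 1
    grid = times[0] + np.arange(n) * tick
    idx = np.minimum(np.searchsorted(times, grid + 0.5 * tick) - 1, len(times) - 1)
    idx = np.maximum(idx, 0)
    return UniformSignal(float(times[0]), tick, levels[idx])


def write_events(path: str, series: EventSeries, fmt: str = "%.9g") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "kind"])
        for t in series.times:
            writer.writerow([fmt % t, series.kind])


def read_events(path: str, kind: Optional[str] = None) -> EventSeries:
    """Load an annotation file, optionally filtering to one event kind."""
    times: List[float] = []
    kinds: List[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and not _is_number(row[0]):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            try:
                times.append(float(row[0]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric time ({exc})") from exc
            kinds.append(row[1].strip())
    if kind is not None:
        times = [t for t, k in zip(times, kinds) if k == kind]
        out_kind = kind
    else:
        out_kind = kinds[0] if kinds else "event"
    return EventSeries(out_kind, np.asarray(times))
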