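"""Readers and writers for the two external data dialects.

Two plain-text formats are supported:

* **Voltage trace files** — a self-describing columnar format with a ``# key: value``
  header block (sampling rate plus recording metadata) followed by one membrane-potential
  sample (mV) per line.  Time is implicit from the sampling rate.
* **TriKinetics-style monitor files** — the classic 42-column Drosophila Activity
  Monitor (DAM) layout: record index, date, time, a status column, five extra columns,
  a light-status column, then 32 per-fly beam-crossing counts, tab-delimited, one row
  per minute.

Both parsers are strict: any deviation from the dialect (wrong column count,
non-integer counts, NaN voltages, non-monotonic timestamps) is surfaced as an error
naming the offending line, never silently repaired.  Gaps in monitor timestamps are
reported via a warning but the rows are returned in file order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

VALID_WAVELENGTHS = (365, 405, 450, 635)

DAM_N_CHANNELS = 32
DAM_N_COLUMNS = 42  # index, date, time, status, 5 extras, light, 32 counts
_DAM_LIGHT_COL = 9
_DAM_FIRST_COUNT_COL = 10
_DAM_DATE_FMT = "%d %b %y"
_DAM_TIME_FMT = "%H:%M:%S"


class ParseError(ValueError):
    """A file deviates from its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (e.g. non-monotonic timestamps)."""


# ---------------------------------------------------------------------------
# voltage trace files
# ---------------------------------------------------------------------------

@dataclass
class TraceMeta:
    """Per-recording metadata carried in the trace-file header.

    ``wavelength_nm`` and ``intensity_uw_cm2`` describe the light stimulus
    (365/405/450/635 nm at 200 uW/cm2 in the standard protocol); ``zt_hour`` is the
    zeitgeber time of the recording.  Any field may be absent (``None``).
    """

    genotype: str | None = None
    wavelength_nm: int | None = None
    intensity_uw_cm2: float | None = None
    zt_hour: float | None = None
    cell_id: str | None = None
    sweep: int | None = None

    def __post_init__(self) -> None:
        if self.wavelength_nm is not None and self.wavelength_nm not in VALID_WAVELENGTHS:
            raise ValidationError(
                f"wavelength {self.wavelength_nm} nm not one of {VALID_WAVELENGTHS}"
            )
        if self.sweep is not None and self.sweep < 1:
            raise ValidationError(f"sweep index must be >= 1, got {self.sweep}")


@dataclass
class TraceFile:
    """A uniformly sampled membrane-potential sweep.

    Attributes
    ----------
    sampling_rate : float
        Samples per second (> 0).
    voltage : ndarray
        Membrane potential in mV; must be finite.
    meta : TraceMeta
        Recording metadata.
    """

    sampling_rate: float
    voltage: np.ndarray
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        self.voltage = np.asarray(self.voltage, dtype=float)
        if not np.all(np.isfinite(self.voltage)):
            bad = np.flatnonzero(~np.isfinite(self.voltage))
            raise ValidationError(f"non-finite voltage at sample indices {bad[:10].tolist()}")

    @property
    def duration(self) -> float:
        """Sweep duration in seconds."""
        return self.voltage.size / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds, implicit from the sampling rate."""
        return np.arange(self.voltage.size) / self.sampling_rate


_META_FIELDS = {
    "genotype": str,
    "wavelength_nm": int,
    "intensity_uw_cm2": float,
    "zt_hour": float,
    "cell_id": str,
    "sweep": int,
}


def write_trace_file(trace: TraceFile, path: str | Path) -> None:
    """Write ``trace`` in the self-describing columnar text dialect.

    Voltages are written with ``repr`` precision so a read/write cycle is lossless.
    """
    path = Path(path)
    lines = ["# lnvlight-trace v1", f"# sampling_rate_hz: {trace.sampling_rate!r}"]
    for name in _META_FIELDS:
        value = getattr(trace.meta, name)
        if value is not None:
            lines.append(f"# {name}: {value}")
    lines.append(f"# n_samples: {trace.voltage.size}")
    body = "\n".join(repr(float(v)) for v in trace.voltage)
    path.write_text("\n".join(lines) + "\n" + body + ("\n" if trace.voltage.size else ""))


def read_trace_file(path: str | Path) -> TraceFile:
    """Read a voltage trace file written by :func:`write_trace_file`.

    Raises
    ------
    ParseError
        If the header lacks ``sampling_rate_hz`` or a voltage line is not a number.
    ValidationError
        If any voltage sample is NaN/inf (indices listed) or the sample count is
        inconsistent with the declared length by more than one sample.
    """
    path = Path(path)
    header: dict[str, str] = {}
    samples: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    header[key.strip()] = val.strip()
                continue
            try:
                samples.append(float(line))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: not a voltage sample: {line!r}") from exc
    if "sampling_rate_hz" not in header:
        raise ParseError(f"{path}: header missing sampling_rate_hz")
    meta_kwargs = {}
    for name, conv in _META_FIELDS.items():
        if name in header:
            meta_kwargs[name] = conv(header[name])
    if "wavelength_nm" not in meta_kwargs:
        logger.warning("%s: header lacks wavelength_nm; marked absent", path)
    voltage = np.array(samples, dtype=float)
    if "n_samples" in header:
        declared = int(header["n_samples"])
        if abs(voltage.size - declared) > 1:
            raise ValidationError(
                f"{path}: {voltage.size} samples but header declares {declared}"
            )
    return TraceFile(
        sampling_rate=float(header["sampling_rate_hz"]),
        voltage=voltage,
        meta=TraceMeta(**meta_kwargs),
    )


# ---------------------------------------------------------------------------
# TriKinetics-style monitor files
# ---------------------------------------------------------------------------

@dataclass
class DamRecord:
    """One Drosophila Activity Monitor's worth of 1-min beam-crossing counts.

    Attributes
    ----------
    monitor_id : int
        Monitor identifier (the record-index column restarts at 1 per file).
    times : ndarray of datetime64[m]
        Local-clock timestamp of each row; strictly increasing.
    counts : ndarray, shape (n_minutes, 32)
        Non-negative integer crossings per fly channel.
    light : ndarray, shape (n_minutes,)
        Light-status column (0 dark / 1 lights or pulse on).
    zt0_hour : float
        Local hour corresponding to ZT0 (lights-on of the entraining 12:12 LD
        cycle).  Analysis is done on the ZT clock; the file itself stores local time.
    """

    monitor_id: int
    times: np.ndarray
    counts: np.ndarray
    light: np.ndarray
    zt0_hour: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[m]")
        self.counts = np.asarray(self.counts, dtype=int)
        self.light = np.asarray(self.light, dtype=int)
        n = self.times.size
        if self.counts.shape != (n, DAM_N_CHANNELS):
            raise ValidationError(
                f"counts shape {self.counts.shape} != ({n}, {DAM_N_CHANNELS})"
            )
        if self.light.shape != (n,):
            raise ValidationError("light column length mismatch")
        if np.any(self.counts < 0):
            raise ValidationError("negative beam-crossing counts")
        if n > 1 and np.any(np.diff(self.times) <= np.timedelta64(0, "m")):
            raise ValidationError("timestamps not strictly increasing")

    @property
    def n_minutes(self) -> int:
        return self.times.size

    def zt_minutes(self) -> np.ndarray:
        """Minutes since the most recent ZT0 preceding the first row, per row.

        The value keeps growing past 1440 on subsequent days so that day/night
        boundaries can be recovered by ``// 1440`` and ``% 1440``.
        """
        start = self.times[0].astype(datetime)
        offset = ((start.hour + start.minute / 60.0 - self.zt0_hour) % 24.0) * 60.0
        rel = (self.times - self.times[0]) / np.timedelta64(1, "m")
        return np.round(offset + rel).astype(int)

    def __eq__(self, other: object) -> bool:  # arrays need explicit comparison
        if not isinstance(other, DamRecord):
            return NotImplemented
        return (
            self.monitor_id == other.monitor_id
            and self.zt0_hour == other.zt0_hour
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.light, other.light)
        )


def write_dam_file(record: DamRecord, path: str | Path) -> None:
    """Write ``record`` as a classic 42-column tab-delimited monitor file.

    The output is bit-stable: two writes of the same record are byte-identical.
    An empty record produces a header-free empty file.
    """
    path = Path(path)
    rows = []
    for i in range(record.n_minutes):
        ts = record.times[i].astype(datetime)
        cols = [
            str(i + 1),
            ts.strftime(_DAM_DATE_FMT).lstrip("0"),
            ts.strftime(_DAM_TIME_FMT),
            "1",  # monitor status
            "0", "0", "0", "0", "0",
            str(int(record.light[i])),
        ]
        cols.extend(str(int(c)) for c in record.counts[i])
        rows.append("\t".join(cols))
    path.write_text("\n".join(rows) + ("\n" if rows else ""))


def read_dam_file(path: str | Path, monitor_id: int = 1, zt0_hour: float = 0.0) -> DamRecord:
    """Read a 42-column TriKinetics-style monitor file.

    Parameters
    ----------
    monitor_id, zt0_hour
        Sidecar metadata not representable in the dialect itself; ``zt0_hour`` is the
        local hour of lights-on used to place rows on the ZT clock.

    Raises
    ------
    ParseError
        Wrong column count or a non-integer count, naming the line number.
    ValidationError
        Non-monotonic timestamps.

    Gaps (spacing > 1 min) are reported with :func:`warnings.warn` and left as-is.
    """
    path = Path(path)
    times: list[np.datetime64] = []
    light: list[int] = []
    counts: list[list[int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != DAM_N_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected {DAM_N_COLUMNS} columns, got {len(cols)}"
                )
            try:
                ts = datetime.strptime(f"{cols[1]} {cols[2]}", f"{_DAM_DATE_FMT} {_DAM_TIME_FMT}")
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad timestamp {cols[1]!r} {cols[2]!r}") from exc
            try:
                row = [int(c) for c in cols[_DAM_FIRST_COUNT_COL:]]
                light_val = int(cols[_DAM_LIGHT_COL])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer count") from exc
            if any(c < 0 for c in row):
                raise ParseError(f"{path}:{lineno}: negative count")
            times.append(np.datetime64(ts, "m"))
            light.append(light_val)
            counts.append(row)
    times_arr = np.array(times, dtype="datetime64[m]")
    if times_arr.size > 1:
        diffs = np.diff(times_arr) / np.timedelta64(1, "m")
        if np.any(diffs <= 0):
            raise ValidationError(f"{path}: timestamps not strictly increasing")
        gaps = np.flatnonzero(diffs > 1)
        if gaps.size:
            warnings.warn(
                f"{path}: {gaps.size} timestamp gap(s) (first after row {gaps[0] + 1}); "
                "rows returned in file order, gaps not filled",
                stacklevel=2,
            )
    return DamRecord(
        monitor_id=monitor_id,
        times=times_arr,
        counts=np.array(counts, dtype=int).reshape(-1, DAM_N_CHANNELS),
        light=np.array(light, dtype=int),
        zt0_hour=zt0_hour,
    )


__all__ = [
    "DAM_N_CHANNELS",
    "DamRecord",
    "ParseError",
    "TraceFile",
    "TraceMeta",
    "VALID_WAVELENGTHS",
    "ValidationError",
    "read_dam_file",
    "read_trace_file",
    "write_dam_file",
    "write_trace_file",
]
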