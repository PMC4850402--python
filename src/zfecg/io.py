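"""Reading and writing sampled ECG traces and analysis reports.

The canonical on-disk trace format is delimited text: optional ``# key=value``
header comments (``# fs_hz=...`` carries the sampling rate, ``# meta=...`` a
JSON annotation block), then a header row ``time_s,<channel>,...`` and one row
per sample.  Times are seconds, voltages millivolts.  Readers never resample
or rescale; vendor formats can be plugged in through :func:`register_reader`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "TraceParseError",
    "read_trace",
    "write_trace",
    "write_report",
    "register_reader",
]


class TraceParseError(ValueError):
    """Raised when a trace file cannot be parsed into a valid :class:`Trace`."""


@dataclass
class Trace:
    """A multi-channel sampled voltage recording.

    Parameters
    ----------
    data:
        Array of shape ``(n_samples, n_channels)`` in millivolts.
    channel_names:
        One unique name per channel (e.g. ``["probe1", "probe2"]``).
    fs_hz:
        Sampling rate in Hz.
    t0:
        Time of the first sample in seconds (default 0).
    meta:
        Free-form annotations (subject id, probe labels, filter history, ...).
    """

    data: np.ndarray
    channel_names: list[str]
    fs_hz: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("trace data must be 2-D (n_samples, n_channels)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[1]} data columns but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trace contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs_hz

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel as a 1-D array (a view, not a copy)."""
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise KeyError(
                    f"no channel {name_or_index!r}; have {self.channel_names}"
                ) from None
        else:
            idx = int(name_or_index)
        return self.data[:, idx]

    def with_data(self, data: np.ndarray, **meta_updates) -> "Trace":
        """Copy of this trace with replaced samples and updated metadata."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Trace(
            data=data,
            channel_names=list(self.channel_names),
            fs_hz=self.fs_hz,
            t0=self.t0,
            meta=meta,
        )


# --------------------------------------------------------------------------
# readers

_READERS: dict[str, Callable[[Path], Trace]] = {}


def register_reader(fmt: str, reader: Callable[[Path], Trace]) -> None:
    """Register an adapter so ``read_trace(path, format=fmt)`` dispatches to it.

    Adapters must honour the :class:`Trace` contract (no silent resampling or
    rescaling).  This is the hook for vendor/biosignal formats.
    """
    _READERS[fmt] = reader


def _parse_header_comments(path: Path) -> dict:
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                out[key.strip()] = val.strip()
    return out


def _infer_fs(time_s: np.ndarray, path: Path) -> float:
    dt = np.diff(time_s)
    if dt.size == 0:
        raise TraceParseError(
            f"{path}: cannot infer sampling rate from a single sample; "
            "add a '# fs_hz=' header"
        )
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
        raise TraceParseError(
            f"{path}: time column is not uniformly sampled; "
            "add a '# fs_hz=' header"
        )
    return 1.0 / float(np.median(dt))


def _read_csv(path: Path) -> Trace:
    header = _parse_header_comments(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise TraceParseError(f"{path}: malformed delimited text: {exc}") from exc
    if df.shape[1] < 2:
        raise TraceParseError(
            f"{path}: need a time column plus at least one channel column"
        )
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header row, one for 1-based numbering.  Comment
            # lines above the header shift this further; report both counts.
            row = int(bad.idxmax())
            n_comments = len(header)
            raise TraceParseError(
                f"{path}: non-numeric value {df[col][row]!r} in column "
                f"{col!r} at data row {row + 1} "
                f"(file line ~{row + 2 + n_comments})"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise TraceParseError(
                f"{path}: missing value in column {col!r} at data row {row + 1}"
            )
        df[col] = coerced

    time_col = df.columns[0]
    time_s = df[time_col].to_numpy(dtype=float)
    if "fs_hz" in header:
        fs = float(header["fs_hz"])
    else:
        fs = _infer_fs(time_s, path)
    t0 = float(header.get("t0", time_s[0] if time_s.size else 0.0))
    meta = {}
    if "meta" in header:
        try:
            meta = json.loads(header["meta"])
        except json.JSONDecodeError:
            meta = {"raw": header["meta"]}
    names = [str(c) for c in df.columns[1:]]
    return Trace(
        data=df[df.columns[1:]].to_numpy(dtype=float),
        channel_names=names,
        fs_hz=fs,
        t0=t0,
        meta=meta,
    )


def read_trace(path: str | Path, format: str = "auto") -> Trace:
    """Read a recording from disk.

    ``format`` is ``"csv"``, ``"auto"`` (dispatch on extension, falling back
    to csv), or any name previously passed to :func:`register_reader`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    if format == "auto":
        ext = path.suffix.lower().lstrip(".")
        format = ext if ext in _READERS else "csv"
    if format == "csv":
        return _read_csv(path)
    if format in _READERS:
        return _READERS[format](path)
    raise ValueError(
        f"unknown trace format {format!r}; known: csv, "
        + ", ".join(sorted(_READERS))
    )


# --------------------------------------------------------------------------
# writers


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write ``trace`` as delimited text with header comments.

    Layout: ``# fs_hz=...`` / ``# t0=...`` / ``# meta=<json>`` comments, then
    ``time_s,<ch>,...`` and one row per sample with a locale-independent
    decimal point.  Round-trips through :func:`read_trace` at the stored
    precision (%.10g).
    """
    if trace.n_channels == 0:
        raise ValueError("refusing to write a zero-channel trace")
    path = Path(path)
    t = trace.time()
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# fs_hz={trace.fs_hz:.10g}\n")
        fh.write(f"# t0={trace.t0:.10g}\n")
        if trace.meta:
            fh.write(f"# meta={json.dumps(trace.meta, sort_keys=True)}\n")
        fh.write("time_s," + ",".join(trace.channel_names) + "\n")
        cols = np.column_stack([t, trace.data])
        for row in cols:
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def report_to_dict(report) -> dict:
    """Flatten a report dataclass to JSON-ready primitives (absent -> null)."""
    if dataclasses.is_dataclass(report) and not isinstance(report, type):
        d = dataclasses.asdict(report)
    elif isinstance(report, dict):
        d = dict(report)
    else:
        raise TypeError(f"cannot serialize report of type {type(report)!r}")
    return _jsonable(d)


def write_report(report, path: str | Path, format: str = "json") -> None:
    """Serialize an interval / rhythm / vector report.

    JSON keeps the full nested structure; CSV is a flat single-row export
    (nested lists are JSON-encoded in their cell).  Absent measurements are
    written as null (JSON) or empty (CSV), never as 0.
    """
    d = report_to_dict(report)
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "csv":
        flat = {
            k: (json.dumps(v) if isinstance(v, (list, dict)) else v)
            for k, v in d.items()
        }
        pd.DataFrame([flat]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r} (json or csv)")


def read_report(path: str | Path) -> dict:
    """Load a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return json.load(fh)
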