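"""Reading, writing and regridding of 3-axis accelerometer traces.

Traces arrive as delimited text with columns ``t, x, y, z`` (comma or tab,
optional header). Internally everything is stored in m/s²; values recorded
in units of g are converted on load. Counters operate on uniformly sampled
signals, so irregular recordings are linearly interpolated onto a fixed-rate
grid.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BoundsError, MalformedTraceError, ParameterError

__all__ = [
    "G_STANDARD",
    "AccelTrace",
    "UniformTrace",
    "read_trace",
    "write_trace",
    "resample_uniform",
    "trim",
]

#: Standard gravity, m/s² per g.
G_STANDARD = 9.80665

log = logging.getLogger(__name__)

# relative slack when matching floating-point grid times
_GRID_EPS = 1e-9


@dataclasses.dataclass(frozen=True)
class AccelTrace:
    """Raw timestamped 3-axis acceleration, stored in m/s².

    Parameters
    ----------
    t
        Sample times in seconds, strictly increasing.
    x, y, z
        Per-axis acceleration in m/s², same length as ``t``.
    unit_declared
        Unit the source file declared (``"m/s2"`` or ``"g"``); values are
        always converted to m/s² before construction.
    source_id
        Opaque label for provenance (usually the file path).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    unit_declared: str = "m/s2"
    source_id: str = ""

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise MalformedTraceError("t, x, y, z must have equal length")
        if n < 2:
            raise MalformedTraceError("a trace needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise MalformedTraceError("timestamps must strictly increase")

    def __len__(self) -> int:
        return len(self.t)


@dataclasses.dataclass(frozen=True)
class UniformTrace:
    """3-axis acceleration on a uniform time grid ``t0 + k/fs``."""

    fs: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        for name in ("x", "y", "z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.x)
        if not (len(self.y) == len(self.z) == n):
            raise MalformedTraceError("channels must have equal length")
        if n < 2:
            raise MalformedTraceError("a trace needs at least 2 samples")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        """Time spanned by the grid, ``(n - 1) / fs`` seconds."""
        return (len(self) - 1) / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    def as_matrix(self) -> np.ndarray:
        """Samples as an ``(n, 3)`` array, columns x, y, z."""
        return np.column_stack([self.x, self.y, self.z])


def read_trace(path: str | Path, unit: str = "m/s2", time_unit: str = "s") -> AccelTrace:
    """Read a delimited-text trace with columns t, x, y, z.

    The delimiter (comma or tab) and an optional header row are auto-detected.
    Rows containing non-finite values are dropped with a warning; duplicate
    timestamps keep the first occurrence. ``unit="g"`` multiplies accelerations
    by 9.80665 so internal storage is always m/s²; ``time_unit="ms"`` divides
    timestamps by 1000.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    MalformedTraceError
        If fewer than 2 valid rows remain.
    """
    path = Path(path)
    if unit not in ("m/s2", "g"):
        raise ParameterError(f"unit must be 'm/s2' or 'g', got {unit!r}")
    if time_unit not in ("s", "ms"):
        raise ParameterError(f"time_unit must be 's' or 'ms', got {time_unit!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    raw = pd.read_csv(path, sep=None, engine="python", header=None,
                      comment="#", dtype=str, skip_blank_lines=True)
    if raw.shape[1] < 4:
        raise MalformedTraceError(f"{path}: expected ≥ 4 columns, found {raw.shape[1]}")
    num = raw.iloc[:, :4].apply(pd.to_numeric, errors="coerce")
    # header row: first row fails numeric coercion
    if num.iloc[0].isna().any():
        num = num.iloc[1:]
    values = num.to_numpy(dtype=float)
    finite = np.isfinite(values).all(axis=1)
    n_bad = int((~finite).sum())
    if n_bad:
        log.warning("%s: dropped %d row(s) with non-finite values", path, n_bad)
    values = values[finite]

    # keep-first rule for duplicated timestamps
    if len(values):
        dup = pd.Series(values[:, 0]).duplicated().to_numpy()
        if dup.any():
            log.warning("%s: dropped %d duplicate timestamp(s), keeping first",
                        path, int(dup.sum()))
            values = values[~dup]

    if len(values) < 2:
        raise MalformedTraceError(f"{path}: fewer than 2 valid samples")

    t = values[:, 0] / (1000.0 if time_unit == "ms" else 1.0)
    scale = G_STANDARD if unit == "g" else 1.0
    return AccelTrace(t=t, x=values[:, 1] * scale, y=values[:, 2] * scale,
                      z=values[:, 3] * scale, unit_declared=unit, source_id=str(path))


def write_trace(trace: AccelTrace | UniformTrace, path: str | Path) -> None:
    """Write a trace as a comma-delimited file with a header and 6-decimal values."""
    path = Path(path)
    if isinstance(trace, UniformTrace):
        t = trace.times()
    else:
        t = trace.t
    df = pd.DataFrame({"t": t, "x": trace.x, "y": trace.y, "z": trace.z})
    df.to_csv(path, index=False, float_format="%.6f")


def resample_uniform(trace: AccelTrace, fs: float = 50.0) -> UniformTrace:
    """Linearly interpolate a trace onto the grid ``t0 + k/fs``.

    The grid covers ``k = 0 .. floor((t_end - t0)·fs)``; no extrapolation
    beyond the recorded interval.
    """
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    t0, t_end = trace.t[0], trace.t[-1]
    n = int(math.floor((t_end - t0) * fs + _GRID_EPS)) + 1
    if n < 2:
        raise ParameterError(
            f"trace spans {t_end - t0:.6g} s, too short to resample at {fs} Hz")
    grid = t0 + np.arange(n) / fs
    return UniformTrace(
        fs=fs,
        x=np.interp(grid, trace.t, trace.x),
        y=np.interp(grid, trace.t, trace.y),
        z=np.interp(grid, trace.t, trace.z),
        t0=t0,
    )


def trim(trace: UniformTrace, t_start: float, t_end: float) -> UniformTrace:
    """Keep samples with time in the closed interval [t_start, t_end].

    The sampling rate is unchanged; this mirrors the manual trimming of the
    beginning and end of a recording session.
    """
    if not t_start < t_end:
        raise BoundsError(f"need t_start < t_end, got [{t_start}, {t_end}]")
    end = trace.t0 + trace.duration_s
    if t_start < trace.t0 - _GRID_EPS or t_end > end + _GRID_EPS:
        raise BoundsError(
            f"[{t_start}, {t_end}] outside trace span [{trace.t0}, {end}]")
    k0 = int(math.ceil((t_start - trace.t0) * trace.fs - _GRID_EPS))
    k1 = int(math.floor((t_end - trace.t0) * trace.fs + _GRID_EPS))
    if k1 - k0 + 1 < 2:
        raise BoundsError(f"trim [{t_start}, {t_end}] keeps fewer than 2 samples")
    sl = slice(k0, k1 + 1)
    return UniformTrace(fs=trace.fs, x=trace.x[sl], y=trace.y[sl], z=trace.z[sl],
                        t0=trace.t0 + k0 / trace.fs)
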