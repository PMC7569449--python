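"""Signed-magnitude preprocessing.

The counters consume a single scalar signal per session. Taking the plain
Euclidean norm of the 3-axis acceleration would half-wave-rectify the
motion: every excursion, whether along or against gravity, would come out
positive. To avoid that, the norm is multiplied by a sign derived from the
orientation of the dynamic component relative to a slowly varying gravity
baseline (a long-window centered moving average of each axis): positive when
the motion points with gravity, negative when it points against it.

Two modes are provided. ``dynamic`` (default) signs the gravity-removed
dynamic component ``a - g``; ``raw`` signs the full vector norm ``|a|``,
which stays almost always positive because gravity dominates, and is kept
only for fidelity to the literal signed-magnitude description.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import ParameterError
from .signal_io import UniformTrace

__all__ = [
    "GravityEstimate",
    "SignedMagnitudeSeries",
    "PreprocessConfig",
    "compute_magnitude",
    "estimate_gravity",
    "signed_magnitude",
    "preprocess_trace",
]


@dataclasses.dataclass(frozen=True)
class GravityEstimate:
    """Per-sample gravity baseline from a long-window moving average."""

    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    window_s: float

    def as_matrix(self) -> np.ndarray:
        return np.column_stack([self.gx, self.gy, self.gz])


@dataclasses.dataclass(frozen=True)
class SignedMagnitudeSeries:
    """Uniformly sampled signed scalar acceleration, m/s²."""

    fs: float
    s: np.ndarray
    mode: str = "dynamic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "s", np.asarray(self.s, dtype=float))
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if len(self.s) < 2:
            raise ParameterError("series needs at least 2 samples")
        if not np.all(np.isfinite(self.s)):
            raise ParameterError("series contains non-finite values")

    def __len__(self) -> int:
        return len(self.s)

    @property
    def duration_s(self) -> float:
        return (len(self) - 1) / self.fs


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing knobs.

    gravity_window_s
        Length of the gravity moving-average window in seconds. Default 2.0:
        long against any plausible repetition half-cycle, short enough to
        track slow orientation drift.
    sign_mode
        ``dynamic`` or ``raw``; see module docstring.
    """

    gravity_window_s: float = 2.0
    sign_mode: str = "dynamic"

    def __post_init__(self) -> None:
        if self.gravity_window_s <= 0:
            raise ParameterError("gravity_window_s must be positive")
        if self.sign_mode not in ("dynamic", "raw"):
            raise ParameterError(f"unknown sign_mode {self.sign_mode!r}")


def compute_magnitude(trace: UniformTrace) -> np.ndarray:
    """Per-sample Euclidean norm of the acceleration vector, m/s²."""
    return np.sqrt(trace.x ** 2 + trace.y ** 2 + trace.z ** 2)


def estimate_gravity(trace: UniformTrace, window_s: float = 2.0) -> GravityEstimate:
    """Centered moving average of each axis over ``round(window_s·fs)`` samples.

    The window is truncated at the edges so every output sample averages only
    available data (no padding, no phase lag).
    """
    if window_s <= 0:
        raise ParameterError(f"window_s must be positive, got {window_s}")
    w = int(round(window_s * trace.fs))
    if w < 1:
        raise ParameterError(
            f"window_s·fs = {window_s * trace.fs:.3g} < 1 sample")

    def roll(a: np.ndarray) -> np.ndarray:
        return (pd.Series(a)
                .rolling(window=w, center=True, min_periods=1)
                .mean()
                .to_numpy())

    return GravityEstimate(gx=roll(trace.x), gy=roll(trace.y), gz=roll(trace.z),
                           window_s=window_s)


def signed_magnitude(trace: UniformTrace, gravity: GravityEstimate,
                     mode: str = "dynamic") -> SignedMagnitudeSeries:
    """Signed scalar magnitude relative to the gravity baseline.

    With dynamic component ``d = a - g`` and unit gravity direction ``ĝ``,
    the sign is +1 when ``d·ĝ ≥ 0`` and −1 otherwise (sgn(0) = +1 by
    convention; samples with a zero gravity vector fall back to +1). The
    magnitude is ``|d|`` in ``dynamic`` mode or ``|a|`` in ``raw`` mode, so
    sign restoration never changes absolute values.
    """
    if mode not in ("dynamic", "raw"):
        raise ParameterError(f"unknown mode {mode!r}")
    a = trace.as_matrix()
    g = gravity.as_matrix()
    if a.shape != g.shape:
        raise ParameterError(
            f"trace length {a.shape[0]} != gravity length {g.shape[0]}")
    d = a - g
    gnorm = np.linalg.norm(g, axis=1)
    ok = gnorm > 0
    dot = np.einsum("ij,ij->i", d, g)
    sigma = np.ones(len(a))
    sigma[ok & (dot < 0)] = -1.0
    base = np.linalg.norm(d if mode == "dynamic" else a, axis=1)
    return SignedMagnitudeSeries(fs=trace.fs, s=sigma * base, mode=mode)


def preprocess_trace(trace: UniformTrace,
                     cfg: PreprocessConfig | None = None) -> SignedMagnitudeSeries:
    """Full pipeline: gravity baseline then signed magnitude."""
    cfg = cfg or PreprocessConfig()
    grav = estimate_gravity(trace, cfg.gravity_window_s)
    return signed_magnitude(trace, grav, cfg.sign_mode)
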