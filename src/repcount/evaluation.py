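"""RMSE-of-counts evaluation harness and threshold tuning.

Counters are scored by the root-mean-square error between estimated and
true repetition counts over a set of sessions, tabulated per exercise and
per method. The per-method average row is the *pooled* RMSE (square root
of the mean squared error over every session of that method), not the mean
of the per-exercise RMSEs; both aggregations are carried in the report
because they genuinely differ.

Sessions loaded from a manifest are excluded when the participant and
observer counts disagree — mirroring the standard ground-truth hygiene rule
for manually counted repetitions.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .counters import METHODS, CounterConfig, run_counter
from .errors import EvaluationError, ParameterError
from .preprocess import PreprocessConfig, preprocess_trace
from .signal_io import read_trace, resample_uniform, write_trace
from .synthgen import SessionRecord

__all__ = [
    "EvaluationReport",
    "rmse",
    "evaluate",
    "tune_threshold",
    "write_sessions",
    "load_sessions",
]

log = logging.getLogger(__name__)


def rmse(estimates, truths) -> float:
    """Root-mean-square error between paired count sequences."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape or est.ndim != 1 or est.size == 0:
        raise ParameterError(
            f"need equal-length nonempty sequences, got {est.shape} vs {tru.shape}")
    return float(np.sqrt(np.mean((est - tru) ** 2)))


@dataclasses.dataclass(frozen=True)
class EvaluationReport:
    """Per-exercise × per-method RMSE matrix with averages.

    ``per_method_avg`` is the pooled RMSE over all sessions of a method;
    ``per_method_mean_of_cells`` averages the per-exercise RMSEs instead.
    ``estimates`` keeps the raw per-session counts for reproducibility
    checks and downstream analysis.
    """

    per_cell: dict[tuple[str, str], float]
    per_method_avg: dict[str, float]
    per_method_mean_of_cells: dict[str, float]
    n_sessions: dict[str, int]
    estimates: pd.DataFrame

    def table(self) -> pd.DataFrame:
        """RMSE matrix: rows = exercises, columns = methods, final Avg row."""
        exercises = sorted(self.n_sessions)
        methods = [m for m in METHODS if m in self.per_method_avg] or \
            sorted(self.per_method_avg)
        rows = {ex: [self.per_cell[(ex, m)] for m in methods] for ex in exercises}
        df = pd.DataFrame.from_dict(rows, orient="index", columns=methods)
        df.loc["Avg RMSE"] = [self.per_method_avg[m] for m in methods]
        df.index.name = "exercise"
        return df

    def to_csv(self, path: str | Path) -> None:
        self.table().to_csv(path, float_format="%.4f")

    def to_dict(self) -> dict:
        """Machine-readable form with both aggregation variants."""
        return {
            "per_cell": {f"{ex}|{m}": v for (ex, m), v in self.per_cell.items()},
            "per_method_pooled_rmse": dict(self.per_method_avg),
            "per_method_mean_of_exercise_rmse": dict(self.per_method_mean_of_cells),
            "n_sessions": dict(self.n_sessions),
        }


def evaluate(sessions: list[SessionRecord],
             methods: tuple[str, ...] = METHODS,
             cfg: CounterConfig | None = None,
             pre_cfg: PreprocessConfig | None = None) -> EvaluationReport:
    """Run preprocessing and each counter on every session and score RMSEs.

    A session that fails preprocessing is excluded with a log message; if
    every session fails, an :class:`EvaluationError` is raised.
    """
    if not methods:
        raise ParameterError("methods must be nonempty")
    cfg = cfg or CounterConfig()
    pre_cfg = pre_cfg or PreprocessConfig()

    records = []
    n_failed = 0
    for i, sess in enumerate(sessions):
        try:
            series = preprocess_trace(sess.trace, pre_cfg)
        except Exception as exc:  # noqa: BLE001 — any bad session is skipped
            n_failed += 1
            log.warning("session %s failed preprocessing: %s",
                        sess.session_id or i, exc)
            continue
        for m in methods:
            res = run_counter(m, series, cfg)
            records.append({"session_id": sess.session_id or str(i),
                            "exercise": sess.archetype, "method": m,
                            "estimate": res.count, "truth": sess.true_count})
    if not records:
        raise EvaluationError(f"all {n_failed} session(s) failed preprocessing")
    est = pd.DataFrame.from_records(records)

    per_cell: dict[tuple[str, str], float] = {}
    for (ex, m), grp in est.groupby(["exercise", "method"], sort=True):
        per_cell[(ex, m)] = rmse(grp["estimate"], grp["truth"])
    per_method_avg = {
        m: rmse(grp["estimate"], grp["truth"])
        for m, grp in est.groupby("method", sort=True)
    }
    per_method_mean = {
        m: float(np.mean([v for (ex, mm), v in per_cell.items() if mm == m]))
        for m in per_method_avg
    }
    n_sessions = {
        ex: int(grp["session_id"].nunique())
        for ex, grp in est.groupby("exercise", sort=True)
    }
    return EvaluationReport(per_cell=per_cell, per_method_avg=per_method_avg,
                            per_method_mean_of_cells=per_method_mean,
                            n_sessions=n_sessions, estimates=est)


def tune_threshold(sessions: list[SessionRecord],
                   grid: list[float] | None = None,
                   method: str = "threshold_lowpass",
                   cfg: CounterConfig | None = None,
                   pre_cfg: PreprocessConfig | None = None
                   ) -> tuple[float, pd.DataFrame]:
    """Grid-sample the threshold fraction and pick the pooled-RMSE minimiser.

    Returns the best fraction and the per-fraction RMSE table. Ties break
    toward the smaller fraction.
    """
    if grid is None:
        grid = [round(0.05 * k, 2) for k in range(1, 20)]
    if not grid:
        raise ParameterError("grid must be nonempty")
    if any(not 0 < f < 1 for f in grid):
        raise ParameterError("all grid fractions must be in (0,1)")
    cfg = cfg or CounterConfig()
    rows = []
    for frac in sorted(grid):
        trial = dataclasses.replace(cfg, threshold_frac=frac)
        report = evaluate(sessions, methods=(method,), cfg=trial, pre_cfg=pre_cfg)
        rows.append({"threshold_frac": frac,
                     "pooled_rmse": report.per_method_avg[method]})
    table = pd.DataFrame.from_records(rows)
    best = table.loc[table["pooled_rmse"].idxmin()]  # idxmin: first minimum
    return float(best["threshold_frac"]), table


def write_sessions(sessions: list[SessionRecord], out_dir: str | Path) -> Path:
    """Write session traces plus a manifest table; returns the manifest path.

    The manifest has columns session_id, path, exercise, participant_count,
    observer_count, true_count. Simulated observers always agree, so both
    count columns equal the true count.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sess in enumerate(sessions):
        sid = sess.session_id or f"session{i:04d}"
        fname = f"{sid}.csv"
        write_trace(sess.trace, out_dir / fname)
        rows.append({"session_id": sid, "path": fname,
                     "exercise": sess.archetype,
                     "participant_count": sess.true_count,
                     "observer_count": sess.true_count,
                     "true_count": sess.true_count})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame.from_records(rows).to_csv(manifest, index=False)
    return manifest


def load_sessions(manifest_path: str | Path, fs: float = 50.0,
                  unit: str = "m/s2") -> list[SessionRecord]:
    """Load sessions listed in a manifest, applying the agreement filter.

    Rows whose participant and observer counts differ are excluded (their
    ground truth is unreliable); rows pointing at missing trace files are
    skipped with a warning. Traces are resampled onto a uniform ``fs`` grid.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep=None, engine="python")
    required = {"session_id", "path", "exercise", "participant_count",
                "observer_count", "true_count"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"manifest missing columns: {sorted(missing)}")

    sessions: list[SessionRecord] = []
    n_disagree = n_missing = 0
    for _, row in df.iterrows():
        if int(row["participant_count"]) != int(row["observer_count"]):
            n_disagree += 1
            continue
        trace_path = Path(row["path"])
        if not trace_path.is_absolute():
            trace_path = manifest_path.parent / trace_path
        if not trace_path.exists():
            n_missing += 1
            log.warning("trace file missing, skipping: %s", trace_path)
            continue
        uniform = resample_uniform(read_trace(trace_path, unit=unit), fs=fs)
        sessions.append(SessionRecord(
            trace=uniform, archetype=str(row["exercise"]),
            true_count=int(row["true_count"]),
            duration_s=uniform.duration_s, seed=-1,
            session_id=str(row["session_id"])))
    if n_disagree:
        log.info("excluded %d session(s) with disagreeing counts", n_disagree)
    if not sessions:
        raise EvaluationError(f"no usable sessions in {manifest_path}")
    return sessions
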