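"""Trial recordings and performance metrics.

A trial is a 1 Hz record of the measured blood temperature together with the
warming-unit setting in effect at each second.  The canonical CSV schema is

    time_s,temp_c,heat,speed

with ``heat`` in {21, 32, 38, 43} (21 = unheated ambient air) and ``speed``
in {standby, slow, fast}; lines starting with ``#`` carry provenance
metadata.  ``column_map`` adapts foreign dialects.

Metrics follow the time-in-range convention of targeted temperature
management: every present 1 Hz sample contributes one second, a sample is
outside a band when |T - target| exceeds the tolerance, and percentages and
hourly rates are reported to two decimals (half-up).  Setting adaptions are
counted as recorded state transitions between consecutive rows.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .controller import Controller, ControllerConfig, TemperatureSample, state_to_setting
from .device import DeviceSetting, FanSpeed, HeatLevel

CANONICAL_COLUMNS = ("time_s", "temp_c", "heat", "speed")

_HEAT_DIALECTS = {
    "21": "21", "c21": "21", "ambient": "21", "ambient21": "21",
    "32": "32", "c32": "32",
    "38": "38", "c38": "38",
    "43": "43", "c43": "43",
}
_SPEED_DIALECTS = {"standby": "standby", "slow": "slow", "fast": "fast",
                   "off": "standby", "low": "slow", "high": "fast"}


class TrialLoadError(ValueError):
    """Unreadable or invariant-violating trial file."""


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties away from zero (reporting convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TrialSeries:
    """Ordered 1 Hz trial record plus metadata.

    ``df`` holds the canonical columns; ``metadata`` carries at least a trial
    label and, for controlled trials, the target temperature.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise TrialLoadError(f"missing canonical columns: {missing}")
        times = self.df["time_s"].to_numpy()
        if len(times) and np.any(np.diff(times) <= 0):
            raise TrialLoadError("time_s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_seconds(self) -> int:
        """Accounted trial duration: one second per present sample."""
        return len(self.df)

    @property
    def temps(self) -> np.ndarray:
        return self.df["temp_c"].to_numpy(dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.df["time_s"].to_numpy(dtype=np.int64)

    def settings(self) -> list[DeviceSetting]:
        return [
            DeviceSetting(HeatLevel(h), FanSpeed(s))
            for h, s in zip(self.df["heat"], self.df["speed"])
        ]

    def to_csv(self, path: str | Path) -> None:
        """Write canonical CSV with ``# key: value`` metadata header lines."""
        path = Path(path)
        with path.open("w", newline="") as fh:
            for key in sorted(self.metadata):
                fh.write(f"# {key}: {self.metadata[key]}\n")
            self.df.to_csv(fh, index=False)


def make_series(
    times: Sequence[int],
    temps: Sequence[float],
    heats: Sequence[str],
    speeds: Sequence[str],
    metadata: dict | None = None,
) -> TrialSeries:
    df = pd.DataFrame(
        {
            "time_s": np.asarray(times, dtype=np.int64),
            "temp_c": np.asarray(temps, dtype=float),
            "heat": list(heats),
            "speed": list(speeds),
        }
    )
    return TrialSeries(df, metadata or {})


def _read_metadata(path: Path) -> dict:
    meta: dict = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
    return meta


def read_trial_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    label: str | None = None,
) -> TrialSeries:
    """Load a trial CSV, normalizing heat/speed dialects.

    ``column_map`` maps canonical names (``time_s``, ``temp_c``, ``heat``,
    ``speed``) to the file's column names.  Rows are sorted by time;
    duplicate timestamps are an error.  Heat values such as ``38``, ``38.0``
    or ``c38`` and speed aliases (off/low/high) are normalized to the
    canonical vocabulary.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TrialLoadError(f"cannot read trial CSV {path}: {exc}") from exc
    column_map = dict(column_map or {c: c for c in CANONICAL_COLUMNS})
    missing = [src for src in column_map.values() if src not in raw.columns]
    if missing:
        raise TrialLoadError(f"{path}: missing columns {missing}; have {list(raw.columns)}")
    df = pd.DataFrame({canon: raw[src] for canon, src in column_map.items()})

    temps = pd.to_numeric(df["temp_c"], errors="coerce")
    if temps.isna().any():
        bad = df["temp_c"][temps.isna()].iloc[0]
        raise TrialLoadError(f"{path}: unparseable temperature value {bad!r}")
    df["temp_c"] = temps.astype(float)
    df["time_s"] = pd.to_numeric(df["time_s"], errors="raise").astype(np.int64)

    def norm(column: pd.Series, dialects: Mapping[str, str], what: str) -> list[str]:
        out = []
        for value in column:
            key = str(value).strip().lower()
            if key.endswith(".0"):
                key = key[:-2]
            if key not in dialects:
                raise TrialLoadError(f"{path}: unrecognized {what} value {value!r}")
            out.append(dialects[key])
        return out

    df["heat"] = norm(df["heat"], _HEAT_DIALECTS, "heat")
    df["speed"] = norm(df["speed"], _SPEED_DIALECTS, "speed")
    df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
    if df["time_s"].duplicated().any():
        dup = int(df["time_s"][df["time_s"].duplicated()].iloc[0])
        raise TrialLoadError(f"{path}: duplicate timestamp {dup} s")
    meta = _read_metadata(path)
    if label is not None:
        meta["label"] = label
    return TrialSeries(df[list(CANONICAL_COLUMNS)], meta)


# ---------------------------------------------------------------------------
# performance metrics


def within_range_fraction(
    series: TrialSeries, target: float, tolerance: float
) -> tuple[int, float]:
    """Seconds outside ``target +/- tolerance`` and percent within.

    Each present 1 Hz sample counts one second; percent is
    100 * (1 - outside/total), two decimals half-up.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    outside = int(np.sum(np.abs(series.temps - target) > tolerance))
    total = series.total_seconds
    return outside, round_half_up(100.0 * (total - outside) / total)


def count_setting_changes(series: TrialSeries) -> tuple[int, float]:
    """Number of recorded (heat, speed) transitions and the hourly rate."""
    if len(series) == 0:
        raise ValueError("empty series")
    heat = series.df["heat"].to_numpy()
    speed = series.df["speed"].to_numpy()
    changed = (heat[1:] != heat[:-1]) | (speed[1:] != speed[:-1])
    count = int(np.sum(changed))
    hours = series.total_seconds / 3600.0
    return count, round_half_up(count / hours)


def sliding_median(series: TrialSeries, window: float = 120.0) -> np.ndarray:
    """Centered running median over samples within +/- window/2 seconds.

    Edges use the available partial window.  Filters short interruptions
    (flushes, cold-fluid injections) for display and sensitivity analysis.
    """
    if window < 1:
        raise ValueError("window must be >= 1 s")
    times = series.times
    temps = series.temps
    n = len(temps)
    half = window / 2.0
    if n == 0:
        return np.empty(0)
    # fast path: uniform 1 s spacing -> count-based centered window
    if n > 1 and np.all(np.diff(times) == 1):
        width = 2 * int(half) + 1
        return (
            pd.Series(temps).rolling(width, center=True, min_periods=1).median().to_numpy()
        )
    out = np.empty(n)
    lo = hi = 0
    for i in range(n):
        while times[lo] < times[i] - half:
            lo += 1
        while hi < n and times[hi] <= times[i] + half:
            hi += 1
        out[i] = np.median(temps[lo:hi])
    return out


@dataclass
class PerformanceReport:
    """Time-in-range and adaption-count summary of one trial."""

    label: str
    target_temp: float
    total_seconds: int
    outside_seconds: dict[float, int]
    within_percent: dict[float, float]
    n_setting_changes: int
    changes_per_hour: float
    settling_excluded_s: int = 0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "target_temp": self.target_temp,
            "total_seconds": self.total_seconds,
            "settling_excluded_s": self.settling_excluded_s,
            **{f"outside_s_{tol}": s for tol, s in self.outside_seconds.items()},
            **{f"within_pct_{tol}": p for tol, p in self.within_percent.items()},
            "n_setting_changes": self.n_setting_changes,
            "changes_per_hour": self.changes_per_hour,
        }

    def to_text(self) -> str:
        lines = [
            f"trial           : {self.label}",
            f"target          : {self.target_temp:.1f} degC",
            f"total duration  : {self.total_seconds} s"
            + (f" (first {self.settling_excluded_s} s settling excluded)"
               if self.settling_excluded_s else ""),
        ]
        for tol in sorted(self.outside_seconds):
            lines.append(
                f"  +/-{tol} degC : outside {self.outside_seconds[tol]} s, "
                f"within {self.within_percent[tol]:.2f}%"
            )
        lines.append(
            f"setting changes : {self.n_setting_changes} "
            f"({self.changes_per_hour:.2f} per hour)"
        )
        return "\n".join(lines)


def evaluate(
    series: TrialSeries,
    target: float,
    tolerances: Sequence[float] = (0.5, 1.0),
    *,
    settling_s: int = 0,
    filtered: bool = False,
    filter_window: float = 120.0,
) -> PerformanceReport:
    """Compute the full performance report for one trial.

    ``settling_s`` drops the initial equilibration phase before scoring
    (0 scores the whole trial, the reference convention).  ``filtered``
    applies the centered sliding median before banding, for sensitivity
    analysis; the reference tables are computed on raw 1 Hz readings.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    scored = series
    if settling_s:
        t0 = int(series.times[0]) + settling_s
        df = series.df[series.df["time_s"] >= t0].reset_index(drop=True)
        if df.empty:
            raise ValueError("settling exclusion removes the entire trial")
        scored = TrialSeries(df, dict(series.metadata))
    if filtered:
        df = scored.df.copy()
        df["temp_c"] = sliding_median(scored, filter_window)
        scored = TrialSeries(df, dict(scored.metadata))
    outside: dict[float, int] = {}
    within: dict[float, float] = {}
    for tol in tolerances:
        outside[tol], within[tol] = within_range_fraction(scored, target, tol)
    n_changes, per_hour = count_setting_changes(scored)
    return PerformanceReport(
        label=str(series.metadata.get("label", "trial")),
        target_temp=target,
        total_seconds=scored.total_seconds,
        outside_seconds=outside,
        within_percent=within,
        n_setting_changes=n_changes,
        changes_per_hour=per_hour,
        settling_excluded_s=settling_s,
    )


# ---------------------------------------------------------------------------
# controller replay


@dataclass
class ReplayResult:
    """Outcome of re-running the control law over recorded temperatures."""

    events: list[tuple[int, DeviceSetting]]
    predicted: list[DeviceSetting]
    agreement_percent: float
    n_changes_recorded: int
    n_changes_predicted: int

    def to_text(self) -> str:
        return (
            f"evaluations        : {len(self.events)}\n"
            f"agreement          : {self.agreement_percent:.2f}% of seconds\n"
            f"changes recorded   : {self.n_changes_recorded}\n"
            f"changes predicted  : {self.n_changes_predicted}"
        )


def replay_controller(series: TrialSeries, config: ControllerConfig) -> ReplayResult:
    """Feed the recorded temperatures through the control law and compare
    the predicted setting stream with the recorded one.

    The predicted stream starts from the neutral state's setting (s = 0) and
    holds each emitted setting until the next evaluation; agreement is the
    percentage of rows whose recorded (heat, speed) tuple matches.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    controller = Controller(config)
    current = state_to_setting(0.0)
    events: list[tuple[int, DeviceSetting]] = []
    predicted: list[DeviceSetting] = []
    matches = 0
    recorded = series.settings()
    for (t, temp), rec in zip(
        zip(series.times, series.temps), recorded
    ):
        emitted = controller.feed(TemperatureSample(time=float(t), temp=float(temp)))
        if emitted is not None:
            events.append((int(t), emitted))
            current = emitted
        predicted.append(current)
        if current == rec:
            matches += 1
    n_pred = sum(
        1 for a, b in zip(predicted[1:], predicted[:-1]) if a != b
    )
    n_rec, _ = count_setting_changes(series)
    return ReplayResult(
        events=events,
        predicted=predicted,
        agreement_percent=round_half_up(100.0 * matches / len(series)),
        n_changes_recorded=n_rec,
        n_changes_predicted=n_pred,
    )
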