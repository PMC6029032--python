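"""Independent brute-force oracles the implementation is checked against.

These deliberately re-derive everything from first principles — full-array
masking for the window mean, a textbook clamp, an interval-table setting
lookup, naive row-by-row metric loops — and share no code with the package's
incremental implementations.
"""
from __future__ import annotations

import numpy as np

# state interval table: (lower, upper, lower_open, upper_closed, heat, speed)
_SETTING_TABLE = [
    (-1.0, -1.0, False, True, "21", "fast"),
    (-1.0, -0.5, True, True, "21", "slow"),
    (-0.5, 0.0, True, True, "32", "slow"),
    (0.0, 0.5, True, True, "38", "slow"),
    (0.5, 1.0, True, False, "43", "slow"),
    (1.0, 1.0, False, True, "43", "fast"),
]


def oracle_setting(s: float) -> tuple[str, str]:
    """Look the setting up in the interval table; errors if the table does
    not cover s exactly once (partition check)."""
    hits = [
        (heat, speed)
        for lo, hi, lo_open, hi_closed, heat, speed in _SETTING_TABLE
        if (lo < s if lo_open else lo <= s) and (s <= hi if hi_closed else s < hi)
    ]
    if len(hits) != 1:
        raise AssertionError(f"interval table covers s={s} {len(hits)} times")
    return hits[0]


def brute_force_run(times, temps, valid, target, eval_interval, scaling_factor):
    """Re-run the integral control law storing *all* samples and recomputing
    each window mean from scratch with a full-array mask over (t-c_t, t].

    Returns the (s, heat, speed) sequence of every fired evaluation.
    """
    times = np.asarray(times, dtype=float)
    temps = np.asarray(temps, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    index = np.arange(len(times))
    s = 0.0
    last_eval = 0.0
    out = []
    for i, t in enumerate(times):
        if t - last_eval < eval_interval:
            continue
        mask = (times > t - eval_interval) & (times <= t) & valid & (index <= i)
        last_eval = t
        if not mask.any():
            continue
        in_window = temps[mask].tolist()  # sequential textbook mean
        error = target - sum(in_window) / len(in_window)
        s = min(1.0, max(-1.0, s + error * scaling_factor))
        heat, speed = oracle_setting(s)
        out.append((s, heat, speed))
    return out


def naive_outside_seconds(temps, target, tolerance) -> int:
    return sum(1 for T in temps if abs(T - target) > tolerance)


def naive_change_count(heats, speeds) -> int:
    pairs = list(zip(heats, speeds))
    return sum(1 for prev, cur in zip(pairs, pairs[1:]) if prev != cur)


def naive_sliding_median(times, temps, window) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    temps = np.asarray(temps, dtype=float)
    half = window / 2.0
    return np.array(
        [
            np.median(temps[(times >= t - half) & (times <= t + half)])
            for t in times
        ]
    )
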