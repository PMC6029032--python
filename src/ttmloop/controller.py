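"""Closed-loop annealing controller for targeted temperature management.

The control law reads 1 Hz body-temperature samples, averages them over an
evaluation window of ``c_t`` seconds (a short arithmetic-mean filter that
absorbs flushing and cold-injection artifacts), computes the error against
the target ``e = T_tar - mean(T)``, accumulates it into a saturating state
``s`` clamped to [-1, 1], and quantizes ``s`` onto the warming unit's
discrete settings.  ``s = +1`` means maximal heating (43 °C, fast blower),
``s = -1`` maximal cooling (ambient air, fast blower); the standby speed is
never commanded because it would deflate the blanket.

Two error-to-state modes exist: the default ``integral`` mode accumulates
(``s += e * c_s``, clamped), which makes the loop anneal toward the best
available setting in several small steps; the ``proportional`` mode maps the
instantaneous error directly (``s = e * c_s``, clamped) and is provided for
comparison.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .device import DeviceSetting, FanSpeed, HeatLevel


class NoValidDataError(ValueError):
    """Raised when an evaluation window holds no valid sample."""


class ControlMode(str, enum.Enum):
    INTEGRAL = "integral"
    PROPORTIONAL = "proportional"


@dataclass(frozen=True)
class ControllerConfig:
    """Tunable parameters of the control loop.

    target_temp
        Target core temperature T_tar in °C (study value 38.0 for the
        normothermic porcine setting).
    eval_interval
        Evaluation/averaging interval c_t in seconds (study value 120).
    scaling_factor
        Gain c_s applied to the mean error per evaluation (study value 0.7,
        chosen to give a sufficiently fast response without overshoot).
    mode
        Error-to-state law; see module docstring.
    """

    target_temp: float = 38.0
    eval_interval: int = 120
    scaling_factor: float = 0.7
    mode: ControlMode = ControlMode.INTEGRAL

    def __post_init__(self) -> None:
        if not 30.0 <= self.target_temp <= 42.0:
            raise ValueError(
                f"target_temp must be in [30, 42] degC, got {self.target_temp}"
            )
        if int(self.eval_interval) != self.eval_interval or self.eval_interval < 1:
            raise ValueError(
                f"eval_interval must be a positive integer number of seconds, "
                f"got {self.eval_interval}"
            )
        if not self.scaling_factor > 0:
            raise ValueError(f"scaling_factor must be > 0, got {self.scaling_factor}")
        object.__setattr__(self, "mode", ControlMode(self.mode))


@dataclass(frozen=True)
class TemperatureSample:
    """One monitor reading: seconds since trial start, temperature in °C.

    ``valid`` is False for missing or explicitly artifact-flagged readings;
    such samples are excluded from the window mean.
    """

    time: float
    temp: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and not 15.0 <= self.temp <= 45.0:
            raise ValueError(
                f"valid temperature {self.temp} degC outside plausible range [15, 45]"
            )


@dataclass
class ControllerState:
    """Mutable loop state: saturating action s, current window, bookkeeping."""

    s: float = 0.0
    window: list[TemperatureSample] = field(default_factory=list)
    last_setting: DeviceSetting | None = None
    last_eval_time: float = 0.0


def clamp(value: float, lo: float = -1.0, hi: float = 1.0) -> float:
    return lo if value < lo else hi if value > hi else value


def window_mean(window: Sequence[TemperatureSample]) -> float:
    """Arithmetic mean of the valid samples' temperatures.

    Raises :class:`NoValidDataError` on an empty or all-invalid window; the
    caller then holds the previous setting.
    """
    temps = [sample.temp for sample in window if sample.valid]
    if not temps:
        raise NoValidDataError("no valid temperature sample in window")
    return sum(temps) / len(temps)


def compute_error(mean_temp: float, target_temp: float) -> float:
    """Feedback error e = T_tar - mean(T); positive means the subject is too
    cold and heating is needed."""
    return target_temp - mean_temp


def update_state(
    s_prev: float,
    error: float,
    scaling_factor: float,
    mode: ControlMode = ControlMode.INTEGRAL,
) -> float:
    """Advance the saturating state, clamped to [-1, 1] on every update."""
    if not -1.0 <= s_prev <= 1.0:
        raise ValueError(f"s_prev must be in [-1, 1], got {s_prev}")
    if ControlMode(mode) is ControlMode.INTEGRAL:
        return clamp(s_prev + error * scaling_factor)
    return clamp(error * scaling_factor)


def state_to_setting(s: float) -> DeviceSetting:
    """Quantize the state onto the device's settings.

    Six contiguous intervals partition [-1, 1]; interiors are upper-inclusive
    and only the exact endpoints engage the fast blower:

    ====================  =================
    s                     setting
    ====================  =================
    s = -1                (ambient 21, fast)
    -1   < s <= -0.5      (ambient 21, slow)
    -0.5 < s <=  0        (32 °C, slow)
     0   < s <=  0.5      (38 °C, slow)
     0.5 < s <   1        (43 °C, slow)
    s = 1                 (43 °C, fast)
    ====================  =================
    """
    if not -1.0 <= s <= 1.0:
        raise ValueError(f"state must be in [-1, 1], got {s}")
    if s == -1.0:
        return DeviceSetting(HeatLevel.AMBIENT21, FanSpeed.FAST)
    if s <= -0.5:
        return DeviceSetting(HeatLevel.AMBIENT21, FanSpeed.SLOW)
    if s <= 0.0:
        return DeviceSetting(HeatLevel.C32, FanSpeed.SLOW)
    if s <= 0.5:
        return DeviceSetting(HeatLevel.C38, FanSpeed.SLOW)
    if s < 1.0:
        return DeviceSetting(HeatLevel.C43, FanSpeed.SLOW)
    return DeviceSetting(HeatLevel.C43, FanSpeed.FAST)


def controller_step(
    state: ControllerState,
    config: ControllerConfig,
    sample: TemperatureSample,
) -> tuple[ControllerState, DeviceSetting | None]:
    """Feed one sample; return the (mutated) state and a setting if an
    evaluation fired.

    Samples must arrive in non-decreasing time order.  An evaluation fires
    when at least ``eval_interval`` seconds have elapsed since the previous
    one; it averages the valid samples with timestamps in
    ``(t - eval_interval, t]``, updates ``s``, clears the window and emits
    the (possibly unchanged) setting.  If the window holds no valid sample
    the state is left untouched, the previous setting is retained and no
    setting is emitted, but the evaluation clock still advances.
    """
    if state.window and sample.time < state.window[-1].time:
        raise ValueError(
            f"out-of-order sample at t={sample.time} "
            f"(last seen t={state.window[-1].time})"
        )
    state.window.append(sample)
    t = sample.time
    if t - state.last_eval_time < config.eval_interval:
        return state, None
    in_window = [x for x in state.window if t - config.eval_interval < x.time <= t]
    state.window.clear()
    state.last_eval_time = t
    try:
        mean_temp = window_mean(in_window)
    except NoValidDataError:
        return state, None
    error = compute_error(mean_temp, config.target_temp)
    state.s = update_state(state.s, error, config.scaling_factor, config.mode)
    state.last_setting = state_to_setting(state.s)
    return state, state.last_setting


class Controller:
    """Convenience wrapper binding a config to an evolving state.

    >>> ctl = Controller(ControllerConfig())
    >>> for t in range(240):
    ...     setting = ctl.feed(TemperatureSample(time=t, temp=37.0))
    """

    def __init__(self, config: ControllerConfig) -> None:
        self.config = config
        self.state = ControllerState()

    def feed(self, sample: TemperatureSample) -> DeviceSetting | None:
        _, setting = controller_step(self.state, self.config, sample)
        return setting

    def run(self, samples: Iterable[TemperatureSample]) -> list[tuple[float, DeviceSetting]]:
        """Feed a whole stream; return the (time, setting) evaluation events."""
        events = []
        for sample in samples:
            setting = self.feed(sample)
            if setting is not None:
                events.append((sample.time, setting))
        return events
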