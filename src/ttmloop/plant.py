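"""Synthetic thermal plant: a lumped-parameter model of an anesthetized
subject under a forced-air blanket.

The subject is a single well-mixed compartment with heat capacity
``C = mass * specific_heat`` obeying

    C dT/dt = P_met(t) - k_ambient (T - T_amb) - k_blanket(speed) (T - T_air)

where ``P_met(t)`` is basal metabolic power plus an optional fever ramp
(long-term narcosis in the emulated porcine setting reliably produces
drug-induced hyperthermia, an incidental fever model), ``k_ambient`` lumps
passive radiative/convective losses to the room, and ``k_blanket`` couples
the core to the blanket's air stream, more strongly at the fast blower speed.
Integration is explicit Euler at 1 s steps; with time constants of hours the
scheme is far from its stability limit and tracks the exact exponential
solution to well under 0.01 °C.

Measurements add Gaussian sensor noise and scheduled transient offsets
emulating the cold-fluid calibration injections and flushes of an arterial
catheter thermistor.  Artifacts are deliberately *not* flagged invalid: the
controller's window averaging has to absorb them, as it must on real data.

Defaults emulate a ~42 kg juvenile pig in a 21 °C room under a full-body
blanket.  They are chosen so that (a) the uncontrolled subject drifts above
39.5 °C within roughly a day, and (b) no discrete device setting balances the
plant exactly at 38.0 °C, so the closed loop must alternate between adjacent
settings — the characteristic ramp-and-correct pattern of a quantized
actuator.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .controller import (
    Controller,
    ControllerConfig,
    TemperatureSample,
    state_to_setting,
)
from .device import BairHuggerEmulator, DeviceSetting, FanSpeed, HeatLevel, delivered_air_temp
from .trial import TrialSeries, make_series


@dataclass(frozen=True)
class Artifact:
    """Transient additive measurement offset (e.g. a cold-fluid injection)."""

    onset: float  # s
    duration: float  # s
    offset: float  # °C, typically negative

    def active(self, t: float) -> bool:
        return self.onset <= t < self.onset + self.duration


def injection_schedule(
    duration: float = 90 * 3600.0,
    first_onset: float = 3 * 3600.0,
    period: float = 4 * 3600.0,
    artifact_duration: float = 30.0,
    offset: float = -2.0,
) -> tuple[Artifact, ...]:
    """Periodic calibration-injection artifacts: every ``period`` seconds a
    ``artifact_duration``-second dip of ``offset`` °C."""
    onsets = np.arange(first_onset, duration, period)
    return tuple(Artifact(float(t), artifact_duration, offset) for t in onsets)


@dataclass(frozen=True)
class PlantConfig:
    """Parameters of the synthetic subject and its measurement channel.

    mass, specific_heat
        Subject mass (kg) and effective tissue specific heat (J/(kg K));
        defaults 42 kg and 3500 give C ~ 1.47e5 J/K.
    k_ambient
        Passive loss coefficient to room air, W/K.
    k_blanket_slow, k_blanket_fast
        Blanket air-to-core exchange coefficients at the two blower speeds,
        W/K (fast > slow, scaling with the 20 vs 23 L/s airflow).
    basal_metabolic_power
        Constant metabolic heat production, W (~2 W/kg under anesthesia).
    fever_peak_power, fever_onset, fever_ramp
        Fever modeled as extra power ramping linearly from 0 at ``fever_onset``
        to ``fever_peak_power`` over ``fever_ramp`` seconds, then held.
    noise_sd
        Gaussian sd of the thermistor reading, °C.
    artifact_schedule
        Transient measurement offsets; see :class:`Artifact`.
    initial_temp
        Core temperature at trial start, °C (slightly hypothermic after
        preparation).
    seed
        Default RNG seed for the measurement channel.
    """

    mass: float = 42.0
    specific_heat: float = 3500.0
    k_ambient: float = 5.0
    k_blanket_slow: float = 12.0
    k_blanket_fast: float = 14.0
    ambient_temp: float = 21.0
    basal_metabolic_power: float = 87.0
    fever_peak_power: float = 15.0
    fever_onset: float = 4 * 3600.0
    fever_ramp: float = 12 * 3600.0
    noise_sd: float = 0.02
    artifact_schedule: tuple[Artifact, ...] = field(default_factory=injection_schedule)
    initial_temp: float = 37.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mass", "specific_heat", "k_ambient", "k_blanket_slow", "k_blanket_fast"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not self.k_blanket_fast > self.k_blanket_slow:
            raise ValueError("k_blanket_fast must exceed k_blanket_slow")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def heat_capacity(self) -> float:
        """Lumped heat capacity C in J/K."""
        return self.mass * self.specific_heat

    def fever_power(self, t: float) -> float:
        """Fever contribution to metabolic power at time t, W."""
        if self.fever_peak_power == 0 or t <= self.fever_onset:
            return 0.0
        frac = min(1.0, (t - self.fever_onset) / self.fever_ramp)
        return self.fever_peak_power * frac

    def metabolic_power(self, t: float) -> float:
        return self.basal_metabolic_power + self.fever_power(t)

    def blanket_coefficient(self, speed: FanSpeed) -> float:
        """Exchange coefficient in W/K for a blower speed (standby: blanket
        deflated, no forced exchange)."""
        return {
            FanSpeed.FAST: self.k_blanket_fast,
            FanSpeed.SLOW: self.k_blanket_slow,
            FanSpeed.STANDBY: 0.0,
        }[FanSpeed(speed)]


@dataclass
class PlantState:
    time: float = 0.0
    core_temp: float = 37.5


def plant_step(
    state: PlantState, setting: DeviceSetting, config: PlantConfig, dt: float = 1.0
) -> PlantState:
    """One explicit-Euler step of the heat balance.

    ``dt`` must stay at or below 1 s; the scheme is then effectively exact
    for the hours-scale time constants of the model.
    """
    if not 0 < dt <= 1.0:
        raise ValueError(f"dt must be in (0, 1] s, got {dt}")
    T = state.core_temp
    air_temp = delivered_air_temp(setting, ambient=config.ambient_temp)
    k_blanket = config.blanket_coefficient(setting.speed)
    power = (
        config.metabolic_power(state.time)
        - config.k_ambient * (T - config.ambient_temp)
        - k_blanket * (T - air_temp)
    )
    return PlantState(time=state.time + dt, core_temp=T + dt * power / config.heat_capacity)


def equilibrium_temp(config: PlantConfig, setting: DeviceSetting, t: float = 0.0) -> float:
    """Algebraic balance point of the heat equation for a fixed setting."""
    k_blanket = config.blanket_coefficient(setting.speed)
    air_temp = delivered_air_temp(setting, ambient=config.ambient_temp)
    return (
        config.metabolic_power(t) + config.k_ambient * config.ambient_temp + k_blanket * air_temp
    ) / (config.k_ambient + k_blanket)


def relaxation_temp(config: PlantConfig, t0_temp: float, t: float) -> float:
    """Closed-form homogeneous solution (no metabolic power, blanket in
    standby): exponential relaxation to ambient with rate k_ambient / C."""
    tau = config.heat_capacity / config.k_ambient
    return config.ambient_temp + (t0_temp - config.ambient_temp) * math.exp(-t / tau)


def artifact_offset(config: PlantConfig, t: float) -> float:
    """Sum of scheduled artifact offsets active at time t."""
    return sum(a.offset for a in config.artifact_schedule if a.active(t))


def measure(state: PlantState, config: PlantConfig, rng: np.random.Generator) -> TemperatureSample:
    """Simulated thermistor reading: core temperature + Gaussian noise +
    any active artifact offset.  The sample is flagged valid even during an
    artifact — downstream averaging must absorb it."""
    temp = state.core_temp + artifact_offset(config, state.time)
    if config.noise_sd > 0:
        temp += rng.normal(0.0, config.noise_sd)
    return TemperatureSample(time=state.time, temp=float(temp), valid=True)


#: Setting held throughout an uncontrolled (open-loop) trial: blanket off.
OPEN_LOOP_SETTING = DeviceSetting(HeatLevel.AMBIENT21, FanSpeed.STANDBY)


def generate_trial(
    config: PlantConfig,
    controller_config: ControllerConfig | None = None,
    duration: float = 90 * 3600.0,
    *,
    seed: int | None = None,
    label: str = "synthetic",
    open_loop_setting: DeviceSetting = OPEN_LOOP_SETTING,
    record_core: bool = False,
) -> TrialSeries:
    """Roll out the plant for ``duration`` seconds at 1 Hz.

    With a controller config, the loop is closed: each second the measured
    sample is fed to the controller, any emitted setting is applied to the
    device emulator via front-panel key presses, and the plant integrates
    under the device's current setting.  Without one, the setting column is
    held at ``open_loop_setting`` (the uncontrolled scenario).

    The recorded setting in each row is the device state in effect during
    that second, i.e. after any controller action on that second's sample —
    so replaying the recorded temperatures through the same controller
    configuration regenerates the recorded settings exactly.

    ``record_core`` adds a ``core_c`` column holding the plant's true core
    temperature (no sensor noise or artifacts), for judging closed-loop
    performance against the subject's actual state rather than the corrupted
    measurement channel.
    """
    duration = int(duration)
    if controller_config is not None and duration < controller_config.eval_interval:
        raise ValueError("duration must be at least one evaluation interval")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    state = PlantState(time=0.0, core_temp=config.initial_temp)

    controller = emulator = None
    if controller_config is not None:
        controller = Controller(controller_config)
        # the loop starts from the neutral state s=0; park the device there
        emulator = BairHuggerEmulator(state_to_setting(0.0))
        setting = emulator.setting
    else:
        setting = open_loop_setting

    n = duration
    times = np.empty(n, dtype=np.int64)
    temps = np.empty(n, dtype=np.float64)
    cores = np.empty(n, dtype=np.float64) if record_core else None
    heats: list[str] = []
    speeds: list[str] = []
    for i in range(n):
        sample = measure(state, config, rng)
        if controller is not None:
            commanded = controller.feed(sample)
            if commanded is not None and commanded != emulator.setting:
                emulator.apply_setting(commanded)
            setting = emulator.setting
        times[i] = int(state.time)
        temps[i] = sample.temp
        if cores is not None:
            cores[i] = state.core_temp
        heats.append(setting.heat.value)
        speeds.append(setting.speed.value)
        state = plant_step(state, setting, config, dt=1.0)

    metadata = {
        "label": label,
        "seed": config.seed if seed is None else seed,
        "controlled": controller_config is not None,
    }
    if controller_config is not None:
        metadata["target_temp"] = controller_config.target_temp
    series = make_series(times, temps, heats, speeds, metadata=metadata)
    if cores is not None:
        series.df["core_c"] = cores
    return series


def config_grid(
    base: PlantConfig,
    masses: Sequence[float] = (30.0, 45.0, 60.0),
    fever_scales: Sequence[float] = (0.0, 1.0, 2.0),
) -> list[PlantConfig]:
    """Documented robustness grid: subject mass 30-60 kg crossed with fever
    power 0-2x the default peak."""
    return [
        replace(base, mass=m, fever_peak_power=base.fever_peak_power * f)
        for m in masses
        for f in fever_scales
    ]
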