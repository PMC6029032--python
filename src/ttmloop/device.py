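"""Emulation of a forced-air patient warming unit (3M Bair Hugger 755 class)
and the byte-level serial protocol of its remote-control add-on board.

The physical unit accepts a small, quantized setting space: four heat levels
(ambient air, nominally 21 °C room temperature, plus 32 °C, 38 °C and 43 °C,
each held within ±1.5 °C by the unit) and three blower speeds (standby, slow
at ~20 L/s, fast at ~23 L/s).  Front-panel LEDs expose the active setting plus
a fault and a temperature-in-range indicator; an add-on microcontroller board
reads those LEDs (ten input pins), simulates front-panel key presses
(eight switches) and talks to a host computer over a serial line.

The protocol emulated here is the add-on board's: ASCII payloads framed by
STX (0x02) and ETX (0x03).  The board reports the LED state once per second
as a 10-character string of '0'/'1'; the host selects settings by sending
``S:X`` where X is the switch number 1–8.

The true LED pin order and switch wiring are not published; this module fixes
a canonical, documented assignment (see :data:`LED_ORDER`,
:data:`SPEED_SWITCHES`, :data:`HEAT_SWITCHES`) and lets callers supply their
own maps.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

STX = 0x02
ETX = 0x03

#: Documentation constants of the emulated hardware; no bit-level timing is
#: simulated.
BAUD_RATE = 9600
PRESS_DURATION_S = 0.150
STATUS_PERIOD_S = 1.0


class ProtocolError(ValueError):
    """Malformed frame or payload on the emulated serial link."""


class HeatLevel(str, enum.Enum):
    """Heat setting of the warming unit.

    ``AMBIENT21`` blows unheated room air (about 21 °C in the reference
    setting); the other three are the unit's regulated set points.
    """

    AMBIENT21 = "21"
    C32 = "32"
    C38 = "38"
    C43 = "43"

    @property
    def nominal_temp(self) -> float | None:
        """Regulated set point in °C, or ``None`` for ambient air."""
        return None if self is HeatLevel.AMBIENT21 else float(self.value)


class FanSpeed(str, enum.Enum):
    STANDBY = "standby"
    SLOW = "slow"
    FAST = "fast"


@dataclass(frozen=True)
class DeviceSetting:
    """Actuator command tuple: one heat level and one fan speed."""

    heat: HeatLevel
    speed: FanSpeed

    def __post_init__(self) -> None:
        if not isinstance(self.heat, HeatLevel):
            object.__setattr__(self, "heat", HeatLevel(str(self.heat)))
        if not isinstance(self.speed, FanSpeed):
            object.__setattr__(self, "speed", FanSpeed(str(self.speed)))


#: All 12 valid settings (4 heat levels x 3 speeds).
ALL_SETTINGS: tuple[DeviceSetting, ...] = tuple(
    DeviceSetting(h, s) for h in HeatLevel for s in FanSpeed
)


@dataclass(frozen=True)
class DeviceStatus:
    """Snapshot of the unit's ten status indicators.

    The tenth indicator input is unassigned on the emulated board and is
    modeled as a reserved bit.
    """

    setting: DeviceSetting
    fault: bool = False
    temp_in_range: bool = False
    reserved: bool = False


#: Canonical indicator order of the 10-bit status payload.
LED_ORDER: tuple[str, ...] = (
    "fault",
    "temp_in_range",
    "standby",
    "slow",
    "fast",
    "ambient",
    "c32",
    "c38",
    "c43",
    "reserved",
)

_SPEED_LEDS = {"standby": FanSpeed.STANDBY, "slow": FanSpeed.SLOW, "fast": FanSpeed.FAST}
_HEAT_LEDS = {
    "ambient": HeatLevel.AMBIENT21,
    "c32": HeatLevel.C32,
    "c38": HeatLevel.C38,
    "c43": HeatLevel.C43,
}


def frame(payload: str) -> bytes:
    """Wrap an ASCII payload in STX/ETX framing."""
    if any(ord(c) in (STX, ETX) for c in payload):
        raise ProtocolError("payload must not contain STX/ETX")
    try:
        body = payload.encode("ascii")
    except UnicodeEncodeError as exc:  # pragma: no cover - defensive
        raise ProtocolError(f"payload is not ASCII: {payload!r}") from exc
    return bytes([STX]) + body + bytes([ETX])


def unframe(data: bytes) -> str:
    """Strip and validate STX/ETX framing, returning the ASCII payload."""
    if len(data) < 2 or data[0] != STX or data[-1] != ETX:
        raise ProtocolError(f"bad framing: {data!r} (expected STX ... ETX)")
    body = data[1:-1]
    if STX in body or ETX in body:
        raise ProtocolError(f"framing bytes inside payload: {data!r}")
    return body.decode("ascii")


def encode_status(status: DeviceStatus, led_order: Sequence[str] = LED_ORDER) -> bytes:
    """Encode a status as an STX-framed 10-character '0'/'1' string."""
    flags = {
        "fault": status.fault,
        "temp_in_range": status.temp_in_range,
        "reserved": status.reserved,
    }
    for name, speed in _SPEED_LEDS.items():
        flags[name] = status.setting.speed is speed
    for name, heat in _HEAT_LEDS.items():
        flags[name] = status.setting.heat is heat
    return frame("".join("1" if flags[name] else "0" for name in led_order))


def decode_status(data: bytes, led_order: Sequence[str] = LED_ORDER) -> DeviceStatus:
    """Decode an STX-framed status frame; inverse of :func:`encode_status`.

    Exactly one speed bit and exactly one heat bit must be set (anything else
    cannot name a valid :class:`DeviceSetting`).
    """
    payload = unframe(data)
    if len(payload) != len(led_order) or set(payload) - {"0", "1"}:
        raise ProtocolError(
            f"status payload must be {len(led_order)} binary digits, got {payload!r}"
        )
    flags = {name: bit == "1" for name, bit in zip(led_order, payload)}
    speeds = [s for name, s in _SPEED_LEDS.items() if flags[name]]
    heats = [h for name, h in _HEAT_LEDS.items() if flags[name]]
    if len(speeds) != 1:
        raise ProtocolError(f"expected exactly one speed bit, got {len(speeds)}: {payload!r}")
    if len(heats) != 1:
        raise ProtocolError(f"expected exactly one heat bit, got {len(heats)}: {payload!r}")
    return DeviceStatus(
        setting=DeviceSetting(heats[0], speeds[0]),
        fault=flags["fault"],
        temp_in_range=flags["temp_in_range"],
        reserved=flags["reserved"],
    )


def encode_command(switch_number: int) -> bytes:
    """Encode a switch-press command ``S:X`` for switch 1–8."""
    if not isinstance(switch_number, int) or not 1 <= switch_number <= 8:
        raise ValueError(f"switch number must be in 1..8, got {switch_number!r}")
    return frame(f"S:{switch_number}")


def decode_command(data: bytes) -> int:
    """Decode a framed ``S:X`` command to its switch number."""
    payload = unframe(data)
    if len(payload) != 3 or not payload.startswith("S:") or not payload[2].isdigit():
        raise ProtocolError(f"not a switch command: {payload!r}")
    number = int(payload[2])
    if not 1 <= number <= 8:
        raise ProtocolError(f"switch number out of range 1..8: {number}")
    return number


#: Canonical switch wiring: 1-3 select the speed, 4-7 the heat level,
#: switch 8 is unassigned (a press is a no-op).
SPEED_SWITCHES: Mapping[int, FanSpeed] = {
    1: FanSpeed.STANDBY,
    2: FanSpeed.SLOW,
    3: FanSpeed.FAST,
}
HEAT_SWITCHES: Mapping[int, HeatLevel] = {
    4: HeatLevel.AMBIENT21,
    5: HeatLevel.C32,
    6: HeatLevel.C38,
    7: HeatLevel.C43,
}


def press_switch(
    setting: DeviceSetting,
    switch_number: int,
    speed_switches: Mapping[int, FanSpeed] = SPEED_SWITCHES,
    heat_switches: Mapping[int, HeatLevel] = HEAT_SWITCHES,
) -> DeviceSetting:
    """Apply one front-panel key press to a setting.

    Presses are instantaneous discrete events (the physical 150 ms hold is
    not modeled).  Re-pressing the active selection, or pressing an
    unassigned switch, leaves the setting unchanged.
    """
    if not 1 <= switch_number <= 8:
        raise ValueError(f"switch number must be in 1..8, got {switch_number!r}")
    if switch_number in speed_switches:
        return replace(setting, speed=speed_switches[switch_number])
    if switch_number in heat_switches:
        return replace(setting, heat=heat_switches[switch_number])
    return setting


def presses_for_transition(
    current: DeviceSetting,
    target: DeviceSetting,
    speed_switches: Mapping[int, FanSpeed] = SPEED_SWITCHES,
    heat_switches: Mapping[int, HeatLevel] = HEAT_SWITCHES,
) -> list[int]:
    """Minimal switch-press sequence mapping ``current`` to ``target``.

    At most two presses are ever needed (one heat, one speed); heat is
    pressed first by convention.
    """
    heat_by_level = {level: number for number, level in heat_switches.items()}
    speed_by_level = {speed: number for number, speed in speed_switches.items()}
    presses: list[int] = []
    if target.heat is not current.heat:
        presses.append(heat_by_level[target.heat])
    if target.speed is not current.speed:
        presses.append(speed_by_level[target.speed])
    return presses


def airflow(speed: FanSpeed) -> float:
    """Blower airflow in L/s: 23 fast, 20 slow, 0 in standby."""
    return {FanSpeed.FAST: 23.0, FanSpeed.SLOW: 20.0, FanSpeed.STANDBY: 0.0}[FanSpeed(speed)]


def delivered_air_temp(
    setting: DeviceSetting, ambient: float = 21.0, bias: float = 0.0
) -> float:
    """Temperature of the delivered air stream in °C.

    Regulated levels return their nominal set point; the ambient level
    returns the supplied room temperature.  ``bias`` models the unit's
    regulation band and must stay within the ±1.5 °C the hardware holds.
    """
    if abs(bias) > 1.5:
        raise ValueError(f"bias {bias} exceeds the unit's +/-1.5 degC regulation band")
    nominal = setting.heat.nominal_temp
    if nominal is None:
        return float(ambient)
    return nominal + bias


class BairHuggerEmulator:
    """Software stand-in for the warming unit plus its add-on board.

    The emulator holds the current :class:`DeviceSetting` and the fault /
    temperature-in-range indicators, consumes framed ``S:X`` command bytes
    via :meth:`handle`, and emits one framed status message per simulated
    second via :meth:`tick` (the board's 1 Hz reporting cadence).
    """

    def __init__(
        self,
        setting: DeviceSetting = DeviceSetting(HeatLevel.AMBIENT21, FanSpeed.STANDBY),
        *,
        speed_switches: Mapping[int, FanSpeed] = SPEED_SWITCHES,
        heat_switches: Mapping[int, HeatLevel] = HEAT_SWITCHES,
        led_order: Sequence[str] = LED_ORDER,
    ) -> None:
        self.setting = setting
        self.fault = False
        self.temp_in_range = False
        self.time = 0.0
        self._speed_switches = speed_switches
        self._heat_switches = heat_switches
        self._led_order = led_order

    def press(self, switch_number: int) -> DeviceSetting:
        """Simulate a front-panel key press; returns the new setting."""
        self.setting = press_switch(
            self.setting, switch_number, self._speed_switches, self._heat_switches
        )
        return self.setting

    def apply_setting(self, target: DeviceSetting) -> list[int]:
        """Drive the unit to ``target`` via key presses; returns the presses."""
        presses = presses_for_transition(
            self.setting, target, self._speed_switches, self._heat_switches
        )
        for number in presses:
            self.press(number)
        return presses

    def handle(self, data: bytes) -> None:
        """Process one framed command received from the host."""
        self.press(decode_command(data))

    def status(self) -> DeviceStatus:
        return DeviceStatus(
            setting=self.setting, fault=self.fault, temp_in_range=self.temp_in_range
        )

    def tick(self) -> bytes:
        """Advance one second of emulated time and emit the status frame."""
        self.time += STATUS_PERIOD_S
        return encode_status(self.status(), self._led_order)
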