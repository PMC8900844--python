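"""European XFEL pulse-train timing and sample-replenishment requirements.

The EuXFEL delivers X-rays in 10 Hz bursts ("trains") of up to 2700
femtosecond pulses.  Within a train, consecutive pulses are separated by as
little as ~222 ns (a 4.5 MHz intra-train repetition rate).  A liquid jet
carrying crystals through the interaction region must move each probed
sample volume out of the way before the next pulse (or the next pump-probe
cycle) arrives, which ties the machine timing directly to a minimum jet
velocity:

    v_required = dx * f_pulse / k

where ``dx`` is the displacement a sample volume must achieve between
consecutive events, ``f_pulse`` is the intra-train repetition rate and
``k`` an optional integer divisor for pump lasers running at a sub-multiple
of the X-ray rate.

Canonical machine modes are stored by their exact inter-pulse spacings
(221.6, 443.3, 886.5, 1773.0 ns).  The repetition rates quoted alongside
them ("4.51 MHz", "1.13 MHz", ...) are rounded labels; rates are always
derived from the spacings so that timing arithmetic is self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PulsePattern:
    """An X-ray delivery mode.

    Parameters
    ----------
    pulse_spacing_ns:
        Time between two consecutive pulses within a train, in nanoseconds.
    pulses_per_train:
        Number of pulses per 10 Hz train (0 is allowed for bookkeeping,
        but duration queries then fail).
    train_rate_hz:
        Train repetition rate; 10 Hz at the EuXFEL.
    label:
        Free-text mode name, e.g. ``"1.13 MHz mode"``.
    """

    pulse_spacing_ns: float
    pulses_per_train: int
    train_rate_hz: float = 10.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.pulse_spacing_ns <= 0:
            raise ValueError("pulse_spacing_ns must be positive")
        if self.pulses_per_train < 0 or int(self.pulses_per_train) != self.pulses_per_train:
            raise ValueError("pulses_per_train must be a non-negative integer")
        if self.train_rate_hz <= 0:
            raise ValueError("train_rate_hz must be positive")

    @property
    def intra_train_rate_hz(self) -> float:
        """Intra-train pulse repetition rate, 1 / spacing."""
        return 1e9 / self.pulse_spacing_ns


#: The four canonical EuXFEL example settings (SPB/SFX instrument).
#: Keys are the rounded intra-train-rate labels commonly used in print.
CANONICAL_MODES: dict[str, PulsePattern] = {
    "4.51 MHz": PulsePattern(221.6, 2700, label="4.51 MHz mode"),
    "2.26 MHz": PulsePattern(443.3, 1350, label="2.26 MHz mode"),
    "1.13 MHz": PulsePattern(886.5, 352, label="1.13 MHz mode"),
    "0.564 MHz": PulsePattern(1773.0, 202, label="0.564 MHz mode"),
}


def canonical_mode(name: str) -> PulsePattern:
    """Look up a canonical mode by label, tolerant of spacing/case ("1.13MHz")."""
    key = name.replace(" ", "").removesuffix("mode").lower()
    for label, pattern in CANONICAL_MODES.items():
        if label.replace(" ", "").lower() == key:
            return pattern
    raise KeyError(f"unknown pulse mode {name!r}; known: {list(CANONICAL_MODES)}")


@dataclass(frozen=True)
class ReplenishmentRequirement:
    """Sample-displacement requirement between consecutive pump or probe events.

    ``displacement_um`` is the distance a probed sample volume must travel
    before the next relevant pulse; for pump-probe schemes where the pump
    laser runs at the intra-train rate divided by ``pump_divisor``, the
    effective event rate drops accordingly.
    """

    displacement_um: float
    pump_divisor: int = 1

    def __post_init__(self) -> None:
        if self.displacement_um < 0:
            raise ValueError("displacement_um must be non-negative")
        if self.pump_divisor < 1 or int(self.pump_divisor) != self.pump_divisor:
            raise ValueError("pump_divisor must be an integer >= 1")


def pulse_spacing(pattern: PulsePattern) -> float:
    """Time between two pulses within a train, in ns."""
    return pattern.pulse_spacing_ns


def train_duration(pattern: PulsePattern) -> float:
    """Duration of one pulse train in microseconds.

    Uses the ``n_pulses * spacing`` convention, which reproduces all four
    published train durations (598/598/312/358 us).  Report rounded to the
    nearest microsecond to match the published granularity.
    """
    if pattern.pulses_per_train == 0:
        raise ValueError("empty train: duration undefined for zero pulses")
    return pattern.pulses_per_train * pattern.pulse_spacing_ns * 1e-3


def pulses_per_second(pattern: PulsePattern) -> float:
    """Total pulses delivered per second: pulses per train x train rate."""
    return pattern.pulses_per_train * pattern.train_rate_hz


def required_jet_velocity(req: ReplenishmentRequirement, pattern: PulsePattern) -> float:
    """Minimum jet velocity (m/s) achieving the requested displacement.

    v = dx * (intra-train rate / pump_divisor).  A zero displacement
    requirement trivially yields zero.
    """
    rate = pattern.intra_train_rate_hz / req.pump_divisor
    return req.displacement_um * 1e-6 * rate


def displacement_between_pulses(velocity_m_s: float, pattern: PulsePattern) -> float:
    """Displacement (um) a jet at ``velocity_m_s`` covers between two pulses.

    Halving the intra-train rate doubles the displacement; this is the exact
    inverse of :func:`required_jet_velocity` with unit pump divisor.
    """
    if velocity_m_s < 0:
        raise ValueError("velocity must be non-negative")
    return velocity_m_s / pattern.intra_train_rate_hz * 1e6
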