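"""Stress input protocols gamma(t).

The model is driven by a non-negative stress input gamma(t) (arbitrary stress
units per day).  Four protocol kinds cover the experimental situations:

``none``
    unstressed control, gamma(t) = 0;
``pulse``
    an irradiation exposure, gamma(t) = gamma on
    [pulse_start, pulse_start + pulse_duration) and 0 otherwise
    (right-continuous at both edges);
``constant``
    sustained stress, e.g. culture at atmospheric (20%) oxygen;
``linear``
    slowly accumulating replicative stress gamma(t) = alpha + beta*t, with a
    time-independent offset alpha and an accrual slope beta (telomere
    shortening, accumulating oxidative damage).

Pulses are represented exactly and exposed as solver breakpoints: a 27-second
exposure would otherwise be stepped over by adaptive step-size control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

__all__ = [
    "StressProtocol",
    "gamma_at",
    "irradiation_protocol",
    "SECONDS",
    "MINUTES",
]

#: one second / one minute expressed in days
SECONDS = 1.0 / 86400.0
MINUTES = 1.0 / 1440.0

_KINDS = ("none", "pulse", "constant", "linear")


@dataclass(frozen=True)
class StressProtocol:
    """A gamma(t) specification (all times in days, stress in units/day)."""

    kind: str = "none"
    gamma: float = 0.0
    pulse_start: float = 0.0
    pulse_duration: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}; expected one of {_KINDS}")
        for name in ("gamma", "pulse_start", "pulse_duration", "alpha", "beta"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0:
                # beta >= 0 keeps gamma(t) >= 0 for all t >= 0
                raise ValueError(f"{name} must be >= 0, got {v!r}")

    # -- evaluation -------------------------------------------------------
    def gamma_at(self, t: float) -> float:
        """Stress level at time ``t`` (days); raises for negative ``t``."""
        if t < 0:
            raise ValueError(f"t must be >= 0, got {t!r}")
        if self.kind == "none":
            return 0.0
        if self.kind == "constant":
            return self.gamma
        if self.kind == "pulse":
            if self.pulse_start <= t < self.pulse_start + self.pulse_duration:
                return self.gamma
            return 0.0
        return self.alpha + self.beta * t

    def breakpoints(self, t_end: float) -> list[float]:
        """Discontinuity times in (0, t_end) at which the solver must restart."""
        if self.kind != "pulse" or self.pulse_duration == 0.0:
            return []
        edges = (self.pulse_start, self.pulse_start + self.pulse_duration)
        return [t for t in edges if 0.0 < t < t_end]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StressProtocol":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown StressProtocol keys: {sorted(unknown)}")
        return cls(**d)


def gamma_at(protocol: StressProtocol, t: float) -> float:
    """Functional alias for :meth:`StressProtocol.gamma_at`."""
    return protocol.gamma_at(t)


def irradiation_protocol(
    dose_label: str,
    gamma_amplitude: float,
    duration: float,
    *,
    exposure_time: float = 1.0,
) -> StressProtocol:
    """Pulse protocol for a gamma-irradiation exposure.

    Parameters
    ----------
    dose_label:
        Free-form label such as ``"2Gy"``; kept for bookkeeping only (the
        Gy -> gamma mapping is an asserted constant, not modelled).
    gamma_amplitude:
        Pulse height in stress units/day.
    duration:
        Exposure duration in days (use the :data:`SECONDS`/:data:`MINUTES`
        constants for printed exposure times).  ``0`` yields the unstressed
        ``none`` protocol.
    exposure_time:
        Pulse start in days; cultures are seeded one day before exposure,
        hence the default of 1.
    """
    if gamma_amplitude < 0:
        raise ValueError(f"gamma_amplitude must be >= 0, got {gamma_amplitude!r}")
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration!r}")
    if duration == 0.0:
        return StressProtocol(kind="none")
    return StressProtocol(
        kind="pulse",
        gamma=gamma_amplitude,
        pulse_start=exposure_time,
        pulse_duration=duration,
    )
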