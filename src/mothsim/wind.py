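"""Prescribed wind field: constant streamwise flow plus sinusoidal meandering.

The wind is spatially uniform.  Its streamwise component is a constant mean
speed ``A``; its crosswind component is a slow, large-amplitude sinusoid
``B * sin(omega * t)`` that swings the odor plume laterally (meandering).
Optionally a zero-mean white noise of amplitude ``beta`` is added to both
components to mimic turbulent velocity fluctuations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np


class Velocity(NamedTuple):
    """Local wind vector: streamwise component u, crosswind component v (m/s)."""

    u: float
    v: float


@dataclass(frozen=True)
class WindParams:
    """Parameters of the forcing wind field.

    Parameters
    ----------
    mean_speed:
        Constant streamwise speed A (m/s).
    meander_amplitude:
        Amplitude B of the crosswind sinusoid (m/s).
    meander_omega:
        Angular rate omega of the meandering (rad/s); the meandering period
        is ``2*pi/omega``.
    noise_amplitude:
        Amplitude beta of the optional white noise (m/s); each component
        receives an independent draw from ``U[-beta, +beta]`` per evaluation.
        The benchmark study runs with ``beta = 0``.
    phase:
        Phase offset (rad) of the meandering sinusoid.  A trial started at a
        random point of the meandering cycle is equivalent to a trial with a
        random phase.
    """

    mean_speed: float = 1.0
    meander_amplitude: float = 0.0
    meander_omega: float = 0.1
    noise_amplitude: float = 0.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mean_speed", "meander_amplitude", "meander_omega",
                     "noise_amplitude"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")

    @property
    def period(self) -> float:
        """Meandering period 2*pi/omega (s); inf when omega = 0."""
        return 2.0 * math.pi / self.meander_omega if self.meander_omega > 0 else math.inf

    def replace(self, **changes) -> "WindParams":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


def wind_velocity(params: WindParams, t: float,
                  rng: np.random.Generator | None = None) -> Velocity:
    """Evaluate the wind vector at time ``t``.

    The field has no spatial dependence, so no position argument is needed.
    With ``noise_amplitude = 0`` the result is deterministic and ``rng`` is
    not consulted.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    u = params.mean_speed
    v = params.meander_amplitude * math.sin(params.meander_omega * t + params.phase)
    if params.noise_amplitude > 0.0:
        if rng is None:
            raise ValueError("rng required when noise_amplitude > 0")
        beta = params.noise_amplitude
        u += rng.uniform(-beta, beta)
        v += rng.uniform(-beta, beta)
    return Velocity(u, v)
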