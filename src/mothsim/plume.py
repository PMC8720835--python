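"""Puff-based odor plume: release, advection, growth, concentration, detection.

The source emits discrete *puffs* — parcels of odorant that are carried
passively by the (spatially uniform) wind and spread as they age.  Each puff
is a 2-D Gaussian blob: its squared width ``s`` starts at ``r0**2`` and grows
linearly in time at the spread rate ``sigma`` (m^2/s), so the peak
concentration ``m_p / (2 s)`` decays as the puff disperses.  A navigator
carries a binary sensor: it "detects" odor wherever the summed concentration
meets a threshold ``C0``, which for a single puff is a disc of radius

    r_det(s)^2 = 2 s ln(m_p / (2 s C0))

around the puff center (empty once the peak falls below the threshold).

Because the wind is spatially uniform, all puffs share the same displacement
history; the state therefore stores one running displacement integral and,
per puff, the value of that integral at birth.  This makes advection and
growth O(1) per step regardless of the number of active puffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .domain import DEFAULT_DOMAIN, SOURCE_POSITION, Domain
from .wind import Velocity, WindParams, wind_velocity

__all__ = [
    "PlumeParams",
    "SensorParams",
    "Puff",
    "PlumeState",
    "advect_puff",
    "grow_puff",
    "release_puffs",
    "concentration_at",
    "detect",
    "step_plume",
    "detection_radius_squared",
    "max_detection_radius",
]


@dataclass(frozen=True)
class PlumeParams:
    """Source and dispersion parameters.

    Parameters
    ----------
    source_position:
        Location of the emitting source (m).
    release_rate:
        Puff release rate f_r (puffs/s).
    r0:
        Initial puff radius at release (m).
    spread_rate:
        Linear growth rate sigma of the squared puff radius (m^2/s).
    puff_mass:
        Odorant mass m_p per puff (arbitrary units).
    transverse_diffusivity:
        Table-level transverse diffusivity R (m^2/s).  Carried for
        configuration fidelity; it enters no equation of this model and is
        unused by default.
    """

    source_position: tuple[float, float] = SOURCE_POSITION
    release_rate: float = 100.0
    r0: float = 0.001
    spread_rate: float = 0.0002
    puff_mass: float = 1.0
    transverse_diffusivity: float = 0.5

    def __post_init__(self) -> None:
        if self.release_rate <= 0:
            raise ValueError("release_rate must be > 0")
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0")
        if self.spread_rate < 0:
            raise ValueError("spread_rate must be >= 0")
        if self.puff_mass <= 0:
            raise ValueError("puff_mass must be > 0")

    def replace(self, **changes) -> "PlumeParams":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


@dataclass(frozen=True)
class SensorParams:
    """Binary odor sensor: fires where concentration >= threshold C0 (a.u.).

    The default threshold is the benchmark calibration: with unit puff mass
    it keeps the whole spread-rate treatment ladder (sigma up to 4e-4 m^2/s)
    detectable out to the navigator release point.
    """

    threshold: float = 620.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


@dataclass
class Puff:
    """A single odor puff: Gaussian blob center, squared width, birth time."""

    x: float
    y: float
    r_squared: float
    birth_time: float = 0.0


def advect_puff(puff: Puff, wind: Velocity, dt: float) -> Puff:
    """One explicit-Euler advection step: the center rides the wind."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return Puff(puff.x + wind.u * dt, puff.y + wind.v * dt,
                puff.r_squared, puff.birth_time)


def grow_puff(puff: Puff, params: PlumeParams, dt: float) -> Puff:
    """One growth step: squared radius increases linearly at rate sigma."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return Puff(puff.x, puff.y, puff.r_squared + params.spread_rate * dt,
                puff.birth_time)


def detection_radius_squared(s: float, puff_mass: float, threshold: float) -> float:
    """Squared radius of the above-threshold disc of one puff of width ``s``.

    Negative when the puff's peak concentration is already below threshold
    (no point detects it); zero exactly at peak == threshold.
    """
    return 2.0 * s * math.log(puff_mass / (2.0 * s * threshold))


def max_detection_radius(params: PlumeParams, sensor: SensorParams) -> float:
    """Largest detection-disc radius any puff attains over its lifetime.

    ``r_det(s)^2 = 2 s ln(m_p/(2 s C0))`` is maximised at
    ``s* = m_p / (2 C0 e)``; clip to the attainable range ``s >= r0^2``.
    """
    s_death = params.puff_mass / (2.0 * sensor.threshold)
    s_star = s_death / math.e
    s0 = params.r0 ** 2
    best = 0.0
    for s in (max(s_star, s0), s0):
        if s < s_death:
            best = max(best, detection_radius_squared(s, params.puff_mass,
                                                      sensor.threshold))
    return math.sqrt(max(best, 0.0))


class PlumeState:
    """Population of active puffs plus release bookkeeping.

    Internally each puff stores the running wind-displacement integral at its
    birth; its current center is ``source + (D(t) - D(birth))``.
    """

    def __init__(self, params: PlumeParams, domain: Domain = DEFAULT_DOMAIN):
        self.params = params
        self.domain = domain
        self.clock = 0.0
        self.release_accumulator = 0.0
        self.released = 0
        self.pruned = 0
        # per-puff birth records
        self._dxb = np.empty(0)
        self._dyb = np.empty(0)
        self._tb = np.empty(0)
        # running displacement integral D(t)
        self._dx = 0.0
        self._dy = 0.0

    # ------------------------------------------------------------------ views

    @property
    def n_active(self) -> int:
        return self._tb.size

    def positions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Current puff centers and squared widths as arrays (x, y, r2)."""
        sx, sy = self.params.source_position
        x = sx + (self._dx - self._dxb)
        y = sy + (self._dy - self._dyb)
        r2 = self.params.r0 ** 2 + self.params.spread_rate * (self.clock - self._tb)
        return x, y, r2

    def puffs(self) -> list[Puff]:
        x, y, r2 = self.positions()
        return [Puff(float(xi), float(yi), float(r2i), float(tbi))
                for xi, yi, r2i, tbi in zip(x, y, r2, self._tb)]

    # ------------------------------------------------------------------ steps

    def release(self, dt: float) -> int:
        """Accumulate fractional puffs and append the whole ones at the source."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.release_accumulator += self.params.release_rate * dt
        n_new = int(math.floor(self.release_accumulator))
        self.release_accumulator -= n_new
        if n_new:
            self._dxb = np.append(self._dxb, np.full(n_new, self._dx))
            self._dyb = np.append(self._dyb, np.full(n_new, self._dy))
            self._tb = np.append(self._tb, np.full(n_new, self.clock))
            self.released += n_new
        return n_new

    def _prune(self) -> None:
        x, y, r2 = self.positions()
        r = np.sqrt(r2)
        sx, sy = self.params.source_position
        d = self.domain
        keep = ((x <= d.x_max + r) & (x >= d.x_min - r)
                & (y <= d.y_max + r) & (y >= d.y_min - r))
        n_drop = int((~keep).sum())
        if n_drop:
            self._dxb = self._dxb[keep]
            self._dyb = self._dyb[keep]
            self._tb = self._tb[keep]
            self.pruned += n_drop

    def step(self, wind: Velocity, dt: float) -> None:
        """Advance one timestep: advect, grow, release, prune, tick the clock.

        The wind is held constant over the step (zero-order hold).
        """
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self._dx += wind.u * dt
        self._dy += wind.v * dt
        self.clock += dt
        # growth is implicit: widths are computed from age at the state clock;
        # releasing after the tick leaves a newborn puff at r^2 = r0^2 at the
        # end of the step
        self.release(dt)
        self._prune()

    # ------------------------------------------------------------ field views

    def concentration_at(self, x: float, y: float) -> float:
        """Summed Gaussian concentration of all active puffs at a point (a.u.)."""
        if self.n_active == 0:
            return 0.0
        px, py, r2 = self.positions()
        s = r2  # Gaussian squared width is tied to the squared puff radius
        d2 = (px - x) ** 2 + (py - y) ** 2
        mp = self.params.puff_mass
        return float(np.sum(mp / (2.0 * s) * np.exp(-d2 / (2.0 * s))))

    def detect(self, sensor: SensorParams, x: float, y: float) -> bool:
        """Binary sensor: is the point inside any puff's above-threshold disc?

        Equivalent to ``concentration_at(x, y) >= C0`` for non-overlapping
        puffs; the benchmark adopts the per-puff disc form throughout.
        """
        if self.n_active == 0:
            return False
        px, py, r2 = self.positions()
        s = r2
        d2 = (px - x) ** 2 + (py - y) ** 2
        mp = self.params.puff_mass
        with np.errstate(divide="ignore", invalid="ignore"):
            rdet2 = 2.0 * s * np.log(mp / (2.0 * s * sensor.threshold))
        return bool(np.any(d2 <= rdet2))


# ------------------------------------------------------- functional interface


def release_puffs(state: PlumeState, params: PlumeParams, dt: float,
                  rng: np.random.Generator | None = None) -> PlumeState:
    """Release step on ``state`` (which must carry ``params``); returns state."""
    assert state.params is params or state.params == params
    state.release(dt)
    return state


def concentration_at(state: PlumeState, params: PlumeParams,
                     x: Sequence[float], t: float | None = None) -> float:
    return state.concentration_at(x[0], x[1])


def detect(state: PlumeState, sensor: SensorParams, params: PlumeParams,
           x: Sequence[float], t: float | None = None) -> bool:
    return state.detect(sensor, x[0], x[1])


def step_plume(state: PlumeState, wind_params: WindParams, params: PlumeParams,
               dt: float, rng: np.random.Generator | None = None) -> PlumeState:
    """Advance the plume one step, evaluating the wind at the state clock."""
    wind = wind_velocity(wind_params, state.clock, rng)
    state.step(wind, dt)
    return state
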