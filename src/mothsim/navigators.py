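"""Moth-inspired navigation state machines (models A1, A2, B1, B2).

All four navigators share the same sensorimotor repertoire, inspired by the
odor-tracking flight of male moths:

* **detection** — while the binary sensor is on, fly straight upwind; the
  contiguous on-time is the puff-crossing (detection) time ``t_c``;
* **surging** — after losing the signal, keep flying upwind for a budget
  ``lambda``;
* **casting / zigzagging** — if the surge ends without re-detection, fly
  alternating crosswind legs of half-period ``delta1``;
* **sweeping** (strategy B only) — after a fixed number of casting
  half-cycles, one long crosswind excursion of duration
  ``delta2 = sweep_multiplier * delta1`` in a random direction.

Strategy A (models A1, A2) is *temporal*: its budgets derive from the last
detection time, ``lambda = t_c`` and ``delta1 = alpha * t_c`` (A1, with
``alpha = 1.5``) or ``delta1 = alpha * growth**k * t_c`` growing with the
half-cycle index k (A2).  Strategy A never sweeps.  Strategy B uses fixed
constants ``lambda`` and ``delta1`` and adds the sweep, with multiplier 7
(B1) or 3 (B2).

A new detection interrupts any mode and resets ``t_c``.  Navigators move at
a constant ground speed and steer relative to the *instantaneous local*
wind direction (optomotor anemotaxis); no neural processing, memory, or
global positioning is modelled.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

from .domain import (DEFAULT_DOMAIN, SOURCE_POSITION, START_POSITION,
                     SUCCESS_RADIUS, Domain)
from .plume import PlumeState, SensorParams
from .wind import Velocity

__all__ = ["Mode", "StrategyParams", "NavigatorState", "init_navigator",
           "transition", "heading", "step_navigator", "MODEL_IDS"]

MODEL_IDS = ("A1", "A2", "B1", "B2")


class Mode(enum.Enum):
    WAITING = "waiting"
    DETECTING = "detecting"
    SURGING = "surging"
    CASTING = "casting"
    SWEEPING = "sweeping"
    DONE_SUCCESS = "done_success"
    DONE_FAILED = "done_failed"

    @property
    def terminal(self) -> bool:
        return self in (Mode.DONE_SUCCESS, Mode.DONE_FAILED)


@dataclass(frozen=True)
class StrategyParams:
    """Tunable constants of one navigation model.

    ``alpha``/``alpha_growth`` drive strategy A's detection-time-based
    budgets; ``surge_time``/``cast_time`` are strategy B's fixed budgets;
    ``sweep_multiplier`` (7 for B1, 3 for B2) scales the sweep duration;
    ``cast_half_cycles`` is the number of casting half-cycles strategy B
    completes before each sweep.
    """

    model_id: str
    alpha: float = 1.5
    alpha_growth: float = 1.1
    surge_time: float = 0.5
    cast_time: float = 1.5
    sweep_multiplier: float | None = None
    cast_half_cycles: int = 4
    ground_speed: float = 0.4

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.ground_speed <= 0:
            raise ValueError("ground_speed must be > 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.strategy == "B":
            default = 7.0 if self.model_id == "B1" else 3.0
            if self.sweep_multiplier is None:
                object.__setattr__(self, "sweep_multiplier", default)
            if self.surge_time <= 0 or self.cast_time <= 0:
                raise ValueError("strategy B needs positive surge/cast times")
            if self.cast_half_cycles < 1:
                raise ValueError("cast_half_cycles must be >= 1")
        elif self.sweep_multiplier is not None:
            raise ValueError("sweep_multiplier applies to strategy B only")

    @property
    def strategy(self) -> str:
        return self.model_id[0]

    @classmethod
    def for_model(cls, model_id: str, **overrides) -> "StrategyParams":
        return cls(model_id=model_id, **overrides)

    def replace(self, **changes) -> "StrategyParams":
        return replace(self, **changes)


@dataclass
class NavigatorState:
    """Mutable flight state of one navigator."""

    x: float
    y: float
    mode: Mode = Mode.WAITING
    t_c: float = 0.0            # last/current contiguous detection duration (s)
    mode_clock: float = 0.0     # time spent in current mode (s)
    lam: float = 0.0            # current surge budget (s)
    delta1: float = 0.0         # current casting half-period (s)
    delta2: float = 0.0         # current sweep duration (s)
    cast_turn_index: int = 0    # completed half-cycles in this casting bout
    cast_sign: int = 1          # current crosswind direction (+1/-1)
    sweep_sign: int = 1
    t0: float | None = None     # navigation start time (first detection)
    last_heading: tuple[float, float] = (-1.0, 0.0)
    trajectory: list[tuple[float, float, float, str]] | None = None

    @property
    def started(self) -> bool:
        return self.t0 is not None

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


def init_navigator(model_id_or_params: str | StrategyParams,
                   start_position: tuple[float, float] = START_POSITION,
                   domain: Domain = DEFAULT_DOMAIN,
                   record_trajectory: bool = False) -> NavigatorState:
    """Place a fresh navigator at its release point, waiting for odor."""
    if isinstance(model_id_or_params, str):
        StrategyParams.for_model(model_id_or_params)  # validate model id
    x, y = start_position
    if not domain.contains(x, y):
        raise ValueError(f"start position {start_position} outside domain")
    state = NavigatorState(x=x, y=y)
    if record_trajectory:
        state.trajectory = [(0.0, x, y, Mode.WAITING.value)]
    return state


def _set_delta1(state: NavigatorState, params: StrategyParams) -> None:
    """Casting half-period for the current half-cycle index."""
    if params.model_id == "A1":
        state.delta1 = params.alpha * state.t_c
    elif params.model_id == "A2":
        state.delta1 = (params.alpha * params.alpha_growth ** state.cast_turn_index
                        * state.t_c)
    else:
        state.delta1 = params.cast_time


def transition(state: NavigatorState, detected: bool, t: float, dt: float,
               params: StrategyParams, rng: np.random.Generator) -> NavigatorState:
    """Advance the behavioral state machine by one timestep.

    Mutates and returns ``state``.  Movement is applied separately (see
    :func:`step_navigator`); this function only updates mode, clocks and
    budgets.
    """
    mode = state.mode
    if mode.terminal:
        raise ValueError("cannot transition a terminal navigator")

    if detected:
        if mode is Mode.WAITING:
            # odor is sensed at the pre-move position: navigation starts at
            # the beginning of this step
            state.t0 = t - dt
        if mode is not Mode.DETECTING:
            state.mode = Mode.DETECTING
            state.t_c = 0.0
            state.mode_clock = 0.0
        state.t_c += dt
        state.mode_clock += dt
        return state

    if mode is Mode.WAITING:
        return state

    if mode is Mode.DETECTING:
        # signal lost: surge upwind on the budget set by the strategy
        state.mode = Mode.SURGING
        state.mode_clock = 0.0
        state.lam = state.t_c if params.strategy == "A" else params.surge_time
        return state

    state.mode_clock += dt

    if mode is Mode.SURGING:
        if state.mode_clock > state.lam:
            state.mode = Mode.CASTING
            state.mode_clock = 0.0
            state.cast_turn_index = 0
            state.cast_sign = 1 if rng.random() < 0.5 else -1
            _set_delta1(state, params)
        return state

    if mode is Mode.CASTING:
        if state.mode_clock > state.delta1:
            state.cast_turn_index += 1
            state.cast_sign = -state.cast_sign
            state.mode_clock = 0.0
            _set_delta1(state, params)
            if (params.strategy == "B"
                    and state.cast_turn_index >= params.cast_half_cycles):
                state.mode = Mode.SWEEPING
                state.delta2 = params.sweep_multiplier * state.delta1
                state.sweep_sign = 1 if rng.random() < 0.5 else -1
        return state

    if mode is Mode.SWEEPING:
        if state.mode_clock > state.delta2:
            state.mode = Mode.CASTING
            state.mode_clock = 0.0
            state.cast_turn_index = 0
        return state

    return state


def heading(state: NavigatorState, wind: Velocity,
            rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Unit movement direction for the current mode.

    Upwind while detecting/surging; perpendicular to the instantaneous wind
    while casting/sweeping.  A zero wind vector holds the previous heading
    (the contract never emits a zero heading).
    """
    norm = math.hypot(wind.u, wind.v)
    if norm == 0.0:
        return state.last_heading
    ux, uy = wind.u / norm, wind.v / norm
    mode = state.mode
    if mode in (Mode.DETECTING, Mode.SURGING):
        h = (-ux, -uy)
    elif mode is Mode.CASTING:
        h = (-uy * state.cast_sign, ux * state.cast_sign)
    elif mode is Mode.SWEEPING:
        h = (-uy * state.sweep_sign, ux * state.sweep_sign)
    else:
        return state.last_heading
    state.last_heading = h
    return h


def step_navigator(state: NavigatorState, plume: PlumeState, wind: Velocity,
                   sensor: SensorParams, params: StrategyParams, t: float,
                   dt: float, rng: np.random.Generator,
                   domain: Domain = DEFAULT_DOMAIN,
                   source: tuple[float, float] = SOURCE_POSITION,
                   success_radius: float = SUCCESS_RADIUS,
                   time_cap: float = math.inf) -> NavigatorState:
    """One full navigator step: sense, transition, move, log, terminal checks.

    ``t`` is the time at the *end* of the step (the plume has already been
    stepped to it).  Waiting navigators hold their release position.
    """
    if state.mode.terminal:
        return state
    detected = plume.detect(sensor, state.x, state.y)
    transition(state, detected, t, dt, params, rng)

    if state.mode is not Mode.WAITING:
        hx, hy = heading(state, wind)
        state.x += hx * params.ground_speed * dt
        state.y += hy * params.ground_speed * dt
        if math.hypot(state.x - source[0], state.y - source[1]) <= success_radius:
            state.mode = Mode.DONE_SUCCESS
        elif not domain.contains(state.x, state.y):
            state.mode = Mode.DONE_FAILED

    if not state.mode.terminal and t >= time_cap:
        state.mode = Mode.DONE_FAILED

    if state.trajectory is not None:
        state.trajectory.append((t, state.x, state.y, state.mode.value))
    return state
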