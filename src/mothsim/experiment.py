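"""Factorial benchmark campaigns and the two performance metrics.

A *trial* flies one navigator against one independently-seeded wind + plume
realization until it succeeds (reaches the source), fails (leaves the arena
or exhausts the time cap) or never starts (no odor encountered).  A
*treatment* sweeps one physical variable — the wind meandering amplitude or
the puff spread rate — over a set of levels, flying ``n_per_model``
navigators of each model at each level.

Two metrics summarise a cell of the design:

* **success rate** — percentage of *started* navigators (those that detected
  odor at least once) that reached within 0.15 m of the source;
* **efficient navigation time** ``tau = T / T_hat`` — navigation time from
  first detection to arrival, over the shortest possible time
  ``T_hat = (|start - source| - success_radius) / ground_speed``; ``tau >= 1``
  with equality for a perfectly straight flight.

Navigators are released sequentially into the ongoing meandering wind; each
trial therefore draws a uniformly random phase of the meandering sinusoid
(see docs/methods.md).  Campaigns are pure functions of (config, seed): a
master seed spawns one counter-keyed stream per trial, so trials are
independent and order-insensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._kernel import run_trial_kernel
from .domain import (DEFAULT_DOMAIN, SOURCE_POSITION, START_POSITION,
                     SUCCESS_RADIUS, Domain)
from .navigators import (MODEL_IDS, Mode, StrategyParams, init_navigator,
                         step_navigator)
from .plume import PlumeParams, PlumeState, SensorParams
from .wind import WindParams, wind_velocity

__all__ = ["TreatmentSpec", "TrialResult", "ResultsTable", "run_trial",
           "run_treatment", "success_rate", "efficiency_tau",
           "straight_line_time", "simulate_trajectory", "TREATMENT_VARIABLES"]

TREATMENT_VARIABLES = ("meander_amplitude", "spread_rate")

#: Trials are capped at this multiple of the straight-line flight time.
TIME_CAP_FACTOR = 50.0

@dataclass(frozen=True)
class TreatmentSpec:
    """One arm of the factorial benchmark."""

    variable: str
    levels: tuple[float, ...]
    n_per_model: int = 250
    models: tuple[str, ...] = MODEL_IDS
    seed: int = 0
    share_plume: bool = False

    def __post_init__(self) -> None:
        if self.variable not in TREATMENT_VARIABLES:
            raise ValueError(f"unknown treatment variable {self.variable!r}")
        if not self.levels:
            raise ValueError("levels must be non-empty")
        if self.n_per_model <= 0:
            raise ValueError("n_per_model must be > 0")
        for m in self.models:
            if m not in MODEL_IDS:
                raise ValueError(f"unknown model {m!r}")


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one navigator trial."""

    model: str
    variable: str
    level: float
    trial: int
    started: bool
    success: bool
    T_total: float  # navigation time t0 -> terminal (s); NaN if never started
    T_hat: float    # shortest possible navigation time (s)
    tau: float      # T_total / T_hat; NaN unless successful


def straight_line_time(start: tuple[float, float] = START_POSITION,
                       source: tuple[float, float] = SOURCE_POSITION,
                       ground_speed: float = 0.4,
                       success_radius: float = SUCCESS_RADIUS) -> float:
    """Shortest possible navigation time: straight flight to the success disc."""
    dist = math.hypot(start[0] - source[0], start[1] - source[1])
    return (dist - success_radius) / ground_speed


def efficiency_tau(result: TrialResult) -> float:
    """tau = T_total / T_hat for a successful trial."""
    if not result.success:
        raise ValueError("tau is defined for successful trials only")
    return result.T_total / result.T_hat


def _strategy_code(model_id: str) -> int:
    return MODEL_IDS.index(model_id)


def run_trial(wind: WindParams, plume: PlumeParams, sensor: SensorParams,
              strategy: StrategyParams, *, dt: float = 0.01,
              time_cap: float | None = None,
              seed: int | None = None,
              rng: np.random.Generator | None = None,
              start: tuple[float, float] = START_POSITION,
              domain: Domain = DEFAULT_DOMAIN,
              randomize_phase: bool = True,
              variable: str = "meander_amplitude",
              level: float | None = None,
              trial: int = 0,
              engine: str = "auto") -> TrialResult:
    """Fly one navigator; fully reproducible from the seed/rng.

    ``engine="fast"`` uses the compiled kernel, ``"python"`` the object-level
    reference; ``"auto"`` picks the kernel whenever the wind is noise-free.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if time_cap is None:
        time_cap = TIME_CAP_FACTOR * math.hypot(start[0] - plume.source_position[0],
                                                start[1] - plume.source_position[1]
                                                ) / strategy.ground_speed
    n_steps = int(round(time_cap / dt))
    phase = wind.phase
    if randomize_phase and wind.meander_omega > 0 and wind.meander_amplitude > 0:
        phase = phase + rng.uniform(0.0, 2.0 * math.pi)

    if engine == "auto":
        engine = "python" if wind.noise_amplitude > 0 else "fast"
    if engine == "fast" and wind.noise_amplitude > 0:
        raise ValueError("fast engine supports noise-free wind only")

    T_hat = straight_line_time(start, plume.source_position,
                               strategy.ground_speed)

    if engine == "fast":
        signs = rng.random(n_steps + 1)
        sweep_mult = strategy.sweep_multiplier or 0.0
        mode_code, t0, t_end, _rel, _pru, _act = run_trial_kernel(
            wind.mean_speed, wind.meander_amplitude, wind.meander_omega, phase,
            plume.release_rate, plume.r0 ** 2, plume.spread_rate,
            plume.puff_mass, sensor.threshold,
            plume.source_position[0], plume.source_position[1],
            domain.x_min, domain.x_max, domain.y_min, domain.y_max,
            start[0], start[1], strategy.ground_speed, SUCCESS_RADIUS,
            _strategy_code(strategy.model_id), strategy.alpha,
            strategy.alpha_growth, strategy.surge_time, strategy.cast_time,
            sweep_mult, strategy.cast_half_cycles,
            dt, n_steps, signs,
        )
        started = t0 >= 0.0
        success = mode_code == 5
    else:
        wind_p = wind.replace(phase=phase)
        plume_state = PlumeState(plume, domain)
        nav = init_navigator(strategy.model_id, start, domain)
        for _ in range(n_steps):
            w = wind_velocity(wind_p, plume_state.clock, rng)
            plume_state.step(w, dt)
            step_navigator(nav, plume_state, w, sensor, strategy,
                           plume_state.clock, dt, rng, domain,
                           plume.source_position, SUCCESS_RADIUS)
            if nav.mode.terminal:
                break
        started = nav.started
        success = nav.mode is Mode.DONE_SUCCESS
        t0 = nav.t0 if nav.started else -1.0
        t_end = plume_state.clock

    T_total = (t_end - t0) if started else math.nan
    tau = (T_total / T_hat) if success else math.nan
    lvl = level if level is not None else _current_level(wind, plume, variable)
    return TrialResult(strategy.model_id, variable, lvl, trial, started,
                       success, T_total if started else math.nan, T_hat, tau)


def _current_level(wind: WindParams, plume: PlumeParams, variable: str) -> float:
    return (wind.meander_amplitude if variable == "meander_amplitude"
            else plume.spread_rate)


def simulate_trajectory(wind: WindParams, plume: PlumeParams,
                        sensor: SensorParams, strategy: StrategyParams, *,
                        dt: float = 0.01, time_cap: float | None = None,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None,
                        start: tuple[float, float] = START_POSITION,
                        domain: Domain = DEFAULT_DOMAIN,
                        randomize_phase: bool = True
                        ) -> tuple[TrialResult, pd.DataFrame]:
    """Python-engine trial that also records the flight path.

    Returns the trial result and a frame with columns t, x, y, mode.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if time_cap is None:
        time_cap = TIME_CAP_FACTOR * math.hypot(start[0] - plume.source_position[0],
                                                start[1] - plume.source_position[1]
                                                ) / strategy.ground_speed
    n_steps = int(round(time_cap / dt))
    phase = wind.phase
    if randomize_phase and wind.meander_omega > 0 and wind.meander_amplitude > 0:
        phase = phase + rng.uniform(0.0, 2.0 * math.pi)
    wind_p = wind.replace(phase=phase)
    plume_state = PlumeState(plume, domain)
    nav = init_navigator(strategy.model_id, start, domain,
                         record_trajectory=True)
    for _ in range(n_steps):
        w = wind_velocity(wind_p, plume_state.clock, rng)
        plume_state.step(w, dt)
        step_navigator(nav, plume_state, w, sensor, strategy,
                       plume_state.clock, dt, rng, domain,
                       plume.source_position, SUCCESS_RADIUS)
        if nav.mode.terminal:
            break
    if not nav.mode.terminal:
        nav.mode = Mode.DONE_FAILED
    started = nav.started
    success = nav.mode is Mode.DONE_SUCCESS
    t0 = nav.t0 if started else -1.0
    t_end = plume_state.clock
    T_hat = straight_line_time(start, plume.source_position,
                               strategy.ground_speed)
    T_total = (t_end - t0) if started else math.nan
    tau = (T_total / T_hat) if success else math.nan
    result = TrialResult(strategy.model_id, "meander_amplitude",
                         wind.meander_amplitude, 0, started, success,
                         T_total, T_hat, tau)
    traj = pd.DataFrame(nav.trajectory, columns=["t", "x", "y", "mode"])
    return result, traj


class ResultsTable:
    """Trial results of a campaign, with per-cell aggregate accessors."""

    COLUMNS = ["model", "variable", "level", "trial", "started", "success",
               "T_total", "T_hat", "tau"]

    def __init__(self, results: list[TrialResult] | pd.DataFrame):
        if isinstance(results, pd.DataFrame):
            self.df = results.reset_index(drop=True)[self.COLUMNS]
        else:
            self.df = pd.DataFrame([r.__dict__ for r in results],
                                   columns=self.COLUMNS)

    def __len__(self) -> int:
        return len(self.df)

    def cell(self, model: str, level: float) -> pd.DataFrame:
        df = self.df
        return df[(df["model"] == model) & (np.isclose(df["level"], level))]

    def success_rate(self, model: str, level: float) -> float:
        """Percentage of started navigators that reached the source.

        NaN (the undefined sentinel) when no navigator in the cell started.
        """
        cell = self.cell(model, level)
        n_started = int(cell["started"].sum())
        if len(cell) == 0 or n_started == 0:
            return math.nan
        return 100.0 * float(cell["success"].sum()) / n_started

    def tau_values(self, model: str, level: float) -> np.ndarray:
        cell = self.cell(model, level)
        return cell.loc[cell["success"], "tau"].to_numpy()

    def counts(self, model: str, level: float) -> tuple[int, int, int]:
        """(released, started, succeeded) for one cell."""
        cell = self.cell(model, level)
        return (len(cell), int(cell["started"].sum()),
                int(cell["success"].sum()))

    @property
    def models(self) -> list[str]:
        return list(dict.fromkeys(self.df["model"]))

    @property
    def levels(self) -> list[float]:
        return sorted(self.df["level"].unique())


def success_rate(results: ResultsTable, model: str, level: float) -> float:
    return results.success_rate(model, level)


def run_treatment(spec: TreatmentSpec, wind: WindParams, plume: PlumeParams,
                  sensor: SensorParams,
                  strategies: dict[str, StrategyParams] | None = None, *,
                  dt: float = 0.01, time_cap: float | None = None,
                  domain: Domain = DEFAULT_DOMAIN,
                  engine: str = "auto") -> ResultsTable:
    """Run one full treatment arm: models x levels x n_per_model trials.

    Every trial draws its random stream from
    ``SeedSequence(spec.seed, spawn_key=(variable, model, level, trial))``,
    so the campaign is a pure function of (spec, configs) and trials may be
    evaluated in any order.  With ``spec.share_plume`` all trials of one
    level share a single wind/plume realization (one common meandering
    phase) instead of each drawing their own.
    """
    if strategies is None:
        strategies = {m: StrategyParams.for_model(m) for m in spec.models}
    vi = TREATMENT_VARIABLES.index(spec.variable)
    rows: list[TrialResult] = []
    for li, level in enumerate(spec.levels):
        if spec.variable == "meander_amplitude":
            wind_l, plume_l = wind.replace(meander_amplitude=level), plume
        else:
            wind_l, plume_l = wind, plume.replace(spread_rate=level)
        shared_phase = None
        if spec.share_plume:
            level_rng = np.random.default_rng(
                np.random.SeedSequence(spec.seed, spawn_key=(vi, 999, li)))
            shared_phase = level_rng.uniform(0.0, 2.0 * math.pi)
            wind_l = wind_l.replace(phase=wind_l.phase + shared_phase)
        for mi, model in enumerate(spec.models):
            strat = strategies[model]
            for ti in range(spec.n_per_model):
                rng = np.random.default_rng(
                    np.random.SeedSequence(spec.seed, spawn_key=(vi, mi, li, ti)))
                rows.append(run_trial(
                    wind_l, plume_l, sensor, strat, dt=dt, time_cap=time_cap,
                    rng=rng, domain=domain,
                    randomize_phase=not spec.share_plume,
                    variable=spec.variable, level=level, trial=ti,
                    engine=engine))
    return ResultsTable(rows)
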