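"""The frozen benchmark study: treatment ladders and campaign runners.

Two factorial campaigns, each flying 250 navigators of every model at every
level of one physical variable:

* **meandering amplitude** ladder 0.05-0.2 m/s (spread rate at its default
  0.0002 m^2/s);
* **puff spread rate** ladder 0.0001-0.0004 m^2/s (meandering amplitude at
  its default 0.15 m/s).

All other parameters are the package defaults (mean wind 1 m/s, meandering
rate 0.1 rad/s, no wind noise, release rate 100 puffs/s, r0 = 1 mm,
detection threshold 620 a.u., unit puff mass, ground speed 0.4 m/s).
"""

from __future__ import annotations

from .experiment import ResultsTable, TreatmentSpec, run_treatment
from .navigators import MODEL_IDS, StrategyParams
from .plume import PlumeParams, SensorParams
from .wind import WindParams

__all__ = ["MEANDER_LEVELS", "SPREAD_LEVELS", "DEFAULT_MEANDER",
           "benchmark_wind", "benchmark_plume", "benchmark_sensor",
           "run_meander_campaign", "run_spread_campaign"]

MEANDER_LEVELS = (0.05, 0.1, 0.15, 0.2)
SPREAD_LEVELS = (0.0001, 0.0002, 0.0003, 0.0004)

#: Fixed meandering amplitude of the spread-rate campaign (m/s).
DEFAULT_MEANDER = 0.15


def benchmark_wind() -> WindParams:
    return WindParams(meander_amplitude=DEFAULT_MEANDER)


def benchmark_plume() -> PlumeParams:
    return PlumeParams()


def benchmark_sensor() -> SensorParams:
    return SensorParams()


def _strategies(models=MODEL_IDS):
    return {m: StrategyParams.for_model(m) for m in models}


def run_meander_campaign(seed: int, n_per_model: int = 250,
                         models=MODEL_IDS,
                         levels=MEANDER_LEVELS) -> ResultsTable:
    spec = TreatmentSpec("meander_amplitude", tuple(levels),
                         n_per_model=n_per_model, models=tuple(models),
                         seed=seed)
    return run_treatment(spec, benchmark_wind(), benchmark_plume(),
                         benchmark_sensor(), _strategies(models))


def run_spread_campaign(seed: int, n_per_model: int = 250,
                        models=MODEL_IDS,
                        levels=SPREAD_LEVELS) -> ResultsTable:
    spec = TreatmentSpec("spread_rate", tuple(levels),
                         n_per_model=n_per_model, models=tuple(models),
                         seed=seed)
    return run_treatment(spec, benchmark_wind(), benchmark_plume(),
                         benchmark_sensor(), _strategies(models))
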