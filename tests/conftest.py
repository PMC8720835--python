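import numpy as np
import pytest

import mothsim as ms


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def calm_wind():
    """No meandering, no noise: wind is exactly (1, 0) m/s."""
    return ms.WindParams(mean_speed=1.0, meander_amplitude=0.0)


@pytest.fixture
def default_plume():
    return ms.PlumeParams()


@pytest.fixture
def default_sensor():
    return ms.SensorParams()


@pytest.fixture
def strategies():
    return {m: ms.StrategyParams.for_model(m) for m in ms.MODEL_IDS}


def naive_plume_reference(params, wind_series, dt, domain=ms.DEFAULT_DOMAIN):
    """Independent per-puff reference of the plume update.

    Keeps explicit Puff objects and applies advect/grow/release/prune
    object-by-object; used as the oracle for the vectorized PlumeState.
    Yields the puff list after each step.
    """
    puffs: list[ms.Puff] = []
    acc = 0.0
    clock = 0.0
    for w in wind_series:
        puffs = [ms.grow_puff(ms.advect_puff(p, w, dt), params, dt)
                 for p in puffs]
        acc += params.release_rate * dt
        n_new = int(np.floor(acc))
        acc -= n_new
        sx, sy = params.source_position
        for _ in range(n_new):
            puffs.append(ms.Puff(sx, sy, params.r0 ** 2, clock))
        kept = []
        for p in puffs:
            r = np.sqrt(p.r_squared)
            if (p.x <= domain.x_max + r and p.x >= domain.x_min - r
                    and p.y <= domain.y_max + r and p.y >= domain.y_min - r):
                kept.append(p)
        puffs = kept
        clock += dt
        yield puffs
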