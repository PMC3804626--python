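import numpy as np
import pytest

from groupforage import landscape as ls


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def uniform_landscape():
    """Default-geometry landscape with uniform weights: every cell max 140."""
    w = ls.WeightGrid(np.ones((ls.DEFAULT_N_ROWS, ls.DEFAULT_N_COLS)))
    return ls.build_landscape(w)


@pytest.fixture
def small_landscape():
    """6x5 uniform landscape, max 20 per cell, for hand-checkable scenarios."""
    w = ls.WeightGrid(np.ones((5, 6)))
    return ls.build_landscape(w, total_resources=600.0, grow_back_rate=4.0)


@pytest.fixture
def hotspot_weights():
    return ls.synthesize_weights(40, 30, n_hotspots=12, hotspot_intensity=8.0, seed=7)


@pytest.fixture(scope="session")
def directional_battery():
    """12 agent types x 5 matched seeds, 60-day trials (the heavy battery).

    Built lazily and shared by every directional test.
    """
    from groupforage import experiment as exp

    plan = exp.ExperimentPlan(replicates=5, base_seed=100, days=60)
    bundle = exp.run_experiment(plan)
    return bundle.features
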