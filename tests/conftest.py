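import numpy as np
import pytest

import thermacclim as ta


@pytest.fixture(scope="session")
def tcore_p1():
    return ta.preset_from_table3("Tcore/P1")


@pytest.fixture(scope="session")
def adfi_p1():
    return ta.preset_from_table3("ADFI/P1")


@pytest.fixture(scope="session")
def all_presets():
    return [ta.preset_from_table3(label) for label in ta.available_presets()]


@pytest.fixture(scope="session")
def small_tcore_data(tcore_p1):
    """A small fixed cohort from the pooled-P1 core-temperature preset."""
    return ta.simulate_trajectories(tcore_p1, n_animals=6, seed=42)


@pytest.fixture(scope="session")
def noiseless_sharp_data():
    """Noise-free broken-stick trajectories (tiny jitter breaks exact ties)."""
    preset = ta.preset_from_table3("Tcore/P1")
    params = preset.params
    days = np.arange(-1.0, 11.0)
    rng = np.random.default_rng(7)
    rows = []
    from thermacclim.model import evaluate_sharp

    for i in range(4):
        vals = evaluate_sharp(params, days) + rng.normal(0, 1e-8, size=len(days))
        rows += [(f"a{i}", "g", d, v) for d, v in zip(days, vals)]
    import pandas as pd

    frame = pd.DataFrame(rows, columns=["animal_id", "group", "day", "value"])
    return ta.TrajectoryDataset(frame, variable="Tcore_C"), params
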