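import numpy as np
import pandas as pd
import pytest

from varmerge import (ScaleConfig, TrainingConfig, fit, make_toy)
from varmerge.reflection_io import ReflectionTable


@pytest.fixture(scope="session")
def toy():
    return make_toy(seed=1)


@pytest.fixture(scope="session")
def toy_fit(toy):
    """One converged toy fit shared by the tests that only inspect it."""
    table, _ = toy
    return fit(table, "P1",
               training=TrainingConfig(iterations=4000, seed=1),
               scale_config=ScaleConfig(width=8))


@pytest.fixture()
def tiny_table():
    """Three observations of two reflections, two metadata columns."""
    df = pd.DataFrame({
        "h": [1, 1, 2], "k": [0, 0, 0], "l": [0, 0, 0],
        "image_id": [0, 1, 1], "dataset_id": 0,
        "intensity": [1.0, 1.2, 4.0], "sigma_I": [0.1, 0.1, 0.2],
        "xdet": [0.0, 1.0, 2.0], "ydet": [5.0, 5.0, 8.0]})
    return ReflectionTable(df, ["xdet", "ydet"])
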