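import numpy as np
import pandas as pd
import pytest

from ricelpn.indices import FeatureTable
from ricelpn.synth import SensorModel, Spectrum


@pytest.fixture(scope="session")
def default_sensor() -> SensorModel:
    return SensorModel()


@pytest.fixture(scope="session")
def noise_free_sensor() -> SensorModel:
    return SensorModel(noise_sd=0.0)


@pytest.fixture
def flat_spectrum(default_sensor) -> Spectrum:
    wl = default_sensor.wavelengths
    return Spectrum(wavelengths=wl, reflectance=np.full_like(wl, 0.5))


@pytest.fixture
def toy_table() -> FeatureTable:
    """Small seeded regression table: y driven by f1, plus noise features."""
    rng = np.random.default_rng(123)
    n = 60
    f1 = rng.normal(size=n)
    noise = rng.normal(size=(n, 4))
    y = 2.0 * f1 + 0.1 * rng.normal(size=n)
    values = pd.DataFrame(
        np.column_stack([f1, noise]), columns=["f1", "n1", "n2", "n3", "n4"]
    )
    return FeatureTable(values=values, target=pd.Series(y, name="lpn"))
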