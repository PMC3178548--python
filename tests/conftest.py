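import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from medea import ToleranceModel, default_schedule
from medea.simulate import SyntheticConfig, generate

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def tol():
    """The canonical tolerance box: 2.93 ppm in m/z, 0.3 min in RT."""
    return ToleranceModel(2.93, 0.3)


@pytest.fixture
def schedule():
    return default_schedule()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def well_separated_peaks():
    """50 isolated peptides x 12 replicates, scatter well inside the box."""
    return generate(SyntheticConfig(n_peptides=50, n_samples=12,
                                    dropout_rate=0.0, n_noise=0, rng_seed=11))


def make_peaks(mz, rt, z=2, **extra):
    """Build a minimal peak table from coordinate arrays."""
    mz = np.atleast_1d(np.asarray(mz, dtype=float))
    rt = np.atleast_1d(np.asarray(rt, dtype=float))
    data = {"mz": mz, "rt": rt, "z": np.broadcast_to(z, mz.shape).astype(int)}
    data.update(extra)
    return pd.DataFrame(data)
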