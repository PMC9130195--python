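import numpy as np
import pytest

from chronopls.core import BinMeta, FeatureMatrix, SampleMeta
from chronopls.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic study (feeding, control, growth, truth)."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def quiet_sim():
    """Low-noise synthetic study for structure-recovery checks."""
    return simulate_dataset(SimConfig(seed=11, replicate_cv=0.02))


@pytest.fixture
def small_fm():
    """Hand-sized 6-sample x 4-bin matrix with full metadata."""
    rng = np.random.default_rng(7)
    samples = [
        SampleMeta(f"{g}{d}_r{r}", g, d, r)
        for g in ("B", "F")
        for d, r in ((1, 1), (1, 2), (4, 1))
    ]
    bins = [BinMeta(j + 1, rt_min=12.0 + 3 * j, mz=100.0 + j, label=None) for j in range(4)]
    values = rng.uniform(10, 100, size=(6, 4))
    return FeatureMatrix(values, samples, bins, stage="raw")
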