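import numpy as np
import pytest

from metabroscreen.feature_io import FeatureMatrix, IonID, SampleTable
from metabroscreen.synthetic_data import GeneratorConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 55/50 train + 32/15 test cohort with 6 strong planted markers."""
    cfg = GeneratorConfig(n_ions=400, n_markers=6, seed=7)
    return generate_cohort(cfg)


def make_matrix(intensity, rng=None):
    """Wrap a raw array in a FeatureMatrix with synthetic ion labels."""
    intensity = np.asarray(intensity, dtype=float)
    n, p = intensity.shape
    ions = [IonID(rt=round(0.5 + 0.07 * i, 2), mz=round(50.0 + 1.001 * i, 3))
            for i in range(p)]
    samples = [f"s{i:03d}" for i in range(n)]
    return FeatureMatrix(ions=ions, samples=samples, intensity=intensity)


def make_samples(n_case, n_control, split="train", n_case_test=0, n_control_test=0):
    records = []
    i = 0
    for grp, spl, n in (("case", split, n_case), ("control", split, n_control),
                        ("case", "test", n_case_test),
                        ("control", "test", n_control_test)):
        for _ in range(n):
            records.append((f"s{i:03d}", grp, spl))
            i += 1
    return SampleTable.from_records(records)
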