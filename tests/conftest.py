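import numpy as np
import pandas as pd
import pytest

from sakemet import GeneratorConfig, generate_dataset
from sakemet.containers import PeakTable
from sakemet.synthetic import AttributeSpec


def small_generator_config(seed: int = 11) -> GeneratorConfig:
    """A scaled-down study: 16 samples, 60 retained peaks, 8 panelists."""
    return GeneratorConfig(
        n_samples=16,
        n_informative_peaks=60,
        n_zero_max_peaks=3,
        n_high_cv_peaks=5,
        n_panelists=8,
        n_rounds=3,
        attributes=[
            AttributeSpec("sweetness", n_driver_peaks=4),
            AttributeSpec("sourness", n_driver_peaks=4),
            AttributeSpec("body", n_driver_peaks=4),
        ],
        n_block_factors=4,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_config():
    return small_generator_config()


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def tiny_table():
    """Hand-built peak table: 2 samples x 3 replicates, 4 peaks.

    peak CVs: p_high 20% (worst sample), p_flat 0%, p_edge exactly 10%,
    p_zero all-zero.
    """
    intensities = pd.DataFrame(
        {
            "p_high": [8.0, 10.0, 12.0, 10.0, 10.0, 10.0],
            "p_flat": [5.0, 5.0, 5.0, 7.0, 7.0, 7.0],
            "p_edge": [9.0, 10.0, 11.0, 20.0, 20.0, 20.0],
            "p_zero": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        }
    )
    injections = pd.DataFrame(
        {"sample_id": ["A"] * 3 + ["B"] * 3, "replicate": [1, 2, 3] * 2}
    )
    meta = pd.DataFrame(
        {"rt": [5.0, 6.0, 7.0, 8.0], "mz": [200.0, 300.0, 400.0, 500.0]},
        index=pd.Index(["p_high", "p_flat", "p_edge", "p_zero"], name="peak_id"),
    )
    return PeakTable(intensities=intensities, injections=injections, peak_meta=meta)


def random_regression(seed, n=30, p=50, noise=0.1):
    """A generic linear-regression instance for estimator tests."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    k = min(5, p)
    beta[rng.choice(p, k, replace=False)] = rng.normal(0, 1, k)
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y
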