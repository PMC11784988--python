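import numpy as np
import pandas as pd
import pytest

from mpscrp.scoring import MethylationMatrix
from mpscrp.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort draw shared by read-only tests."""
    cfg = GeneratorConfig(
        n_total=300, n_reference=60, n_filler=10, n_plates=4,
        use_extended=False, rng_seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def tiny_matrix(rng):
    """20 samples x 10 correlated probes, complete."""
    base = rng.uniform(0.2, 0.8, size=10)
    latent = rng.normal(0, 1, size=20)
    betas = np.clip(
        base + 0.05 * latent[:, None] + rng.normal(0, 0.02, size=(20, 10)), 0, 1
    )
    df = pd.DataFrame(
        betas,
        index=[f"s{i}" for i in range(20)],
        columns=[f"cg{j:02d}" for j in range(10)],
    )
    return MethylationMatrix(df, "450k")
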