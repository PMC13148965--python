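import numpy as np
import pytest

from discrep import EffectTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def two_study_table():
    """The minimal hand-checkable table: effects 0 and 1, unit SEs."""
    return EffectTable(beta_hat=[0.0, 1.0], se=[1.0, 1.0])


@pytest.fixture
def small_table():
    return EffectTable(
        beta_hat=[0.12, -0.05, 0.30, 0.18],
        se=[0.10, 0.15, 0.20, 0.12],
        study=["a", "b", "c", "d"],
    )


def random_table(rng, m=None, beta_bar=0.1, k=0.25, se_scale=0.2):
    """A random effect table drawn from the reference replicability model."""
    m = m if m is not None else int(rng.integers(3, 9))
    se = se_scale * (0.5 + rng.random(m))
    betas = rng.normal(beta_bar, k * abs(beta_bar), m)
    return EffectTable(beta_hat=rng.normal(betas, se), se=se)
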