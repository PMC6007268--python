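import numpy as np
import pytest

from nnmelt.datasets import benchmark_duplexes, literature_params
from nnmelt.thermo_model import FEATURES, NNParamSet


@pytest.fixture(scope="session")
def duplexes34():
    return benchmark_duplexes()


@pytest.fixture(scope="session")
def lit_params():
    return literature_params()


@pytest.fixture()
def zero_params():
    return NNParamSet({f: 0.0 for f in FEATURES}, {f: 0.0 for f in FEATURES})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_param_set(rng: np.random.Generator) -> NNParamSet:
    """Random but physically bounded parameter set: per-feature dG37 in
    [-3, 2] kcal/mol so Boltzmann factors never overflow at 0-100 C."""
    n = len(FEATURES)
    dg37 = rng.uniform(-3.0, 2.0, n)
    dh = rng.uniform(-12.0, 0.0, n)
    ds = (dh - dg37) / 310.15 * 1000.0
    return NNParamSet(dict(zip(FEATURES, dh)), dict(zip(FEATURES, ds)))
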