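import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cfakit.estimator import ParamLayout
from cfakit.model_spec import (
    FactorModelSpec,
    FactorStructure,
    build_catalog,
    simple_structure_pattern,
    with_free_cell,
)
from cfakit.synthetic_data import (
    SyntheticConfig,
    exact_population_matrix,
    modified_chc_truth,
)

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


@pytest.fixture(scope="session")
def chc_truth():
    """Generating config for the modified-CHC reference solution."""
    return modified_chc_truth()


@pytest.fixture(scope="session")
def chc_population(chc_truth):
    """Noise-free population matrix implied by the reference solution."""
    return exact_population_matrix(chc_truth)


def make_toy_spec():
    """9 variables, 3 orthonormal simple-structure factors."""
    names = tuple("ABCDEFGHI")
    groups = {"F1": names[:3], "F2": names[3:6], "F3": names[6:]}
    return FactorModelSpec(
        "toy3", simple_structure_pattern(groups, names), FactorStructure("orthonormal")
    )


def toy_population(spec, loading=0.7, overrides=None, n_obs=1000):
    """Exact population matrix for a toy spec; overrides maps (row, col) -> value."""
    layout = ParamLayout(spec)
    params = np.full(layout.nl, loading)
    for j, (r, c) in enumerate(zip(layout.free_rows, layout.free_cols)):
        if overrides and (r, c) in overrides:
            params[j] = overrides[(r, c)]
    cfg = SyntheticConfig(spec=spec, true_params=params, n_obs=n_obs)
    return exact_population_matrix(cfg)


@pytest.fixture(scope="session")
def toy_spec():
    return make_toy_spec()


@pytest.fixture(scope="session")
def toy_true_spec(toy_spec):
    """Toy spec plus one cross-loading (A on F2) of 0.4 in truth."""
    return with_free_cell(toy_spec, "A", "F2")


@pytest.fixture(scope="session")
def toy_true_population(toy_true_spec):
    return toy_population(toy_true_spec, overrides={(0, 1): 0.4})
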