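import numpy as np
import pytest

from lstar import (build_default_spec, make_paperlike_params,
                   template_parameters, unflatten_parameters)
from lstar.spec import parameter_layout


@pytest.fixture(scope="session")
def spec1():
    return build_default_spec(3, 4, 1)


@pytest.fixture(scope="session")
def spec2():
    return build_default_spec(3, 4, 2)


@pytest.fixture(scope="session")
def paperlike(spec2):
    return make_paperlike_params(spec2)


@pytest.fixture(scope="session")
def target_params(spec1, paperlike):
    """Single-rater parameters: the reference-rater side of the fixture."""
    return single_rater_slice(spec1, paperlike)


def single_rater_slice(spec1, mr_params):
    p = template_parameters(spec1)
    p.intercepts[:, 0, :] = mr_params.intercepts[:, 0, :]
    p.lam_T[:, 0, :] = mr_params.lam_T[:, 0, :]
    p.lam_O[:, 0, :] = mr_params.lam_O[:, 0, :]
    p.phi[:, :] = mr_params.phi[:spec1.n_indicators, :spec1.n_indicators]
    p.beta[:] = mr_params.beta
    p.sr_var[:] = mr_params.sr_var
    p.err_var[:, 0, :] = mr_params.err_var[:, 0, :]
    return p


def random_params(spec, rng, simulable=False):
    """Random conforming ParameterSet via a random flat vector.

    ``simulable=True`` replaces the trait block with a block-diagonal PSD
    matrix (needed by the data generator); otherwise entries are free-range,
    which is fine for algebraic identity checks.
    """
    layout = parameter_layout(spec)
    x = np.empty(len(layout))
    for j, slot in enumerate(layout):
        name = slot.name
        if name.startswith("a."):
            x[j] = rng.uniform(3.0, 5.0)
        elif name.startswith("lambda"):
            x[j] = rng.uniform(0.4, 1.3)
        elif name.startswith("beta"):
            x[j] = rng.uniform(0.0, 0.8)
        elif name.startswith("phi.") and slot.transform == "identity":
            x[j] = rng.uniform(-0.05, 0.1)  # covariances
        elif slot.transform == "log":
            x[j] = np.log(rng.uniform(0.05, 0.4))
        else:  # pragma: no cover
            x[j] = rng.normal()
    params = unflatten_parameters(x, spec)
    if simulable:
        I = spec.n_indicators
        a = rng.uniform(0.2, 0.6, size=(I, I)) * rng.choice([1.0], size=(I, I))
        block = a @ a.T + 0.1 * np.eye(I)
        params.phi[:I, :I] = block
        if spec.is_multi_rater:
            b = rng.uniform(0.2, 0.6, size=(I, I))
            params.phi[I:, I:] = b @ b.T + 0.1 * np.eye(I)
            params.phi[:I, I:] = 0.0
            params.phi[I:, :I] = 0.0
    return params


@pytest.fixture
def rng():
    return np.random.default_rng(0)
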