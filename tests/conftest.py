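import numpy as np
import pytest

from biohekf import (
    FilterConfig,
    default_process_noise,
    extend_state,
    get_fixture,
    linear_output,
    positivity_constraints,
    simulate_measurements,
)
from biohekf.filtering import default_P0
from biohekf.models import ODEModel


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def scalar_decay_model():
    """x' = -a x with a single parameter a."""
    return ODEModel(
        n_states=1,
        rhs=lambda x, u, t, p: np.array([-p[0] * x[0]]),
        param_names=("a",),
        name="scalar_decay",
        default_params={"a": 1.0},
    )


@pytest.fixture
def heat_shock_setup():
    """2-free-parameter heat-shock estimation setup (the paper's small case)."""
    spec = get_fixture("heat_shock")
    model = spec.build()
    output = spec.output()
    x0 = spec.default_x0()
    free = spec.default_free
    guess = np.asarray(spec.default_guess, float)
    fixed = {k: v for k, v in model.default_params.items() if k not in free}
    ext = extend_state(
        model,
        free,
        fixed,
        output,
        Q=default_process_noise(x0, guess),
        constraints=positivity_constraints(model.n_states, len(free)),
    )
    x0_ext = np.concatenate([x0, guess])
    cfg = FilterConfig(
        x0_ext=x0_ext,
        P0=default_P0(x0_ext),
        R=spec.default_R(),
        rtol=1e-6,
        atol=1e-8,
    )
    return {
        "spec": spec,
        "model": model,
        "output": output,
        "x0": x0,
        "ext": ext,
        "cfg": cfg,
        "schedule": spec.default_schedule(),
        "R": spec.default_R(),
    }


@pytest.fixture
def heat_shock_data(heat_shock_setup):
    s = heat_shock_setup
    return simulate_measurements(
        s["model"], s["x0"], s["schedule"], s["output"], R=s["R"], seed=2
    )


def make_linear_model(A):
    """LTI model x' = A x with no parameters."""
    A = np.asarray(A, float)
    return ODEModel(
        n_states=A.shape[0],
        rhs=lambda x, u, t, p: A @ x,
        param_names=(),
        jac_x=lambda x, u, t, p: A,
        jac_p=lambda x, u, t, p: np.zeros((A.shape[0], 0)),
        name="lti",
        default_params={},
    )


@pytest.fixture
def lti_2d():
    A = np.array([[-0.4, 0.3], [0.1, -0.7]])
    model = make_linear_model(A)
    output = linear_output(np.eye(2))
    ext = extend_state(model, (), {}, output, Q=np.array([0.05, 0.02]))
    return {"A": A, "model": model, "ext": ext, "output": output}
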