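"""Built-in models and the synthetic measurement generator.

Three fixture models are registered by name:

``heat_shock``
    Reduced 3-state model of the bacterial heat-shock response: chaperones
    ``x1``, sigma-factor ``x2`` and unfolded proteins ``x3``, with a step
    temperature input at t = 0.  A sharp sequestration feedback (unfolded
    proteins shielding the sigma factor from chaperone-mediated degradation)
    produces the transient sigma-factor spike after the shock.  The numeric
    coefficients are nominal surrogate values chosen to reproduce the
    qualitative behavior (rapid post-shock rise, settling within ~50-100 time
    units, ~5x induction); they are not literature values.  The two synthesis
    rates ``ks`` and ``eta1`` default to 3.0 and are the standard 2-parameter
    estimation targets.

``heat_shock_nospike``
    The same model with the sequestration feedback loop turned off.  Both
    variants evolve to (nearly) the same steady state but differ in the
    transient — the no-spike variant lacks most of the sigma-factor overshoot.

``repressilator``
    Generalized three-gene ring oscillator in which each gene/protein pair
    carries its own 6 kinetic rates (transcription, repression threshold,
    cooperativity, mRNA decay, translation, protein decay), 18 parameters in
    total.  Default rates give a limit cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import fsolve

from .errors import ConfigurationError, InputError
from .models import (
    LinearConstraintSet,
    ODEModel,
    OutputMap,
    linear_output,
    simulate,
)

__all__ = [
    "MeasurementSeries",
    "SamplingSchedule",
    "heat_shock_model",
    "heat_shock_nospike_model",
    "repressilator_model",
    "heat_shock_schedule",
    "uniform_schedule",
    "simulate_measurements",
    "heat_shock_steady_state",
    "default_process_noise",
    "positivity_constraints",
    "MODEL_REGISTRY",
    "get_fixture",
]


# ---------------------------------------------------------------------------
# measurement container

@dataclass
class MeasurementSeries:
    """Discrete-time, possibly per-channel-incomplete measurements.

    ``values`` is (N x n_channels) with NaN marking unobserved pairs.  ``R``
    is the diagonal of the (known) measurement-noise covariance.
    """

    times: np.ndarray
    values: np.ndarray
    R: np.ndarray
    channel_names: tuple = ()
    seed: int | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.atleast_2d(np.asarray(self.values, float))
        self.R = np.atleast_1d(np.asarray(self.R, float))
        if self.times.ndim != 1 or self.values.shape[0] != self.times.size:
            raise InputError("values must have one row per sample time")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("sample times must be strictly increasing")
        if np.any(np.all(np.isnan(self.values), axis=1)):
            raise InputError("every sample time must observe at least one channel")
        if not self.channel_names:
            self.channel_names = tuple(
                f"y{j + 1}" for j in range(self.values.shape[1])
            )

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def observed_mask(self, k: int) -> np.ndarray:
        return ~np.isnan(self.values[k])

    def observed_values(self, k: int) -> np.ndarray:
        row = self.values[k]
        return row[~np.isnan(row)]

    def mask_matrix(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class SamplingSchedule:
    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        if np.any(np.diff(self.times) <= 0):
            raise InputError("schedule times must be strictly increasing")

    def __len__(self):
        return self.times.size


# ---------------------------------------------------------------------------
# heat-shock fixtures

#: Nominal surrogate coefficients (time unit: minutes, counts of molecules).
HEAT_SHOCK_DEFAULTS = {
    "ks": 3.0,     # chaperone synthesis per sigma-factor molecule
    "d1": 0.06,    # chaperone decay
    "eta0": 0.12,  # basal sigma-factor synthesis
    "eta1": 3.0,   # heat-induced sigma-factor synthesis
    "d2": 1e-4,    # chaperone-mediated sigma-factor degradation
    "kseq": 7.0,   # max degradation suppression by sequestration
    "K3": 100.0,   # unfolded-protein threshold of the sequestration switch
    "ku0": 0.5,    # basal unfolding
    "ku1": 50.0,   # heat-induced unfolding
    "kf": 1e-3,    # refolding by chaperones
    "d3": 0.01,    # unfolded-protein decay
}

_HS_NAMES = tuple(HEAT_SHOCK_DEFAULTS)
_HILL_N = 6  # structural cooperativity of the sequestration switch


def _hs_params(overrides: dict) -> dict:
    unknown = [n for n in overrides if n not in HEAT_SHOCK_DEFAULTS]
    if unknown:
        raise ConfigurationError(f"unknown heat-shock parameter(s): {unknown}")
    p = dict(HEAT_SHOCK_DEFAULTS)
    p.update({k: float(v) for k, v in overrides.items()})
    return p


def _hs_rhs(spike: bool):
    def rhs(x, u, t, p):
        ks, d1, eta0, eta1, d2, kseq, K3, ku0, ku1, kf, d3 = p
        x1, x2, x3 = x
        x3c = max(x3, 0.0)
        if spike:
            hill = x3c**_HILL_N / (K3**_HILL_N + x3c**_HILL_N)
            seq = 1.0 + kseq * hill
        else:
            seq = 1.0
        return np.array(
            [
                ks * x2 - d1 * x1,
                eta0 + eta1 * u - d2 * x1 * x2 / seq,
                ku0 + ku1 * u - kf * x1 * x3 - d3 * x3,
            ]
        )

    return rhs


def _hs_jac_x(spike: bool):
    def jac(x, u, t, p):
        ks, d1, eta0, eta1, d2, kseq, K3, ku0, ku1, kf, d3 = p
        x1, x2, x3 = x
        x3c = max(x3, 0.0)
        n = _HILL_N
        if spike:
            num = x3c**n
            den = K3**n + num
            hill = num / den
            seq = 1.0 + kseq * hill
            # d(hill)/dx3 = n K3^n x3^(n-1) / den^2
            dhill = n * K3**n * x3c ** (n - 1) / den**2 if x3c > 0 else 0.0
            dseq = kseq * dhill
        else:
            seq = 1.0
            dseq = 0.0
        deg = d2 * x1 * x2 / seq
        return np.array(
            [
                [-d1, ks, 0.0],
                [-d2 * x2 / seq, -d2 * x1 / seq, deg * dseq / seq],
                [-kf * x3, 0.0, -kf * x1 - d3],
            ]
        )

    return jac


def _hs_jac_p(spike: bool):
    def jac(x, u, t, p):
        ks, d1, eta0, eta1, d2, kseq, K3, ku0, ku1, kf, d3 = p
        x1, x2, x3 = x
        x3c = max(x3, 0.0)
        n = _HILL_N
        J = np.zeros((3, 11))
        if spike:
            num = x3c**n
            den = K3**n + num
            hill = num / den
            seq = 1.0 + kseq * hill
            dseq_dkseq = hill
            # d(hill)/dK3 = -n K3^(n-1) x3^n / den^2
            dseq_dK3 = -kseq * n * K3 ** (n - 1) * num / den**2
        else:
            seq = 1.0
            dseq_dkseq = 0.0
            dseq_dK3 = 0.0
        deg = d2 * x1 * x2 / seq
        J[0, 0] = x2          # ks
        J[0, 1] = -x1         # d1
        J[1, 2] = 1.0         # eta0
        J[1, 3] = u           # eta1
        J[1, 4] = -x1 * x2 / seq  # d2
        J[1, 5] = deg * dseq_dkseq / seq   # kseq
        J[1, 6] = deg * dseq_dK3 / seq     # K3
        J[2, 7] = 1.0         # ku0
        J[2, 8] = u           # ku1
        J[2, 9] = -x1 * x3    # kf
        J[2, 10] = -x3        # d3
        return J

    return jac


def _step_input(t: float) -> float:
    """Temperature upshift applied at t = 0."""
    return 1.0 if t >= 0.0 else 0.0


def heat_shock_model(**overrides) -> ODEModel:
    """Heat-shock fixture with the sigma-factor spike (sequestration loop on)."""
    return ODEModel(
        n_states=3,
        rhs=_hs_rhs(spike=True),
        param_names=_HS_NAMES,
        input=_step_input,
        jac_x=_hs_jac_x(spike=True),
        jac_p=_hs_jac_p(spike=True),
        name="heat_shock",
        default_params=_hs_params(overrides),
    )


def heat_shock_nospike_model(**overrides) -> ODEModel:
    """Heat-shock variant with the sequestration feedback loop turned off."""
    return ODEModel(
        n_states=3,
        rhs=_hs_rhs(spike=False),
        param_names=_HS_NAMES,
        input=_step_input,
        jac_x=_hs_jac_x(spike=False),
        jac_p=_hs_jac_p(spike=False),
        name="heat_shock_nospike",
        default_params=_hs_params(overrides),
    )


def heat_shock_steady_state(params: dict | None = None, u: float = 0.0) -> np.ndarray:
    """Steady state of the heat-shock model at constant input ``u``.

    Starts from the closed form that neglects the (tiny) sequestration term
    and polishes it with a root solve on the full RHS.
    """
    p = _hs_params(params or {})
    eta = p["eta0"] + p["eta1"] * u
    ku = p["ku0"] + p["ku1"] * u
    ratio = p["ks"] / p["d1"]
    x2 = np.sqrt(eta / (p["d2"] * ratio))
    x1 = ratio * x2
    x3 = ku / (p["kf"] * x1 + p["d3"])
    rhs = _hs_rhs(spike=True)
    pv = np.array([p[n] for n in _HS_NAMES])
    sol = fsolve(lambda x: rhs(x, u, 0.0, pv), np.array([x1, x2, x3]), full_output=False)
    return np.asarray(sol, float)


def heat_shock_output() -> OutputMap:
    """Chaperone and sigma-factor channels (the measured species)."""
    C = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    return linear_output(C, channel_names=("chaperone", "sigma_factor"))


#: Known measurement-noise variances used by the heat-shock experiments.
HEAT_SHOCK_R = np.array([400.0, 2.0])


# ---------------------------------------------------------------------------
# repressilator fixture

_REPR_ROLES = ("alpha", "K", "n", "gamma", "beta", "delta")
REPRESSILATOR_PARAM_NAMES = tuple(
    f"{role}{i}" for role in _REPR_ROLES for i in (1, 2, 3)
)

#: Symmetric default rates giving a limit cycle (period ~ 12 time units).
REPRESSILATOR_DEFAULTS = np.array(
    [60.0] * 3 + [20.0] * 3 + [2.0] * 3 + [1.0] * 3 + [5.0] * 3 + [1.0] * 3
)

REPRESSILATOR_X0 = np.array([10.0, 1.0, 1.0, 20.0, 1.0, 1.0])


def _repr_rhs(x, u, t, p):
    m = x[:3]
    pr = np.maximum(x[3:], 0.0)
    al, K, n, ga, be, de = (p[3 * i : 3 * i + 3] for i in range(6))
    prev = pr[[2, 0, 1]]  # p0 == p3 convention: gene i repressed by protein i-1
    dm = al / (1.0 + (prev / K) ** n) - ga * m
    dp = be * m - de * x[3:]
    return np.concatenate([dm, dp])


def _repr_jac_x(x, u, t, p):
    m = x[:3]
    pr = np.maximum(x[3:], 0.0)
    al, K, n, ga, be, de = (p[3 * i : 3 * i + 3] for i in range(6))
    J = np.zeros((6, 6))
    prev_idx = [2, 0, 1]
    for i in range(3):
        q = pr[prev_idx[i]] / K[i]
        den = (1.0 + q ** n[i]) ** 2
        dq = n[i] * q ** (n[i] - 1) / K[i] if q > 0 else (n[i] / K[i] if n[i] == 1 else 0.0)
        J[i, i] = -ga[i]
        J[i, 3 + prev_idx[i]] = -al[i] * dq / den
        J[3 + i, i] = be[i]
        J[3 + i, 3 + i] = -de[i]
    return J


def _repr_jac_p(x, u, t, p):
    m = x[:3]
    pr = np.maximum(x[3:], 0.0)
    al, K, n, ga, be, de = (p[3 * i : 3 * i + 3] for i in range(6))
    J = np.zeros((6, 18))
    prev_idx = [2, 0, 1]
    for i in range(3):
        q = pr[prev_idx[i]] / K[i]
        qn = q ** n[i]
        den = 1.0 + qn
        J[i, 0 + i] = 1.0 / den                                # alpha_i
        J[i, 3 + i] = al[i] * n[i] * qn / (K[i] * den**2)      # K_i
        if q > 0:
            J[i, 6 + i] = -al[i] * qn * np.log(q) / den**2     # n_i
        J[i, 9 + i] = -m[i]                                    # gamma_i
        J[3 + i, 12 + i] = m[i]                                # beta_i
        J[3 + i, 15 + i] = -x[3 + i]                           # delta_i
    return J


def repressilator_model(params=None) -> ODEModel:
    """Generalized repressilator: 3 mRNAs, 3 proteins, 18 free kinetic rates."""
    if params is not None:
        params = np.asarray(params, float)
        if params.shape != (18,):
            raise ConfigurationError(
                f"repressilator takes 18 rates, got shape {params.shape}"
            )
        if np.any(params <= 0):
            raise ConfigurationError("repressilator rates must be positive")
    else:
        params = REPRESSILATOR_DEFAULTS
    return ODEModel(
        n_states=6,
        rhs=_repr_rhs,
        param_names=REPRESSILATOR_PARAM_NAMES,
        input=0.0,
        jac_x=_repr_jac_x,
        jac_p=_repr_jac_p,
        name="repressilator",
        default_params=dict(zip(REPRESSILATOR_PARAM_NAMES, params)),
    )


def repressilator_output() -> OutputMap:
    """mRNA concentrations are measured; proteins are not."""
    C = np.zeros((3, 6))
    C[0, 0] = C[1, 1] = C[2, 2] = 1.0
    return linear_output(C, channel_names=("m1", "m2", "m3"))


# ---------------------------------------------------------------------------
# schedules

def heat_shock_schedule() -> SamplingSchedule:
    """22-point dense-then-sparse design.

    Seven dense instants inside the ~50-minute settling transient, then a
    constant 25-minute sampling period out to the horizon.  Only the total
    count (22) and the 25-unit tail spacing are normative; the dense instants
    are implementation choices within that design.
    """
    dense = [2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 50.0]
    tail = list(np.arange(75.0, 450.0, 25.0))  # 75, 100, ..., 425
    return SamplingSchedule(np.array(dense + tail))


def uniform_schedule(n: int, horizon, t_start: float = 0.0) -> SamplingSchedule:
    """``n`` equally spaced instants from ``t_start`` to ``horizon``."""
    if n < 2:
        raise InputError(f"need at least 2 schedule points, got {n}")
    return SamplingSchedule(np.linspace(t_start, float(horizon), int(n)))


# ---------------------------------------------------------------------------
# synthetic measurements

def simulate_measurements(
    model: ODEModel,
    x0,
    schedule: SamplingSchedule,
    output: OutputMap,
    R=None,
    seed: int | None = None,
    params: dict | np.ndarray | None = None,
    relative_noise: float | None = None,
    t0: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> MeasurementSeries:
    """Solve the model, sample the outputs, add zero-mean Gaussian noise.

    ``R`` gives per-channel noise variances (scalar, vector, or diagonal
    matrix; zeros allowed for noise-free channels).  With ``relative_noise``
    set, each channel's variance is instead that fraction of the absolute
    mean of its noise-free signal over the schedule.  Reproducible per seed.
    """
    times = np.asarray(schedule.times, float)
    if params is None:
        p = model.default_param_vector()
    elif isinstance(params, dict):
        p = model.param_vector(params)
    else:
        p = np.asarray(params, float)

    class _Wrapped:
        def rhs_ext(self, t, x):
            return model(x, t, p)

    t_begin = min(t0, times[0])
    traj = simulate(_Wrapped(), x0, (t_begin, times[-1]), rtol=rtol, atol=atol)

    clean = np.full((times.size, output.n_channels), np.nan)
    for k, t in enumerate(times):
        mask = output.observed(k)
        y = output.full(k, np.asarray(traj(t), float))
        clean[k, mask] = y[mask]

    if relative_noise is not None:
        R = relative_noise * np.nanmean(np.abs(clean), axis=0)
    if R is None:
        raise InputError("either R or relative_noise must be supplied")
    R = np.asarray(R, float)
    if R.ndim == 2:
        R = np.diag(R)
    R = np.broadcast_to(np.atleast_1d(R), (output.n_channels,)).copy()
    if np.any(R < 0):
        raise InputError("noise variances must be nonnegative")

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(clean.shape) * np.sqrt(R)[None, :]
    values = clean + np.where(np.isnan(clean), 0.0, noise)
    return MeasurementSeries(
        times=times,
        values=values,
        R=R,
        channel_names=output.channel_names,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# standard run configuration pieces

def default_process_noise(
    x0_states,
    param_guess=(),
    state_frac: float = 0.01,
    param_frac: float = 0.05,
) -> np.ndarray:
    """Scale-relative diagonal Q for the extended state.

    State entries: ``(state_frac * max(|x0_i|, 1))^2``; parameter entries:
    ``param_frac * max(|guess_i|, 1e-6)^2`` — a random walk whose step tracks
    the magnitude of the initial guess.
    """
    x0_states = np.atleast_1d(np.asarray(x0_states, float))
    q_states = (state_frac * np.maximum(np.abs(x0_states), 1.0)) ** 2
    guess = np.atleast_1d(np.asarray(param_guess, float))
    q_params = param_frac * np.maximum(np.abs(guess), 1e-6) ** 2
    return np.concatenate([q_states, q_params])


def positivity_constraints(
    n_states: int, n_free: int, param_lower: float = 0.0
) -> LinearConstraintSet:
    """States nonnegative, free parameters bounded below by ``param_lower``.

    A strictly positive ``param_lower`` keeps rate constants away from zero so
    the model RHS stays evaluable (division by a threshold, 0**n, ...).
    """
    n = n_states + n_free
    lower = np.concatenate([np.zeros(n_states), np.full(n_free, float(param_lower))])
    return LinearConstraintSet(np.eye(n), lower, ">=")


# ---------------------------------------------------------------------------
# registry

@dataclass
class FixtureSpec:
    """Everything needed to run a named fixture end to end."""

    name: str
    build: callable
    output: callable
    default_x0: callable
    default_params: callable
    default_R: callable
    default_schedule: callable
    default_free: tuple = ()
    default_guess: tuple = ()
    relative_noise: float | None = None
    t0: float = 0.0
    param_lower: float = 0.0  # lower bound for free-parameter components


def _hs_x0(params=None):
    return heat_shock_steady_state(params, u=0.0)


MODEL_REGISTRY = {
    "heat_shock": FixtureSpec(
        name="heat_shock",
        build=heat_shock_model,
        output=heat_shock_output,
        default_x0=_hs_x0,
        default_params=lambda: dict(HEAT_SHOCK_DEFAULTS),
        default_R=lambda: HEAT_SHOCK_R.copy(),
        default_schedule=heat_shock_schedule,
        default_free=("ks", "eta1"),
        default_guess=(1.0, 1.0),
    ),
    "heat_shock_nospike": FixtureSpec(
        name="heat_shock_nospike",
        build=heat_shock_nospike_model,
        output=heat_shock_output,
        default_x0=_hs_x0,
        default_params=lambda: dict(HEAT_SHOCK_DEFAULTS),
        default_R=lambda: HEAT_SHOCK_R.copy(),
        default_schedule=heat_shock_schedule,
        default_free=("ks", "eta1"),
        default_guess=(1.0, 1.0),
    ),
    "repressilator": FixtureSpec(
        name="repressilator",
        build=repressilator_model,
        output=repressilator_output,
        default_x0=lambda params=None: REPRESSILATOR_X0.copy(),
        default_params=lambda: dict(
            zip(REPRESSILATOR_PARAM_NAMES, REPRESSILATOR_DEFAULTS)
        ),
        default_R=lambda: None,
        default_schedule=lambda: uniform_schedule(30, 30.0),
        default_free=REPRESSILATOR_PARAM_NAMES,
        default_guess=tuple(REPRESSILATOR_DEFAULTS * 0.5),
        relative_noise=0.05,
        param_lower=1e-3,
    ),
}


def get_fixture(name: str) -> FixtureSpec:
    if name not in MODEL_REGISTRY:
        raise ConfigurationError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        )
    return MODEL_REGISTRY[name]
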