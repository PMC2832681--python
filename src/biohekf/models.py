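"""ODE process models, parameter-extended models, simulation and Jacobians.

A model is an autonomous-in-structure ODE ``x' = f(x, u(t), t, p)`` with a
named parameter vector ``p`` and a scalar external input ``u``.  Unknown
parameters are estimated by *state extension*: they are appended to the state
vector with zero time-derivative, so that parameter estimation becomes state
estimation on the extended system.

Conventions
-----------
* Extended-state ordering: dynamic states first, then free parameters in
  declaration order.  Every covariance matrix in the package follows this
  ordering.
* Jacobians are analytic when the model supplies them, otherwise central
  finite differences with per-component relative steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import linprog

from .errors import ConfigurationError, DomainError, IntegrationError

__all__ = [
    "ODEModel",
    "OutputMap",
    "LinearConstraintSet",
    "ExtendedModel",
    "extend_state",
    "rhs_jacobian",
    "output_jacobian",
    "simulate",
    "linear_output",
]

_FD_STEP = np.sqrt(np.finfo(float).eps)


def _as_input(u) -> Callable[[float], float]:
    """Normalize an input specification (constant or callable) to a callable."""
    if callable(u):
        return u
    value = float(u)
    return lambda t: value


@dataclass
class ODEModel:
    """A parametric ODE process model.

    Parameters
    ----------
    n_states:
        Number of dynamic state variables.
    rhs:
        ``rhs(x, u, t, p) -> dx`` with ``p`` ordered as ``param_names``.
    param_names:
        Ordered names of all model parameters.
    input:
        External forcing ``u(t)``; a constant or a callable of time.
    jac_x, jac_p:
        Optional analytic Jacobians ``df/dx`` (n_states x n_states) and
        ``df/dp`` (n_states x n_params), same signature as ``rhs``.
    """

    n_states: int
    rhs: Callable[..., np.ndarray]
    param_names: Sequence[str]
    input: object = 0.0
    jac_x: Callable[..., np.ndarray] | None = None
    jac_p: Callable[..., np.ndarray] | None = None
    name: str = ""
    default_params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.param_names = tuple(self.param_names)
        self.input_fn = _as_input(self.input)

    def default_param_vector(self) -> np.ndarray:
        if not self.default_params:
            raise ConfigurationError(f"model {self.name!r} has no default parameters")
        return self.param_vector(self.default_params)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def param_vector(self, values: Mapping[str, float]) -> np.ndarray:
        """Assemble the full parameter vector from a name -> value mapping."""
        missing = [n for n in self.param_names if n not in values]
        if missing:
            raise ConfigurationError(f"missing parameter values: {missing}")
        unknown = [n for n in values if n not in self.param_names]
        if unknown:
            raise ConfigurationError(f"unknown parameter name(s): {unknown}")
        return np.array([float(values[n]) for n in self.param_names])

    def __call__(self, x, t, p):
        return np.asarray(self.rhs(np.asarray(x, float), self.input_fn(t), t, p), float)


class OutputMap:
    """Per-time-point output functions with channel masking.

    ``h(k, x_ext)`` returns the full ``n_channels`` output vector at time
    index ``k``; ``observed(k)`` is the boolean mask of channels actually
    measured at ``k``.  The observed rows at ``k`` are ``h(k, x)[observed(k)]``.
    """

    def __init__(self, n_channels, h, mask=None, jacobian=None, channel_names=None):
        self.n_channels = int(n_channels)
        self._h = h
        self._mask = mask
        self.jacobian = jacobian  # (k, x_ext) -> n_channels x n_ext, optional
        self.channel_names = (
            tuple(channel_names)
            if channel_names is not None
            else tuple(f"y{j + 1}" for j in range(self.n_channels))
        )

    def observed(self, k: int) -> np.ndarray:
        if self._mask is None:
            return np.ones(self.n_channels, dtype=bool)
        m = self._mask(k) if callable(self._mask) else self._mask[k]
        m = np.asarray(m, dtype=bool)
        if m.shape != (self.n_channels,):
            raise ConfigurationError(
                f"channel mask at index {k} has shape {m.shape}, "
                f"expected ({self.n_channels},)"
            )
        return m

    def full(self, k: int, x_ext: np.ndarray) -> np.ndarray:
        y = np.asarray(self._h(k, np.asarray(x_ext, float)), float)
        if y.shape != (self.n_channels,):
            raise ConfigurationError(
                f"output function returned shape {y.shape} at index {k}, "
                f"expected ({self.n_channels},)"
            )
        return y

    def h_obs(self, k: int, x_ext: np.ndarray) -> np.ndarray:
        """Observed output rows at time index ``k``."""
        return self.full(k, x_ext)[self.observed(k)]


def linear_output(C, mask=None, channel_names=None) -> OutputMap:
    """Output map ``y = C @ x_ext`` (rows = channels); ships its own Jacobian."""
    C = np.atleast_2d(np.asarray(C, float))
    return OutputMap(
        n_channels=C.shape[0],
        h=lambda k, x: C @ x[: C.shape[1]],
        mask=mask,
        jacobian=lambda k, x: _pad_cols(C, x.size),
        channel_names=channel_names,
    )


def _pad_cols(C: np.ndarray, n: int) -> np.ndarray:
    if C.shape[1] == n:
        return C
    out = np.zeros((C.shape[0], n))
    out[:, : C.shape[1]] = C
    return out


class LinearConstraintSet:
    """Linear inequality constraints ``a_i . x (<=|>=) b_i`` on the extended state.

    Internally normalized to ``G x >= h``.  Feasibility is verified at
    construction by a linear program.
    """

    def __init__(self, matrix, bounds, sense):
        A = np.atleast_2d(np.asarray(matrix, float))
        b = np.atleast_1d(np.asarray(bounds, float))
        if isinstance(sense, str):
            sense = [sense] * A.shape[0]
        sense = list(sense)
        if A.shape[0] != b.size or A.shape[0] != len(sense):
            raise ConfigurationError(
                "constraint matrix rows, bounds and senses must have equal length"
            )
        for s in sense:
            if s not in ("<=", ">="):
                raise ConfigurationError(f"unknown constraint sense {s!r}")
        flip = np.array([-1.0 if s == "<=" else 1.0 for s in sense])
        self.G = A * flip[:, None]
        self.h = b * flip
        self.matrix = A
        self.bounds = b
        self.sense = tuple(sense)
        self._check_feasible()

    @property
    def n_rows(self) -> int:
        return self.G.shape[0]

    @property
    def n_vars(self) -> int:
        return self.G.shape[1]

    def _check_feasible(self):
        n = self.n_vars
        res = linprog(
            c=np.zeros(n),
            A_ub=-self.G,
            b_ub=-self.h,
            bounds=[(None, None)] * n,
            method="highs",
        )
        if not res.success:
            raise ConfigurationError("constraint set has an empty feasible region")

    def satisfied(self, x, tol: float = 1e-9) -> bool:
        return bool(np.all(self.G @ np.asarray(x, float) >= self.h - tol))

    def violation(self, x) -> float:
        """Largest constraint violation (0 when feasible)."""
        slack = self.G @ np.asarray(x, float) - self.h
        return float(max(0.0, -slack.min(initial=0.0)))


def nonnegativity_constraints(n: int) -> LinearConstraintSet:
    """x_i >= 0 for every extended-state component."""
    return LinearConstraintSet(np.eye(n), np.zeros(n), ">=")


@dataclass
class ExtendedModel:
    """An ODE model whose state is ``[dynamic states ; free parameters]``.

    The extended right-hand side reproduces the base RHS on the state block
    (with free parameters read from the extended state) and is identically
    zero on the parameter block.
    """

    base: ODEModel
    free_param_names: tuple
    fixed_params: dict
    output: OutputMap
    Q: np.ndarray
    constraints: LinearConstraintSet | None = None
    _free_idx: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.free_param_names = tuple(self.free_param_names)
        names = self.base.param_names
        self._free_idx = np.array(
            [names.index(n) for n in self.free_param_names], dtype=int
        )
        self._fixed_template = np.zeros(self.base.n_params)
        for n, v in self.fixed_params.items():
            self._fixed_template[names.index(n)] = float(v)

    @property
    def n_states(self) -> int:
        return self.base.n_states

    @property
    def n_free(self) -> int:
        return len(self.free_param_names)

    @property
    def n_ext(self) -> int:
        return self.base.n_states + self.n_free

    def split(self, x_ext):
        x_ext = np.asarray(x_ext, float)
        return x_ext[: self.n_states], x_ext[self.n_states :]

    def full_params(self, theta) -> np.ndarray:
        """Full base-model parameter vector for free-parameter values ``theta``."""
        p = self._fixed_template.copy()
        if self.n_free:
            p[self._free_idx] = np.asarray(theta, float)
        return p

    def rhs_ext(self, t: float, x_ext: np.ndarray) -> np.ndarray:
        x, theta = self.split(x_ext)
        p = self.full_params(theta)
        dx = self.base(x, t, p)
        if dx.shape != (self.n_states,):
            raise ConfigurationError(
                f"base RHS returned shape {dx.shape}, expected ({self.n_states},)"
            )
        return np.concatenate([dx, np.zeros(self.n_free)])

    def extended_x0(self, x0, theta0) -> np.ndarray:
        return np.concatenate([np.asarray(x0, float), np.asarray(theta0, float)])


def extend_state(
    model: ODEModel,
    free_params: Sequence[str],
    fixed_values: Mapping[str, float],
    output: OutputMap,
    Q,
    constraints: LinearConstraintSet | None = None,
) -> ExtendedModel:
    """Build the parameter-extended model for ``free_params``.

    ``free_params`` and ``fixed_values`` must partition the model's parameter
    names.  ``Q`` is the diagonal process-noise covariance of the extended
    state (a vector of diagonal entries or a diagonal matrix).
    """
    free = tuple(free_params)
    for n in free:
        if n not in model.param_names:
            raise ConfigurationError(f"unknown free parameter {n!r}")
    for n in fixed_values:
        if n not in model.param_names:
            raise ConfigurationError(f"unknown fixed parameter {n!r}")
    overlap = set(free) & set(fixed_values)
    if overlap:
        raise ConfigurationError(f"parameters both free and fixed: {sorted(overlap)}")
    covered = set(free) | set(fixed_values)
    if covered != set(model.param_names):
        missing = set(model.param_names) - covered
        raise ConfigurationError(f"parameters neither free nor fixed: {sorted(missing)}")

    n_ext = model.n_states + len(free)
    Q = np.asarray(Q, float)
    if Q.ndim == 2:
        if not np.allclose(Q, np.diag(np.diag(Q))):
            raise ConfigurationError("Q must be diagonal")
        Q = np.diag(Q)
    if Q.shape != (n_ext,):
        raise ConfigurationError(
            f"Q has {Q.size} diagonal entries, expected n_ext = {n_ext}"
        )
    if np.any(Q < 0):
        raise ConfigurationError("Q diagonal entries must be nonnegative")
    if constraints is not None and constraints.n_vars != n_ext:
        raise ConfigurationError(
            f"constraint set acts on {constraints.n_vars} variables, expected {n_ext}"
        )
    return ExtendedModel(
        base=model,
        free_param_names=free,
        fixed_params=dict(fixed_values),
        output=output,
        Q=Q,
        constraints=constraints,
    )


def _fd_jacobian(fun, x, tol_context="RHS"):
    """Central finite-difference Jacobian of ``fun`` at ``x``.

    Step per component: sqrt(machine eps) * max(|x_i|, 1).
    """
    x = np.asarray(x, float)
    f0 = np.asarray(fun(x), float)
    J = np.empty((f0.size, x.size))
    for i in range(x.size):
        h = _FD_STEP * max(abs(x[i]), 1.0)
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        fp = np.asarray(fun(xp), float)
        fm = np.asarray(fun(xm), float)
        if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fm))):
            raise DomainError(
                f"{tol_context} not evaluable at perturbation of component {i}"
            )
        J[:, i] = (fp - fm) / (2 * h)
    return J


def rhs_jacobian(ext: ExtendedModel, x_ext, t: float) -> np.ndarray:
    """Jacobian of the extended RHS w.r.t. the extended state.

    Analytic when the base model provides ``jac_x`` and ``jac_p``; otherwise
    central finite differences.  Parameter rows are exactly zero either way.
    """
    x_ext = np.asarray(x_ext, float)
    n, m = ext.n_states, ext.n_free
    J = np.zeros((n + m, n + m))
    x, theta = ext.split(x_ext)
    p = ext.full_params(theta)
    u = ext.base.input_fn(t)
    if ext.base.jac_x is not None and (m == 0 or ext.base.jac_p is not None):
        J[:n, :n] = np.asarray(ext.base.jac_x(x, u, t, p), float)
        if m:
            Jp = np.asarray(ext.base.jac_p(x, u, t, p), float)
            J[:n, n:] = Jp[:, ext._free_idx]
    else:
        full = _fd_jacobian(lambda z: ext.rhs_ext(t, z), x_ext, "extended RHS")
        J[:n, :] = full[:n, :]
    return J


def output_jacobian(ext: ExtendedModel, k: int, x_ext) -> np.ndarray:
    """Jacobian of the observed output rows at time index ``k``.

    Rows are ordered as the observed-channel mask; analytic-else-FD policy as
    for :func:`rhs_jacobian`.
    """
    x_ext = np.asarray(x_ext, float)
    mask = ext.output.observed(k)
    if not mask.any():
        raise ConfigurationError(f"no observed channels at time index {k}")
    if ext.output.jacobian is not None:
        H = np.asarray(ext.output.jacobian(k, x_ext), float)
        if H.shape != (ext.output.n_channels, x_ext.size):
            raise ConfigurationError(
                f"output Jacobian has shape {H.shape}, expected "
                f"({ext.output.n_channels}, {x_ext.size})"
            )
        return H[mask]
    full = _fd_jacobian(lambda z: ext.output.full(k, z), x_ext, "output function")
    return full[mask]


class _BlowUpError(Exception):
    """Internal: integration left the representable range."""

    def __init__(self, t):
        self.t = t


def guard_rhs(fun, cap: float = 1e100):
    """Wrap an ODE RHS to abort promptly on non-finite or huge values.

    Adaptive solvers can otherwise grind with ever-smaller steps toward a
    finite-time blow-up.
    """

    def wrapped(t, y):
        if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > cap:
            raise _BlowUpError(t)
        dy = np.asarray(fun(t, y), float)
        if not np.all(np.isfinite(dy)):
            raise _BlowUpError(t)
        return dy

    return wrapped


class Trajectory:
    """Dense ODE solution queryable at arbitrary times within its span."""

    def __init__(self, sol, t_span):
        self._sol = sol
        self.t_span = t_span

    def __call__(self, t):
        return self._sol.sol(t)


def simulate(
    ext,
    x0_ext,
    t_span,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Dense solution of the (extended) model over ``t_span``.

    Accepts an :class:`ExtendedModel` or a bare :class:`ODEModel` with a full
    parameter vector baked in via ``functools.partial``-style wrapper; the
    standard entry point is the extended model.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ConfigurationError(f"degenerate time span ({t0}, {t1})")
    if rtol <= 0 or atol <= 0:
        raise ConfigurationError("integrator tolerances must be positive")
    fun = ext.rhs_ext if hasattr(ext, "rhs_ext") else ext
    try:
        sol = solve_ivp(
            guard_rhs(fun),
            (t0, t1),
            np.asarray(x0_ext, float),
            method=method,
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
    except _BlowUpError as exc:
        raise IntegrationError(
            f"integration blew up near t = {exc.t}", t_last=float(exc.t)
        ) from None
    if not sol.success:
        raise IntegrationError(
            f"integration failed: {sol.message}",
            t_last=float(sol.t[-1]) if sol.t.size else t0,
        )
    return Trajectory(sol, (t0, t1))
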