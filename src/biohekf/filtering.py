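"""Constrained hybrid extended Kalman filter.

Prediction integrates the nonlinear extended ODE together with the
differential Lyapunov equation ``P' = F P + P F' + Q`` (F evaluated along the
evolving state estimate), correction applies the linearized gain update at
each measurement instant, and a strictly convex QP projects the corrected
estimate back onto the feasible region when linear constraints are violated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import cholesky, eigh
from scipy.optimize import nnls

from .errors import (
    ConfigurationError,
    FilterDivergenceError,
    InputError,
    IntegrationError,
)
from .models import (
    ExtendedModel,
    LinearConstraintSet,
    _BlowUpError,
    guard_rhs,
    output_jacobian,
    rhs_jacobian,
)

__all__ = [
    "FilterConfig",
    "FilterStep",
    "FilterTrajectory",
    "time_update",
    "kalman_gain",
    "measurement_update",
    "constrain_estimate",
    "run_hekf",
    "final_estimate",
]


@dataclass
class FilterConfig:
    """Initial conditions and numerical settings for the filter.

    ``x0_ext`` is the initial extended-state estimate (expected value of the
    initial extended state) and ``P0`` the initial error covariance.  ``R`` is
    the diagonal of the measurement-noise covariance over all channels, taken
    as known.  ``t0`` is the time at which ``x0_ext`` applies.
    """

    x0_ext: np.ndarray
    P0: np.ndarray
    R: np.ndarray
    t0: float = 0.0
    rtol: float = 1e-8
    atol: float = 1e-10
    cov_rtol: float = 1e-6
    cov_atol: float = 1e-8
    integrator: str = "LSODA"
    averaging_window: int = 10
    joseph: bool = False
    cond_limit: float = 1e12
    eig_floor_tol: float = 1e-10

    def __post_init__(self):
        self.x0_ext = np.asarray(self.x0_ext, float)
        P0 = np.asarray(self.P0, float)
        if P0.ndim == 1:
            P0 = np.diag(P0)
        if P0.shape != (self.x0_ext.size, self.x0_ext.size):
            raise ConfigurationError("P0 dimension does not match x0_ext")
        if not np.allclose(P0, P0.T, atol=1e-12):
            raise ConfigurationError("P0 must be symmetric (tolerance 1e-12)")
        self.P0 = P0
        R = np.asarray(self.R, float)
        if R.ndim == 2:
            R = np.diag(R)
        if np.any(R <= 0):
            raise ConfigurationError("R diagonal must be strictly positive")
        self.R = R


def default_P0(x0_ext) -> np.ndarray:
    """diag(max(|x0_i|, 1)^2) — the package default when none is supplied."""
    x0_ext = np.asarray(x0_ext, float)
    return np.diag(np.maximum(np.abs(x0_ext), 1.0) ** 2)


@dataclass
class FilterStep:
    k: int
    t: float
    x_prior: np.ndarray
    x_post: np.ndarray
    x_constrained: np.ndarray
    P_prior: np.ndarray
    P_post: np.ndarray
    gain: np.ndarray | None = None
    innovation: np.ndarray | None = None


@dataclass
class FilterTrajectory:
    """Ordered filter steps plus the window-averaged final parameter estimate."""

    steps: list
    final_params: np.ndarray | None
    diverged: bool = False
    divergence_message: str = ""
    n_states: int = 0

    @property
    def times(self):
        return np.array([s.t for s in self.steps])

    def param_track(self) -> np.ndarray:
        """Constrained a posteriori parameter components, one row per step."""
        return np.array([s.x_constrained[self.n_states :] for s in self.steps])

    def state_estimates(self) -> np.ndarray:
        return np.array([s.x_constrained for s in self.steps])

    def to_json(self, include_covariances: bool = False) -> dict:
        out = {
            "diverged": self.diverged,
            "final_params": None
            if self.final_params is None
            else self.final_params.tolist(),
            "steps": [],
        }
        if self.divergence_message:
            out["divergence_message"] = self.divergence_message
        for s in self.steps:
            entry = {
                "k": s.k,
                "t": s.t,
                "x_prior": s.x_prior.tolist(),
                "x_post": s.x_post.tolist(),
                "x_constrained": s.x_constrained.tolist(),
                "innovation": None if s.innovation is None else s.innovation.tolist(),
            }
            if include_covariances:
                entry["P_prior"] = s.P_prior.tolist()
                entry["P_post"] = s.P_post.tolist()
            out["steps"].append(entry)
        return out


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return 0.5 * (P + P.T)


def _floor_eigenvalues(P: np.ndarray, tol: float) -> np.ndarray:
    """Clip slightly negative eigenvalues to zero; error on genuinely negative ones."""
    w, V = eigh(P)
    if w.min() >= 0:
        return P
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise FilterDivergenceError(
            f"covariance lost positive semidefiniteness (min eigenvalue {w.min():.3e})"
        )
    w = np.clip(w, 0.0, None)
    return _symmetrize((V * w) @ V.T)


def time_update(x_start, P_start, ext: ExtendedModel, t_start, t_next, cfg: FilterConfig):
    """Propagate state and covariance from ``t_start`` to ``t_next``.

    The extended state and the Lyapunov equation are integrated as one stacked
    system so F is evaluated along the evolving estimate.  Returns the
    symmetrized a priori pair ``(x_prior, P_prior)``.
    """
    if not t_next > t_start:
        raise InputError(f"time update requires t_next > t_start ({t_next} <= {t_start})")
    n = ext.n_ext
    Qm = np.diag(ext.Q)

    def stacked(t, z):
        x = z[:n]
        P = z[n:].reshape(n, n)
        F = rhs_jacobian(ext, x, t)
        dP = F @ P + P @ F.T + Qm
        return np.concatenate([ext.rhs_ext(t, x), dP.ravel()])

    z0 = np.concatenate([np.asarray(x_start, float), np.asarray(P_start, float).ravel()])
    atol = np.concatenate(
        [np.full(n, cfg.atol), np.full(n * n, cfg.cov_atol)]
    )
    try:
        sol = solve_ivp(
            guard_rhs(stacked),
            (float(t_start), float(t_next)),
            z0,
            method=cfg.integrator,
            rtol=max(cfg.rtol, cfg.cov_rtol),
            atol=atol,
        )
    except _BlowUpError as exc:
        raise IntegrationError(
            f"time update blew up near t = {exc.t}", t_last=float(exc.t)
        ) from None
    if not sol.success:
        raise IntegrationError(
            f"time update failed: {sol.message}",
            t_last=float(sol.t[-1]) if sol.t.size else t_start,
        )
    zT = sol.y[:, -1]
    x_prior = zT[:n]
    P_prior = _symmetrize(zT[n:].reshape(n, n))
    return x_prior, P_prior


def kalman_gain(P_prior, H, R_k, cond_limit: float = 1e12):
    """K = P H' (H P H' + R_k)^{-1}, computed with a linear solve."""
    P_prior = np.asarray(P_prior, float)
    H = np.atleast_2d(np.asarray(H, float))
    R_k = np.asarray(R_k, float)
    if R_k.ndim == 1:
        R_k = np.diag(R_k)
    S = H @ P_prior @ H.T + R_k
    S = _symmetrize(S)
    if not np.all(np.isfinite(S)) or np.linalg.cond(S) > cond_limit:
        raise FilterDivergenceError(
            "innovation covariance is numerically singular"
        )
    # K S = P H'  =>  S' K' = H P'  (S symmetric)
    K = np.linalg.solve(S, H @ P_prior).T
    return K


def measurement_update(x_prior, P_prior, y_k, ext: ExtendedModel, k: int, cfg: FilterConfig):
    """Correct the a priori pair with the observed channels at step ``k``.

    Returns ``(x_post, P_post, gain, innovation)``.  ``y_k`` holds only the
    observed channels, ordered as the channel mask.
    """
    mask = ext.output.observed(k)
    if not mask.any():
        raise InputError(f"no observed channel at time index {k}")
    y_k = np.atleast_1d(np.asarray(y_k, float))
    if y_k.size != mask.sum():
        raise InputError(
            f"{y_k.size} measurements supplied at index {k}, {mask.sum()} channels observed"
        )
    H = output_jacobian(ext, k, x_prior)
    R_k = np.diag(cfg.R[mask])
    K = kalman_gain(P_prior, H, R_k, cfg.cond_limit)
    innovation = y_k - ext.output.h_obs(k, x_prior)
    x_post = x_prior + K @ innovation
    I = np.eye(x_prior.size)
    if cfg.joseph:
        A = I - K @ H
        P_post = A @ P_prior @ A.T + K @ R_k @ K.T
    else:
        P_post = (I - K @ H) @ P_prior
    P_post = _floor_eigenvalues(_symmetrize(P_post), cfg.eig_floor_tol)
    return x_post, P_post, K, innovation


def _ldp(G, h):
    """Least-distance program: min ||z|| s.t. G z >= h (Lawson–Hanson via NNLS)."""
    m, n = G.shape
    E = np.vstack([G.T, h[None, :]])  # (n+1) x m
    f = np.zeros(n + 1)
    f[-1] = 1.0
    u, rnorm = nnls(E, f)
    r = E @ u - f
    if abs(r[-1]) < 1e-12:
        raise FilterDivergenceError("constraint projection failed (LDP degenerate)")
    return -r[:-1] / r[-1]


def constrain_estimate(x_post, P_post, constraints: LinearConstraintSet | None, tol: float = 1e-9):
    """Project ``x_post`` onto the feasible region in the P-inverse metric.

    The projection minimizes ``(x - x_post)' P^{-1} (x - x_post)`` subject to
    the linear constraints — the maximizer of the conditional Gaussian
    log-density over the feasible set.  Feasible inputs are returned
    unchanged (bitwise).
    """
    if constraints is None or constraints.satisfied(x_post, tol):
        return x_post
    P = _symmetrize(np.asarray(P_post, float))
    n = P.shape[0]
    try:
        L = cholesky(P, lower=True)
    except np.linalg.LinAlgError:
        L = cholesky(P + 1e-12 * np.eye(n), lower=True)
    # x = x_post + L z  turns the QP into min ||z|| s.t. (G L) z >= h - G x_post
    G = constraints.G @ L
    h = constraints.h - constraints.G @ np.asarray(x_post, float)
    z = _ldp(G, h)
    x_c = np.asarray(x_post, float) + L @ z
    if not constraints.satisfied(x_c, tol):
        raise FilterDivergenceError("constrained estimate infeasible after projection")
    return x_c


def run_hekf(ext: ExtendedModel, data, cfg: FilterConfig) -> FilterTrajectory:
    """Run the constrained hybrid filter over a measurement series.

    Per time point: propagate (state + Lyapunov covariance), compute the gain,
    correct with the observed channels, then enforce the constraints via the
    QP when violated.  The final parameter estimate averages the parameter
    components of the last ``averaging_window`` constrained estimates.
    Divergence is flagged, not raised; the partial trajectory is retained.
    """
    times = np.asarray(data.times, float)
    if times.size == 0:
        raise InputError("empty measurement series")
    if np.any(np.diff(times) <= 0):
        raise InputError("measurement times must be strictly increasing")
    if cfg.R.size != ext.output.n_channels:
        raise ConfigurationError(
            f"R has {cfg.R.size} entries, output map has {ext.output.n_channels} channels"
        )
    if cfg.averaging_window > times.size:
        raise InputError(
            f"averaging_window ({cfg.averaging_window}) exceeds number of steps ({times.size})"
        )
    if cfg.x0_ext.size != ext.n_ext:
        raise ConfigurationError("x0_ext dimension does not match extended model")

    steps: list[FilterStep] = []
    x_c = cfg.x0_ext.copy()
    P = cfg.P0.copy()
    t_prev = cfg.t0
    diverged = False
    message = ""
    for k, t_k in enumerate(times):
        try:
            if t_k > t_prev:
                x_prior, P_prior = time_update(x_c, P, ext, t_prev, t_k, cfg)
            else:
                x_prior, P_prior = x_c.copy(), P.copy()
            y_k = data.observed_values(k)
            mask = data.observed_mask(k)
            if mask.any():
                x_post, P_post, K, innov = measurement_update(
                    x_prior, P_prior, y_k, ext, k, cfg
                )
            else:
                x_post, P_post, K, innov = x_prior.copy(), P_prior.copy(), None, None
            if not np.all(np.isfinite(x_post)):
                raise FilterDivergenceError("non-finite state estimate", k=k)
            x_c = constrain_estimate(x_post, P_post, ext.constraints)
        except (IntegrationError, FilterDivergenceError) as exc:
            diverged = True
            message = f"step {k} (t={t_k}): {exc}"
            break
        P = P_post
        steps.append(
            FilterStep(
                k=k,
                t=float(t_k),
                x_prior=x_prior,
                x_post=x_post,
                x_constrained=x_c,
                P_prior=P_prior,
                P_post=P_post,
                gain=K,
                innovation=innov,
            )
        )
        t_prev = t_k

    traj = FilterTrajectory(
        steps=steps,
        final_params=None,
        diverged=diverged,
        divergence_message=message,
        n_states=ext.n_states,
    )
    window = min(cfg.averaging_window, len(steps))
    if window >= 1 and ext.n_free:
        traj.final_params = final_estimate(traj, window)
    return traj


def final_estimate(traj: FilterTrajectory, window: int) -> np.ndarray:
    """Mean of the parameter components over the last ``window`` constrained estimates."""
    if window < 1 or window > len(traj.steps):
        raise InputError(
            f"window must be in [1, {len(traj.steps)}], got {window}"
        )
    track = traj.param_track()
    return track[-window:].mean(axis=0)
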