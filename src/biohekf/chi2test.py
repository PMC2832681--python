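"""A posteriori chi-square identifiability test.

Residuals between measurements and predicted outputs are treated as samples
of the (zero-mean, known-variance) measurement noise.  A point estimate of
each channel's variance is formed from the sum of squared residuals, an
interval estimate follows from chi-square quantiles, and an estimate is
rejected when the known true variance falls outside the interval.

The noise mean is known to be zero by assumption, so the point estimate uses
the zero-mean sum-of-squares form and the interval uses N (not N-1) degrees
of freedom; an ``ddof`` switch selects the mean-corrected variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .errors import InputError
from .models import ExtendedModel, simulate

__all__ = [
    "ResidualSet",
    "ChannelTest",
    "VarianceTestReport",
    "residuals",
    "variance_point_estimate",
    "variance_interval",
    "chi2_test",
    "predict_from_model",
    "predict_from_filter",
]


@dataclass
class ResidualSet:
    """Per-channel residual samples y_j(t_k) - h_j(x(t_k)) over observed pairs."""

    samples: list  # list of 1-D arrays, one per channel
    channel_names: tuple

    @property
    def n_channels(self) -> int:
        return len(self.samples)

    def counts(self) -> np.ndarray:
        return np.array([s.size for s in self.samples])


@dataclass
class ChannelTest:
    channel: str
    point_estimate: float
    lo: float
    hi: float
    true_variance: float
    n_samples: int
    passed: bool
    degenerate: bool = False


@dataclass
class VarianceTestReport:
    gamma: float
    channels: list
    overall_pass: bool = field(init=False)

    def __post_init__(self):
        self.overall_pass = all(c.passed for c in self.channels)

    def to_json(self) -> dict:
        return {
            "gamma": self.gamma,
            "overall_pass": self.overall_pass,
            "channels": [
                {
                    "channel": c.channel,
                    "point_estimate": c.point_estimate,
                    "interval": [c.lo, c.hi],
                    "true_variance": c.true_variance,
                    "n_samples": c.n_samples,
                    "pass": c.passed,
                    "degenerate": c.degenerate,
                }
                for c in self.channels
            ],
        }

    def to_text(self) -> str:
        lines = [
            f"chi-square variance test (gamma = {self.gamma})",
            f"{'channel':<12}{'point':>12}{'interval':>28}{'true var':>12}{'verdict':>10}",
        ]
        for c in self.channels:
            iv = f"[{c.lo:.4g}, {c.hi:.4g}]"
            verdict = "pass" if c.passed else "FAIL"
            lines.append(
                f"{c.channel:<12}{c.point_estimate:>12.4g}{iv:>28}"
                f"{c.true_variance:>12.4g}{verdict:>10}"
            )
        lines.append(f"overall: {'pass' if self.overall_pass else 'FAIL'}")
        return "\n".join(lines)


def residuals(data, predicted) -> ResidualSet:
    """Residuals over observed (time, channel) pairs.

    ``predicted`` is an (N x n_channels) array of predicted outputs; entries
    at unobserved pairs are ignored (may be NaN).  A NaN prediction at an
    observed pair is an input error.
    """
    predicted = np.asarray(predicted, float)
    values = data.values
    if predicted.shape != values.shape:
        raise InputError(
            f"predicted outputs shape {predicted.shape} does not match data {values.shape}"
        )
    samples = []
    for j in range(values.shape[1]):
        obs = ~np.isnan(values[:, j])
        pred_j = predicted[obs, j]
        if np.any(np.isnan(pred_j)):
            raise InputError(f"missing prediction at observed pair(s) in channel {j}")
        samples.append(values[obs, j] - pred_j)
    return ResidualSet(samples=samples, channel_names=tuple(data.channel_names))


def variance_point_estimate(res: ResidualSet, j: int, ddof: int = 0) -> float:
    """Zero-mean sum-of-squares variance estimate of channel ``j``."""
    e = res.samples[j]
    if e.size < 2:
        raise InputError(f"channel {j} has {e.size} residual samples; need >= 2")
    if ddof == 0:
        return float(np.sum(e**2) / e.size)
    return float(np.sum((e - e.mean()) ** 2) / (e.size - ddof))


def variance_interval(S_j: float, N_j: int, gamma: float, ddof: int = 0):
    """Confidence interval for the true variance from the chi-square law.

    ``[N S / q_{(1+g)/2}, N S / q_{(1-g)/2}]`` with quantiles of the
    chi-square distribution with ``N - ddof`` degrees of freedom.
    """
    if not 0.0 < gamma < 1.0:
        raise InputError(f"gamma must be in (0, 1), got {gamma}")
    if N_j < 2:
        raise InputError(f"need at least 2 samples, got {N_j}")
    if S_j < 0:
        raise InputError("variance point estimate must be nonnegative")
    dof = N_j - ddof
    q_hi = chi2.ppf((1.0 + gamma) / 2.0, dof)
    q_lo = chi2.ppf((1.0 - gamma) / 2.0, dof)
    return N_j * S_j / q_hi, N_j * S_j / q_lo


def chi2_test(data, predicted, R, gamma: float, ddof: int = 0) -> VarianceTestReport:
    """Accept or reject an estimate against the known noise variances.

    A channel passes when its known variance ``R_jj`` lies inside the interval
    estimate built from the residuals; the overall verdict is the conjunction
    over channels.
    """
    R = np.asarray(R, float)
    if R.ndim == 2:
        R = np.diag(R)
    if np.any(R <= 0):
        raise InputError("R diagonal entries must be strictly positive")
    res = residuals(data, predicted)
    if R.size != res.n_channels:
        raise InputError(
            f"R has {R.size} entries for {res.n_channels} channels"
        )
    channels = []
    for j in range(res.n_channels):
        S = variance_point_estimate(res, j, ddof)
        N = res.samples[j].size
        if S == 0.0:
            channels.append(
                ChannelTest(
                    channel=res.channel_names[j],
                    point_estimate=0.0,
                    lo=0.0,
                    hi=0.0,
                    true_variance=float(R[j]),
                    n_samples=N,
                    passed=False,
                    degenerate=True,
                )
            )
            continue
        lo, hi = variance_interval(S, N, gamma, ddof)
        channels.append(
            ChannelTest(
                channel=res.channel_names[j],
                point_estimate=S,
                lo=lo,
                hi=hi,
                true_variance=float(R[j]),
                n_samples=N,
                passed=bool(lo <= R[j] <= hi),
            )
        )
    return VarianceTestReport(gamma=gamma, channels=channels)


def predict_from_model(
    ext: ExtendedModel,
    theta,
    x0,
    times,
    t0: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Predicted outputs from the model solution at parameters ``theta``.

    Solves the extended ODE from state initial condition ``x0`` (applying at
    time ``t0``) and evaluates the output map at every sample time.  Returns
    an (N x n_channels) array with NaN at unobserved pairs.
    """
    times = np.asarray(times, float)
    x0_ext = ext.extended_x0(x0, theta)
    t0 = min(t0, times[0])
    traj = simulate(ext, x0_ext, (t0, times[-1]), rtol=rtol, atol=atol)
    out = np.full((times.size, ext.output.n_channels), np.nan)
    for k, t in enumerate(times):
        mask = ext.output.observed(k)
        y = ext.output.full(k, traj(t))
        out[k, mask] = y[mask]
    return out


def predict_from_filter(traj, ext: ExtendedModel) -> np.ndarray:
    """Predicted outputs from the filter's constrained a posteriori estimates.

    Usable when initial conditions are unknown: the filter state estimates
    stand in for the model solution.
    """
    out = np.full((len(traj.steps), ext.output.n_channels), np.nan)
    for s in traj.steps:
        mask = ext.output.observed(s.k)
        y = ext.output.full(s.k, s.x_constrained)
        out[s.k, mask] = y[mask]
    return out
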