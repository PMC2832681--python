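"""Chi-square model selection among candidate models of the same process.

Each candidate is filtered against the shared measurement series; residuals
against the filter-predicted outputs (so unknown initial conditions are
tolerated) feed the variance point/interval estimates, and candidates whose
intervals exclude the known noise variances are discarded.  Among retained
candidates, the one whose point estimates sit closest to the true variances
(sum of per-channel relative absolute deviations) is selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chi2test import VarianceTestReport, chi2_test, predict_from_filter
from .errors import InputError
from .filtering import FilterConfig, run_hekf
from .models import ExtendedModel

__all__ = ["Candidate", "ModelSelectionReport", "select_model"]


@dataclass
class Candidate:
    name: str
    ext: ExtendedModel
    filter_cfg: FilterConfig


@dataclass
class ModelSelectionReport:
    gamma: float
    reports: dict  # name -> VarianceTestReport | None (None when diverged)
    retained: list
    rejected: list
    best: str | None
    divergence: dict  # name -> message, for auto-rejected candidates

    def to_json(self) -> dict:
        return {
            "gamma": self.gamma,
            "retained": self.retained,
            "rejected": self.rejected,
            "best": self.best,
            "divergence": self.divergence,
            "reports": {
                name: (rep.to_json() if rep is not None else None)
                for name, rep in self.reports.items()
            },
        }


def _closeness(report: VarianceTestReport) -> float:
    return sum(
        abs(c.point_estimate - c.true_variance) / c.true_variance
        for c in report.channels
    )


def select_model(candidates, data, gamma: float = 0.95) -> ModelSelectionReport:
    """Run the filter per candidate and keep those consistent with the noise.

    Candidates with no free parameters are allowed (pure state estimation).
    A candidate whose filter diverges is auto-rejected with an annotation.
    """
    candidates = list(candidates)
    if not candidates:
        raise InputError("need at least one candidate model")
    reports: dict = {}
    divergence: dict = {}
    retained: list = []
    rejected: list = []
    for cand in candidates:
        traj = run_hekf(cand.ext, data, cand.filter_cfg)
        if traj.diverged or not traj.steps:
            reports[cand.name] = None
            divergence[cand.name] = traj.divergence_message or "filter diverged"
            rejected.append(cand.name)
            continue
        predicted = predict_from_filter(traj, cand.ext)
        report = chi2_test(data, predicted, data.R, gamma)
        reports[cand.name] = report
        if report.overall_pass:
            retained.append(cand.name)
        else:
            rejected.append(cand.name)
    best = None
    if retained:
        best = min(retained, key=lambda n: _closeness(reports[n]))
    return ModelSelectionReport(
        gamma=gamma,
        reports=reports,
        retained=retained,
        rejected=rejected,
        best=best,
        divergence=divergence,
    )
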