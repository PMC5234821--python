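"""Between-subjects analysis of headway adaptation to occlusion.

Two competing task-capability-interface formulations are compared on
per-subject aggregates: the baseline-independent relationship
dT ~ o (headway increase proportional to mean occlusion duration alone)
against the baseline-relative one dT/T0 ~ o (increase scaled by the
undistracted headway).  Spearman correlations are compared with Zou's
confidence interval for dependent overlapping correlations, and the
headway-increase slope is fit by OLS with a joint test of the identity
line dT = o.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import statcore
from .preprocess import SubjectSummary
from .statcore import Interval, OLSResult

__all__ = [
    "CorrelationComparison",
    "SlopeFit",
    "CapabilityEstimate",
    "compare_models",
    "fit_headway_slope",
    "capability_estimate",
]


@dataclass(frozen=True)
class CorrelationComparison:
    r_indep: float  # Spearman(dT, o)
    r_rel: float  # Spearman(dT/T0, o)
    ci_indep: Interval
    ci_rel: Interval
    r_overlap: float  # Spearman(dT, dT/T0)
    diff_ci: Interval  # 95% CI for r_indep - r_rel (Zou)
    n: int


@dataclass(frozen=True)
class SlopeFit:
    alpha: float
    alpha0: float
    r_squared: float
    slope_ci: Interval
    intercept_ci: Interval
    identity_line_inside: bool
    joint_p: float
    n: int


@dataclass(frozen=True)
class CapabilityEstimate:
    C_hat: float  # 1/s
    o_hat: float
    T_hat_0: float


def _arrays(summaries: list[SubjectSummary]):
    dT = np.array([s.delta_T for s in summaries])
    dRel = np.array([s.delta_rel for s in summaries])
    o = np.array([s.o_hat_D for s in summaries])
    return dT, dRel, o


def compare_models(summaries: list[SubjectSummary], level: float = 0.95) -> CorrelationComparison:
    """Spearman comparison of the two formulations against mean occlusion.

    Both correlations share the occlusion variable, so the difference CI
    uses Zou's dependent-overlapping procedure with the overlap
    correlation estimated from the data; everything operates on average
    ranks (Spearman = Pearson on ranks).
    """
    n = len(summaries)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    dT, dRel, o = _arrays(summaries)
    r_indep = statcore.spearman_rho(o, dT)
    r_rel = statcore.spearman_rho(o, dRel)
    r_overlap = statcore.spearman_rho(dT, dRel)
    return CorrelationComparison(
        r_indep=r_indep,
        r_rel=r_rel,
        ci_indep=statcore.fisher_z_ci(r_indep, n, level),
        ci_rel=statcore.fisher_z_ci(r_rel, n, level),
        r_overlap=r_overlap,
        diff_ci=statcore.zou_diff_ci(r_indep, r_rel, r_overlap, n, level),
        n=n,
    )


def fit_headway_slope(summaries: list[SubjectSummary], level: float = 0.95) -> SlopeFit:
    """OLS of headway increase dT on mean occlusion duration o.

    ``identity_line_inside`` reports whether (slope, intercept) = (1, 0) —
    a one-to-one headway/occlusion trade — lies inside the joint
    confidence region (F test not rejected at 1 - level).
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 subjects")
    dT, _, o = _arrays(summaries)
    res: OLSResult = statcore.ols_fit(o, dT, level=level, joint=(1.0, 0.0))
    return SlopeFit(
        alpha=res.slope,
        alpha0=res.intercept,
        r_squared=res.r_squared,
        slope_ci=res.slope_ci,
        intercept_ci=res.intercept_ci,
        identity_line_inside=bool(res.joint_p >= 1.0 - level),
        joint_p=float(res.joint_p),
        n=len(summaries),
    )


def capability_estimate(o_hat: float, T_hat_0: float) -> CapabilityEstimate:
    """Operationalised driver capability C = 1/(o + T0), in 1/s.

    Mean occlusion duration indexes distraction and the unoccluded headway
    indexes the inverse of base capability, so capability under
    distraction is the inverse of their sum.
    """
    if o_hat < 0:
        raise ValueError("o_hat must be >= 0")
    if T_hat_0 <= 0:
        raise ValueError("T_hat_0 must be positive")
    return CapabilityEstimate(
        C_hat=1.0 / (o_hat + T_hat_0), o_hat=o_hat, T_hat_0=T_hat_0
    )
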