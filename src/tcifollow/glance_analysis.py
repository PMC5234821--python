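"""Within-trial, glance-by-glance analysis.

Both signals — instantaneous headway at glance onset T(t_g) and the
following occlusion duration o(t_g) — drift slowly with a driver's
within-trial preferences, so each trial's signals are detrended with a
robust (Theil–Sen) line over onset time before correlating.  Evidence is
summarised by per-trial Spearman correlations, exact binomial sign tests
over trials and over subjects, and per-subject Passing–Bablok regressions
of detrended occlusion duration on detrended headway (symmetric in the
variables, since neither is under experimental control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import statcore
from .driver_sim import TrialRecord
from .preprocess import GlanceSample, glance_onset_samples
from .statcore import Interval

logger = logging.getLogger(__name__)

MIN_PAIRS_RHO = 3
MIN_PAIRS_PB = 10

__all__ = [
    "DetrendedPairs",
    "TrialGlanceStats",
    "PBFit",
    "robust_detrend",
    "detrend_trial",
    "per_trial_correlations",
    "sign_tests",
    "subject_pb_fit",
]


@dataclass
class DetrendedPairs:
    """Detrended (headway, occlusion) pairs of one occluded trial."""

    subject_id: str
    trial_id: str
    t_g: np.ndarray
    T_d: np.ndarray  # T(t_g) - T_trend(t_g), s
    o_d: np.ndarray  # o(t_g) - o_trend(t_g), s
    T_trend: tuple[float, float]  # (slope, intercept)
    o_trend: tuple[float, float]


@dataclass(frozen=True)
class TrialGlanceStats:
    subject_id: str
    trial_id: str
    n_glance_pairs: int
    rho: float


@dataclass(frozen=True)
class PBFit:
    subject_id: str
    slope: float
    intercept: float
    slope_ci: Interval
    n_pairs: int
    n_slopes: int
    low_n: bool


def robust_detrend(t, y) -> tuple[np.ndarray, tuple[float, float]]:
    """Subtract a Theil–Sen line of y over t; returns (residuals, (slope, intercept))."""
    slope, intercept = statcore.theil_sen(t, y)
    resid = np.asarray(y, dtype=float) - (slope * np.asarray(t, dtype=float) + intercept)
    return resid, (slope, intercept)


def detrend_trial(record: TrialRecord, samples: list[GlanceSample] | None = None) -> DetrendedPairs | None:
    """Detrend one occluded trial's glance-onset signals over onset time.

    Returns None when the trial has fewer than two usable glance pairs
    (no trend can be fit).
    """
    if samples is None:
        samples = glance_onset_samples(record)
    if len(samples) < 2:
        return None
    t_g = np.array([s.t_g for s in samples])
    T = np.array([s.T_at_onset for s in samples])
    o = np.array([s.o_next for s in samples])
    T_d, T_trend = robust_detrend(t_g, T)
    o_d, o_trend = robust_detrend(t_g, o)
    return DetrendedPairs(
        subject_id=record.subject_id,
        trial_id=record.trial_id,
        t_g=t_g,
        T_d=T_d,
        o_d=o_d,
        T_trend=T_trend,
        o_trend=o_trend,
    )


def per_trial_correlations(pairs_list: list[DetrendedPairs]) -> list[TrialGlanceStats]:
    """Spearman rho of (T_d, o_d) per trial; trials with < 3 pairs are excluded."""
    out = []
    for p in pairs_list:
        n = len(p.t_g)
        if n < MIN_PAIRS_RHO:
            logger.info("trial %s/%s excluded from correlations: %d pairs",
                        p.subject_id, p.trial_id, n)
            continue
        try:
            rho = statcore.spearman_rho(p.T_d, p.o_d)
        except ValueError:
            logger.info("trial %s/%s excluded: constant detrended signal",
                        p.subject_id, p.trial_id)
            continue
        out.append(TrialGlanceStats(p.subject_id, p.trial_id, n, rho))
    return out


def sign_tests(trial_stats: list[TrialGlanceStats]) -> dict:
    """Exact binomial sign tests on correlation signs.

    Trial level: count of strictly positive per-trial rhos against
    Binomial(n_trials, 1/2).  Subject level: count of subjects whose
    median trial rho is strictly positive against Binomial(n_subjects, 1/2).
    Zero correlations count as non-positive.
    """
    if not trial_stats:
        raise ValueError("no trial statistics given")
    rhos = np.array([s.rho for s in trial_stats])
    k_trials = int(np.sum(rhos > 0))
    n_trials = len(rhos)
    by_subject: dict[str, list[float]] = {}
    for s in trial_stats:
        by_subject.setdefault(s.subject_id, []).append(s.rho)
    medians = {sid: float(np.median(v)) for sid, v in by_subject.items()}
    k_subjects = int(sum(1 for m in medians.values() if m > 0))
    n_subjects = len(medians)
    return {
        "k_trials": k_trials,
        "n_trials": n_trials,
        "p_trials": statcore.binom_test_exact(k_trials, n_trials, 0.5),
        "k_subjects": k_subjects,
        "n_subjects": n_subjects,
        "p_subjects": statcore.binom_test_exact(k_subjects, n_subjects, 0.5),
        "median_rho": float(np.median(rhos)),
        "median_of_subject_medians": float(np.median(list(medians.values()))),
    }


def subject_pb_fit(subject_id: str, pairs_list: list[DetrendedPairs],
                   level: float = 0.95) -> PBFit:
    """Passing–Bablok fit of o_d on T_d, pooling a subject's occluded trials."""
    mine = [p for p in pairs_list if p.subject_id == subject_id]
    if not mine:
        raise ValueError(f"no detrended pairs for subject {subject_id}")
    T_d = np.concatenate([p.T_d for p in mine])
    o_d = np.concatenate([p.o_d for p in mine])
    n = len(T_d)
    low_n = n < MIN_PAIRS_PB
    if low_n:
        logger.info("subject %s PB fit on only %d pairs", subject_id, n)
    slope, intercept, ci, n_slopes = statcore.passing_bablok(T_d, o_d, level)
    return PBFit(
        subject_id=subject_id,
        slope=slope,
        intercept=intercept,
        slope_ci=ci,
        n_pairs=n,
        n_slopes=n_slopes,
        low_n=low_n,
    )
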