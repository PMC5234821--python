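"""Turn raw trial records into analysis units.

Filtering follows the experiment's preprocessing: the first and last 300 m
of each trial are discarded (initial acceleration from standstill;
strategic coasting to the finish line) and samples with follower ground
speed below 1.0 m/s are dropped to avoid blow-up of the time-headway
ratio.  Aggregates are geometric means, the estimator used for preferred
headway and average visual distraction throughout the analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .driver_sim import TrialRecord

logger = logging.getLogger(__name__)

TRIM_M = 300.0
MIN_SPEED = 1.0  # m/s

__all__ = [
    "HeadwaySeries",
    "GlanceSample",
    "SubjectSummary",
    "time_headway",
    "trim_and_filter",
    "geometric_mean",
    "glance_onset_samples",
    "subject_summary",
    "subject_summaries",
]


@dataclass
class HeadwaySeries:
    """Filtered time-headway samples of one trial."""

    subject_id: str
    trial_id: str
    condition: str
    t: np.ndarray
    odometer: np.ndarray  # follower distance travelled, m
    T: np.ndarray  # time headway, s

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class GlanceSample:
    """Headway at a glance onset paired with the following occlusion duration."""

    t_g: float
    T_at_onset: float
    o_next: float


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject aggregates: the unit of the between-subjects analysis."""

    subject_id: str
    T_hat_0: float  # geometric-mean unoccluded headway, s
    T_hat_D: float  # geometric-mean occluded headway, s
    o_hat_D: float  # geometric-mean occlusion duration, s
    delta_T: float  # T_hat_D - T_hat_0, s
    delta_rel: float  # delta_T / T_hat_0
    n_trials_unoccluded: int
    n_trials_occluded: int
    n_glances: int


def time_headway(
    x_lead: float | np.ndarray,
    x_fol: float | np.ndarray,
    v_fol: float | np.ndarray,
    vehicle_length: float = 4.0,
):
    """Bumper-to-bumper gap divided by follower speed, in seconds.

    Undefined (the caller filters) at v_fol <= 0.
    """
    return (np.asarray(x_lead) - np.asarray(x_fol) - vehicle_length) / np.asarray(v_fol)


def trim_and_filter(record: TrialRecord) -> HeadwaySeries:
    """Apply the 300 m end trims and the 1.0 m/s speed floor.

    Retains exactly the samples with follower odometer in
    [300, trial_length - 300] and v_fol >= 1.0 m/s.
    """
    odo = record.x_fol  # follower starts at x = 0
    mask = (
        (odo >= TRIM_M)
        & (odo <= record.trial_length - TRIM_M)
        & (record.v_fol >= MIN_SPEED)
    )
    T = time_headway(
        record.x_lead[mask], record.x_fol[mask], record.v_fol[mask],
        record.vehicle_length,
    )
    if not np.any(mask):
        logger.info(
            "trial %s/%s: no samples survive trimming/filtering",
            record.subject_id, record.trial_id,
        )
    return HeadwaySeries(
        subject_id=record.subject_id,
        trial_id=record.trial_id,
        condition=record.condition,
        t=record.t[mask],
        odometer=odo[mask],
        T=np.asarray(T, dtype=float),
    )


def geometric_mean(xs) -> float:
    """exp(mean(log xs)); requires a non-empty, strictly positive input."""
    a = np.asarray(xs, dtype=float)
    if a.size == 0:
        raise ValueError("geometric mean of an empty collection")
    if np.any(a <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(a))))


def glance_onset_samples(
    record: TrialRecord,
    series: HeadwaySeries | None = None,
) -> list[GlanceSample]:
    """Pair each glance onset with headway there and the next occlusion duration.

    o_next = next_onset - (t_g + glance_dur), i.e. the eyes-off interval
    after the glance.  The last onset has no following occlusion and is
    dropped, as are onsets outside the trimmed window or during filtered
    (v < 1 m/s) stretches.  T at the onset is linearly interpolated
    between the two nearest retained samples.
    """
    if record.condition != "occluded":
        raise ValueError("glance samples are defined only for occluded trials")
    if series is None:
        series = trim_and_filter(record)
    out: list[GlanceSample] = []
    onsets = record.glance_onsets
    if len(onsets) < 2 or len(series) == 0:
        return out
    # raw-series interpolation for validity checks at the onset instant
    odo_at = np.interp(onsets, record.t, record.x_fol)
    v_at = np.interp(onsets, record.t, record.v_fol)
    t_lo, t_hi = series.t[0], series.t[-1]
    for i in range(len(onsets) - 1):
        t_g = float(onsets[i])
        if not (TRIM_M <= odo_at[i] <= record.trial_length - TRIM_M):
            continue
        if v_at[i] < MIN_SPEED:
            continue
        if not (t_lo <= t_g <= t_hi):
            continue
        o_next = float(onsets[i + 1] - (t_g + record.glance_dur))
        T_at = float(np.interp(t_g, series.t, series.T))
        out.append(GlanceSample(t_g=t_g, T_at_onset=T_at, o_next=o_next))
    return out


def _pooled_gm(series_list: list[HeadwaySeries], pooling: str) -> float | None:
    usable = [s for s in series_list if len(s) > 0]
    if not usable:
        return None
    if pooling == "pooled":
        return geometric_mean(np.concatenate([s.T for s in usable]))
    if pooling == "per-trial":
        return geometric_mean([geometric_mean(s.T) for s in usable])
    raise ValueError(f"unknown pooling {pooling!r}")


def subject_summary(
    records: list[TrialRecord],
    pooling: str = "pooled",
    include_crashed: bool = False,
) -> SubjectSummary | None:
    """Aggregate one subject's trials into a SubjectSummary.

    Crashed trials are excluded unless ``include_crashed``.  Returns None
    (and logs) when either condition has no usable trial.  ``pooling``
    selects between pooling all samples of a condition ("pooled", the
    default) and a geometric mean of per-trial geometric means
    ("per-trial").
    """
    if not records:
        raise ValueError("no records given")
    sid = records[0].subject_id
    used = [r for r in records if include_crashed or not r.crashed]
    unocc = [trim_and_filter(r) for r in used if r.condition == "unoccluded"]
    occ_recs = [r for r in used if r.condition == "occluded"]
    occ = [trim_and_filter(r) for r in occ_recs]
    T0 = _pooled_gm(unocc, pooling)
    TD = _pooled_gm([s for s in occ if len(s) > 0], pooling)
    glances: list[GlanceSample] = []
    for r, s in zip(occ_recs, occ):
        glances.extend(glance_onset_samples(r, s))
    o_vals = [g.o_next for g in glances if g.o_next > 0]
    if T0 is None or TD is None or not o_vals:
        logger.info("subject %s excluded: a condition has no usable trial", sid)
        return None
    oD = geometric_mean(o_vals)
    return SubjectSummary(
        subject_id=sid,
        T_hat_0=T0,
        T_hat_D=TD,
        o_hat_D=oD,
        delta_T=TD - T0,
        delta_rel=(TD - T0) / T0,
        n_trials_unoccluded=sum(1 for s in unocc if len(s) > 0),
        n_trials_occluded=sum(1 for s in occ if len(s) > 0),
        n_glances=len(glances),
    )


def subject_summaries(
    records: list[TrialRecord],
    pooling: str = "pooled",
    include_crashed: bool = False,
) -> list[SubjectSummary]:
    """Group records by subject and summarise each; excluded subjects dropped."""
    by_subject: dict[str, list[TrialRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    out = []
    for sid in sorted(by_subject):
        s = subject_summary(by_subject[sid], pooling, include_crashed)
        if s is not None:
            out.append(s)
    return out
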