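"""Synthetic occluded car-following experiment generator.

Simulates a leader–follower pair on a straight 2000 m road.  The leader
tracks a target speed resampled without replacement every 10 s from
{0, 30, 40, 50, 60, 70, 80} km/h under proportional control.  The follower
is a linear speed-plus-gap tracker operating on a dead-reckoned belief of
the leader state: in the occluded condition the true leader state is
visible only during self-requested 300 ms glances, and the duration of the
occlusion following each glance is chosen by the task-difficulty
homeostasis law

    o = clip(o' + beta * (T - T'), o_min, o_max)

where T is the headway perceived at glance onset and T' the driver's
preferred headway.  The preferred headway itself adapts to the running
geometric mean of realised occlusion durations, either baseline
independently (T' = T0 + c * o_mean) or baseline relatively
(T' = TH' * (m_d^3 + 1), the Hoogendoorn form).

All randomness flows through numpy Generators seeded from explicit integer
seeds; identical seeds give bit-identical trial records.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

KMH = 1.0 / 3.6  # km/h -> m/s, exact conversion factor
SPEED_SET_KMH = (0.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)
SEGMENT_S = 10.0
VEHICLE_LENGTH = 4.0  # m, subtracted from centre distance for bumper gap
STANDSTILL_GAP = 2.0  # m, added to the initial bumper gap

BASELINE_INDEPENDENT = "baseline_independent"
BASELINE_RELATIVE = "baseline_relative"

NOISE_SPEED_SCALE = 3.0  # m/s; pedal noise ramps in linearly below this speed
MARGIN_SPEED_SCALE = 1.5  # m/s; standstill gap margin fades out by this speed

__all__ = [
    "LeaderSchedule",
    "DriverParams",
    "TrialRecord",
    "PopulationSpec",
    "make_leader_schedule",
    "leader_accel",
    "preferred_headway",
    "next_occlusion_duration",
    "update_belief",
    "follower_accel",
    "simulate_trial",
    "simulate_experiment",
    "write_dataset",
    "read_dataset",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeaderSchedule:
    """Piecewise-constant target-speed profile for the lead vehicle."""

    segment_start_times: np.ndarray  # s, non-decreasing
    target_speeds_kmh: np.ndarray  # members of SPEED_SET_KMH
    gain: float = 0.5  # 1/s proportional gain
    accel_bounds: tuple[float, float] = (-1.0, 0.8)  # m/s^2

    def target_at(self, t: float) -> float:
        """Target speed in m/s at simulation time t (holds last beyond end)."""
        idx = int(np.searchsorted(self.segment_start_times, t, side="right")) - 1
        idx = min(max(idx, 0), len(self.target_speeds_kmh) - 1)
        return float(self.target_speeds_kmh[idx]) * KMH


@dataclass(frozen=True)
class DriverParams:
    """Generative driver model parameters.

    T0 is the preferred unoccluded time headway (s), c the
    headway-per-occlusion slope, beta the glance-adaptation gain and
    o_base the preferred occlusion duration o' (s).  The follower control
    law is a = k_speed*(v_lead_hat - v) + k_gap*(gap_hat - T'*v) + noise.
    """

    T0: float = 1.0
    c: float = 1.0
    beta: float = 1.0
    o_base: float = 2.0
    o_min: float = 0.3
    o_max: float = 6.0
    glance_dur: float = 0.3
    k_speed: float = 2.0
    k_gap: float = 0.3
    accel_bounds: tuple[float, float] = (-8.0, 3.0)
    noise_sd: float = 0.8
    variant: str = BASELINE_INDEPENDENT
    hoogendoorn_TH: float = 1.0
    hoogendoorn_md_scale: float = 2.0
    occl_headway_shift: float = 0.0  # s; subject's extra caution margin when occluded

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ValueError("T0 must be positive")
        if self.o_min <= 0 or not self.o_min <= self.o_base <= self.o_max:
            raise ValueError("need 0 < o_min <= o_base <= o_max")
        if self.glance_dur <= 0:
            raise ValueError("glance_dur must be positive")
        if not (math.isfinite(self.beta) and math.isfinite(self.c)):
            raise ValueError("beta and c must be finite")
        if self.variant not in (BASELINE_INDEPENDENT, BASELINE_RELATIVE):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class TrialRecord:
    """One simulated (or loaded) car-following trial."""

    subject_id: str
    trial_id: str
    condition: str  # "occluded" | "unoccluded"
    seed: int
    dt: float
    t: np.ndarray
    x_lead: np.ndarray
    v_lead: np.ndarray
    x_fol: np.ndarray
    v_fol: np.ndarray
    glance_onsets: np.ndarray  # s, strictly increasing; empty if unoccluded
    occlusion_durations: np.ndarray  # s, scheduled after each onset
    crashed: bool
    trial_length: float = 2000.0
    glance_dur: float = 0.3
    vehicle_length: float = VEHICLE_LENGTH


@dataclass(frozen=True)
class PopulationSpec:
    """Between-subject heterogeneity of the simulated cohort.

    Per-subject T0 and o_base (and optionally beta, c) are drawn from
    log-normal distributions: ``*_log_loc`` is the log-scale location
    (log median) and ``*_log_scale`` the log-scale SD.
    """

    n_subjects: int = 18
    trials_per_condition: int = 4
    T0_log_loc: float = 0.0  # median 1.0 s
    T0_log_scale: float = 0.4
    o_base_log_loc: float = math.log(2.0)  # median 2.0 s
    o_base_log_scale: float = 0.25
    beta_log_loc: float = 0.0
    beta_log_scale: float = 0.0
    c_log_loc: float = 0.0
    c_log_scale: float = 0.0
    occl_shift_sd: float = 0.0  # s; SD of an optional additive occluded-headway margin
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        for s in (self.T0_log_scale, self.o_base_log_scale,
                  self.beta_log_scale, self.c_log_scale):
            if s < 0:
                raise ValueError("scale parameters must be >= 0")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def make_leader_schedule(
    duration: float,
    gain: float = 0.5,
    rng: np.random.Generator | None = None,
    accel_bounds: tuple[float, float] = (-1.0, 0.8),
) -> LeaderSchedule:
    """Draw a leader target-speed schedule covering ``duration`` seconds.

    Targets are sampled without replacement from the 7-value speed set,
    reshuffling the full set each time it is exhausted; each segment lasts
    10 s (the last may be truncated by ``duration``).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng() if rng is None else rng
    n_seg = int(math.ceil(duration / SEGMENT_S))
    targets: list[float] = []
    while len(targets) < n_seg:
        block = list(SPEED_SET_KMH)
        rng.shuffle(block)
        targets.extend(block)
    targets = targets[:n_seg]
    starts = np.arange(n_seg) * SEGMENT_S
    return LeaderSchedule(
        segment_start_times=starts,
        target_speeds_kmh=np.array(targets),
        gain=gain,
        accel_bounds=accel_bounds,
    )


def leader_accel(
    v: float,
    v_target: float,
    gain: float,
    accel_bounds: tuple[float, float],
) -> float:
    """Proportional speed control: a = clip(gain * (v_target - v))."""
    return float(np.clip(gain * (v_target - v), *accel_bounds))


def preferred_headway(params: DriverParams, o_mean: float) -> float:
    """Preferred time headway T' as a function of mean occlusion duration.

    baseline_independent: T' = T0 + c * o_mean  (Saifuzzaman-style direct
    proportionality); baseline_relative: T' = TH' * (m_d^3 + 1) with
    m_d = o_mean / md_scale (Hoogendoorn-style task-difficulty scaling).
    """
    if o_mean < 0:
        raise ValueError("o_mean must be >= 0")
    if params.variant == BASELINE_INDEPENDENT:
        return params.T0 + params.c * o_mean
    m_d = o_mean / params.hoogendoorn_md_scale
    return params.hoogendoorn_TH * (m_d**3 + 1.0)


def next_occlusion_duration(params: DriverParams, T_now: float, T_pref: float) -> float:
    """Occlusion duration chosen at a glance onset: clip(o' + beta*(T - T'))."""
    o = params.o_base + params.beta * (T_now - T_pref)
    return float(np.clip(o, params.o_min, params.o_max))


@dataclass
class Belief:
    """Dead-reckoned leader state held by the follower during occlusion."""

    x: float
    v: float


def update_belief(belief: Belief, dt: float) -> Belief:
    """Advance the believed leader position at its last-perceived speed."""
    return Belief(x=belief.x + belief.v * dt, v=belief.v)


def follower_accel(
    belief: Belief,
    x_fol: float,
    v_fol: float,
    T_pref: float,
    params: DriverParams,
    rng: np.random.Generator | None = None,
) -> float:
    """Linear speed+gap tracking law on the believed leader state.

    a = clip(k_speed*(v_hat - v) + k_gap*(gap_hat - T'*v) + eps), with
    eps ~ Normal(0, noise_sd).  Noiseless equilibrium: gap = T'*v at
    matched speeds.
    """
    gap_hat = belief.x - x_fol - VEHICLE_LENGTH
    # the standstill margin vanishes above MARGIN_SPEED_SCALE, just above
    # the 1 m/s analysis floor, so analysed samples obey gap = T_pref * v
    margin = STANDSTILL_GAP * max(0.0, 1.0 - v_fol / MARGIN_SPEED_SCALE)
    a = params.k_speed * (belief.v - v_fol) + params.k_gap * (
        gap_hat - T_pref * v_fol - margin
    )
    if rng is not None and params.noise_sd > 0:
        # pedal jitter scales with speed so queued vehicles do not creep
        a += rng.normal(0.0, params.noise_sd) * min(1.0, v_fol / NOISE_SPEED_SCALE)
    return float(np.clip(a, *params.accel_bounds))


# ---------------------------------------------------------------------------
# trial integration core
# ---------------------------------------------------------------------------

def _integrate_core(
    occluded: bool,
    dt: float,
    trial_length: float,
    max_steps: int,
    seg_starts: np.ndarray,
    seg_targets_ms: np.ndarray,
    lead_gain: float,
    lead_amin: float,
    lead_amax: float,
    T0: float,
    c: float,
    beta: float,
    o_base: float,
    o_min: float,
    o_max: float,
    glance_dur: float,
    k_speed: float,
    k_gap: float,
    fol_amin: float,
    fol_amax: float,
    noise: np.ndarray,
    relative_variant: bool,
    th_prime: float,
    md_scale: float,
    olog_sum0: float,
    olog_n0: float,
    occl_shift: float,
    x_lead0: float,
    v0: float,
    t_arr: np.ndarray,
    xl_arr: np.ndarray,
    vl_arr: np.ndarray,
    xf_arr: np.ndarray,
    vf_arr: np.ndarray,
    onsets: np.ndarray,
    odurs: np.ndarray,
):
    """Explicit-Euler integration loop (numba-compiled when available).

    Returns (n_steps, n_glances, crashed, olog_sum, olog_n).
    """
    xl = x_lead0
    vl = v0
    xf = 0.0
    vf = v0
    bel_x = xl
    bel_v = vl
    olog_sum = olog_sum0
    olog_n = olog_n0
    o_mean = math.exp(olog_sum / olog_n)
    if relative_variant:
        t_pref = th_prime * ((o_mean / md_scale) ** 3 + 1.0) + occl_shift if occluded else th_prime
    else:
        t_pref = T0 + c * o_mean + occl_shift if occluded else T0
    next_onset = 0.0
    glance_end = -1.0
    n_glances = 0
    crashed = False
    seg_idx = 0
    n_seg = len(seg_starts)
    i = 0
    while i < max_steps:
        t = i * dt
        t_arr[i] = t
        xl_arr[i] = xl
        vl_arr[i] = vl
        xf_arr[i] = xf
        vf_arr[i] = vf
        gap = xl - xf - 4.0
        if gap <= 0.0:
            crashed = True
            i += 1
            break
        if xf >= trial_length:
            i += 1
            break
        # perception and glance scheduling
        if occluded:
            if t >= next_onset and n_glances < len(onsets):
                onset_t = next_onset
                glance_end = onset_t + glance_dur
                bel_x = xl
                bel_v = vl
                # perceived headway saturates at low speed: a queued driver
                # judges the gap in metres, not in blow-up seconds
                t_perceived = gap / max(vf, 3.0)
                o_next = o_base + beta * (t_perceived - t_pref)
                o_next = min(max(o_next, o_min), o_max)
                onsets[n_glances] = onset_t
                odurs[n_glances] = o_next
                n_glances += 1
                olog_sum += math.log(o_next)
                olog_n += 1.0
                o_mean = math.exp(olog_sum / olog_n)
                if relative_variant:
                    t_pref = th_prime * ((o_mean / md_scale) ** 3 + 1.0) + occl_shift
                else:
                    t_pref = T0 + c * o_mean + occl_shift
                next_onset = onset_t + glance_dur + o_next
            if t < glance_end:
                bel_x = xl
                bel_v = vl
            else:
                bel_x = bel_x + bel_v * dt
        else:
            bel_x = xl
            bel_v = vl
        # leader proportional control
        while seg_idx + 1 < n_seg and t >= seg_starts[seg_idx + 1]:
            seg_idx += 1
        v_tgt = seg_targets_ms[seg_idx]
        a_l = lead_gain * (v_tgt - vl)
        a_l = min(max(a_l, lead_amin), lead_amax)
        # follower tracking on believed state
        gap_hat = bel_x - xf - 4.0
        eps = noise[i] * min(1.0, vf / 3.0)
        margin = 2.0 * max(0.0, 1.0 - vf / 1.5)
        a_f = k_speed * (bel_v - vf) + k_gap * (gap_hat - t_pref * vf - margin) + eps
        a_f = min(max(a_f, fol_amin), fol_amax)
        # Euler step: positions advance at current speed, then speeds update
        xl = xl + vl * dt
        xf = xf + vf * dt
        vl = max(0.0, vl + a_l * dt)
        vf = max(0.0, vf + a_f * dt)
        i += 1
    return i, n_glances, crashed, olog_sum, olog_n


try:  # JIT-compile the hot loop; the pure-Python path computes identically
    import numba

    _integrate_core = numba.njit(cache=True)(_integrate_core)
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False


def simulate_trial(
    condition: str,
    params: DriverParams,
    schedule: LeaderSchedule,
    seed: int,
    dt: float = 0.01,
    trial_length: float = 2000.0,
    max_time: float = 600.0,
    subject_id: str = "s00",
    trial_id: str = "t00",
    o_log_state: tuple[float, float] | None = None,
    initial_gap: float | None = None,
) -> tuple[TrialRecord, tuple[float, float]]:
    """Integrate one trial; returns the record and the carried o-mean state.

    ``o_log_state`` is the subject's (sum of log occlusion durations,
    count) accumulator that makes the preferred headway track the running
    geometric mean of realised occlusions across that subject's trials; it
    is initialised at (log(o_base), 1) for a fresh subject.
    """
    if condition not in ("occluded", "unoccluded"):
        raise ValueError(f"unknown condition {condition!r}")
    if dt <= 0 or trial_length <= 0:
        raise ValueError("dt and trial_length must be positive")
    occluded = condition == "occluded"
    if o_log_state is None:
        o_log_state = (math.log(params.o_base), 1.0)
    max_steps = int(max_time / dt) + 1
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, params.noise_sd, size=max_steps)
        if params.noise_sd > 0
        else np.zeros(max_steps)
    )
    v0 = schedule.target_at(0.0)
    if initial_gap is None:
        # start at the condition's preferred headway (trials follow practice
        # runs, so subjects begin warmed up); the trimmed first 300 m
        # absorbs the remaining transient
        o0 = math.exp(o_log_state[0] / o_log_state[1]) if occluded else 0.0
        t_pref0 = preferred_headway(params, o0) + (
            params.occl_headway_shift if occluded else 0.0
        )
        gap0 = t_pref0 * v0 + STANDSTILL_GAP
    else:
        gap0 = initial_gap
    x_lead0 = gap0 + VEHICLE_LENGTH
    t_arr = np.empty(max_steps)
    xl_arr = np.empty(max_steps)
    vl_arr = np.empty(max_steps)
    xf_arr = np.empty(max_steps)
    vf_arr = np.empty(max_steps)
    cap = max(16, int(max_time / (params.glance_dur + params.o_min)) + 2)
    onsets = np.empty(cap)
    odurs = np.empty(cap)
    n, n_glances, crashed, olog_sum, olog_n = _integrate_core(
        occluded,
        dt,
        trial_length,
        max_steps,
        np.asarray(schedule.segment_start_times, dtype=float),
        np.asarray(schedule.target_speeds_kmh, dtype=float) * KMH,
        schedule.gain,
        schedule.accel_bounds[0],
        schedule.accel_bounds[1],
        params.T0,
        params.c,
        params.beta,
        params.o_base,
        params.o_min,
        params.o_max,
        params.glance_dur,
        params.k_speed,
        params.k_gap,
        params.accel_bounds[0],
        params.accel_bounds[1],
        noise,
        params.variant == BASELINE_RELATIVE,
        params.hoogendoorn_TH,
        params.hoogendoorn_md_scale,
        o_log_state[0],
        o_log_state[1],
        params.occl_headway_shift,
        x_lead0,
        v0,
        t_arr,
        xl_arr,
        vl_arr,
        xf_arr,
        vf_arr,
        onsets,
        odurs,
    )
    if not crashed and xf_arr[n - 1] < trial_length:
        raise RuntimeError(
            f"trial did not finish within {max_time} s; check parameters"
        )
    record = TrialRecord(
        subject_id=subject_id,
        trial_id=trial_id,
        condition=condition,
        seed=int(seed),
        dt=dt,
        t=t_arr[:n].copy(),
        x_lead=xl_arr[:n].copy(),
        v_lead=vl_arr[:n].copy(),
        x_fol=xf_arr[:n].copy(),
        v_fol=vf_arr[:n].copy(),
        glance_onsets=onsets[:n_glances].copy(),
        occlusion_durations=odurs[:n_glances].copy(),
        crashed=bool(crashed),
        trial_length=trial_length,
        glance_dur=params.glance_dur,
    )
    return record, (olog_sum, olog_n)


# ---------------------------------------------------------------------------
# experiment-level generation
# ---------------------------------------------------------------------------

def _trial_seed(master_seed: int, subj: int, cond: int, trial: int) -> int:
    ss = np.random.SeedSequence([master_seed, subj, cond, trial])
    return int(ss.generate_state(1)[0] % (2**31))


def draw_subject_params(
    pop: PopulationSpec,
    subj: int,
    defaults: DriverParams | None = None,
) -> DriverParams:
    """Draw one subject's DriverParams from the population distributions."""
    defaults = DriverParams() if defaults is None else defaults
    ss = np.random.SeedSequence([pop.master_seed, subj, 982451653])
    rng = np.random.default_rng(ss.generate_state(4))
    T0 = math.exp(rng.normal(pop.T0_log_loc, pop.T0_log_scale))
    o_base = math.exp(rng.normal(pop.o_base_log_loc, pop.o_base_log_scale))
    beta = math.exp(rng.normal(pop.beta_log_loc, pop.beta_log_scale))
    c = math.exp(rng.normal(pop.c_log_loc, pop.c_log_scale))
    shift = rng.normal(0.0, pop.occl_shift_sd) if pop.occl_shift_sd > 0 else 0.0
    o_base = min(max(o_base, defaults.o_min), defaults.o_max)
    return replace(
        defaults,
        T0=T0,
        o_base=o_base,
        beta=beta,
        c=c,
        hoogendoorn_TH=T0,
        occl_headway_shift=shift,
    )


def simulate_experiment(
    pop: PopulationSpec,
    defaults: DriverParams | None = None,
    dt: float = 0.01,
    trial_length: float = 2000.0,
) -> list[TrialRecord]:
    """Simulate the full cohort: each subject runs ``trials_per_condition``
    unoccluded and occluded trials; occluded trials carry the subject's
    running geometric-mean occlusion state forward."""
    defaults = DriverParams() if defaults is None else defaults
    records: list[TrialRecord] = []
    for subj in range(pop.n_subjects):
        sp = draw_subject_params(pop, subj, defaults)
        sid = f"s{subj:02d}"
        olog = (math.log(sp.o_base), 1.0)
        for cond_idx, condition in enumerate(("unoccluded", "occluded")):
            for k in range(pop.trials_per_condition):
                seed = _trial_seed(pop.master_seed, subj, cond_idx, k)
                sched_rng = np.random.default_rng(seed + 1)
                schedule = make_leader_schedule(600.0, rng=sched_rng)
                rec, new_olog = simulate_trial(
                    condition,
                    sp,
                    schedule,
                    seed=seed,
                    dt=dt,
                    trial_length=trial_length,
                    subject_id=sid,
                    trial_id=f"{condition[:3]}{k}",
                    o_log_state=olog,
                )
                if condition == "occluded":
                    olog = new_olog
                records.append(rec)
    return records


# ---------------------------------------------------------------------------
# trial log I/O (delimited text, exact round-trip)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # shortest format that round-trips IEEE doubles


def write_dataset(records: list[TrialRecord], out_dir: str | Path) -> None:
    """Write trial logs, the glance companion file and a JSON manifest.

    One CSV per trial (subject_id, trial_id, condition, t_s, x_lead_m,
    v_lead_ms, x_fol_m, v_fol_ms), a single glances.csv, and manifest.json
    holding seeds, dt, trial lengths and crash flags.  Floats are rendered
    at %.17g so read(write(x)) is exact.
    """
    out = Path(out_dir)
    trials_dir = out / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"trials": []}
    glance_rows = []
    for rec in records:
        name = f"{rec.subject_id}_{rec.trial_id}.csv"
        df = pd.DataFrame(
            {
                "subject_id": rec.subject_id,
                "trial_id": rec.trial_id,
                "condition": rec.condition,
                "t_s": rec.t,
                "x_lead_m": rec.x_lead,
                "v_lead_ms": rec.v_lead,
                "x_fol_m": rec.x_fol,
                "v_fol_ms": rec.v_fol,
            }
        )
        df.to_csv(trials_dir / name, index=False, float_format=_FLOAT_FMT)
        for onset in rec.glance_onsets:
            glance_rows.append((rec.subject_id, rec.trial_id, onset))
        manifest["trials"].append(
            {
                "subject_id": rec.subject_id,
                "trial_id": rec.trial_id,
                "condition": rec.condition,
                "file": f"trials/{name}",
                "seed": rec.seed,
                "dt": rec.dt,
                "trial_length": rec.trial_length,
                "glance_dur": rec.glance_dur,
                "vehicle_length": rec.vehicle_length,
                "crashed": rec.crashed,
                "occlusion_durations": [float(o) for o in rec.occlusion_durations],
            }
        )
    gdf = pd.DataFrame(
        glance_rows, columns=["subject_id", "trial_id", "glance_onset_s"]
    )
    gdf.to_csv(out / "glances.csv", index=False, float_format=_FLOAT_FMT)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_dataset(in_dir: str | Path) -> list[TrialRecord]:
    """Read a dataset written by :func:`write_dataset`."""
    src = Path(in_dir)
    manifest_path = src / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {src}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    glances_path = src / "glances.csv"
    gdf = (
        pd.read_csv(glances_path, float_precision="round_trip")
        if glances_path.exists()
        else pd.DataFrame(columns=["subject_id", "trial_id", "glance_onset_s"])
    )
    records = []
    for meta in manifest["trials"]:
        path = src / meta["file"]
        if not path.exists():
            raise FileNotFoundError(
                f"trial file {meta['file']} listed in manifest is missing"
            )
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"t_s", "x_lead_m", "v_lead_ms", "x_fol_m", "v_fol_ms"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path} is missing columns {sorted(missing)}")
        sel = (gdf["subject_id"] == meta["subject_id"]) & (
            gdf["trial_id"] == meta["trial_id"]
        )
        onsets = gdf.loc[sel, "glance_onset_s"].to_numpy(dtype=float)
        if meta["condition"] == "occluded" and len(onsets) == 0:
            raise ValueError(
                f"occluded trial {meta['subject_id']}/{meta['trial_id']} "
                "has no glance entries in glances.csv"
            )
        records.append(
            TrialRecord(
                subject_id=meta["subject_id"],
                trial_id=meta["trial_id"],
                condition=meta["condition"],
                seed=int(meta["seed"]),
                dt=float(meta["dt"]),
                t=df["t_s"].to_numpy(dtype=float),
                x_lead=df["x_lead_m"].to_numpy(dtype=float),
                v_lead=df["v_lead_ms"].to_numpy(dtype=float),
                x_fol=df["x_fol_m"].to_numpy(dtype=float),
                v_fol=df["v_fol_ms"].to_numpy(dtype=float),
                glance_onsets=onsets,
                occlusion_durations=np.asarray(
                    meta.get("occlusion_durations", []), dtype=float
                ),
                crashed=bool(meta["crashed"]),
                trial_length=float(meta["trial_length"]),
                glance_dur=float(meta.get("glance_dur", 0.3)),
                vehicle_length=float(meta.get("vehicle_length", VEHICLE_LENGTH)),
            )
        )
    return records
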