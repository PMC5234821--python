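# Methods

## The behavioural model

The package studies how a car-following driver trades *visual sampling*
against *safety margin*. Task demand is indexed by time headway
T = (x_lead − x_fol − L)/v_fol (bumper-to-bumper gap over own speed, with
vehicle length L = 4 m), and visual distraction by the occlusion duration
o — the self-chosen eyes-off interval between 300 ms glances. Driver
capability under distraction is operationalised as

    C = 1 / (o + T_0),

the inverse of the mean occlusion duration plus the undistracted preferred
headway T_0 (so C_0 = 1/T_0 with zero distraction).

Two generative laws define the simulated driver:

* **Slow adaptation of preferred headway.** The preferred headway rises
  with the running average of accepted occlusion durations. In the
  baseline-independent form T′ = T_0 + c·ō (default c = 1); in the
  baseline-relative (Hoogendoorn-style) form T′ = T_H′·(m_d³ + 1) with
  task difficulty m_d = ō / s_m. The running average ō is the geometric
  mean of the occlusion durations the subject has realised so far,
  initialised at the subject's preference o′ — this makes the generative
  quantity the same statistic the analysis estimates.
* **Fast glance-by-glance adaptation.** At each glance onset the driver
  perceives the true headway T and commits to the next occlusion
  duration o = clip(o′ + β(T − T′), o_min, o_max), default β = 1: a
  transiently large margin buys a longer eyes-off period, a small margin
  forces a quick re-check.

The mapping constant s_m of the baseline-relative form is not pinned down
by the literature; the default s_m = 2 s puts m_d ≈ 1 at the median
occlusion preference of 2 s, so the relative form predicts roughly a
doubling of headway — the same magnitude of adaptation the
baseline-independent form produces — rather than the implausible 9-fold
increases a 1 s scale would give.

## Vehicle and perception model

Both vehicles integrate with explicit Euler at dt = 10 ms (60 Hz-scale
fidelity at negligible cost). The leader applies proportional speed
control a = clip(g·(v_target − v), −1.0, +0.8) m/s², g = 0.5 1/s, toward
targets redrawn every 10 s without replacement from
{0, 30, 40, 50, 60, 70, 80} km/h (the full 7-value set is reshuffled each
time it is exhausted). The gentle acceleration bounds reflect the
unhurried lead-vehicle behaviour of the task being emulated; large target
steps are therefore not always reached within one segment.

The follower is a linear speed-plus-gap tracker operating on a
*dead-reckoned belief* of the leader state:

    a = clip(k_v·(v̂_lead − v) + k_g·(ĝ − T′·v − m(v)) + ε, −8, +3)

with k_v = 2.0 1/s, k_g = 0.3 1/s². During occlusion the believed leader
position advances at the last-perceived speed; every simulation step
inside a glance window (and continuously in unoccluded trials) the belief
snaps to the truth. The standstill margin m(v) = 2·max(0, 1 − v/1.5) m
prevents zero-speed contact while vanishing above 1.5 m/s, so every
analysed sample (the pipeline drops v < 1 m/s) obeys the pure law whose
noiseless equilibrium is gap = T′·v at matched speeds — the closed loop
is overdamped at all realistic headways and converges to within 1% of T′
in under a minute. Pedal noise ε ~ N(0, 0.8 m/s²) is scaled by
min(1, v/3) so that queued vehicles do not creep into contact.

At a glance onset the perceived headway uses max(v, 3 m/s) in the
denominator: a near-stationary driver judges the gap in metres rather
than in blow-up seconds. Without this saturation, every stop of the
leader would trigger a maximal occlusion (the formal headway is enormous
at crawl speed) and the leader would then pull away unseen, producing
pathological headway tails that no real driver exhibits. Occlusion
durations clip to [0.3, 6] s. A crash is a bumper gap ≤ 0; crashed trials
terminate immediately, stay in the dataset, and are excluded from
analysis by default (an `--include-crashed` switch reverses this).

Trials are 2000 m; both vehicles start at the first target speed with the
follower at its current preferred headway (the emulated procedure runs
practice trials before the recorded ones, so subjects begin warmed up);
the analysis trims the first and last 300 m, absorbing the remaining
transient. Glance onsets are recorded on the continuous scheduling clock,
so occlusion durations are recoverable from the onset times to float
precision.

## The simulated cohort

18 subjects × 4 trials per condition by default. Per-subject parameters
are log-normal: T_0 with median 1.0 s and log-SD 0.4 (realised
unoccluded headways ≈ 0.5–2 s), o′ with median 2.0 s and log-SD 0.25
(realised per-subject mean occlusions ≈ 1.3–3.5 s); β and c are fixed at
1.0 by default (log-scale spreads are available, as is an additive
per-subject occluded-headway margin `occl_shift_sd`, default off). These
spreads were set so the synthetic cohort reproduces the between-subject
ranges and the ≈ 85% variance-explained of the aggregate
headway–occlusion relation observed in this paradigm. Trial seeds derive
from the master seed through `numpy` SeedSequence, making every record
bit-reproducible.

With these settings crashes are rare (0–3 per 144-trial cohort, almost
always occluded trials) — the simulated leader brakes more gently than a
worst-case real one, so the cohort is somewhat safer than a human one.

## What the generator does and does not emulate

It emulates: the trial design and trial counts; the leader speed process;
intermittent self-paced vision with discrete glances; slow and fast
headway/occlusion adaptation with subject heterogeneity; crashes through
genuinely emergent dynamics (stale beliefs during a leader stop).

It does not emulate: steering or lateral control; the fuel-consumption
incentive and its display; anticipatory (non-proportional) human braking;
perceptual noise in distance/speed estimation; learning across trials.
Consequently, passing tests show that the *analysis pipeline* recovers
the generative laws from data of this structure — not that human drivers
obey those laws; and the within-trial headway–occlusion correlations are
nearly perfect here (median ρ ≈ 1.0) because the fast adaptation law is
deterministic, whereas real drivers show ρ ≈ 0.5–0.6.

## Analysis pipeline

Preprocessing retains exactly the samples with follower odometer in
[300 m, trial_length − 300 m] and v ≥ 1.0 m/s. Per-subject aggregates
pool all retained samples of a condition (a per-trial-mean variant is
switchable): T̂_0 and T̂_D are geometric means of unoccluded and occluded
headway, ô_D the geometric mean of realised occlusion durations
(onset-to-next-onset minus the 300 ms glance), ΔT̂ = T̂_D − T̂_0.

Between subjects, Spearman correlations (average ranks) of ΔT̂ ∼ ô_D and
ΔT̂/T̂_0 ∼ ô_D are compared; each gets a Fisher-z interval
tanh(atanh r ± z/√(n−3)), and their difference a Zou
modified-asymptotic interval for dependent overlapping correlations, with
the overlap correlation estimated from the rank-transformed data. The
headway-increase slope is ordinary least squares of ΔT̂ on ô_D with
t-based parameter intervals; the one-to-one trade (slope 1, intercept 0)
is tested jointly with an F-type region, not two marginal tests.

Within trials, both signals are sampled at glance onsets, detrended with
a Theil–Sen line over onset time (slope = median pairwise slope,
intercept = median residual — exact on linear input, insensitive to
isolated outliers), correlated per trial (Spearman, ≥ 3 pairs), and
summarised by exact two-sided binomial sign tests at the trial and
subject level (the two-sided p sums all outcome probabilities not
exceeding the observed one; zero correlations count as non-positive).
Per-subject slopes use Passing–Bablok regression — symmetric in the
variables, appropriate since neither signal is under experimental
control — pooling the subject's occluded trials: all pairwise slopes with
distinct x, slopes of exactly −1 discarded, the estimate is the median
shifted by the count of slopes below −1, with rank-based confidence
bounds from the normal approximation; fits on fewer than 10 pairs are
flagged low-n.

## Numerical and edge-case choices

* Speeds are km/h in configuration and m/s internally (factor exactly
  1/3.6).
* Geometric means require strictly positive inputs; empty conditions
  exclude the trial (and, if nothing remains, the subject), with INFO
  logging so exclusions are auditable.
* Normal quantiles come from SciPy (accuracy far beyond the 1e-9 the
  interval bounds need); the binomial pmf equality in the two-sided test
  uses a 1e-7 relative guard against floating-point ties.
* Trial logs render floats at 17 significant digits and are parsed in
  round-trip mode, so `read(write(x))` is bit-exact.
* The inner integration loop is JIT-compiled with numba when available;
  a pure-Python fallback computes identical floats.

## Known limitations

* The dwell-time asymmetry of the fast adaptation law (large headway →
  long blind interval → slow correction) biases realised occluded
  headway slightly above preference; noiseless single-subject runs show
  ΔT̂/ô_D ≈ 1.04–1.09 rather than exactly 1. At cohort level the OLS
  slope of ΔT̂ on ô_D is unbiased (≈ 1.00 across replicates).
* Passing–Bablok scale equivariance (slope(kx, y) = slope(x, y)/k) holds
  exactly only while no pairwise slope crosses −1, a consequence of the
  estimator's K offset.
* The capability estimate Ĉ = 1/(ô + T̂_0) inherits every bias of its
  two inputs; it is reported per subject, not tested against external
  ground truth.
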