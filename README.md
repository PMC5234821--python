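# tcifollow

Simulation and analysis of **task-difficulty homeostasis in car
following**, studied with the self-paced visual-occlusion paradigm.

In an occluded car-following task a driver follows a lead vehicle whose
view is masked except during brief (300 ms) self-requested "glances". The
chosen eyes-off interval — the *occlusion duration* o — is a direct
measure of visual distraction, and the *time headway* T (bumper-to-bumper
gap divided by own speed) measures task demand. Task-capability-interface
(TCI) models of driver behaviour predict that drivers hold task difficulty
at a preferred level, so headway should rise as distraction rises. Two
competing quantitative forms exist:

* **baseline independent** — the headway increase is proportional to mean
  occlusion duration alone: ΔT̂ = T̂_D − T̂_0 ∼ ô, following from
  T̂ ≈ c·ô + T̂_0 with driver capability Ĉ ≈ (ô + T̂_0)⁻¹;
* **baseline relative** — the increase scales with the undistracted
  headway: ΔT̂/T̂_0 ∼ ô, following from T′ = T_H′·(m_d³ + 1).

`tcifollow` provides

1. a **seeded synthetic-data generator** (`driver_sim`) that reproduces
   the experiment design — 18 subjects × 4 occluded + 4 unoccluded trials
   of 2000 m behind a leader whose target speed is resampled without
   replacement every 10 s from {0, 30, 40, 50, 60, 70, 80} km/h — with
   drivers that follow the generative laws T′ = T_0 + c·ō and
   o = o′ + β(T − T′);
2. the **analysis pipeline**: geometric-mean aggregates with the 300 m
   end-trims and 1 m/s speed floor (`preprocess`), Spearman model
   comparison with Fisher-z and Zou difference intervals plus the
   headway-increase slope fit (`aggregate_analysis`), and the
   glance-by-glance analysis with Theil–Sen detrending, exact binomial
   sign tests and per-subject Passing–Bablok regressions
   (`glance_analysis`);
3. self-contained statistical primitives (`statcore`) — Passing–Bablok,
   Theil–Sen, Spearman with average ranks, Fisher-z and Zou confidence
   intervals, exact two-sided binomial test — each verified against a
   brute-force oracle in the test suite.

## Worked example

```python
import tcifollow as tf
from tcifollow.cli import analyze_records

records = tf.simulate_experiment(tf.PopulationSpec(master_seed=7))
report = analyze_records(records)

c = report["comparison"]
print(f"Spearman dT ~ o   : {c.r_indep:.2f}  (95% CI {c.ci_indep.low:.2f}..{c.ci_indep.high:.2f})")
print(f"Spearman dT/T0 ~ o: {c.r_rel:.2f}  (95% CI {c.ci_rel.low:.2f}..{c.ci_rel.high:.2f})")
s = report["slope_fit"]
print(f"OLS slope {s.alpha:.2f}, R^2 {s.r_squared:.2f}, identity line inside: {s.identity_line_inside}")
g = report["sign_tests"]
print(f"positive trials {g['k_trials']}/{g['n_trials']}, sign-test p = {g['p_trials']:.1e}")
print(f"median Passing-Bablok slope {report['median_pb_slope']:.2f}")
```

prints

```
Spearman dT ~ o   : 0.86  (95% CI 0.66..0.95)
Spearman dT/T0 ~ o: 0.51  (95% CI 0.06..0.79)
OLS slope 1.10, R^2 0.90, identity line inside: True
positive trials 72/72, sign-test p = 4.2e-22
median Passing-Bablok slope 1.00
```

The direct (baseline-independent) relationship correlates markedly better
than the baseline-relative one; the fitted slope of headway increase on
mean occlusion duration is statistically compatible with the one-to-one
trade ΔT̂ = ô; and within trials, detrended headway and the following
occlusion duration co-vary positively in essentially every trial, with a
Passing–Bablok slope near the generative glance-adaptation gain β = 1.

## Command line

```sh
tcifollow simulate --subjects 18 --trials 4 --seed 1 --out data/
tcifollow analyze  --data data/ --out report/ [--pooling per-trial] [--include-crashed]
tcifollow reproduce --out report/ --seed 1
```

`simulate` writes one CSV trial log per trial, a glance-onset companion
file and a JSON manifest (seeds, parameters, crash flags); `analyze` runs
the full pipeline on such a directory and emits JSON + CSV + Markdown
reports; `reproduce` runs the seeded end-to-end checks and prints
pass/fail per item.

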