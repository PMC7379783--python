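# calfcontrib

Muscle-force estimation for the calf during running: from marker and
force-plate recordings of a stride, estimate the forces of 17 calf muscle
elements by inverse dynamics plus squared-activation static optimization,
convert them into phase-wise individual muscle contribution percentages, and
compare shoe-weight conditions with one-way repeated-measures ANOVA and LSD
post hoc tests. A seeded synthetic-trial generator with per-frame ground
truth makes the whole pipeline testable without any recorded data.

## Pipeline

1. **io_signal** — reads/writes the documented TSV trial dialect
   (200 Hz markers in mm, 1000 Hz force plate in N, metadata), fills short
   marker gaps, applies zero-phase fourth-order Butterworth low-pass filters
   (12 Hz kinematics / 50 Hz force; forward–backward, so the gain at the
   nominal cutoff is 0.5), and provides body-mass and 101-point gait-cycle
   normalization.
2. **events** — stance from the 10 N vertical-GRF threshold (interpolated
   crossings, spike/dip guards), braking→propulsion transition from the AP
   GRF zero crossing, and the four-phase partition (50 ms preactivation,
   stance = braking ∪ push-off).
3. **dynamics** — Newton–Euler balance of the foot (+ shoe mass) about the
   ankle, subtalar and MTP axes: gravity, rigid-body inertia from
   differentiated marker kinematics, and the GRF at the CoP.
4. **optimization** — per frame, the convex QP
   `min Σ (F_i / F_max,i)²  s.t.  R·F = M,  0 ≤ F_i ≤ F_max,i`, solved by a
   semismooth-Newton dual method with an active-set/LP fallback; infeasible
   frames are reported, never silently relaxed (`relax=True` projects onto
   the attainable moment polytope first).
5. **contributions** — phase contribution of muscle *i* =
   `100 · ∫ F_i dt / ∫ Σ_j F_j dt` over the phase (trapezoidal, solved
   frames); vectors sum to 100 %.
6. **stats** — skewness screen (advisory), repeated-measures ANOVA with the
   classical SS decomposition (no sphericity correction; Greenhouse–Geisser
   ε reported informationally), and Fisher's LSD (uncorrected pairwise t on
   the ANOVA error term).
7. **model / synthetic_data** — the reduced 17-muscle, 3-DOF model with
   configurable surrogate parameters (`src/calfcontrib/data/default_model.tsv`),
   and the trial/cohort generator (double-hump vertical GRF,
   braking-then-propulsive AP GRF, CoP solved from designed joint-moment
   targets so the inverse problem is exactly feasible, ground-truth forces
   as the squared-activation optimum).

Note on reported statistics: group tables show mean and SD of contribution
percentages both on the percent scale.

## CLI

```sh
calfcontrib simulate --seed 1 --out trial_dir            # one synthetic trial
calfcontrib simulate --seed 1 --subjects 10 --out cohort # whole cohort
calfcontrib analyze trial_dir/trial_markers.tsv \
    trial_dir/trial_forces.tsv trial_dir/trial_meta.tsv --out results_dir
calfcontrib cohort --subjects 10 --seed 1 --out cohort_results
calfcontrib stats cohort_results/contributions_long.tsv --alpha 0.05
```

`simulate` accepts `--config params.json` overriding any `TrialParams` field
(body_mass, stance_duration, shoe_mass, noise SDs, ...).

## Python API sketch

```python
import calfcontrib as cc

model = cc.default_model()
trial = cc.generate_trial(model, cc.TrialParams(seed=1))
result = cc.analyze_trial(trial.recording, model)   # phases, moments, forces
result.contributions                                 # phase × muscle table

trials = cc.generate_cohort(model, n_subjects=10, seed=1)
table = cc.analyze_cohort(((t.subject, t.condition, t.recording)
                           for t in trials), model)
cc.aggregate_cohort(table, phase="braking")          # mean ± SD per condition
cc.compare_conditions(table, phase="braking")        # ANOVA + LSD per muscle
```
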