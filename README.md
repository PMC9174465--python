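# mocapuq

Monte Carlo uncertainty propagation for marker-based motion-capture
inverse analyses.

## The problem

Joint angles from optical motion capture are not measurements: they are
the output of a constrained inverse-kinematics (IK) fit of a calibrated
link-segment model to marker trajectories, and the joint moments and
powers derived from them inherit every calibration error. Two calibration
steps are uncertain in any marker-based study:

* **marker registration** — where each physical marker actually sits in
  its body segment's anatomical frame (placing markers on bony landmarks
  is repeatable to roughly a centimeter at best), and
* **model scaling** — the dimensions of the model's body segments, which
  are themselves estimated from marker distances.

`mocapuq` quantifies the downstream effect of these errors. Instead of a
single IK solution, it generates an ensemble of *N* equally plausible
models per uncertainty level *e*, runs every model through the identical
processing pipeline, and reports the resulting spread in joint angles,
moments, powers, nine peak gait metrics, and crouch-gait severity
classification. It is aimed at gait-lab researchers, clinical movement
scientists, and anyone deciding whether an observed kinematic or kinetic
difference is larger than their modeling uncertainty.

## Method

For a model with generalized coordinates **q**, model markers
m_i(**q**), observed markers o_i, and tracking weights w_i, each frame
solves the bounded weighted least-squares problem

    q* = argmin_q  Σ_i w_i ‖ m_i(q) − o_i ‖²

(trust-region solver, analytic geometric Jacobian, warm-started from the
previous frame). Coordinate trajectories are unwrapped, low-pass filtered
(zero-phase Butterworth, 6 Hz default), and differentiated with central
differences. Net joint moments follow from a recursive Newton–Euler
inverse dynamics pass over the segment tree under the measured external
loads τ = ID(q, q̇, q̈, F_ext); the unactuated free-base residual wrench
is reported, never hidden. Joint powers are P_k = τ_k · q̇_k.

Two ensemble samplers perturb the calibration:

* **registration**: every marker's local position is offset by a draw
  uniform in the ball of radius *e* (cube sampling with rejection, so the
  ball is sampled uniformly);
* **scaling**: per-segment scale factors are drawn uniformly on
  [90%, 110%]; a candidate is accepted only if, after re-posing the
  scaled model by IK against the original model's calibration-pose
  markers, every marker lies within *e* of its original counterpart.

Levels are analyzed cumulatively (each level's set augments the lower
levels), so peak-metric ranges can only widen with *e*. Ensemble quality
is verified by two marker-error metrics:
per-model RMSE across tracked markers, averaged over frames and
maximized over models, must stay below *e*.

A synthetic-gait module generates dynamically consistent fixture data
(prescribed harmonic joint curves, markers by forward kinematics, ground
reaction loads constructed from whole-body dynamics), so the entire
pipeline is testable offline with full ground truth.

## Worked example

```python
from mocapuq import UncertaintyConfig, analyze_uncertainty, generate_trial

trial = generate_trial(seed=1)  # noise-free 100-frame gait cycle, 14 markers
config = UncertaintyConfig(
    strategy="marker_registration",
    levels_e=(0.005, 0.01, 0.02),   # 0.5, 1, 2 cm
    N=10,
    seed=42,
)
report = analyze_uncertainty(trial.model, trial.trajectories, trial.loads, config)

for lv in report.levels:
    lo, hi = lv.ranges["peak_ankle_plantarflexion_angle"]
    print(
        f"e = {lv.level_e*100:.1f} cm ({lv.n_models:3d} models): "
        f"max RMSE = {lv.rmse_avg_frames_max_models*100:.2f} cm, "
        f"peak ankle plantarflexion angle {lo:.1f}..{hi:.1f} deg"
    )
```

prints

```
e = 0.5 cm ( 10 models): max RMSE = 0.36 cm, peak ankle plantarflexion angle 12.8..16.2 deg
e = 1.0 cm ( 20 models): max RMSE = 0.77 cm, peak ankle plantarflexion angle 10.5..16.8 deg
e = 2.0 cm ( 30 models): max RMSE = 1.36 cm, peak ankle plantarflexion angle 5.1..21.4 deg
```

Reading: even though every ensemble model fits the identical marker data
with sub-*e* RMSE (all are "equally plausible"), a 2 cm registration
uncertainty already spreads the peak ankle plantarflexion angle over a
16° range. `report.levels[-1].classification` maps the ensemble's
minimum stance knee-flexion angles onto crouch-gait severity categories
(typically developing < 15° ≤ mild < 30° ≤ moderate < 50° ≤ severe) and
flags ambiguity when the range straddles a boundary.

The same workflow is available from the shell:

```
mocap-uq synth --out data/                   # synthetic model + TRC + MOT
mocap-uq run --model data/model.yaml --trc data/markers.trc \
    --grf data/grf.mot --strategy registration --levels 0.5,1,2 \
    --n 10 --seed 42 --out study/
mocap-uq classify --report study/
```

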