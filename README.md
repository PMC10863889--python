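# footmech

Foot and ankle mechanics during running stance, computed with two foot
model topologies side by side:

* **SINGLE** — the traditional single rigid foot segment from the ankle to
  the metatarsophalangeal (MTP) joint, toes kept only as a point where the
  ground reaction force can act;
* **MULTI** — a three-segment foot (rearfoot = calcaneus, forefoot =
  navicular through metatarsals, toes), with ankle, midtarsal ("midfoot")
  and MTP joints.

The two models share one anatomical ankle convention (the single-segment
foot frame is the rearfoot frame), so their ankle kinematics and kinetics
are directly comparable.  The package is for biomechanists who want to
quantify what a rigid-foot assumption does to ankle angles, angular
velocities, resultant moments, instantaneous power and mechanical work —
and to test those differences over the whole stance phase rather than at
hand-picked instants.

## What it computes

Given a neutral-standing calibration trial, a running-stance marker trial
and a synchronized force-plate record:

1. **Kinematics** — zero-lag second-order Butterworth filtering (forward
   and reverse passes; residual-analysis cutoff selection available),
   least-squares (Procrustes) cluster poses per segment, joint rotations
   expressed relative to the neutral standing pose and decomposed into
   Cardan angles with a ZXY sequence
   (`R = R_z(flexion) R_x(inversion) R_y(adduction)`), angular velocities
   from the rotation series, all normalised to 101 stance nodes.
2. **Inverse dynamics** — recursive Newton–Euler over the foot chain
   (TOE → FF → RF), with the entire GRF assigned per sample to the one
   segment whose boundary (proximal and distal joint centres projected on
   the foot's long axis) contains the centre of pressure.  Joint power is
   the scalar product of the resultant joint moment and the relative
   segment angular velocity, `P_j = M_j · ω_j`; work is its time integral
   split into positive/negative parts; everything is normalised to body
   mass.
3. **Statistics** — statistical parametric mapping over the 0–100% stance
   fields: paired Hotelling's T² for 3-component series with Šidák-gated
   post-hoc paired t fields (`α = 1 − 0.95^{1/3} = 0.0170`), paired t
   fields for scalar series (random-field-theory thresholds, with an
   exact sign-flip permutation mode), Bonferroni-corrected paired t tests
   for scalar work, and Shapiro–Wilk normality checks.
4. **Synthetic data** — a forward-kinematics generator that emulates the
   target protocol (barefoot heel-strike running at ~3.1 m/s, 150 Hz
   markers / 1500 Hz forces, ~0.24 s stance, COP travelling heel → toe)
   with exact ground truth, plus planar dynamically consistent chain
   motions with closed-form joint moments for verifying the recursion.

## A worked example

```sh
python examples/02_joint_angles_two_models.py
```

```
SINGLE ankle: dorsiflexion peak  +19.0 deg, plantarflexion peak  -24.4 deg, excursion  43.4 deg
MULTI  ankle: dorsiflexion peak  +17.0 deg, plantarflexion peak  -20.3 deg, excursion  37.3 deg
MULTI midfoot: excursion  16.6 deg (motion SINGLE silently attributes to the ankle)
SINGLE - MULTI sagittal ankle difference: max 4.1 deg at 100% stance
```

The single-segment foot is tracked by markers spanning the whole foot, so
midfoot motion folds into its "ankle" angle: the sagittal excursion is
inflated by ~6° on this synthetic trial.  The kinetic consequence
(`examples/03_inverse_dynamics_power_work.py`):

```
work partition: SINGLE ankle 1.104 J/kg vs MULTI ankle+midfoot 1.160 J/kg (5.1% discrepancy)
```

i.e. the positive work a single-segment model books under the ankle is
accounted for, in the multi-segment model, by the ankle *plus* the
midfoot joint.  `examples/05_full_study.py` runs the full seven-subject
comparison with the SPM battery and prints the significant late-stance
power clusters where SINGLE overestimates ankle power.

## Command line

A thin CLI wraps the library:

```sh
footmech generate --out study/ --subjects 7 --seed 0
footmech run-trial study/subject01 --out out1/
footmech run-study study/ --out report/ --seed 0
footmech report report/study_results.json
```

Exit codes: 0 success, 2 validation error, 3 data error.  All marker
schemas, tracking clusters, lab axes, filter cutoffs, stance thresholds
and anthropometric fractions live in one YAML config
(`PipelineConfig.from_yaml`).

## Layout

```
src/footmech/     io_formats, rigid_body, foot_models, anthropometry,
                  inverse_dynamics, spm_stats, synthetic_data, planar,
                  pipeline, cli
examples/         one short narrative script per capability
docs/methods.md   models, assumptions, numerical choices, limitations
tests/            pytest suite (unit, property and acceptance tests)
```
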