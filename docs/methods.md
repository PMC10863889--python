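# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package, in the spirit of a methods appendix.

## Conventions

The laboratory frame is X anterior (direction of travel), Y vertical up,
Z to the subject's right; the default side is the right foot.  Rotation
matrices map segment coordinates into the lab frame.  Joint rotations are
distal segment relative to proximal, offset by the neutral-standing pose
so that quiet standing reads (0, 0, 0) at every joint:

    R_joint(t) = [R_prox(t)^T R_dist(t)] [R_prox0^T R_dist0]^T

Cardan decomposition uses the ZXY sequence, R = R_z(γ) R_x(α) R_y(β),
with clinical signs dorsiflexion(+)/plantarflexion(−) about z,
inversion(+)/eversion(−) about x, abduction(+)/adduction(−) about y.  For
a right foot with the axis convention above, the raw (γ, α, β) angles map
to clinical components with signs (+1, +1, −1); the frontal and
transverse signs flip for a left foot.  These sign maps are verified by
geometric unit tests (rotating the foot so the toes rise must read
dorsiflexion-positive, and so on), not assumed.

## Segment frames and models

Anatomical frames are built once, from the time-averaged neutral standing
trial:

* **Rearfoot (and the SINGLE foot segment, identically)** — x along
  CA→M1H; y normal to the plane through CA, M1H and the M1H/M5H midpoint,
  signed superior; z = x × y.
* **Toes** — x along M1H→HAL; y from x and the T5→HAL direction, signed
  superior; z = x × y.
* **Forefoot** — z along M1H→M5H; the frame is completed through the base
  of the first metatarsal: y = unit(z × unit(M1B→M1H)) signed superior,
  x = y × z.  The dorsal axis has to come from a marker off the
  metatarsal-head line, and M1B is the marker in the set that provides a
  well-conditioned one.
* **Shank** — y from the ankle centre (malleoli midpoint) toward the
  shank-cluster centroid; x = unit(y × malleolar line); z = x × y.

Dynamic orientation is obtained separately, by a weighted least-squares
rigid fit (SVD with determinant correction; reflections are corrected,
never returned) of each segment's *tracking* cluster against its static
configuration.  This tracking/anatomy separation is what lets SINGLE and
MULTI share the identical ankle convention while disagreeing dynamically:
the SINGLE foot is tracked by three markers spanning the whole foot
(posterior calcaneus, first and fifth metatarsal heads), so articulation
between calcaneus and forefoot is absorbed into its single-segment pose.

Joint centres: ankle = malleoli midpoint; midtarsal = midpoint of the
navicular tuberosity and the base of the fifth metatarsal; MTP = first
metatarsal head.  The "midfoot joint" is the single modelled midtarsal
articulation, standing in for the midtarsal + tarsometatarsal complex.

## Filtering and derivatives

Marker positions are low-pass filtered at 10 Hz and force-plate channels
at 45 Hz (both configurable) with a second-order Butterworth applied
forward and reverse (zero lag; two-pass gain at the cutoff is 0.5, DC
gain 1).  A Winter-style residual analysis (`residual_cutoff`) is
provided for data-driven cutoff selection: the RMS residual between raw
and filtered signal is computed over a candidate grid, the
noise-dominated upper half is fit with a line, and the lowest cutoff
whose residual does not exceed the line's intercept is chosen; pure-noise
input returns the top of the grid with a warning.

Derivatives are central differences (one-sided at the ends) applied after
filtering: angular velocity from the skew-symmetric part of Ṙ Rᵀ
(lab frame), angular acceleration by differencing ω, COM acceleration by
twice differencing the per-frame COM point.  Angles are computed from
filtered marker data; the angle series themselves are not re-filtered.

## Anthropometry

Segment masses are fractions of body mass and inertia tensors come from
radii of gyration scaled by a characteristic length.  The shipped
fractions (shank 0.0465, whole foot 0.0145, hindfoot 0.0119 of body
mass) are editable defaults drawn from standard anthropometric
literature — they are defaults, not subject-specific measurements.  The
hindfoot entry is split into equal halves (mass and inertia alike) for
the rearfoot and forefoot segments, so foot-segment masses sum exactly to
the whole-foot value together with the toes entry.  The SINGLE model's
one foot segment receives the full hindfoot entry; its toes carry no
mass, acting only as a point of force application.  Each segment's COM is
the geometric average of its own marker positions, evaluated per frame;
the equal-halves split applies to mass and inertia only.  All dynamics
correctness tests use synthetic chains with known inertial parameters, so
the verification of the solver never depends on these table defaults.

## Inverse dynamics

The GRF, COP and vertical free moment are assigned each sample to exactly
one foot segment: COP and joint centres are projected onto the horizontal
projection of the rearfoot long axis, and the segment whose
joint-centre-delimited interval contains the COP receives the entire
load.  A COP exactly on a boundary assigns distally — the COP migrates
anteriorly during stance, so distal tie-breaking avoids chatter; an
optional hysteresis mode (assignment may only advance distally) is off by
default.  In SINGLE the whole GRF acts on the one foot segment at the
measured COP and only the ankle is solved.

The recursion runs distal to proximal.  For each segment, in the lab
frame with the inertia tensor rotated per sample:

    F_p = m a_com − m g − F_ext − F_d
    M_p = I α + ω × (I ω) − M_d − r_d × F_d − r_ext × F_ext − M_free − r_p × F_p

where `F_d, M_d` are reactions from the previously solved distal joint,
`F_ext, M_free` the assigned external load at the COP, and `r_*` vectors
from the segment COM to the application points.  Joint moments are
reported as the couple on the distal segment.  Power uses the relative
angular velocity `ω_dist − ω_prox` in the lab frame (the scalar product
is frame-invariant once both factors share a frame); reported moment and
angular-velocity *components* are resolved in the proximal anatomical
frame with the clinical sign map, which is a reporting choice.

Two independent checks are built in: a whole-system free-body oracle that
sums every inertial, gravitational and external term over all segments
distal to a joint (no recursion, no reaction bookkeeping), and planar
1–3-link chain motions with sinusoidal absolute angles whose kinematics
and joint moments are closed-form, with the external load constructed
from the prescribed motion so the base residual vanishes exactly.  The
single-link pendulum (fixed pivot, no external load) provides the
work–energy identity: net joint work equals the change in total
mechanical energy.

## Statistics

Stance-normalised fields (101 nodes) are compared across matched subjects.

* **Paired t fields** use a random-field-theory critical height: solve
  `α = ρ₀(u) + R·ρ₁(u)` for the expected exceedance of the field maximum,
  with ρ₀ the t survival function,
  `ρ₁(u) = (√(4 ln 2)/2π)(1 + u²/ν)^{−(ν−1)/2}` the 1-D
  Euler-characteristic density, and `R = (Q−1)/FWHM` the resel count.
  Smoothness is estimated from the normalised residual-field gradients.
  Inference is two-sided.  Cluster-level p-values use the standard 1-D
  approximation (expected cluster count from the EC density with an
  exponential extent distribution) and are capped at α: a supra-threshold
  cluster is family-significant by the height threshold itself.
* **Paired Hotelling's T² fields** use the exhaustive paired sign-flip
  permutation distribution of the field maximum (2⁷ = 128 flips at the
  design size n = 7), which is exact under the paired null.  A parametric
  T² field threshold was deliberately not implemented: the 1-D
  Euler-characteristic density for T² fields could not be verified
  against an independent source in this environment, and at n = 7 the
  exact permutation approach is the statistically safer default anyway.
  The permutation mode is available for t fields too.
* Post-hoc component t fields are gated on a significant T² field and run
  at the Šidák level `1 − (1 − α)^{1/3} = 0.0170`.
* Scalar work contrasts use classical paired t tests with Bonferroni
  thresholds; normality is checked with Shapiro–Wilk (a constant sample
  fails by convention, with a warning).

Monte-Carlo calibration under smooth Gaussian nulls (n = 7, FWHM 20
nodes) puts the family-wise error of both field tests within 0.05 ± 0.02;
the acceptance script re-runs this calibration (2000 replicates each).
Zero-variance nodes set the t statistic to 0 with a warning; singular
node covariances fall back to a pseudo-inverse with a warning.

## Synthetic data

The generator emulates the protocol the pipeline targets: barefoot
heel-strike running at ~3.1 m/s, markers at 150 Hz, one force plate at
1500 Hz, stance ~0.24 s, a neutral-standing calibration capture of 1 s.
A neutral right-foot geometry carries the marker set; the dynamic trial
is forward kinematics — a prescribed shank lean (smooth −14°→+24° ramp)
and ankle-centre translation, then rearfoot, forefoot and toe poses
obtained by rotating each segment about its proximal joint centre by
prescribed joint-angle profiles.  Profiles are sums of raised-cosine
bumps with closed-form derivatives, parameterised in % stance; the
shipped defaults give ~17° dorsiflexion / 23° plantarflexion at the
ankle, ~18° of midfoot sagittal excursion, and MTP extension during
push-off.  Bump widths are at least 1.25× stance so the profiles'
spectral content sits well below the 10 Hz marker cutoff (two-pass
attenuation of the shipped profiles is ≤ 0.3°).  The MTP is modelled as a
pure dorsiflexion hinge about the M1H→M5H axis — non-sagittal toe motion
is negligible in practice, and the hinge makes the M1H and M5H markers
exactly rigid to both the forefoot and the toes, which conditions the toe
cluster.

The GRF is a double-peak vertical profile (active peak ~2.3 BW as a
half-sine, plus an impact bump near 12% stance), sinusoidal shear, a
small vertical free moment, and a COP interpolated between the
instantaneous heel and hallux marker positions — monotone heel → toe and
within the foot's extent by construction.  Marker noise is isotropic
Gaussian, added after the ground truth is recorded; the same spec (and
seed) yields byte-identical output.

The marker set is a dense, research-grade instrumented foot: a
five-marker heel cluster with anterior depth (posterior calcaneus,
Achilles-insertion wings, sustentaculum-tali / peroneal-tubercle style
placements), eight forefoot markers including two dorsal ones, five toe
markers plus M1H/M5H, and an eight-marker shank shell.  This density is
what the pose-fit noise floor demands: after the 10 Hz two-pass filter, a
1 mm white marker noise leaves ~0.33 mm effective noise, which propagates
to ~0.2–0.4° of rotation noise per joint axis even with these clusters.
The maximum recovery error over all joints and nodes then sits near
0.7–0.9° for typical noise seeds — close to, and for unlucky seeds
occasionally above, 1°.  That is the pipeline's physical noise floor, not
an implementation artifact; sparser real-world marker sets will do worse.

Because a threshold detector necessarily locates foot contact a fraction
of a sample late, ground-truth angle series should be evaluated on the
*detected* stance window (`GroundTruth.angles_on_window`); comparing
against the truth sampled on the nominal window aliases the onset offset
into a spurious error at steep profile regions.

**What the synthetic data does not emulate**: soft-tissue artifact
(marker noise is isotropic and white, real noise is correlated and
movement-locked), subtalar/talocrural separation, forefoot flexibility
within the segment, and dynamically consistent 3-D ground reaction forces
(the 3-D running trial is kinematically prescribed only; dynamic
consistency is provided by the planar cases, which is where the
Newton-Euler solver is verified quantitatively).  Passing tests on
synthetic data therefore validate the *pipeline machinery*, not the
biological realism of any particular output magnitude.

## Numerical choices and degenerate inputs

* Pose estimation rejects collinear clusters (rank test on the
  cross-covariance singular values) and never returns a reflection.
* Gimbal lock (|inversion| within ~1e−6 of 90°) warns and resolves the
  flexion/adduction split by convention; running stance stays far from it.
* Stance detection: vertical GRF ≥ 20 N with a 10 ms debounce; a record
  that never unloads returns the full record with a warning; one that
  never loads raises.
* Time normalisation is linear interpolation onto 101 nodes; at 150 Hz
  and the shipped profile smoothness its error is < 0.05°.
* Marker gaps are not interpolated; trials with gaps in the dynamic
  record are rejected (gap-filling is out of scope).
* Forces are anti-alias filtered and decimated to the marker rate;
  non-integer rate ratios require explicit opt-in to interpolation.
* Normalising by body mass twice is an error (a flag guards it).

## Problem sizes

Defaults used by the shipped tests and the acceptance script: trials of
~0.5 s (79 marker frames / 781 force samples), cohorts of 7 subjects,
10⁴ instances for pose/Cardan precision sweeps, 2000 replicates for the
family-wise-error calibration.  The full test suite runs in well under a
minute; the acceptance script in ~15 s.

## Known limitations

* Only the foot chain is solved; no knee/hip inverse dynamics.
* One force plate, one stance per trial; no bilateral handling.
* The parametric cluster-p approximation is crude for very rough fields
  (FWHM ≲ 5 nodes); the permutation mode is preferable there.
* Kinetics "truth" for the full 3-D running trial is not available by
  construction (see above); assertions about 3-D kinetics are therefore
  qualitative (directions, partitions) rather than magnitude-exact.
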