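# Methods

This note documents the models, conventions and numerical choices behind
`rimdyn`, and what the synthetic validation does and does not establish.

## Data model and conventions

All internal quantities are SI (m, N, Nm, rad, s); degrees appear only at
the reporting boundary. The lab frame is x = travel direction,
y = lateral (positive left), z = up. Marker files carry the 15-label
reduced upper-limb model; the wheel stream carries the force and moment
the hand applies to the rim plus the encoder angle θ.

The wheel sensor frame is treated as fixed (x backward, y up, z along the
axle pointing left), with θ carrying the rotation and its zero reference
at the backward horizontal, so the rim top sits at θ = 90°. Under this
convention the classic tangential-force formula
`Ftang = −Fx·sinθ + Fy·cosθ` recovers the propulsive component, and the
in-plane force magnitudes (tangential, radial, axial) are rotation
invariants. Writers of rim CSV files must use this reference; readers
unwrap θ to a continuous signal.

## Preprocessing

* **Filtering.** Rim forces and moments get a 4th-order Butterworth
  low-pass at 20 Hz applied forward–backward (zero phase). The
  forward–backward pass squares the magnitude response, so a sinusoid at
  the cutoff emerges with amplitude 0.5 — this is the documented contract,
  not an artifact. Edges are reflect-padded with 3× the filter order.
  Marker trajectories receive the same filter at 6 Hz before
  differentiation. This marker filter is an extension of the protocol
  (which filters kinetics only): inverse dynamics needs smooth
  accelerations, and 6 Hz is the conventional kinematic cutoff; it is
  configurable (`marker_filter.cutoff_hz`).
* **Gap handling.** Marker gaps are flagged at read time, never silently
  filled. `fill_gaps` interpolates interior runs up to 0.1 s with a cubic
  through the two nearest valid samples on each side (linear when fewer
  support points exist) and refuses to extrapolate boundary gaps.
  Occluded epicondyle or metacarpal markers can instead be rebuilt
  rigidly from their reference cluster (orthogonal Procrustes against a
  static calibration).
* **Synchronization.** Both trigger-started streams are resampled onto a
  common 240 Hz timebase — kinematics are upsampled rather than kinetics
  downsampled, so force rate-of-rise measures keep their bandwidth.
  Interpolation is cubic: linear interpolation of a 2 Hz signal sampled
  at 50 Hz leaves ~3·10⁻³ relative error, an order of magnitude above the
  round-trip fidelity we require; a cubic brings it below 10⁻³. The final
  partial source interval is edge-held, and gap flags propagate to any
  output sample whose bracket touches a flagged input.

## Events, cycles, temporal–spatial variables

Push detection is a per-sample threshold scan on the filtered axle moment
M_z: on when the moment exceeds 1 Nm, off when it falls below, samples
exactly at the threshold keep the current state. Pushes shorter than
0.1 s are discarded as chatter (debounce; configurable). A trailing push
with no off-crossing is dropped. Cycles run hand-on → next hand-on; the
analysis selects the first five consecutive cycles inside the configured
analysis window (the protocol's "most representative minute" selection is
replaced by this explicit window).

Within a cycle, TC is the push-phase sample where the hand marker is
highest; FT/AR are the extremes of hand x over the whole cycle, ties
breaking to the earliest sample. The hand landmark is the third
metacarpal (3m), a mid-hand point.

Temporal–spatial variables: cadence PF = n/duration of the selected
cycles; Dist = wheel radius × encoder rotation per cycle (so
PF × Dist equals belt speed at steady state); the push/recovery ratio is
reported as mean(Pphase)/mean(Rphase) with per-cycle ratios also emitted.
Contact and release angles are taken from the *hand's* rim angle (grip
marker projected about the axle) rather than the encoder, because the
encoder angle only coincides with the hand while it grips the rim and
drifts relative to it across cycles. Two reporting references are
offered: from the backward horizontal (default; rim top = 90°) or signed
from top dead centre.

The axle position needed for the hand's rim angle and for load
application is taken from the wheelchair geometry when declared, and
otherwise estimated by a least-squares circle fit (Kåsa) of the grip
trajectory during force application — on synthetic data this recovers the
axle and rim radius to micrometres.

## Hand-rim kinetics

`Feff` is the mean per-sample ratio Ftang/Ftot over the push phase —
consistent with reported values around 0.5–0.8 — with samples below 1 N
total force excluded to keep the ratio bounded at the push edges.
ERF/ERM are the maximum central-difference derivative of Ftot/Mtot
between push onset and the in-push peak, matching the "rate of rise"
reading of elevation rate (mean slope would be several times smaller than
published magnitudes). Whether such variables should be aggregated per
cycle and then averaged, or pooled, is genuinely open; we average
per-cycle values.

## Segment frames and joint kinematics

Frames use axis columns (x anterior, y longitudinal pointing proximal,
z lateral) per segment:

* trunk: lateral axis along acrl→acrr, anterior from c7 toward the
  acromion midpoint, orthonormalized;
* arm: longitudinal from the elbow centre (midpoint epc–ipc) to the
  glenohumeral centre (midpoint hha–hhp), lateral from ipc→epc;
* forearm: longitudinal wrist centre (midpoint ulr–rdl) → elbow centre,
  lateral from the styloid line;
* hand: longitudinal 3m → wrist centre, lateral from the styloid line.

The glenohumeral centre as the humeral-head marker midpoint is a
pragmatic landmark construction; regression-based centre estimation is
out of scope. Euler sequences are the ISB recommendations: shoulder
Y–X′–Y″ (plane of elevation, elevation — reported negative per
convention — and axial rotation) and Z–X′–Y″ for elbow and wrist
(flexion, carrying angle/deviation, axial rotation). The "elbow internal
rotation" variable β_e is implemented as forearm pronation–supination
(the third, long-axis rotation). Angles are unwrapped over time; samples
whose middle angle comes within 1° of a gimbal singularity are flagged
and linearly interpolated from neighbours.

## Inertial model and inverse dynamics

Segments are solids of revolution: mass fractions of body mass 2.8 %
(upper arm), 1.6 % (forearm), 0.6 % (hand); COM at 43.6/43.0/50.6 % of
segment length from the proximal joint; inertia tensors from an
equivalent cylinder with the mean of the proximal and distal radii
(I_long = m r²/2, I_trans = m(3r² + L²)/12). All values are explicit and
overridable — they are standard anthropometric scalings, not measured
subject properties.

Motion derivatives use central differences; angular velocity comes from
the skew part of ṘRᵀ and angular acceleration from differentiating it.
The measured rim load is decomposed into its rotation-invariant
components using θ, re-attached in the lab at the hand's rim angle, and
any measured axle moment in excess of r×F is carried as a pure couple on
the hand (the distribution of grip forces is unobservable; the SmartWheel
measures the net load). The Newton–Euler recursion then runs hand →
wrist → elbow → glenohumeral; joint loads are reported as the action on
the distal segment at the joint centre. For reporting, forces map to
(+anterior, +lateral, +superior) — lateral flips sign between sides — and
moments are projected on the proximal segment's axes as (+adduction,
+flexion, +internal rotation), the sign set derived for the right side
and mirrored for the left.

## The simulator and what the tests show

`rimdyn.synthetic` generates steady propulsion on a 600 mm wheel at
0.833 m/s: during each push the hand rides the rim over a 0.97 rad arc
centred on the top (cadence 1.25 strokes/s by default, push ≈ 0.35 s);
during recovery it returns along a lower path — a degree-7 interpolant
matching rim position, velocity, centripetal acceleration and jerk at
both ends (C³ overall), with a 0.10 m downward bulge, emulating the
semicircular style. The elbow follows from two-link inverse kinematics
with the elbow held posterior of the shoulder–wrist line; all 15 markers
are placed rigidly on segment frames. The push force is a half-sine in
total force (peak 47 N, 76 % tangential by default, echoing low-lesion
propulsion scales; the two-group kit adds a 93 N / 49 % variant), written
in the sensor frame so the tangential-force formula and the axle moment
(M_z = r·Ftang) are exact by construction. Gaussian noise (1 mm markers,
0.5 N forces) is added after the ground truth is recorded.

`forward_loads` computes ground-truth joint kinetics with a separate
Newton–Euler implementation (different angular-velocity algorithm,
different difference stencils, no shared helpers) and serves as the
oracle for the analysis-side inverse dynamics: noise-free agreement is
within 2 % for forces and 5 % for moments — in practice ~0.2 % — and
static random poses match hand-written statics to 1e-6 relative.

What the simulator does *not* emulate: soft-tissue artifact and marker
misplacement, hand–rim force distribution over the grasp, braking
moments, trunk motion, left/right asymmetry, and rolling-resistance power
balance. Passing tests therefore demonstrate internal consistency and
numerical correctness of the chain, not robustness to every artifact of
real recordings. Published cohort tables from patient recordings are not
reproducible from synthetic data, and the package does not attempt it;
group-level machinery is instead exercised on the synthetic two-group
kit, where the generated separation makes the exact rank-sum test attain
its minimum two-sided p of 2/252 at five subjects per group.

Numerical and scene parameters worth knowing: analysis timebase 240 Hz;
five cycles, 101 normalization stations; trial length 5.2 s in tests and
the acceptance script (seven pushes — enough for five cycles after
segmentation, kept short because all contracts are deterministic at this
size); simulator shoulder fixed 0.55 m above and 0.05 m behind the axle,
grip landmark 0.07 m distal of the wrist on the hand axis; rim radius
0.26 m.

## Known limitations

* Single-side analysis: left/right streams are analyzed independently;
  no bilateral symmetry or side-pooling logic beyond a side flag.
* The wheel-angle zero reference must be declared by the data writer;
  encoder-only contact/release angles are not comparable across cycles
  unless the hand's rim angle is available from markers.
* The glenohumeral model is a single ball joint; scapulothoracic and
  clavicular kinematics are out of scope.
* C3D input is not supported; markers are read from the CSV dialect.
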