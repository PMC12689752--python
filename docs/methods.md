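# Methods

This note describes the models implemented in `sacronav`, the choices made
where the design was genuinely open, and what the simulation results do and
do not say about a physical AR navigation system.

## Problem setting

Percutaneous sacroiliac (SI) screw fixation requires driving a 7.5 mm screw
through a narrow osseous corridor into the S1 or S2 vertebral body without
breaching cortex: anteriorly into the small pelvis, posteriorly into the
spinal canal, or superiorly/inferiorly into the neuroforamina. An AR
navigation workflow registers a pre-planned pelvis model to the patient by
probing three palpable landmarks — both anterior superior iliac spines
(ASIS) and the pubic symphysis — and then displays the planned trajectory
to the surgeon. `sacronav` reimplements that geometry so the error
propagation from landmark probing to screw placement can be studied in
software.

## Anatomical frame

The frame is derived purely from the three landmarks: origin at the
inter-ASIS midpoint; `lateral_right` along the inter-ASIS axis;
`inferior` toward the symphysis, orthogonalised against the lateral axis;
`anterior = lateral_right × inferior`, giving a right-handed orthonormal
triad. The symphysis lies in the lateral–inferior plane by construction.
Landmark triangles with area below 1 mm² are rejected as degenerate —
palpated pelvic landmarks are centimetres apart in any real subject, so
this threshold only guards against malformed input. All lengths are
millimetres; angles are reported in degrees and computed in radians.

## Registration

`fit_similarity` solves absolute orientation in closed form: SVD of the
cross-covariance of the centred point pairs, determinant sign correction on
the smallest singular vector so the rotation is always proper (a reflection
can never be returned), and — with scale enabled, the default, since the
workflow explicitly resizes the model to the patient — the least-squares
optimal isotropic scale `s = Σᵢ σᵢ(C)·sgnᵢ / var(X)` (Umeyama). This is the
exact minimiser of `Σ‖sRxᵢ + t − yᵢ‖²`, verified in the tests against a
7-parameter numerical minimisation. Fitted scales outside [0.5, 2.0] are
flagged as implausible but still returned.

Two consequences of using only three landmarks matter scientifically:

* Three points are coplanar, so a mirrored configuration is *directly*
  congruent (a triangle can be flipped in 3-D); the determinant correction
  therefore matters for noisy near-degenerate data and for ≥ 4 points, and
  the "reflection" failure mode manifests as a flip rotation, not as a
  large residual.
* A similarity can map any triangle almost exactly onto any slightly
  perturbed triangle. The fiducial registration error (FRE) is therefore
  near zero even under a grossly systematic probing error — the residual
  *cannot* diagnose the tilt. The target registration error (TRE) at the
  corridors is the quantity that matters, and the package reports both.

`SimilarityRegistration` exposes the same solver as a scikit-learn
transformer (`fit(X, y)` / `transform` / `get_params`), so it composes with
sklearn tooling; the landmark-level functions wrap it.

## Phantom

The phantom is parametric-geometric, not an anatomical atlas: the analysis
depends only on landmark geometry and corridor width, and both are
parameters. Model space is the canonical frame (+x lateral-right,
+y anterior, +z superior, origin at the inter-ASIS midpoint).

Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| ASIS span | 240 mm | adult pelvis order of magnitude |
| symphysis drop | 90 mm | symphysis much closer to the inter-ASIS axis than the ASIS are to each other — the lever-arm asymmetry that makes the landmark plane tilt-prone |
| S1 corridor radius | 7.5 mm | wide corridor; 3.75 mm clearance for the 7.5 mm screw |
| S2 corridor radius | 5.5 mm | narrow corridor; 1.75 mm clearance |
| screw diameter | 7.5 mm | cannulated SI screw |
| S1 centre offset | 50 mm posterior, 30 mm inferior | distance from inter-ASIS axis ≈ 58 mm |
| S2 centre offset | 55 mm posterior, 65 mm inferior | distance ≈ 85 mm; predominantly *inferior* to the axis |
| corridor axis | transverse, entry 80 mm lateral, aim at the body centre | insertion depth 80 mm |

The corridor centres encode the two structural facts the simulation is
meant to reproduce: S2 lies **farther** from the inter-ASIS axis than S1
(so any registration tilt about that axis displaces it more), and its
offset is predominantly **inferior** rather than posterior. The second
choice is what makes an anterior symphysis bias displace S2 *anteriorly*:
for a rotation of angle ω about the inter-ASIS axis the displacement of a
corridor point $q=(0,q_y,q_z)$ is $(0, -ω q_z, ω q_y)$ — the anterior
component scales with the inferior offset $|q_z|$ and the inferior
component with the posterior offset $|q_y|$. With $|q_z|>|q_y|$ for S2 the
induced breaches are anterior-dominant, the clinically observed pattern;
with the ratio reversed they would be inferior-dominant. The S1 centre
keeps $|q_z|<|q_y|$, but S1's larger clearance dominates its robustness
either way.

The optional surface mesh (corridor capsules plus landmark knobs,
exportable as STL/OBJ/PLY) is a stylised synthetic stand-in for a segmented
bone surface, intended for file-format round-trips and visualisation, not
anatomy.

## Noise model

* `landmark_sigma` — isotropic Gaussian per probed landmark coordinate
  (default 2 mm in the default trial configuration: landmark probing
  through a see-through display with hologram instability is considerably
  worse than pointer-based probing on exposed bone, for which ~1 mm is
  typical).
* `symphysis_anterior_bias` — one systematic offset of the probed symphysis
  along the patient's anterior axis (default 0; swept in the tilt
  experiment). This is the specific failure mode hypothesised for
  anterior S2 breaches: the symphysis depth is hard to judge through skin,
  and a too-anterior mark tilts the whole registration about the
  inter-ASIS axis. A pure bias $b$ with symphysis drop $h$ induces, to
  first order, a rotation of exactly $ω = b/h$ about that axis (the
  linearised least-squares solution; verified numerically), with zero
  first-order residual — i.e. an invisible-to-FRE tilt.
* `operator_entry_sigma`, `operator_angle_sigma` — drill-handling jitter
  (defaults 1 mm, 1°): entry-point scatter and independent Gaussian angular
  components about two axes perpendicular to the trajectory.

The lumped "guidance error" transform applied to each drilled trajectory is
the registration's target error `T_est ∘ T_true⁻¹`. A physical system adds
display-side errors (hologram "swimming", tracking latency); the simulator
deliberately folds everything display-side into this one transform-error
term plus operator jitter, because the two cannot be separated downstream
anyway.

## Metric conventions

* **MLD** is measured from the *planned infinite axis* over the *drilled
  inserted segment* (entry → tip). Distance to a line is convex along a
  segment, so the maximum is provably at an endpoint; the reported
  `base`/`tip` localisation is exact, not sampled. Ties report `tip`, the
  clinically riskier end.
* **Central-aim deviation** is measured to the drilled screw *tip*, making
  it depth-dependent (stopping short counts); the depth-independent
  closest-approach alternative was rejected because two screws with
  identical axes but different depths are not clinically equivalent.
* **Perforation** uses capsule-vs-capsule excess
  `d(axis point, corridor axis) + r_screw − R_corridor`, again convex along
  the insertion, so the verdict and worst-breach location come from the
  endpoints. Direction labels use an 8-sector compass in the (anterior,
  superior) plane: the secondary component is appended when it reaches
  `tan(22.5°) ≈ 0.414` of the primary, yielding the four pure and four
  adjacent combined labels. Posterior combinations are representable even
  though they are not expected in practice.
* The mesh-based detector samples the screw capsule surface (default
  1 point/mm²) and tests containment by ray parity (a vectorised
  Möller–Trumbore crossing count, written here because it needs nothing
  beyond numpy and works on any watertight mesh), with breach depth from a
  naive closest-point query.

## Guidance semantics

The intraoperative feedback is a replayable state machine over a JSONL pose
stream. Flags: `entry_ok` while positioning means the drill *tip* is within
`ε_entry` (default 2 mm) of the planned entry; `axis_ok` additionally
requires the drill ray to pass within `ε_aim` (default 2 mm) of the planned
central aim point. Once the aligned phase is reached — drilling underway —
the tip is inside the bone, so the entry criterion switches to the drill
*shaft* (the axis line) passing through the entry point; without this, any
full-depth pose would spuriously "lose" the entry. Defaults sit well below
the corridor radii, so satisfied guidance implies geometric safety in the
default phantom. Phases progress monotonically
(`searching → entry_captured → aligned → depth_reached`) per screw, screws
advance in the fixed order S1 right, S1 left, S2 right, S2 left, and a pose
gap longer than 1 s emits a tracking-stale event while flags hold their
last values. Events fire on every flag transition, so identical pose logs
produce byte-identical event logs.

## Monte-Carlo trial design

Each simulated pelvis receives a random rigid world pose, **one** landmark
probing and **one** registration shared by all four screws — the
matching-once protocol. This makes the systematic component of the four
deviations within a pelvis identical, which is why direction-concordant
perforations within a pelvis diagnose a matching error rather than operator
error; the summary reports the fraction of multi-perforation pelves whose
breaches share a direction. Per-pelvis random streams are spawned from a
single seed sequence, so runs are deterministic and order-independent.
Summaries report per-type correct rates, medians and IQRs of all metrics,
the perforation-direction histogram, and (descriptively only — no p-value
gates anything) rank-based S1-vs-S2 comparisons for the distance metrics
and a t-test for the angular deviation.

Problem sizes used by the test suite and the acceptance script — 1000
random transform/trajectory/capsule cases for the oracle comparisons, 500
pelves per bias level for the tilt sweep, 200 pelves per noise level for
the monotonicity sweep, 10 pelves for the default trial — were chosen to
make the binomial and maximum statistics stable at the asserted tolerances.

## What the simulations do and do not show

The phantom reproduces the *structural* asymmetry (corridor widths and
distances from the registration's weak axis) and the *protocol* (three
landmarks, matching once, fixed drilling order). It does not model bone
anatomy beyond capsules, soft tissue, hologram drift dynamics, tracking
latency, or operator learning, and the physical trial's headline rates are
not reproduction targets: they depend on hardware and operator specifics
the simulator deliberately lumps into configurable noise. What the package
establishes is the mechanism chain — anterior symphysis bias → rotation
about the inter-ASIS axis (axis alignment exact in the noise-free fit) →
anterior-dominant S2 breaches at biases ~3× smaller than S1 — and the
monotone degradation of placement safety with landmark noise.

## Numerical choices

Angular deviations use `atan2(‖d₁×d₂‖, d₁·d₂)`, accurate near 0° and 180°
where `arccos` loses half the significant digits. Perforation and MLD
evaluations are closed-form at segment endpoints (convexity), so no
sampling tolerances enter the reported metrics. Unit-vector checks use
1e-9; degenerate trajectories (zero length, non-positive diameter or
depth) and landmark triangles below 1 mm² raise typed errors rather than
propagating NaNs.
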