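# Methods

This note documents the models, conventions and numerical choices behind
`reachkin`, in the order the pipeline runs: synthetic trial generation,
preprocessing and segmentation, parameter extraction, and statistics. It
also states what the synthetic generator does and does not emulate, and
therefore what passing tests do and do not show about real capture data.

## Coordinate and unit conventions

Right-handed world frame: +Z vertical (up), +Y anterior (toward the
panel), +X toward the subject's right. Positions in cm, time in s,
angles in degrees. Left-arm recordings are mirrored about the sagittal
plane (x → −x, L/R labels swapped) to a canonical right-arm convention
before any angle computation, so signs are comparable across sides.

## Task geometry

The panel is vertical, its center aligned with the acromion of the
tested arm. Twelve targets sit on a 20 cm circle, target *i* at
`i · 30°` clockwise from 12 o'clock as seen by the subject. The start
target lies on the line from the panel center toward the shoulder at
forearm distance from the center. By default the panel distance is set
so the farthest target is just reachable with the arm chain alone
(`sqrt((arm_length − 1 cm)² − radius²)`): compensatory trunk motion is
then an *injected* impairment parameter, never something the geometry
forces.

## Synthetic trial generator

The generator produces one out-and-back reach as:

* **Spatial path** `P(w) = start + w·chord + g·L·sin(πw)·n̂`,
  `w ∈ [0, 1]`, with `L` the chord length and `n̂` a horizontal unit
  normal to the chord. The half-sine bump gives curvature a single gain
  knob `g` and a one-dimensional quadrature oracle for path length.
* **Time course**: path progress is driven by minimum-jerk submovements
  — an outbound composite of `k` bells (defaults: geometrically decaying
  amplitudes, near-disjoint windows), a 0.2 s hold at the target, and a
  single minimum-jerk return; static lead-in/lead-out pads (0.3 s)
  surround the movement. The minimum-jerk kernel is the quintic
  `x(τ) = A(10τ³ − 15τ⁴ + 6τ⁵)` whose speed peaks at `1.875·A/T`.
* **Trunk compensation**: the six trunk-attached markers translate along
  the horizontal reach direction by `trunk_translation · w(t)` and
  rotate about the vertical through the mid-acromion point by
  `trunk_rotation · w(t)` — time-locked to path progress, which is how
  compensatory recruitment presents in reaching.
* **Arm chain**: a two-link inverse kinematics (upper arm = acromion →
  lateral epicondyle; forearm + hand = epicondyle → endpoint) places the
  elbow in the plane of the shoulder–endpoint axis and the downward
  vertical (elbow-below-the-axis swivel). Wrist and hand markers are
  placed along the distal link; the second metacarpal marker *is* the
  commanded endpoint, so the apex coincides with the target exactly.
* **Noise**: i.i.d. zero-mean Gaussian, per marker, frame and axis,
  added after ground truth is extracted. Output is a pure function of
  (config, geometry, target, seed).

**Ground truth** is computed from the generating functions on a 10×
denser grid: outbound path length by quadrature, joint-angle series from
the same closed-form chain the markers are built from, trunk excursion
from the commanded trunk transform. Two definitions deserve note:

* `true_MT` is the movement duration *under the measurement convention*:
  the span between the first and last crossings of 5% of peak speed of
  the continuous noiseless speed profile. A relative-threshold
  segmentation can never see the full commanded duration (the quintic
  tails spend ≈ 5.9% of each submovement below a 5% threshold), so the
  commanded duration is stored separately as `true_cycle_duration`.
* True joint ranges are taken over the whole commanded movement
  (the pads are static, contributing only the rest posture).

`true_n_velocity_peaks` is `k + 1`: the `k` outbound submovements plus
the single return bell of the full out-and-back cycle.

A second generator (`synth_joint_trial`) animates the arm directly from
*prescribed* joint-angle ramps with a static trunk. It is the clean
vehicle for angle-recovery tests, since recovery error then cannot be
confounded with inverse-kinematics conditioning (below).

### What the generator does not emulate

Real capture data contain soft-tissue artifact (correlated,
movement-locked marker error, not i.i.d. noise), marker occlusions and
swaps, scapular elevation and protraction (our trunk is rigid),
anatomical variation in marker placement, and hand/finger motion (the
study's reaches are fist-closed; distal kinematics are out of scope).
Passing recovery tests therefore demonstrates the correctness of the
*computations* under the stated generative model — not robustness to
every artifact of optical capture. Per-session designs, sampling rate
(120 frames/s), target count and repetition structure do follow the
study design (36 movements per arm and session = 12 targets × 3
repetitions in a fixed randomized order shared across sessions).

Simulated NVP values (≈ 2–5 per cycle) are lower than those reported
for real chronic-stroke reaches (≈ 15–17): genuine impaired movement
fragments far more than a few clean submovements. The recovery question
— does the counter return the generated number? — is unaffected.

## Preprocessing and segmentation

* **Filter**: zero-phase (forward–backward) 4th-order Butterworth,
  6 Hz cutoff at 120 frames/s — the standard choice for upper-limb
  capture before differentiation; configurable, surfaced in reports.
* **Speed**: central differences on the filtered endpoint marker
  (one-sided at the ends).
* **Segmentation**: threshold at 5% of peak speed (relative, hence
  invariant to uniform speed scaling). Onset = last frame below
  threshold before the first up-crossing; full-cycle end = first frame
  below threshold after the last down-crossing. Using the first/last
  crossings (rather than crossings adjacent to the global peak) keeps
  leading and trailing submovements inside the segment even when
  inter-submovement dips fall below threshold. In outbound mode the end
  additionally requires the endpoint within a 2 cm capture radius of the
  target when the target is known.
* The default analysis phase is the full out-and-back cycle, since
  movement time is defined over the complete movement; outbound-only
  mode is available and reports label the phase used. Note that time to
  peak speed is phase-sensitive: over a full cycle whose largest
  submovement comes early, T%V_max lands early (single-digit percent in
  the synthetic cohorts), whereas outbound-only analysis of a clean
  reach gives the textbook ≈ 50%.

Discrete sampling plus filtering widen the detected window by a few
frame periods relative to the continuous-time convention; movement-time
recovery is tested at 4 frame periods, and detected duration converges
to the commanded duration as the threshold shrinks.

## Parameter definitions and numerics

* **CurvI**: sum of inter-frame distances over the endpoint-to-endpoint
  chord. For a full cycle the endpoints coincide, so directness is
  computed per half-cycle (split at the frame farthest from the start)
  and averaged.
* **NVP**: `scipy.signal.find_peaks` with prominence ≥ 5% of peak speed
  and ≥ 0.1 s separation (both configurable — no standard criteria
  exist); at least 1 whenever movement exists. Ties in peak speed break
  to the earliest frame.
* **LDJ**: jerk is obtained from the *filtered speed series* by two
  numerical differentiations (third derivatives of raw 120 Hz positions
  are unusable), then `−ln(MT³/V_max² · ∫j²dt)` with the trapezoid rule.
  Validated against the closed form for the minimum-jerk profile
  (`∫₀¹(60−360τ+360τ²)²dτ = 720`, so DLJ = 720/1.875² = 204.8). The
  duration-rescaling invariance is exact when the dilated movement is
  sampled with the same number of points, and is tested that way.
* **Thorax frame**: vertical = mid(C7, CLAV) → mid(T10, STRN) reversed;
  lateral = inter-acromion line orthogonalized; anterior = their cross
  product. Joints are treated as universal (two-axis) joints; axial
  humeral rotation is not computed (no parameter uses it).
* **Shoulder angles**: projection angles of the humerus in the thorax
  sagittal and frontal planes, measured from the downward thorax
  vertical. When the in-plane component of the humerus falls below 5% of
  its length the projection is ill-conditioned; such frames are flagged
  (NaN) and excluded from ranges. This conditioning is intrinsic: for
  near-sagittal elevated reaches (top targets) small marker
  perturbations produce large frontal-projection (ShAA) swings, and the
  recovery guarantee of 0.5° holds where the in-plane fraction stays
  ≥ 0.2 (recovery error scales roughly as 0.1°/fraction). The
  round-trip battery records this conditioning number per trial.
* **Th**: transverse-plane angle of the inter-acromion line relative to
  its onset orientation, the transverse plane being normal to the
  *onset* thorax vertical — which makes the measure invariant to a
  global rotation of the capture volume.
* **TExc**: maximum 3D displacement of the suprasternal-notch (CLAV)
  marker from segment onset. The construct targets trunk displacement
  in the transverse and sagittal planes; since those planes jointly span
  all three axes, the full Euclidean displacement is used.
* **Missing markers**: gaps ≤ 10% of a segment are linearly
  interpolated; beyond that the segment is rejected.
* **Aggregation**: per subject-session-arm mean over movements (the
  paired t-test framework compares means); median is available.

## Statistics

* **Spearman correlations**: average ranks for ties. For tie-free
  samples of n ≤ 30 the two-sided p-value comes from a Monte-Carlo
  permutation null of the rank correlation (200,000 permutations under
  a fixed internal seed, cached per n). The usual t-approximation is
  liberal deep in the tail, exactly where Holm needs p ≈ α/m; the
  permutation null restores family-wise error control (measured ≈ 0.05
  at a 3 × 11 grid, consistent with the Holm bound).
* **Cross-sectional scope** pools the pre and post subject-level
  observations (two rows per subject); the non-independence is
  acknowledged in reports, not corrected. **Longitudinal scope**
  correlates per-subject (post − pre) deltas; subjects missing a session
  are dropped with a logged warning.
* **Holm families**: one family per grid/table (all cells of a
  correlation panel; all 11 kinematic group tests; all clinical group
  tests; per-subject parameter sets).
* **Bootstrap paired test**: pairs are resampled with replacement
  (B = 1000 default). The CI is the percentile interval of the mean
  difference. The p-value is studentized (bootstrap-t): the bootstrap
  distribution of the centered t statistic is compared with the observed
  t, with a (count + 1)/(B_valid + 1) tail estimate. The plain
  percentile p-value `2·min(P(Δ*≤0), P(Δ*≥0))` has type-I error ≈ 0.11
  at n = 10 under a Gaussian null; the studentized version measures
  ≈ 0.04 and is the default. Zero-variance differences yield a
  degenerate-test flag (p undefined, d = 0).
* **Subject-level tests** treat the 36 pre vs. 36 post movements as the
  paired bootstrap units, paired by position in the fixed target order
  (per-subject inference otherwise has n = 1).
* **Cohen's d**: `(m_post − m_pre)/s_pre`, sign-adjusted so improvement
  is positive for decrease-is-better variables (MT, CurvI, NVP, Th,
  TExc, WMFT-Time); published summary tables print magnitudes, and the
  worked-example checks compare |d|.
* **Labels**: correlation magnitudes negligible < 0.30 ≤ low < 0.50 ≤
  moderate < 0.70 ≤ high, boundaries to the higher class; effect sizes
  0.20/0.50/0.80.
* **MCID flags**: improvement (direction-aware) ≥ MCID, boundary
  inclusive; a responder has ≥ 1 flagged measure. Shipped defaults
  (FMA-UE 5.25 pts, WMFT-FAS 0.37 pts, WMFT-Time 1.5 s, MAL 0.5 pts)
  are user-editable configuration, not constants of the method.
* **Non-paretic band**: mean ± 1 SD of pooled non-paretic aggregates;
  paretic subject-session means are flagged in/out per parameter.

## Synthetic cohorts

A cohort draws one latent severity per subject (uniform on [0, 1]) that
coherently sets submovement count (2–4), movement duration (1.8–3.2 s),
path curvature (0.05–0.25), trunk translation (2–14 cm) and trunk
rotation (2–10°); the non-paretic arm is fast (1.4 s), single-bell and
nearly trunk-still. Within-subject variability comes from per-movement
duration and submovement-amplitude jitter plus 0.05 cm marker noise —
ranges chosen to bracket moderate chronic hemiparesis (the study's
inclusion window) while keeping every trial reachable. A pre → post
severity drop (0 for null cohorts) injects intervention response.

Linked clinical scores are generated by mixing the normal scores of a
measured kinematic aggregate (LDJ by default) with Gaussian noise at
correlation ρ and mapping monotonically onto each clinical scale;
for bivariate-normal latents the expected Spearman correlation is
`(6/π)·asin(ρ/2)`, so ρ = 0.7167 targets r_s = 0.70 — the generative
target the recovery checks compare against.

## Validation batteries and problem sizes

The replicated batteries (run by both the test suite and
`scripts/acceptance.py`) use: 200 trials for velocity-peak and
trunk-excursion recovery; 40 prescribed-excursion trials for joint
ranges; 1000 replicates for bootstrap type-I error (n = 10, B = 1000)
and for the Holm grid family-wise error; 100 cohort replicates for the
null-cohort check and 30 for the linked-cohort correlation recovery.
Replicated cohorts use 12 movements per subject-session (one per
target); single-cohort analyses default to the study's 36. The observed
family-wise error is judged against its one-sided binomial tolerance at
1000 replicates (0.05 + 2.33·√(0.05·0.95/1000) ≈ 0.066), since Holm's
true rate sits just below 0.05 and a Monte-Carlo estimate fluctuates
around it.

## Known limitations

* The marker-based joint angles are a documented replacement for the
  proprietary model used with the original capture system; absolute
  angle values are convention-dependent even though ranges are robust.
* Frontal-plane shoulder projection (ShAA) is ill-conditioned for
  near-sagittal elevated reaches (see above); reports should read ShAA
  for top-target movements with care.
* The original study's raw data are not public, so its correlation
  tables and subject matrices cannot be reproduced numerically; the
  end-to-end checks validate the machinery on generatively known
  cohorts instead.
* No mixed-effects or regression modeling, no responder clustering, no
  imputation of missing sessions; C3D ingestion is not included —
  convert exports to the documented long-format CSV.
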