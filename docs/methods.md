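# Methods

`lumbarseg` re-implements, as a reusable pipeline, a marker-based
comparison of lumbar-spine segmentation strategies during flexion and
extension exercises, together with a synthetic motion-capture generator
that stands in for laboratory recordings.

## The analysis pipeline

**Inputs.** 120 Hz trajectories of 18 reflective markers: spinous
processes C7, T10, L1–L5, S1; lateral lumbar markers flanking L2 and L4;
bilateral PSIS, ASIS and iliac-crest (TIP) pelvis markers. The internal
unit is mm; the CSV reader converts metre-denominated files.

**Preprocessing.** Missing spans are filled before filtering: interior
gaps of at most `max_gap_frames` (default 24 frames = 0.2 s) by a cubic
spline over time per axis; longer or boundary gaps in lumbar markers by
lateral-marker reconstruction — the target is modelled as the donor
pair's midpoint plus a constant offset learned by least squares in the
pelvis anatomical frame over the window where target and donors are
simultaneously valid. This is exact when the segment moves rigidly with
the pelvis and degrades gracefully (RMSE of order the marker noise)
otherwise. Remaining unfillable gaps are reported, never silently
filled. Trajectories are then low-pass filtered with a fourth-order
Butterworth at 5 Hz, applied forward–backward (zero phase), so the
effective gain is the squared single-pass response (0.5 at the cutoff)
and event timing is not lagged.

**Pelvis frame and sagittal projection.** Per frame, the mediolateral
axis follows the line through the right and left pelvis-marker midpoints
(per-side PSIS/ASIS midpoints by default; the TIP pair is available via
`ml_definition="tip"` since the anatomical reading of "the right and
left pelvis markers" is ambiguous). The anteroposterior axis is the
ASIS-midpoint minus PSIS-midpoint direction orthogonalized against ML;
the longitudinal axis completes a right-handed triad pointing cranially.
Spine markers are projected onto (u, v) = (longitudinal,
anteroposterior) coordinates relative to the pelvis origin; u is the
independent variable of all fits. All downstream quantities are
invariant under global rigid motion by construction.

**Events.** The torso angle is the signed sagittal angle of the
projected C7→S1 line against the pelvis longitudinal axis (extension
positive, flexion negative). For dynamic trials, alternating extrema are
found by peak prominence (threshold: 25 % of the series' peak-to-peak
range) and refined by a parabolic-vertex fit over a 0.25 s window —
the refinement suppresses in-band noise that otherwise shifts the raw
argmax on flat extrema and is exact for noiseless symmetric waveforms.
Of the five performed cycles the first is dropped (familiarization) and
four are analyzed; each yields a flexion (max-extension → max-flexion)
and an extension half-cycle, sampled at 0/25/50/75/100 % of the frame
span (nearest-frame rounding, ties down). For stationary trials the
steady-state hold is the longest span within ±2° of the series median;
interior window edges are eroded by a 0.5 s guard (the raised-cosine
transient tail passes the tolerance test early), and four capture
instants are evenly spaced inside. A capture with any missing required
marker is dropped with a logged reason.

**Segment models.** Model 1: L1, L5 (line). Model 2: T10, S1 (line; the
Plug-in-Gait-adjacent choice). Model 3: L1, L3, L5 (quadratic). Model 4:
L1–L5 (quadratic). Each is fitted by least squares with v as a
polynomial in u (exact interpolation when the point count equals
degree + 1) and evaluated at five equidistant points of a shared
abscissa — the capture's L1..L5 span — so that model pairs are compared
over the same spatial range (per-model spans are available via
`shared_eval_range=False`). Markers that are not strictly monotone in u
(a spine folded past the pelvis axis) are a per-capture error, not a
silent fit.

**Lordosis.** Lumbar lordosis is the central angle of a circle fitted
to the five lumbar markers (Taubin algebraic fit; the exact circumcircle
for three points) between the radii through L1 and L5. The sign is
positive in flexion and negative in extension (anatomical lordosis), so
relative lordosis — the capture's angle minus the participant's mean
over their four neutral-standing (STA) captures — is positive toward
flexion. Marker sets within 1e-6 mm of their best-fit line (maximum
perpendicular PCA residual, i.e. the sagitta) take a distinct
straight-spine path with angle 0 by continuity.

**Agreement statistics.** For every capture and model pair, the sample
Pearson correlation of the five paired ordinates; zero-variance
ordinates make r undefined and exclude the capture with a log entry
(imputation would bias means). Cells are exercise × phase (statics pool
their four instants; dynamics are keyed by direction × percentage);
each cell reports mean ± sample SD (ddof = 1) and its actual n, with
relative lordosis aggregated identically. The formatted report rounds
half-away-from-zero to two decimals.

## The synthetic cohort

The generator emulates the study conditions: 17 participants (heights
drawn from the reported cohort mix, 6/17 male 178.5 ± 8.1 cm, 11/17
female 160.3 ± 6.6 cm), six exercises each — neutral standing (STA),
standing flexion–extension (FE, five 4 s cycles), sitting flexion (F,
five cycles), and 20 s holds of cobra (COB), shoulder-flexion stretch
(SHO) and cobra-arms-up (CUP) with 3 s neutral↔hold transitions.

Each frame's latent pose is: the lumbar arc angle (L1..L5 central angle
of a circular arc on which L1..L5 and S1 lie, equally spaced by arc
length; flexion positive), the thoracic tilt of the straight T10–C7
chain relative to the lumbar tangent at L1, and the pelvis tilt in the
world. The lumbar chain length is 0.16 × height; the tangent at S1 is
tipped 15° anteriorly relative to the pelvis longitudinal axis (sacral
slope), which keeps the sagittal curve's linear trend away from zero in
every pose — without it, poses with near-zero arc produce a degenerate
constant v(u). The neutral standing arc is −37°, a typical adult
standing L1–L5 lordosis. Exercise waveforms are raised-cosine
interpolations between extension and flexion targets calibrated so
commanded relative lordosis spans roughly −18° (cobra variants) to +57°
(peak sitting flexion) — the regime in which the two-segment and
all-vertebrae models are expected to agree — while per-FSU increments
stay below the 10–14° physiological ceiling (enforced at pose
validation). A per-participant flexibility factor (uniform 0.85–1.0 on
the lordosis/thoracic waveforms) adds between-participant spread while
keeping every pose inside that validity region.

Soft-tissue artefact is i.i.d. Gaussian noise per marker per axis
(default σ = 2 mm, configurable up to the ~14.8 mm reported for lumbar
skin markers); occlusions are random interior gaps (default 0.02
starts/marker/s, 3–15 frames). Identical seeds give bit-identical
output; the commanded pose per frame is stored as ground truth for
recovery tests.

**What the generator does not model** — and hence what passing tests do
not show about real data: posture- and frequency-correlated soft-tissue
artefact fields (real skin noise is neither white nor isotropic),
muscle-driven intra-cycle timing variation, out-of-sagittal-plane
motion beyond isotropic noise, and non-circular lumbar curvature
profiles (real vertebral angles are unevenly distributed, which is
precisely why the real study compares marker sets). The generator's
spine *is* a circular arc, so the circle-fit recovers curvature exactly
by construction; agreement between Models 3 and 4 on synthetic data
validates the pipeline's numerics and bookkeeping, not the anatomical
claim.

## Numerical choices and limitations

* Noise floor of the lordosis measurement: at σ = 2 mm the post-filter
  per-axis noise is ≈ 0.57 mm, and the single-frame central-angle
  estimate has a Cramér–Rao floor of ≈ 1.0° for this marker geometry;
  the Taubin-based estimator is essentially efficient (≈ 1.04°).
  Recovery tests therefore measure each commanded pose as the mean over
  four capture instants 0.25 s apart — the same four-sample convention
  the protocol uses for held postures — giving ≈ 0.46° RMSE.
* Problem sizes: the default verification cohort is 17 participants ×
  6 exercises (1 632 captures); the recovery sweep uses 100 poses over
  a 50 s ramp. Both run in seconds on one core.
* Tie-breaks: phase-percentage frames round to the nearest frame with
  ties toward the earlier frame; the first performed cycle is always
  the one dropped; L3's lateral donors are the L2 pair.
* Degenerate inputs: collinear pelvis markers, zero-length C7–S1
  vectors, monotone torso-angle series, folded spines and zero-variance
  ordinates all raise typed errors that the pipeline attributes to
  (participant, exercise, stage) and logs while continuing over the
  remaining trials.
* C3D support requires the optional `ezc3d` dependency; the CSV dialect
  (documented in `lumbarseg.io`) is the canonical format.
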