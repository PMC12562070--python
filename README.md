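# lumbarseg

How many segments does a marker-based motion-capture study need to track
the lumbar spine during large flexion–extension, such as the torso
motions of acrobatic athletes? `lumbarseg` is a Python pipeline for
answering that question from raw 3D marker trajectories. It compares
four lumbar marker-set models in the sagittal plane and quantifies
lumbar curvature with the circle-fit lordosis angle:

| Model | Markers | Fit |
|---|---|---|
| 1 | L1, L5 | degree-1 polynomial (one segment) |
| 2 | T10, S1 | degree-1 polynomial (Plug-in-Gait-adjacent) |
| 3 | L1, L3, L5 | degree-2 polynomial (two segments) |
| 4 | L1, L2, L3, L4, L5 | degree-2 polynomial (every FSU) |

Each model's curve v(u) — anteroposterior position as a polynomial in
the pelvis-longitudinal coordinate u — is fitted per *capture* (a
selected posture: one of four instants of a 20 s static hold, or a
0/25/50/75/100 % phase of a flexion or extension half-cycle) and
evaluated at five equidistant points of the capture's L1..L5 span.
Model pairs are scored with the sample Pearson correlation of those
five ordinates, aggregated to mean ± SD per exercise × phase cell.
Lumbar lordosis is the central angle of a circle fitted to the five
lumbar markers between the radii through L1 and L5, reported relative
to the participant's neutral-standing value (flexion positive).

The pipeline covers everything from file reading to the report:
Vicon-Nexus-style CSV (and optionally C3D) input, cubic-spline gap
filling with lateral-marker reconstruction of lumbar markers,
zero-phase 5 Hz Butterworth filtering, pelvis anatomical frame and
sagittal projection, torso-angle cycle segmentation, model fitting and
agreement statistics. A synthetic motion-capture generator produces
study-shaped cohorts — 17 participants, six exercises, realistic
curvature ranges, soft-tissue noise and marker gaps — so the whole
pipeline is testable without laboratory data. See `docs/methods.md`
for the model and its assumptions.

## Worked example

Run the full pipeline on a synthetic 17-participant cohort (2 mm marker
noise, seeded):

```python
import lumbarseg as ls

result = ls.run_synthetic(n_participants=17, seed=7, out_dir="runs/demo")
print(result.report.to_text())
```

which prints (excerpt):

```
Exercise / phase                 1v2           1v3           1v4           2v3           2v4           3v4   Rel. lordosis (deg)
--------------------------------------------------------------------------------------------------------------------------------
STA                      1.00 ± 0.00   0.91 ± 0.01   0.91 ± 0.01   0.91 ± 0.01   0.91 ± 0.01   1.00 ± 0.00          -0.00 ± 1.78
FE in flexion
  0%                     1.00 ± 0.00   0.94 ± 0.00   0.94 ± 0.00   0.94 ± 0.00   0.94 ± 0.00   1.00 ± 0.00         -12.87 ± 1.20
  25%                    1.00 ± 0.00   0.93 ± 0.00   0.93 ± 0.00   0.93 ± 0.00   0.93 ± 0.00   1.00 ± 0.00          -7.05 ± 1.45
  ...
COB                      1.00 ± 0.00   0.94 ± 0.00   0.94 ± 0.00   0.94 ± 0.00   0.94 ± 0.00   1.00 ± 0.00         -16.95 ± 1.41
```

Reading the output: every cell pools 68 captures (17 participants × 4
static instants, or × 4 cycles per dynamic phase). The `3v4` column —
the two-segment model against the all-vertebrae model — is 1.00 ± 0.00
throughout, the quantitative form of "two lumbar segments carry the
same sagittal-shape information as tracking every vertebra" within the
−18°…+57° relative-lordosis range the cohort spans. The relative
lordosis column tracks the commanded posture: ≈ 0° standing, ≈ −17°
in the cobra hold, sweeping to ≈ +29° at peak standing flexion.
`out_dir` receives `report.csv`/`report.txt`, the per-capture and
per-fit tidy tables, per-trial event JSONs and a run log.

The same is available from a shell:

```sh
lumbarseg synth --exercise FE --participants 17 --seed 42 --noise-sd 2.0 --out data/
lumbarseg run --synthetic --participants 17 --seed 7 --out runs/demo
lumbarseg preprocess data/P01_FE.csv --out data/P01_FE_filt.csv
```

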