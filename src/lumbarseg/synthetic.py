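"""Synthetic Vicon-style trial generator.

Emulates the capture protocol this pipeline analyzes: 120 Hz marker
trajectories for six exercises (STA, FE, F, COB, SHO, CUP) performed by a
cohort of 17 athletes.  The latent state of every frame is a small set of
pose parameters:

* ``lumbar_arc_deg`` — central angle of the circular arc on which the
  lumbar markers L1..L5 lie (S1 continues the same arc one gap below L5).
  Sign convention: flexion positive, extension (lordosis) negative.
* ``thoracic_tilt_deg`` — orientation of the straight T10-C7 chain
  relative to the lumbar tangent at L1 (flexion positive).
* ``pelvis_tilt_deg`` — sagittal rotation of the whole pelvis-plus-spine
  assembly in the world (anterior lean positive).

Because the spine chain is built in the pelvis frame, pelvis tilt moves
markers in the world but leaves all pelvis-relative quantities untouched;
this is what makes ground-truth recovery tests exact.

The neutral standing (STA) lumbar arc is fixed at -37 deg, a typical adult
standing L1-L5 lordosis; relative lordosis commanded by the exercise
waveforms then spans roughly -18 deg (cobra variants) to +57 deg (sitting
flexion), with per-FSU increments kept below the 10-14 deg physiological
ceiling.  Soft-tissue artefact is modelled as i.i.d. Gaussian noise per
marker per axis (default sigma 2 mm, configurable up to the ~14.8 mm values
reported for lumbar skin markers), plus random interior occlusion gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .markers import EXERCISES, LUMBAR_LABELS
from .trial import TrialRecording, TrialError

DEFAULT_RATE_HZ = 120.0

#: Neutral standing lumbar arc (L1..L5 central angle), extension-negative.
STA_ARC_DEG = -37.0

#: Largest physiological flexion-extension excursion of one lumbar FSU.
MAX_FSU_DEG = 14.0


# ---------------------------------------------------------------------------
# pose and geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpinePoseParams:
    """Latent pose of one frame (angles in degrees, lengths in mm)."""

    lumbar_arc_deg: float
    thoracic_tilt_deg: float
    pelvis_tilt_deg: float
    lumbar_chain_mm: float

    def validate(self) -> "SpinePoseParams":
        vals = (self.lumbar_arc_deg, self.thoracic_tilt_deg,
                self.pelvis_tilt_deg, self.lumbar_chain_mm)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite pose parameters: {vals}")
        if self.lumbar_chain_mm <= 0:
            raise ValueError("lumbar_chain_mm must be positive")
        if abs(self.lumbar_arc_deg) >= 180:
            raise ValueError("|lumbar_arc_deg| must be < 180")
        # the arc spans 4 FSUs between L1 and L5 (the L5-S1 gap is equal)
        fsu = abs(self.lumbar_arc_deg) / 4.0
        if fsu > MAX_FSU_DEG:
            raise ValueError(
                f"per-FSU increment {fsu:.2f} deg exceeds the {MAX_FSU_DEG} deg bound"
            )
        return self


@dataclass(frozen=True)
class ParticipantGeometry:
    """Per-participant segment lengths (mm), fixed for all of their trials.

    Lengths are anthropometric fractions of standing height; the lumbar
    chain (arc length L1 -> L5) uses the fixed fraction 0.16.
    """

    height_mm: float
    lumbar_chain_mm: float
    sacral_slope_deg: float
    l1_t10_mm: float
    t10_c7_mm: float
    psis_halfwidth_mm: float
    asis_halfwidth_mm: float
    ap_halfdepth_mm: float
    lateral_halfwidth_mm: float
    tip_halfwidth_mm: float
    tip_up_mm: float
    s1_up_mm: float
    standing_up_mm: float

    @classmethod
    def from_height(cls, height_mm: float = 1700.0) -> "ParticipantGeometry":
        if not math.isfinite(height_mm) or height_mm <= 0:
            raise ValueError(f"height must be positive, got {height_mm}")
        h = float(height_mm)
        return cls(
            height_mm=h,
            lumbar_chain_mm=0.16 * h,
            sacral_slope_deg=15.0,
            l1_t10_mm=0.07 * h,
            t10_c7_mm=0.14 * h,
            psis_halfwidth_mm=0.03 * h,
            asis_halfwidth_mm=0.07 * h,
            ap_halfdepth_mm=0.04 * h,
            lateral_halfwidth_mm=0.03 * h,  # same width as the PSIS pair
            tip_halfwidth_mm=0.08 * h,
            tip_up_mm=0.025 * h,
            s1_up_mm=0.02 * h,
            standing_up_mm=0.55 * h,
        )


# ---------------------------------------------------------------------------
# marker construction
# ---------------------------------------------------------------------------

def _sagittal_rotations(beta_rad: np.ndarray) -> np.ndarray:
    """Stack of rotations about the mediolateral (y) axis.

    Positive angles rotate the cranial (+z) direction toward anterior (+x).
    """
    c, s = np.cos(beta_rad), np.sin(beta_rad)
    n = beta_rad.shape[0]
    R = np.zeros((n, 3, 3))
    R[:, 0, 0] = c
    R[:, 0, 2] = s
    R[:, 1, 1] = 1.0
    R[:, 2, 0] = -s
    R[:, 2, 2] = c
    return R


def _arc_positions(theta_rad: np.ndarray, s: float, chain_mm: float,
                   phi0_rad: float) -> tuple[np.ndarray, np.ndarray]:
    """(anterior, up) coordinates of the point at arc length ``s`` from S1.

    The chain curves with constant curvature kappa = theta / chain, where
    ``theta`` is the signed L1..L5 central angle and ``chain`` the L1..L5
    arc length.  The tangent at S1 is the pelvis longitudinal axis tipped
    anteriorly by the sacral slope ``phi0`` (anatomically the sacrum is
    not aligned with the pelvis vertical axis), so the sagittal curve
    v(u) keeps a linear trend even when the arc passes through zero.
    """
    kappa = theta_rad / chain_mm
    phi = phi0_rad + kappa * s
    small = np.abs(kappa) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        ant = np.where(small, s * np.sin(phi0_rad) + 0.5 * kappa * s * s * np.cos(phi0_rad),
                       (np.cos(phi0_rad) - np.cos(phi)) / kappa)
        up = np.where(small, s * np.cos(phi0_rad) - 0.5 * kappa * s * s * np.sin(phi0_rad),
                      (np.sin(phi) - np.sin(phi0_rad)) / kappa)
    return ant, up


def spine_chain_batch(
    arc_deg: np.ndarray,
    thoracic_deg: np.ndarray,
    pelvis_deg: np.ndarray,
    geometry: ParticipantGeometry,
) -> dict[str, np.ndarray]:
    """Noiseless marker positions for a batch of poses.

    Returns a mapping label -> (n, 3) world coordinates (x anterior,
    y left, z cranial; mm).  All spine and lumbar markers lie in the pelvis
    midsagittal plane (y = 0 before lateral offsets and noise).
    """
    arc_deg = np.atleast_1d(np.asarray(arc_deg, dtype=float))
    thoracic_deg = np.broadcast_to(np.asarray(thoracic_deg, dtype=float), arc_deg.shape)
    pelvis_deg = np.broadcast_to(np.asarray(pelvis_deg, dtype=float), arc_deg.shape)
    if not (np.isfinite(arc_deg).all() and np.isfinite(thoracic_deg).all()
            and np.isfinite(pelvis_deg).all()):
        raise ValueError("non-finite pose values")

    g = geometry
    n = arc_deg.shape[0]
    theta = np.deg2rad(arc_deg)
    gap = g.lumbar_chain_mm / 4.0
    base_s1 = np.array([-g.ap_halfdepth_mm, 0.0, g.s1_up_mm])

    local: dict[str, np.ndarray] = {}
    # pelvis rigid body (local frame origin = mean of the 4 PSIS/ASIS markers)
    pelvis_local = {
        "RPSIS": (-g.ap_halfdepth_mm, -g.psis_halfwidth_mm, 0.0),
        "LPSIS": (-g.ap_halfdepth_mm, g.psis_halfwidth_mm, 0.0),
        "RASIS": (g.ap_halfdepth_mm, -g.asis_halfwidth_mm, 0.0),
        "LASIS": (g.ap_halfdepth_mm, g.asis_halfwidth_mm, 0.0),
        "RTIP": (0.0, -g.tip_halfwidth_mm, g.tip_up_mm),
        "LTIP": (0.0, g.tip_halfwidth_mm, g.tip_up_mm),
    }
    for lb, p in pelvis_local.items():
        local[lb] = np.broadcast_to(np.asarray(p), (n, 3)).copy()

    # lumbar arc: S1 at s=0, then L5..L1 at equal arc-length gaps
    s_values = {"S1": 0.0, "L5": gap, "L4": 2 * gap, "L3": 3 * gap,
                "L2": 4 * gap, "L1": 5 * gap}
    phi0 = math.radians(g.sacral_slope_deg)
    for lb, s in s_values.items():
        ant, up = _arc_positions(theta, s, g.lumbar_chain_mm, phi0)
        pts = np.zeros((n, 3))
        pts[:, 0] = base_s1[0] + ant
        pts[:, 2] = base_s1[2] + up
        local[lb] = pts

    # straight thoracic chain from L1 along (lumbar tangent at L1 + tilt)
    phi_l1 = phi0 + (theta / g.lumbar_chain_mm) * (5 * gap)
    phi_t = phi_l1 + np.deg2rad(thoracic_deg)
    direction = np.zeros((n, 3))
    direction[:, 0] = np.sin(phi_t)
    direction[:, 2] = np.cos(phi_t)
    local["T10"] = local["L1"] + g.l1_t10_mm * direction
    local["C7"] = local["T10"] + g.t10_c7_mm * direction

    # lateral lumbar markers flank L2 and L4 at PSIS width
    w = np.array([0.0, g.lateral_halfwidth_mm, 0.0])
    local["LL2"] = local["L2"] + w
    local["RL2"] = local["L2"] - w
    local["LL4"] = local["L4"] + w
    local["RL4"] = local["L4"] - w

    R = _sagittal_rotations(np.deg2rad(pelvis_deg))
    base = np.array([0.0, 0.0, g.standing_up_mm])
    return {lb: np.einsum("nij,nj->ni", R, pts) + base for lb, pts in local.items()}


def build_spine_chain(pose: SpinePoseParams, geometry: ParticipantGeometry) -> dict[str, np.ndarray]:
    """Noiseless marker positions (label -> (3,) mm) for a single pose."""
    pose.validate()
    batch = spine_chain_batch(
        np.array([pose.lumbar_arc_deg]),
        np.array([pose.thoracic_tilt_deg]),
        np.array([pose.pelvis_tilt_deg]),
        geometry,
    )
    return {lb: pts[0] for lb, pts in batch.items()}


# ---------------------------------------------------------------------------
# exercise protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExerciseProtocol:
    """Waveform definition of one exercise.

    For static exercises the pose ramps from neutral to the hold targets
    over ``lead_in_s`` (raised cosine), is held for ``duration_s`` and ramps
    back over ``lead_out_s``.  For dynamic exercises the pose oscillates
    ``n_cycles`` times between the extension extreme (at t = 0) and the
    flexion extreme, again with raised-cosine interpolation, so extrema are
    unambiguous and the waveform is C1-smooth.

    Targets are expressed as *relative* lordosis (deg, versus the STA arc),
    thoracic tilt (deg) and pelvis tilt (deg).
    """

    exercise_id: str
    duration_s: float
    n_cycles: int
    is_dynamic: bool
    rel_ext: float
    rel_flex: float
    thor_ext: float
    thor_flex: float
    pelv_ext: float
    pelv_flex: float
    lead_in_s: float = 0.0
    lead_out_s: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.is_dynamic and self.n_cycles < 1:
            raise ValueError("dynamic protocol needs n_cycles >= 1")
        if not self.is_dynamic and self.n_cycles != 0:
            raise ValueError("static protocol must have n_cycles = 0")

    @property
    def total_duration_s(self) -> float:
        return self.lead_in_s + self.duration_s + self.lead_out_s

    def waveform(self, t: np.ndarray, amplitude_scale: float = 1.0
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(relative lordosis, thoracic tilt, pelvis tilt) at times ``t``.

        Dynamics oscillate between the extension and flexion targets;
        statics ramp neutral -> hold -> neutral with the hold targets in
        the ``*_ext`` fields.
        """
        t = np.asarray(t, dtype=float)
        a = amplitude_scale
        if self.is_dynamic:
            x = 0.5 * (1.0 - np.cos(2.0 * np.pi * self.n_cycles * t / self.duration_s))
            rel = a * (self.rel_ext + (self.rel_flex - self.rel_ext) * x)
            thor = a * (self.thor_ext + (self.thor_flex - self.thor_ext) * x)
            pelv = self.pelv_ext + (self.pelv_flex - self.pelv_ext) * x
            return rel, thor, pelv
        x = np.ones_like(t)
        if self.lead_in_s > 0:
            ramp = t < self.lead_in_s
            x[ramp] = 0.5 * (1.0 - np.cos(np.pi * t[ramp] / self.lead_in_s))
        if self.lead_out_s > 0:
            t_end = self.lead_in_s + self.duration_s
            ramp = t > t_end
            frac = np.minimum((t[ramp] - t_end) / self.lead_out_s, 1.0)
            x[ramp] = 0.5 * (1.0 + np.cos(np.pi * frac))
        return a * self.rel_ext * x, a * self.thor_ext * x, self.pelv_ext * x

    def hold_window_s(self) -> tuple[float, float]:
        """(start, end) of the held posture, in seconds (statics only)."""
        if self.is_dynamic:
            raise ValueError("hold window is defined for static protocols only")
        return self.lead_in_s, self.lead_in_s + self.duration_s


def _static(exercise_id: str, rel: float, thor: float, pelv: float,
            lead_s: float) -> ExerciseProtocol:
    return ExerciseProtocol(
        exercise_id=exercise_id, duration_s=20.0, n_cycles=0, is_dynamic=False,
        rel_ext=rel, rel_flex=rel, thor_ext=thor, thor_flex=thor,
        pelv_ext=pelv, pelv_flex=pelv, lead_in_s=lead_s, lead_out_s=lead_s,
    )


def _dynamic(exercise_id: str, rel: tuple[float, float], thor: tuple[float, float],
             pelv: tuple[float, float]) -> ExerciseProtocol:
    return ExerciseProtocol(
        exercise_id=exercise_id, duration_s=20.0, n_cycles=5, is_dynamic=True,
        rel_ext=rel[0], rel_flex=rel[1], thor_ext=thor[0], thor_flex=thor[1],
        pelv_ext=pelv[0], pelv_flex=pelv[1],
    )


def default_protocols() -> dict[str, ExerciseProtocol]:
    """The six study exercises with their commanded pose targets.

    Relative-lordosis targets reproduce the observed per-exercise extremes
    (about -18 deg for the cobra variants up to +57 deg at peak sitting
    flexion); thoracic and pelvis targets are chosen for realistic torso
    excursions (standing flexion-extension sweeps the torso angle by well
    over 100 deg, the cobra holds are performed prone).
    """
    return {
        "STA": _static("STA", rel=0.0, thor=0.0, pelv=0.0, lead_s=0.0),
        "FE": _dynamic("FE", rel=(-13.74, 31.98), thor=(-40.0, 80.0), pelv=(0.0, 0.0)),
        "F": _dynamic("F", rel=(34.94, 57.30), thor=(20.0, 80.0), pelv=(10.0, 25.0)),
        "COB": _static("COB", rel=-17.91, thor=-40.0, pelv=75.0, lead_s=3.0),
        "SHO": _static("SHO", rel=-14.98, thor=-30.0, pelv=30.0, lead_s=3.0),
        "CUP": _static("CUP", rel=-18.30, thor=-45.0, pelv=75.0, lead_s=3.0),
    }


# ---------------------------------------------------------------------------
# noise and trial generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Soft-tissue artefact and occlusion model.

    ``soft_tissue_sd_mm`` is the per-axis Gaussian sigma; ``gap_rate_per_s``
    the probability per marker per second of an occlusion starting;
    ``gap_length_frames`` inclusive bounds of the (uniform) gap length.
    Identical seeds give bit-identical output.
    """

    soft_tissue_sd_mm: float = 2.0
    gap_rate_per_s: float = 0.0
    gap_length_frames: tuple[int, int] = (3, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.soft_tissue_sd_mm < 0:
            raise ValueError("soft_tissue_sd_mm must be >= 0")
        if self.gap_rate_per_s < 0:
            raise ValueError("gap_rate_per_s must be >= 0")
        lo, hi = self.gap_length_frames
        if not (1 <= lo <= hi):
            raise ValueError("gap_length_frames must satisfy 1 <= lo <= hi")


def generate_trial(
    protocol: ExerciseProtocol,
    geometry: ParticipantGeometry,
    noise: NoiseModel | None = None,
    participant_id: str = "P01",
    amplitude_scale: float = 1.0,
    rate: float = DEFAULT_RATE_HZ,
) -> TrialRecording:
    """Generate one trial at ``rate`` Hz with per-frame ground truth.

    The returned recording stores the commanded pose per frame under
    ``meta["ground_truth"]`` (lumbar arc, relative lordosis, thoracic and
    pelvis tilt), plus the hold window for static exercises.
    """
    if protocol.total_duration_s <= 0:
        raise ValueError("protocol duration must be positive")
    n = int(round(protocol.total_duration_s * rate))
    t = np.arange(n) / rate
    rel, thor, pelv = protocol.waveform(t, amplitude_scale)
    arc = STA_ARC_DEG + rel

    # validate the extreme poses once (the waveform is bounded by them)
    for idx in (int(np.argmin(arc)), int(np.argmax(arc))):
        SpinePoseParams(arc[idx], thor[idx], pelv[idx], geometry.lumbar_chain_mm).validate()

    markers = spine_chain_batch(arc, thor, pelv, geometry)

    ground_truth = {
        "lumbar_arc_deg": arc,
        "relative_lordosis_deg": arc - STA_ARC_DEG,
        "thoracic_tilt_deg": np.asarray(thor, dtype=float).copy(),
        "pelvis_tilt_deg": np.asarray(pelv, dtype=float).copy(),
    }
    meta: dict = {"ground_truth": ground_truth, "amplitude_scale": amplitude_scale,
                  "n_cycles": protocol.n_cycles}
    if not protocol.is_dynamic:
        lo_s, hi_s = protocol.hold_window_s()
        meta["hold_window"] = (int(round(lo_s * rate)),
                               min(n - 1, int(round(hi_s * rate))))

    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        for lb in sorted(markers):
            if noise.soft_tissue_sd_mm > 0:
                markers[lb] = markers[lb] + rng.normal(
                    0.0, noise.soft_tissue_sd_mm, size=markers[lb].shape)
            if noise.gap_rate_per_s > 0:
                p = noise.gap_rate_per_s / rate
                starts = np.flatnonzero(rng.random(n) < p)
                lo, hi = noise.gap_length_frames
                lengths = rng.integers(lo, hi + 1, size=starts.size)
                for s0, length in zip(starts, lengths):
                    a = max(1, int(s0))            # keep trial boundaries valid
                    b = min(n - 1, a + int(length))
                    if a < b:
                        markers[lb][a:b] = np.nan
                if np.all(~np.isfinite(markers[lb][:, 0])):
                    raise TrialError(f"gap model occluded marker {lb} entirely")

    return TrialRecording(
        participant_id=participant_id,
        exercise_id=protocol.exercise_id,
        rate=rate,
        markers=markers,
        meta=meta,
    ).validate()


def sample_geometry(rng: np.random.Generator) -> tuple[ParticipantGeometry, str]:
    """Draw one participant's geometry from the cohort anthropometrics.

    Heights follow the reported cohort: 6/17 males at 178.47 +/- 8.08 cm and
    11/17 females at 160.27 +/- 6.58 cm.
    """
    if rng.random() < 6.0 / 17.0:
        height_cm, sex = rng.normal(178.47, 8.08), "M"
    else:
        height_cm, sex = rng.normal(160.27, 6.58), "F"
    height_cm = float(np.clip(height_cm, 140.0, 205.0))
    return ParticipantGeometry.from_height(height_cm * 10.0), sex


def generate_cohort(
    n_participants: int = 17,
    protocols: dict[str, ExerciseProtocol] | None = None,
    seed: int = 0,
    noise_sd_mm: float = 2.0,
    gap_rate_per_s: float = 0.02,
    rate: float = DEFAULT_RATE_HZ,
) -> list[TrialRecording]:
    """Generate the full study: one trial per exercise per participant.

    Geometry and a flexibility factor (uniform 0.85-1.0, applied to the
    lordosis/thoracic waveforms) are drawn once per participant and reused
    across their trials; all randomness derives from ``seed``.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if protocols is None:
        protocols = default_protocols()
    master = np.random.default_rng(seed)
    trials: list[TrialRecording] = []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        geometry, sex = sample_geometry(master)
        scale = float(master.uniform(0.85, 1.0))
        for ex in EXERCISES:
            if ex not in protocols:
                continue
            noise = NoiseModel(
                soft_tissue_sd_mm=noise_sd_mm,
                gap_rate_per_s=gap_rate_per_s,
                seed=int(master.integers(2 ** 31)),
            )
            trial = generate_trial(protocols[ex], geometry, noise,
                                   participant_id=pid, amplitude_scale=scale,
                                   rate=rate)
            trial.meta.update(height_mm=geometry.height_mm, sex=sex)
            trials.append(trial)
    return trials


def lordosis_sweep_trial(
    n_poses: int = 100,
    rel_range: tuple[float, float] = (-18.3, 57.3),
    noise_sd_mm: float = 2.0,
    seed: int = 0,
    duration_s: float = 50.0,
    rate: float = DEFAULT_RATE_HZ,
    geometry: ParticipantGeometry | None = None,
    samples_per_pose: int = 4,
    sample_spacing_s: float = 0.25,
) -> tuple[TrialRecording, np.ndarray, np.ndarray]:
    """Slow linear ramp of commanded relative lordosis, for recovery tests.

    Returns ``(trial, capture_frames, commanded_relative_lordosis)``.
    ``capture_frames`` has shape (n_poses, samples_per_pose): each commanded
    pose is measured at four capture instants distributed around it and
    averaged, mirroring the protocol's four-sample measurement of held
    postures.  The commanded value per pose is the mean of the commanded
    values at those instants (exact for a linear ramp).  A 1 s margin keeps
    captures away from filter edge transients.
    """
    if geometry is None:
        geometry = ParticipantGeometry.from_height(1700.0)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    rel = rel_range[0] + (rel_range[1] - rel_range[0]) * t / t[-1]
    arc = STA_ARC_DEG + rel
    markers = spine_chain_batch(arc, np.zeros(n), np.zeros(n), geometry)
    if noise_sd_mm > 0:
        rng = np.random.default_rng(seed)
        for lb in sorted(markers):
            markers[lb] = markers[lb] + rng.normal(0.0, noise_sd_mm, markers[lb].shape)
    trial = TrialRecording("SWEEP", "FE", rate, markers,
                           meta={"ground_truth": {"lumbar_arc_deg": arc,
                                                  "relative_lordosis_deg": rel}})
    offsets = (np.arange(samples_per_pose) - (samples_per_pose - 1) / 2.0)
    offsets = offsets * sample_spacing_s * rate
    margin = int(rate + np.abs(offsets).max()) + 1
    centers = np.linspace(margin, n - 1 - margin, n_poses)
    frames = np.rint(centers[:, None] + offsets[None, :]).astype(int)
    commanded = rel[frames].mean(axis=1)
    return trial.validate(), frames, commanded
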