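"""Trajectory conditioning and sagittal-plane projection.

Order of operations in the pipeline: gap filling (cubic spline for short
interior gaps, lateral-marker reconstruction for lumbar markers), then
zero-phase low-pass filtering, then construction of the per-frame pelvis
anatomical frame and projection of the spine markers into the sagittal
plane it defines.

The sagittal plane is perpendicular to the mediolateral line through the
midpoints of the right and left pelvis markers; the projection's abscissa
``u`` is the pelvis longitudinal (cranial) axis — the independent variable
of all downstream polynomial fits — and its ordinate ``v`` the
anteroposterior axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .markers import LATERAL_DONORS
from .trial import TrialRecording, TrialError


class GapFillError(ValueError):
    """Unfillable gap in a context where the contract requires filling."""


class DegeneratePelvisError(ValueError):
    """Pelvis markers do not span a plane."""


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def lowpass_filter(trial: TrialRecording, cutoff_hz: float = 5.0,
                   order: int = 4) -> TrialRecording:
    """Zero-phase Butterworth low-pass of every trajectory.

    The filter is applied forward and backward (``sosfiltfilt``), so event
    timing is not lagged and the effective magnitude response is the square
    of the single-pass Butterworth response (gain 0.5 at the cutoff).
    Requires a gap-free trial: run gap filling first.
    """
    if cutoff_hz >= trial.rate / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist rate {trial.rate / 2} Hz"
        )
    if trial.has_missing():
        raise GapFillError("trial contains missing samples; fill gaps before filtering")
    if trial.frame_count <= 3 * order:
        raise ValueError(
            f"trial too short to filter: {trial.frame_count} frames <= 3 x order"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trial.rate, output="sos")
    out = trial.copy()
    for lb, arr in out.markers.items():
        out.markers[lb] = signal.sosfiltfilt(sos, arr, axis=0)
    return out


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------

@dataclass
class GapEntry:
    marker: str
    start: int
    end: int  # exclusive
    method: str  # "spline" | "reconstructed" | "unfilled"

    def as_dict(self) -> dict:
        return {"marker": self.marker, "start": self.start,
                "end": self.end, "method": self.method}


@dataclass
class GapReport:
    entries: list[GapEntry] = field(default_factory=list)

    @property
    def unfilled(self) -> list[GapEntry]:
        return [e for e in self.entries if e.method == "unfilled"]

    def as_dict(self) -> dict:
        return {"gaps": [e.as_dict() for e in self.entries],
                "n_unfilled": len(self.unfilled)}


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, end) index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(a), int(b)) for a, b in zip(idx[::2], idx[1::2])]


def fill_gaps(trial: TrialRecording, max_gap: int = 24,
              ml_definition: str = "side_midpoints"
              ) -> tuple[TrialRecording, GapReport]:
    """Fill missing spans and report what was done to each.

    Interior gaps of at most ``max_gap`` frames are filled by a cubic
    spline over time, per axis.  Longer (or boundary) gaps in lumbar
    markers are reconstructed from the lateral donor pair when possible.
    A boundary gap with no donor route is an error; other unfillable gaps
    are reported, never silently filled.
    """
    out = trial.copy()
    report = GapReport()
    n = out.frame_count

    # pass 1: spline-fill short interior gaps everywhere
    for lb in out.markers:
        mask = out.missing_mask(lb)
        if not mask.any():
            continue
        valid = np.flatnonzero(~mask)
        if valid.size < 4:
            continue  # not enough support; handled in pass 2/3
        spline = CubicSpline(valid, out.markers[lb][valid], axis=0)
        for a, b in _missing_runs(mask):
            interior = a > 0 and b < n
            if interior and (b - a) <= max_gap:
                out.markers[lb][a:b] = spline(np.arange(a, b))
                report.entries.append(GapEntry(lb, a, b, "spline"))

    # pass 2: lateral reconstruction for lumbar markers still missing
    for lb in LATERAL_DONORS:
        if lb in out.markers and out.missing_mask(lb).any():
            before = out.missing_mask(lb)
            try:
                out = reconstruct_lumbar(out, lb, ml_definition=ml_definition)
            except GapFillError:
                continue
            after = out.missing_mask(lb)
            for a, b in _missing_runs(before & ~after):
                report.entries.append(GapEntry(lb, a, b, "reconstructed"))

    # pass 3: report what remains; boundary gaps are contract violations
    for lb in out.markers:
        mask = out.missing_mask(lb)
        for a, b in _missing_runs(mask):
            if a == 0 or b == n:
                raise GapFillError(
                    f"marker {lb}: gap at trial boundary (frames {a}..{b - 1}) "
                    "with no donor markers"
                )
            report.entries.append(GapEntry(lb, a, b, "unfilled"))
    return out, report


def reconstruct_lumbar(trial: TrialRecording, target: str,
                       ml_definition: str = "side_midpoints") -> TrialRecording:
    """Rebuild a lumbar marker from its lateral donor pair.

    The target is modelled as the donors' midpoint plus a constant offset
    vector expressed in the pelvis anatomical frame, learned by least
    squares (the mean) over the calibration window where target, donors
    and pelvis are simultaneously valid.  Exact whenever the target moves
    rigidly with the pelvis.
    """
    if target not in LATERAL_DONORS:
        raise ValueError(f"{target!r} is not a reconstructible lumbar marker")
    trial.require([target, *LATERAL_DONORS[target]])
    d1, d2 = LATERAL_DONORS[target]

    target_ok = ~trial.missing_mask(target)
    donors_ok = ~trial.missing_mask(d1) & ~trial.missing_mask(d2)
    pf = pelvis_frame(trial, ml_definition=ml_definition, allow_missing=True)
    pelvis_ok = np.isfinite(pf.origin).all(axis=1)

    calib = target_ok & donors_ok & pelvis_ok
    if not calib.any():
        raise GapFillError(
            f"marker {target}: no calibration window (target and donors never "
            "simultaneously valid)"
        )
    mid = 0.5 * (trial.markers[d1] + trial.markers[d2])
    axes = np.stack([pf.ml, pf.ap, pf.longitudinal], axis=1)  # rows = axes
    local = np.einsum("nij,nj->ni", axes, trial.markers[target] - mid)
    offset = local[calib].mean(axis=0)

    fill = ~target_ok & donors_ok & pelvis_ok
    out = trial.copy()
    if fill.any():
        world = np.einsum("nji,j->ni", axes[fill], offset) + mid[fill]
        out.markers[target][fill] = world
    return out


# ---------------------------------------------------------------------------
# pelvis frame and projection
# ---------------------------------------------------------------------------

@dataclass
class PelvisFrames:
    """Per-frame right-handed pelvis anatomical frame.

    ``ml`` points left, ``ap`` anterior, ``longitudinal`` cranial; the
    origin is the mean of the four PSIS/ASIS markers.  All arrays are
    (n_frames, 3).
    """

    origin: np.ndarray
    ml: np.ndarray
    ap: np.ndarray
    longitudinal: np.ndarray

    @property
    def frame_count(self) -> int:
        return self.origin.shape[0]


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    finite = np.isfinite(norm[:, 0])
    if np.any(norm[finite, 0] < 1e-9):
        raise DegeneratePelvisError(f"degenerate pelvis: zero-length {what} axis")
    return v / norm


def pelvis_frame(trial: TrialRecording, ml_definition: str = "side_midpoints",
                 allow_missing: bool = False) -> PelvisFrames:
    """Build the pelvis anatomical frame for every frame.

    The mediolateral axis follows the line through the midpoints of the
    right and left pelvis markers — by default the per-side PSIS/ASIS
    midpoints (``"side_midpoints"``), alternatively the iliac-crest TIP
    pair (``"tip"``).  The anteroposterior axis is the ASIS-midpoint minus
    PSIS-midpoint direction orthogonalized against ML, and the
    longitudinal axis completes the right-handed triad pointing cranially.
    """
    trial.require(["LPSIS", "RPSIS", "LASIS", "RASIS"])
    m = trial.markers
    if not allow_missing:
        for lb in ("LPSIS", "RPSIS", "LASIS", "RASIS") + (
                ("LTIP", "RTIP") if ml_definition == "tip" else ()):
            if trial.missing_mask(lb).any():
                raise TrialError(f"pelvis marker {lb} has missing samples")

    if ml_definition == "side_midpoints":
        right = 0.5 * (m["RPSIS"] + m["RASIS"])
        left = 0.5 * (m["LPSIS"] + m["LASIS"])
    elif ml_definition == "tip":
        trial.require(["LTIP", "RTIP"])
        right, left = m["RTIP"], m["LTIP"]
    else:
        raise ValueError(f"unknown ml_definition {ml_definition!r}")

    mid_psis = 0.5 * (m["LPSIS"] + m["RPSIS"])
    mid_asis = 0.5 * (m["LASIS"] + m["RASIS"])
    origin = 0.25 * (m["LPSIS"] + m["RPSIS"] + m["LASIS"] + m["RASIS"])

    ml = _unit(left - right, "mediolateral")
    ap_raw = mid_asis - mid_psis
    ap_raw = ap_raw - np.sum(ap_raw * ml, axis=1, keepdims=True) * ml
    ap = _unit(ap_raw, "anteroposterior")
    longitudinal = np.cross(ap, ml)  # anterior x left = cranial
    return PelvisFrames(origin=origin, ml=ml, ap=ap, longitudinal=longitudinal)


def project_series(trial: TrialRecording, frames: PelvisFrames, label: str
                   ) -> np.ndarray:
    """Sagittal coordinates (n_frames, 2) = (u longitudinal, v anterior)."""
    trial.require([label])
    rel = trial.markers[label] - frames.origin
    u = np.sum(rel * frames.longitudinal, axis=1)
    v = np.sum(rel * frames.ap, axis=1)
    return np.column_stack([u, v])


def project_capture(trial: TrialRecording, frames: PelvisFrames,
                    frame_index: int, labels: tuple[str, ...] | list[str]
                    ) -> dict[str, np.ndarray]:
    """Sagittal (u, v) of the requested markers at one frame.

    Raises on missing samples — the caller decides whether to drop the
    capture.
    """
    trial.require(labels)
    out: dict[str, np.ndarray] = {}
    for lb in labels:
        p = trial.markers[lb][frame_index]
        if not np.isfinite(p).all():
            raise TrialError(
                f"marker {lb} missing at frame {frame_index} "
                f"({trial.participant_id}/{trial.exercise_id})"
            )
        rel = p - frames.origin[frame_index]
        out[lb] = np.array([
            float(rel @ frames.longitudinal[frame_index]),
            float(rel @ frames.ap[frame_index]),
        ])
    return out
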