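"""Torso angle, movement-cycle segmentation and capture extraction.

The torso angle is the signed sagittal angle of the C7->S1 line against
the pelvis longitudinal axis (extension positive, flexion negative).  Its
local maxima mark maximum extension, its minima maximum flexion; a
flexion half-cycle runs max-extension -> max-flexion and an extension
half-cycle the reverse.  Dynamic trials keep four interior cycles (the
first performed cycle is dropped as familiarization) analyzed at
0/25/50/75/100 % of each half-cycle; stationary trials contribute four
capture instants evenly spaced inside the detected steady-state hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .markers import MODEL_REQUIRED_LABELS
from .preprocessing import PelvisFrames, project_capture, project_series
from .trial import TrialRecording, TrialError


class CycleDetectionError(ValueError):
    """The torso-angle series does not contain the required extrema."""


@dataclass
class TorsoAngleSeries:
    """Signed torso angle per frame, degrees; extension positive."""

    angle_deg: np.ndarray
    rate: float

    def __len__(self) -> int:
        return self.angle_deg.shape[0]


@dataclass
class CycleSpec:
    """One analyzed half-cycle with its phase-percentage frames."""

    direction: str  # "flexion" | "extension"
    start_frame: int
    end_frame: int
    phase_frames: dict[int, int]  # percentage -> frame index


@dataclass
class CaptureInstant:
    """One analyzed posture: projected spine markers at a selected frame."""

    participant_id: str
    exercise_id: str
    phase: str  # "static_1".."static_4" or e.g. "flexion_25"
    frame_index: int
    points: dict[str, np.ndarray]  # label -> (u, v) mm
    cycle_index: int | None = None


def torso_angle(trial: TrialRecording, frames: PelvisFrames) -> TorsoAngleSeries:
    """Signed angle of the projected C7-S1 line versus the pelvis
    longitudinal axis (flexion, i.e. anterior lean, negative)."""
    trial.require(["C7", "S1"])
    c7 = project_series(trial, frames, "C7")
    s1 = project_series(trial, frames, "S1")
    d = c7 - s1
    length = np.linalg.norm(d, axis=1)
    if np.any(length[np.isfinite(length)] < 1e-9):
        raise TrialError("zero-length C7-S1 vector")
    angle = -np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    return TorsoAngleSeries(angle_deg=angle, rate=trial.rate)


def _phase_frame(start: int, end: int, pct: int) -> int:
    """Nearest-frame rounding of a percentage position; ties round down."""
    x = start + (pct / 100.0) * (end - start)
    return int(np.ceil(x - 0.5))


def _alternating_extrema(x: np.ndarray, prominence_frac: float
                         ) -> list[tuple[int, str]]:
    """Interior extrema by prominence, endpoints promoted when they extend
    the alternating pattern; returns (frame, 'max'|'min') sorted by frame."""
    ptp = float(np.ptp(x))
    if ptp < 1e-9:
        raise CycleDetectionError("torso-angle series is constant")
    prom = prominence_frac * ptp
    maxima = find_peaks(x, prominence=prom)[0]
    minima = find_peaks(-x, prominence=prom)[0]
    ext = sorted([(int(i), "max") for i in maxima] + [(int(i), "min") for i in minima])
    if not ext:
        raise CycleDetectionError("no interior extrema found (monotone series?)")

    # de-duplicate consecutive same-type extrema, keeping the more extreme
    cleaned: list[tuple[int, str]] = []
    for frame, kind in ext:
        if cleaned and cleaned[-1][1] == kind:
            prev = cleaned[-1][0]
            better = frame if ((kind == "max") == (x[frame] > x[prev])) else prev
            cleaned[-1] = (better, kind)
        else:
            cleaned.append((frame, kind))

    first, last = cleaned[0], cleaned[-1]
    n = len(x)
    if first[1] == "min" and x[0] > x[first[0]]:
        cleaned.insert(0, (0, "max"))
    elif first[1] == "max" and x[0] < x[first[0]]:
        cleaned.insert(0, (0, "min"))
    if last[1] == "min" and x[n - 1] > x[last[0]]:
        cleaned.append((n - 1, "max"))
    elif last[1] == "max" and x[n - 1] < x[last[0]]:
        cleaned.append((n - 1, "min"))
    return cleaned


def _refine_extremum(x: np.ndarray, idx: int, half_window: int) -> int:
    """Re-locate an extremum as the vertex of a local quadratic fit.

    Averaging over the window suppresses in-band noise that shifts the
    raw argmax on flat extrema; for a noiseless symmetric waveform the
    vertex coincides with the true extremum.
    """
    n = len(x)
    hw = min(half_window, idx, n - 1 - idx)
    if hw < 2:
        return idx
    k = np.arange(-hw, hw + 1)
    c = np.polynomial.polynomial.polyfit(k, x[idx - hw: idx + hw + 1], 2)
    if abs(c[2]) < 1e-15:
        return idx
    vertex = -c[1] / (2.0 * c[2])
    vertex = float(np.clip(vertex, -hw, hw))
    return idx + int(np.ceil(vertex - 0.5))


def detect_cycles(series: TorsoAngleSeries, n_keep: int = 4,
                  percentages: tuple[int, ...] = (0, 25, 50, 75, 100),
                  prominence_frac: float = 0.25,
                  drop_first: bool = True) -> list[CycleSpec]:
    """Segment a dynamic trial into flexion and extension half-cycles.

    A full cycle runs between consecutive maximum-extension instants and
    contains one maximum-flexion instant.  ``n_keep`` cycles are retained
    after optionally dropping the first; each yields one flexion and one
    extension CycleSpec whose phase frames sample the stated percentages
    of the half-cycle's frame span.
    """
    x = series.angle_deg
    ext = _alternating_extrema(x, prominence_frac)
    # refine interior extrema on a quarter-second window
    hw = max(2, int(round(series.rate / 4.0)))
    ext = [(f if f in (0, len(x) - 1) else _refine_extremum(x, f, hw), kind)
           for f, kind in ext]
    cycles: list[tuple[int, int, int]] = []  # (max, min, next max)
    for k in range(len(ext) - 2):
        if (ext[k][1], ext[k + 1][1], ext[k + 2][1]) == ("max", "min", "max"):
            cycles.append((ext[k][0], ext[k + 1][0], ext[k + 2][0]))

    needed = n_keep + (1 if drop_first else 0)
    if len(cycles) < needed:
        raise CycleDetectionError(
            f"found {len(cycles)} full cycles, need {needed} "
            f"(n_keep={n_keep}, drop_first={drop_first})"
        )
    if drop_first:
        cycles = cycles[1:]
    cycles = cycles[:n_keep]

    specs: list[CycleSpec] = []
    for m0, mn, m1 in cycles:
        specs.append(CycleSpec(
            direction="flexion", start_frame=m0, end_frame=mn,
            phase_frames={p: _phase_frame(m0, mn, p) for p in percentages}))
        specs.append(CycleSpec(
            direction="extension", start_frame=mn, end_frame=m1,
            phase_frames={p: _phase_frame(mn, m1, p) for p in percentages}))
    return specs


def static_captures(series: TorsoAngleSeries, n: int = 4,
                    tolerance_deg: float = 2.0,
                    guard_s: float = 0.5) -> list[int]:
    """Frames of the analyzed postures of a stationary trial.

    The steady-state hold is the longest span where the torso angle stays
    within ``tolerance_deg`` of its median; ``n`` frames are evenly spaced
    inside it, so rise/fall transients are excluded.  A window edge that
    does not touch a trial boundary was entered from a transient, whose
    tail approaches the hold asymptotically and passes the tolerance test
    early — such edges are eroded by ``guard_s`` seconds.
    """
    x = series.angle_deg
    within = np.abs(x - np.median(x)) <= tolerance_deg
    best: tuple[int, int] | None = None
    idx = np.flatnonzero(np.diff(np.concatenate(([0], within.view(np.int8), [0]))))
    for a, b in zip(idx[::2], idx[1::2]):
        if best is None or (b - a) > (best[1] - best[0]):
            best = (int(a), int(b))
    if best is None or (best[1] - best[0]) < n:
        raise CycleDetectionError(
            f"no steady-state window of at least {n} frames found"
        )
    a, b = best
    guard = int(round(guard_s * series.rate))
    a2 = a + guard if a > 0 else a
    b2 = b - guard if b < len(x) else b
    if (b2 - a2) >= n:
        a, b = a2, b2
    return [a + int(round(k * (b - 1 - a) / (n - 1))) for k in range(n)]


def extract_captures(
    trial: TrialRecording,
    frames: PelvisFrames,
    cycles: list[CycleSpec] | None = None,
    static_indices: list[int] | None = None,
    labels: tuple[str, ...] = MODEL_REQUIRED_LABELS,
) -> tuple[list[CaptureInstant], list[dict]]:
    """Package cycle phases / static instants into CaptureInstants.

    A capture whose markers are incomplete after preprocessing is dropped
    with a logged reason, not silently imputed.  Returns
    ``(captures, dropped)``.
    """
    captures: list[CaptureInstant] = []
    dropped: list[dict] = []

    def grab(phase: str, frame: int, cycle_index: int | None) -> None:
        try:
            pts = project_capture(trial, frames, frame, labels)
        except TrialError as exc:
            dropped.append({"participant": trial.participant_id,
                            "exercise": trial.exercise_id,
                            "phase": phase, "frame": frame, "reason": str(exc)})
            return
        captures.append(CaptureInstant(
            participant_id=trial.participant_id, exercise_id=trial.exercise_id,
            phase=phase, frame_index=frame, points=pts, cycle_index=cycle_index))

    if static_indices is not None:
        for k, frame in enumerate(static_indices):
            grab(f"static_{k + 1}", int(frame), None)
    if cycles is not None:
        flex_i = ext_i = 0
        for spec in cycles:
            if spec.direction == "flexion":
                flex_i += 1
                ci = flex_i
            else:
                ext_i += 1
                ci = ext_i
            for pct, frame in spec.phase_frames.items():
                grab(f"{spec.direction}_{pct}", int(frame), ci)
    return captures, dropped
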