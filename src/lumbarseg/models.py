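"""The four lumbar marker-set models and circle-fit lordosis.

Model 1 treats the lumbar spine as a single segment (L1, L5, line);
Model 2 uses the Plug-in-Gait-adjacent markers (T10, S1, line); Model 3
splits the lumbar spine into two segments (L1, L3, L5, quadratic); and
Model 4 tracks every lumbar vertebra (L1..L5, quadratic).  Each model is
fitted in the sagittal plane with the longitudinal coordinate ``u`` as the
independent variable and evaluated at five equidistant points of a shared
``u`` range (the capture's L1..L5 span), so the curves of different models
are compared on the same abscissa.

Lumbar lordosis is the central angle, at the center of a circle fitted to
the five lumbar markers, between the radii through L1 and L5; the sign is
positive for flexion (curvature convex toward posterior) and negative for
extension (anatomical lordosis).  Relative lordosis subtracts the
participant's neutral-standing (STA) value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as P

from .events import CaptureInstant
from .markers import LUMBAR_LABELS


class NonMonotoneSpineError(ValueError):
    """Model markers are not strictly ordered along the longitudinal axis."""


class CircleFitError(ValueError):
    """Circle fit is not defined for the given points."""


@dataclass(frozen=True)
class SpineModelSpec:
    model_id: int
    marker_labels: tuple[str, ...]
    degree: int

    def __post_init__(self) -> None:
        if self.degree != (1 if len(self.marker_labels) == 2 else 2):
            raise ValueError(
                "two-marker models are lines, multi-marker models quadratics"
            )


MODEL_SPECS: dict[int, SpineModelSpec] = {
    1: SpineModelSpec(1, ("L1", "L5"), 1),
    2: SpineModelSpec(2, ("T10", "S1"), 1),
    3: SpineModelSpec(3, ("L1", "L3", "L5"), 2),
    4: SpineModelSpec(4, ("L1", "L2", "L3", "L4", "L5"), 2),
}


@dataclass
class SpineModelFit:
    """Polynomial v(u) of one model on one capture plus its evaluation."""

    model_id: int
    coefficients: np.ndarray  # ascending powers of u
    u_range: tuple[float, float]
    eval_u: np.ndarray  # (n_eval,) equidistant over u_range
    eval_v: np.ndarray


@dataclass
class LordosisResult:
    center_uv: tuple[float, float]
    radius_mm: float
    angle_deg: float
    straight: bool = False
    relative_deg: float | None = None


def fit_model(capture: CaptureInstant, spec: SpineModelSpec,
              u_range: tuple[float, float] | None = None,
              n_eval: int = 5) -> SpineModelFit:
    """Least-squares polynomial of the model's markers in the sagittal plane.

    With point count = degree + 1 the fit interpolates exactly.  The
    default evaluation range is the model's own marker span; the pipeline
    passes the capture's shared L1..L5 span instead so that all models are
    evaluated over the same abscissa.
    """
    missing = [lb for lb in spec.marker_labels if lb not in capture.points]
    if missing:
        raise ValueError(f"capture lacks markers {missing} for model {spec.model_id}")
    u = np.array([capture.points[lb][0] for lb in spec.marker_labels])
    v = np.array([capture.points[lb][1] for lb in spec.marker_labels])
    du = np.diff(u)
    if np.any(du == 0):
        raise NonMonotoneSpineError(
            f"model {spec.model_id}: duplicate longitudinal coordinates"
        )
    if not (np.all(du > 0) or np.all(du < 0)):
        raise NonMonotoneSpineError(
            f"model {spec.model_id}: markers not monotone along the "
            f"longitudinal axis (u = {np.round(u, 2).tolist()})"
        )
    coeffs = P.polyfit(u, v, spec.degree)
    if u_range is None:
        u_range = (float(u[0]), float(u[-1]))
    eval_u = np.linspace(u_range[0], u_range[1], n_eval)
    return SpineModelFit(
        model_id=spec.model_id,
        coefficients=coeffs,
        u_range=(float(u_range[0]), float(u_range[1])),
        eval_u=eval_u,
        eval_v=P.polyval(eval_u, coeffs),
    )


def is_collinear(points: np.ndarray, tol_mm: float = 1e-6) -> bool:
    """True when the points deviate from their best-fit line by < tol.

    The deviation is the maximum perpendicular residual from the principal
    (PCA) line — the sagitta of the point set — so the test does not
    require a monotone abscissa.
    """
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-12:
        return True  # all points coincide
    residual = np.abs(centered @ vt[1])
    return bool(residual.max() < tol_mm)


def fit_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Taubin algebraic circle fit; exact circumcircle for three points.

    Parameters
    ----------
    points : ndarray, shape (n, 2)
        Sagittal (u, v) coordinates, n >= 3 and not collinear.

    Returns
    -------
    center : ndarray (2,), radius : float
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise CircleFitError(f"need >= 3 planar points, got shape {pts.shape}")
    if is_collinear(pts, tol_mm=1e-12):
        raise CircleFitError("points are collinear; no finite circle exists")
    mean = pts.mean(axis=0)
    x, y = (pts - mean).T
    z = x * x + y * y
    zm = z.mean()
    z0 = (z - zm) / (2.0 * math.sqrt(zm))
    _, _, vt = np.linalg.svd(np.column_stack([z0, x, y]), full_matrices=False)
    a0, b, c = vt[2]
    a = a0 / (2.0 * math.sqrt(zm))
    d = -zm * a
    if abs(a) < 1e-15:
        raise CircleFitError("points are nearly collinear; radius diverges")
    center = np.array([-b, -c]) / (2.0 * a) + mean
    radius = math.sqrt(b * b + c * c - 4.0 * a * d) / (2.0 * abs(a))
    return center, radius


def lordosis_angle(capture: CaptureInstant,
                   sta_reference_deg: float | None = None,
                   collinearity_tol_mm: float = 1e-6) -> LordosisResult:
    """Circle-fit lumbar lordosis of one capture.

    Always computed from the five lumbar markers regardless of the model
    under comparison (the lordosis is a property of the capture, reported
    once).  Collinear-within-tolerance marker sets take the straight-spine
    path: angle 0 by continuity, distinct from a fit failure.
    """
    missing = [lb for lb in LUMBAR_LABELS if lb not in capture.points]
    if missing:
        raise ValueError(f"capture lacks lumbar markers {missing}")
    pts = np.array([capture.points[lb] for lb in LUMBAR_LABELS])

    if is_collinear(pts, tol_mm=collinearity_tol_mm):
        result = LordosisResult(center_uv=(math.nan, math.nan),
                                radius_mm=math.inf, angle_deg=0.0, straight=True)
    else:
        center, radius = fit_circle(pts)
        r1 = pts[0] - center   # L1
        r5 = pts[-1] - center  # L5
        # signed central angle of the L5 -> L1 sweep; positive = flexion
        cross = r5[0] * r1[1] - r5[1] * r1[0]
        dot = float(r5 @ r1)
        angle = math.degrees(math.atan2(cross, dot))
        result = LordosisResult(center_uv=(float(center[0]), float(center[1])),
                                radius_mm=float(radius), angle_deg=angle)
    if sta_reference_deg is not None:
        result.relative_deg = result.angle_deg - sta_reference_deg
    return result
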