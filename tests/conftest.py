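import numpy as np
import pytest

import lumbarseg as ls
from lumbarseg.synthetic import DEFAULT_RATE_HZ


@pytest.fixture(scope="session")
def geometry():
    return ls.ParticipantGeometry.from_height(1700.0)


@pytest.fixture(scope="session")
def protocols():
    return ls.default_protocols()


def make_trial(exercise="FE", noise_sd=0.0, gap_rate=0.0, seed=0,
               scale=1.0, height=1700.0, participant="P01"):
    """One synthetic trial with explicit noise settings."""
    geometry = ls.ParticipantGeometry.from_height(height)
    protocol = ls.default_protocols()[exercise]
    noise = None
    if noise_sd > 0 or gap_rate > 0:
        noise = ls.NoiseModel(soft_tissue_sd_mm=noise_sd,
                              gap_rate_per_s=gap_rate, seed=seed)
    return ls.generate_trial(protocol, geometry, noise,
                             participant_id=participant,
                             amplitude_scale=scale)


@pytest.fixture(scope="session")
def fe_trial_clean():
    return make_trial("FE", noise_sd=0.0)


@pytest.fixture(scope="session")
def sta_trial_clean():
    return make_trial("STA", noise_sd=0.0)


def rotation_about(axis, angle_deg):
    """Rodrigues rotation matrix (independent of any package geometry)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def triangle_area(pts):
    """Unsigned area of a planar triangle given as a (3, 2) array."""
    (ax, ay), (bx, by), (cx, cy) = pts
    return abs((bx - ax) * (cy - ay) - (by - ay) * (cx - ax)) / 2.0


def circumcircle(p1, p2, p3):
    """Closed-form circumcenter/radius of three planar points (oracle)."""
    (ax, ay), (bx, by), (cx, cy) = p1, p2, p3
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        raise ValueError("collinear points")
    ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
          + (cx * cx + cy * cy) * (ay - by)) / d
    uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
          + (cx * cx + cy * cy) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(center - np.array(p1)))


RATE = DEFAULT_RATE_HZ
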