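"""In-memory container for a labelled marker-trajectory recording."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np


class TrialError(ValueError):
    """Invalid trial structure or content."""


@dataclass
class TrialRecording:
    """Labelled 3D marker trajectories of one trial.

    Parameters
    ----------
    participant_id : str
        Subject identifier (e.g. ``"P01"``).
    exercise_id : str
        Exercise tag (``STA``, ``FE``, ``F``, ``COB``, ``SHO``, ``CUP``).
    rate : float
        Sampling rate in Hz.
    markers : dict of str -> ndarray, shape (n_frames, 3)
        Trajectories in mm.  Missing samples are rows of NaN; a partially
        missing coordinate triple counts as a missing sample.
    meta : dict
        Free-form metadata.  The synthetic generator stores its per-frame
        ground truth under ``meta["ground_truth"]``.
    """

    participant_id: str
    exercise_id: str
    rate: float
    markers: dict[str, np.ndarray]
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def frame_count(self) -> int:
        if not self.markers:
            return 0
        return next(iter(self.markers.values())).shape[0]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.markers)

    def validate(self) -> "TrialRecording":
        if self.rate <= 0:
            raise TrialError(f"sampling rate must be positive, got {self.rate}")
        if not self.markers:
            raise TrialError("trial has no markers")
        n = self.frame_count
        for label, arr in self.markers.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise TrialError(f"marker {label!r}: expected (n, 3) array, got {arr.shape}")
            if arr.shape[0] != n:
                raise TrialError(
                    f"marker {label!r}: {arr.shape[0]} frames, expected {n}"
                )
            finite = np.isfinite(arr)
            # a sample is either fully present or fully missing
            partial = finite.any(axis=1) & ~finite.all(axis=1)
            if partial.any():
                raise TrialError(
                    f"marker {label!r}: partially missing coordinates at frames "
                    f"{np.flatnonzero(partial)[:5].tolist()}"
                )
        return self

    def missing_mask(self, label: str) -> np.ndarray:
        """Boolean mask (n_frames,), True where the sample is missing."""
        return ~np.isfinite(self.markers[label]).all(axis=1)

    def has_missing(self) -> bool:
        return any(self.missing_mask(lb).any() for lb in self.markers)

    def require(self, labels: Iterable[str]) -> None:
        missing = [lb for lb in labels if lb not in self.markers]
        if missing:
            raise TrialError(
                f"trial {self.participant_id}/{self.exercise_id} lacks markers: {missing}"
            )

    def copy(self) -> "TrialRecording":
        return TrialRecording(
            participant_id=self.participant_id,
            exercise_id=self.exercise_id,
            rate=self.rate,
            markers={lb: arr.copy() for lb, arr in self.markers.items()},
            meta=dict(self.meta),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TrialRecording":
        """Apply a global rigid transform ``p -> R p + t`` to every marker.

        ``rotation`` may be a single (3, 3) matrix or a per-frame stack
        (n_frames, 3, 3); ``translation`` a (3,) vector or (n_frames, 3).
        """
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = self.copy()
        for label, arr in out.markers.items():
            if rotation.ndim == 2:
                moved = arr @ rotation.T
            else:
                moved = np.einsum("nij,nj->ni", rotation, arr)
            out.markers[label] = moved + translation
        return out
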