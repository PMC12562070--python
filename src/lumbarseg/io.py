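"""Read and write labelled marker-trajectory files.

The canonical format is a CSV in the Vicon-Nexus export layout:

.. code-block:: text

    Trajectories,exercise=FE,participant=P01
    120.0
    ,,P01:C7,,,P01:T10,,, ...
    Frame,Sub Frame,X,Y,Z,X,Y,Z, ...
    ,,mm,mm,mm, ...
    1,0,12.3,4.5,6.7, ...

Two leading columns (frame number, sub-frame), then one X/Y/Z triplet per
marker with the (optionally subject-prefixed) marker name above the X
column.  Missing samples are empty cells.  A units row of ``m`` triggers
conversion to the canonical internal unit, mm.  C3D is supported through
the optional ``ezc3d`` dependency.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Any

import numpy as np

from .markers import ALL_LABELS, normalize_label
from .trial import TrialRecording, TrialError


class ParseError(ValueError):
    """Malformed trajectory file; the message names the offending line."""


_FLOAT_FMT = repr  # shortest round-trip representation


def write_trial_csv(trial: TrialRecording, path: str | Path) -> None:
    """Write a trial in the CSV dialect above (inverse of read_trial_csv)."""
    trial.validate()
    labels = list(trial.markers)
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["Trajectories",
                    f"exercise={trial.exercise_id}",
                    f"participant={trial.participant_id}"])
        w.writerow([_FLOAT_FMT(float(trial.rate))])
        name_row: list[str] = ["", ""]
        for lb in labels:
            name_row += [f"{trial.participant_id}:{lb}", "", ""]
        w.writerow(name_row)
        w.writerow(["Frame", "Sub Frame"] + ["X", "Y", "Z"] * len(labels))
        w.writerow(["", ""] + ["mm", "mm", "mm"] * len(labels))
        data = np.concatenate([trial.markers[lb] for lb in labels], axis=1)
        for i in range(trial.frame_count):
            row: list[str] = [str(i + 1), "0"]
            row += ["" if not np.isfinite(v) else _FLOAT_FMT(float(v))
                    for v in data[i]]
            w.writerow(row)


def read_trial_csv(
    path: str | Path,
    label_map: dict[str, str] | None = None,
    allow_unknown_labels: bool = False,
) -> TrialRecording:
    """Parse a trajectory CSV into a TrialRecording.

    Labels are normalized through the built-in alias table plus
    ``label_map``; unknown (non-vocabulary) labels raise unless
    ``allow_unknown_labels`` is set.  Empty cells become missing samples.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 6:
        raise ParseError(f"{path}: expected >= 6 lines, found {len(rows)}")

    meta: dict[str, Any] = {}
    for cell in rows[0][1:]:
        if "=" in cell:
            k, v = cell.split("=", 1)
            meta[k.strip()] = v.strip()

    try:
        rate = float(rows[1][0])
    except (IndexError, ValueError):
        raise ParseError(f"{path}, line 2: missing or non-numeric sampling rate")
    if rate <= 0:
        raise ParseError(f"{path}, line 2: sampling rate must be positive, got {rate}")

    name_row = rows[2]
    labels: list[str] = []
    participant = meta.get("participant", "")
    for col in range(2, len(name_row), 3):
        raw = name_row[col]
        if not raw.strip():
            raise ParseError(f"{path}, line 3: empty marker name at column {col + 1}")
        if ":" in raw and not participant:
            participant = raw.split(":", 1)[0].strip()
        lb = normalize_label(raw, label_map)
        if lb in labels:
            raise ParseError(f"{path}, line 3: duplicate marker label {lb!r}")
        if lb not in ALL_LABELS and not allow_unknown_labels:
            raise ParseError(f"{path}, line 3: unknown marker label {raw!r} -> {lb!r}")
        labels.append(lb)
    if not labels:
        raise ParseError(f"{path}, line 3: no marker columns found")
    n_cols = 2 + 3 * len(labels)
    if len(name_row) != n_cols:
        raise ParseError(
            f"{path}, line 3: {len(name_row)} columns, expected {n_cols} "
            f"for {len(labels)} markers"
        )

    units_row = rows[4]
    scale: list[float] = []
    for col in range(2, n_cols):
        unit = (units_row[col] if col < len(units_row) else "mm").strip().lower() or "mm"
        if unit == "mm":
            scale.append(1.0)
        elif unit == "m":
            scale.append(1000.0)
        else:
            raise ParseError(f"{path}, line 5: unsupported unit {unit!r}")

    data_rows = rows[5:]
    n = len(data_rows)
    data = np.full((n, 3 * len(labels)), np.nan)
    for i, row in enumerate(data_rows):
        lineno = i + 6
        if len(row) != n_cols:
            raise ParseError(
                f"{path}, line {lineno}: {len(row)} columns, expected {n_cols}"
            )
        for j, cell in enumerate(row[2:]):
            cell = cell.strip()
            if cell:
                try:
                    data[i, j] = float(cell) * scale[j]
                except ValueError:
                    raise ParseError(
                        f"{path}, line {lineno}: non-numeric cell {cell!r}"
                    )

    markers: dict[str, np.ndarray] = {}
    for k, lb in enumerate(labels):
        block = data[:, 3 * k: 3 * k + 3]
        # a triple with any missing coordinate is a missing sample
        block[~np.isfinite(block).all(axis=1)] = np.nan
        markers[lb] = block

    return TrialRecording(
        participant_id=participant or "unknown",
        exercise_id=meta.get("exercise", "unknown"),
        rate=rate,
        markers=markers,
        meta={k: v for k, v in meta.items() if k not in ("exercise", "participant")},
    ).validate()


# ---------------------------------------------------------------------------
# ground-truth sidecar (synthetic trials)
# ---------------------------------------------------------------------------

def write_ground_truth_csv(trial: TrialRecording, path: str | Path) -> None:
    """One row per frame of the generator's commanded pose parameters."""
    gt = trial.meta.get("ground_truth")
    if gt is None:
        raise TrialError("trial carries no ground truth")
    import pandas as pd

    pd.DataFrame({k: np.asarray(v) for k, v in gt.items()}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# C3D (optional dependency)
# ---------------------------------------------------------------------------

def _require_ezc3d():
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "C3D support requires the optional dependency 'ezc3d' "
            "(pip install lumbarseg[c3d]); CSV remains fully supported"
        ) from exc
    return ezc3d


def read_trial_c3d(path: str | Path, label_map: dict[str, str] | None = None
                   ) -> TrialRecording:
    """Read a C3D file; residual-flagged invalid points become missing."""
    ezc3d = _require_ezc3d()
    c3d = ezc3d.c3d(str(path))
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    if pts.shape[1] == 0:
        raise ParseError(f"{path}: C3D file contains no points")
    raw_labels = [str(lb) for lb in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    unlabeled = [i for i, lb in enumerate(raw_labels) if not lb.strip()]
    if unlabeled:
        raise ParseError(f"{path}: unlabeled points at indices {unlabeled}")
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    residuals = c3d["data"]["meta_points"]["residuals"][0]  # (n_markers, n_frames)
    markers: dict[str, np.ndarray] = {}
    for i, raw in enumerate(raw_labels):
        lb = normalize_label(raw, label_map)
        xyz = np.asarray(pts[:3, i, :].T, dtype=float)
        xyz[residuals[i] < 0] = np.nan
        markers[lb] = xyz
    return TrialRecording("unknown", "unknown", rate, markers).validate()


def write_trial_c3d(trial: TrialRecording, path: str | Path) -> None:
    ezc3d = _require_ezc3d()
    trial.validate()
    c3d = ezc3d.c3d()
    labels = list(trial.markers)
    c3d["parameters"]["POINT"]["RATE"]["value"] = [float(trial.rate)]
    c3d["parameters"]["POINT"]["LABELS"]["value"] = labels
    n = trial.frame_count
    pts = np.ones((4, len(labels), n))
    for i, lb in enumerate(labels):
        pts[:3, i, :] = trial.markers[lb].T
    c3d["data"]["points"] = pts
    c3d.write(str(path))
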