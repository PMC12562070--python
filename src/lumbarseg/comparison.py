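"""Model agreement statistics and the end-to-end pipeline driver.

For every capture the four model curves are evaluated at five shared
points and each model pair is scored with a sample Pearson correlation;
per exercise (and, for dynamic trials, per direction-and-percentage
phase) the per-capture coefficients are aggregated to mean +/- SD, next
to the relative-lordosis summary — the layout of the study's results
table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .events import (CaptureInstant, detect_cycles, extract_captures,
                     static_captures, torso_angle)
from .markers import DYNAMIC_EXERCISES, EXERCISES, STATIC_EXERCISES
from .models import (MODEL_SPECS, NonMonotoneSpineError, fit_model,
                     lordosis_angle)
from .preprocessing import fill_gaps, lowpass_filter, pelvis_frame
from .trial import TrialRecording

MODEL_PAIRS: tuple[tuple[int, int], ...] = tuple(combinations((1, 2, 3, 4), 2))


class UndefinedCorrelationError(ValueError):
    """Pearson r undefined (zero variance in an ordinate set)."""


@dataclass
class PairCorrelation:
    participant_id: str
    exercise_id: str
    phase: str
    pair: tuple[int, int]
    r: float
    cycle_index: int | None = None


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the printed table)."""
    if not math.isfinite(x):
        return x
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def pearson_pair(fit_i, fit_j, capture: CaptureInstant) -> PairCorrelation:
    """Sample Pearson r of the two models' evaluated ordinates.

    Requires identical evaluation abscissae (guaranteed by the shared
    evaluation range).  Zero variance in either ordinate set makes r
    undefined and raises, so the caller can exclude and log the capture
    instead of silently storing 0 or 1.
    """
    if fit_i.model_id > fit_j.model_id:
        fit_i, fit_j = fit_j, fit_i
    if not np.allclose(fit_i.eval_u, fit_j.eval_u):
        raise ValueError("fits were evaluated on different abscissae")
    vi, vj = fit_i.eval_v, fit_j.eval_v
    si, sj = vi.std(), vj.std()
    if si < 1e-12 or sj < 1e-12:
        raise UndefinedCorrelationError(
            f"zero variance in model {fit_i.model_id if si < 1e-12 else fit_j.model_id} "
            f"ordinates at {capture.participant_id}/{capture.exercise_id}/{capture.phase}"
        )
    r = float(np.corrcoef(vi, vj)[0, 1])
    return PairCorrelation(
        participant_id=capture.participant_id, exercise_id=capture.exercise_id,
        phase=capture.phase, pair=(fit_i.model_id, fit_j.model_id), r=r,
        cycle_index=capture.cycle_index)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _cell_phase(exercise: str, phase: str) -> str:
    """Aggregation key: statics pool their four capture instants."""
    return "static" if phase.startswith("static") else phase


@dataclass
class ComparisonReport:
    """Per exercise x phase x model-pair mean/SD Pearson matrix plus the
    relative-lordosis summary."""

    correlation_summary: pd.DataFrame  # exercise, phase, pair, mean_r, sd_r, n
    lordosis_summary: pd.DataFrame     # exercise, phase, mean_deg, sd_deg, n
    missing_cells: list[tuple[str, str, str]] = field(default_factory=list)

    def cell(self, exercise: str, phase: str, pair: tuple[int, int]
             ) -> tuple[float, float, int]:
        df = self.correlation_summary
        row = df[(df.exercise == exercise) & (df.phase == phase)
                 & (df.pair == f"{pair[0]}v{pair[1]}")]
        if row.empty:
            raise KeyError((exercise, phase, pair))
        row = row.iloc[0]
        return float(row.mean_r), float(row.sd_r), int(row.n)

    def to_text(self, percentages: tuple[int, ...] = (0, 25, 50, 75, 100)) -> str:
        """Formatted table mirroring the study's layout (2 decimals,
        half-away-from-zero)."""
        pair_names = [f"{i}v{j}" for i, j in MODEL_PAIRS]
        header = (f"{'Exercise / phase':<22}"
                  + "".join(f"{p:>14}" for p in pair_names)
                  + f"{'Rel. lordosis (deg)':>22}")
        lines = [header, "-" * len(header)]

        def fmt_cell(mean: float, sd: float, dec: int = 2) -> str:
            if not math.isfinite(mean):
                return "--"
            sd_txt = "nan" if not math.isfinite(sd) else f"{round_half_away(sd, dec):.{dec}f}"
            return f"{round_half_away(mean, dec):.{dec}f} ± {sd_txt}"

        def add_row(title: str, exercise: str, phase: str) -> None:
            cells = []
            for pair in MODEL_PAIRS:
                try:
                    mean, sd, _ = self.cell(exercise, phase, pair)
                    cells.append(fmt_cell(mean, sd))
                except KeyError:
                    cells.append("--")
            ldf = self.lordosis_summary
            row = ldf[(ldf.exercise == exercise) & (ldf.phase == phase)]
            lord = (fmt_cell(float(row.iloc[0].mean_deg), float(row.iloc[0].sd_deg))
                    if not row.empty else "--")
            lines.append(f"{title:<22}" + "".join(f"{c:>14}" for c in cells)
                         + f"{lord:>22}")

        for ex in EXERCISES:
            if ex in STATIC_EXERCISES:
                add_row(ex, ex, "static")
            else:
                for direction in ("flexion", "extension"):
                    lines.append(f"{ex} in {direction}")
                    for p in percentages:
                        add_row(f"  {p}%", ex, f"{direction}_{p}")
        return "\n".join(lines) + "\n"


def aggregate(correlations: pd.DataFrame, lordosis: pd.DataFrame
              ) -> ComparisonReport:
    """Mean +/- sample SD (ddof=1) per cell over the retained captures.

    ``correlations`` needs columns exercise, phase, pair, r; ``lordosis``
    exercise, phase, relative_deg.  Cells with no captures are reported as
    missing, never NaN-propagated into neighbouring cells.
    """
    corr = correlations.copy()
    corr["phase"] = [_cell_phase(e, p) for e, p in zip(corr.exercise, corr.phase)]
    summary = (corr.groupby(["exercise", "phase", "pair"], as_index=False)
               .agg(mean_r=("r", "mean"), sd_r=("r", lambda s: s.std(ddof=1)),
                    n=("r", "size")))

    lord = lordosis.copy()
    lord["phase"] = [_cell_phase(e, p) for e, p in zip(lord.exercise, lord.phase)]
    lord = lord.dropna(subset=["relative_deg"])
    lord_summary = (lord.groupby(["exercise", "phase"], as_index=False)
                    .agg(mean_deg=("relative_deg", "mean"),
                         sd_deg=("relative_deg", lambda s: s.std(ddof=1)),
                         n=("relative_deg", "size")))

    missing: list[tuple[str, str, str]] = []
    seen = {(e, p, q) for e, p, q in
            zip(summary.exercise, summary.phase, summary.pair)}
    phases_by_ex: dict[str, list[str]] = {}
    for ex in EXERCISES:
        if ex in STATIC_EXERCISES:
            phases_by_ex[ex] = ["static"]
        else:
            phases_by_ex[ex] = [f"{d}_{p}" for d in ("flexion", "extension")
                                for p in (0, 25, 50, 75, 100)]
    present_ex = set(corr.exercise)
    for ex, phases in phases_by_ex.items():
        if ex not in present_ex:
            continue
        for ph in phases:
            for i, j in MODEL_PAIRS:
                if (ex, ph, f"{i}v{j}") not in seen:
                    missing.append((ex, ph, f"{i}v{j}"))
    return ComparisonReport(correlation_summary=summary,
                            lordosis_summary=lord_summary,
                            missing_cells=missing)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    report: ComparisonReport
    captures: pd.DataFrame       # one row per capture (lordosis bookkeeping)
    fits: pd.DataFrame           # one row per capture x model
    correlations: pd.DataFrame   # one row per capture x model pair
    events: dict[str, dict]      # per trial: cycle spans / capture frames / gaps
    log: list[dict] = field(default_factory=list)


def _analyze_trial(trial: TrialRecording, config: PipelineConfig
                   ) -> tuple[list[CaptureInstant], list[dict], dict]:
    filled, gap_report = fill_gaps(trial, max_gap=config.max_gap_frames,
                                   ml_definition=config.ml_definition)
    filtered = lowpass_filter(filled, cutoff_hz=config.filter_cutoff_hz,
                              order=config.filter_order)
    pframes = pelvis_frame(filtered, ml_definition=config.ml_definition)
    series = torso_angle(filtered, pframes)

    event_record: dict = {"gaps": gap_report.as_dict()}
    if trial.exercise_id in DYNAMIC_EXERCISES:
        cycles = detect_cycles(series, n_keep=config.n_cycles_extracted,
                               percentages=config.phase_percentages,
                               prominence_frac=config.prominence_frac,
                               drop_first=config.drop_first_cycle)
        captures, dropped = extract_captures(filtered, pframes, cycles=cycles)
        event_record["cycles"] = [
            {"direction": c.direction, "start": c.start_frame,
             "end": c.end_frame, "phase_frames": c.phase_frames} for c in cycles]
    else:
        statics = static_captures(series, n=config.n_static_captures,
                                  tolerance_deg=config.static_tolerance_deg)
        captures, dropped = extract_captures(filtered, pframes,
                                             static_indices=statics)
        event_record["static_frames"] = statics
    event_record["capture_frames"] = [c.frame_index for c in captures]
    return captures, dropped, event_record


def run_pipeline(trials: list[TrialRecording],
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis over a set of trials.

    Stage failures are attributed to (participant, exercise, stage) in the
    log and the pipeline continues over the remaining trials.  Output is
    deterministic for a given input set and configuration.
    """
    if config is None:
        config = PipelineConfig()
    log: list[dict] = []
    events: dict[str, dict] = {}
    all_captures: list[CaptureInstant] = []

    for trial in trials:
        key = f"{trial.participant_id}/{trial.exercise_id}"
        try:
            captures, dropped, record = _analyze_trial(trial, config)
        except Exception as exc:  # noqa: BLE001 - attributed and surfaced
            log.append({"participant": trial.participant_id,
                        "exercise": trial.exercise_id,
                        "stage": "events", "message": str(exc)})
            continue
        for d in dropped:
            log.append({**d, "stage": "capture"})
        events[key] = record
        all_captures.extend(captures)

    capture_rows: list[dict] = []
    fit_rows: list[dict] = []
    corr_rows: list[dict] = []
    lordosis_by_capture: list[float] = []

    for ci, cap in enumerate(all_captures):
        u_range = (float(cap.points["L1"][0]), float(cap.points["L5"][0]))
        fits = {}
        try:
            for mid, spec in MODEL_SPECS.items():
                fits[mid] = fit_model(
                    cap, spec,
                    u_range=u_range if config.shared_eval_range else None,
                    n_eval=config.n_eval_points)
            lres = lordosis_angle(cap, collinearity_tol_mm=config.collinearity_tol_mm)
        except (NonMonotoneSpineError, ValueError) as exc:
            log.append({"participant": cap.participant_id,
                        "exercise": cap.exercise_id, "phase": cap.phase,
                        "stage": "fit", "message": str(exc)})
            continue

        capture_rows.append({
            "capture": ci, "participant": cap.participant_id,
            "exercise": cap.exercise_id, "phase": cap.phase,
            "cycle": cap.cycle_index, "frame": cap.frame_index,
            "lordosis_deg": lres.angle_deg, "straight": lres.straight,
        })
        for mid, fit in fits.items():
            row = {"capture": ci, "participant": cap.participant_id,
                   "exercise": cap.exercise_id, "phase": cap.phase,
                   "model": mid, "u_lo": fit.u_range[0], "u_hi": fit.u_range[1]}
            for k, c in enumerate(fit.coefficients):
                row[f"c{k}"] = float(c)
            for k, v in enumerate(fit.eval_v):
                row[f"v{k}"] = float(v)
            fit_rows.append(row)
        for i, j in MODEL_PAIRS:
            try:
                pc = pearson_pair(fits[i], fits[j], cap)
            except UndefinedCorrelationError as exc:
                log.append({"participant": cap.participant_id,
                            "exercise": cap.exercise_id, "phase": cap.phase,
                            "stage": "correlation", "message": str(exc)})
                continue
            corr_rows.append({"capture": ci, "participant": pc.participant_id,
                              "exercise": pc.exercise_id, "phase": pc.phase,
                              "cycle": pc.cycle_index,
                              "pair": f"{i}v{j}", "r": pc.r})

    captures_df = pd.DataFrame(capture_rows)
    # relative lordosis against each participant's mean STA angle
    if not captures_df.empty:
        sta = (captures_df[captures_df.exercise == "STA"]
               .groupby("participant").lordosis_deg.mean())
        ref = captures_df.participant.map(sta)
        captures_df["relative_deg"] = captures_df.lordosis_deg - ref
        for pid in sorted(set(captures_df.participant) - set(sta.index)):
            log.append({"participant": pid, "stage": "reference",
                        "message": "no STA captures; relative lordosis undefined"})
    else:
        captures_df["relative_deg"] = pd.Series(dtype=float)

    corr_df = pd.DataFrame(corr_rows)
    report = aggregate(
        corr_df if not corr_df.empty else
        pd.DataFrame(columns=["exercise", "phase", "pair", "r"]),
        captures_df[["exercise", "phase", "relative_deg"]] if not captures_df.empty
        else pd.DataFrame(columns=["exercise", "phase", "relative_deg"]),
    )
    result = PipelineResult(report=report, captures=captures_df,
                            fits=pd.DataFrame(fit_rows),
                            correlations=corr_df, events=events, log=log)
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir))
    return result


def run_synthetic(n_participants: int = 17, seed: int = 0,
                  noise_sd_mm: float = 2.0, gap_rate_per_s: float = 0.02,
                  config: PipelineConfig | None = None,
                  out_dir: str | Path | None = None) -> PipelineResult:
    """Generate a synthetic cohort and run the full pipeline on it."""
    from .synthetic import generate_cohort

    trials = generate_cohort(n_participants=n_participants, seed=seed,
                             noise_sd_mm=noise_sd_mm,
                             gap_rate_per_s=gap_rate_per_s)
    return run_pipeline(trials, config=config, out_dir=out_dir)


def _write_outputs(result: PipelineResult, config: PipelineConfig,
                   out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    merged = result.report.correlation_summary
    merged.to_csv(out_dir / "report.csv", index=False)
    result.report.lordosis_summary.to_csv(out_dir / "lordosis.csv", index=False)
    (out_dir / "report.txt").write_text(result.report.to_text(config.phase_percentages))
    result.captures.to_csv(out_dir / "captures.csv", index=False)
    result.fits.to_csv(out_dir / "fits.csv", index=False)
    result.correlations.to_csv(out_dir / "correlations.csv", index=False)
    ev = out_dir / "events"
    ev.mkdir(exist_ok=True)
    for key, record in result.events.items():
        (ev / (key.replace("/", "_") + ".json")).write_text(
            json.dumps(record, indent=1, default=int))
    (out_dir / "run.log").write_text(
        "\n".join(json.dumps(entry, default=str) for entry in result.log) + "\n")
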