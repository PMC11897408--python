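"""The two headline pipelines.

* :func:`run_invitro_pipeline` — border-smoothness scoring of fixed
  chromatin substrates across conditions: segment, score each object,
  summarize hierarchically per condition, and (for two conditions) run the
  normality-gated two-sample test on the unit-level scores.
* :func:`run_livecell_pipeline` — mitotic-exit analysis of single-cell
  time-lapses: segment every frame, link objects, detect anaphase onset,
  build anaphase-aligned normalized area curves, classify phases, read off
  dwell times, and aggregate curves per condition. Trajectories without a
  qualifying mitosis are discarded and every discard is logged with its
  reason.

Outputs are CSV tables (column names carry units: px2, um2, min) and a
JSON report stamped with the package version and a hash of the full
configuration, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .frames import ImageFrame, TimeLapse
from .io import PipelineConfig, config_hash
from .segmentation import extract_objects, segment_livecell
from .smoothness import score_image
from .stats import TestResult, choose_test, summarize_hierarchical
from .timecourse import (
    AmbiguousSceneError,
    AreaCurve,
    NoMitosisError,
    aggregate_curves,
    classify_phases,
    detect_anaphase_onset,
    dwell_times,
    link_objects,
    normalize_area_curve,
)

logger = logging.getLogger("decondenseq")

__all__ = ["InvitroResult", "LivecellResult", "run_invitro_pipeline",
           "run_livecell_pipeline"]


@dataclass
class InvitroResult:
    scores: pd.DataFrame  # condition, experiment, image, object_id, smoothness, ...
    summaries: dict
    test: TestResult | None
    report: dict


@dataclass
class LivecellResult:
    curves: pd.DataFrame  # condition, cell_id, time_min, normalized_area
    phases: pd.DataFrame  # condition, cell_id, frame, phase
    dwell: pd.DataFrame  # condition, cell_id, phase, dwell_min
    aggregated: pd.DataFrame  # condition, time_min, mean, sem, n
    discarded: list[tuple[str, str]] = field(default_factory=list)
    report: dict = field(default_factory=dict)


def _write_report(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))


def run_invitro_pipeline(
    config: PipelineConfig,
    inputs: dict[str, list[tuple[str, str, "ImageFrame | np.ndarray"]]],
    output_dir: "str | Path | None" = None,
) -> InvitroResult:
    """Score border smoothness across conditions.

    ``inputs`` maps condition -> list of (experiment_id, image_id, frame).
    With exactly two conditions the gate-selected two-tailed test is run
    on the pooled per-object scores; with one condition a summary is
    produced with a warning in the report.
    """
    rows = []
    for condition, images in inputs.items():
        for experiment_id, image_id, frame in images:
            for res in score_image(frame, config.segmentation, config.smoothness):
                rows.append(
                    {
                        "condition": condition,
                        "experiment": experiment_id,
                        "image": image_id,
                        "object_id": res.object_id,
                        "smoothness": res.score,
                        "intersection_px2": res.intersection_px,
                        "union_px2": res.union_px,
                        "area_px2": res.area_px2,
                        "area_um2": res.area_px2 * config.pixel_size_um**2,
                    }
                )
        logger.info("scored condition %s", condition)
    scores = pd.DataFrame(rows)

    summaries = {}
    for condition, sub in scores.groupby("condition", sort=False):
        groups = {
            exp: sub.loc[sub["experiment"] == exp, "smoothness"].to_numpy()
            for exp in sub["experiment"].unique()
        }
        summaries[condition] = {
            basis: summarize_hierarchical(groups, basis=basis)
            for basis in ("experiments", "units")
        }

    test = None
    warning = None
    conditions = list(inputs)
    if len(conditions) == 2:
        a = scores.loc[scores["condition"] == conditions[0], "smoothness"]
        b = scores.loc[scores["condition"] == conditions[1], "smoothness"]
        test = choose_test(a.to_numpy(), b.to_numpy(), config.stats)
    else:
        warning = (
            f"{len(conditions)} condition(s) supplied; two-sample test "
            f"requires exactly 2 — summary only"
        )
        logger.warning(warning)

    report = {
        "pipeline": "invitro_smoothness",
        "package_version": __version__,
        "config_hash": config_hash(config),
        "conditions": {
            cond: {
                "n_objects": int((scores["condition"] == cond).sum()),
                "mean_smoothness_units": s["units"].overall_mean,
                "sem_units": s["units"].sem,
                "mean_smoothness_experiments": s["experiments"].overall_mean,
                "sem_experiments": s["experiments"].sem,
                "experiment_means": s["experiments"].experiment_means,
            }
            for cond, s in summaries.items()
        },
    }
    if test is not None:
        report["test"] = {
            "name": test.test,
            "statistic": test.statistic,
            "p_value": test.p_value,
            "gate": test.gate,
            "alpha": config.stats.alpha,
        }
    if warning:
        report["warning"] = warning

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        scores.to_csv(out / "scores.csv", index=False)
        _write_report(out / "report.json", report)
    return InvitroResult(scores, summaries, test, report)


def run_livecell_pipeline(
    config: PipelineConfig,
    inputs: dict[str, list[tuple[str, TimeLapse]]],
    output_dir: "str | Path | None" = None,
) -> LivecellResult:
    """Mitotic-exit analysis of single-cell time-lapse crops.

    ``inputs`` maps condition -> list of (cell_id, lapse). Cells whose
    trajectory has no qualifying mitosis (or an ambiguous scene) are
    discarded; each discard is logged and listed in the result.
    """
    curve_rows, phase_rows, dwell_rows = [], [], []
    aggregated_parts = []
    discarded: list[tuple[str, str]] = []
    for condition, cells in inputs.items():
        cond_curves: list[AreaCurve] = []
        for cell_id, lapse in cells:
            try:
                per_frame = [
                    extract_objects(
                        segment_livecell(
                            frame, config.segmentation, empty_on_degenerate=True
                        ),
                        config.segmentation.min_object_area_px2,
                        config.pixel_size_um,
                        frame_index=i,
                    )
                    for i, frame in enumerate(lapse)
                ]
                traj = link_objects(
                    per_frame, lapse.frame_interval_min, cell_id=cell_id
                )
                onset = detect_anaphase_onset(
                    traj, config.phases.anaphase_min_daughter_frac
                )
            except (NoMitosisError, AmbiguousSceneError) as exc:
                discarded.append((cell_id, str(exc)))
                logger.info("discarding %s: %s", cell_id, exc)
                continue
            curve = normalize_area_curve(traj, onset)
            phases = classify_phases(traj, config.phases, onset=onset)
            dwell = dwell_times(phases)
            cond_curves.append(curve)
            for t, v in zip(curve.time_min, curve.normalized_area):
                curve_rows.append(
                    {
                        "condition": condition,
                        "cell_id": cell_id,
                        "time_min": t,
                        "normalized_area": v,
                    }
                )
            for f, lab in enumerate(phases.labels):
                phase_rows.append(
                    {
                        "condition": condition,
                        "cell_id": cell_id,
                        "frame": f,
                        "phase": lab,
                    }
                )
            for phase, minutes in dwell.items():
                dwell_rows.append(
                    {
                        "condition": condition,
                        "cell_id": cell_id,
                        "phase": phase,
                        "dwell_min": minutes,
                    }
                )
        agg = aggregate_curves(cond_curves)
        agg.insert(0, "condition", condition)
        aggregated_parts.append(agg)
        logger.info(
            "condition %s: %d cells analyzed, %d discarded",
            condition,
            len(cond_curves),
            len(cells) - len(cond_curves),
        )

    curves = pd.DataFrame(
        curve_rows, columns=["condition", "cell_id", "time_min", "normalized_area"]
    )
    phases_df = pd.DataFrame(
        phase_rows, columns=["condition", "cell_id", "frame", "phase"]
    )
    dwell_df = pd.DataFrame(
        dwell_rows, columns=["condition", "cell_id", "phase", "dwell_min"]
    )
    aggregated = (
        pd.concat(aggregated_parts, ignore_index=True)
        if aggregated_parts
        else pd.DataFrame(columns=["condition", "time_min", "mean", "sem", "n"])
    )

    telophase = dwell_df[dwell_df["phase"] == "telophase"]
    report = {
        "pipeline": "livecell_mitotic_exit",
        "package_version": __version__,
        "config_hash": config_hash(config),
        "n_discarded": len(discarded),
        "discarded": [{"cell_id": c, "reason": r} for c, r in discarded],
        "telophase_dwell_min": {
            cond: float(sub["dwell_min"].mean())
            for cond, sub in telophase.groupby("condition")
        },
    }

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        curves.to_csv(out / "curves.csv", index=False)
        phases_df.to_csv(out / "phases.csv", index=False)
        dwell_df.to_csv(out / "dwell.csv", index=False)
        aggregated.to_csv(out / "aggregated_curves.csv", index=False)
        _write_report(out / "report.json", report)
    return LivecellResult(curves, phases_df, dwell_df, aggregated, discarded, report)
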