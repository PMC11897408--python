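"""Anaphase-aligned area curves, mitotic phase labels, and dwell times.

A segmented single-cell time-lapse is turned into a :class:`Trajectory`
(per-frame chromatin objects), the anaphase onset is detected as the first
persistent frame with two qualifying daughter masses, areas are normalized
to the onset frame (t = 0), phases are classified from chromatin-mass
sizes relative to an interphase reference area, and per-phase dwell times
are read off as run length x frame interval. Telophase dwell time is the
headline readout.

All size thresholds live in :class:`PhaseThresholds` and are deliberately
explicit and tunable: the size rule replaces trained morphology
classifiers, so its cut-offs are conventions calibrated on synthetic
fixtures, not measured constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import ChromatinObject

__all__ = [
    "Trajectory",
    "AreaCurve",
    "PhaseSequence",
    "PhaseThresholds",
    "NoMitosisError",
    "AmbiguousSceneError",
    "link_objects",
    "detect_anaphase_onset",
    "normalize_area_curve",
    "classify_phases",
    "dwell_times",
    "aggregate_curves",
    "fit_expansion_rate",
    "estimate_interphase_reference",
]


class NoMitosisError(RuntimeError):
    """No qualifying 1 -> 2 split found; the trajectory is discarded."""


class AmbiguousSceneError(RuntimeError):
    """More than two candidate objects in a frame after area filtering."""


@dataclass
class Trajectory:
    """Ordered per-frame object lists for one cell."""

    frames: list[list[ChromatinObject]]
    frame_interval_min: float
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    def total_area(self, f: int) -> float:
        return float(sum(o.area_px2 for o in self.frames[f]))


@dataclass
class AreaCurve:
    """Normalized chromatin area vs time (min) relative to anaphase onset."""

    time_min: np.ndarray
    normalized_area: np.ndarray
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.normalized_area = np.asarray(self.normalized_area, dtype=float)
        if self.time_min.shape != self.normalized_area.shape:
            raise ValueError("time and area vectors must have equal length")


@dataclass
class PhaseSequence:
    labels: list[str]
    frame_interval_min: float
    thresholds: "PhaseThresholds | None" = None
    cell_id: str = "cell"


@dataclass
class PhaseThresholds:
    """Size cut-offs of the phase classifier, as fractions of the
    interphase reference area.

    metaphase_area_frac: a single mass below this fraction is metaphase
    (condensed). anaphase_min_daughter_frac: each daughter must reach this
    fraction of the pre-split mass to count as a real split.
    telophase_exit_frac: a daughter at/above this fraction of the
    reference is interphase again. anaphase_frames: number of frames from
    onset labeled anaphase before telophase begins.
    """

    metaphase_area_frac: float = 0.4
    anaphase_min_daughter_frac: float = 0.2
    telophase_exit_frac: float = 0.8
    anaphase_frames: int = 2
    interphase_reference_area_px2: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "metaphase_area_frac",
            "anaphase_min_daughter_frac",
            "telophase_exit_frac",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.anaphase_frames < 1:
            raise ValueError("anaphase_frames must be >= 1")


def link_objects(
    frames: list[list[ChromatinObject]],
    frame_interval_min: float = 3.0,
    cell_id: str = "cell",
    max_objects: int = 2,
) -> Trajectory:
    """Order per-frame objects into a trajectory by nearest-centroid linking.

    Frames must contain at most ``max_objects`` relevant objects (largest
    by area); more raises :class:`AmbiguousSceneError`. For two-object
    frames following a two-object frame, the identity assignment is the
    pairing minimizing the summed centroid displacement, so daughters keep
    a stable order after the split.
    """
    linked: list[list[ChromatinObject]] = []
    prev: list[ChromatinObject] = []
    for f, objs in enumerate(frames):
        if len(objs) > max_objects:
            areas = sorted((o.area_px2 for o in objs), reverse=True)
            raise AmbiguousSceneError(
                f"frame {f}: {len(objs)} candidate objects (areas {areas}); "
                f"at most {max_objects} supported"
            )
        objs = sorted(objs, key=lambda o: o.area_px2, reverse=True)
        if len(objs) == 2:
            if len(prev) == 2:
                d_keep = _pair_cost(prev, objs)
                d_swap = _pair_cost(prev, objs[::-1])
                if d_swap < d_keep:
                    objs = objs[::-1]
            else:
                objs = sorted(objs, key=lambda o: o.centroid[1])  # left, right
        linked.append(objs)
        if objs:
            prev = objs
    return Trajectory(linked, frame_interval_min, cell_id)


def _pair_cost(a: list[ChromatinObject], b: list[ChromatinObject]) -> float:
    return sum(
        float(np.hypot(x.centroid[0] - y.centroid[0], x.centroid[1] - y.centroid[1]))
        for x, y in zip(a, b)
    )


def detect_anaphase_onset(
    traj: Trajectory,
    min_daughter_frac: float = 0.2,
    persistence: int = 2,
) -> int:
    """First frame with two persistent daughter masses (t = 0 reference).

    The onset is the smallest frame index with exactly two objects, each at
    least ``min_daughter_frac`` of the last preceding single-mass area,
    where the two-object configuration persists for ``persistence``
    consecutive frames (a 1-frame spurious split from segmentation noise
    does not qualify). Raises :class:`NoMitosisError` when no frame
    qualifies.
    """

    def qualifies(f: int, ref_area: float) -> bool:
        objs = traj.frames[f]
        if len(objs) != 2:
            return False
        return all(o.area_px2 >= min_daughter_frac * ref_area for o in objs)

    last_single_area: float | None = None
    for f in range(len(traj)):
        objs = traj.frames[f]
        if len(objs) == 1:
            last_single_area = float(objs[0].area_px2)
            continue
        if len(objs) == 2 and last_single_area is not None:
            run = 0
            g = f
            while g < len(traj) and qualifies(g, last_single_area):
                run += 1
                g += 1
            if run >= min(persistence, len(traj) - f):
                if run >= persistence or g == len(traj):
                    return f
    raise NoMitosisError(
        f"trajectory {traj.cell_id!r}: no persistent 1->2 split found"
    )


def normalize_area_curve(traj: Trajectory, onset: int) -> AreaCurve:
    """Summed chromatin area normalized to the onset frame.

    t = (frame - onset) * interval; frames before onset appear at negative
    time, normalized by the same denominator. The value at t = 0 is
    exactly 1.
    """
    if not (0 <= onset < len(traj)):
        raise ValueError(f"onset {onset} outside trajectory of length {len(traj)}")
    denom = traj.total_area(onset)
    if denom <= 0:
        raise ValueError("zero chromatin area at onset frame")
    times = []
    values = []
    for f in range(len(traj)):
        times.append((f - onset) * traj.frame_interval_min)
        values.append(traj.total_area(f) / denom)
    return AreaCurve(np.array(times), np.array(values), traj.cell_id)


def estimate_interphase_reference(traj: Trajectory, n_frames: int = 5) -> float:
    """Median single-object area over the first ``n_frames`` frames.

    Intended for trajectories that start in interphase; trajectories that
    start mid-mitosis should supply the reference explicitly.
    """
    areas = [
        float(traj.frames[f][0].area_px2)
        for f in range(min(n_frames, len(traj)))
        if len(traj.frames[f]) == 1
    ]
    if not areas:
        raise ValueError(
            "no single-object frames at trajectory start; supply "
            "interphase_reference_area_px2 explicitly"
        )
    return float(np.median(areas))


def classify_phases(
    traj: Trajectory,
    thresholds: PhaseThresholds | None = None,
    onset: int | None = None,
) -> PhaseSequence:
    """Label every frame by chromatin-mass size.

    Single mass: >= telophase_exit_frac * reference -> interphase;
    < metaphase_area_frac * reference -> metaphase; in between -> prophase.
    Two masses: anaphase for the first ``anaphase_frames`` frames from
    onset, then telophase until a daughter reaches
    telophase_exit_frac * reference, after which frames are interphase.
    """
    thresholds = thresholds or PhaseThresholds()
    ref = thresholds.interphase_reference_area_px2
    if ref is None:
        ref = estimate_interphase_reference(traj)
    if onset is None:
        try:
            onset = detect_anaphase_onset(
                traj, thresholds.anaphase_min_daughter_frac
            )
        except NoMitosisError:
            onset = None

    labels: list[str] = []
    exited = False
    for f in range(len(traj)):
        objs = traj.frames[f]
        if len(objs) == 0:
            labels.append(labels[-1] if labels else "interphase")
            continue
        if len(objs) == 1:
            a = objs[0].area_px2
            if a >= thresholds.telophase_exit_frac * ref:
                labels.append("interphase")
            elif a < thresholds.metaphase_area_frac * ref:
                labels.append("metaphase")
            else:
                labels.append("prophase")
            continue
        # two daughter masses
        if exited:
            labels.append("interphase")
        elif onset is not None and onset <= f < onset + thresholds.anaphase_frames:
            labels.append("anaphase")
        else:
            biggest = max(o.area_px2 for o in objs)
            if biggest >= thresholds.telophase_exit_frac * ref:
                exited = True
                labels.append("interphase")
            else:
                labels.append("telophase")
    return PhaseSequence(labels, traj.frame_interval_min, thresholds, traj.cell_id)


def dwell_times(phases: PhaseSequence) -> dict[str, float]:
    """Minutes spent in each phase (frame count x interval).

    Telophase dwell time is the headline readout of the live-cell
    pipeline.
    """
    out: dict[str, float] = {}
    for lab in phases.labels:
        out[lab] = out.get(lab, 0.0) + phases.frame_interval_min
    return out


def aggregate_curves(curves: list[AreaCurve]) -> pd.DataFrame:
    """Per-timepoint mean and s.e.m. over cells (ragged ends allowed).

    s.e.m. = sd / sqrt(n) with sd over the cells available at that
    timepoint; a timepoint with a single cell reports s.e.m. 0 and n = 1.
    """
    if not curves:
        return pd.DataFrame(columns=["time_min", "mean", "sem", "n"])
    records: dict[float, list[float]] = {}
    for c in curves:
        for t, v in zip(c.time_min, c.normalized_area):
            records.setdefault(float(t), []).append(float(v))
    rows = []
    for t in sorted(records):
        vals = np.array(records[t])
        n = len(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append({"time_min": t, "mean": float(vals.mean()), "sem": sem, "n": n})
    return pd.DataFrame(rows)


def fit_expansion_rate(curve: AreaCurve, t_max_min: float | None = None) -> float:
    """Least-squares slope k of (normalized_area - 1) = k * t through the
    origin, over t >= 0 (optionally truncated at ``t_max_min``)."""
    sel = curve.time_min >= 0
    if t_max_min is not None:
        sel &= curve.time_min <= t_max_min
    t = curve.time_min[sel]
    y = curve.normalized_area[sel] - 1.0
    denom = float(np.sum(t * t))
    if denom == 0:
        raise ValueError("no positive-time points to fit")
    return float(np.sum(t * y) / denom)
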