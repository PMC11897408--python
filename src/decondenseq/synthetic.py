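"""Synthetic fluorescence-microscopy generator with exact ground truth.

The three generators emulate the imaging experiments the analysis modules
quantify:

* :func:`make_chromatin_mass` — a single DAPI-like chromatin mass whose
  boundary roughness is tunable, standing in for in-vitro chromatin
  substrates (condensed cluster vs decondensed smooth mass).
* :func:`make_decondensation_timelapse` — an H2B-like mitotic time-lapse:
  one condensed mass (metaphase plate) that splits at a known onset frame
  into two separating daughter masses whose summed area grows linearly in
  time, A(t) = A0 * (1 + k*t).
* :func:`make_two_channel_cell` — a two-channel cell with a perichromatin
  rim in the marker channel, uniform cytoplasm, and optional bright
  cytoplasmic foci.

Mass boundaries are drawn in polar form::

    r(theta) = R * (1 + a * sum_j c_j * cos(j*theta + phi_j)),  j = 1..m

with the harmonic weights normalized so sum(|c_j|) = 1; the roughness
amplitude ``a`` is then the maximal fractional radial excursion, making it
the single interpretable "condensation" knob. Rasterization is
pixel-center-in-region. Noise is Gaussian, added after the blur, and the
result is clipped at zero.

Every generator is a pure function of its parameter dataclass (which
includes the seed): identical parameters give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .frames import ImageFrame, TimeLapse

__all__ = [
    "MassParams",
    "TimelapseParams",
    "TwoChannelParams",
    "GroundTruth",
    "make_chromatin_mass",
    "make_decondensation_timelapse",
    "make_two_channel_cell",
]

PHASES = ("interphase", "prophase", "metaphase", "anaphase", "telophase")


class BoundaryExitsFrameError(ValueError):
    """A drawn boundary would leave the image frame."""


class FociPlacementError(RuntimeError):
    """Foci could not be placed after the retry cap."""


@dataclass(frozen=True)
class MassParams:
    """Parameters of a single synthetic chromatin mass.

    ``roughness_amplitude`` is dimensionless (fraction of ``radius_px``);
    0 gives a perfect disk before blur/noise. ``blur_sigma_px`` is a PSF
    surrogate; ``noise_sd`` is additive Gaussian noise in intensity units.
    """

    image_size_px: tuple[int, int] = (128, 128)
    radius_px: float = 50.0
    roughness_amplitude: float = 0.0
    n_harmonics: int = 12
    foreground_intensity: float = 200.0
    background_intensity: float = 10.0
    noise_sd: float = 0.0
    blur_sigma_px: float = 0.0
    seed: int = 0
    center: tuple[float, float] | None = None  # (row, col); default image center

    def __post_init__(self) -> None:
        nr, nc = self.image_size_px
        if nr <= 0 or nc <= 0:
            raise ValueError("image_size_px entries must be positive")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be > 0")
        if self.roughness_amplitude < 0:
            raise ValueError("roughness_amplitude must be >= 0")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.background_intensity < 0 or self.foreground_intensity < 0:
            raise ValueError("intensities must be non-negative")
        if self.foreground_intensity <= self.background_intensity:
            raise ValueError("foreground_intensity must exceed background_intensity")
        if self.noise_sd < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise_sd and blur_sigma_px must be >= 0")


@dataclass(frozen=True)
class TimelapseParams:
    """Parameters of a synthetic mitotic-exit time-lapse.

    Before ``onset_frame`` each frame holds one condensed mass of area
    ``initial_area_px2``; from ``onset_frame`` on, two daughter masses whose
    summed true area at t minutes after onset is
    ``initial_area_px2 * (1 + expansion_rate_per_min * t)`` (clipped at
    ``area_max_px2`` when set). Daughters separate symmetrically at
    ``separation_speed_px_per_frame``.

    Ground-truth phase labels default to: metaphase before onset, anaphase
    for ``anaphase_frames`` frames from onset, then telophase until a
    daughter's true area reaches ``telophase_exit_frac`` of
    ``interphase_reference_area_px2``, then interphase. An explicit
    ``phase_truth`` tuple overrides this.
    """

    n_frames: int = 20
    frame_interval_min: float = 3.0
    onset_frame: int = 8
    initial_area_px2: float = 1000.0
    expansion_rate_per_min: float = 0.05
    area_max_px2: float | None = None
    # integer default keeps the daughters' subpixel phase constant, so the
    # rasterized area of a non-growing daughter is exactly conserved
    separation_speed_px_per_frame: float = 2.0
    initial_gap_px: float = 6.0  # clearance between daughter boundaries at onset
    image_size_px: tuple[int, int] = (256, 256)
    roughness_amplitude: float = 0.0  # pre-onset (metaphase) mass roughness
    daughter_roughness: float = 0.0
    n_harmonics: int = 12
    foreground_intensity: float = 200.0
    background_intensity: float = 10.0
    noise_sd: float = 0.0
    blur_sigma_px: float = 1.0
    seed: int = 0
    anaphase_frames: int = 2
    interphase_reference_area_px2: float | None = None  # default A0 / 0.3
    telophase_exit_frac: float = 0.8
    phase_truth: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (0 < self.onset_frame < self.n_frames):
            raise ValueError("onset_frame must satisfy 0 < onset_frame < n_frames")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.initial_area_px2 <= 0:
            raise ValueError("initial_area_px2 must be > 0")
        if self.expansion_rate_per_min < 0:
            raise ValueError("expansion_rate_per_min must be >= 0")
        if self.separation_speed_px_per_frame < 0:
            raise ValueError("separation_speed_px_per_frame must be >= 0")
        if self.phase_truth is not None:
            if len(self.phase_truth) != self.n_frames:
                raise ValueError("phase_truth must have one label per frame")
            bad = set(self.phase_truth) - set(PHASES)
            if bad:
                raise ValueError(f"unknown phase labels: {sorted(bad)}")

    @property
    def reference_area_px2(self) -> float:
        if self.interphase_reference_area_px2 is not None:
            return self.interphase_reference_area_px2
        # condensed metaphase mass is taken as 30% of the interphase nucleus
        return self.initial_area_px2 / 0.3


@dataclass(frozen=True)
class TwoChannelParams:
    """Parameters of a two-channel cell (chromatin + perichromatin marker).

    The marker channel is ``rim_intensity`` on the perichromatin rim band
    (dilation of the chromatin mask by ``rim_width_px`` minus the mask),
    ``cytoplasm_intensity`` elsewhere inside the cell disk, and
    ``chromatin_marker_intensity`` (default: the rim value, i.e. the marker
    coats the chromatin) on the chromatin body, before noise. Foci are
    bright disks rejection-sampled into the cytoplasm, pairwise at least
    ``4 * focus_radius_px`` apart and clear of chromatin and rim.
    """

    chromatin: MassParams = field(
        default_factory=lambda: MassParams(image_size_px=(256, 256), radius_px=30.0)
    )
    rim_width_px: int = 4
    rim_intensity: float = 150.0
    chromatin_marker_intensity: float | None = None
    cytoplasm_intensity: float = 30.0
    cytoplasm_radius_px: float = 100.0
    n_foci: int = 0
    focus_radius_px: float = 3.0
    focus_intensity: float = 150.0
    marker_noise_sd: float = 0.0
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.rim_width_px < 1:
            raise ValueError("rim_width_px must be >= 1")
        if self.n_foci < 0:
            raise ValueError("n_foci must be >= 0")
        if self.focus_radius_px <= 0:
            raise ValueError("focus_radius_px must be > 0")
        if min(self.rim_intensity, self.cytoplasm_intensity, self.focus_intensity) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def marker_on_chromatin(self) -> float:
        return (
            self.rim_intensity
            if self.chromatin_marker_intensity is None
            else self.chromatin_marker_intensity
        )


@dataclass
class GroundTruth:
    """The generator's record of what it drew.

    ``table`` is one row per frame/object (frame, object_id, true_area_px2,
    phase, roughness amplitude, expansion rate); ``masks`` holds the
    pre-blur label image per frame; ``info`` carries scalar truths such as
    onset frame, rim/cytoplasm intensities and foci centers.
    """

    table: pd.DataFrame
    masks: list[np.ndarray] = field(default_factory=list)
    info: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# boundary drawing and rasterization


def _draw_harmonics(rng: np.random.Generator, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded harmonic weights with sum(|c|) = 1, and phases."""
    c = rng.uniform(-1.0, 1.0, size=m)
    total = np.sum(np.abs(c))
    if total == 0:  # vanishing draw; fall back to a single harmonic
        c = np.zeros(m)
        c[0] = 1.0
        total = 1.0
    c = c / total
    phi = rng.uniform(0.0, 2.0 * np.pi, size=m)
    return c, phi


def _radial_profile(theta: np.ndarray, c: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """sum_j c_j cos(j*theta + phi_j) for j = 1..m (unit-normalized weights)."""
    j = np.arange(1, len(c) + 1)
    return np.cos(np.multiply.outer(theta, j) + phi) @ c


def _shape_area_factor(c: np.ndarray, a: float) -> float:
    """Analytic area of the polar shape divided by pi*R^2.

    Integrating r(theta)^2 / 2: the cross terms vanish and each harmonic
    contributes pi * c_j^2, so area = pi R^2 (1 + a^2 * sum(c^2) / 2).
    """
    return 1.0 + 0.5 * a * a * float(np.sum(c * c))


def _rasterize_boundary(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    a: float,
    c: np.ndarray,
    phi: np.ndarray,
    mirror: bool = False,
) -> np.ndarray:
    """Boolean mask: pixel centers whose distance <= r(theta)."""
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    dy = rows - center[0]
    dx = cols - center[1]
    dist = np.hypot(dy, dx)
    if a == 0:
        return dist <= radius
    theta = np.arctan2(dy, dx)
    if mirror:
        theta = np.pi - theta  # reflection across the vertical axis
    r = radius * (1.0 + a * _radial_profile(theta.ravel(), c, phi).reshape(theta.shape))
    return dist <= r


def _check_inside(
    shape: tuple[int, int], center: tuple[float, float], rmax: float
) -> None:
    nr, nc = shape
    cy, cx = center
    if cy - rmax < 0 or cx - rmax < 0 or cy + rmax > nr - 1 or cx + rmax > nc - 1:
        raise BoundaryExitsFrameError(
            f"boundary with maximal radius {rmax:.2f} px at center "
            f"({cy:.1f}, {cx:.1f}) exits the {nr}x{nc} frame"
        )


def _finish_image(
    field_: np.ndarray, blur_sigma: float, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    out = field_.astype(float)
    if blur_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=blur_sigma, mode="reflect")
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# generators


def make_chromatin_mass(
    params: MassParams, pixel_size_um: float = 1.0
) -> tuple[ImageFrame, np.ndarray, GroundTruth]:
    """Generate a single chromatin mass image, its true mask and ground truth.

    Returns
    -------
    frame, true_mask, truth:
        ``true_mask`` is the pre-blur rasterization; the frame is the
        rasterized intensity field after blur and additive noise (clipped
        at zero).
    """
    rng = np.random.default_rng(params.seed)
    c, phi = _draw_harmonics(rng, params.n_harmonics)
    a = params.roughness_amplitude
    nr, nc = params.image_size_px
    center = params.center or ((nr - 1) / 2.0, (nc - 1) / 2.0)
    _check_inside((nr, nc), center, params.radius_px * (1.0 + a))
    mask = _rasterize_boundary((nr, nc), center, params.radius_px, a, c, phi)
    img = np.where(mask, params.foreground_intensity, params.background_intensity)
    img = _finish_image(img, params.blur_sigma_px, params.noise_sd, rng)
    frame = ImageFrame(img, pixel_size_um=pixel_size_um, channel="chromatin")
    table = pd.DataFrame(
        {
            "frame": [0],
            "object_id": [0],
            "true_area_px2": [int(mask.sum())],
            "phase": [""],
            "roughness_amplitude": [a],
            "expansion_rate_per_min": [0.0],
        }
    )
    truth = GroundTruth(
        table=table,
        masks=[mask.astype(np.int32)],
        info={
            "roughness_amplitude": a,
            "radius_px": params.radius_px,
            "center": center,
            "harmonic_weights": c,
            "harmonic_phases": phi,
            "analytic_area_px2": math.pi * params.radius_px**2 * _shape_area_factor(c, a),
        },
    )
    return frame, mask, truth


def _default_phase_truth(params: TimelapseParams) -> list[str]:
    ref = params.reference_area_px2
    labels: list[str] = []
    k = params.expansion_rate_per_min
    for f in range(params.n_frames):
        if f < params.onset_frame:
            labels.append("metaphase")
        elif f < params.onset_frame + params.anaphase_frames:
            labels.append("anaphase")
        else:
            t = (f - params.onset_frame) * params.frame_interval_min
            total = params.initial_area_px2 * (1.0 + k * t)
            if params.area_max_px2 is not None:
                total = min(total, params.area_max_px2)
            per_daughter = total / 2.0
            if per_daughter >= params.telophase_exit_frac * ref:
                labels.append("interphase")
            else:
                labels.append("telophase")
    return labels


def make_decondensation_timelapse(
    params: TimelapseParams, pixel_size_um: float = 1.0
) -> tuple[TimeLapse, GroundTruth]:
    """Generate a mitotic-exit time-lapse with exact per-frame truth.

    Frames before the onset contain exactly one mass; frames at/after the
    onset contain two non-touching daughter masses (reflections of one
    boundary draw) separating symmetrically, whose summed analytic area
    follows A(t) = A0 * (1 + k*t). Raises an error if masses would touch
    or exit the frame.
    """
    rng = np.random.default_rng(params.seed)
    c_meta, phi_meta = _draw_harmonics(rng, params.n_harmonics)
    c_d, phi_d = _draw_harmonics(rng, params.n_harmonics)
    nr, nc = params.image_size_px
    center = ((nr - 1) / 2.0, (nc - 1) / 2.0)
    A0 = params.initial_area_px2
    k = params.expansion_rate_per_min
    a_meta = params.roughness_amplitude
    a_d = params.daughter_roughness

    # radius giving the requested analytic area for the (possibly rough) shape
    R_meta = math.sqrt(A0 / (math.pi * _shape_area_factor(c_meta, a_meta)))
    r_onset = math.sqrt(
        (A0 / 2.0) / (math.pi * _shape_area_factor(c_d, a_d))
    )
    half_sep0 = r_onset * (1.0 + a_d) + params.initial_gap_px / 2.0

    phase_truth = (
        list(params.phase_truth)
        if params.phase_truth is not None
        else _default_phase_truth(params)
    )

    frames: list[ImageFrame] = []
    masks: list[np.ndarray] = []
    rows: list[dict] = []
    for f in range(params.n_frames):
        label = np.zeros((nr, nc), dtype=np.int32)
        if f < params.onset_frame:
            _check_inside((nr, nc), center, R_meta * (1.0 + a_meta))
            m = _rasterize_boundary(
                (nr, nc), center, R_meta, a_meta, c_meta, phi_meta
            )
            label[m] = 1
            rows.append(
                {
                    "frame": f,
                    "object_id": 0,
                    "true_area_px2": int(m.sum()),
                    "true_area_analytic_px2": A0,
                    "true_normalized_area": float("nan"),
                    "phase": phase_truth[f],
                    "roughness_amplitude": a_meta,
                    "expansion_rate_per_min": k,
                }
            )
        else:
            t = (f - params.onset_frame) * params.frame_interval_min
            total = A0 * (1.0 + k * t)
            if params.area_max_px2 is not None:
                total = min(total, params.area_max_px2)
            per_d = total / 2.0
            r_d = math.sqrt(per_d / (math.pi * _shape_area_factor(c_d, a_d)))
            half_sep = half_sep0 + params.separation_speed_px_per_frame * (
                f - params.onset_frame
            )
            rmax = r_d * (1.0 + a_d)
            if 2.0 * half_sep <= 2.0 * rmax + 1.0:
                raise ValueError(
                    f"daughter masses would touch at frame {f}: separation "
                    f"{2 * half_sep:.1f} px vs diameter {2 * rmax:.1f} px"
                )
            for side, mirror in ((-1.0, False), (1.0, True)):
                ctr = (center[0], center[1] + side * half_sep)
                _check_inside((nr, nc), ctr, rmax)
                m = _rasterize_boundary((nr, nc), ctr, r_d, a_d, c_d, phi_d, mirror)
                label[m] = 1 if side < 0 else 2
            for oid in (1, 2):
                rows.append(
                    {
                        "frame": f,
                        "object_id": oid - 1,
                        "true_area_px2": int((label == oid).sum()),
                        "true_area_analytic_px2": per_d,
                        "true_normalized_area": total / A0,
                        "phase": phase_truth[f],
                        "roughness_amplitude": a_d,
                        "expansion_rate_per_min": k,
                    }
                )
        img = np.where(
            label > 0, params.foreground_intensity, params.background_intensity
        )
        img = _finish_image(img, params.blur_sigma_px, params.noise_sd, rng)
        frames.append(
            ImageFrame(
                img, pixel_size_um=pixel_size_um, channel="chromatin", frame_index=f
            )
        )
        masks.append(label)

    truth = GroundTruth(
        table=pd.DataFrame(rows),
        masks=masks,
        info={
            "onset_frame": params.onset_frame,
            "expansion_rate_per_min": k,
            "initial_area_px2": A0,
            "interphase_reference_area_px2": params.reference_area_px2,
            "phase_truth": phase_truth,
            "frame_interval_min": params.frame_interval_min,
        },
    )
    return TimeLapse(frames, params.frame_interval_min), truth


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(math.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= radius * radius
    return dy[keep], dx[keep]


def make_two_channel_cell(
    params: TwoChannelParams, pixel_size_um: float = 1.0
) -> tuple[ImageFrame, ImageFrame, GroundTruth]:
    """Generate a chromatin frame, a marker frame, and their ground truth.

    The marker channel follows the :class:`TwoChannelParams` contract
    exactly before noise; foci centers are rejection-sampled in the
    cytoplasm, pairwise >= 4 * focus_radius apart, and re-drawn (up to
    ``max_retries``) if they would overlap chromatin or rim.
    """
    chrom_params = replace(params.chromatin, seed=params.chromatin.seed)
    chrom_frame, chrom_mask, chrom_truth = make_chromatin_mass(
        chrom_params, pixel_size_um
    )
    nr, nc = chrom_mask.shape
    center = chrom_truth.info["center"]

    from skimage.morphology import disk  # structuring element

    dilated = ndimage.binary_dilation(chrom_mask, structure=disk(params.rim_width_px))
    rim = dilated & ~chrom_mask
    rows = np.arange(nr, dtype=float)[:, None]
    cols = np.arange(nc, dtype=float)[None, :]
    cell = (
        np.hypot(rows - center[0], cols - center[1]) <= params.cytoplasm_radius_px
    )
    if (rim & ~cell).any():
        raise ValueError(
            "perichromatin rim extends beyond the cell disk; increase "
            "cytoplasm_radius_px or shrink the chromatin mass"
        )
    cytoplasm = cell & ~dilated

    marker = np.zeros((nr, nc), dtype=float)
    marker[cytoplasm] = params.cytoplasm_intensity
    marker[rim] = params.rim_intensity
    marker[chrom_mask] = params.marker_on_chromatin

    rng = np.random.default_rng(params.seed)
    dy, dx = _disk_offsets(params.focus_radius_px)
    foci_centers: list[tuple[int, int]] = []
    cyto_idx = np.flatnonzero(cytoplasm.ravel())
    for _ in range(params.n_foci):
        placed = False
        for _try in range(params.max_retries):
            flat = int(rng.choice(cyto_idx))
            cy, cx = divmod(flat, nc)
            yy, xx = cy + dy, cx + dx
            if (yy < 0).any() or (yy >= nr).any() or (xx < 0).any() or (xx >= nc).any():
                continue
            if not cytoplasm[yy, xx].all():
                continue  # would overlap chromatin, rim, or leave the cell
            if any(
                math.hypot(cy - fy, cx - fx) < 4.0 * params.focus_radius_px
                for fy, fx in foci_centers
            ):
                continue
            foci_centers.append((cy, cx))
            marker[yy, xx] = params.focus_intensity
            placed = True
            break
        if not placed:
            raise FociPlacementError(
                f"could not place focus {len(foci_centers)} after "
                f"{params.max_retries} retries; reduce n_foci or focus_radius_px"
            )

    if params.marker_noise_sd > 0:
        marker = marker + rng.normal(0.0, params.marker_noise_sd, size=marker.shape)
    marker = np.clip(marker, 0.0, None)
    marker_frame = ImageFrame(marker, pixel_size_um=pixel_size_um, channel="marker")

    table = pd.DataFrame(
        {
            "frame": [0],
            "object_id": [0],
            "true_area_px2": [int(chrom_mask.sum())],
            "phase": [""],
            "roughness_amplitude": [params.chromatin.roughness_amplitude],
            "expansion_rate_per_min": [0.0],
        }
    )
    truth = GroundTruth(
        table=table,
        masks=[chrom_mask.astype(np.int32)],
        info={
            "rim_intensity": params.rim_intensity,
            "cytoplasm_intensity": params.cytoplasm_intensity,
            "marker_on_chromatin": params.marker_on_chromatin,
            "foci_centers": foci_centers,
            "focus_radius_px": params.focus_radius_px,
            "focus_intensity": params.focus_intensity,
            "chromatin_mask": chrom_mask,
            "rim_mask": rim,
            "cell_mask": cell,
            "cytoplasm_mask": cytoplasm,
        },
    )
    return chrom_frame, marker_frame, truth
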