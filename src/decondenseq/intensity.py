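"""Marker intensity on chromatin, background correction, line scans, foci.

The perichromatin readout is the mean marker intensity over the chromatin
mask, background-corrected by the mean inside a circular ROI placed at a
seeded random position in the cytoplasm (rejection sampling until the
whole disk lies in cytoplasm). Line scans sample exactly 200 points with
bilinear interpolation. Cytoplasmic foci are detected as bright connected
components in the cytoplasm, an explicit algorithmic surrogate for visual
scoring: every threshold is in :class:`FociConfig` and echoed in the
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .frames import ImageFrame

__all__ = [
    "IntensityMeasurement",
    "LineScanProfile",
    "FociConfig",
    "Focus",
    "FociResult",
    "mean_on_mask",
    "sample_background",
    "corrected_intensity",
    "line_scan",
    "detect_foci",
]

LINE_SCAN_SAMPLES = 200
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class IntensityMeasurement:
    on_mask_mean: float
    background_mean: float
    corrected: float  # on_mask_mean - background_mean; may be negative (flagged)
    bg_roi_center: tuple[int, int]
    bg_roi_radius_px: float
    rng_seed: int | None = None
    negative_corrected: bool = False


@dataclass
class LineScanProfile:
    values: np.ndarray  # exactly 200 gray values, endpoints inclusive
    p0: tuple[float, float]
    p1: tuple[float, float]


@dataclass
class FociConfig:
    """Thresholds of the foci detector.

    A cytoplasmic pixel is focus candidate if its intensity is at least
    ``fold_threshold`` x the cytoplasm median; candidate components of
    area >= ``min_area_px2`` are foci; a cell has "big" foci if any focus
    has area >= ``big_area_px2`` and mean intensity >= fold x median.
    ``exclusion_dilation_px`` grows the chromatin mask before defining the
    cytoplasm, excluding the perichromatin rim.
    """

    fold_threshold: float = 3.0
    min_area_px2: float = 4.0
    big_area_px2: float = 25.0
    exclusion_dilation_px: int = 5

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if self.min_area_px2 <= 0 or self.big_area_px2 < self.min_area_px2:
            raise ValueError("need 0 < min_area_px2 <= big_area_px2")


@dataclass
class Focus:
    center: tuple[float, float]
    area_px2: int
    mean_intensity: float


@dataclass
class FociResult:
    foci: list[Focus]
    big_foci_present: bool
    cytoplasm_median: float
    config: FociConfig


def _data(frame: ImageFrame | np.ndarray) -> np.ndarray:
    return frame.data if isinstance(frame, ImageFrame) else np.asarray(frame)


def mean_on_mask(marker: ImageFrame | np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of the marker over mask pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mean over an empty mask is undefined")
    return float(_data(marker)[mask].mean())


def _cytoplasm_region(
    chromatin_mask: np.ndarray, cell_mask: np.ndarray, dilation_px: int
) -> np.ndarray:
    from skimage.morphology import disk

    chrom = np.asarray(chromatin_mask, dtype=bool)
    if dilation_px > 0:
        chrom = ndimage.binary_dilation(chrom, structure=disk(dilation_px))
    return np.asarray(cell_mask, dtype=bool) & ~chrom


def sample_background(
    marker: ImageFrame | np.ndarray,
    chromatin_mask: np.ndarray,
    cell_mask: np.ndarray,
    radius_px: float = 10.0,
    seed: int | None = None,
    exclusion_dilation_px: int = 5,
    max_retries: int = 1000,
) -> tuple[tuple[int, int], float]:
    """Random circular background ROI fully inside the cytoplasm.

    The cytoplasm is the cell minus the dilated chromatin mask. A center is
    drawn uniformly over cytoplasm pixels and accepted iff the whole disk
    lies in cytoplasm (and in frame); after ``max_retries`` rejections an
    error suggests a smaller radius. Returns (center, mean inside disk).
    """
    data = _data(marker)
    cyto = _cytoplasm_region(chromatin_mask, cell_mask, exclusion_dilation_px)
    idx = np.flatnonzero(cyto.ravel())
    if idx.size == 0:
        raise ValueError("cytoplasm region is empty")
    nr, nc = cyto.shape
    r = int(np.ceil(radius_px))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= radius_px * radius_px
    dy, dx = dy[keep], dx[keep]
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        flat = int(rng.choice(idx))
        cy, cx = divmod(flat, nc)
        yy, xx = cy + dy, cx + dx
        if (yy < 0).any() or (yy >= nr).any() or (xx < 0).any() or (xx >= nc).any():
            continue
        if not cyto[yy, xx].all():
            continue
        return (cy, cx), float(data[yy, xx].mean())
    raise RuntimeError(
        f"no admissible ROI of radius {radius_px} px found in {max_retries} "
        f"draws; try a smaller radius"
    )


def corrected_intensity(
    marker: ImageFrame | np.ndarray,
    chromatin_mask: np.ndarray,
    cell_mask: np.ndarray,
    radius_px: float = 10.0,
    seed: int | None = None,
    exclusion_dilation_px: int = 5,
) -> IntensityMeasurement:
    """Mean marker on the chromatin mask minus cytoplasmic background."""
    on = mean_on_mask(marker, chromatin_mask)
    center, bg = sample_background(
        marker,
        chromatin_mask,
        cell_mask,
        radius_px=radius_px,
        seed=seed,
        exclusion_dilation_px=exclusion_dilation_px,
    )
    corrected = on - bg
    return IntensityMeasurement(
        on_mask_mean=on,
        background_mean=bg,
        corrected=corrected,
        bg_roi_center=center,
        bg_roi_radius_px=radius_px,
        rng_seed=seed,
        negative_corrected=corrected < 0,
    )


def line_scan(
    frame: ImageFrame | np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
) -> LineScanProfile:
    """200 equally spaced bilinear samples from p0 to p1 inclusive.

    Endpoints are (row, col) pixel coordinates and must lie inside the
    frame.
    """
    data = _data(frame).astype(float)
    nr, nc = data.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= nr - 1 and 0 <= p[1] <= nc - 1):
            raise ValueError(f"line-scan endpoint {p} outside frame {nr}x{nc}")
    frac = np.linspace(0.0, 1.0, LINE_SCAN_SAMPLES)
    rows = p0[0] + frac * (p1[0] - p0[0])
    cols = p0[1] + frac * (p1[1] - p0[1])
    values = ndimage.map_coordinates(
        data, np.vstack([rows, cols]), order=1, mode="nearest"
    )
    return LineScanProfile(values=values, p0=tuple(p0), p1=tuple(p1))


def detect_foci(
    marker: ImageFrame | np.ndarray,
    chromatin_mask: np.ndarray,
    cell_mask: np.ndarray,
    cfg: FociConfig | None = None,
) -> FociResult:
    """Detect bright cytoplasmic foci.

    Thresholds the cytoplasm at fold_threshold x its median intensity and
    keeps 8-connected components of sufficient area. Pixels on chromatin
    or within the rim exclusion band are never counted.
    """
    cfg = cfg or FociConfig()
    data = _data(marker)
    cyto = _cytoplasm_region(chromatin_mask, cell_mask, cfg.exclusion_dilation_px)
    if not cyto.any():
        raise ValueError("cytoplasm region is empty")
    median = float(np.median(data[cyto]))
    cand = cyto & (data >= cfg.fold_threshold * median)
    labels, n = ndimage.label(cand, structure=_STRUCT8)
    foci: list[Focus] = []
    big = False
    for lab in range(1, n + 1):
        comp = labels == lab
        area = int(comp.sum())
        if area < cfg.min_area_px2:
            continue
        mean_int = float(data[comp].mean())
        cen = ndimage.center_of_mass(comp)
        foci.append(Focus(center=(float(cen[0]), float(cen[1])), area_px2=area,
                          mean_intensity=mean_int))
        if area >= cfg.big_area_px2 and mean_int >= cfg.fold_threshold * median:
            big = True
    return FociResult(foci=foci, big_foci_present=big, cytoplasm_median=median,
                      config=cfg)
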