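"""Border-smoothness scoring of segmented chromatin masses.

Decondensed chromatin relaxes into a smooth compact mass, while condensed
clusters keep a ragged outline of individualized chromosomes. The score
exploits this: a binary median filter (majority vote in an odd square
window) produces a "soft-border" version of the segmentation mask, and the
smoothness is the intersection-over-union of the mask with its softened
self,

    s = |M & soft(M)| / |M | soft(M)|,  s in [0, 1].

A mask that is a fixed point of softening scores exactly 1; roughness at
scales below the kernel is shaved off by the majority vote, and the lost
(plus gained) pixels push the IoU down. The kernel therefore sets the
scale of "roughness": the default 15 px is calibrated for objects of
~50 px radius (about 0.3 * R) so that a digital disk scores >= 0.99 while
a strongly lobed cluster scores well below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .frames import ImageFrame
from .segmentation import SegmentationConfig, extract_objects, segment_invitro

__all__ = [
    "SmoothnessConfig",
    "SmoothnessResult",
    "soften_border",
    "border_smoothness",
    "score_image",
]


@dataclass
class SmoothnessConfig:
    """soft_kernel_px: edge of the odd binary-median window (>= 3)."""

    soft_kernel_px: int = 15

    def __post_init__(self) -> None:
        if self.soft_kernel_px < 3 or self.soft_kernel_px % 2 == 0:
            raise ValueError("soft_kernel_px must be an odd integer >= 3")


@dataclass
class SmoothnessResult:
    score: float
    hard_mask: np.ndarray
    soft_mask: np.ndarray
    intersection_px: int
    union_px: int
    area_px2: int = 0
    object_id: int = 0


def soften_border(mask: np.ndarray, soft_kernel_px: int) -> np.ndarray:
    """Binary median (strict-majority) filter with reflect edges.

    A pixel is foreground iff more than half of its soft_kernel_px^2
    neighborhood is foreground; with an odd window the count can never tie.
    """
    if soft_kernel_px < 3 or soft_kernel_px % 2 == 0:
        raise ValueError(
            f"soft kernel must be odd and >= 3, got {soft_kernel_px}"
        )
    mask = np.asarray(mask, dtype=bool)
    soft = ndimage.median_filter(
        mask.astype(np.uint8), size=soft_kernel_px, mode="reflect"
    )
    return soft.astype(bool)


def border_smoothness(
    mask: np.ndarray, cfg: SmoothnessConfig | None = None
) -> SmoothnessResult:
    """Intersection-over-union of a mask with its soft-border version."""
    cfg = cfg or SmoothnessConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("border smoothness is undefined for an empty mask")
    soft = soften_border(mask, cfg.soft_kernel_px)
    inter = int(np.count_nonzero(mask & soft))
    union = int(np.count_nonzero(mask | soft))
    if not soft.any():
        warnings.warn(
            "softened mask is empty; the object is thinner than the kernel "
            "everywhere, score set to 0",
            stacklevel=2,
        )
    return SmoothnessResult(
        score=inter / union,
        hard_mask=mask,
        soft_mask=soft,
        intersection_px=inter,
        union_px=union,
        area_px2=int(mask.sum()),
    )


def score_image(
    frame: ImageFrame | np.ndarray,
    seg_cfg: SegmentationConfig | None = None,
    sm_cfg: SmoothnessConfig | None = None,
) -> list[SmoothnessResult]:
    """Segment an image (in-vitro recipe) and score each object.

    Objects are scored individually on their own component mask, sorted by
    area descending; an image with no objects returns an empty list with a
    warning.
    """
    seg_cfg = seg_cfg or SegmentationConfig()
    mask = segment_invitro(frame, seg_cfg, empty_on_degenerate=True)
    objects = extract_objects(mask, seg_cfg.min_object_area_px2)
    if not objects:
        warnings.warn("no objects found in frame; empty score table", stacklevel=2)
        return []
    results = []
    for i, obj in enumerate(objects):
        res = border_smoothness(obj.mask, sm_cfg)
        res.object_id = i
        results.append(res)
    return results
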