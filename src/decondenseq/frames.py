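"""In-memory containers for single frames and time-lapses.

Conventions used throughout the package: images are 2D arrays indexed
(row, col) with the origin at the top-left, coordinates are 0-based, and a
pixel is identified with its center. Physical scale is carried as
``pixel_size_um`` (µm per pixel edge) so areas convert as
``area_um2 = area_px2 * pixel_size_um**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageFrame", "TimeLapse"]


@dataclass
class ImageFrame:
    """A single 2D intensity image plus the metadata all operators consume.

    Parameters
    ----------
    data:
        2D array of intensities (any numeric dtype).
    pixel_size_um:
        Physical pixel edge length in micrometres.
    channel:
        Free-text channel tag, e.g. ``"chromatin"`` or ``"marker"``.
    frame_index:
        Position within a time-lapse; 0 for single frames.
    """

    data: np.ndarray
    pixel_size_um: float = 1.0
    channel: str = "chromatin"
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(
                f"ImageFrame requires a 2D array, got shape {self.data.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class TimeLapse:
    """An ordered sequence of frames acquired at a fixed interval."""

    frames: list[ImageFrame] = field(default_factory=list)
    frame_interval_min: float = 3.0

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> ImageFrame:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)
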