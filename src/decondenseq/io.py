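"""Reading/writing images, configuration, and report stamping.

TIFF (single frame and multi-page) is the interchange format; grayscale
PNG is accepted for single frames. Axes resolve to (time, channel, row,
col) with singleton axes inserted; dtype is preserved. Pixel size and
frame interval come from :class:`PipelineConfig` (image metadata, when
present, can be overridden there), and the config round-trips through
YAML losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .frames import ImageFrame, TimeLapse
from .intensity import FociConfig
from .segmentation import SegmentationConfig
from .smoothness import SmoothnessConfig
from .stats import StatsConfig
from .timecourse import PhaseThresholds

__all__ = [
    "PipelineConfig",
    "read_image",
    "write_frame",
    "write_timelapse",
    "write_mask",
    "config_hash",
]


@dataclass
class PipelineConfig:
    """One config object governs a run; CLI flags override fields."""

    pixel_size_um: float = 1.0
    frame_interval_min: float = 3.0
    chromatin_channel: int = 0
    marker_channel: int = 1
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    smoothness: SmoothnessConfig = field(default_factory=SmoothnessConfig)
    phases: PhaseThresholds = field(default_factory=PhaseThresholds)
    foci: FociConfig = field(default_factory=FociConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("segmentation", SegmentationConfig),
            ("smoothness", SmoothnessConfig),
            ("phases", PhaseThresholds),
            ("foci", FociConfig),
            ("stats", StatsConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def config_hash(cfg: PipelineConfig) -> str:
    """Short stable hash of the full configuration, stamped into reports."""
    canon = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def read_image(
    path, pixel_size_um: float = 1.0, frame_interval_min: float = 3.0
) -> ImageFrame | TimeLapse:
    """Read TIFF/OME-TIFF (or grayscale PNG) as a frame or time-lapse.

    2D data yields an :class:`ImageFrame`; 3D data is interpreted as
    (time, row, col) and yields a :class:`TimeLapse`. RGB images are
    rejected: the pipelines operate on single-channel intensities.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        data = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format: {path.name}")
    data = np.asarray(data)
    if data.ndim == 3 and data.shape[-1] in (3, 4) and suffix == ".png":
        raise ValueError(
            f"{path.name} is RGB(A); convert to single-channel grayscale first"
        )
    if data.ndim == 2:
        return ImageFrame(data, pixel_size_um=pixel_size_um)
    if data.ndim == 3:
        frames = [
            ImageFrame(data[i], pixel_size_um=pixel_size_um, frame_index=i)
            for i in range(data.shape[0])
        ]
        return TimeLapse(frames, frame_interval_min)
    raise ValueError(
        f"{path.name}: unsupported axes (ndim={data.ndim}); expected 2D frame "
        f"or (time, row, col) stack"
    )


def write_frame(path, frame: ImageFrame) -> None:
    tifffile.imwrite(Path(path), np.asarray(frame.data))


def write_timelapse(path, lapse: TimeLapse) -> None:
    stack = np.stack([f.data for f in lapse.frames])
    tifffile.imwrite(Path(path), stack, metadata={"axes": "TYX"})


def write_mask(path, mask: np.ndarray) -> None:
    """Masks are written as 8-bit TIFF with foreground 255."""
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))
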