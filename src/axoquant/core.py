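"""Core data containers shared across the pipeline.

Coordinate conventions: images are indexed ``[frame, (channel,) row, col]``;
positions are reported as ``(x, y)`` with ``x`` rightward (columns) and ``y``
downward (rows), origin at the top-left pixel center, 0-based. All physical
distances are Euclidean in the image plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass(frozen=True)
class Calibration:
    """Pixel/time calibration of an acquisition.

    Parameters
    ----------
    pixel_size_nm:
        Lateral pixel size in nm/pixel. The organelle-trafficking setup uses
        229.55 nm/pixel (100x objective with EMCCD camera); the growth-cone
        bright-field setup (40x) defaults to 160 nm/pixel.
    frame_interval_s:
        Time between consecutive frames of one channel, in seconds.
        3.3 frames/s per channel for organelle movies; 20 s (3 frames/min)
        for growth-cone movies.
    exposure_ms:
        Per-frame exposure time in ms; metadata only, not used in any
        computation.
    """

    pixel_size_nm: float = 229.55
    frame_interval_s: float = 1.0 / 3.3
    exposure_ms: float | None = 115.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    def px_to_um(self, px: float | np.ndarray) -> float | np.ndarray:
        return np.asarray(px) * self.pixel_size_um if isinstance(px, np.ndarray) else px * self.pixel_size_um

    def um_to_px(self, um: float | np.ndarray) -> float | np.ndarray:
        return np.asarray(um) / self.pixel_size_um if isinstance(um, np.ndarray) else um / self.pixel_size_um

    def speed_um_per_s(self, px_per_frame: float) -> float:
        """Convert a per-frame pixel displacement to µm/s."""
        return px_per_frame * self.pixel_size_um / self.frame_interval_s

    def speed_px_per_frame(self, um_per_s: float) -> float:
        """Inverse of :meth:`speed_um_per_s`."""
        return um_per_s * self.frame_interval_s / self.pixel_size_um


# Growth-cone bright-field setup: 40x DIC, 3 frames/min over 2 h.
GROWTH_CONE_CALIBRATION = Calibration(pixel_size_nm=160.0, frame_interval_s=20.0, exposure_ms=None)


@dataclass
class ImageStack:
    """An N-frame (optionally multi-channel) pixel array with calibration.

    ``data`` has shape ``(T, H, W)`` for a single channel or ``(T, C, H, W)``
    for multi-channel stacks; a still multi-channel image is stored as a
    single-frame stack ``(1, C, H, W)``.
    """

    data: np.ndarray
    calibration: Calibration
    channel_names: tuple[str, ...] = ("ch0",)

    def __post_init__(self) -> None:
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (T, H, W) or (T, C, H, W)")
        if self.data.ndim == 4 and self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must match the channel axis")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]

    def channel(self, name: str) -> np.ndarray:
        """Single-channel view ``(T, H, W)`` by channel name."""
        if self.data.ndim == 3:
            if name != self.channel_names[0]:
                raise KeyError(name)
            return self.data
        return self.data[:, self.channel_names.index(name)]

    def save_tiff(self, path: str | Path) -> None:
        """Write a multi-page TIFF (pages = frames, interleaved channels)."""
        meta = {
            "axes": "TYX" if self.data.ndim == 3 else "TCYX",
            "channel_names": list(self.channel_names),
            "pixel_size_nm": self.calibration.pixel_size_nm,
            "frame_interval_s": self.calibration.frame_interval_s,
        }
        tifffile.imwrite(path, self.data.astype(np.float32), metadata=meta)

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        calibration: Calibration | None = None,
        channel_names: tuple[str, ...] | None = None,
    ) -> "ImageStack":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if data.ndim == 2:
            data = data[None]
        if calibration is None:
            calibration = Calibration(
                pixel_size_nm=float(meta.get("pixel_size_nm", 229.55)),
                frame_interval_s=float(meta.get("frame_interval_s", 1.0 / 3.3)),
            )
        if channel_names is None:
            names = meta.get("channel_names")
            channel_names = tuple(names) if names else ("ch0",) if data.ndim == 3 else tuple(
                f"ch{i}" for i in range(data.shape[1])
            )
        return cls(data=data, calibration=calibration, channel_names=channel_names)


@dataclass
class GroundTruth:
    """Ground truth of a synthetic scene.

    ``objects`` holds one row per rendered object (id, class labels, true
    parameters); ``positions`` holds per-object per-frame true positions
    (empty for still images). Every rendered object has exactly one row in
    ``objects``.
    """

    objects: pd.DataFrame
    positions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["object_id", "frame", "x_px", "y_px"])
    )

    def to_csv(self, objects_path: str | Path, positions_path: str | Path | None = None) -> None:
        self.objects.to_csv(objects_path, index=False)
        if positions_path is not None:
            self.positions.to_csv(positions_path, index=False)
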