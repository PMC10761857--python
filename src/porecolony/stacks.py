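"""Time-lapse image stack container shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageStack", "CHANNELS"]

CHANNELS = ("brightfield", "gfp", "mcherry", "tracer")


@dataclass
class ImageStack:
    """Ordered time-lapse frames of one optical channel.

    frames: (T, H, W) array; acquisition dtype is 16-bit unsigned, corrected
    (background-subtracted) stacks are float. ``times`` are seconds, strictly
    increasing; ``pixel_size`` is µm per pixel.
    """

    frames: np.ndarray
    times: np.ndarray
    channel: str
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if len(self.times) != len(self.frames):
            raise ValueError("one acquisition time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]
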