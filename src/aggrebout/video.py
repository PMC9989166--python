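"""In-memory video container shared by the generator, classifier and I/O."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VideoSession"]


@dataclass
class VideoSession:
    """A frame sequence with its frame rate and optional per-frame labels.

    ``frames`` is (T, H, W) uint8 grayscale or (T, H, W, 3) uint8 RGB.
    ``labels``, when present, is a length-T 0/1 vector marking aggression
    frames (the frame-classifier training target).
    """

    frames: np.ndarray
    fps: float
    labels: np.ndarray | None = None
    video_id: str = ""
    meta: dict | None = None  # generator ground truth, acquisition notes

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T,H,W) or (T,H,W,3)")
        if self.frames.ndim == 4 and self.frames.shape[-1] != 3:
            raise ValueError("color video must have 3 channels")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (self.n_frames,):
                raise ValueError("labels length must equal frame count")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be 0/1")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps
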