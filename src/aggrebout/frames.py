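"""Frame preprocessing for the pose-free classifier.

Color frames are reduced to grayscale, and the classifier input is built
not from color channels but from temporal structure: channel 0 is the
current grayscale frame and each further channel is the signed
difference between the current frame and a lagged previous frame.  A
static scene therefore produces all-zero difference channels, and motion
shows up directly as input signal, which is what lets a small network
recognize tussling without any pose estimation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["to_grayscale", "build_difference_stack", "LUMA_WEIGHTS"]

# ITU-R BT.601 luma weights, the standard convention for 8-bit video
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB frame to grayscale via BT.601 luma weights.

    A single-channel input passes through unchanged; any other channel
    count is an error.  Output is uint8 (rounded).
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[-1] == 3:
        return np.rint(frame.astype(float) @ LUMA_WEIGHTS).clip(0, 255).astype(
            np.uint8
        )
    raise ValueError(
        f"expected (H,W) or (H,W,3) frame, got shape {frame.shape}"
    )


def build_difference_stack(
    gray_frames: np.ndarray, lags: tuple[int, ...] = (1, 2)
) -> np.ndarray:
    """Per-frame channel stack: current frame plus lagged differences.

    For frame t and lag L the difference channel is ``g(t) - g(t-L)``
    (signed, full float precision); frames earlier than L get a zero
    channel.  Returns (T, 1+len(lags), H, W) float32.
    """
    lags = tuple(int(l) for l in lags)
    if len(lags) == 0 or any(l < 1 for l in lags):
        raise ValueError("lags must be >= 1")
    if any(b <= a for a, b in zip(lags, lags[1:])):
        raise ValueError("lags must be strictly increasing")
    g = np.asarray(gray_frames, dtype=np.float32)
    if g.ndim != 3 or g.shape[0] == 0:
        raise ValueError("gray_frames must be a non-empty (T,H,W) array")
    t = g.shape[0]
    stack = np.zeros((t, 1 + len(lags)) + g.shape[1:], dtype=np.float32)
    stack[:, 0] = g
    for c, lag in enumerate(lags, start=1):
        if lag < t:
            stack[lag:, c] = g[lag:] - g[:-lag]
    return stack
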