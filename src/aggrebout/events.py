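"""Bout detection on per-frame attack-probability traces.

A classifier emits one attack probability per video frame.  Scoring a
resident-intruder session means turning that trace into discrete attack
events: smooth with a centered moving average, keep frames above a
threshold, merge runs separated by short gaps, drop runs that are too
short, and report the cumulative attack duration over the session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EventSet",
    "EventDetectionConfig",
    "SessionSummary",
    "moving_average",
    "detect_events",
    "cumulative_attack_duration",
    "event_match_metrics",
]


@dataclass(frozen=True)
class EventSet:
    """Sorted, disjoint, 0-based closed frame intervals plus the frame rate.

    ``intervals`` has shape (n_events, 2); ``intervals[i] = (start, end)``
    with both endpoints inclusive, so an event spans ``end - start + 1``
    frames.
    """

    intervals: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "intervals", iv)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if len(iv):
            if np.any(iv[:, 0] > iv[:, 1]):
                raise ValueError("event start after end")
            if np.any(iv[:, 0] < 0):
                raise ValueError("negative frame index")
            order = np.argsort(iv[:, 0], kind="stable")
            iv = iv[order]
            object.__setattr__(self, "intervals", iv)
            if np.any(iv[1:, 0] <= iv[:-1, 1]):
                raise ValueError("events overlap")

    def __len__(self) -> int:
        return len(self.intervals)

    def to_labels(self, n_frames: int) -> np.ndarray:
        """Per-frame 0/1 indicator of event membership."""
        lab = np.zeros(n_frames, dtype=np.int8)
        for s, e in self.intervals:
            lab[s : e + 1] = 1
        return lab

    @classmethod
    def from_labels(cls, labels: np.ndarray, fps: float) -> "EventSet":
        """Maximal runs of 1s in a 0/1 per-frame label vector."""
        lab = np.asarray(labels).astype(bool)
        if lab.ndim != 1:
            raise ValueError("labels must be 1-D")
        padded = np.concatenate([[False], lab, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1) - 1
        return cls(np.column_stack([starts, ends]), fps)

    def to_frame(self) -> pd.DataFrame:
        iv = self.intervals
        return pd.DataFrame(
            {
                "start_frame": iv[:, 0],
                "end_frame": iv[:, 1],
                "start_s": iv[:, 0] / self.fps,
                "end_s": iv[:, 1] / self.fps,
                "duration_s": (iv[:, 1] - iv[:, 0] + 1) / self.fps,
            }
        )


@dataclass(frozen=True)
class EventDetectionConfig:
    """Smoothing window (odd frames), probability threshold, merge gap and
    minimum duration (frames) applied in that order."""

    smoothing_window: int = 5
    threshold: float = 0.5
    min_duration: int = 1
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


@dataclass(frozen=True)
class SessionSummary:
    video_id: str
    cumulative_attack_duration_s: float
    n_events: int
    config: EventDetectionConfig = field(default_factory=EventDetectionConfig)

    def to_dict(self) -> dict:
        return {
            "video_id": self.video_id,
            "cumulative_attack_duration_s": self.cumulative_attack_duration_s,
            "n_events": self.n_events,
            "config": {
                "smoothing_window": self.config.smoothing_window,
                "threshold": self.config.threshold,
                "min_duration": self.config.min_duration,
                "merge_gap": self.config.merge_gap,
            },
        }


def moving_average(trace: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with the window shrinking at the edges.

    ``w`` must be odd so the window is symmetric around each frame; near
    the edges the mean is taken over the frames that exist, so the output
    has the same length as the input and stays inside the input's range.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ValueError("trace must be 1-D")
    if w % 2 == 0:
        raise ValueError("window must be odd")
    if w < 1 or w > len(x):
        raise ValueError("window must be in [1, len(trace)]")
    return (
        pd.Series(x).rolling(window=w, center=True, min_periods=1).mean().to_numpy()
    )


def detect_events(
    smoothed: np.ndarray, config: EventDetectionConfig, fps: float = 1.0
) -> EventSet:
    """Bound events in a smoothed probability trace.

    Three rules, applied in order: (1) maximal runs of frames strictly
    above the threshold become candidate events; (2) candidates separated
    by at most ``merge_gap`` sub-threshold frames are merged; (3) merged
    candidates shorter than ``min_duration`` frames are discarded.
    Merging precedes the duration filter so a bout fragmented by a brief
    probability dip is not thrown away piecewise.
    """
    x = np.asarray(smoothed, dtype=float)
    above = x > config.threshold
    runs = EventSet.from_labels(above, fps).intervals
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 <= config.merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    kept = [(s, e) for s, e in merged if e - s + 1 >= config.min_duration]
    return EventSet(np.array(kept, dtype=np.int64).reshape(-1, 2), fps)


def cumulative_attack_duration(events: EventSet) -> float:
    """Total seconds inside events: sum of (end - start + 1) / fps."""
    iv = events.intervals
    if not len(iv):
        return 0.0
    return float(np.sum(iv[:, 1] - iv[:, 0] + 1) / events.fps)


def event_match_metrics(
    predicted: EventSet, truth: EventSet, min_overlap: float = 0.5
) -> tuple[float, float, float]:
    """Precision / recall / F1 of predicted events against ground truth.

    A predicted event matches a truth event when their frame intersection
    covers at least ``min_overlap`` of the truth event; matching is
    one-to-one and greedy in temporal order.  With no predictions
    precision is 1; with no truth recall is 1.
    """
    if not 0.0 < min_overlap <= 1.0:
        raise ValueError("min_overlap must be in (0, 1]")
    pred = predicted.intervals
    tru = truth.intervals
    used = np.zeros(len(pred), dtype=bool)
    matched_truth = 0
    for ts, te in tru:
        tlen = te - ts + 1
        for j, (ps, pe) in enumerate(pred):
            if used[j]:
                continue
            inter = min(te, pe) - max(ts, ps) + 1
            if inter >= min_overlap * tlen:
                used[j] = True
                matched_truth += 1
                break
    precision = used.sum() / len(pred) if len(pred) else 1.0
    recall = matched_truth / len(tru) if len(tru) else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return float(precision), float(recall), float(f1)
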