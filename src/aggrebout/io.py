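"""Readers and writers for every artifact the pipeline exchanges.

All tabular formats are plain CSV with a one-line header; zone geometry
is JSON or YAML.  Video is stored as multi-page TIFF (lossless) with the
frame rate in the TIFF description tag, or as ``.npz``; AVI/MP4 reading
is attempted through imageio when such a file is handed in and a plugin
is available.  Every reader validates the schema and the invariants of
the object it constructs, naming the offending row/column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import ProbabilityTrace
from .events import EventSet, SessionSummary
from .tct import Trajectory, ZoneSet
from .video import VideoSession

__all__ = [
    "write_video", "read_video",
    "write_labels", "read_labels",
    "write_intervals", "read_intervals",
    "write_trace", "read_trace",
    "write_events", "read_events",
    "write_trajectory", "read_trajectory",
    "write_zones", "read_zones",
    "write_cohort", "read_cohort",
    "write_summary",
]

_TRAJ_COLS = [
    "time_s", "nose_x_cm", "nose_y_cm", "center_x_cm", "center_y_cm",
    "tail_x_cm", "tail_y_cm",
]
_COHORT_COLS = [
    "animal_id", "genotype", "age_months", "treatment", "session",
    "attack_duration_s",
]


# ---- video ----------------------------------------------------------------

def write_video(session: VideoSession, path: str | Path) -> None:
    """Write frames losslessly (.tif/.tiff multi-page, or .npz)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(
            path, session.frames,
            description=json.dumps(
                {"fps": session.fps, "video_id": session.video_id}
            ),
        )
    elif path.suffix.lower() == ".npz":
        np.savez_compressed(
            path, frames=session.frames, fps=session.fps,
            video_id=session.video_id,
        )
    else:
        raise ValueError(f"unsupported video format {path.suffix!r}")


def read_video(path: str | Path, fps: float | None = None) -> VideoSession:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"video file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            desc = tf.pages[0].description or "{}"
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
        return VideoSession(
            frames=frames, fps=fps or meta.get("fps", 30.0),
            video_id=meta.get("video_id", path.stem),
        )
    if suffix == ".npz":
        with np.load(path) as z:
            return VideoSession(
                frames=z["frames"], fps=float(fps or z["fps"]),
                video_id=str(z["video_id"]),
            )
    if suffix in (".avi", ".mp4", ".mov"):
        try:
            import imageio.v3 as iio

            frames = np.stack(list(iio.imiter(path)))
            meta = iio.immeta(path)
            return VideoSession(
                frames=frames, fps=fps or meta.get("fps", 30.0),
                video_id=path.stem,
            )
        except Exception as exc:  # plugin/codec missing or corrupt file
            raise OSError(
                f"could not decode {path} ({suffix} container): {exc}"
            ) from exc
    raise ValueError(f"unsupported video format {path.suffix!r}")


# ---- frame labels and ground-truth intervals ------------------------------

def write_labels(labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        {"frame_index": np.arange(len(labels)), "label": labels}
    ).to_csv(path, index=False)


def read_labels(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if list(df.columns) != ["frame_index", "label"]:
        raise ValueError(
            f"labels CSV must have columns frame_index,label; got {list(df.columns)}"
        )
    bad = ~df["label"].isin([0, 1])
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(f"invalid label {df['label'][row]!r} at row {row}")
    out = np.zeros(int(df["frame_index"].max()) + 1, dtype=np.int8)
    out[df["frame_index"].to_numpy()] = df["label"].to_numpy()
    return out


def write_intervals(events: EventSet, path: str | Path) -> None:
    iv = events.intervals
    pd.DataFrame(
        {"start_frame": iv[:, 0], "end_frame": iv[:, 1]}
    ).to_csv(path, index=False)


def read_intervals(path: str | Path, fps: float) -> EventSet:
    df = pd.read_csv(path)
    if list(df.columns) != ["start_frame", "end_frame"]:
        raise ValueError("intervals CSV must have columns start_frame,end_frame")
    return EventSet(df.to_numpy(dtype=np.int64), fps)


# ---- probability traces and detected events -------------------------------

def write_trace(trace: ProbabilityTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frame_index": np.arange(len(trace)),
            "probability": trace.probs,
        }
    ).to_csv(path, index=False, float_format="%.6g")
    meta = Path(path).with_suffix(".meta.json")
    meta.write_text(json.dumps({"fps": trace.fps, "video_id": trace.video_id}))


def read_trace(path: str | Path, fps: float | None = None) -> ProbabilityTrace:
    df = pd.read_csv(path)
    if list(df.columns) != ["frame_index", "probability"]:
        raise ValueError("trace CSV must have columns frame_index,probability")
    meta_path = Path(path).with_suffix(".meta.json")
    video_id = ""
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        fps = fps or meta.get("fps")
        video_id = meta.get("video_id", "")
    if fps is None:
        raise ValueError("fps not given and no sidecar metadata found")
    return ProbabilityTrace(
        probs=df["probability"].to_numpy(), fps=float(fps), video_id=video_id
    )


def write_events(events: EventSet, path: str | Path) -> None:
    events.to_frame().to_csv(path, index=False)


def read_events(path: str | Path, fps: float | None = None) -> EventSet:
    df = pd.read_csv(path)
    need = {"start_frame", "end_frame"}
    if not need.issubset(df.columns):
        raise ValueError(f"events CSV must contain columns {sorted(need)}")
    if fps is None:
        fps = 1.0
        if "end_s" in df.columns and len(df):
            # recover fps from a frame/second pair (end_s = end_frame / fps)
            usable = df[df["end_s"] > 0]
            if len(usable):
                row = usable.iloc[-1]
                fps = float(row["end_frame"] / row["end_s"])
    return EventSet(
        df[["start_frame", "end_frame"]].to_numpy(dtype=np.int64), fps
    )


def write_summary(summary: SessionSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2))


# ---- trajectories and zones -----------------------------------------------

def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": traj.time_s,
            "nose_x_cm": traj.nose[:, 0], "nose_y_cm": traj.nose[:, 1],
            "center_x_cm": traj.body_center[:, 0],
            "center_y_cm": traj.body_center[:, 1],
            "tail_x_cm": traj.tail_base[:, 0],
            "tail_y_cm": traj.tail_base[:, 1],
        }
    ).to_csv(path, index=False, float_format="%.4f")


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    if list(df.columns) != _TRAJ_COLS:
        raise ValueError(
            f"trajectory CSV must have columns {_TRAJ_COLS}; got {list(df.columns)}"
        )
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValueError(f"time_s not strictly increasing at row {row}")
    return Trajectory(
        time_s=t,
        nose=df[["nose_x_cm", "nose_y_cm"]].to_numpy(),
        body_center=df[["center_x_cm", "center_y_cm"]].to_numpy(),
        tail_base=df[["tail_x_cm", "tail_y_cm"]].to_numpy(),
    )


def write_zones(zones: ZoneSet, path: str | Path) -> None:
    path = Path(path)
    d = zones.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d))
    else:
        path.write_text(json.dumps(d, indent=2))


def read_zones(path: str | Path) -> ZoneSet:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return ZoneSet.from_dict(d)


# ---- cohort tables --------------------------------------------------------

def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table[_COHORT_COLS].to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"cohort CSV {path} is empty")
    missing = set(_COHORT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns {sorted(missing)}")
    neg = df["attack_duration_s"] < 0
    if neg.any():
        raise ValueError(
            f"negative attack_duration_s at row {int(df.index[neg][0])}"
        )
    dup = df.duplicated(["animal_id", "age_months", "treatment", "session"])
    if dup.any():
        raise ValueError(
            f"duplicate (animal_id, age_months, treatment, session) at row "
            f"{int(df.index[dup][0])}"
        )
    return df[_COHORT_COLS]
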