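"""Three-chamber sociability test readouts from tracked trajectories.

The tracker exports three body points (nose, body center, tail base) per
sample.  Exploration of a stimulus is scored as time with the nose within
a 2.5 cm margin of a cylinder wall, i.e. nose-to-center distance at most
cylinder radius + margin; locomotion is the body-center path length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "ZoneSet",
    "PhaseSummary",
    "default_zones",
    "proximity_time",
    "path_length",
    "phase_summary",
]


@dataclass
class Trajectory:
    """Timestamped nose / body-center / tail-base coordinates in cm.

    ``time_s`` must be strictly increasing; coordinate arrays are (n, 2).
    NaN coordinates mark tracking dropouts and are skipped by the
    analyses rather than interpolated.
    """

    time_s: np.ndarray
    nose: np.ndarray
    body_center: np.ndarray
    tail_base: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        for name in ("nose", "body_center", "tail_base"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.time_s), 2):
                raise ValueError(f"{name} must be (n_samples, 2)")
            setattr(self, name, arr)
        if len(self.time_s) and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if len(self) > 1 else 0.0


# stimulus layout of each phase: cylinder slot -> stimulus role
_PHASE_STIMULI: dict[str, dict[str, str] | None] = {
    "habituation": None,
    "test1": {"A": "stimulus1", "B": "object"},
    "test2": {"A": "familiar", "B": "unfamiliar"},
    "test3": {"A": "familiar", "B": "unfamiliar"},
}


@dataclass(frozen=True)
class ZoneSet:
    """Arena and cylinder geometry plus per-phase stimulus assignment.

    The two cylinders sit in the lateral compartments of the long axis.
    ``counterbalanced=True`` swaps which physical cylinder holds which
    stimulus, mirroring counterbalancing of sides across subjects; the
    per-cylinder dwell times are unaffected, only the stimulus labels
    move.
    """

    cylinder_centers: dict[str, tuple[float, float]]
    cylinder_radius_cm: float = 5.0
    proximity_margin_cm: float = 2.5
    compartment_bounds_cm: tuple[float, float] = (20.0, 40.0)
    arena_w_cm: float = 40.5
    arena_l_cm: float = 60.0
    phase_stimuli: dict = field(
        default_factory=lambda: {k: v for k, v in _PHASE_STIMULI.items()}
    )
    counterbalanced: bool = False

    def __post_init__(self) -> None:
        if self.proximity_margin_cm <= 0:
            raise ValueError("proximity_margin_cm must be > 0")
        if set(self.cylinder_centers) != {"A", "B"}:
            raise ValueError("cylinder_centers must have keys 'A' and 'B'")

    def stimulus_of(self, phase: str, cylinder_id: str) -> str | None:
        assignment = self.phase_stimuli.get(phase)
        if assignment is None:
            return None
        if self.counterbalanced:
            cylinder_id = {"A": "B", "B": "A"}[cylinder_id]
        return assignment[cylinder_id]

    def to_dict(self) -> dict:
        return {
            "cylinder_centers": {
                k: list(v) for k, v in self.cylinder_centers.items()
            },
            "cylinder_radius_cm": self.cylinder_radius_cm,
            "proximity_margin_cm": self.proximity_margin_cm,
            "compartment_bounds_cm": list(self.compartment_bounds_cm),
            "arena_w_cm": self.arena_w_cm,
            "arena_l_cm": self.arena_l_cm,
            "phase_stimuli": self.phase_stimuli,
            "counterbalanced": self.counterbalanced,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZoneSet":
        return cls(
            cylinder_centers={
                k: tuple(v) for k, v in d["cylinder_centers"].items()
            },
            cylinder_radius_cm=d.get("cylinder_radius_cm", 5.0),
            proximity_margin_cm=d.get("proximity_margin_cm", 2.5),
            compartment_bounds_cm=tuple(d.get("compartment_bounds_cm", (20.0, 40.0))),
            arena_w_cm=d.get("arena_w_cm", 40.5),
            arena_l_cm=d.get("arena_l_cm", 60.0),
            phase_stimuli=d.get(
                "phase_stimuli", {k: v for k, v in _PHASE_STIMULI.items()}
            ),
            counterbalanced=d.get("counterbalanced", False),
        )


def default_zones(
    arena_w_cm: float = 40.5,
    arena_l_cm: float = 60.0,
    cylinder_radius_cm: float = 5.0,
    proximity_margin_cm: float = 2.5,
    counterbalanced: bool = False,
) -> ZoneSet:
    """Standard apparatus: cylinders centered in the two lateral thirds."""
    third = arena_l_cm / 3.0
    cx = arena_w_cm / 2.0
    return ZoneSet(
        cylinder_centers={
            "A": (cx, third / 2.0),
            "B": (cx, arena_l_cm - third / 2.0),
        },
        cylinder_radius_cm=cylinder_radius_cm,
        proximity_margin_cm=proximity_margin_cm,
        compartment_bounds_cm=(third, 2 * third),
        arena_w_cm=arena_w_cm,
        arena_l_cm=arena_l_cm,
        counterbalanced=counterbalanced,
    )


def _sample_dwell(time_s: np.ndarray) -> np.ndarray:
    """Per-sample dwell: the following inter-sample interval; the last
    sample inherits the preceding one."""
    if len(time_s) == 1:
        return np.zeros(1)
    dt = np.diff(time_s)
    return np.concatenate([dt, dt[-1:]])


def proximity_time(traj: Trajectory, zones: ZoneSet, cylinder_id: str) -> float:
    """Seconds the nose spends within the proximity margin of a cylinder.

    The proximity zone is an annulus-free disc of radius
    ``cylinder_radius_cm + proximity_margin_cm`` around the cylinder
    center (the margin is measured from the wall; boundary inclusive).
    Samples with NaN nose coordinates contribute nothing.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if cylinder_id not in zones.cylinder_centers:
        raise KeyError(f"unknown cylinder {cylinder_id!r}")
    center = np.asarray(zones.cylinder_centers[cylinder_id])
    d = np.hypot(*(traj.nose - center).T)
    reach = zones.cylinder_radius_cm + zones.proximity_margin_cm
    inside = d <= reach  # NaN distance compares False
    return float(np.sum(_sample_dwell(traj.time_s)[inside]))


def path_length(traj: Trajectory, point: str = "body_center") -> float:
    """Total locomotion in cm: summed Euclidean distance between
    consecutive samples of the chosen body point; segments touching a NaN
    sample are skipped."""
    arr = getattr(traj, point)
    if len(arr) < 2:
        warnings.warn("path_length of a single-sample trajectory is 0")
        return 0.0
    seg = np.hypot(*np.diff(arr, axis=0).T)
    return float(np.nansum(seg))


@dataclass(frozen=True)
class PhaseSummary:
    """Per-phase readouts: dwell per cylinder, locomotion, and the same
    dwell times relabeled by stimulus identity (when the phase has
    stimuli)."""

    phase: str
    proximity_s: dict[str, float]
    locomotion_cm: float
    stimulus_proximity_s: dict[str, float] | None

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "proximity_s": self.proximity_s,
            "locomotion_cm": self.locomotion_cm,
            "stimulus_proximity_s": self.stimulus_proximity_s,
        }


def phase_summary(traj: Trajectory, zones: ZoneSet, phase: str) -> PhaseSummary:
    """Score one phase: both cylinders' proximity times, locomotion, and
    the stimulus-resolved relabeling under the (possibly counterbalanced)
    side assignment."""
    if phase not in zones.phase_stimuli:
        raise KeyError(f"phase {phase!r} has no stimulus assignment in ZoneSet")
    prox = {cid: proximity_time(traj, zones, cid) for cid in ("A", "B")}
    loco = path_length(traj)
    if zones.phase_stimuli[phase] is None:
        stim = None
    else:
        stim = {zones.stimulus_of(phase, cid): prox[cid] for cid in ("A", "B")}
    return PhaseSummary(
        phase=phase,
        proximity_s=prox,
        locomotion_cm=loco,
        stimulus_proximity_s=stim,
    )
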