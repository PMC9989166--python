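"""Synthetic inputs for every pipeline stage.

Three generators, all pure functions of their parameters and seed:

* :func:`simulate_ri_video` — top-view resident-intruder footage as two
  Gaussian-edged discs (a light resident, a dark intruder on a mid-grey
  background) performing reflecting random walks.  During scheduled
  attack bouts the two centers stay in contact and both animals receive
  high-frequency jitter, mimicking the tussling motion a frame-difference
  classifier keys on.  Ground-truth bout intervals are returned exactly.
* :func:`simulate_tct_session` — three-chamber-test trajectories of the
  three tracked body points (nose, body center, tail base) as a biased
  random walk whose bias field points at the two cylinders with strength
  proportional to the configured preference weights.
* :func:`simulate_cohort` — per-animal attack-duration tables with
  genotype, age and treatment effects on the log scale, between-subject
  heterogeneity, and occasional exact-zero sessions.

Attack frames default to roughly 1% of all frames, the prevalence regime
reported for real resident-intruder recordings, which is what makes the
class-imbalance handling in the classifier worth testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventSet
from .tct import Trajectory, ZoneSet, default_zones
from .video import VideoSession

__all__ = [
    "SimVideoParams",
    "SimTctParams",
    "SimCohortParams",
    "simulate_ri_video",
    "simulate_tct_session",
    "simulate_cohort",
    "TCT_PHASES",
]

TCT_PHASES = ("habituation", "test1", "test2", "test3")


# --------------------------------------------------------------------------
# resident-intruder video


@dataclass(frozen=True)
class SimVideoParams:
    """Geometry, photometry and kinematics of the simulated R-I session.

    Intensities are 8-bit grayscale levels and must satisfy
    ``resident > background > intruder`` (light-coated resident, dark
    intruder).  ``attack_rate`` is expected bouts per minute; with the
    default rate and bout durations the attack-frame prevalence is about
    1%.  Speeds are px/frame.
    """

    width_px: int = 64
    height_px: int = 64
    fps: float = 15.0
    duration_s: float = 120.0
    resident_intensity: float = 220.0
    intruder_intensity: float = 40.0
    background_intensity: float = 128.0
    blob_radius_px: int = 6
    walk_speed: float = 1.5
    attack_rate: float = 0.25
    bout_duration_s: tuple[float, float] = (1.5, 3.5)
    attack_jitter: float = 3.0
    contact_distance_px: float = 10.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be positive")
        if not (
            self.resident_intensity
            > self.background_intensity
            > self.intruder_intensity
        ):
            raise ValueError(
                "need resident_intensity > background_intensity > intruder_intensity"
            )
        if self.attack_rate < 0:
            raise ValueError("attack_rate must be >= 0")
        lo, hi = self.bout_duration_s
        if not 0 < lo <= hi:
            raise ValueError("bout_duration_s must satisfy 0 < min <= max")
        if self.blob_radius_px < 1:
            raise ValueError("blob_radius_px must be >= 1")


def _schedule_bouts(params: SimVideoParams, rng: np.random.Generator) -> np.ndarray:
    """Poisson bout starts, thinned so bouts never overlap.

    Returns closed frame intervals (n, 2).  A 1-s refractory gap between
    bouts keeps events distinct after thinning.
    """
    n_frames = int(round(params.duration_s * params.fps))
    expected = params.attack_rate * params.duration_s / 60.0
    n = rng.poisson(expected)
    if n == 0:
        return np.empty((0, 2), dtype=np.int64)
    starts = np.sort(rng.uniform(0.0, params.duration_s, size=n))
    durs = rng.uniform(*params.bout_duration_s, size=n)
    kept: list[tuple[int, int]] = []
    last_end_s = -np.inf
    for t0, d in zip(starts, durs):
        if t0 < last_end_s + 1.0:  # refractory: drop overlapping bout
            continue
        t1 = min(t0 + d, params.duration_s)
        s = int(round(t0 * params.fps))
        e = min(int(round(t1 * params.fps)) - 1, n_frames - 1)
        if e >= s:
            kept.append((s, e))
            last_end_s = t1
    return np.array(kept, dtype=np.int64).reshape(-1, 2)


def simulate_ri_video(params: SimVideoParams) -> tuple[VideoSession, EventSet]:
    """Render a resident-intruder session and its ground-truth bouts.

    Outside bouts the two animals walk independently (with a soft mutual
    repulsion so chance near-contacts are rare); inside a bout the
    intruder is kept within ``contact_distance_px`` of the resident and
    both centers receive zero-mean jitter of scale ``attack_jitter`` each
    frame.  Every frame inside a returned interval satisfies the contact
    constraint exactly.  Identical params (including seed) give
    bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    H, W = params.height_px, params.width_px
    r = params.blob_radius_px
    n_frames = int(round(params.duration_s * params.fps))
    bouts = _schedule_bouts(params, rng)
    in_bout = np.zeros(n_frames, dtype=bool)
    for s, e in bouts:
        in_bout[s : e + 1] = True

    lo = np.array([r, r], dtype=float)
    hi = np.array([W - 1 - r, H - 1 - r], dtype=float)

    def reflect(p: np.ndarray) -> np.ndarray:
        # fold coordinates back into [lo, hi]
        span = hi - lo
        q = np.mod(p - lo, 2 * span)
        q = np.where(q > span, 2 * span - q, q)
        return lo + q

    res = rng.uniform(lo, hi)
    intr = rng.uniform(lo, hi)
    centers = np.empty((n_frames, 2, 2), dtype=float)  # (t, animal, xy)
    sep_min = 1.6 * params.contact_distance_px
    for t in range(n_frames):
        if in_bout[t]:
            res = reflect(res + rng.normal(0, 0.5 * params.walk_speed, 2))
            res += rng.normal(0, params.attack_jitter, 2)
            res = np.clip(res, lo, hi)
            intr = intr + rng.normal(0, params.attack_jitter, 2)
            intr = np.clip(intr, lo, hi)
            d = intr - res
            dist = float(np.hypot(*d))
            if dist > params.contact_distance_px:
                # pull onto the contact disc; box is convex so this stays in bounds
                intr = res + d * (params.contact_distance_px / dist)
        else:
            res = reflect(res + rng.normal(0, params.walk_speed, 2))
            intr = reflect(intr + rng.normal(0, params.walk_speed, 2))
            d = intr - res
            dist = float(np.hypot(*d))
            if dist < sep_min:
                u = d / dist if dist > 1e-9 else np.array([1.0, 0.0])
                res = np.clip(res - u * (sep_min - dist) / 2, lo, hi)
                intr = np.clip(intr + u * (sep_min - dist) / 2, lo, hi)
        centers[t, 0] = res
        centers[t, 1] = intr

    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    edge = 1.5  # px of linear intensity falloff at the disc rim
    frames = np.empty((n_frames, H, W), dtype=np.uint8)
    for t in range(n_frames):
        img = np.full((H, W), params.background_intensity, dtype=float)
        for animal, level in (
            (0, params.resident_intensity),
            (1, params.intruder_intensity),
        ):
            cx, cy = centers[t, animal]
            dist = np.hypot(xs - cx, ys - cy)
            alpha = np.clip((r + edge - dist) / edge, 0.0, 1.0)
            img = img * (1 - alpha) + level * alpha
        img += rng.normal(0, params.noise_sd, size=img.shape)
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)

    labels = in_bout.astype(np.int8)
    session = VideoSession(
        frames=frames, fps=params.fps, labels=labels,
        video_id=f"sim-ri-{params.seed}",
        meta={"centers_px": centers},  # (t, animal, xy) ground truth
    )
    return session, EventSet(bouts, params.fps)


# --------------------------------------------------------------------------
# three-chamber test


@dataclass(frozen=True)
class SimTctParams:
    """Arena geometry and kinematics of the simulated three-chamber test.

    Defaults reproduce the physical apparatus: a 40.5 x 60 cm arena split
    into three compartments along the long axis, with a 5 cm-radius wired
    cylinder in each lateral compartment.  ``preference_weights`` set the
    relative attraction toward (cylinder A, cylinder B); equal weights
    give symmetric dwell.  Default speed of 6 cm/s yields ~3600 cm of
    locomotion per 10-min phase, the magnitude seen in real sessions.
    """

    arena_w_cm: float = 40.5
    arena_l_cm: float = 60.0
    cylinder_radius_cm: float = 5.0
    sample_rate_hz: float = 12.5
    phase_duration_s: float = 600.0
    preference_weights: tuple[float, float] = (1.0, 1.0)
    speed_cm_s: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arena_w_cm <= 0 or self.arena_l_cm <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.sample_rate_hz <= 0 or self.phase_duration_s <= 0:
            raise ValueError("sample_rate_hz and phase_duration_s must be positive")
        if any(w < 0 for w in self.preference_weights):
            raise ValueError("preference_weights must be >= 0")
        if self.speed_cm_s < 0:
            raise ValueError("speed_cm_s must be >= 0")


_NOSE_OFFSET_CM = 3.0
_TAIL_OFFSET_CM = 4.0


def simulate_tct_session(
    params: SimTctParams, phase: str
) -> tuple[Trajectory, ZoneSet]:
    """Simulate one phase of the three-chamber test.

    The body center follows a persistent random walk; in test phases a
    bias field pulls it toward each cylinder with strength proportional
    to that cylinder's preference weight, producing controllable dwell
    preference.  Nose and tail base are placed ahead of / behind the body
    center along the heading.  During habituation no bias is applied.
    """
    if phase not in TCT_PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {TCT_PHASES}")
    rng = np.random.default_rng(params.seed)
    zones = default_zones(
        arena_w_cm=params.arena_w_cm,
        arena_l_cm=params.arena_l_cm,
        cylinder_radius_cm=params.cylinder_radius_cm,
    )
    cyl = np.array([zones.cylinder_centers["A"], zones.cylinder_centers["B"]])
    weights = np.asarray(params.preference_weights, dtype=float)
    if phase == "habituation":
        weights = np.zeros(2)

    n = int(round(params.phase_duration_s * params.sample_rate_hz))
    dt = 1.0 / params.sample_rate_hz
    step = params.speed_cm_s * dt
    lo = np.zeros(2)
    hi = np.array([params.arena_w_cm, params.arena_l_cm])
    exclude = params.cylinder_radius_cm + 1.0  # body cannot enter the cylinder

    p = np.array([params.arena_w_cm / 2, params.arena_l_cm / 2])
    heading = np.array([1.0, 0.0])
    v = heading.copy()
    pos = np.empty((n, 2))
    headings = np.empty((n, 2))

    # Exploration is bout-structured: the walk alternates between free
    # roaming and seek excursions toward one cylinder.  Excursion targets
    # are stride-scheduled (largest weighted dwell deficit first) so the
    # long-run dwell near each cylinder tracks preference_weights without
    # multinomial visit noise.
    bias_gain = 0.6
    seek_s, roam_s = 12.0, 8.0
    w_sum = float(weights.sum())
    state = "roam"
    t_state = roam_s / 2.0
    target = 0
    spent = np.zeros(2)
    total_seek = 0.0
    for t in range(n):
        if step > 0:
            if w_sum > 0:
                t_state -= dt
                if state == "roam" and t_state <= 0:
                    share = weights / w_sum
                    target = int(np.argmax(share * total_seek - spent
                                           + share * 1e-9))
                    state, t_state = "seek", seek_s
                elif state == "seek":
                    spent[target] += dt
                    total_seek += dt
                    if t_state <= 0:
                        state, t_state = "roam", roam_s
            if state == "seek":
                d = cyl[target] - p
                dist = np.hypot(*d)
                bias = bias_gain * d / dist if dist > 1e-9 else np.zeros(2)
            else:
                bias = np.zeros(2)
            v = 0.85 * v + rng.normal(0, 0.6, 2) + bias
            norm = np.hypot(*v)
            if norm > 1e-9:
                heading = v / norm
            p = p + heading * step
            # reflect off arena walls
            for ax in range(2):
                if p[ax] < lo[ax]:
                    p[ax] = 2 * lo[ax] - p[ax]
                    v[ax] = -v[ax]
                elif p[ax] > hi[ax]:
                    p[ax] = 2 * hi[ax] - p[ax]
                    v[ax] = -v[ax]
            p = np.clip(p, lo, hi)
            # keep the body outside each cylinder footprint
            for k in range(2):
                d = p - cyl[k]
                dist = np.hypot(*d)
                if dist < exclude:
                    u = d / dist if dist > 1e-9 else np.array([1.0, 0.0])
                    p = cyl[k] + u * exclude
                    v = v - 2 * np.dot(v, u) * u  # bounce tangentially
            p = np.clip(p, lo, hi)
        pos[t] = p
        headings[t] = heading

    nose = np.clip(pos + _NOSE_OFFSET_CM * headings, lo, hi)
    tail = np.clip(pos - _TAIL_OFFSET_CM * headings, lo, hi)
    time_s = np.arange(n) * dt
    traj = Trajectory(
        time_s=time_s, nose=nose, body_center=pos, tail_base=tail
    )
    return traj, zones


# --------------------------------------------------------------------------
# cohort tables


@dataclass(frozen=True)
class SimCohortParams:
    """Design and effect sizes of the simulated longitudinal cohort.

    One resident per row of ``n_per_genotype`` in each of two genotypes
    (control SAMR1-like, aggression-prone SAMP8-like), tested monthly at
    ``ages_months``.  At the final age each animal is tested twice in a
    cross-over (vehicle and drug); earlier ages are untreated single
    sessions.  Effects act additively on log attack duration:
    ``genotype_effect`` from ``onset_age_months`` onward in the prone
    line, ``treatment_effect`` under drug.  ``zero_prob`` injects exact
    zeros (sessions without a single attack), the feature that motivates
    the zero-safe log transform downstream.
    """

    n_per_genotype: int = 18
    ages_months: tuple[int, ...] = (4, 5, 6, 7)
    genotype_effect: float = 0.8
    onset_age_months: int = 5
    treatment_effect: float = -1.0
    subject_sd: float = 0.6
    residual_sd: float = 0.5
    zero_prob: float = 0.15
    baseline_log_s: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_genotype < 2:
            raise ValueError("n_per_genotype must be >= 2")
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.zero_prob <= 1.0:
            raise ValueError("zero_prob must be in [0, 1]")
        if len(self.ages_months) == 0:
            raise ValueError("ages_months must be non-empty")


GENOTYPES = ("SAMR1", "SAMP8")


def simulate_cohort(params: SimCohortParams) -> pd.DataFrame:
    """Long-format cohort table of per-session attack durations.

    Columns: animal_id, genotype, age_months, treatment, session,
    attack_duration_s.  Durations are exp of a normal linear model on the
    log scale, clamped to [0, 600] s (a 10-min session), with exact zeros
    injected at ``zero_prob``.
    """
    rng = np.random.default_rng(params.seed)
    final_age = max(params.ages_months)
    rows = []
    for g in GENOTYPES:
        for i in range(params.n_per_genotype):
            animal = f"{g}-{i:03d}"
            u = rng.normal(0, params.subject_sd)
            for age in params.ages_months:
                treatments = (
                    ("vehicle", "drug") if age == final_age else ("none",)
                )
                for session, trt in enumerate(treatments):
                    mu = params.baseline_log_s + u
                    if g == "SAMP8" and age >= params.onset_age_months:
                        mu += params.genotype_effect
                    if trt == "drug":
                        mu += params.treatment_effect
                    y = float(np.exp(mu + rng.normal(0, params.residual_sd)))
                    if rng.uniform() < params.zero_prob:
                        y = 0.0
                    rows.append(
                        {
                            "animal_id": animal,
                            "genotype": g,
                            "age_months": age,
                            "treatment": trt,
                            "session": session,
                            "attack_duration_s": min(y, 600.0),
                        }
                    )
    return pd.DataFrame(rows)
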