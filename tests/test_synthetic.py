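"""Generator contracts: determinism, ground-truth consistency, and the
statistical structure the downstream analyses assume."""

import numpy as np
import pytest

import aggrebout as ab
from aggrebout.synthetic import GENOTYPES


class TestRiVideo:
    def test_no_bouts_when_rate_zero(self):
        v, ev = ab.simulate_ri_video(
            ab.SimVideoParams(duration_s=30, attack_rate=0.0, seed=1)
        )
        assert len(ev) == 0
        assert v.labels.sum() == 0

    def test_same_seed_bit_identical(self):
        p = ab.SimVideoParams(duration_s=20, attack_rate=2.0, seed=5)
        v1, e1 = ab.simulate_ri_video(p)
        v2, e2 = ab.simulate_ri_video(p)
        assert np.array_equal(v1.frames, v2.frames)
        assert np.array_equal(e1.intervals, e2.intervals)

    def test_labels_match_intervals(self):
        v, ev = ab.simulate_ri_video(
            ab.SimVideoParams(duration_s=60, attack_rate=3.0, seed=2)
        )
        assert np.array_equal(v.labels, ev.to_labels(v.n_frames))

    def test_contact_constraint_inside_bouts(self):
        """Every frame inside a bout satisfies the bout's geometric
        definition exactly: blob centers within the contact distance."""
        p = ab.SimVideoParams(duration_s=60, attack_rate=3.0, noise_sd=0.0,
                              seed=3)
        v, ev = ab.simulate_ri_video(p)
        centers = v.meta["centers_px"]
        assert len(ev) > 0
        for s, e in ev.intervals:
            sep = np.hypot(
                *(centers[s : e + 1, 0] - centers[s : e + 1, 1]).T
            )
            assert np.all(sep <= p.contact_distance_px + 1e-9)

    def test_rendered_peaks_track_centers(self):
        """The intensity extrema of the two coats stay close to the
        ground-truth centers (rendering consistency; occlusion during
        contact allows a few px of slack)."""
        p = ab.SimVideoParams(duration_s=20, attack_rate=3.0, noise_sd=0.0,
                              seed=3)
        v, _ = ab.simulate_ri_video(p)
        centers = v.meta["centers_px"]
        cut = (p.background_intensity + p.intruder_intensity) / 2
        for t in range(0, v.n_frames, 10):
            ys, xs = np.nonzero(v.frames[t] < cut)  # dark-coat mask
            centroid = np.array([xs.mean(), ys.mean()])
            assert np.hypot(*(centers[t, 1] - centroid)) <= 2.0

    def test_prevalence_near_one_percent(self):
        """Default bout rate yields the rare-event regime: attack frames
        are 0.5-2% of an hour of footage."""
        tot = pos = 0
        for seed in range(30):  # 30 x 2 min = 60 min
            v, _ = ab.simulate_ri_video(ab.SimVideoParams(seed=seed))
            tot += v.n_frames
            pos += int(v.labels.sum())
        assert 0.005 <= pos / tot <= 0.02

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ab.SimVideoParams(width_px=0)
        with pytest.raises(ValueError):
            ab.SimVideoParams(fps=-1)
        with pytest.raises(ValueError):
            ab.SimVideoParams(resident_intensity=50)  # darker than background

    def test_intensity_ordering_visible(self):
        v, _ = ab.simulate_ri_video(
            ab.SimVideoParams(duration_s=5, noise_sd=0.0, seed=4)
        )
        f = v.frames[0].astype(float)
        assert f.max() > 200 and f.min() < 60  # light and dark coat present


class TestTctSession:
    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            ab.simulate_tct_session(ab.SimTctParams(), "test9")

    def test_zero_speed_zero_path(self):
        traj, _ = ab.simulate_tct_session(
            ab.SimTctParams(speed_cm_s=0.0, phase_duration_s=30), "test1"
        )
        assert ab.path_length(traj) == 0.0

    def test_confined_to_arena(self):
        p = ab.SimTctParams(phase_duration_s=120, seed=9)
        traj, _ = ab.simulate_tct_session(p, "test2")
        for arr in (traj.nose, traj.body_center, traj.tail_base):
            assert arr[:, 0].min() >= 0 and arr[:, 0].max() <= p.arena_w_cm
            assert arr[:, 1].min() >= 0 and arr[:, 1].max() <= p.arena_l_cm

    def test_equal_weights_symmetric_dwell(self):
        """With equal preference the long-run dwell near the two cylinders
        differs by <10% (100 simulated minutes)."""
        p = ab.SimTctParams(phase_duration_s=6000, seed=21)
        traj, zones = ab.simulate_tct_session(p, "test1")
        ta = ab.proximity_time(traj, zones, "A")
        tb = ab.proximity_time(traj, zones, "B")
        assert ta > 0 and tb > 0
        assert abs(ta - tb) / max(ta, tb) < 0.10

    def test_preference_weights_shift_dwell(self):
        p = ab.SimTctParams(
            phase_duration_s=1200, preference_weights=(3.0, 1.0), seed=4
        )
        traj, zones = ab.simulate_tct_session(p, "test1")
        assert ab.proximity_time(traj, zones, "A") > ab.proximity_time(
            traj, zones, "B"
        )

    def test_determinism(self):
        p = ab.SimTctParams(phase_duration_s=30, seed=8)
        t1, _ = ab.simulate_tct_session(p, "test1")
        t2, _ = ab.simulate_tct_session(p, "test1")
        assert np.array_equal(t1.body_center, t2.body_center)


class TestCohort:
    def test_schema_and_design(self):
        p = ab.SimCohortParams(seed=1)
        df = ab.simulate_cohort(p)
        assert set(df.genotype) == set(GENOTYPES)
        assert df.attack_duration_s.between(0, 600).all()
        # cross-over at the final age: two sessions per animal
        final = df[df.age_months == max(p.ages_months)]
        assert set(final.treatment) == {"vehicle", "drug"}
        assert final.groupby("animal_id").size().eq(2).all()

    def test_all_zero_when_zero_prob_one(self):
        df = ab.simulate_cohort(ab.SimCohortParams(zero_prob=1.0, seed=2))
        assert (df.attack_duration_s == 0).all()

    def test_determinism(self):
        p = ab.SimCohortParams(seed=3)
        assert ab.simulate_cohort(p).equals(ab.simulate_cohort(p))

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            ab.SimCohortParams(n_per_genotype=1)

    def test_log_scale_marginals_converge(self):
        """At n = 10000 subjects/genotype the mean log-duration contrast
        between genotypes (post-onset, untreated) matches the configured
        effect within 3 standard errors."""
        p = ab.SimCohortParams(
            n_per_genotype=10000, ages_months=(6, 7), onset_age_months=5,
            genotype_effect=0.8, zero_prob=0.0, seed=4,
        )
        df = ab.simulate_cohort(p)
        sub = df[(df.age_months == 6) & (df.treatment == "none")]
        logs = np.log(sub.attack_duration_s.to_numpy())
        g = sub.genotype.to_numpy()
        diff = logs[g == "SAMP8"].mean() - logs[g == "SAMR1"].mean()
        sd = np.sqrt(p.subject_sd**2 + p.residual_sd**2)
        se = sd * np.sqrt(2 / p.n_per_genotype)
        assert abs(diff - p.genotype_effect) < 3 * se
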