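import numpy as np
import pytest

from posturekit.annotation import NONE_LABEL, sample_labels
from posturekit.errors import ConfigError
from posturekit.synthetic import (
    GUIDED_ACTIVITIES,
    default_guided_schedule,
    default_signatures,
    make_reliability_track,
    simulate_cohort,
    simulate_session,
)

from conftest import quiet_signatures, short_schedule


class TestDefaultGuidedSchedule:
    def test_sitting_elicited_in_at_least_two_guided_segments(self):
        sched = default_guided_schedule(seed=0)
        guided = sched.entries[: len(GUIDED_ACTIVITIES)]
        sitting = [e for e in guided if e.label == "sitting"]
        assert len(sitting) >= 2  # floor sitting and highchair

    def test_total_duration_about_fifteen_minutes_plus_gaps(self):
        sched = default_guided_schedule(seed=0)
        activity_s = sum(e.duration_s for e in sched.entries)
        assert activity_s == pytest.approx(9 * 60 + 300)
        assert sched.total_s > activity_s  # gaps and lead-in/out on top

    def test_free_play_bouts_in_range(self):
        sched = default_guided_schedule(seed=1)
        free = sched.entries[len(GUIDED_ACTIVITIES):]
        assert all(5.0 <= e.duration_s <= 30.0 for e in free[:-1])

    def test_young_profile_has_no_upright(self):
        sched = default_guided_schedule(seed=2, ability="young")
        assert all(e.label != "upright" for e in sched.entries)

    def test_two_sync_impulses_scheduled(self):
        sched = default_guided_schedule(seed=0)
        assert 0 < sched.opening_sync_s < sched.lead_in_s
        assert sched.total_s - sched.lead_out_s < sched.closing_sync_s < sched.total_s


class TestSimulateSession:
    def test_zero_noise_supine_segment_constant_gravity(self):
        sigs = quiet_signatures()
        sched = short_schedule()
        session = simulate_session(sched, signatures=sigs, seed=0)
        # supine is the second 30-s segment
        on, off, _, label = sched.segments()[1]
        assert label == "supine"
        grid = session.truth_grid
        m = (grid >= on + 1) & (grid < off - 1)
        hip = session.recording.sensors["right_hip"]
        block = hip.accel[m]
        assert np.allclose(block, block[0], atol=1e-12)
        assert np.linalg.norm(block[0]) == pytest.approx(1.0, abs=1e-9)

    def test_static_positions_have_unit_accel_magnitude(self):
        session = simulate_session(short_schedule(), signatures=quiet_signatures(), seed=1)
        static = np.isin(session.truth_labels, ["supine", "prone", "sitting", "held"])
        # exclude the impulse neighbourhood
        static[:300] = False
        for series in session.recording.sensors.values():
            mags = np.linalg.norm(series.accel[static], axis=1)
            np.testing.assert_allclose(mags, 1.0, atol=1e-9)

    def test_same_seed_bit_identical(self):
        s1 = simulate_session(short_schedule(seed=5), seed=5)
        s2 = simulate_session(short_schedule(seed=5), seed=5)
        for p in s1.recording.placements:
            np.testing.assert_array_equal(
                s1.recording.sensors[p].accel, s2.recording.sensors[p].accel
            )
            np.testing.assert_array_equal(
                s1.recording.sensors[p].timestamps, s2.recording.sensors[p].timestamps
            )
        assert list(s1.truth_labels) == list(s2.truth_labels)

    def test_scheduled_durations_equal_annotated_durations(self):
        sched = short_schedule(seed=2)
        session = simulate_session(sched, seed=2)
        by_label: dict[str, float] = {}
        for e in session.track.events:
            by_label[e.label] = by_label.get(e.label, 0.0) + e.duration
        expected: dict[str, float] = {}
        for entry in sched.entries:
            expected[entry.label] = expected.get(entry.label, 0.0) + entry.duration_s
        for label, dur in expected.items():
            assert by_label[label] == pytest.approx(dur)

    def test_truth_labels_match_annotation_on_session_clock(self, short_session):
        shifted = short_session.track.shifted(-short_session.video_sync_opening)
        # annotation clock zeroes at the sync impulse; truth grid starts at
        # session t=0, opening_sync_s earlier
        session_track = shifted.shifted(short_session.schedule.opening_sync_s)
        expected = sample_labels(session_track, short_session.truth_grid)
        # shifting by the float video offset wobbles boundaries by ~1 ulp,
        # so compare away from event edges
        boundaries = np.array(
            [t for e in session_track.events for t in (e.onset, e.offset)]
        )
        dist = np.abs(short_session.truth_grid[:, None] - boundaries[None, :]).min(axis=1)
        interior = dist > 1e-6
        assert interior.mean() > 0.99
        np.testing.assert_array_equal(
            expected[interior], short_session.truth_labels[interior]
        )

    def test_window_prevalence_recovers_schedule_proportions(self, short_session):
        labels = short_session.truth_labels
        coded = labels[labels != NONE_LABEL]
        sched = short_session.schedule
        total = sum(e.duration_s for e in sched.entries)
        for entry in sched.entries:
            share = (coded == entry.label).mean()
            assert share == pytest.approx(entry.duration_s / total, abs=0.02)

    def test_missing_signature_rejected(self):
        sigs = default_signatures()
        del sigs["prone"]
        with pytest.raises(ConfigError, match="prone"):
            simulate_session(short_schedule(), signatures=sigs, seed=0)

    def test_eight_g_impulses_visible_in_every_sensor(self, short_session):
        rate = short_session.recording.nominal_rate
        i = int(round(short_session.schedule.opening_sync_s * rate))
        for series in short_session.recording.sensors.values():
            assert np.linalg.norm(series.accel[i]) == pytest.approx(8.0, abs=0.01)


class TestSimulateCohort:
    def test_distinct_seeds_and_ids(self):
        cohort = simulate_cohort(n_participants=4, seed=3, free_play_s=20.0)
        seeds = {p.session.seed for p in cohort}
        assert len(seeds) == 4
        assert [p.participant_id for p in cohort] == ["P01", "P02", "P03", "P04"]

    def test_young_profile_sessions_lack_upright(self):
        cohort = simulate_cohort(
            n_participants=2, ability_profiles=["young", "standard"], seed=0,
            free_play_s=20.0,
        )
        young_labels = {e.label for e in cohort[0].session.track.events}
        assert "upright" not in young_labels
        standard_labels = {e.label for e in cohort[1].session.track.events}
        assert "upright" in standard_labels

    def test_profile_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            simulate_cohort(n_participants=3, ability_profiles=["standard"])


def test_reliability_track_preserves_labels_and_jitters_boundaries():
    session = simulate_session(short_schedule(seed=9), seed=9)
    rel = make_reliability_track(session.track, seed=1, max_shift_s=0.2)
    assert len(rel.events) == len(session.track.events)
    for a, b in zip(session.track.events, rel.events):
        assert a.label == b.label
        assert abs(a.onset - b.onset) <= 0.2 + 1e-9
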