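"""Detection-log processing: burst deduplication, camera-day binning,
response-curve proportions, and the encounter-interval arithmetic."""

import logging
from datetime import timedelta

import numpy as np
import pytest

from fearcurve import eval_arps
from fearcurve.response_curves import (
    HUMAN,
    build_camera_days,
    compute_response_curve,
    deduplicate_events,
    encounter_interval,
    read_curve,
    read_events,
    write_curve,
)
from fearcurve.synthetic_data import simulate_response_data

from conftest import ev


# ---------------------------------------------------------------------------
# Deduplication


def brute_force_merge_count(times, window_minutes):
    """O(n^2) oracle: connected components of the 'within window' graph.

    For time-sorted events, pairwise closeness components coincide with
    chains of consecutive gaps below the window, which is what the merge
    must implement.
    """
    n = len(times)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs((times[i] - times[j]).total_seconds()) < window_minutes * 60:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def test_human_records_within_hour_collapse():
    events = [ev("c1", "2010-05-01T09:00", HUMAN), ev("c1", "2010-05-01T09:30", HUMAN)]
    assert len(deduplicate_events(events)) == 1


def test_human_records_two_hours_apart_stay_separate():
    events = [ev("c1", "2010-05-01T09:00", HUMAN), ev("c1", "2010-05-01T11:00", HUMAN)]
    assert len(deduplicate_events(events)) == 2


def test_mammal_chain_merges_through_consecutive_gaps():
    """10:00 / 10:03 / 10:06 coyote events chain into one record even though
    the endpoints are 6 min apart: merging uses consecutive gaps."""
    events = [
        ev("c1", "2010-05-01T10:00", "coyote"),
        ev("c1", "2010-05-01T10:03", "coyote"),
        ev("c1", "2010-05-01T10:06", "coyote"),
    ]
    out = deduplicate_events(events)
    assert len(out) == 1
    assert out[0].timestamp.isoformat() == "2010-05-01T10:00:00"
    assert out[0].n == 3  # individuals summed, not lost


def test_merge_keeps_streams_separate():
    """Humans and each mammal taxon deduplicate independently."""
    events = [
        ev("c1", "2010-05-01T10:00", "coyote"),
        ev("c1", "2010-05-01T10:02", HUMAN),
        ev("c1", "2010-05-01T10:04", "bobcat"),
        ev("c2", "2010-05-01T10:04", "coyote"),
    ]
    assert len(deduplicate_events(events)) == 4


def test_dedup_matches_bruteforce_oracle_and_is_idempotent(rng):
    """Random event sets of up to 50 events: the chained merge equals the
    O(n^2) pairwise component oracle, and a second pass changes nothing."""
    for trial in range(30):
        n = int(rng.integers(1, 51))
        subject = HUMAN if trial % 2 == 0 else "mule_deer"
        window = 60 if subject == HUMAN else 5
        base = ev("c1", "2012-07-01T00:00", subject).timestamp
        times = sorted(
            base + timedelta(minutes=float(m))
            for m in rng.uniform(0, 60 if window == 5 else 2000, n)
        )
        events = [ev("c1", t.isoformat(), subject) for t in times]
        once = deduplicate_events(events)
        assert len(once) == brute_force_merge_count(times, window)
        assert deduplicate_events(once) == once


# ---------------------------------------------------------------------------
# Camera-days


def test_camera_day_counts_humans_and_flags_taxa():
    events = deduplicate_events(
        [
            ev("c1", "2010-05-01T06:00", HUMAN),
            ev("c1", "2010-05-01T09:00", HUMAN),
            ev("c1", "2010-05-01T12:00", HUMAN),
            ev("c1", "2010-05-01T22:00", "bobcat"),
        ]
    )
    days = build_camera_days(events)
    assert len(days) == 1
    assert days[0].human_count == 3
    assert days[0].detected == {"bobcat": 1}


def test_humans_only_day_has_zero_detections():
    events = [ev("c1", "2010-05-01T06:00", HUMAN), ev("c1", "2010-05-02T07:00", "coyote")]
    days = build_camera_days(deduplicate_events(events))
    assert days[0].human_count == 1 and days[0].detected["coyote"] == 0
    assert days[1].human_count == 0 and days[1].detected["coyote"] == 1


def test_two_cameras_same_day_yield_two_rows():
    events = [ev("c1", "2010-05-01T06:00", "puma"), ev("c2", "2010-05-01T06:00", "puma")]
    assert len(build_camera_days(events)) == 2


def test_empty_input_gives_empty_output():
    assert build_camera_days([]) == []


def test_rolling_window_counts_previous_evening():
    """A 23:30 human record lands in the next day's 24-h look-back under the
    rolling window, but not under calendar binning."""
    events = [
        ev("c1", "2010-05-01T23:30", HUMAN),
        ev("c1", "2010-05-02T08:00", "coyote"),
    ]
    cal = build_camera_days(deduplicate_events(events), window="calendar")
    roll = build_camera_days(deduplicate_events(events), window="rolling")
    day2_cal = [d for d in cal if d.date.day == 2][0]
    day2_roll = [d for d in roll if d.date.day == 2][0]
    assert day2_cal.human_count == 0
    assert day2_roll.human_count == 1


# ---------------------------------------------------------------------------
# Response curves


def test_response_proportion_arithmetic():
    """10 camera-days at x=0 with 7 detections -> point (0, 0.7, 10)."""
    events = []
    for i in range(10):
        day = f"2010-06-{i + 1:02d}"
        if i < 7:
            events.append(ev("c1", f"{day}T06:00", "bobcat"))
        else:
            events.append(ev("c1", f"{day}T06:00", "coyote"))
    days = build_camera_days(deduplicate_events(events), taxa=["bobcat", "coyote"])
    curve = compute_response_curve(days, "bobcat", min_days=5)
    assert curve.x.tolist() == [0.0]
    assert curve.y[0] == pytest.approx(0.7)
    assert curve.n_days[0] == 10


def test_all_detected_level_gives_unity():
    events = [ev("c1", f"2010-06-{i + 1:02d}T06:00", "puma") for i in range(6)]
    days = build_camera_days(events)
    curve = compute_response_curve(days, "puma", min_days=5)
    assert curve.y[0] == 1.0


def test_missing_taxon_raises_with_name():
    events = [ev("c1", "2010-06-01T06:00", "puma")]
    with pytest.raises(KeyError, match="wolverine"):
        compute_response_curve(build_camera_days(events), "wolverine")


def test_no_day_lost_or_double_counted(rng):
    """Sum of supporting day counts over levels equals the number of
    camera-days with human_count <= max_x (min_days=1)."""
    events = []
    for i in range(40):
        day = f"2011-03-{(i % 28) + 1:02d}"
        cam = f"c{i % 3}"
        for _ in range(int(rng.integers(0, 4))):
            events.append(ev(cam, f"{day}T{int(rng.integers(6, 20)):02d}:00", HUMAN))
        if rng.random() < 0.6:
            events.append(ev(cam, f"{day}T05:00", "coyote"))
    days = build_camera_days(deduplicate_events(events))
    assert any(d.detected["coyote"] for d in days)  # seeded draw has coyote days
    curve = compute_response_curve(days, "coyote", max_x=2, min_days=1)
    expected = sum(1 for d in days if d.human_count <= 2)
    assert int(curve.n_days.sum()) == expected


def test_simulated_curve_within_binomial_error(combined_params):
    """At 2000 days per level, every observed proportion lies within 3
    binomial standard errors of the generating Arps curve."""
    curve = simulate_response_data(combined_params, "arps", range(16), 2000, rng=7)
    truth = eval_arps(curve.x, combined_params)
    se = np.sqrt(truth * (1 - truth) / 2000)
    assert np.all(np.abs(curve.y - truth) <= 3 * se + 1e-12)


# ---------------------------------------------------------------------------
# Encounter intervals


@pytest.mark.parametrize(
    "visitors, minutes",
    [(20.0, 72.0), (1.0, 1440.0), (2.0, 720.0)],
)
def test_encounter_interval_exact(visitors, minutes):
    assert encounter_interval(visitors) == pytest.approx(minutes, rel=1e-12)


def test_encounter_interval_one_more_visitor():
    """Adding the 21st visitor shortens the interval from 72 to 68.6 min."""
    assert round(encounter_interval(21.0), 1) == 68.6


def test_encounter_interval_ratio_property(rng):
    for _ in range(20):
        a, b = rng.uniform(0.1, 500.0, 2)
        assert encounter_interval(a) / encounter_interval(b) == pytest.approx(b / a, rel=1e-12)


def test_encounter_interval_rejects_nonpositive():
    with pytest.raises(ValueError):
        encounter_interval(0.0)


# ---------------------------------------------------------------------------
# I/O


def test_events_csv_roundtrip_and_malformed_timestamp(tmp_path, caplog):
    path = tmp_path / "events.csv"
    path.write_text(
        "camera_id,timestamp,subject,n\n"
        "c1,2010-05-01T09:00:00,human,2\n"
        "c1,not-a-time,bobcat,1\n"
        "c2,2010-05-01T10:00:00,coyote,1\n"
    )
    with caplog.at_level(logging.WARNING):
        events = read_events(path)
    assert len(events) == 2  # malformed row dropped, not fatal
    assert "not-a-time" in caplog.text
    assert events[0].n == 2


def test_curve_csv_roundtrip(tmp_path, combined_params):
    curve = simulate_response_data(combined_params, "arps", range(8), 50, rng=3, taxon="puma")
    path = tmp_path / "curve.csv"
    write_curve(curve, path)
    back = read_curve(path)
    assert back.taxon == "puma"
    np.testing.assert_allclose(back.x, curve.x)
    np.testing.assert_allclose(back.y, curve.y)
    np.testing.assert_array_equal(back.n_days, curve.n_days)
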