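"""Hour-of-week profiles, windowing, activity metrics and strata."""

import math

import numpy as np
import pandas as pd
import pytest

from mobstates.entropy import fano_predictability, shannon_entropy
from mobstates.io import Dataset, Trajectory, dataset_from_frame
from mobstates.states import (
    activity_metrics,
    binned_predictability,
    distribution_mode,
    population_profile,
    slot_predictability,
    stratified_profiles,
    windowed_predictability,
)
from mobstates.synthetic import CohortSpec, gen_cohort


def _traj(rows):
    """Trajectory from (timestamp, location[, lat, lon]) tuples."""
    recs = []
    for r in rows:
        ts, loc = r[0], r[1]
        lat, lon = (r[2], r[3]) if len(r) > 2 else (40.0, -75.0)
        recs.append(
            {"user_id": "u", "timestamp": pd.Timestamp(ts), "lat": lat, "lon": lon,
             "location_id": loc, "category": None}
        )
    df = pd.DataFrame(recs)
    return dataset_from_frame(df).trajectories["u"]


class TestSlotPredictability:
    def test_deterministic_slot_is_fully_predictable(self):
        # same venue every Monday 09:xx over 10 weeks
        rows = [(pd.Timestamp("2024-01-01 09:00") + pd.Timedelta(weeks=w), "office")
                for w in range(10)]
        prof = slot_predictability(_traj(rows))
        assert prof[9] == 1.0
        assert np.isnan(prof[10])

    def test_two_equally_frequent_venues_give_half(self):
        rows = []
        for w in range(10):
            rows.append((pd.Timestamp("2024-01-01 09:00") + pd.Timedelta(weeks=w),
                         "office" if w % 2 == 0 else "cafe"))
        prof = slot_predictability(_traj(rows))
        assert prof[9] == pytest.approx(0.5, abs=1e-10)

    def test_matches_entropy_pipeline_bit_exactly(self, small_cohort):
        ds, _ = small_cohort
        traj = next(iter(ds))
        prof = slot_predictability(traj)
        slots = traj.slots()
        symbols = np.asarray(traj.symbols(), dtype=object)
        for s in range(168):
            sub = symbols[slots == s]
            if sub.size == 0:
                assert np.isnan(prof[s])
                continue
            res = shannon_entropy(sub.tolist())
            expect = 1.0 if res.S == 1 else fano_predictability(res.H_u, res.S).Pi
            assert prof[s] == expect


class TestPopulationProfile:
    def test_mean_and_population_sd(self):
        rows_a = [(pd.Timestamp("2024-01-01 00:10") + pd.Timedelta(weeks=w),
                   ["a", "a", "a", "a", "b"][w]) for w in range(5)]
        # user A slot 0: p=(4/5,1/5)
        rows_b = [(pd.Timestamp("2024-01-01 00:20") + pd.Timedelta(weeks=w), "z")
                  for w in range(5)]
        da = _traj(rows_a).df.assign(user_id="A")
        db = _traj(rows_b).df.assign(user_id="B")
        ds = dataset_from_frame(pd.concat([da, db], ignore_index=True))
        prof = population_profile(ds)
        pa = slot_predictability(ds.trajectories["A"])[0]
        assert prof.mean[0] == pytest.approx((pa + 1.0) / 2)
        assert prof.sd[0] == pytest.approx(abs(1.0 - pa) / 2)  # ddof=0 over two users
        assert prof.count[0] == 2

    def test_single_user_profile_has_zero_spread(self, small_cohort):
        ds, _ = small_cohort
        uid, traj = next(iter(ds.trajectories.items()))
        solo = population_profile(Dataset(trajectories={uid: traj}))
        observed = ~np.isnan(solo.mean)
        assert np.allclose(solo.sd[observed], 0.0)
        assert np.allclose(solo.mean[observed], slot_predictability(traj)[observed])

    def test_night_slots_beat_midday_on_circadian_cohort(self, small_cohort):
        ds, _ = small_cohort
        prof = population_profile(ds)
        byhour = prof.mean.reshape(7, 24)
        night = np.nanmean(byhour[:, 3:6])
        midday = np.nanmean(byhour[:, 12:15])
        assert night > midday


class TestActivityMetrics:
    def test_single_point_has_zero_radius(self):
        rows = [(f"2024-01-0{d} 10:00", "home", 40.0, -75.0) for d in range(1, 6)]
        assert activity_metrics(_traj(rows)).r_g == pytest.approx(0.0, abs=1e-9)

    def test_two_points_ten_km_apart(self):
        # 10 km along a meridian is ~10/111.32 degrees of latitude
        dlat = 10.0 / 111.32
        rows = [
            ("2024-01-01 10:00", "a", 40.0, -75.0),
            ("2024-01-02 10:00", "b", 40.0 + dlat, -75.0),
        ]
        m = activity_metrics(_traj(rows))
        assert m.r_g == pytest.approx(5.0, rel=0.01)

    def test_monthly_rate_arithmetic(self):
        # 90 check-ins over exactly three 30.44-day months -> 30 per month
        start = pd.Timestamp("2024-01-01")
        span = pd.Timedelta(days=3 * 30.44)
        times = [start + span * i / 89 for i in range(90)]
        rows = [(t, "x", 40.0, -75.0) for t in times]
        assert activity_metrics(_traj(rows)).f_c == pytest.approx(30.0, rel=1e-9)

    def test_distinct_location_count(self, small_cohort):
        ds, _ = small_cohort
        traj = next(iter(ds))
        assert activity_metrics(traj).S == len(set(traj.symbols()))


class TestWindowing:
    def test_full_week_window_equals_whole_trajectory(self, small_cohort):
        ds, _ = small_cohort
        for traj in list(ds)[:5]:
            assert windowed_predictability(traj, 168) == windowed_predictability(traj, "full")

    def test_weekly_repeating_user_is_fully_predictable(self):
        # single-venue repeating user: predictability 1 at every window size
        rows = [
            (pd.Timestamp("2024-01-01 09:00") + pd.Timedelta(weeks=w), "office")
            for w in range(8)
        ]
        traj = _traj(rows)
        for w in (1, 6, 24, 168):
            assert windowed_predictability(traj, w) == pytest.approx(1.0)
        # multi-venue weekly schedule: still 1 whenever each bin isolates
        # one venue (bins wider than that pool distinct venues)
        rows = []
        for w in range(8):
            for slot_h, loc in ((9, "office"), (13, "cafe"), (20, "home")):
                rows.append(
                    (pd.Timestamp("2024-01-01") + pd.Timedelta(weeks=w, hours=slot_h), loc)
                )
        traj = _traj(rows)
        for w in (1, 4):
            assert windowed_predictability(traj, w) == pytest.approx(1.0)

    def test_partition_conserves_checkin_count(self, small_cohort):
        ds, _ = small_cohort
        traj = next(iter(ds))
        slots = traj.slots()
        for w in (1, 5, 24, 72, 167, 168):
            bins = slots // w
            n_bins = math.ceil(168 / w)
            counts = np.bincount(bins, minlength=n_bins)
            assert counts.sum() == len(traj)
            assert len(counts) == n_bins

    def test_mean_predictability_shrinks_with_window_size(self, small_cohort):
        ds, _ = small_cohort
        means = {
            w: np.mean([windowed_predictability(t, w) for t in ds]) for w in (1, 24, 72)
        }
        assert means[1] >= means[24] >= means[72]


class TestStratification:
    def test_all_users_land_in_one_stratum(self, small_cohort):
        ds, _ = small_cohort
        profs = stratified_profiles(ds, "S", [1, 1000])
        assert profs["S=[1,1000)"].n_users == len(ds)

    def test_stratum_counts_partition_users(self, small_cohort):
        ds, _ = small_cohort
        profs = stratified_profiles(ds, "S", [1, 10, 20, 60, np.inf])
        assert sum(p.n_users for p in profs.values()) == len(ds)

    def test_empty_stratum_is_all_missing(self, small_cohort):
        ds, _ = small_cohort
        profs = stratified_profiles(ds, "S", [100000, 200000])
        p = profs["S=[100000,200000)"]
        assert p.n_users == 0 and np.isnan(p.mean).all()

    def test_diversity_gradient_orders_strata(self, small_cohort):
        # predictability decreases as the number of distinct locations grows;
        # allow a single inversion at this cohort size
        ds, _ = small_cohort
        profs = stratified_profiles(ds, "S", [1, 10, 20, 60, np.inf])
        means = [float(np.nanmean(p.mean)) for p in profs.values() if p.n_users > 0]
        inversions = sum(1 for a, b in zip(means, means[1:]) if a < b)
        assert inversions <= 1

    def test_bad_edges_rejected(self, small_cohort):
        ds, _ = small_cohort
        with pytest.raises(ValueError):
            stratified_profiles(ds, "S", [20, 10])
        with pytest.raises(ValueError):
            stratified_profiles(ds, "altitude")


class TestDistributionMode:
    def test_degenerate_sample(self):
        assert distribution_mode([0.75] * 10) == pytest.approx(0.75, abs=0.01)

    def test_tie_broken_toward_higher_bin(self):
        vals = [0.101, 0.103, 0.901, 0.903]
        assert distribution_mode(vals, bin_width=0.02) > 0.5

    def test_matches_bruteforce_histogram_on_bimodal_sample(self, rng):
        vals = np.concatenate(
            [rng.normal(0.5, 0.05, 300), rng.normal(0.9, 0.03, 700)]
        ).clip(0, 1)
        got = distribution_mode(vals, bin_width=0.02)
        edges = np.minimum(np.arange(51) * 0.02, 1.0)
        counts, _ = np.histogram(vals, bins=edges)
        best = max(range(50), key=lambda i: (counts[i], i))
        assert got == pytest.approx((edges[best] + edges[best + 1]) / 2)
        assert abs(got - 0.9) < 0.05

    def test_empty_and_bad_width_rejected(self):
        with pytest.raises(ValueError):
            distribution_mode([])
        with pytest.raises(ValueError):
            distribution_mode([0.5], bin_width=0)


def test_daily_repeating_cohort_saturates_at_24h():
    # when the schedule has no day-of-week structure, pooling beyond 24 h
    # adds no diversity: the windowed-mode stays put between w=24 and w=48
    from mobstates.synthetic import gen_schedule_user
    from mobstates.io import dataset_from_frame
    import pandas as pd

    frames = [
        gen_schedule_user(f"d{i}", 1000 + i, weeks=20, daily_only=True, attendance=0.5)
        for i in range(50)
    ]
    ds = dataset_from_frame(pd.concat(frames, ignore_index=True))
    m1 = distribution_mode([windowed_predictability(t, 1) for t in ds])
    m24 = distribution_mode([windowed_predictability(t, 24) for t in ds])
    m48 = distribution_mode([windowed_predictability(t, 48) for t in ds])
    assert abs(m24 - m48) < 0.02
    assert m1 - m24 > 0.02  # but the hourly mode sits well above the daily one
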