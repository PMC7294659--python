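"""Travel/stopover classification, threshold derivation, window detection."""

import numpy as np
import pytest

from gullmig.geo import geodesic_km
from gullmig.segment import (ClassifierConfig, classify_days,
                             derive_thresholds, find_migration_window,
                             group_stopovers, segment_track,
                             STOPOVER_LABEL, TRAVEL_LABEL)

from conftest import make_daily

KM_PER_DEG = 110.574


def brute_force_labels(daily, cfg):
    """Independent rule-by-rule reimplementation: explicit loops over
    every 3-transition window and every single-day jump."""
    n = len(daily)
    dlat = np.full(n, np.nan)
    disp = np.full(n, np.nan)
    for t in range(1, n):
        if daily.gap_flag[t] or daily.gap_flag[t - 1]:
            continue
        dlat[t] = daily.lat[t] - daily.lat[t - 1]
        disp[t] = geodesic_km((daily.lon[t - 1], daily.lat[t - 1]),
                              (daily.lon[t], daily.lat[t]))
    travel = [False] * n
    for t in range(n):
        if np.isfinite(disp[t]) and disp[t] > cfg.jump_km:
            travel[t] = True
    for w0 in range(1, n - 2):
        window = [w0, w0 + 1, w0 + 2]
        if any(not np.isfinite(dlat[t]) for t in window):
            continue
        for sign in (+1, -1):
            qualifying = [t for t in window if sign * dlat[t] > cfg.lat_step_deg]
            if len(qualifying) >= 2:
                for t in qualifying:
                    travel[t] = True
    labels = np.array([TRAVEL_LABEL if tr else STOPOVER_LABEL
                       for tr in travel], dtype=object)
    labels[daily.gap_flag] = ""
    return labels


class TestClassifyDays:
    def test_stationary_track_all_stopover(self):
        daily = make_daily([44.5] * 10)
        labels = classify_days(daily)
        assert set(labels) == {STOPOVER_LABEL}

    def test_eighty_km_jump_is_travel(self):
        # one 80 km jump due east: no latitude trend, criterion 2 only
        lons = [-66.0] * 5 + [-66.0 + 80 / (KM_PER_DEG * np.cos(np.radians(44.5)))] * 5
        daily = make_daily([44.5] * 10, lons)
        labels = classify_days(daily)
        assert labels[5] == TRAVEL_LABEL
        assert all(l == STOPOVER_LABEL for i, l in enumerate(labels) if i != 5)

    def test_latitude_trend_labels_qualifying_days_only(self):
        # steps: -0.4, -0.4, +0.1 -> the two -0.4 days qualify, the +0.1
        # day does not (sign-consistency within the window)
        daily = make_daily([45.0, 44.6, 44.2, 44.3])
        labels = classify_days(daily)
        assert labels.tolist() == [STOPOVER_LABEL, TRAVEL_LABEL,
                                   TRAVEL_LABEL, STOPOVER_LABEL]

    def test_all_flagged_is_error(self):
        daily = make_daily([44.5] * 5, gap=[True] * 5)
        with pytest.raises(ValueError):
            classify_days(daily)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        lat = 44.0 + np.cumsum(rng.choice([0.0, -0.5, 0.8], n,
                                          p=[0.5, 0.35, 0.15]))
        lat += rng.normal(0, 0.15, n)
        lon = -66.0 + np.cumsum(rng.normal(0, 0.4, n))
        gap = rng.random(n) < 0.1
        daily = make_daily(lat, lon, gap=gap)
        cfg = ClassifierConfig()
        assert np.array_equal(classify_days(daily, cfg),
                              brute_force_labels(daily, cfg))

    def test_jump_dominates_latitude_pattern(self):
        """Any day moving > jump_km is travel regardless of trend."""
        rng = np.random.default_rng(3)
        lat = 44.0 + np.cumsum(rng.normal(0, 1.2, 40))
        daily = make_daily(lat)
        cfg = ClassifierConfig()
        labels = classify_days(daily, cfg)
        for t in range(1, 40):
            d = geodesic_km((daily.lon[t - 1], daily.lat[t - 1]),
                            (daily.lon[t], daily.lat[t]))
            if d > cfg.jump_km:
                assert labels[t] == TRAVEL_LABEL

    def test_exhaustive_labeling(self, small_population):
        """Every unflagged day gets exactly one of the two labels."""
        _, truths = small_population
        for truth in truths:
            labels = classify_days(truth.daily)
            assert set(labels) <= {TRAVEL_LABEL, STOPOVER_LABEL}


class TestDeriveThresholds:
    def test_constant_steps(self):
        # 10 equal 50 km steps northwards
        lat = 44.0 + np.arange(11) * (50.0 / KM_PER_DEG)
        daily = make_daily(lat)
        dlat, jump = derive_thresholds([daily], 90.0)
        # constant sample: any percentile equals the common value
        # (ellipsoidal metric differs from the mean-degree scale by <1%)
        assert jump == pytest.approx(50.0, rel=1e-2)
        assert dlat == pytest.approx(50.0 / KM_PER_DEG, rel=1e-6)

    def test_matches_order_statistic(self):
        # northward steps of 1..100 km: compare with sort-and-interpolate
        steps_km = np.arange(1.0, 101.0)
        lat = 44.0 + np.concatenate([[0.0], np.cumsum(steps_km / KM_PER_DEG)])
        daily = make_daily(lat)
        _, jump = derive_thresholds([daily], 90.0)
        expect = np.percentile(
            [geodesic_km((-66.0, lat[i]), (-66.0, lat[i + 1]))
             for i in range(100)], 90.0)
        assert jump == pytest.approx(float(expect), rel=1e-9)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            derive_thresholds([], 90.0)

    def test_percentile_domain(self):
        daily = make_daily([44.0, 44.5, 45.0])
        with pytest.raises(ValueError):
            derive_thresholds([daily], 100.0)


class TestMigrationWindow:
    def test_detected_window_matches_schedule(self, small_population):
        """On noiseless daily positions the detected window equals the
        simulator's scheduled departure/arrival days (within +/- 1 day)."""
        _, truths = small_population
        assert len(truths) == 6
        for truth in truths:
            series = segment_track(truth.daily, truth.colony)
            w, tw = series.migration_window, truth.migration_window
            assert w.detected
            assert abs(w.start_idx - tw.start_idx) <= 1
            assert abs(w.end_idx - tw.end_idx) <= 1
            # window containment within the tracked span
            assert 0 <= w.start_idx <= w.end_idx < len(truth.daily)
            for site in series.stopover_sites:
                assert w.start_idx <= site.start_idx <= site.end_idx <= w.end_idx

    def test_never_leaving_colony_radius(self):
        # wander within 150 km: jumps may label travel days, but no exit
        rng = np.random.default_rng(1)
        ang = rng.uniform(0, 2 * np.pi, 30)
        r = rng.uniform(0, 140.0, 30)
        lat = 44.57 + r * np.cos(ang) / KM_PER_DEG
        lon = -66.75 + r * np.sin(ang) / (KM_PER_DEG * np.cos(np.radians(44.57)))
        daily = make_daily(lat, lon)
        labels = classify_days(daily)
        w = find_migration_window(labels, daily, (-66.75, 44.57))
        assert not w.detected
        assert "colony radius" in w.reason

    def test_redeparture_supersedes_aborted_exit(self):
        # out beyond 200 km, back to the colony, then the real departure
        lat = np.array([44.57] * 3
                       + [44.57 + 2.5, 44.57 + 5.0]     # exit ~550 km
                       + [44.57 + 2.5, 44.57]           # return
                       + [44.57] * 3
                       + list(44.57 - 2.0 * np.arange(1, 6))   # re-departure
                       + [34.57 - 0.01] * 25)
        daily = make_daily(lat)
        labels = classify_days(daily)
        w = find_migration_window(labels, daily, (-66.0, 44.57),
                                  ClassifierConfig(winter_dwell_days=20))
        assert w.detected
        assert w.start_idx == 10          # first day of the final transit
        assert len(w.candidate_start_idx) >= 2


class TestGroupStopovers:
    def _series(self, pattern):
        lat = 44.0 + np.cumsum([2.0 if c == "T" else 0.0 for c in pattern])
        daily = make_daily(lat)
        labels = np.array([TRAVEL_LABEL if c == "T" else STOPOVER_LABEL
                           for c in pattern], dtype=object)
        return daily, labels

    def test_run_lengths(self):
        daily, labels = self._series("TSSSTST")
        from gullmig.segment import MigrationWindow
        w = MigrationWindow(detected=True, start_idx=0, end_idx=6,
                            start=daily.days[0], end=daily.days[6])
        sites = group_stopovers(labels, daily, w)
        assert [s.length_days for s in sites] == [3, 1]

    def test_no_stopovers_empty(self):
        daily, labels = self._series("TTTT")
        from gullmig.segment import MigrationWindow
        w = MigrationWindow(detected=True, start_idx=0, end_idx=3,
                            start=daily.days[0], end=daily.days[3])
        assert group_stopovers(labels, daily, w) == []

    def test_runs_not_spatially_merged(self):
        # two stopover runs at the same place, split by one travel day
        lat = [44.0, 44.0, 45.0, 44.0, 44.0]
        daily = make_daily(lat)
        labels = np.array([STOPOVER_LABEL, STOPOVER_LABEL, TRAVEL_LABEL,
                           STOPOVER_LABEL, STOPOVER_LABEL], dtype=object)
        from gullmig.segment import MigrationWindow
        w = MigrationWindow(detected=True, start_idx=0, end_idx=4,
                            start=daily.days[0], end=daily.days[4])
        sites = group_stopovers(labels, daily, w)
        assert [s.length_days for s in sites] == [2, 2]
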