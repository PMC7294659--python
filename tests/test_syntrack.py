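"""Synthetic-track generator: DCRW dynamics, observation model, truth."""

import io

import numpy as np
import pytest
from scipy import stats

from gullmig.geo import geodesic_km
from gullmig.migmetrics import CHARACTERISTICS, summarize
from gullmig.ssm import ErrorModel, SSMParams, TRAVEL
from gullmig.syntrack import (DutyCycle, SimConfig, observe_track,
                              simulate_dcrw, simulate_population)
from gullmig.trackio import write_tracks

START = (-66.75, 44.57)


class TestSimulateDCRW:
    def test_zero_persistence_gives_iid_steps(self):
        p = SSMParams(gamma=(0.0, 0.0), theta=(0.0, 0.0))
        tr = simulate_dcrw(p, 3000, START, seed=0)
        x = np.column_stack(tr.plane.to_plane(tr.daily.lon, tr.daily.lat))
        d = np.diff(x, axis=0)
        for c in range(2):
            r = np.corrcoef(d[:-1, c], d[1:, c])[0, 1]
            assert abs(r) < 0.05

    def test_identity_transition_absorbs(self):
        p = SSMParams(trans=np.eye(2))
        tr = simulate_dcrw(p, 50, START, seed=1, init_state=TRAVEL)
        assert (tr.states == TRAVEL).all()

    def test_occupancy_matches_stationary_distribution(self, dcrw_params):
        """Empirical travel occupancy vs the chain's stationary
        distribution from eigendecomposition, within 3 binomial SEs
        (inflated by the chain's integrated autocorrelation time)."""
        n = 2000
        tr = simulate_dcrw(dcrw_params, n, START, seed=2)
        pi = dcrw_params.stationary_distribution()
        occ = float(np.mean(tr.states == TRAVEL))
        # lag-1 autocorrelation of the 2-state chain is (p11 + p22 - 1)
        rho = dcrw_params.trans[0, 0] + dcrw_params.trans[1, 1] - 1.0
        se = np.sqrt(pi[0] * pi[1] / n * (1 + rho) / (1 - rho))
        assert abs(occ - pi[0]) < 3 * se

    def test_state_conditional_step_lengths_ordered(self, dcrw_params):
        tr = simulate_dcrw(dcrw_params, 2000, START, seed=3)
        x = np.column_stack(tr.plane.to_plane(tr.daily.lon, tr.daily.lat))
        step = np.linalg.norm(np.diff(x, axis=0), axis=1)
        s = tr.states[1:]
        assert step[s == TRAVEL].mean() > step[s != TRAVEL].mean()

    def test_deterministic_given_seed(self, dcrw_params):
        a = simulate_dcrw(dcrw_params, 100, START, seed=9)
        b = simulate_dcrw(dcrw_params, 100, START, seed=9)
        assert np.array_equal(a.daily.lat, b.daily.lat)
        assert np.array_equal(a.states, b.states)

    def test_invalid_inputs(self, dcrw_params):
        with pytest.raises(ValueError):
            simulate_dcrw(dcrw_params, 1, START, seed=0)
        with pytest.raises(ValueError):
            SSMParams(gamma=(np.inf, 0.1))


class TestObserveTrack:
    @pytest.fixture
    def truth(self, dcrw_params):
        return simulate_dcrw(dcrw_params, 60, START, seed=4)

    def test_zero_error_lies_on_interpolated_path(self, truth):
        gps = ErrorModel(class_freqs={"F": 1.0})
        obs = observe_track(truth, DutyCycle(24.0, 0.0, 8.0), gps, seed=0)
        x, y = truth.plane.to_plane(truth.daily.lon, truth.daily.lat)
        tau = (obs.fixes["time"] - truth.daily.days[0]).dt.total_seconds() / 86400
        days = np.arange(len(truth.daily), dtype=float)
        ox, oy = truth.plane.to_plane(obs.fixes["lon"], obs.fixes["lat"])
        # timestamps are written to whole seconds; 1 s of travel < 1 m
        assert np.allclose(ox, np.interp(tau, days, x), atol=1e-2)
        assert np.allclose(oy, np.interp(tau, days, y), atol=1e-2)

    def test_all_f_class_zero_perturbation(self, truth):
        gps = ErrorModel(class_freqs={"F": 1.0})
        obs = observe_track(truth, DutyCycle(10.0, 24.0, 6.0), gps, seed=1)
        assert (obs.fixes["lc"] == "F").all()

    def test_t_error_scale_matches_analytic_mad(self, dcrw_params):
        """Scale-5 km, nu=4 class: sample MAD of the coordinate
        perturbations within 10% of the scaled-t analytic MAD."""
        truth = simulate_dcrw(dcrw_params, 1500, START, seed=5)
        em = ErrorModel(scales_km={"0": 5.0}, df={"0": 4.0},
                        class_freqs={"0": 1.0})
        obs = observe_track(truth, DutyCycle(24.0, 0.0, 8.0), em, seed=2)
        assert len(obs.fixes) > 8000
        x, y = truth.plane.to_plane(truth.daily.lon, truth.daily.lat)
        tau = (obs.fixes["time"] - truth.daily.days[0]).dt.total_seconds() / 86400
        days = np.arange(len(truth.daily), dtype=float)
        ox, _ = truth.plane.to_plane(obs.fixes["lon"], obs.fixes["lat"])
        perturb = ox - np.interp(tau, days, x)
        mad = np.median(np.abs(perturb))
        assert mad == pytest.approx(5.0 * stats.t.ppf(0.75, 4.0), rel=0.10)

    def test_duty_cycle_gaps_respected(self, truth):
        em = ErrorModel(class_freqs={"F": 1.0})
        obs = observe_track(truth, DutyCycle(6.0, 18.0, 5.0), em, seed=3)
        hours = (obs.fixes["time"] - truth.daily.days[0]
                 ).dt.total_seconds() / 3600.0
        assert (np.mod(hours, 24.0) <= 6.0 + 1e-9).all()

    def test_empty_duty_cycle_rejected(self):
        with pytest.raises(ValueError):
            DutyCycle(on_hours=0.0)


class TestSimulatePopulation:
    def test_counts_and_unique_ids(self, small_population):
        tracks, truths = small_population
        assert len(tracks) == len(truths) == 6
        ids = [t.individual for t in tracks]
        assert len(set(ids)) == 6

    def test_duplicate_ids_rejected(self):
        cfg = SimConfig(population_label="p", n_individuals=2, seed=0)
        with pytest.raises(ValueError):
            simulate_population([cfg, cfg])

    def test_byte_identical_reruns(self):
        cfg = SimConfig(population_label="p", n_individuals=2, n_days=60,
                        seed=5)
        outs = []
        for _ in range(2):
            tracks, _ = simulate_population([cfg])
            buf_f, buf_m = io.StringIO(), io.StringIO()
            write_tracks(tracks, buf_f, buf_m)
            outs.append(buf_f.getvalue() + buf_m.getvalue())
        assert outs[0] == outs[1]

    def test_long_vs_short_distance_by_construction(self, small_population):
        """Truth migration distances differ according to the geodesic
        separation of the configured endpoints (the oracle)."""
        _, truths = small_population
        near = [t for t in truths if t.population == "near"]
        far = [t for t in truths if t.population == "far"]
        d_near = geodesic_km((-66.75, 44.57), (-70.0, 41.8))
        d_far = geodesic_km((-66.75, 44.57), (-88.0, 29.0))
        for t in near:
            assert t.summary.migration_distance_km > d_near * 0.95
            assert t.summary.migration_distance_km < d_far
        for t in far:
            assert t.summary.migration_distance_km > d_far * 0.95
        assert (np.mean([t.summary.migration_distance_km for t in far])
                > 2 * np.mean([t.summary.migration_distance_km for t in near]))

    def test_truth_summary_consistency(self, small_population):
        """Re-running the metric code on the stored truth reproduces the
        stored summary exactly."""
        _, truths = small_population
        for truth in truths:
            again = summarize(truth.daily, truth.true_labels())
            for f in CHARACTERISTICS:
                got, want = getattr(again, f), getattr(truth.summary, f)
                if isinstance(got, float) and np.isnan(got):
                    assert np.isnan(want)
                else:
                    assert got == want

    def test_noise_monotonicity(self, dcrw_params):
        """RMS deviation of fixes from the interpolated truth grows with
        the error-class scale."""
        truth = simulate_dcrw(dcrw_params, 200, START, seed=6)
        x, _ = truth.plane.to_plane(truth.daily.lon, truth.daily.lat)
        days = np.arange(len(truth.daily), dtype=float)
        rms = []
        for scale in (0.5, 2.0, 8.0):
            em = ErrorModel(scales_km={"1": scale}, df={"1": 6.0},
                            class_freqs={"1": 1.0})
            obs = observe_track(truth, DutyCycle(24.0, 0.0, 6.0), em, seed=7)
            tau = (obs.fixes["time"] - truth.daily.days[0]
                   ).dt.total_seconds() / 86400
            ox, _ = truth.plane.to_plane(obs.fixes["lon"], obs.fixes["lat"])
            rms.append(float(np.sqrt(np.mean((ox - np.interp(tau, days, x)) ** 2))))
        assert rms[0] < rms[1] < rms[2]
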