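import numpy as np
import pandas as pd
import pytest

from gullmig.ssm import DailyPath, SSMParams
from gullmig.syntrack import SimConfig, simulate_population
from gullmig.trackio import Track


@pytest.fixture(scope="session")
def dcrw_params():
    return SSMParams(gamma=(0.85, 0.15), theta=(0.05, -0.1),
                     process_cov=np.diag([400.0, 400.0]),
                     trans=np.array([[0.9, 0.1], [0.2, 0.8]]))


@pytest.fixture(scope="session")
def small_population():
    """Two tiny populations (3 tracks each) with full ground truth."""
    configs = [
        SimConfig(population_label="near", n_individuals=3,
                  colony=(-66.75, 44.57), winter_target=(-70.0, 41.8),
                  waypoints=(), detour_frac=0.25, n_days=70,
                  travel_step_km=220.0, seed=11),
        SimConfig(population_label="far", n_individuals=3,
                  colony=(-66.75, 44.57), winter_target=(-88.0, 29.0),
                  waypoints=(), detour_frac=0.25, n_days=100,
                  travel_step_km=320.0, seed=12),
    ]
    return simulate_population(configs)


def make_daily(lats, lons=None, gap=None, individual="t1",
               start="2015-09-01"):
    """DailyPath from latitude (and optional longitude) sequences."""
    n = len(lats)
    lons = np.full(n, -66.0) if lons is None else np.asarray(lons, float)
    gap = np.zeros(n, dtype=bool) if gap is None else np.asarray(gap, bool)
    days = pd.date_range(pd.Timestamp(start, tz="UTC"), periods=n, freq="D")
    return DailyPath(individual=individual, days=days, lon=lons,
                     lat=np.asarray(lats, float),
                     p_travel=np.zeros(n), gap_flag=gap)


def make_track(times, lons, lats, lcs=None, individual="t1",
               population="p", colony=(-66.75, 44.57)):
    n = len(times)
    lcs = ["F"] * n if lcs is None else list(lcs)
    fixes = pd.DataFrame({
        "time": pd.DatetimeIndex(pd.to_datetime(times, utc=True)),
        "lon": np.asarray(lons, float), "lat": np.asarray(lats, float),
        "lc": lcs})
    return Track(individual=individual, population=population,
                 colony=colony, fixes=fixes)
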