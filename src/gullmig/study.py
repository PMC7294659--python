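"""The four-population synthetic study conditions.

One long-distance population breeding in the eastern Arctic (Southampton
Island) wintering on the Gulf of Mexico coast, and three short-distance
Atlantic populations (Newfoundland, Sable Island, Bay of Fundy)
wintering between the Gulf of Maine and the mid-Atlantic coast.  Colony
coordinates, track counts (8/12/17/11 with several individuals tracked
in more than one year), duty cycles and device mixes mirror the tracked
deployments; routes follow coastal via-points, which is what makes the
long-distance route markedly less direct than the short ones.  Travel
step lengths and stopover schedules are set so the populations differ
in distance by roughly a factor of four while overall migration pace
stays comparable - the contrast structure the population models are
meant to detect.
"""

from __future__ import annotations

from .ssm.model import ErrorModel
from .syntrack import DutyCycle, SimConfig

#: Argos-heavy platform-terminal transmitter (no GPS fixes)
PTT_ERRORS = ErrorModel(class_freqs={"3": 0.15, "2": 0.25, "1": 0.3, "0": 0.3})
#: GPS logger: error-free class F only
GPS_ERRORS = ErrorModel(class_freqs={"F": 1.0})
#: GPS-PTT hybrid: mostly GPS with some Doppler fixes
HYBRID_ERRORS = ErrorModel(
    class_freqs={"F": 0.7, "2": 0.1, "1": 0.1, "0": 0.1})


def study_configs(seed: int = 0) -> list:
    """The four population configurations, seeded from one master seed."""
    return [
        SimConfig(
            population_label="eastern_arctic",
            n_individuals=8,
            colony=(-81.75, 64.01),            # Southampton Island, NU
            winter_target=(-93.5, 28.0),       # Gulf of Mexico coast
            waypoints=((-65.0, 61.0), (-56.0, 53.0), (-53.0, 47.0),
                       (-70.0, 43.0), (-76.5, 35.8), (-80.0, 28.0),
                       (-88.0, 29.8)),
            n_days=130, start_date="2014-08-20",
            duty_cycle=DutyCycle(on_hours=10.0, off_hours=24.0,
                                 fixes_per_day=7.0),
            error_model=PTT_ERRORS,
            travel_step_km=370.0, step_sd_between=45.0,
            travel_bout_days=3.5, stopover_bout_days=9.0, p_stopover=0.85,
            pre_days=10.0, winter_min_days=35,
            seed=seed * 10 + 1),
        SimConfig(
            population_label="newfoundland",
            n_individuals=9,
            tracks_per_individual=(2, 2, 2, 1, 1, 1, 1, 1, 1),
            colony=(-52.77, 47.26),            # Witless Bay, NL
            winter_target=(-74.0, 40.2),       # Long Island Sound
            waypoints=((-55.8, 50.8), (-60.0, 44.3), (-67.0, 42.8)),
            n_days=110, start_date="2014-09-01",
            duty_cycle=DutyCycle(on_hours=24.0, off_hours=0.0,
                                 fixes_per_day=6.0),
            error_model=GPS_ERRORS,
            travel_step_km=240.0, step_sd_between=40.0,
            travel_bout_days=2.5, stopover_bout_days=6.0, p_stopover=0.75,
            pre_days=8.0, winter_min_days=32,
            seed=seed * 10 + 2),
        SimConfig(
            population_label="sable_island",
            n_individuals=8,
            tracks_per_individual=(3, 2, 2, 2, 2, 2, 2, 2),
            colony=(-60.0, 43.92),             # Sable Island, NS
            winter_target=(-75.2, 38.8),       # Delaware Bay
            waypoints=((-62.5, 46.0), (-65.8, 46.0), (-69.5, 44.6), (-71.3, 42.0)),
            n_days=90, start_date="2014-09-05",
            duty_cycle=DutyCycle(on_hours=24.0, off_hours=0.0,
                                 fixes_per_day=8.0),
            error_model=HYBRID_ERRORS,
            travel_step_km=220.0, step_sd_between=35.0,
            travel_bout_days=2.5, stopover_bout_days=5.0, p_stopover=0.7,
            pre_days=8.0, winter_min_days=30,
            seed=seed * 10 + 3),
        SimConfig(
            population_label="bay_of_fundy",
            n_individuals=8,
            tracks_per_individual=(2, 2, 2, 1, 1, 1, 1, 1),
            colony=(-66.75, 44.57),            # Kent Island, NB
            winter_target=(-74.5, 39.4),       # New Jersey coast
            waypoints=((-70.0, 44.8), (-72.0, 43.0), (-73.0, 41.0)),
            n_days=90, start_date="2014-09-10",
            duty_cycle=DutyCycle(on_hours=6.0, off_hours=34.0,
                                 fixes_per_day=5.0),
            error_model=HYBRID_ERRORS,
            travel_step_km=185.0, step_sd_between=30.0,
            travel_bout_days=2.0, stopover_bout_days=3.5, p_stopover=0.7,
            pre_days=8.0, winter_min_days=30,
            seed=seed * 10 + 4),
    ]
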