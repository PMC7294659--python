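"""Post-hoc pruning of regularized positions in observation gaps.

State-space estimates interpolate freely through data holes, and the
interpolation becomes biologically meaningless once the hole is long;
daily estimates with no observed fix within +/- 1 day are therefore
flagged and withheld from downstream segmentation.  Contiguous
observation gaps longer than 7 days are additionally logged.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .model import DailyPath

log = logging.getLogger(__name__)

GAP_TOLERANCE_DAYS = 1.0
LONG_GAP_DAYS = 7.0


def prune_gaps(daily: DailyPath, observed_times,
               tolerance_days: float = GAP_TOLERANCE_DAYS) -> DailyPath:
    """Flag days with no observed fix within ``tolerance_days``.

    ``observed_times`` is a sequence of tz-aware timestamps (the fixes
    that entered the model, post speed-filter).  Never unflags a day and
    is idempotent.  With an empty observation list every day is flagged.
    """
    times = pd.DatetimeIndex(observed_times)
    day_num = (daily.days.tz_localize("UTC") if daily.days.tz is None
               else daily.days).asi8 / 86_400e9
    flag = daily.gap_flag.copy()
    if len(times) == 0:
        flag[:] = True
    else:
        obs_num = np.sort(times.asi8 / 86_400e9)
        idx = np.searchsorted(obs_num, day_num)
        prev_gap = np.where(idx > 0, day_num - obs_num[np.maximum(idx - 1, 0)], np.inf)
        next_gap = np.where(idx < len(obs_num),
                            obs_num[np.minimum(idx, len(obs_num) - 1)] - day_num, np.inf)
        flag |= np.minimum(prev_gap, next_gap) > tolerance_days

        holes = np.diff(obs_num)
        n_long = int(np.sum(holes > LONG_GAP_DAYS))
        if n_long:
            log.warning("%s: %d observation gap(s) longer than %d days",
                        daily.individual, n_long, int(LONG_GAP_DAYS))
    return replace(daily, gap_flag=flag)
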