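import numpy as np
import pandas as pd
import pytest

from beatvar.beat_io import COLUMNS, BeatSeries, compute_map


def make_series(times, sbp, dbp, **optional) -> BeatSeries:
    """Build a consistent BeatSeries from minimal inputs (test helper)."""
    t = np.asarray(times, dtype=float)
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    n = len(t)
    sv = np.asarray(optional.get("sv", np.full(n, 70.0)), dtype=float)
    hr = np.asarray(optional.get("hr", np.full(n, 60.0)), dtype=float)
    map_ = np.asarray(optional.get("map", compute_map(sbp, dbp)), dtype=float)
    co = np.asarray(optional.get("co", sv * hr / 1000.0), dtype=float)
    tpr = np.asarray(optional.get("tpr", map_ / co), dtype=float)
    data = pd.DataFrame(
        {
            "time_s": t, "hr_bpm": hr, "sbp_mmhg": sbp, "dbp_mmhg": dbp,
            "map_mmhg": map_, "sv_ml": sv, "co_lmin": co, "tpr_mu": tpr,
        },
        columns=list(COLUMNS),
    )
    return BeatSeries(data=data, subject_id="test", phase="rest", group="other")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def sinusoid_series():
    """MAP = 90 + 6 sin(2 pi 0.4 t), densely sampled (10 beats/s)."""
    t = np.arange(0, 60, 0.1)
    map_ = 90 + 6 * np.sin(2 * np.pi * 0.4 * t)
    # choose sbp/dbp so that the MAP column equals the designed sinusoid
    dbp = map_ - 10.0
    sbp = dbp + 30.0
    return make_series(t, sbp, dbp, map=map_)
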