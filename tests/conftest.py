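import numpy as np
import pandas as pd
import pytest

from qct.core import BEAT_COLUMNS, BeatSeries

DEFAULTS = {
    "hr": 60.0, "dbp": 80.0, "pp": 40.0, "pep": 100.0, "lvet": 280.0,
    "sv": 80.0, "co": 6.0, "hi": 12.0, "svr": 1200.0, "tac": 1.5, "tfc": 28.0,
}


def make_beats(n=120, hr=60.0, t0=0.0, rng=None, jitter=0.0,
               subject_id="test"):
    """Constant-channel beat series at fixed heart rate (optionally jittered).

    Beat times follow the beat clock exactly: dt = 60/hr of the prior beat.
    """
    hr_vals = np.full(n, float(hr))
    if rng is not None and jitter > 0:
        hr_vals = hr_vals + rng.normal(0, jitter, n)
    t = np.empty(n)
    t[0] = t0
    for k in range(1, n):
        t[k] = t[k - 1] + 60.0 / hr_vals[k - 1]
    cols = {"t_s": t, "hr": hr_vals}
    for ch, v in DEFAULTS.items():
        if ch == "hr":
            continue
        vals = np.full(n, v)
        if rng is not None and jitter > 0 and ch not in ("pp",):
            vals = vals + rng.normal(0, jitter, n)
        cols[ch] = vals
    cols["sbp"] = cols["dbp"] + cols["pp"]
    df = pd.DataFrame({c: cols[c] for c in BEAT_COLUMNS})
    return BeatSeries(subject_id=subject_id, beats=df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully usable cohort (6 fainters / 4 controls)."""
    from qct.synth import CohortSpec, simulate_cohort

    spec = CohortSpec(n_syncope=6, n_control=4, seed=314159)
    return simulate_cohort(spec)
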