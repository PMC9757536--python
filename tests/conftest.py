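import numpy as np
import pandas as pd
import pytest

from resilac.elc import N_DIM
from resilac.preprocessing import LactationSeries


def make_lactation(yields, cow_id="cow1", parity=1, herd="H1", **kw) -> LactationSeries:
    yields = np.asarray(yields, dtype=float)
    return LactationSeries(
        cow_id=cow_id,
        parity=parity,
        yields=yields,
        observed_mask=~np.isnan(yields),
        herd=herd,
        calving_date=pd.Timestamp("2018-04-01"),
        **kw,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated herd shared across integration tests."""
    from resilac.synthetic import SyntheticConfig, simulate_dataset

    cfg = SyntheticConfig(n_sires=8, n_daughters_per_sire=8, seed=7)
    records, pedigree, truth = simulate_dataset(cfg)
    return cfg, records, pedigree, truth


@pytest.fixture
def wood_curve():
    from resilac.elc import evaluate_model

    return evaluate_model("wood", (30.0, 0.2, 0.005))


def brute_force_fluctuations(actual, fitted, min_days=10, frac=0.9):
    """Independent event scanner: enumerate every (start, end) window and
    keep maximal all-negative runs of sufficient length and depth."""
    dev = actual - fitted
    neg = dev < 0
    events = []
    for s in range(N_DIM):
        if not neg[s] or (s > 0 and neg[s - 1]):
            continue  # not the start of a maximal run
        for e in range(s, N_DIM):
            if not neg[e]:
                break
            end = e
        length = end - s + 1
        if length < min_days:
            continue
        if not np.any(actual[s : end + 1] < frac * fitted[s : end + 1]):
            continue
        shortfall = fitted[s : end + 1] - actual[s : end + 1]
        events.append(
            (
                s + 1,
                end + 1,
                s + int(np.argmax(shortfall)) + 1,
                length,
                float(shortfall.sum()),
            )
        )
    return events
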