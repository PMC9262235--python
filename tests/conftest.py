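"""Shared helpers and small fixtures for the test suite."""

import numpy as np
import pandas as pd
import pytest

from saliotime import (
    ActivityParams,
    ChangeSeries,
    DesignSpec,
    LayerTimeSeries,
    ReportModelParams,
    make_design,
    simulate_hierarchy_activity,
    simulate_reports,
)


def mk_series(values, **kw):
    """LayerTimeSeries with sensible defaults; values is (n_trs, n_channels)."""
    defaults = dict(
        tr_seconds=0.8,
        hierarchy="visual",
        layer=0,
        participant=0,
        trial=0,
        scene="office",
        duration_s=8.0,
    )
    defaults.update(kw)
    return LayerTimeSeries(values=np.asarray(values, float), **defaults)


def mk_change(delta, *, standardized=True, metric="signed", **kw):
    """ChangeSeries whose first TR is invalid; delta given for the valid TRs."""
    delta = np.asarray(delta, float)
    full = np.concatenate([[np.nan], delta])
    valid = np.concatenate([[False], np.ones(len(delta), bool)])
    defaults = dict(
        tr_seconds=0.8,
        hierarchy="visual",
        layer=0,
        participant=0,
        trial=0,
        scene="office",
        duration_s=8.0,
    )
    defaults.update(kw)
    return ChangeSeries(
        delta=full, valid=valid, metric=metric, standardized=standardized, **defaults
    )


@pytest.fixture(scope="session")
def small_bundle():
    """4 participants x 1 block x 20 trials, one 3-layer hierarchy."""
    design = DesignSpec(
        n_participants=4, blocks_per_participant=1, trials_per_block=20, seed=11
    )
    trials = simulate_reports(make_design(design), ReportModelParams(seed=12))
    params = ActivityParams(
        hierarchy="visual",
        channels_per_layer=(10, 10, 10),
        event_rate={"office": 0.25, "city": 0.5},
        seed=13,
    )
    series, latent = simulate_hierarchy_activity(trials, params)
    return trials, series, latent


@pytest.fixture(scope="session")
def bias_pair():
    """Correlated (human, model) bias vectors plus participant labels."""
    rng = np.random.default_rng(7)
    n_p, n_t = 8, 30
    pid = np.repeat(np.arange(n_p), n_t)
    model = rng.normal(size=n_p * n_t)
    human = 0.6 * model + rng.normal(size=n_p * n_t)
    return pd.DataFrame({"participant": pid, "bias_model": model, "bias_human": human})
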