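"""Shared fixtures: parameter sets and a reusable DA-generated flicker dataset."""
from __future__ import annotations

import numpy as np
import pytest

from photodyn import (
    FlickerSpec,
    TimeGrid,
    estimate_ln,
    load_paramset,
    make_gaussian_flicker,
    simulate_da,
)

SET_NAMES = ("salamander", "bhl", "b", "dn")


@pytest.fixture(scope="session")
def paramsets():
    return {name: load_paramset(name) for name in SET_NAMES}


@pytest.fixture(scope="session")
def da_flicker_dataset(paramsets):
    """A long flicker stimulus/response pair generated by the DA model with
    the salamander parameter set (the frame-hold, 35%-contrast protocol),
    plus a fitted LN model. Shared across the LN and acceptance tests."""
    p = paramsets["salamander"]
    grid = TimeGrid.from_duration(200_000, 5.0)
    spec = FlickerSpec(mean=30.0, sigma=0.35, correlation="hold", hold_ms=30.0,
                       seed=42)
    stim = make_gaussian_flicker(spec, grid)
    resp = simulate_da(stim, p)
    model = estimate_ln(stim, resp, filter_ms=500.0, degree=3)
    return {"params": p, "stim": stim, "resp": resp, "ln": model, "spec": spec}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
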