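"""Shared fixtures.

The expensive session fixtures simulate the full-size barrel-cortex network
once and are reused by every test that needs network activity:

* ``bcn_batches`` / ``bcn_traces`` — catch and step batches of the bare BCN,
  used for spontaneous rates, the SOM plateau, and integrator/differentiator
  detection statistics (84 trials per condition),
* ``dnr_batches`` / ``dnr_traces`` — a smaller batch set (48 trials per
  condition) with the desk-scale differentiator readout network attached,
  used wherever the explicit readout circuit is required.

Trial counts are desk-scale: they resolve rates and time courses well and
effect sizes at confidence-interval level (the original study used 10 000
trials per condition).
"""

from __future__ import annotations

import numpy as np
import pytest

import nanostim as ns
from nanostim.readouts import compute_traces

N_BCN_TRIALS = 84
N_DNR_TRIALS = 48


@pytest.fixture(scope="session")
def bcn():
    """One frozen full-size BCN realization (no readout network)."""
    return ns.build_network(seed=1)


@pytest.fixture(scope="session")
def bcn_dnr():
    """Full-size BCN with the desk-scale differentiator readout network."""
    preset = ns.desk_small()
    return ns.build_network(preset.network, seed=1,
                            readout_config=preset.readout, with_dnr=True)


@pytest.fixture(scope="session")
def bcn_batches(bcn):
    conds = {
        "catch_a": ns.CATCH,
        "catch_b": ns.CATCH,
        "step100": ns.step_stimulus(100, 0.25),
        "step400": ns.step_stimulus(400, 0.25),
    }
    return {name: ns.simulate_batch(bcn, stim, N_BCN_TRIALS,
                                    master_seed=5000 + j, t_end=700.0)
            for j, (name, stim) in enumerate(conds.items())}


@pytest.fixture(scope="session")
def bcn_traces(bcn, bcn_batches):
    """Integrator and differentiator readout traces for the BCN batches."""
    traces = {name: compute_traces(recs, bcn, which=("ir", "dr"))
              for name, recs in bcn_batches.items()}
    t_grid = traces["catch_a"][0]
    return t_grid, {name: tr for name, (_, tr) in traces.items()}


@pytest.fixture(scope="session")
def dnr_batches(bcn_dnr):
    conds = {
        "catch": ns.CATCH,
        "step400": ns.step_stimulus(400, 0.25),
        "irregular": (lambda j, rng: ns.irregular_stimulus(rng)),
    }
    return {name: ns.simulate_batch(bcn_dnr, stim, N_DNR_TRIALS,
                                    master_seed=7000 + j, t_end=700.0)
            for j, (name, stim) in enumerate(conds.items())}


@pytest.fixture(scope="session")
def dnr_traces(bcn_dnr, dnr_batches):
    """All three readout traces for the DNR-extended batches."""
    traces = {name: compute_traces(recs, bcn_dnr)
              for name, recs in dnr_batches.items()}
    t_grid = traces["catch"][0]
    return t_grid, {name: tr for name, (_, tr) in traces.items()}
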