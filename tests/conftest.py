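import numpy as np
import pytest
from hypothesis import settings

import trackchem as tc

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def network():
    return tc.load_scheme()


@pytest.fixture(scope="session")
def fricke():
    return tc.BulkSolution.fricke(0.0)


@pytest.fixture(scope="session")
def params():
    """Frozen calibrated track-geometry defaults."""
    return tc.TrackModelParams()


@pytest.fixture(scope="session")
def small_track(params):
    """A small low-LET segment for fast engine tests."""
    beam = tc.BeamSpec(let_value=9.3)
    return tc.generate_track(beam, params, seed=42, target_particles=1500)


@pytest.fixture(scope="session")
def small_log(small_track, network, fricke):
    rng = np.random.default_rng(43)
    return tc.run_track_stage(small_track, network, fricke, 1.0e-6, rng)


def g_fe3_200s(let, cystamine, seed, network, *, mi=0.0, target_particles=None):
    """Full pipeline: one replicate's 200-s ferric yield."""
    from dataclasses import replace

    params = replace(tc.TrackModelParams(), mi_probability=mi)
    bulk = tc.BulkSolution.fricke(cystamine)
    if target_particles is None:
        target_particles = 9000 if let >= 100 else 5000
    seg = tc.generate_track(
        tc.BeamSpec(let_value=let), params, seed=seed,
        target_particles=target_particles,
    )
    log = tc.run_track_stage(seg, network, bulk, 1.0e-6, np.random.default_rng(seed + 7))
    table = tc.propagate_bulk_stage(log.survivor_yields(), bulk, network, t_start=1.0e-6)
    return float(table.g("Fe3+")[-1])
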