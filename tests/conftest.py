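"""Shared fixtures: the default network, the Z profile, and a pool of
seeded 10 s replay simulations reused across analysis and acceptance
tests (session-scoped — the pool is the expensive part of the suite)."""

import numpy as np
import pytest

import ltpie

POOL_SEEDS = (101, 102, 103)


@pytest.fixture(scope="session")
def z_traj():
    return ltpie.z_trajectory()


@pytest.fixture(scope="session")
def default_model():
    return ltpie.assemble_network(seed=1)


@pytest.fixture(scope="session")
def z_profile(default_model, z_traj):
    return ltpie.profile_from_trajectory(default_model.peaks, z_traj)


@pytest.fixture(scope="session")
def pooled_runs(default_model, z_profile):
    """Three independent 10 s default-parameter replay simulations."""
    return [
        ltpie.run_network(default_model, z_profile, duration=10_000.0,
                          seed=s)
        for s in POOL_SEEDS
    ]


@pytest.fixture(scope="session")
def pooled_events(pooled_runs, default_model, z_profile, z_traj):
    """Per-run analyzed events for the pooled simulations."""
    return [
        ltpie.analyze_run(res, z_profile, trajectory=z_traj,
                          peaks=default_model.peaks)
        for res in pooled_runs
    ]


def min_isi(result):
    """Minimum per-neuron inter-spike interval in a SimResult (ms)."""
    ids = result.pc_spike_ids()
    t = result.pc_spike_times()
    order = np.lexsort((t, ids))
    ids_s, t_s = ids[order], t[order]
    same = ids_s[1:] == ids_s[:-1]
    if not same.any():
        return np.inf
    return float(np.min(np.diff(t_s)[same]))
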