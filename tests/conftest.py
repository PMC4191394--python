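"""Shared fixtures: the idealized reference, small ideal helices, and
one pair of matched WT / cut-A/D-loop replica-exchange ensembles reused
by every test that needs sampled conformations."""

import numpy as np
import pytest

from toprna.cg_engine import SimulationProtocol, run_replica_exchange
from toprna.fixtures_reference import build_reference_trna, ideal_duplex
from toprna.secstruct_topology import apply_variant

# matched short-run conditions for the WT / cut comparison: 8 replicas
# (300-450 K), 4e5 steps per replica, first 1.2e5 discarded, snapshots
# every 1000 steps at 300 K
PAIRED_RUN = dict(
    total_steps=500_000,
    n_replicas=8,
    seed=11,
    equilibration_steps=150_000,
    exchange_interval=1000,
    snapshot_interval=1000,
)


@pytest.fixture(scope="session")
def wt_reference():
    return build_reference_trna(seed=0)


@pytest.fixture(scope="session")
def wt_topology(wt_reference):
    return wt_reference.topology


@pytest.fixture(scope="session")
def duplex5():
    return ideal_duplex(5)


@pytest.fixture(scope="session")
def wt_ensemble(wt_reference):
    proto = SimulationProtocol(**PAIRED_RUN)
    return run_replica_exchange(
        wt_reference.topology, proto, wt_reference.coords
    )


@pytest.fixture(scope="session")
def cut_ad_ensemble(wt_reference):
    topo = apply_variant(wt_reference.topology, "cut", residue=8)
    proto = SimulationProtocol(**PAIRED_RUN)
    return run_replica_exchange(topo, proto, wt_reference.coords)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
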