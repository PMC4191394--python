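"""Shared oracle: Langevin samples of one harmonic bond plus the
analytic Boltzmann distance CDF (computed once per session)."""

import functools

import numpy as np

from toprna import forcefield as ff
from toprna.cg_engine import System
from toprna.secstruct_topology import BeadTopology

BOND_K = 4.0    # kcal/mol/A^2 (E = k (b - b0)^2)
BOND_R0 = 4.0   # A
TEMPERATURE = 300.0


def two_bead_bond_topology():
    n = 2
    return BeadTopology(
        sequence="NN",
        pairs=[],
        bead_kind=["P", "P"],
        bead_resid=np.array([1, 2]),
        lj_radius=np.full(n, ff.LJ_RADIUS["P"]),
        lj_eps=np.full(n, ff.EPS_REPULSIVE),
        stacky=np.zeros(n, dtype=bool),
        mass=np.full(n, 95.0),
        bonds=np.array([[0, 1]], dtype=np.int64),
        bond_r0=np.array([BOND_R0]),
        bond_k=np.array([BOND_K]),
        angles=np.empty((0, 3), dtype=np.int64),
        angle_t0=np.empty(0),
        angle_k=np.empty(0),
        impropers=np.empty((0, 4), dtype=np.int64),
        impr_phi0=np.empty(0),
        impr_k=np.empty(0),
        dihedrals=np.empty((0, 4), dtype=np.int64),
        dihe_phi0=np.empty(0),
        dihe_k=np.empty(0),
        m_bead_of_pair={},
        strand_breaks=frozenset(),
    )


@functools.lru_cache(maxsize=1)
def harmonic_bond_samples():
    """(samples, analytic CDF callable) for the bond-length law
    p(r) ~ r^2 exp(-beta k (r - r0)^2)."""
    topo = two_bead_bond_topology()
    sys_ = System(topo)
    x = np.array([[0.0, 0.0, 0.0], [BOND_R0, 0.0, 0.0]])
    v = np.zeros_like(x)
    sys_.run_chunk(x, v, 20_000, TEMPERATURE, 5.0, 0.01, 3)
    samples = np.empty(3000)
    for c in range(3000):
        sys_.run_chunk(x, v, 50, TEMPERATURE, 5.0, 0.01, 1000 + c)
        samples[c] = np.linalg.norm(x[0] - x[1])
    beta = 1.0 / (ff.KB * TEMPERATURE)
    grid = np.linspace(1e-3, BOND_R0 + 4.0, 4000)
    pdf = grid ** 2 * np.exp(-beta * BOND_K * (grid - BOND_R0) ** 2)
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]

    def cdf_fn(r):
        return np.interp(r, grid, cdf)

    return samples, cdf_fn
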