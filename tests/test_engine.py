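"""Potential terms, integrator and replica exchange."""

import numpy as np
import pytest
from scipy import stats

from toprna import _kernels
from toprna import forcefield as ff
from toprna.cg_engine import (
    Ensemble,
    NumericalBlowupError,
    SimulationProtocol,
    System,
    energy_forces,
    exchange_probability,
    fold_with_restraints,
    restraint_energy_force,
    run_replica_exchange,
)
from toprna.fixtures_reference import (
    TERTIARY_PAIRS,
    ideal_duplex,
)
from toprna.secstruct_topology import (
    BeadTopology,
    RestraintSpec,
    build_topology,
    make_restraints,
    parse_secondary_structure,
)


def _bare_topology(n_beads, bonds=(), bond_r0=(), bond_k=(),
                   restraints=()):
    """Minimal hand-built topology for kernel-level checks."""
    return BeadTopology(
        sequence="N" * n_beads,
        pairs=[],
        bead_kind=["P"] * n_beads,
        bead_resid=np.arange(1, n_beads + 1),
        lj_radius=np.full(n_beads, ff.LJ_RADIUS["P"]),
        lj_eps=np.full(n_beads, ff.EPS_REPULSIVE),
        stacky=np.zeros(n_beads, dtype=bool),
        mass=np.full(n_beads, 95.0),
        bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
        bond_r0=np.array(bond_r0, dtype=float),
        bond_k=np.array(bond_k, dtype=float),
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
        restraints=list(restraints),
    )


class TestForces:
    def test_lj_force_zero_at_contact_distance(self):
        topo = _bare_topology(2)
        sys_ = System(topo)
        rmin = 2 * ff.LJ_RADIUS["P"]
        x = np.array([[0.0, 0.0, 0.0], [rmin, 0.0, 0.0]])
        e, f, bd = sys_.energy_forces(x)
        assert np.allclose(f, 0.0, atol=1e-12)
        assert bd["lj"] < 0  # sitting in the (shifted) well

    def test_restraint_zero_inside_window(self):
        spec = RestraintSpec(0, 1, 5.0, 8.0)
        for d in (5.0, 6.1, 7.9, 8.0):
            assert restraint_energy_force(d, spec) == (0.0, 0.0)

    def test_restraint_harmonic_wall(self):
        spec = RestraintSpec(0, 1, 5.5, 7.5)
        e, f = restraint_energy_force(7.6, spec)
        assert f == pytest.approx(-0.2)  # 2.0 * 0.1, pulling inward
        assert e == pytest.approx(0.5 * 2.0 * 0.1 ** 2)

    def test_restraint_force_caps_far_outside(self):
        spec = RestraintSpec(0, 1, 5.5, 7.5)
        _, f_far = restraint_energy_force(17.5, spec)
        assert abs(f_far) == pytest.approx(2.0)
        _, f_in = restraint_energy_force(0.5, spec)
        assert f_in == pytest.approx(2.0)  # pushes outward

    def test_forces_match_finite_differences(self, rng):
        # randomized thermally-perturbed configurations, every term
        # active including a restraint
        topo, x0 = ideal_duplex(4)
        topo.restraints = [RestraintSpec(2, 20, 5.0, 8.0)]
        sys_ = System(topo)
        h = 1e-5
        for _ in range(3):
            x = x0 + rng.normal(scale=0.8, size=x0.shape)
            _, f, _ = sys_.energy_forces(x)
            for _ in range(60):
                i = rng.integers(topo.n_beads)
                c = rng.integers(3)
                xp, xm = x.copy(), x.copy()
                xp[i, c] += h
                xm[i, c] -= h
                ep, _, _ = sys_.energy_forces(xp)
                em, _, _ = sys_.energy_forces(xm)
                fd = -(ep - em) / (2 * h)
                assert fd == pytest.approx(
                    f[i, c], rel=1e-5, abs=1e-5
                )

    def test_coordinate_topology_mismatch_rejected(self, wt_topology):
        with pytest.raises(ValueError):
            energy_forces(np.zeros((10, 3)), wt_topology)


class TestIntegrator:
    def test_nve_energy_drift_small(self, rng):
        # zero-friction, no-thermostat limit is velocity Verlet; a
        # 2-nt chain run 1e5 steps conserves energy to < 0.1%
        topo = build_topology(parse_secondary_structure(".."))
        sys_ = System(topo)
        g = ff.equilibrium_geometry()
        x = np.array([
            [0, 0, 0],
            [g["bond_PS"], 0, 0],
            [g["bond_PS"], g["bond_SB"], 0],
            [g["bond_PS"] + 3.0, 1.0, 1.0],
            [g["bond_PS"] + 6.0, 1.0, 1.0],
            [g["bond_PS"] + 6.0, 5.0, 1.0],
        ], dtype=float)
        x = sys_.minimize(x, maxiter=800)
        v = rng.standard_normal((6, 3)) * np.sqrt(
            _kernels.ACC_FACTOR * ff.KB * 300 / topo.mass
        )[:, None]
        e0, _, _ = sys_.energy_forces(x)
        k0 = _kernels.kinetic_energy(v, topo.mass)
        sys_.run_chunk(x, v, 100_000, 300.0, 4.0, 0.0, 9)
        e1, _, _ = sys_.energy_forces(x)
        k1 = _kernels.kinetic_energy(v, topo.mass)
        assert abs((e1 + k1) - (e0 + k0)) / abs(e0 + k0) < 1e-3

    def test_harmonic_bond_boltzmann_distribution(self):
        # single-temperature Langevin sampling of one harmonic bond
        # reproduces the analytic r^2 exp(-beta k (r-r0)^2) law
        from tests_support_boltzmann import harmonic_bond_samples

        samples, cdf_fn = harmonic_bond_samples()
        assert stats.kstest(samples, cdf_fn).pvalue > 0.01

    def test_kinetic_temperature_equipartition(self, duplex5):
        # thermostat accuracy is checked at a small timestep where the
        # BAOAB kinetic-energy artifact is negligible
        topo, x0 = duplex5
        sys_ = System(topo)
        x = x0.copy()
        v = np.zeros_like(x)
        sys_.run_chunk(x, v, 20_000, 300.0, 5.0, 0.005, 11)
        kes = []
        for c in range(60):
            sys_.run_chunk(x, v, 2000, 300.0, 5.0, 0.005, 500 + c)
            kes.append(_kernels.kinetic_energy(v, topo.mass))
        t_kin = 2 * np.mean(kes) / (3 * topo.n_beads * ff.KB)
        assert t_kin == pytest.approx(300.0, rel=0.02)

    def test_restrained_pair_concentrates_in_window(self):
        # two free beads joined only by a flat-bottom restraint: the
        # stationary distance law is r^2 exp(-beta E_res(r)); compare
        # the observed in-window probability to its 1-D integral
        spec = RestraintSpec(0, 1, 5.0, 8.0)
        topo = _bare_topology(2, restraints=[spec])
        sys_ = System(topo)
        x = np.array([[0.0, 0.0, 0.0], [6.5, 0.0, 0.0]])
        v = np.zeros_like(x)
        sys_.run_chunk(x, v, 20_000, 300.0, 5.0, 0.02, 4)
        inside = []
        for c in range(4000):
            sys_.run_chunk(x, v, 50, 300.0, 5.0, 0.02, 2000 + c)
            d = np.linalg.norm(x[0] - x[1])
            inside.append(spec.r_min <= d <= spec.r_max)
        beta = 1.0 / (ff.KB * 300.0)
        grid = np.linspace(1e-3, 20.0, 8000)
        e_res = np.array([
            restraint_energy_force(r, spec)[0] for r in grid
        ])
        w = grid ** 2 * np.exp(-beta * e_res)
        mask = (grid >= spec.r_min) & (grid <= spec.r_max)
        p_pred = w[mask].sum() / w.sum()
        p_obs = np.mean(inside)
        assert p_obs == pytest.approx(p_pred, abs=0.1)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            SimulationProtocol(
                total_steps=1000, equilibration_steps=1000
            )
        with pytest.raises(ValueError):
            SimulationProtocol(
                total_steps=10_000, t_low=400.0, t_high=300.0
            )
        temps = SimulationProtocol(total_steps=10_000).temperatures
        assert np.all(np.diff(temps) > 0)
        assert temps[0] == 300.0 and temps[-1] == 450.0

    def test_blowup_aborts_with_diagnostic(self, wt_topology):
        proto = SimulationProtocol(
            total_steps=4000, n_replicas=1, seed=0,
            equilibration_steps=0,
        )
        bad = np.zeros((wt_topology.n_beads, 3))  # every bead overlaps
        with pytest.raises(NumericalBlowupError) as err:
            run_replica_exchange(wt_topology, proto, bad)
        assert err.value.last_stable_step >= 0


class TestReplicaExchange:
    def test_exchange_probability_metropolis(self):
        assert exchange_probability(1.0, 0.8, 5.0, 5.0) == 1.0
        assert exchange_probability(1.0, 1.0, 2.0, 9.0) == 1.0
        # unfavorable: colder replica taking the higher energy
        p = exchange_probability(1.0, 0.8, 2.0, 9.0)
        assert 0 < p < 1
        assert p == pytest.approx(np.exp((1.0 - 0.8) * (2.0 - 9.0)))

    def test_same_seed_reproduces_snapshots(self, duplex5):
        topo, coords = duplex5
        proto = SimulationProtocol(
            total_steps=20_000, n_replicas=2, seed=42,
            equilibration_steps=2000,
        )
        e1 = run_replica_exchange(topo, proto, coords)
        e2 = run_replica_exchange(topo, proto, coords)
        assert np.array_equal(e1.coords, e2.coords)
        assert np.array_equal(e1.walker, e2.walker)

    def test_no_restraints_identical_to_plain_run(self, duplex5):
        topo, coords = duplex5
        proto = SimulationProtocol(
            total_steps=12_000, n_replicas=2, seed=3,
            equilibration_steps=2000,
        )
        plain = run_replica_exchange(topo, proto, coords)
        folded = fold_with_restraints(topo, [], proto, coords)
        assert np.array_equal(plain.coords, folded.coords)

    def test_single_replica_matches_ladder_on_toy_bulge(self):
        # coarse observable (mean radius of gyration at 300 K) agrees
        # between a 1-replica run and an 8-replica ladder
        ss = parse_secondary_structure("((((..((((....))))))))")
        topo = build_topology(ss)
        from toprna.fixtures_reference import place_ideal_pairs, _fill_single_strands

        coords = np.full((topo.n_beads, 3), np.nan)
        for h, off in zip(ss.helices, (0.0, 40.0)):
            place_ideal_pairs(
                coords, topo, list(h.pairs),
                translation=np.array([off, 0.0, 0.0]),
            )
        _fill_single_strands(coords, topo)
        coords = System(topo).minimize(coords, maxiter=500)

        def rg_series(n_replicas, seed):
            proto = SimulationProtocol(
                total_steps=300_000, n_replicas=n_replicas, seed=seed,
                equilibration_steps=60_000, snapshot_interval=2000,
            )
            ens = run_replica_exchange(topo, proto, coords)
            rg = [
                np.sqrt(((c - c.mean(0)) ** 2).sum(1).mean())
                for c in ens.coords
            ]
            return np.array(rg)

        rg1 = rg_series(1, 5)
        rg8 = rg_series(8, 5)
        sem = np.hypot(rg1.std() / np.sqrt(8), rg8.std() / np.sqrt(8))
        assert abs(rg1.mean() - rg8.mean()) < 4 * sem + 0.1 * rg1.mean()

    def test_restrained_run_satisfies_windows(self, wt_reference):
        # short restrained run in the spirit of the nine-interaction
        # native-restrained simulation: windows hold in >= 95% of
        # snapshots
        topo = wt_reference.topology
        specs = []
        for (i, j) in TERTIARY_PAIRS:
            kind = "g26_pair" if (i, j) == (26, 44) else "tertiary_pair"
            specs += make_restraints(kind, (i, j), topo)
        proto = SimulationProtocol(
            total_steps=60_000, n_replicas=2, seed=8,
            equilibration_steps=10_000,
        )
        ens = fold_with_restraints(topo, specs, proto, wt_reference.coords)
        assert ens.restraint_satisfaction is not None
        assert ens.restraint_satisfaction.mean() >= 0.95

    def test_missing_restraint_bead_rejected(self, wt_topology):
        proto = SimulationProtocol(total_steps=4000, n_replicas=1)
        bad = [RestraintSpec(0, 10_000, 5.0, 7.0)]
        with pytest.raises(ValueError):
            fold_with_restraints(
                wt_topology, bad, proto,
                np.zeros((wt_topology.n_beads, 3)),
            )

    def test_ensemble_h5_roundtrip(self, tmp_path, duplex5):
        topo, coords = duplex5
        proto = SimulationProtocol(
            total_steps=8000, n_replicas=2, seed=1,
            equilibration_steps=2000,
        )
        ens = run_replica_exchange(topo, proto, coords)
        path = tmp_path / "traj.h5"
        ens.save_h5(path)
        back = Ensemble.load_h5(path)
        assert np.array_equal(back.coords, ens.coords)
        assert back.topology.term_set() == topo.term_set()
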