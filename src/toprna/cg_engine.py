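"""Potential evaluation and temperature replica-exchange Langevin
dynamics.

The potential is the sum of bond, angle, chirality-improper and
(helix-only) backbone-dihedral terms, a 6-12 Lennard-Jones steric term
with the selective paired-B/M stacking attraction, and optional
flat-bottom distance restraints.  Electrostatics are deliberately
absent.  Dynamics use a BAOAB-discretized Langevin integrator (20 fs
timestep, 5 ps^-1 friction by default) with Metropolis temperature
exchanges between neighboring replicas on an exponentially spaced
300-450 K ladder; snapshots are recorded at the lowest-temperature
replica only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels, forcefield as ff
from .secstruct_topology import BeadTopology, RestraintSpec

ENERGY_TERMS = ("bond", "angle", "improper", "dihedral", "lj", "restraint")

NLIST_SKIN = 2.0      # A
NLIST_EVERY = 10      # steps between neighbor-list rebuilds


class NumericalBlowupError(RuntimeError):
    """Coordinates became non-finite during dynamics."""

    def __init__(self, last_stable_step: int):
        self.last_stable_step = last_stable_step
        super().__init__(
            f"non-finite coordinates; last stable step {last_stable_step}"
        )


@dataclass
class SimulationProtocol:
    """Replica-exchange schedule and integrator settings.

    timestep in fs, friction in 1/fs (0.005 = 5 ps^-1), temperatures in
    K with exponential spacing between t_low and t_high.  Snapshots are
    taken from the t_low replica every ``snapshot_interval`` steps; the
    first ``equilibration_steps`` are discarded (default: 10% of the
    run, capped at the 2e6 steps discarded at production scale).
    """

    total_steps: int
    timestep: float = 20.0
    friction: float = 0.005
    n_replicas: int = 8
    t_low: float = 300.0
    t_high: float = 450.0
    exchange_interval: int = 2000
    snapshot_interval: int = 2000
    equilibration_steps: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.equilibration_steps is None:
            self.equilibration_steps = min(2_000_000, self.total_steps // 10)
        if not self.equilibration_steps < self.total_steps:
            raise ValueError("equilibration must be shorter than the run")
        if self.n_replicas >= 2 and not self.t_high > self.t_low:
            raise ValueError("temperatures must be strictly increasing")

    @property
    def temperatures(self) -> np.ndarray:
        if self.n_replicas == 1:
            return np.array([self.t_low])
        k = np.arange(self.n_replicas)
        return self.t_low * (self.t_high / self.t_low) ** (
            k / (self.n_replicas - 1)
        )


@dataclass
class Ensemble:
    """Ordered snapshots (A) of the t_low replica plus provenance."""

    coords: np.ndarray                    # (n_snap, n_beads, 3)
    topology: BeadTopology
    protocol: SimulationProtocol
    steps: np.ndarray = None              # dynamics step of each snapshot
    walker: np.ndarray = None             # walker id occupying t_low
    restraint_satisfaction: np.ndarray | None = None
    exchange_acceptance: np.ndarray | None = None  # per neighbor pair

    @property
    def n_snapshots(self) -> int:
        return len(self.coords)

    def __post_init__(self):
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_beads:
            raise ValueError("snapshot shape does not match topology")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite snapshot coordinates")

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("coords", data=self.coords)
            h5.create_dataset("steps", data=self.steps)
            h5.create_dataset("walker", data=self.walker)
            if self.restraint_satisfaction is not None:
                h5.create_dataset(
                    "restraint_satisfaction", data=self.restraint_satisfaction
                )
            h5.attrs["topology"] = self.topology.to_json()
            for k in (
                "total_steps", "timestep", "friction", "n_replicas",
                "t_low", "t_high", "exchange_interval", "snapshot_interval",
                "equilibration_steps", "seed",
            ):
                h5.attrs[k] = getattr(self.protocol, k)

    @classmethod
    def load_h5(cls, path) -> "Ensemble":
        import h5py

        with h5py.File(path, "r") as h5:
            topo = BeadTopology.from_json(h5.attrs["topology"])
            proto = SimulationProtocol(
                **{
                    k: (
                        int(h5.attrs[k])
                        if k in (
                            "total_steps", "n_replicas", "exchange_interval",
                            "snapshot_interval", "equilibration_steps", "seed",
                        )
                        else float(h5.attrs[k])
                    )
                    for k in (
                        "total_steps", "timestep", "friction", "n_replicas",
                        "t_low", "t_high", "exchange_interval",
                        "snapshot_interval", "equilibration_steps", "seed",
                    )
                }
            )
            rs = (
                h5["restraint_satisfaction"][:]
                if "restraint_satisfaction" in h5
                else None
            )
            return cls(
                coords=h5["coords"][:],
                topology=topo,
                protocol=proto,
                steps=h5["steps"][:],
                walker=h5["walker"][:],
                restraint_satisfaction=rs,
            )


class System:
    """Topology packed into kernel-ready arrays."""

    def __init__(
        self,
        topology: BeadTopology,
        restraints: list[RestraintSpec] | None = None,
    ):
        self.topology = topology
        n = topology.n_beads
        rad = topology.lj_radius
        self.rmin_mat = rad[:, None] + rad[None, :]
        eps = np.full((n, n), ff.EPS_REPULSIVE)
        st = topology.stacky
        eps[np.ix_(st, st)] = topology.eps_stack
        excl = topology.exclusion_matrix()
        eps[excl == 0] = 0.0
        self.eps_mat = eps
        self.excl = excl
        self.cutoff = ff.LJ_CUTOFF
        s2 = (self.rmin_mat / self.cutoff) ** 2
        s6 = s2 ** 3
        self.shift_mat = eps * (s6 ** 2 - 2.0 * s6)
        self.rlist = self.cutoff + NLIST_SKIN

        specs = list(topology.restraints)
        if restraints:
            specs += list(restraints)
        self.restraints = specs
        if specs:
            self.res_idx = np.array(
                [[r.bead_i, r.bead_j] for r in specs], dtype=np.int64
            )
            self.res_rmin = np.array([r.r_min for r in specs])
            self.res_rmax = np.array([r.r_max for r in specs])
            self.res_kmin = np.array([r.k_min for r in specs])
            self.res_kmax = np.array([r.k_max for r in specs])
            self.res_fmax = np.array([r.fmax for r in specs])
        else:
            self.res_idx = np.empty((0, 2), dtype=np.int64)
            self.res_rmin = self.res_rmax = np.empty(0)
            self.res_kmin = self.res_kmax = self.res_fmax = np.empty(0)

    def _term_args(self):
        t = self.topology
        return (
            t.bonds, t.bond_r0, t.bond_k,
            t.angles, t.angle_t0, t.angle_k,
            t.impropers, t.impr_phi0, t.impr_k,
            t.dihedrals, t.dihe_phi0, t.dihe_k,
            self.cutoff,
            self.res_idx, self.res_rmin, self.res_rmax,
            self.res_kmin, self.res_kmax, self.res_fmax,
        )

    def energy_forces(self, coords: np.ndarray):
        x = np.ascontiguousarray(coords, dtype=np.float64)
        if x.shape != (self.topology.n_beads, 3):
            raise ValueError("coordinate/topology mismatch")
        n = x.shape[0]
        maxp = n * (n - 1) // 2
        pi_buf = np.empty(maxp, dtype=np.int64)
        pj_buf = np.empty(maxp, dtype=np.int64)
        rmin_buf = np.empty(maxp)
        eps_buf = np.empty(maxp)
        shift_buf = np.empty(maxp)
        # all-pairs list: exact energies regardless of configuration
        n_pairs = _kernels.build_neighbor_list_params(
            x, 1e9, self.excl, self.rmin_mat, self.eps_mat, self.shift_mat,
            pi_buf, pj_buf, rmin_buf, eps_buf, shift_buf,
        )
        f = np.zeros_like(x)
        e = _kernels.forces_energy(
            x, f, *self._term_args(),
            pi_buf, pj_buf, rmin_buf, eps_buf, shift_buf, n_pairs,
        )
        breakdown = dict(zip(ENERGY_TERMS, e))
        return float(e.sum()), f, breakdown

    def run_chunk(self, x, v, n_steps, temperature, dt, gamma, seed,
                  nlist_every=NLIST_EVERY):
        e = _kernels.langevin_chunk(
            x, v, n_steps, dt, gamma, ff.KB * temperature,
            self.topology.mass, seed, *self._term_args(),
            self.rmin_mat, self.eps_mat, self.shift_mat,
            self.excl, self.rlist, nlist_every,
        )
        return e

    def minimize(self, coords, maxiter=500):
        """L-BFGS minimization using the analytic gradient."""
        from scipy.optimize import minimize as _min

        n = self.topology.n_beads

        def fun(flat):
            e, f, _ = self.energy_forces(flat.reshape(n, 3))
            return e, -f.ravel()

        res = _min(
            fun, np.asarray(coords, float).ravel(), jac=True,
            method="L-BFGS-B", options={"maxiter": maxiter},
        )
        return res.x.reshape(n, 3)


def energy_forces(coords, topology, restraints=None):
    """Total energy (kcal/mol), per-bead forces (kcal/mol/A) and the
    per-term breakdown for one configuration."""
    return System(topology, restraints).energy_forces(coords)


def restraint_energy_force(distance: float, spec: RestraintSpec):
    """Energy and radial force (positive = pushes the beads apart) of a
    flat-bottom restraint at the given distance."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    if spec.r_min <= distance <= spec.r_max:
        return 0.0, 0.0
    if distance < spec.r_min:
        delta, k, sgn = spec.r_min - distance, spec.k_min, 1.0
    else:
        delta, k, sgn = distance - spec.r_max, spec.k_max, -1.0
    dc = spec.fmax / k
    if delta <= dc:
        return 0.5 * k * delta ** 2, sgn * k * delta
    return spec.fmax * (delta - dc) + 0.5 * k * dc ** 2, sgn * spec.fmax


def exchange_probability(beta_a: float, beta_b: float,
                         e_a: float, e_b: float) -> float:
    """Metropolis probability of swapping the configurations at two
    inverse temperatures; 1 when the energy or temperature gap is 0."""
    delta = (beta_a - beta_b) * (e_a - e_b)
    return 1.0 if delta >= 0 else float(np.exp(delta))


def _thermal_velocities(rng, mass, temperature):
    sig = np.sqrt(_kernels.ACC_FACTOR * ff.KB * temperature / mass)
    return rng.standard_normal((len(mass), 3)) * sig[:, None]


def run_replica_exchange(
    topology: BeadTopology,
    protocol: SimulationProtocol,
    initial_coords: np.ndarray,
    restraints: list[RestraintSpec] | None = None,
) -> Ensemble:
    """Temperature replica-exchange Langevin dynamics.

    Exchange attempts alternate between odd and even neighbor pairs
    every ``exchange_interval`` steps with Metropolis acceptance;
    velocities are rescaled by sqrt(T_new/T_old) on accepted swaps.
    Returns the post-equilibration t_low snapshot stream; exactly
    reproducible for a fixed seed.
    """
    sys_ = System(topology, restraints)
    temps = protocol.temperatures
    nr = protocol.n_replicas
    rng = np.random.default_rng(np.random.SeedSequence([protocol.seed, 0x7E9]))

    x = [np.array(initial_coords, dtype=np.float64) for _ in range(nr)]
    v = [_thermal_velocities(rng, topology.mass, t) for t in temps]
    walkers = list(range(nr))

    chunk = protocol.exchange_interval
    if protocol.snapshot_interval % chunk:
        raise ValueError("snapshot_interval must be a multiple of the "
                         "exchange interval")
    snap_every = protocol.snapshot_interval // chunk
    n_rounds = protocol.total_steps // chunk

    seeds = np.random.SeedSequence([protocol.seed, 0xD1CE]).generate_state(
        n_rounds * nr
    ) % (2 ** 31 - 1)

    snaps, steps, walk_ids, rsat = [], [], [], []
    attempts = np.zeros(max(nr - 1, 1))
    accepts = np.zeros(max(nr - 1, 1))

    for rnd in range(n_rounds):
        energies = np.empty(nr)
        for r in range(nr):
            try:
                e = sys_.run_chunk(
                    x[r], v[r], chunk, temps[r], protocol.timestep,
                    protocol.friction, int(seeds[rnd * nr + r]),
                )
            except ZeroDivisionError as exc:
                raise NumericalBlowupError(rnd * chunk) from exc
            if not np.all(np.isfinite(x[r])):
                raise NumericalBlowupError(rnd * chunk)
            energies[r] = e.sum()
        step_now = (rnd + 1) * chunk

        # neighbor exchanges, alternating parity
        for a in range(rnd % 2, nr - 1, 2):
            b = a + 1
            beta_a = 1.0 / (ff.KB * temps[a])
            beta_b = 1.0 / (ff.KB * temps[b])
            p_acc = exchange_probability(
                beta_a, beta_b, energies[a], energies[b]
            )
            attempts[a] += 1
            if rng.random() < p_acc:
                accepts[a] += 1
                x[a], x[b] = x[b], x[a]
                v[a], v[b] = v[b], v[a]
                v[a] *= np.sqrt(temps[a] / temps[b])
                v[b] *= np.sqrt(temps[b] / temps[a])
                energies[a], energies[b] = energies[b], energies[a]
                walkers[a], walkers[b] = walkers[b], walkers[a]

        if step_now > protocol.equilibration_steps and rnd % snap_every == (
            snap_every - 1
        ):
            snaps.append(x[0].copy())
            steps.append(step_now)
            walk_ids.append(walkers[0])
            if sys_.restraints:
                d = np.linalg.norm(
                    x[0][sys_.res_idx[:, 0]] - x[0][sys_.res_idx[:, 1]],
                    axis=1,
                )
                # satisfied = within the window extended by the
                # harmonic wall range fmax/k; past that the restraint
                # force is saturated, i.e. actively violated
                wall = sys_.res_fmax / np.maximum(sys_.res_kmax, 1e-12)
                ok = (d >= sys_.res_rmin - wall) & (
                    d <= sys_.res_rmax + wall
                )
                rsat.append(ok.mean())

    with np.errstate(invalid="ignore"):
        acc = np.where(attempts > 0, accepts / np.maximum(attempts, 1), np.nan)
    return Ensemble(
        coords=np.array(snaps),
        topology=topology,
        protocol=protocol,
        steps=np.array(steps, dtype=np.int64),
        walker=np.array(walk_ids, dtype=np.int64),
        restraint_satisfaction=np.array(rsat) if rsat else None,
        exchange_acceptance=acc[: nr - 1] if nr > 1 else np.empty(0),
    )


def fold_with_restraints(
    topology: BeadTopology,
    restraints: list[RestraintSpec],
    protocol: SimulationProtocol,
    start: np.ndarray,
) -> Ensemble:
    """Replica exchange with flat-bottom restraints active; identical
    machinery to :func:`run_replica_exchange` (and an identical
    trajectory at the same seed when no restraints are supplied).
    Per-snapshot restraint-satisfaction fractions are recorded."""
    for r in restraints:
        if max(r.bead_i, r.bead_j) >= topology.n_beads:
            raise ValueError(f"restraint references missing bead: {r}")
    return run_replica_exchange(topology, protocol, start, restraints=restraints)
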