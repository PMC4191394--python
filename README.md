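# toprna

**Topology-only coarse-grained RNA simulation and analysis.**

How much of an RNA's 3D architecture is decided before any tertiary
interaction forms?  An RNA secondary structure already fixes which
strands are helical and rigid, which are single-stranded and floppy,
and how everything is wired together — and those *topological
constraints* (sterics + connectivity) restrict where the helices can
go.  `toprna` is for structural biophysicists who want to measure that
restriction directly.  It simulates the conformations accessible to a
secondary structure when *only* sterics and connectivity act, then
quantifies how much orientation space the helices sample, how strongly
their orientations are coupled, and what free-energy cost topology
assigns to tertiary contacts.  The canonical study system is the tRNA
cloverleaf and its naturally occurring variants, which ship as
built-in fixtures.

## The model in brief

Each nucleotide is three beads — phosphate (P), sugar (S), base (B) —
plus one M bead per base pair filling the steric gap between paired
bases.  Base pairs are permanently bonded; contiguously paired regions
carry backbone dihedrals that hold them in A-form; single strands and
junction pivots have no dihedrals and rotate freely; electrostatics
are absent and all beads are (almost) purely repulsive, with a small
selective stacking attraction between paired B beads.  Sampling uses
temperature replica-exchange Langevin dynamics (8 replicas, 300–450 K,
20 fs timestep, BAOAB).  Analyses include:

* interhelical Euler angles (α_h, β_h, γ_h) and the fraction of the
  orientation grid sampled (10° bins; 108 bins per pair at 60°,
  108³ for the joint 9D space of four helices),
* mutual information between helix orientations (45° bins, finite-
  sample bias corrected),
* contact probabilities and log-odds free energies
  ΔG^topo = −ln[P/(1−P)] k_BT, coaxial-stack detection, contact-group
  cooperativity C = P(joint)/∏P(cᵢ),
* best-packed conformer selection (E = n_l ε_l + n_s ε_s), smooth
  conformer entropies S_i = ln[1 + Σ exp(−rmsd³/10³)], and the
  entropy-weighted native-likeness ⟨N⟩.

See `docs/methods.md` for the full parameter table and every
convention.

## Worked example

```python
import numpy as np
from toprna import (
    build_reference_trna, SimulationProtocol, run_replica_exchange,
    coverage_3d, coverage_9d,
)
from toprna.contacts_cooperativity import contact_streams, contact_free_energy
from toprna.packing_specificity import packing_report

ref = build_reference_trna(seed=0)                      # idealized L-shaped tRNA
proto = SimulationProtocol(total_steps=200_000, n_replicas=8, seed=1)
ens = run_replica_exchange(ref.topology, proto, ref.coords)
print(f"snapshots at 300 K: {ens.n_snapshots}")
print(f"exchange acceptance: {np.round(ens.exchange_acceptance, 2)}")

cov = coverage_3d(ens, "A-stem", "T-stem")              # 10-degree grid
print(f"A/T-stem orientation coverage: {100 * cov.fraction:.2f}%")
c9 = coverage_9d(ens)                                   # 60-degree grid vs AC-stem
print(f"9D coverage: {100 * c9.fraction:.4f}%  ratio_9D/3x3D: {c9.ratio_9d_3x3d:.3f}")

streams = contact_streams(ens)
dt = contact_free_energy(streams, "D-loop|T-loop")
print(f"D-loop/T-loop contact: P = {dt.p:.3f}, dG_topo = {dt.dg_topo:+.2f} kT"
      + ("  (bound)" if dt.bounded else ""))

report = packing_report(ens, reference_coords=ref.coords)
print(f"best-packed subset: {len(report)} conformers, <N> = {report.attrs['mean_n']:.2f}")
```

Output (a couple of minutes on one CPU):

```
snapshots at 300 K: 90
exchange acceptance: [0.4  0.5  0.36 0.38 0.6  0.36 0.34]
A/T-stem orientation coverage: 0.36%
9D coverage: 0.0063%  ratio_9D/3x3D: 0.009
D-loop/T-loop contact: P = 1.000, dG_topo = -4.50 kT  (bound)
best-packed subset: 9 conformers, <N> = 0.85
```

Reading it: the replica ladder exchanges healthily (35–60%); 90
snapshots cover 0.36% of the A/T-stem orientation grid — coverage
grows monotonically with sampling toward its converged value, so short
runs give lower bounds.  At this tiny scale the molecule still
remembers its folded starting structure: the D-loop/T-loop contact is
present in *every* snapshot, so its ΔG^topo is reported as a one-sided
bound (−ln N) and flagged.  ⟨N⟩ = 0.85 says the entropy-weighted mass
of the best-packed subset is largely native-like.

Secondary-structure variants are one call away
(`fixture_topology("cut-ad")`, `"vl7"`, `"vs"`, ...), and everything
is also reachable from a thin CLI:

```sh
toprna fixtures --name wt
toprna run --fixture wt --steps 1000000 --seed 0 --out wt.h5
toprna analyze euler --traj wt.h5
```

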