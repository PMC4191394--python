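# Methods

## The model

`toprna` isolates the *topological constraints* — excluded volume and
chain connectivity — that an RNA secondary structure imposes on the 3D
arrangement of its helices.  Each nucleotide is represented by three
beads at its phosphate (P), sugar (S) and base (B) moieties; every
secondary-structure base pair carries a permanent B–B bond, a softer
supporting S–S bond, and a fourth M bead bonded midway between the
paired B beads that fills the steric gap at the pair center.
Contiguously paired regions are parameterized to fluctuate around
A-form geometry through backbone dihedral potentials that exist *only*
when all residues of the dihedral quadruple belong to one helix;
single strands and the pivot steps between coaxially adjacent but
distinct helices carry no dihedral terms and rotate freely.
Electrostatics are absent, and all nonbonded interactions are a 6–12
Lennard-Jones potential with a near-purely repulsive well depth of
0.01 kcal/mol.  The only attraction in the model is a selective
stacking well (default 0.5 kcal/mol) between B beads of *paired*
residues (and the M beads between them), which maintains intra-helix
stacking and marginally favors interhelical coaxial stacking across
junctions.  Because nothing else is attractive, the frequency of any
conformation directly reports the (mostly entropic) free-energy cost
that sterics and connectivity assign to it.

### Parameter table

All equilibrium values are measured once from an ideal A-form bead
duplex built with rise 2.81 Å and twist 32.7°/bp; the bead positions
in the base-pair frame are chosen so that paired S–S ≈ 11.2 Å (the
Watson-Crick window), paired B–B ≈ 5.6 Å, backbone bonds ≈ 3–3.8 Å and
the P–S–P backbone angle ≈ 130°.  Functional forms and constants
(kcal/mol, Å, radians):

| term | form | constant |
|---|---|---|
| bond (backbone, intra-nt) | k(b−b₀)² | 64 |
| bond (B–B pair, M–B) | k(b−b₀)² | 32 |
| bond (S–S pair support) | k(b−b₀)² | 8 |
| angle, helical step | k(cosθ−cosθ₀)² | 20 |
| angle, single strand | k(cosθ−cosθ₀)² | 5 |
| angle, pair geometry (S–B–B′) | k(cosθ−cosθ₀)² | 10 |
| chirality (signed volume at S) | k(V−V₀)² | 0.5 kcal/mol/Å⁶ |
| backbone dihedral (helix only) | k(1−cos(φ−φ₀)) | 6 |
| LJ radii P/S/B/M | r_min = rᵢ+rⱼ | 2.7 / 2.9 / 1.9 / 1.6 Å |
| LJ well depth | — | 0.01 (0.5 between paired B and M) |
| masses P/S/B/M | — | 95 / 114 / 110 / 40 amu |

Two numerical choices deserve explanation.  Angles use the
cosine-harmonic form because a harmonic-in-θ force law diverges as
1/sin θ whenever a freely rotating strand passes through a straight
configuration, which destroys energy conservation at a 20 fs timestep.
For the same reason the sugar chirality term is a *signed-volume*
potential on the three bonds leaving each S bead (V ≈ −1.3 ų in the
right-handed geometry): it is polynomial in the coordinates, so it has
no collinearity singularity, and its mirror image costs ≈ 3.4 kcal/mol
(≈ 6 k_BT), enough to preserve handedness without constraining normal
fluctuations.  Masses are group masses; they set sampling efficiency
but not equilibrium observables.

## Dynamics

Replica-exchange Langevin dynamics with a BAOAB discretization, 20 fs
timestep and 5 ps⁻¹ friction.  Eight replicas span 300–450 K with
exponential spacing; neighbor swaps alternate parity every 2000 steps
with Metropolis acceptance and √(T_new/T_old) velocity rescaling, and
snapshots are recorded from the 300 K replica every 2000 steps.  At
these settings the measured swap acceptance is 35–45%.  Nonbonded
interactions use a 10 Å cutoff (energy-shifted), 1-2 and 1-3 bonded
exclusions, and a Verlet neighbor list with a 2 Å skin rebuilt every
10 steps.  Runs are bit-reproducible for a fixed seed.

Two integrator caveats are documented rather than hidden.  First, at
20 fs the BAOAB kinetic energy of the stiffest bond modes reads ~10%
low (the configurational distribution is far more accurate than the
kinetic one); equipartition tests therefore run at 5 fs, where the
kinetic temperature is correct to under 1%.  Second, energy-drift
(NVE) checks run the zero-friction limit at 4 fs on a two-nucleotide
chain, conserving energy to < 0.1% over 10⁵ steps.

Default equilibration for short runs discards the first 10% of steps
(capped at the 2×10⁶ steps discarded at production scale), a
conservative choice because short runs start from the folded reference
and need time to lose memory of it.

## Analysis

**Interhelical Euler angles.**  A helix frame has its z-axis along the
mean Kabsch-rotation axis between consecutive base-pair bead sets
(signed 5′→3′ along strand 1), its origin at the projection of the
first pair's centroid onto that axis, and its x-axis toward the first
pair's S-bead midpoint.  (α_h, β_h, γ_h) is the intrinsic Z-Y-Z
decomposition of the rotation carrying the H1 frame onto the H2 frame;
at β_h = 0 or 180° the twist sum is folded into α_h.  Coverage
fractions and mutual information are invariant to any fixed frame
offset, so they are comparable across runs even though individual
angle values depend on this convention.

**Coverage.**  Triples are binned on equal-width grids: 36×18×36 bins
at 10° and 6×3×6 = 108 bins at 60° per pair; the joint 9D space of the
A-, D- and T-stems measured against the AC-stem has denominator 108³.
The ratio of the 9D fraction to the product of the three 3D fractions
equals 1 for independent helices; values below 1 report interhelical
correlation (or, in short runs, undersampling of the joint space).

**Mutual information** between two orientation triples uses 45°
histograms in bits.  The default finite-sample correction subtracts
the first-order plug-in bias (B_XY − B_X − B_Y + 1)/(2N ln 2); it
assumes independent samples and several points per populated bin, the
regime the converged production analysis sits in.  Short trajectories
violate both assumptions: snapshots are autocorrelated, and a molecule
drifting through a larger space shows *inflated* apparent MI.  For
matched-short-run comparisons the estimator therefore offers
`correct="shift"`, which subtracts the mean plug-in MI of
circular-shift surrogates — the standard dependence null for
correlated time series, preserving each stream's autocorrelation while
destroying their cross-correlation.

**Contacts and free energies.**  Two residues are in contact when
their S beads are within 14 Å and they are ≥ 5 apart in sequence;
loop-level contacts require one such residue pair.  Coaxial stacking
between junction-adjacent helices requires (i) |cos| ≥ 0.7 between the
closing base pairs' plane normals, (ii) closing-pair B-bead centroid
distance ≤ 9 Å (direct link) or ≤ 14 Å (1-nt linker), and (iii) both
acute normal-to-centroid-vector angles < 60°.  Pair planes are fit to
the four S/B beads of the two paired nucleotides: with this bead
geometry the junction P beads swing far out of plane and make a
six-bead fit direction-degenerate.  ΔG^topo(c) = −ln[P(c)/(1−P(c))]
k_BT; when a finite ensemble never (always) shows a contact the
one-sided bound ±ln N is reported and flagged.  Cooperativity is
C = P(joint)/∏P(cᵢ), and combinations observed ≤ 10 times are excluded
from mean-cooperativity curves.

**Best-packed conformers and ⟨N⟩.**  Snapshots are ranked by
E = n_l ε_l + n_s ε_s with ε_l = −0.6 and ε_s = −3.5 k_BT (n_l counts
interloop residue-residue contacts with both residues single-stranded,
n_s coaxial stacks); the subset size defaults to min(500, N/10) so
short runs keep a meaningfully compact subset.  Conformer entropies
use S_i = ln[1 + Σ_{j≠i} exp(−rmsd³_{ij}/10³)] over pairwise P-bead
Kabsch RMSDs (variable-length loops excluded when comparing species),
and ⟨N⟩ weights the native-likeness indicator — D-loop/T-loop contact
present, none of the ten native-inconsistent loop-pair contacts — by
exp(S_i).

## The idealized reference and fixtures

No download is required: an idealized L-shaped tRNA stands in for a
crystal structure.  The acceptor and T-stems are placed as one ideal
coaxial helix, the AC- and D-stems as a second at a right angle, with
the D/AC-linker and the first V-loop residue occupying the
stem-extension register between them.  Single strands are interpolated
between their anchors and the structure is minimized in stages: strong
narrowed-window tertiary restraints without sterics (so loops can
thread into the core), the same with full sterics, then the standard
flat-bottom windows, with weak positional tethers pinning helix beads
to the canonical arm placement.  The tethers matter because the
restrained minimum is a *manifold* — many L geometries satisfy the
windows — and pinning one point on it makes rebuilds reproducible
(helix P-bead RMSD between rebuilds 1–2 Å).  Loop draping still varies
by several Å between rebuilds, which is intentional: single strands
are freely rotatable in this model and their exact conformation is not
part of the reference definition.  A static minimized structure may
penetrate a restraint wall by up to 0.5 Å (0.25 kcal/mol, well under
k_BT); the build reports any larger violation and raises.  The
reference defines the default native residue-contact table; the two
junction coaxial stacks (D/AC, T/A, plus V/AC in Class II topologies)
are included in the native label set by name, since the L fold is
stacked by construction even when the instantaneous geometric test is
marginal on the minimized structure.  When a real PDB structure is
supplied, `coarse_grain_pdb` overrides the idealized reference (P bead
= P atom, S = sugar-ring heavy-atom centroid, B = base heavy-atom
centroid).

Secondary-structure fixtures cover the WT cloverleaf, backbone cuts of
the A/D- and V-loops, V-loop lengths 4–11, A/D-loop lengths 3 and 5,
and a Class II topology with a 3-bp V-stem hairpin plus the
stem-extending 26·44 pair (and its pair-removed control).  The Class II
fixture keeps the WT D-arm; naturally occurring Class II species also
modify the D-loop, which is out of scope here.  Sequences are
placeholders wherever the paper-level inputs do not pin them: single
strands are sequence-independent in this model.

Synthetic generators with planted ground truth (independent uniform
Euler streams, Bernoulli contact streams with a planted joint
probability, Gaussian-jittered reference clouds) validate every
estimator against known values.

## Problem sizes

The production protocol this package emulates runs 10⁹ steps per
replica on a cluster.  The package's own test and reproduction runs
are desk-scale by design: the matched WT / cut-A/D comparisons use 8
replicas × 5×10⁵ steps (1.5×10⁵ discarded, snapshots every 10³ steps)
and the coverage reproduction 8 replicas × 10⁶ steps (snapshots every
2×10³).  Coverage fractions grow monotonically with sampling, so
desk-scale runs report lower bounds on the converged fractions;
directional claims are evaluated on seed-matched pairs of runs.

## Known limitations

* No electrostatics, no sequence-specific tertiary energetics, no
  pseudoknots, and single-strand behavior is sequence independent —
  all by design: the model measures what topology alone does.
* Desk-scale ensembles undersample orientation space by orders of
  magnitude relative to convergence; absolute coverage numbers from
  short runs are bounds, not estimates.
* ⟨N⟩ from a short run rests on a handful of independent compaction
  events, so comparing ⟨N⟩ between two molecules requires far more
  sampling than the other observables (roughly an order of magnitude
  more steps than the matched short runs used in the test suite); the
  suite states that comparison as written and the corresponding test
  documents that it is not resolvable at desk scale.
* The bead geometry is an idealization calibrated to pair-distance
  windows, not a fit to crystallographic coordinates; absolute Euler
  angles depend on the frame convention and should only be compared
  within this package.
* The kinetic-energy readout at the production timestep underestimates
  the stiffest modes by ~10% (configurational sampling is unaffected);
  use a smaller timestep when kinetic observables matter.
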