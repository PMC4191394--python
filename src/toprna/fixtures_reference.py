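"""Built-in inputs: the WT tRNA cloverleaf and its variants, ideal
A-form helices, an idealized L-shaped tRNA reference structure, an
optional all-atom PDB coarse-grainer, and synthetic ensembles with
planted statistics for estimator validation.

Nothing here requires a download: the idealized reference stands in
for a crystal structure and defines the default native-contact tables.
A user-supplied PDB (e.g. a tRNA crystal structure) overrides it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import forcefield as ff
from .cg_engine import Ensemble, SimulationProtocol, System
from .secstruct_topology import (
    BeadTopology,
    SecondaryStructure,
    apply_variant,
    build_topology,
    make_restraints,
    parse_secondary_structure,
)

logger = logging.getLogger(__name__)

# yeast tRNA-Phe, 1-based crystallographic numbering, unmodified analogs
WT_SEQUENCE = (
    "GCGGAUUUAGCUCAGUUGGGAGAGCGCCAGACUGAAGAUCUGGAGGUCCUGUGUUCGAUC"
    "CACAGAAUUCGCACCA"
)
WT_DOTBRACKET = (
    "(((((((..((((........)))).(((((.......))))).....(((((......."
    "))))))))))))...."
)

# conserved tertiary pairs (residue numbers in the WT numbering)
TERTIARY_PAIRS = [(8, 14), (15, 48), (18, 55), (19, 56), (54, 58), (26, 44)]
# default semiconserved base triples: tertiary residue vs a D-stem pair
BASE_TRIPLES = [(46, (22, 13)), (45, (10, 25)), (9, (23, 12))]
# the non-redundant subset sufficient to confine the fold
NONREDUNDANT_PAIRS = [(8, 14), (15, 48), (26, 44), (19, 56)]


def wt_secondary_structure() -> SecondaryStructure:
    return parse_secondary_structure(WT_SEQUENCE + "\n" + WT_DOTBRACKET)


def fixture_secondary_structure(name: str) -> SecondaryStructure:
    """Named secondary-structure fixtures.

    ``wt``; ``vl4``/``vl7``/``vl9``/``vl11`` (V-loop length variants);
    ``adl3``/``adl5`` (A/D-loop length variants); ``vs`` (Class II:
    V-stem hairpin plus the stem-extending 26-44 pair); ``vs-nogu``
    (VS without that pair).  The cut variants (``cut-ad``, ``cut-v``)
    are topology-level edits; see :func:`fixture_topology`.
    """
    name = name.lower()
    ss = wt_secondary_structure()
    if name in ("wt", "cut-ad", "cut-v"):
        return ss
    if name.startswith("vl"):
        target = int(name[2:])
        if target < 4 or target > 11:
            raise ValueError("V-loop variants supported for 4..11 nt")
        if target < 5:
            return apply_variant(ss, "delete_loop_nt", residue=46,
                                 count=5 - target)
        if target > 5:
            return apply_variant(ss, "insert_loop_nt", after=46,
                                 count=target - 5)
        return ss
    if name.startswith("adl"):
        target = int(name[3:])
        if target < 2:
            raise ValueError("A/D-loop variants supported for >= 2 nt")
        if target == 2:
            return ss
        return apply_variant(ss, "insert_loop_nt", after=8, count=target - 2)
    if name in ("vs", "vs-nogu"):
        # replace part of the V-loop with a 3-bp hairpin V-stem
        out = apply_variant(ss, "insert_stem", after=45, n_bp=3, loop_len=4)
        if name == "vs":
            out = apply_variant(out, "toggle_pair", i=26, j=44)
        return out
    raise ValueError(f"unknown fixture {name!r}")


def fixture_topology(name: str) -> BeadTopology:
    """Topology fixture; ``cut-ad`` removes the S(8)-P(9) backbone bond
    and ``cut-v`` the S(46)-P(47) bond of the WT topology."""
    name = name.lower()
    topo = build_topology(fixture_secondary_structure(name))
    if name == "cut-ad":
        topo = apply_variant(topo, "cut", residue=8)
    elif name == "cut-v":
        topo = apply_variant(topo, "cut", residue=46)
    return topo


def fixture_text(name: str) -> str:
    """Dot-bracket text of a fixture (sequence line + structure line)."""
    ss = fixture_secondary_structure(name)
    return ss.sequence + "\n" + ss.to_dotbracket() + "\n"


# ----------------------------------------------------------------------
# ideal helices
# ----------------------------------------------------------------------

def ideal_duplex(n_bp: int) -> tuple[BeadTopology, np.ndarray]:
    """Topology and ideal coordinates of an isolated A-form duplex
    (2 n_bp residues, strand break at the turn)."""
    if n_bp < 2:
        raise ValueError("need >= 2 base pairs")
    db = "(" * n_bp + ")" * n_bp
    ss = parse_secondary_structure(db)
    topo = build_topology(ss, strand_breaks={(n_bp, n_bp + 1)})
    coords = np.zeros((topo.n_beads, 3))
    pair_list = [(k + 1, 2 * n_bp - k) for k in range(n_bp)]
    place_ideal_pairs(coords, topo, pair_list)
    return topo, coords


def build_ideal_helix(n_bp: int) -> np.ndarray:
    """Ideal A-form bead coordinates of an ``n_bp`` duplex (see
    :func:`ideal_duplex` for the matching topology)."""
    return ideal_duplex(n_bp)[1]


def place_ideal_pairs(
    coords: np.ndarray,
    topology: BeadTopology,
    pair_list: list[tuple[int, int]],
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    start_index: int = 0,
) -> None:
    """Write ideal A-form positions for ``pair_list`` into ``coords``.

    Pair k of the list is placed at helical register start_index + k;
    the first residue of each tuple takes the strand-1 local geometry
    (its residues should ascend 5'->3' with k where sequence-adjacent).
    An optional rigid transform places the helix in the global frame.
    Tuples whose residues are unpaired in the topology get coordinates
    only (no M bead).
    """
    R = np.eye(3) if rotation is None else rotation
    t = np.zeros(3) if translation is None else translation
    local = ff.ideal_pair_frame_coords()
    for k, (i, j) in enumerate(pair_list):
        rot, tr = ff.pair_transform(start_index + k)
        for res, sfx in ((i, "1"), (j, "2")):
            for kind, key in (("P", "P"), ("S", "S"), ("B", "B")):
                coords[topology.bead_index(res, kind)] = (
                    R @ (rot @ local[key + sfx] + tr) + t
                )
        m = topology.m_bead_of_pair.get(tuple(sorted((i, j))))
        if m is not None:
            coords[m] = R @ (rot @ local["M"] + tr) + t


# ----------------------------------------------------------------------
# idealized L-shaped tRNA reference
# ----------------------------------------------------------------------

@dataclass
class ReferenceStructure:
    """Coarse coordinates consistent with a topology, plus provenance
    (``ideal`` or ``pdb-derived``)."""

    coords: np.ndarray
    topology: BeadTopology
    provenance: str
    notes: list[str] = field(default_factory=list)

    def native_contacts(self) -> set[str]:
        from .contacts_cooperativity import native_contact_labels

        return native_contact_labels(self.coords, self.topology)


class RestraintBuildError(RuntimeError):
    """The reference build left restraint windows violated."""

    def __init__(self, violations):
        self.violations = violations
        super().__init__(
            "unsatisfied restraint windows: "
            + "; ".join(
                f"{lab}: d={d:.2f} not in [{lo:.2f},{hi:.2f}]"
                for lab, d, lo, hi in violations
            )
        )


def _rot_z(deg):
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


# rigid placement of the two arms of the L (tuned once on the WT
# cloverleaf so that the junction strands can bridge and the tertiary
# windows close during minimization; see docs/methods.md)
ARM_PLACEMENT = {
    "spin1": 270.0,   # deg, acceptor/T arm spin about its axis
    "spin2": 0.0,     # deg, D/AC arm spin
    "x2": 24.0,       # A, D/AC arm axis position
    "y2": 0.0,
    "z_top": -9.0,    # A, height of the elbow-end D-stem pair
}


def build_reference_trna(
    ss: SecondaryStructure | None = None,
    tertiary_pairs: list[tuple[int, int]] | None = None,
    seed: int = 0,
    placement: dict | None = None,
    max_violation: float = 0.5,
) -> ReferenceStructure:
    """Idealized L-shaped tRNA reference.

    The acceptor and T-stems are placed as one coaxial ideal helix
    (arm 1) and the AC- and D-stems as a second coaxial helix at a
    right angle (arm 2, with the D/AC-linker and first V-loop residue
    occupying the stem-extension register between them).  Single
    strands are interpolated between their anchors and the structure is
    minimized in three stages: strong narrowed tertiary restraints
    without sterics (so loops can thread into the core), the same with
    the full force field, and finally the standard flat-bottom
    restraint windows.  Raises :class:`RestraintBuildError` listing any
    window whose wall is penetrated by more than ``max_violation`` A
    after the final stage (0.5 A of wall penetration costs 0.25
    kcal/mol, well under k_B T, so the default tolerance still means
    a thermally satisfied restraint).
    """
    if ss is None:
        ss = wt_secondary_structure()
    if tertiary_pairs is None:
        tertiary_pairs = TERTIARY_PAIRS
    helices = {h.name: h for h in ss.helices}
    for req in ("A-stem", "D-stem", "AC-stem", "T-stem"):
        if req not in helices:
            raise ValueError("reference build needs a cloverleaf structure")
    p = dict(ARM_PLACEMENT)
    if placement:
        p.update(placement)

    topo = build_topology(ss)
    coords = np.full((topo.n_beads, 3), np.nan)

    # arm 1: A-stem + T-stem, axis along +x, acceptor tip at the origin
    arm1 = list(helices["A-stem"].pairs) + list(helices["T-stem"].pairs)
    R1 = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
    place_ideal_pairs(
        coords, topo, arm1, rotation=R1 @ _rot_z(p["spin1"])
    )

    # arm 2: AC-stem (strands swapped, reversed) + linker/V pseudo-pair
    # + D-stem, axis along +z, elbow (D-stem) end on top
    ac, d = helices["AC-stem"], helices["D-stem"]
    arm2 = [(j, i) for (i, j) in reversed(ac.pairs)]
    linker = ss.elements.get("D/AC-linker", ())
    vloop = ss.elements.get("V-loop", ())
    pseudo = None
    if len(linker) == 1 and vloop:
        pseudo = (vloop[0], linker[0])
        arm2.append(pseudo)
    arm2 += list(d.pairs)
    n2 = len(arm2)
    z0 = p["z_top"] - (n2 - 1) * ff.RISE
    place_ideal_pairs(
        coords, topo, arm2,
        rotation=_rot_z(p["spin2"]),
        translation=np.array([p["x2"], p["y2"], z0]),
    )

    _fill_single_strands(coords, topo)

    from dataclasses import replace as _replace

    specs = []
    for (i, j) in tertiary_pairs:
        kind = "g26_pair" if pseudo and set((i, j)) == set(pseudo) else \
            "tertiary_pair"
        specs += make_restraints(kind, (i, j), topo)

    def _narrowed(s, frac=0.35):
        w = s.r_max - s.r_min
        return _replace(
            s, r_min=s.r_min + frac * w, r_max=s.r_max - frac * w,
            k_min=5.0, k_max=5.0, fmax=1e4,
        )

    def _violations(x):
        out = []
        for spec in specs:
            dist = float(
                np.linalg.norm(x[spec.bead_i] - x[spec.bead_j])
            )
            if dist < spec.r_min - max_violation or \
                    dist > spec.r_max + max_violation:
                out.append((spec.label, dist, spec.r_min, spec.r_max))
        return out

    strong = [_narrowed(s) for s in specs]
    soft_topo = build_topology(ss, strand_breaks=set(topo.strand_breaks))
    soft_topo.lj_radius = np.full_like(soft_topo.lj_radius, 0.05)
    sys_strong = System(topo, restraints=strong)
    sys_std = System(topo, restraints=specs)

    # weak positional tethers on helix beads toward the canonical arm
    # placement: the restrained minimum is a manifold (many L
    # geometries satisfy the windows), and the tethers pin which point
    # on it defines the reference, making rebuilds reproducible
    helix_beads = set()
    for h in ss.helices:
        for r in h.residues:
            helix_beads.update(topo.residue_beads(r))
    tether_target = coords.copy()
    # only helix beads are pinned; single strands are freely rotatable
    # by construction and their exact draping is not part of the
    # reference definition
    tether_k = np.where(
        np.isin(np.arange(topo.n_beads), sorted(helix_beads)), 0.2, 0.0
    )[:, None]

    def _tethered_minimize(sys_, x0, maxiter):
        from scipy.optimize import minimize as _min

        nb = topo.n_beads

        def fun(flat):
            xx = flat.reshape(nb, 3)
            e, fvec, _ = sys_.energy_forces(xx)
            d = xx - tether_target
            e += 0.5 * float((tether_k * d ** 2).sum())
            grad = -fvec + tether_k * d
            return e, grad.ravel()

        res = _min(fun, np.asarray(x0, float).ravel(), jac=True,
                   method="L-BFGS-B", options={"maxiter": maxiter})
        return res.x.reshape(nb, 3)

    # the minimization cascade is non-convex; restart from fresh jitters
    # (deterministic sub-seeds) until every window closes
    best_x, best_viol = None, None
    for attempt in range(6):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, attempt, 0x1DEA])
        )
        x = coords + rng.normal(scale=0.05, size=coords.shape)
        x = System(soft_topo, restraints=strong).minimize(x, maxiter=3000)
        for _cycle in range(3):
            x = _tethered_minimize(sys_strong, x, 3000)
            x = _tethered_minimize(sys_std, x, 3000)
            viol = _violations(x)
            if not viol:
                break
        total = sum(
            max(v[2] - v[1], v[1] - v[3]) for v in viol
        ) if viol else 0.0
        if best_viol is None or total < best_viol:
            best_x, best_viol, best_report = x, total, viol
        if not viol:
            break
    if best_report:
        raise RestraintBuildError(best_report)
    return ReferenceStructure(
        coords=best_x, topology=topo, provenance="ideal",
        notes=[f"seed={seed}"],
    )


def _fill_single_strands(coords: np.ndarray, topo: BeadTopology) -> None:
    """Interpolate unplaced residues between their placed neighbors."""
    n = topo.n_nt
    placed = [
        bool(np.all(np.isfinite(coords[topo.residue_beads(r)[0]])))
        for r in [0] + list(range(1, n + 1))
    ]  # placed[r] for r in 1..n (index 0 unused)
    center = np.nanmean(coords, axis=0)
    r = 1
    while r <= n:
        if placed[r]:
            r += 1
            continue
        seg = []
        while r <= n and not placed[r]:
            seg.append(r)
            r += 1
        prev_anchor = (
            coords[topo.bead_index(seg[0] - 1, "S")] if seg[0] > 1 else None
        )
        next_anchor = (
            coords[topo.bead_index(seg[-1] + 1, "P")] if seg[-1] < n else None
        )
        if prev_anchor is None and next_anchor is None:
            prev_anchor = center
            next_anchor = center + np.array([0.0, 0.0, 6.0 * len(seg)])
        elif prev_anchor is None:
            direction = next_anchor - center
            direction /= max(np.linalg.norm(direction), 1e-9)
            prev_anchor = next_anchor + direction * 6.0 * len(seg)
        elif next_anchor is None:
            direction = prev_anchor - center
            direction /= max(np.linalg.norm(direction), 1e-9)
            next_anchor = prev_anchor + direction * 6.0 * len(seg)
        span = next_anchor - prev_anchor
        # deterministic bulge direction away from the molecule center
        mid = 0.5 * (prev_anchor + next_anchor)
        out_dir = mid - center
        nrm = np.linalg.norm(out_dir)
        out_dir = out_dir / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
        arc = max(0.0, 3.0 * len(seg) - np.linalg.norm(span) * 0.5)
        for q, res in enumerate(seg):
            f0 = (q + 0.5) / len(seg)
            base_pt = prev_anchor + span * f0 + out_dir * arc * np.sin(
                np.pi * f0
            )
            pi_, si_, bi_ = topo.residue_beads(res)
            coords[pi_] = base_pt + span / (2.0 * len(seg))
            coords[si_] = base_pt
            coords[bi_] = base_pt + out_dir * 3.0


# ----------------------------------------------------------------------
# coarse-graining an all-atom PDB
# ----------------------------------------------------------------------

SUGAR_RING_ATOMS = ("C1'", "C2'", "C3'", "C4'", "O4'")
BACKBONE_ATOMS = (
    "P", "OP1", "OP2", "OP3", "O5'", "C5'", "O3'", "O2'",
) + SUGAR_RING_ATOMS


def coarse_grain_pdb(pdb_path, ss: SecondaryStructure) -> ReferenceStructure:
    """Coarse-grain one RNA chain of a PDB file.

    P bead = phosphate P atom; S bead = sugar-ring heavy-atom centroid;
    B bead = base heavy-atom centroid; M beads at paired-B midpoints.
    Modified residues contribute whatever standard-named atoms they
    have; residues with missing atoms are flagged and use the centroid
    of the available atoms.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ref", str(pdb_path))
    model = next(structure.get_models())
    chain = next(model.get_chains())
    residues = [r for r in chain if any(a.element != "H" for a in r)]
    if len(residues) != ss.n:
        raise ValueError(
            f"chain has {len(residues)} residues, structure expects {ss.n}"
        )
    topo = build_topology(ss)
    coords = np.zeros((topo.n_beads, 3))
    notes = []
    for k, res in enumerate(residues, start=1):
        atoms = {a.get_name(): a.coord for a in res if a.element != "H"}
        pi_, si_, bi_ = topo.residue_beads(k)
        if "P" in atoms:
            coords[pi_] = atoms["P"]
        else:
            notes.append(f"residue {k}: no P atom; using heavy-atom centroid")
            coords[pi_] = np.mean(list(atoms.values()), axis=0)
        ring = [atoms[nm] for nm in SUGAR_RING_ATOMS if nm in atoms]
        if len(ring) < len(SUGAR_RING_ATOMS):
            notes.append(f"residue {k}: incomplete sugar ring")
        coords[si_] = (
            np.mean(ring, axis=0)
            if ring
            else np.mean(list(atoms.values()), axis=0)
        )
        base = [
            xyz for nm, xyz in atoms.items() if nm not in BACKBONE_ATOMS
        ]
        if not base:
            notes.append(f"residue {k}: no base atoms")
            base = list(atoms.values())
        coords[bi_] = np.mean(base, axis=0)
    for (i, j), m in topo.m_bead_of_pair.items():
        coords[m] = 0.5 * (
            coords[topo.bead_index(i, "B")] + coords[topo.bead_index(j, "B")]
        )
    for note in notes:
        logger.warning(note)
    return ReferenceStructure(
        coords=coords, topology=topo, provenance="pdb-derived", notes=notes
    )


# ----------------------------------------------------------------------
# synthetic ensembles with planted statistics
# ----------------------------------------------------------------------

def synthetic_angle_streams(
    n: int, n_streams: int = 3, seed: int = 0
) -> list[np.ndarray]:
    """Independent uniform Euler-triple streams (alpha, gamma uniform
    on [0, 360), beta uniform on [0, 180)): zero MI, independence
    ratio 1 in the large-n limit."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    out = []
    for _ in range(n_streams):
        a = rng.uniform(0.0, 360.0, n)
        b = rng.uniform(0.0, 180.0, n)
        g = rng.uniform(0.0, 360.0, n)
        out.append(np.column_stack([a, b, g]))
    return out


def synthetic_contact_streams(
    n: int,
    p: tuple[float, float] = (0.1, 0.1),
    planted_c: float = 1.0,
    n_independent: int = 0,
    p_independent: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli contact streams with a planted pairwise cooperativity.

    The first two contacts have marginals p and joint probability
    planted_c * p[0] * p[1]; any additional contacts are independent
    Bernoulli(p_independent).
    """
    p1, p2 = p
    p11 = planted_c * p1 * p2
    if p11 > min(p1, p2) + 1e-12 or p11 < max(0.0, p1 + p2 - 1.0) - 1e-12:
        raise ValueError("planted joint probability is infeasible")
    probs = np.array([
        p11, p1 - p11, p2 - p11, 1.0 - p1 - p2 + p11
    ])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC07]))
    cat = rng.choice(4, size=n, p=probs)
    data = {
        "c1": (cat == 0) | (cat == 1),
        "c2": (cat == 0) | (cat == 2),
    }
    for k in range(n_independent):
        data[f"i{k+1}"] = rng.random(n) < p_independent
    return pd.DataFrame(data)


def jittered_ensemble(
    reference: ReferenceStructure,
    n: int,
    sigma: float = 1.0,
    seed: int = 0,
) -> Ensemble:
    """Gaussian-jittered copies of a reference structure, packaged as
    an Ensemble (for RMSD/entropy estimator validation)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x717]))
    coords = (
        reference.coords[None, :, :]
        + rng.normal(scale=sigma, size=(n,) + reference.coords.shape)
    )
    proto = SimulationProtocol(total_steps=10, equilibration_steps=0)
    return Ensemble(
        coords=coords,
        topology=reference.topology,
        protocol=proto,
        steps=np.arange(n, dtype=np.int64),
        walker=np.zeros(n, dtype=np.int64),
    )


def make_synthetic_ensembles(spec: dict, seed: int = 0):
    """Dispatch on spec['kind']: ``independent_angles``,
    ``bernoulli_contacts`` or ``jittered_cloud`` (remaining spec keys
    are the generator's keyword arguments)."""
    spec = dict(spec)
    kind = spec.pop("kind", None)
    if kind == "independent_angles":
        return synthetic_angle_streams(seed=seed, **spec)
    if kind == "bernoulli_contacts":
        return synthetic_contact_streams(seed=seed, **spec)
    if kind == "jittered_cloud":
        return jittered_ensemble(seed=seed, **spec)
    raise ValueError(f"unknown generator {kind!r}")
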