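"""Contact detection, contact free energies, cooperativity and
restrained-vs-unrestrained coupling.

A residue-residue contact is an S-bead distance < 14 A (the approximate
Watson-Crick S-S separation) between residues >= 5 apart in sequence.
Loop-loop / loop-stem contacts require at least one qualifying residue
pair.  Coaxial stacks between junction-adjacent helices use three
geometric criteria on the closing base pairs.  The free-energy cost of
a contact c in the topology-only ensemble is the log-odds

    dG_topo(c) = -ln( P(c) / (1 - P(c)) )     [k_B T]

and the cooperativity of a contact group is C = P(joint) / prod P(c_i).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cg_engine import Ensemble
from .secstruct_topology import BeadTopology, Helix

CONTACT_CUTOFF = 14.0      # A, S-S
MIN_SEQ_SEPARATION = 5
STACK_COS_MIN = 0.7
STACK_COM_DIRECT = 9.0     # A, directly linked helices
STACK_COM_LINKER1 = 14.0   # A, helices separated by one ss nt
STACK_NORMAL_COM_DEG = 60.0
MIN_COMBO_OBSERVATIONS = 10  # combinations seen <= this are excluded

KCAL_PER_KBT_300K = 0.0019872041 * 300.0


def residue_contact(coords: np.ndarray, topology: BeadTopology,
                    i: int, j: int) -> bool:
    """True iff S-S distance < 14 A and |i - j| >= 5 (1-based)."""
    if abs(i - j) < MIN_SEQ_SEPARATION:
        return False
    si = coords[topology.bead_index(i, "S")]
    sj = coords[topology.bead_index(j, "S")]
    return bool(np.linalg.norm(si - sj) < CONTACT_CUTOFF)


def group_contact(coords: np.ndarray, topology: BeadTopology,
                  element_a, element_b) -> bool:
    """True iff any residue pair across the two disjoint residue groups
    is in contact (loop-loop and loop-stem cases)."""
    a = list(element_a)
    b = list(element_b)
    if set(a) & set(b):
        raise ValueError("elements overlap")
    sa = np.array([coords[topology.bead_index(r, "S")] for r in a])
    sb = np.array([coords[topology.bead_index(r, "S")] for r in b])
    d2 = ((sa[:, None, :] - sb[None, :, :]) ** 2).sum(axis=2)
    sep = np.abs(np.subtract.outer(a, b))
    return bool(np.any((d2 < CONTACT_CUTOFF ** 2)
                       & (sep >= MIN_SEQ_SEPARATION)))


def _closing_pairs(topology: BeadTopology, ha: Helix, hb: Helix):
    """The two junction-facing base pairs of a helix pair, plus the
    number of single-stranded nucleotides on the shortest strand path
    between them (0 = directly linked)."""
    best = None
    for pa in (ha.pairs[0], ha.pairs[-1]):
        for pb in (hb.pairs[0], hb.pairs[-1]):
            gap = min(abs(x - y) for x in pa for y in pb) - 1
            if best is None or gap < best[2]:
                best = (pa, pb, gap)
    return best


def _pair_plane(coords, topology, pair):
    """Least-squares plane of the S and B beads of the two paired
    nucleotides: returns (B-bead COM, unit normal).  P beads are left
    out of the fit: at junctions they swing out of the pair plane and
    make the 6-bead fit direction-degenerate, whereas the four S/B
    beads stay close to planar."""
    i, j = pair
    idx = [
        topology.bead_index(i, "S"), topology.bead_index(i, "B"),
        topology.bead_index(j, "S"), topology.bead_index(j, "B"),
    ]
    pts = coords[idx]
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    com = 0.5 * (
        coords[topology.bead_index(i, "B")] + coords[topology.bead_index(j, "B")]
    )
    return com, normal / np.linalg.norm(normal)


def coaxial_stack(
    coords: np.ndarray,
    topology: BeadTopology,
    helix_a: Helix | str,
    helix_b: Helix | str,
    n_linker: int | None = None,
) -> bool:
    """Coaxial-stacking test on the junction-facing closing pairs.

    (i) |cos| of the angle between the base-pair-plane normals >= 0.7;
    (ii) closing-pair B-bead COM distance <= 9 A (direct link) or
    <= 14 A (one-nt linker); (iii) both (acute) angles between the
    normals and the COM-COM vector < 60 deg.  Plane-normal signs are
    arbitrary, so acute-angle conventions are used throughout.
    """
    ss = topology.secondary_structure
    if isinstance(helix_a, str):
        helix_a = next(h for h in ss.helices if h.name == helix_a)
    if isinstance(helix_b, str):
        helix_b = next(h for h in ss.helices if h.name == helix_b)
    pa, pb, gap = _closing_pairs(topology, helix_a, helix_b)
    if n_linker is None:
        n_linker = gap
    if n_linker not in (0, 1):
        raise ValueError("stacking evaluated for 0- or 1-nt linkers only")
    com_a, na = _pair_plane(coords, topology, pa)
    com_b, nb = _pair_plane(coords, topology, pb)
    if abs(np.dot(na, nb)) < STACK_COS_MIN:
        return False
    v = com_b - com_a
    d = np.linalg.norm(v)
    limit = STACK_COM_DIRECT if n_linker == 0 else STACK_COM_LINKER1
    if d > limit or d < 1e-9:
        return False
    v = v / d
    for nv in (na, nb):
        cosang = abs(np.dot(nv, v))
        if np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))) >= \
                STACK_NORMAL_COM_DEG:
            return False
    return True


def stack_pair_names(topology: BeadTopology) -> list[tuple[str, str]]:
    """Junction stacks evaluated for a cloverleaf: D/AC and T/A, plus
    V/AC when a V-stem exists."""
    names = {h.name for h in topology.secondary_structure.helices}
    out = []
    if {"D-stem", "AC-stem"} <= names:
        out.append(("D-stem", "AC-stem"))
    if {"T-stem", "A-stem"} <= names:
        out.append(("T-stem", "A-stem"))
    if {"V-stem", "AC-stem"} <= names:
        out.append(("V-stem", "AC-stem"))
    return out


# ----------------------------------------------------------------------
# boolean contact streams over an ensemble
# ----------------------------------------------------------------------

def loop_elements(topology: BeadTopology) -> list[str]:
    """Single-stranded elements (loops, linkers, tails), in order."""
    ss = topology.secondary_structure
    stems = {h.name for h in ss.helices}
    return [nm for nm in ss.elements if nm not in stems]


def default_contact_definitions(topology: BeadTopology) -> list[tuple]:
    """Loop-loop pairs, the A/D- and V-loop vs D-stem pairs, and the
    junction stacks: the contact pool used for cooperativity curves."""
    loops = loop_elements(topology)
    defs: list[tuple] = []
    for a, b in itertools.combinations(loops, 2):
        defs.append(("loop", a, b))
    stems = {h.name for h in topology.secondary_structure.helices}
    if "D-stem" in stems:
        for lp in ("A/D-loop", "V-loop"):
            if lp in loops:
                defs.append(("loop_stem", lp, "D-stem"))
    for ha, hb in stack_pair_names(topology):
        defs.append(("stack", ha, hb))
    return defs


def contact_streams(
    ensemble: Ensemble,
    definitions: list[tuple] | None = None,
) -> pd.DataFrame:
    """Boolean occurrence matrix (snapshots x contacts).

    Columns are labelled ``A|B`` for group contacts and ``stack:A|B``
    for coaxial stacks.
    """
    topo = ensemble.topology
    elements = topo.secondary_structure.elements
    if definitions is None:
        definitions = default_contact_definitions(topo)
    cols = {}
    for kind, a, b in definitions:
        label = (f"stack:{a}|{b}" if kind == "stack" else f"{a}|{b}")
        vals = np.empty(ensemble.n_snapshots, dtype=bool)
        for s, c in enumerate(ensemble.coords):
            if kind == "stack":
                vals[s] = coaxial_stack(c, topo, a, b)
            else:
                vals[s] = group_contact(c, topo, elements[a], elements[b])
        cols[label] = vals
    return pd.DataFrame(cols)


def residue_contact_map(ensemble: Ensemble, residues=None) -> pd.DataFrame:
    """Long-format P and dG_topo per residue pair (heatmap-ready)."""
    topo = ensemble.topology
    if residues is None:
        stems = {h.name for h in topo.secondary_structure.helices}
        residues = sorted(
            r
            for nm, mem in topo.secondary_structure.elements.items()
            if nm not in stems
            for r in mem
        )
    s_idx = [topo.bead_index(r, "S") for r in residues]
    n = len(residues)
    counts = np.zeros((n, n))
    for c in ensemble.coords:
        pts = c[s_idx]
        d2 = ((pts[:, None] - pts[None, :]) ** 2).sum(axis=2)
        counts += d2 < CONTACT_CUTOFF ** 2
    rows = []
    n_snap = ensemble.n_snapshots
    for ii in range(n):
        for jj in range(ii + 1, n):
            if abs(residues[ii] - residues[jj]) < MIN_SEQ_SEPARATION:
                continue
            p = counts[ii, jj] / n_snap
            rows.append({
                "res_i": residues[ii],
                "res_j": residues[jj],
                "p": p,
                "dg_topo": free_energy_from_p(p, n_snap)[0],
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# free energies and cooperativity
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ContactStats:
    """Occurrence probability and log-odds free energy of one contact
    (or joint contact set), in k_B T at the analysis temperature."""

    label: str
    p: float
    dg_topo: float
    n: int
    bounded: bool = False   # True when P hit 0 or 1: dg is a bound

    @property
    def dg_kcal_per_mol(self) -> float:
        return self.dg_topo * KCAL_PER_KBT_300K


def free_energy_from_p(p: float, n: int) -> tuple[float, bool]:
    """dG = -ln(P/(1-P)); at P = 0 (or 1) return the one-sided bound
    +-ln(n) implied by zero counts out of n, flagged."""
    if p <= 0.0:
        return float(np.log(n)), True
    if p >= 1.0:
        return float(-np.log(n)), True
    return float(-np.log(p / (1.0 - p))), False


def contact_free_energy(streams: pd.DataFrame | np.ndarray,
                        contacts=None) -> ContactStats:
    """dG_topo of one contact or of jointly forming a contact set
    (joint frequency substituted into the same log-odds)."""
    if isinstance(streams, pd.DataFrame):
        if contacts is None:
            raise ValueError("name the contact column(s)")
        if isinstance(contacts, str):
            contacts = [contacts]
        arr = streams[list(contacts)].to_numpy(dtype=bool)
        label = "&".join(contacts)
    else:
        arr = np.asarray(streams, dtype=bool)
        if arr.ndim == 1:
            arr = arr[:, None]
        label = "joint"
    n = len(arr)
    if n == 0:
        raise ValueError("empty ensemble")
    p = float(np.all(arr, axis=1).mean())
    dg, bounded = free_energy_from_p(p, n)
    return ContactStats(label=label, p=p, dg_topo=dg, n=n, bounded=bounded)


@dataclass(frozen=True)
class CooperativityResult:
    """C = P(joint)/prod P(c_i) for one contact group."""

    contacts: tuple[str, ...]
    p_joint: float
    p_marginals: tuple[float, ...]
    c: float
    n: int
    n_joint_observations: int


def cooperativity(streams: pd.DataFrame, contacts) -> CooperativityResult:
    arr = streams[list(contacts)].to_numpy(dtype=bool)
    n = len(arr)
    marg = arr.mean(axis=0)
    if np.any(marg == 0.0):
        raise ZeroDivisionError(
            "zero marginal probability for "
            + ", ".join(np.asarray(contacts)[marg == 0.0])
        )
    joint = np.all(arr, axis=1)
    p_joint = joint.mean()
    return CooperativityResult(
        contacts=tuple(contacts),
        p_joint=float(p_joint),
        p_marginals=tuple(float(m) for m in marg),
        c=float(p_joint / np.prod(marg)),
        n=n,
        n_joint_observations=int(joint.sum()),
    )


def mean_cooperativity(
    streams: pd.DataFrame,
    native_contacts: set[str],
    n_max: int = 6,
    min_observations: int = MIN_COMBO_OBSERVATIONS,
) -> pd.DataFrame:
    """Mean cooperativity of jointly forming n contacts, averaged over
    all-native combinations and over combinations containing at least
    one non-native contact; combinations observed <= min_observations
    times are excluded."""
    cols = [c for c in streams.columns if streams[c].any()]
    arr = streams[cols].to_numpy(dtype=bool)
    marg = arr.mean(axis=0)
    native_mask = np.array([c in native_contacts for c in cols])
    rows = []
    for n_contacts in range(2, n_max + 1):
        acc = {True: [], False: []}
        for combo in itertools.combinations(range(len(cols)), n_contacts):
            joint = np.all(arr[:, combo], axis=1)
            n_obs = int(joint.sum())
            if n_obs <= min_observations:
                continue
            c_val = joint.mean() / np.prod(marg[list(combo)])
            acc[bool(np.all(native_mask[list(combo)]))].append(c_val)
        for is_native, vals in acc.items():
            if vals:
                rows.append({
                    "n_contacts": n_contacts,
                    "native": is_native,
                    "mean_c": float(np.mean(vals)),
                    "n_combinations": len(vals),
                })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CoupledStability:
    """ddG_coop = dG_topo({TC}) restrained - dG_topo({TC}) unrestrained;
    negative values mean the restrained interactions stabilize the
    target contacts."""

    target_contacts: tuple[str, ...]
    ddg_coop: float
    dg_restrained: float
    dg_unrestrained: float
    bounded: bool


def coupled_stability(
    unrestrained: pd.DataFrame,
    restrained: pd.DataFrame,
    target_contacts,
    restrained_loop_pairs: set[frozenset[str]] | None = None,
) -> CoupledStability:
    """Eq.-of-state of cooperativity between restrained tertiary
    interactions and a target contact set.

    Raises if a target loop-loop contact has an active restraint placed
    between its two loops (those couplings are not meaningful)."""
    if isinstance(target_contacts, str):
        target_contacts = [target_contacts]
    if restrained_loop_pairs:
        for tc in target_contacts:
            pair = frozenset(tc.replace("stack:", "").split("|"))
            if pair in restrained_loop_pairs:
                raise ValueError(
                    f"{tc}: restraint active between these loops; "
                    "coupling not computed"
                )
    su = contact_free_energy(unrestrained, target_contacts)
    sr = contact_free_energy(restrained, target_contacts)
    return CoupledStability(
        target_contacts=tuple(target_contacts),
        ddg_coop=sr.dg_topo - su.dg_topo,
        dg_restrained=sr.dg_topo,
        dg_unrestrained=su.dg_topo,
        bounded=su.bounded or sr.bounded,
    )


def native_contact_labels(
    reference_coords: np.ndarray,
    topology: BeadTopology,
    include_junction_stacks: bool = True,
) -> set[str]:
    """Contacts present in a reference structure under the same rules:
    the native set used to split cooperativity curves.

    The junction coaxial stacks (D/AC, T/A and V/AC where present) are
    native features of the L fold and are included by name regardless
    of whether the static reference happens to pass the instantaneous
    geometric stack test."""
    streams = contact_streams(
        Ensemble(
            coords=reference_coords[None, :, :],
            topology=topology,
            protocol=_dummy_protocol(),
            steps=np.array([0]),
            walker=np.array([0]),
        )
    )
    labels = {c for c in streams.columns if bool(streams[c].iloc[0])}
    if include_junction_stacks:
        labels |= {
            f"stack:{a}|{b}" for a, b in stack_pair_names(topology)
        }
    return labels


def _dummy_protocol():
    from .cg_engine import SimulationProtocol

    return SimulationProtocol(total_steps=10, equilibration_steps=0)
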