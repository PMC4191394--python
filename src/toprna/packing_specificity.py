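"""Best-packed conformer selection, local ensemble entropies and
entropy-weighted native specificity <N>.

Best-packed conformers minimize E = n_l eps_l + n_s eps_s, where n_l
counts residue-residue contacts with both residues single-stranded and
n_s counts coaxial stacks (eps_l = -0.6, eps_s = -3.5 k_B T by
default; the ranking is insensitive to moderate changes in these
weights).  The entropy of conformer i within the best-packed subset,

    S_i = k_B ln[ 1 + sum_{j != i} exp( -rmsd_ij^3 / (10 A)^3 ) ],

is a smooth count of neighbors within ~10 A (pairwise P-bead Kabsch
RMSD).  <N> is the entropy-weighted fraction of best-packed conformers
that are native-like: D-loop/T-loop contact present and none of the
native-inconsistent loop-pair contacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cg_engine import Ensemble
from .contacts_cooperativity import (
    CONTACT_CUTOFF,
    MIN_SEQ_SEPARATION,
    coaxial_stack,
    group_contact,
    stack_pair_names,
)
from .geometry import kabsch_rmsd

logger = logging.getLogger(__name__)

EPS_LOOP = -0.6    # k_B T per interloop residue-residue contact
EPS_STACKING = -3.5  # k_B T per coaxial stack
ENTROPY_KERNEL_RADIUS = 10.0  # A
DEFAULT_SUBSET_SIZE = 500

# loop pairs whose contact precludes a native-like 3D structure
NATIVE_INCONSISTENT_PAIRS = [
    ("A/D-loop", "AC-loop"),
    ("A/D-loop", "ACCA-tail"),
    ("D-loop", "AC-loop"),
    ("D-loop", "ACCA-tail"),
    ("D/AC-linker", "ACCA-tail"),
    ("AC-loop", "V-loop"),
    ("AC-loop", "T-loop"),
    ("AC-loop", "ACCA-tail"),
    ("V-loop", "ACCA-tail"),
    ("T-loop", "ACCA-tail"),
]

# excluded from cross-species RMSD comparisons (variable-length loops)
RMSD_EXCLUDED_ELEMENTS = ("A/D-loop", "V-loop", "ACCA-tail")


@dataclass(frozen=True)
class PackingScore:
    """Per-snapshot packing energies and contact counts."""

    n_loop_contacts: np.ndarray
    n_stacks: np.ndarray
    energy: np.ndarray
    eps_l: float
    eps_s: float


def packing_scores(
    ensemble: Ensemble,
    eps_l: float = EPS_LOOP,
    eps_s: float = EPS_STACKING,
) -> PackingScore:
    """Count interloop residue-residue contacts (both residues
    single-stranded, >= 5 apart) and coaxial stacks per snapshot."""
    topo = ensemble.topology
    ss = topo.secondary_structure
    paired = {r for p in ss.pairs for r in p}
    loop_res = np.array(
        [r for r in range(1, topo.n_nt + 1) if r not in paired]
    )
    s_idx = [topo.bead_index(r, "S") for r in loop_res]
    sep_ok = (
        np.abs(np.subtract.outer(loop_res, loop_res)) >= MIN_SEQ_SEPARATION
    )
    iu = np.triu_indices(len(loop_res), k=1)
    stacks = stack_pair_names(topo)
    n_l = np.empty(ensemble.n_snapshots, dtype=int)
    n_s = np.empty(ensemble.n_snapshots, dtype=int)
    for s, c in enumerate(ensemble.coords):
        pts = c[s_idx]
        d2 = ((pts[:, None] - pts[None, :]) ** 2).sum(axis=2)
        hits = (d2 < CONTACT_CUTOFF ** 2) & sep_ok
        n_l[s] = int(hits[iu].sum())
        n_s[s] = sum(coaxial_stack(c, topo, a, b) for a, b in stacks)
    return PackingScore(
        n_loop_contacts=n_l,
        n_stacks=n_s,
        energy=n_l * eps_l + n_s * eps_s,
        eps_l=eps_l,
        eps_s=eps_s,
    )


def select_best_packed(
    ensemble: Ensemble,
    k: int | None = None,
    eps_l: float = EPS_LOOP,
    eps_s: float = EPS_STACKING,
) -> tuple[np.ndarray, PackingScore]:
    """Indices of the k lowest-packing-energy snapshots (ties broken by
    snapshot order via stable sort).  Default k = min(500, n/10) so that
    short runs keep a meaningfully compact subset; k larger than the
    ensemble returns everything with a warning."""
    n = ensemble.n_snapshots
    if k is None:
        k = min(DEFAULT_SUBSET_SIZE, max(2, n // 10))
        logger.info("best-packed subset size defaulted to %d", k)
    if k > n:
        logger.warning("subset size %d > ensemble size %d; using all", k, n)
        k = n
    scores = packing_scores(ensemble, eps_l=eps_l, eps_s=eps_s)
    order = np.argsort(scores.energy, kind="stable")
    return order[:k], scores


@dataclass(frozen=True)
class ConformerEntropy:
    """Per-conformer entropies (k_B units) and the RMSD matrix behind
    them."""

    indices: np.ndarray
    entropy: np.ndarray
    rmsd_matrix: np.ndarray


def rmsd_selection(topology, cross_species: bool = False) -> np.ndarray:
    """P-bead indices for conformer RMSDs; when comparing across
    species the variable-length loops (A/D, V, ACCA) are excluded."""
    ss = topology.secondary_structure
    excluded: set[int] = set()
    if cross_species:
        for nm in RMSD_EXCLUDED_ELEMENTS:
            excluded.update(ss.elements.get(nm, ()))
    return np.array([
        topology.bead_index(r, "P")
        for r in range(1, topology.n_nt + 1)
        if r not in excluded
    ])


def conformer_entropy(
    coords: np.ndarray,
    selection: np.ndarray,
    indices: np.ndarray | None = None,
) -> ConformerEntropy:
    """Eq.-(kernel) entropies over a conformer subset.

    ``coords`` is (n_conf, n_beads, 3); ``selection`` the bead indices
    entering the pairwise Kabsch RMSD (P beads by convention).
    """
    n = len(coords)
    if n < 2:
        raise ValueError("need >= 2 conformers")
    if len(selection) == 0:
        raise ValueError("empty selection")
    rmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rmat[i, j] = rmat[j, i] = kabsch_rmsd(
                coords[i], coords[j], selection
            )
    kern = np.exp(-(rmat ** 3) / ENTROPY_KERNEL_RADIUS ** 3)
    np.fill_diagonal(kern, 0.0)
    s = np.log1p(kern.sum(axis=1))
    return ConformerEntropy(
        indices=np.arange(n) if indices is None else np.asarray(indices),
        entropy=s,
        rmsd_matrix=rmat,
    )


@dataclass(frozen=True)
class NativeSpecificity:
    """Entropy-weighted fraction of best-packed conformers that are
    native-like."""

    mean_n: float
    n_i: np.ndarray
    weights: np.ndarray
    inconsistent_pairs: tuple[tuple[str, str], ...]


def native_like_flags(
    ensemble: Ensemble, subset: np.ndarray
) -> np.ndarray:
    """N_i = 1 iff the D- and T-loops touch and no native-inconsistent
    loop pair does."""
    topo = ensemble.topology
    elements = topo.secondary_structure.elements
    for required in ("D-loop", "T-loop"):
        if required not in elements:
            raise KeyError(f"element {required!r} missing from topology")
    flags = np.zeros(len(subset), dtype=int)
    for out_idx, snap in enumerate(subset):
        c = ensemble.coords[snap]
        if not group_contact(c, topo, elements["D-loop"], elements["T-loop"]):
            continue
        bad = False
        for a, b in NATIVE_INCONSISTENT_PAIRS:
            if a in elements and b in elements and group_contact(
                c, topo, elements[a], elements[b]
            ):
                bad = True
                break
        flags[out_idx] = 0 if bad else 1
    return flags


def native_specificity(
    n_i: np.ndarray, entropies: np.ndarray
) -> NativeSpecificity:
    """<N> = sum_i N_i exp(S_i) / sum_i exp(S_i)."""
    n_i = np.asarray(n_i, dtype=float)
    s = np.asarray(entropies, dtype=float)
    if len(n_i) != len(s):
        raise ValueError("flags and entropies must align")
    w = np.exp(s - s.max())
    w = w / w.sum()
    return NativeSpecificity(
        mean_n=float(np.dot(n_i, w)),
        n_i=n_i.astype(int),
        weights=w,
        inconsistent_pairs=tuple(NATIVE_INCONSISTENT_PAIRS),
    )


def packing_report(
    ensemble: Ensemble,
    k: int | None = None,
    reference_coords: np.ndarray | None = None,
    cross_species: bool = False,
):
    """Per-conformer table: id, E, n_l, n_s, S_i, N_i (and RMSD to a
    reference when given), as a pandas DataFrame."""
    import pandas as pd

    subset, scores = select_best_packed(ensemble, k=k)
    sel = rmsd_selection(ensemble.topology, cross_species=cross_species)
    ent = conformer_entropy(
        ensemble.coords[subset], sel, indices=subset
    )
    flags = native_like_flags(ensemble, subset)
    spec = native_specificity(flags, ent.entropy)
    df = pd.DataFrame({
        "snapshot": subset,
        "energy": scores.energy[subset],
        "n_loop_contacts": scores.n_loop_contacts[subset],
        "n_stacks": scores.n_stacks[subset],
        "entropy": ent.entropy,
        "native_like": flags,
        "weight": spec.weights,
    })
    if reference_coords is not None:
        df["rmsd_to_reference"] = [
            kabsch_rmsd(ensemble.coords[s], reference_coords, sel)
            for s in subset
        ]
    df.attrs["mean_n"] = spec.mean_n
    return df
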