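"""Secondary-structure parsing, element classification and bead topology.

Residue numbering is 1-based throughout the public interface (matching
tRNA crystallographic convention); bead arrays are 0-based internally.
For residue ``r`` the P, S and B beads occupy indices ``3(r-1)``,
``3(r-1)+1`` and ``3(r-1)+2``; one M bead per base pair is appended
after all nucleotide beads, in base-pair order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import forcefield as ff


class ParseError(ValueError):
    """Malformed dot-bracket or pair-list input."""


class PseudoknotError(ValueError):
    """Crossing base pairs are not supported."""


class VariantError(ValueError):
    """Invalid secondary-structure or topology edit."""


# ----------------------------------------------------------------------
# secondary structure
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Helix:
    """A maximal run of consecutively stacked base pairs.

    ``pairs`` are ordered 5'->3' along strand 1, i.e. pairs[k] =
    (i0 + k, j0 - k).
    """

    name: str
    pairs: tuple[tuple[int, int], ...]

    @property
    def strand1(self) -> tuple[int, ...]:
        return tuple(p[0] for p in self.pairs)

    @property
    def strand2(self) -> tuple[int, ...]:
        return tuple(p[1] for p in self.pairs)

    @property
    def residues(self) -> tuple[int, ...]:
        return tuple(sorted(self.strand1 + self.strand2))


@dataclass
class SecondaryStructure:
    """Pair table plus derived structural elements for one RNA."""

    sequence: str
    pairs: list[tuple[int, int]]
    helices: list[Helix] = field(default_factory=list)
    elements: dict[str, tuple[int, ...]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.sequence)

    def partner(self, i: int) -> int | None:
        for a, b in self.pairs:
            if a == i:
                return b
            if b == i:
                return a
        return None

    def helix_of(self, res: int) -> int:
        """Index of the helix containing ``res``, or -1."""
        for k, h in enumerate(self.helices):
            if res in h.strand1 or res in h.strand2:
                return k
        return -1

    def element_of(self, res: int) -> str:
        for name, members in self.elements.items():
            if res in members:
                return name
        raise KeyError(res)

    def to_dotbracket(self) -> str:
        s = ["."] * self.n
        for i, j in self.pairs:
            s[i - 1] = "("
            s[j - 1] = ")"
        return "".join(s)

    def copy(self) -> "SecondaryStructure":
        return parse_secondary_structure(
            self.sequence + "\n" + self.to_dotbracket()
        )


def _pairs_from_dotbracket(struct: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs = []
    for k, c in enumerate(struct, start=1):
        if c == "(":
            stack.append(k)
        elif c == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at position {k}")
            pairs.append((stack.pop(), k))
        elif c not in ".-":
            raise ParseError(f"unsupported character {c!r} at position {k}")
    if stack:
        raise ParseError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def _check_pairs(pairs: list[tuple[int, int]], n: int) -> None:
    seen: set[int] = set()
    for i, j in pairs:
        if not (1 <= i < j <= n):
            raise ParseError(f"pair ({i},{j}) out of range for length {n}")
        if i in seen or j in seen:
            raise ParseError(f"residue in more than one pair: ({i},{j})")
        seen.update((i, j))
    for a, b in pairs:
        for c, d in pairs:
            if a < c < b < d:
                raise PseudoknotError(
                    f"crossing pairs ({a},{b}) and ({c},{d})"
                )


def _find_helices(pairs: list[tuple[int, int]]) -> list[tuple[tuple[int, int], ...]]:
    pairs = sorted(pairs)
    runs: list[list[tuple[int, int]]] = []
    for p in pairs:
        if runs and runs[-1][-1] == (p[0] - 1, p[1] + 1):
            runs[-1].append(p)
        else:
            runs.append([p])
    return [tuple(r) for r in runs]


def _classify(ss: SecondaryStructure) -> None:
    """Populate ``helices`` and ``elements`` in place.

    Uses the tRNA cloverleaf naming scheme (A-, D-, AC-, T-stem and the
    A/D-, D-, AC-, V-, T-loop, D/AC-linker, T/A-pivot, ACCA-tail
    single strands) when the structure is a four-way cloverleaf, the
    Class II variant names when a V-stem is present, and generic
    H1/L1... names otherwise.
    """
    runs = _find_helices(ss.pairs)
    n = ss.n
    paired = {r for p in ss.pairs for r in p}

    # single-stranded segments
    segments: list[tuple[int, ...]] = []
    cur: list[int] = []
    for r in range(1, n + 1):
        if r in paired:
            if cur:
                segments.append(tuple(cur))
                cur = []
        else:
            cur.append(r)
    if cur:
        segments.append(tuple(cur))

    helix_names, seg_names = _trna_names(runs, segments, n)
    ss.helices = [Helix(nm, run) for nm, run in zip(helix_names, runs)]
    elements: dict[str, tuple[int, ...]] = {}
    for h in ss.helices:
        elements[h.name] = h.residues
    for nm, seg in zip(seg_names, segments):
        elements[nm] = seg
    ss.elements = elements


def _trna_names(runs, segments, n):
    """Name helices and single strands, tRNA-style when possible."""
    generic_h = [f"H{k+1}" for k in range(len(runs))]
    generic_s = [f"L{k+1}" for k in range(len(segments))]
    if runs and segments:
        if segments[0][0] == 1:
            generic_s[0] = "5p-tail"
        if segments[-1][-1] == n and len(segments) > 1:
            generic_s[-1] = "3p-tail"

    if len(runs) not in (4, 5):
        return generic_h, generic_s

    outer, inner = runs[0], runs[1:]
    o_i, o_j = outer[-1]
    if not all(o_i < r[0][0] and r[0][1] < o_j for r in inner):
        return generic_h, generic_s
    # inner helices must be hairpins (nothing nested inside them)
    for r in inner:
        lo, hi = r[-1]
        for other in runs:
            if other is r:
                continue
            if lo < other[0][0] and other[0][1] < hi:
                return generic_h, generic_s

    class2 = len(runs) == 5
    helix_names = (
        ["A-stem", "D-stem", "AC-stem", "V-stem", "T-stem"]
        if class2
        else ["A-stem", "D-stem", "AC-stem", "T-stem"]
    )

    # hairpin loop names per inner stem
    hairpin_name = {}
    loop_names = (
        ["D-loop", "AC-loop", "V-loop", "T-loop"]
        if class2
        else ["D-loop", "AC-loop", "T-loop"]
    )
    for r, nm in zip(inner, loop_names):
        hairpin_name[(r[-1][0], r[-1][1])] = nm

    seg_names = []
    a_s1_end = outer[-1][0]       # 3' end of A-stem strand 1
    a_s2_start = outer[-1][1]     # 5' end of A-stem strand 2
    d_start = inner[0][0][0]
    d_end = inner[0][0][1]
    ac_start = inner[1][0][0]
    ac_end = inner[1][0][1]
    t_run = inner[-1]
    t_start, t_end = t_run[0]
    for seg in segments:
        lo, hi = seg[0], seg[-1]
        nm = None
        for (hl, hh), lname in hairpin_name.items():
            if hl < lo and hi < hh:
                nm = lname
        if nm is None:
            if hi < outer[0][0]:
                nm = "5p-tail"
            elif lo > outer[0][1]:
                nm = "ACCA-tail"
            elif a_s1_end < lo and hi < d_start:
                nm = "A/D-loop"
            elif d_end < lo and hi < ac_start:
                nm = "D/AC-linker"
            elif ac_end < lo and hi < t_start:
                if class2:
                    v_start, v_end = inner[2][0]
                    if hi < v_start:
                        nm = "AC/V-linker"
                    elif lo > v_end:
                        nm = "V/T-linker"
                else:
                    nm = "V-loop"
            elif t_end < lo and hi < a_s2_start:
                nm = "T/A-pivot"
        if nm is None:
            nm = f"L{len(seg_names)+1}"
        seg_names.append(nm)
    return helix_names, seg_names


def parse_secondary_structure(text: str) -> SecondaryStructure:
    """Parse dot-bracket text or a two-column pair list.

    Dot-bracket input is one or two lines: an optional sequence line
    (A/C/G/U) followed by the structure line.  Pair-list input starts
    with a header line ``# pairs n=<length>`` followed by ``i j`` rows
    (1-based).  When no sequence is given a poly-N placeholder is used;
    single strands are sequence independent in this model.
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty input")
    if lines[0].startswith("#"):
        head = lines[0]
        try:
            n = int(head.split("n=")[1].split()[0])
        except (IndexError, ValueError) as exc:
            raise ParseError("pair-list header must be '# pairs n=<len>'") from exc
        pairs = []
        for ln in lines[1:]:
            i, j = (int(x) for x in ln.split()[:2])
            pairs.append((min(i, j), max(i, j)))
        seq = "N" * n
    else:
        if len(lines) == 1:
            struct = lines[0]
            seq = "N" * len(struct)
        else:
            seq, struct = lines[0], lines[1]
            if set(seq) - set("ACGUN"):
                raise ParseError("sequence line may contain only A/C/G/U/N")
            if len(seq) != len(struct):
                raise ParseError(
                    f"sequence length {len(seq)} != structure length {len(struct)}"
                )
        pairs = _pairs_from_dotbracket(struct)
    _check_pairs(sorted(pairs), len(seq))
    ss = SecondaryStructure(sequence=seq, pairs=sorted(pairs))
    _classify(ss)
    return ss


# ----------------------------------------------------------------------
# restraints
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RestraintSpec:
    """Flat-bottom distance restraint between two beads.

    Zero energy and force inside [r_min, r_max]; harmonic walls with
    force constants k_min/k_max just outside; the wall force saturates
    linearly at ``fmax`` (energy becomes linear in distance).
    """

    bead_i: int
    bead_j: int
    r_min: float
    r_max: float
    k_min: float = 2.0
    k_max: float = 2.0
    fmax: float = 2.0
    label: str = ""

    def __post_init__(self):
        if not self.r_min < self.r_max:
            raise ValueError("r_min must be < r_max")


# windows for tertiary-pair restraints (A)
TERTIARY_BB_WINDOW = (5.5, 7.5)
TERTIARY_SS_WINDOW = (11.0, 14.0)
TRIPLE_BB_HALFWIDTH = 1.0
TRIPLE_SS_HALFWIDTH = 1.5


# ----------------------------------------------------------------------
# bead topology
# ----------------------------------------------------------------------

@dataclass
class BeadTopology:
    """Beads plus every bonded / nonbonded force-field term.

    Array conventions: energies E = k(b-b0)^2 for bonds, k(th-th0)^2 for
    angles, k*wrap(phi-phi0)^2 for impropers and k(1-cos(phi-phi0)) for
    dihedrals.  ``stacky`` marks beads carrying the selective stacking
    attraction (paired B beads and M beads).
    """

    sequence: str
    pairs: list[tuple[int, int]]
    bead_kind: list[str]
    bead_resid: np.ndarray
    lj_radius: np.ndarray
    lj_eps: np.ndarray
    stacky: np.ndarray
    mass: np.ndarray
    bonds: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angles: np.ndarray
    angle_t0: np.ndarray
    angle_k: np.ndarray
    impropers: np.ndarray
    impr_phi0: np.ndarray
    impr_k: np.ndarray
    dihedrals: np.ndarray
    dihe_phi0: np.ndarray
    dihe_k: np.ndarray
    m_bead_of_pair: dict[tuple[int, int], int]
    strand_breaks: frozenset[tuple[int, int]]
    restraints: list[RestraintSpec] = field(default_factory=list)
    eps_stack: float = ff.EPS_STACK
    secondary_structure: SecondaryStructure | None = None

    @property
    def n_nt(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return len(self.bead_kind)

    def bead_index(self, res: int, kind: str) -> int:
        """0-based bead index of residue ``res`` (1-based), kind P/S/B/M."""
        if kind in "PSB":
            return 3 * (res - 1) + "PSB".index(kind)
        for (a, b), m in self.m_bead_of_pair.items():
            if res in (a, b):
                return m
        raise KeyError(f"residue {res} has no M bead")

    def residue_beads(self, res: int) -> tuple[int, int, int]:
        base = 3 * (res - 1)
        return base, base + 1, base + 2

    # --- nonbonded bookkeeping -----------------------------------------

    def bonded_pairs(self) -> set[tuple[int, int]]:
        return {tuple(sorted(b)) for b in self.bonds.tolist()}

    def exclusion_matrix(self) -> np.ndarray:
        """N x N int8: 0 = excluded (1-2/1-3 bonded neighbors), 1 = LJ."""
        n = self.n_beads
        adj: list[set[int]] = [set() for _ in range(n)]
        for a, b in self.bonds:
            adj[a].add(b)
            adj[b].add(a)
        mat = np.ones((n, n), dtype=np.int8)
        np.fill_diagonal(mat, 0)
        for i in range(n):
            for j in adj[i]:
                mat[i, j] = 0
                for k in adj[j]:
                    if k != i:
                        mat[i, k] = 0
                        mat[k, i] = 0
        return mat

    def term_set(self) -> dict[str, set]:
        """Hashable view of every term, for topology-diff assertions."""
        return {
            "bonds": {
                (tuple(b), round(r, 6), round(k, 6))
                for b, r, k in zip(
                    self.bonds.tolist(), self.bond_r0, self.bond_k
                )
            },
            "angles": {
                (tuple(a), round(t, 6), round(k, 6))
                for a, t, k in zip(
                    self.angles.tolist(), self.angle_t0, self.angle_k
                )
            },
            "impropers": {
                (tuple(a), round(p, 6), round(k, 6))
                for a, p, k in zip(
                    self.impropers.tolist(), self.impr_phi0, self.impr_k
                )
            },
            "dihedrals": {
                (tuple(a), round(p, 6), round(k, 6))
                for a, p, k in zip(
                    self.dihedrals.tolist(), self.dihe_phi0, self.dihe_k
                )
            },
        }

    # --- serialization --------------------------------------------------

    FORMAT_VERSION = "toprna-topology-1"

    def to_json(self) -> str:
        d = {
            "format": self.FORMAT_VERSION,
            "numbering": "1-based residues",
            "sequence": self.sequence,
            "pairs": self.pairs,
            "strand_breaks": sorted(self.strand_breaks),
            "eps_stack": self.eps_stack,
            "restraints": [
                {
                    "bead_i": r.bead_i, "bead_j": r.bead_j,
                    "r_min": r.r_min, "r_max": r.r_max,
                    "k_min": r.k_min, "k_max": r.k_max,
                    "fmax": r.fmax, "label": r.label,
                }
                for r in self.restraints
            ],
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "BeadTopology":
        d = json.loads(text)
        if d.get("format") != cls.FORMAT_VERSION:
            raise ValueError(f"unknown topology format {d.get('format')!r}")
        ss = SecondaryStructure(
            sequence=d["sequence"], pairs=[tuple(p) for p in d["pairs"]]
        )
        _classify(ss)
        topo = build_topology(
            ss,
            strand_breaks={tuple(b) for b in d["strand_breaks"]},
            eps_stack=d.get("eps_stack", ff.EPS_STACK),
        )
        topo.restraints = [RestraintSpec(**r) for r in d["restraints"]]
        return topo


def build_topology(
    ss: SecondaryStructure,
    strand_breaks: set[tuple[int, int]] | None = None,
    eps_stack: float = ff.EPS_STACK,
) -> BeadTopology:
    """Emit the full bead topology for a secondary structure.

    Helical backbone dihedrals are assigned only to quadruples whose
    residues all belong to one helix; single strands and the pivot
    steps between stacked-but-distinct helices carry none and rotate
    freely.  ``strand_breaks`` lists (i, i+1) backbone links to omit.
    """
    breaks = frozenset(tuple(b) for b in (strand_breaks or set()))
    n = ss.n
    geo = ff.equilibrium_geometry()
    paired = {r for p in ss.pairs for r in p}
    helix_id = {r: ss.helix_of(r) for r in range(1, n + 1)}

    kinds: list[str] = []
    resid: list[int] = []
    for r in range(1, n + 1):
        kinds += ["P", "S", "B"]
        resid += [r, r, r]
    m_of: dict[tuple[int, int], int] = {}
    for p in ss.pairs:
        m_of[p] = len(kinds)
        kinds.append("M")
        resid.append(p[0])

    def P(r):
        return 3 * (r - 1)

    def S(r):
        return 3 * (r - 1) + 1

    def B(r):
        return 3 * (r - 1) + 2

    def linked(r):
        return r < n and (r, r + 1) not in breaks

    def same_helix(*res):
        hid = helix_id[res[0]]
        return hid >= 0 and all(helix_id[r] == hid for r in res)

    bonds, b_r0, b_k = [], [], []
    angles, a_t0, a_k = [], [], []
    imps, i_p0, i_k = [], [], []
    dihes, d_p0, d_k = [], [], []

    for r in range(1, n + 1):
        bonds += [(P(r), S(r)), (S(r), B(r))]
        b_r0 += [geo["bond_PS"], geo["bond_SB"]]
        b_k += [ff.K_BOND, ff.K_BOND]
        if linked(r):
            bonds.append((S(r), P(r + 1)))
            b_r0.append(geo["bond_SP_next"])
            b_k.append(ff.K_BOND)

    for (i, j) in ss.pairs:
        m = m_of[(i, j)]
        bonds += [(B(i), B(j)), (S(i), S(j)), (m, B(i)), (m, B(j))]
        b_r0 += [
            geo["bond_BB_pair"], geo["bond_SS_pair"],
            geo["bond_MB"], geo["bond_MB"],
        ]
        b_k += [ff.K_BOND_PAIR, ff.K_BOND_PAIR_SS,
                ff.K_BOND_PAIR, ff.K_BOND_PAIR]
        angles += [(S(i), B(i), B(j)), (S(j), B(j), B(i))]
        a_t0 += [geo["angle_SBB"], geo["angle_SBB"]]
        a_k += [ff.K_ANGLE_PAIR, ff.K_ANGLE_PAIR]

    for r in range(1, n + 1):
        k_loc = ff.K_ANGLE_HELIX if r in paired else ff.K_ANGLE_SS
        angles.append((P(r), S(r), B(r)))
        a_t0.append(geo["angle_PSB"])
        a_k.append(k_loc)
        if linked(r):
            k_step = (
                ff.K_ANGLE_HELIX if same_helix(r, r + 1) else ff.K_ANGLE_SS
            )
            angles += [
                (P(r), S(r), P(r + 1)),
                (B(r), S(r), P(r + 1)),
                (S(r), P(r + 1), S(r + 1)),
            ]
            a_t0 += [geo["angle_PSP"], geo["angle_BSP"], geo["angle_SPS"]]
            a_k += [k_step, k_step, k_step]
            # chirality at the sugar of r: signed volume of the three
            # bonds leaving S(r), quadruple stored center-first
            imps.append((S(r), P(r), B(r), P(r + 1)))
            i_p0.append(geo["improper_V"])
            i_k.append(ff.K_IMPROPER_VOL)
            if same_helix(r, r + 1):
                dihes.append((P(r), S(r), P(r + 1), S(r + 1)))
                d_p0.append(geo["dihedral_PSPS"])
                d_k.append(ff.K_DIHEDRAL)
                if linked(r + 1) and same_helix(r, r + 1, r + 2):
                    dihes.append((S(r), P(r + 1), S(r + 1), P(r + 2)))
                    d_p0.append(geo["dihedral_SPSP"])
                    d_k.append(ff.K_DIHEDRAL)

    kinds_arr = kinds
    radius = np.array([ff.LJ_RADIUS[k] for k in kinds_arr])
    eps = np.full(len(kinds_arr), ff.EPS_REPULSIVE)
    stacky = np.zeros(len(kinds_arr), dtype=bool)
    for (i, j) in ss.pairs:
        stacky[B(i)] = stacky[B(j)] = True
    for m in m_of.values():
        stacky[m] = True
    mass = np.array([ff.MASS[k] for k in kinds_arr])

    return BeadTopology(
        sequence=ss.sequence,
        pairs=list(ss.pairs),
        bead_kind=kinds_arr,
        bead_resid=np.array(resid),
        lj_radius=radius,
        lj_eps=eps,
        stacky=stacky,
        mass=mass,
        bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
        bond_r0=np.array(b_r0),
        bond_k=np.array(b_k),
        angles=np.array(angles, dtype=np.int64).reshape(-1, 3),
        angle_t0=np.array(a_t0),
        angle_k=np.array(a_k),
        impropers=np.array(imps, dtype=np.int64).reshape(-1, 4),
        impr_phi0=np.array(i_p0),
        impr_k=np.array(i_k),
        dihedrals=np.array(dihes, dtype=np.int64).reshape(-1, 4),
        dihe_phi0=np.array(d_p0),
        dihe_k=np.array(d_k),
        m_bead_of_pair=m_of,
        strand_breaks=breaks,
        eps_stack=eps_stack,
        secondary_structure=ss,
    )


# ----------------------------------------------------------------------
# variants
# ----------------------------------------------------------------------

def _shift_pairs(pairs, at, delta):
    """Renumber pairs after inserting/removing ``delta`` residues at ``at``."""
    out = []
    for i, j in pairs:
        ii = i + delta if i >= at else i
        jj = j + delta if j >= at else j
        out.append((ii, jj))
    return sorted(out)


def apply_variant(obj, edit: str, **kw):
    """Apply a secondary-structure or topology edit.

    Edits on a :class:`SecondaryStructure` (returns a new one):

    * ``insert_loop_nt(after=r, count=k)`` — insert k unpaired residues
      after residue r (r must not sit inside a helix run with r+1).
    * ``delete_loop_nt(residue=r, count=k)`` — delete k unpaired
      residues starting at r.
    * ``insert_stem(after=r, n_bp=b, loop_len=l)`` — insert a hairpin.
    * ``toggle_pair(i=i, j=j)`` — add or remove the pair (i, j).

    Edit on a :class:`BeadTopology` (returns a rebuilt topology):

    * ``cut(residue=r)`` — remove the backbone S(r)-P(r+1) bond and the
      angle/improper/dihedral terms that span the broken link.
    """
    if edit == "cut":
        topo: BeadTopology = obj
        if not isinstance(topo, BeadTopology):
            topo = build_topology(obj)
        r = kw["residue"]
        if r < 1 or r >= topo.n_nt:
            raise VariantError(f"no backbone bond after residue {r}")
        if (r, r + 1) in topo.strand_breaks:
            raise VariantError(f"backbone already cut at ({r},{r+1})")
        ss = topo.secondary_structure
        new = build_topology(
            ss,
            strand_breaks=set(topo.strand_breaks) | {(r, r + 1)},
            eps_stack=topo.eps_stack,
        )
        new.restraints = list(topo.restraints)
        return new

    ss: SecondaryStructure = obj
    paired = {r for p in ss.pairs for r in p}
    if edit == "insert_loop_nt":
        after, count = kw["after"], kw.get("count", 1)
        if after in paired and (after + 1) in paired and \
                ss.helix_of(after) == ss.helix_of(after + 1) >= 0:
            raise VariantError("cannot insert inside a helix")
        seq = ss.sequence[:after] + "N" * count + ss.sequence[after:]
        pairs = _shift_pairs(ss.pairs, after + 1, count)
    elif edit == "delete_loop_nt":
        res, count = kw["residue"], kw.get("count", 1)
        for r in range(res, res + count):
            if r in paired:
                raise VariantError(f"residue {r} is paired; not a loop edit")
        seq = ss.sequence[: res - 1] + ss.sequence[res - 1 + count:]
        pairs = _shift_pairs(ss.pairs, res, -count)
    elif edit == "insert_stem":
        after, n_bp, loop_len = kw["after"], kw["n_bp"], kw.get("loop_len", 4)
        length = 2 * n_bp + loop_len
        seq = ss.sequence[:after] + "N" * length + ss.sequence[after:]
        pairs = _shift_pairs(ss.pairs, after + 1, length)
        for k in range(n_bp):
            pairs.append((after + 1 + k, after + length - k))
        pairs = sorted(pairs)
    elif edit == "toggle_pair":
        i, j = sorted((kw["i"], kw["j"]))
        seq = ss.sequence
        if (i, j) in ss.pairs:
            pairs = [p for p in ss.pairs if p != (i, j)]
        else:
            pairs = sorted(ss.pairs + [(i, j)])
    else:
        raise VariantError(f"unknown edit {edit!r}")
    _check_pairs(pairs, len(seq))
    new = SecondaryStructure(sequence=seq, pairs=pairs)
    _classify(new)
    return new


# ----------------------------------------------------------------------
# restraint construction
# ----------------------------------------------------------------------

def make_restraints(
    kind: str,
    residues,
    topology: BeadTopology,
    reference_coords: np.ndarray | None = None,
) -> list[RestraintSpec]:
    """Build flat-bottom restraints enforcing a tertiary interaction.

    * ``tertiary_pair``, residues=(i, j): B-B window 5.5-7.5 A and S-S
      window 11-14 A.
    * ``base_triple``, residues=(t, (h1, h2)): B-B and S-S windows of
      +-1 A and +-1.5 A around the distances measured in
      ``reference_coords`` between t and each helical partner.
    * ``g26_pair``, residues=(i, j): the tertiary-pair windows, labelled
      so that :func:`apply_g26_modifications` is applied alongside.
    """
    specs: list[RestraintSpec] = []
    if kind in ("tertiary_pair", "g26_pair"):
        i, j = residues
        label = f"{kind}:{i}-{j}"
        specs.append(RestraintSpec(
            topology.bead_index(i, "B"), topology.bead_index(j, "B"),
            *TERTIARY_BB_WINDOW, label=label,
        ))
        specs.append(RestraintSpec(
            topology.bead_index(i, "S"), topology.bead_index(j, "S"),
            *TERTIARY_SS_WINDOW, label=label,
        ))
    elif kind == "base_triple":
        t, (h1, h2) = residues
        if reference_coords is None:
            raise ValueError("base triples need reference coordinates")
        for h in (h1, h2):
            bi = topology.bead_index(t, "B")
            bj = topology.bead_index(h, "B")
            si = topology.bead_index(t, "S")
            sj = topology.bead_index(h, "S")
            dbb = float(np.linalg.norm(
                reference_coords[bi] - reference_coords[bj]
            ))
            dss = float(np.linalg.norm(
                reference_coords[si] - reference_coords[sj]
            ))
            label = f"triple:{t}-{h}"
            specs.append(RestraintSpec(
                bi, bj, dbb - TRIPLE_BB_HALFWIDTH, dbb + TRIPLE_BB_HALFWIDTH,
                label=label,
            ))
            specs.append(RestraintSpec(
                si, sj, dss - TRIPLE_SS_HALFWIDTH, dss + TRIPLE_SS_HALFWIDTH,
                label=label,
            ))
    else:
        raise ValueError(f"unknown restraint kind {kind!r}")
    return specs


def apply_g26_modifications(topology: BeadTopology, i: int, j: int) -> BeadTopology:
    """Force-field changes that accompany restraining a stem-extending
    noncanonical pair (the G26-A44 pattern atop the anticodon stem):
    quarter-height backbone dihedrals on both residues, the paired-B
    stacking attraction on their B beads, and an M bead on residue i's
    B bead to fill the steric gap of the pair.
    """
    geo = ff.equilibrium_geometry()
    topo = replace(topology)
    topo.stacky = topology.stacky.copy()
    topo.stacky[topology.bead_index(i, "B")] = True
    topo.stacky[topology.bead_index(j, "B")] = True

    # quarter-height dihedrals extending A-form bias across i-1,i and j,j+1
    extra, p0s = [], []
    for r in (i - 1, i, j - 1, j):
        if 1 <= r < topology.n_nt and (r, r + 1) not in topology.strand_breaks:
            quad = (
                3 * (r - 1), 3 * (r - 1) + 1, 3 * r, 3 * r + 1
            )  # P(r), S(r), P(r+1), S(r+1)
            if not any(tuple(q) == quad for q in topology.dihedrals.tolist()):
                extra.append(quad)
                p0s.append(geo["dihedral_PSPS"])
    if extra:
        topo.dihedrals = np.vstack([topology.dihedrals, np.array(extra)])
        topo.dihe_phi0 = np.concatenate([topology.dihe_phi0, p0s])
        topo.dihe_k = np.concatenate(
            [topology.dihe_k, np.full(len(extra), ff.K_DIHEDRAL / 4.0)]
        )

    # M bead attached to residue i's B bead
    m_idx = topo.n_beads
    topo.bead_kind = list(topology.bead_kind) + ["M"]
    topo.bead_resid = np.append(topology.bead_resid, i)
    topo.lj_radius = np.append(topology.lj_radius, ff.LJ_RADIUS["M"])
    topo.lj_eps = np.append(topology.lj_eps, ff.EPS_REPULSIVE)
    topo.stacky = np.append(topo.stacky, True)
    topo.mass = np.append(topology.mass, ff.MASS["M"])
    topo.bonds = np.vstack(
        [topology.bonds, [[m_idx, topology.bead_index(i, "B")]]]
    )
    topo.bond_r0 = np.append(topology.bond_r0, geo["bond_MB"])
    topo.bond_k = np.append(topology.bond_k, ff.K_BOND_PAIR)
    topo.m_bead_of_pair = dict(topology.m_bead_of_pair)
    return topo
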