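"""Force-field parameter table and ideal A-form bead geometry.

The model represents each nucleotide with three beads — phosphate (P),
sugar (S) and base (B) — plus one midpoint (M) bead per base pair that
fills the steric gap between paired B beads.  All equilibrium bond
lengths, angles, improper dihedrals and backbone dihedrals are derived
numerically from one idealized A-form duplex built from fiber-like
helical parameters (rise 2.81 A, twist 32.7 deg/bp), so an ideal helix
has zero bonded energy by construction.

Units: length A, energy kcal/mol, angles radians internally (degrees in
documentation), mass amu, time fs.  Energy conventions:

* bond      E = k (b - b0)^2
* angle     E = k (cos theta - cos theta0)^2   (smooth at theta = pi)
* improper  E = k (V - V0)^2 with V the signed volume spanned by the
  three bonds leaving the sugar bead (chirality term; a torsion-based
  improper has singular forces whenever a floppy single strand passes
  through collinearity, the signed volume is polynomial and smooth)
* dihedral  E = k (1 - cos(phi - phi0))
* LJ        E = eps [ (rmin/r)^12 - 2 (rmin/r)^6 ],  rmin = r_i + r_j

Only B beads of paired residues (and the M beads between them) carry an
attractive well (``EPS_STACK``); every other pair interacts with the
near-purely repulsive ``EPS_REPULSIVE`` well, which preserves sterics
while eliminating attraction.
"""

from __future__ import annotations

import numpy as np

# --- ideal A-form helical parameters -----------------------------------
RISE = 2.81          # A per base pair
TWIST_DEG = 32.7     # deg per base pair

# Bead positions of a strand-1 nucleotide in the local frame of its base
# pair (x points from the helix axis through the pair, z along the axis).
# The paired strand-2 nucleotide is generated by the pair's C2 axis
# (x, y, z) -> (x, -y, -z).  Chosen so paired S-S ~ 11.2 A (the
# Watson-Crick window), paired B-B ~ 5.6 A, and backbone P-S / S-P
# bonds ~ 3 A.
LOCAL_B = np.array([4.2, 2.8, 0.0])
LOCAL_S = np.array([7.2, 5.6, 0.3])
# P sits radially outside the S-S line so the P-S-P backbone angle is
# ~130 deg (a collinear P-S-P would make angle forces ill-conditioned)
LOCAL_P = np.array([10.4, 4.08, -1.01])

# --- Lennard-Jones table ------------------------------------------------
# radius = contact radius (rmin of a like pair is twice this); the P
# radius follows the model's stated effective value, B uses the base
# thickness (its minimum dimension), S the ribose minimum dimension.
LJ_RADIUS = {"P": 2.7, "S": 2.9, "B": 1.9, "M": 1.6}
EPS_REPULSIVE = 0.01          # kcal/mol, all beads
EPS_STACK = 0.5               # kcal/mol, paired-B and M beads only
LJ_CUTOFF = 10.0              # A, global nonbonded cutoff (energy-shifted)

# --- masses (moiety group masses, amu) ---------------------------------
MASS = {"P": 95.0, "S": 114.0, "B": 110.0, "M": 40.0}

# --- force constants ----------------------------------------------------
K_BOND = 64.0        # kcal/mol/A^2, covalent backbone and intra-nt bonds
K_BOND_PAIR = 32.0   # kcal/mol/A^2, permanent B-B pair bond and M-B bonds
K_BOND_PAIR_SS = 8.0  # kcal/mol/A^2, supporting S-S pair bond
K_ANGLE_HELIX = 20.0  # kcal/mol/rad^2, angles with both residues in a helix
K_ANGLE_SS = 5.0      # kcal/mol/rad^2, single-strand angles (soft)
K_ANGLE_PAIR = 10.0   # kcal/mol/rad^2, (S, B, B') pair-geometry angles
K_IMPROPER_VOL = 0.5  # kcal/mol/A^6 on the sugar chirality volume; the
#   mirror image (V -> -V0, |V0| ~ 1.3 A^3) costs ~3.4 kcal/mol (~6 kT),
#   a bias strong enough to preserve handedness yet soft enough to
#   integrate at a 20 fs timestep
K_DIHEDRAL = 6.0      # kcal/mol, A-form backbone dihedrals (helical only)

# --- physical constants -------------------------------------------------
KB = 0.0019872041          # kcal/mol/K
ACC_FACTOR = 4.184e-4      # (kcal/mol/A)/amu -> A/fs^2

DEFAULT_TEMPERATURE = 300.0  # K


def ideal_pair_frame_coords() -> dict[str, np.ndarray]:
    """Bead coordinates of one base pair in its local pair frame.

    Keys: P1/S1/B1 (strand 1), P2/S2/B2 (strand 2, C2-related), M.
    """
    c2 = np.diag([1.0, -1.0, -1.0])
    out = {"P1": LOCAL_P.copy(), "S1": LOCAL_S.copy(), "B1": LOCAL_B.copy()}
    out["P2"] = c2 @ LOCAL_P
    out["S2"] = c2 @ LOCAL_S
    out["B2"] = c2 @ LOCAL_B
    out["M"] = 0.5 * (out["B1"] + out["B2"])
    return out


def pair_transform(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rotation + translation placing base pair ``k`` of an ideal helix."""
    t = np.deg2rad(TWIST_DEG) * k
    c, s = np.cos(t), np.sin(t)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return rot, np.array([0.0, 0.0, RISE * k])


def ideal_duplex_beads(n_bp: int) -> dict[tuple[int, str], np.ndarray]:
    """Bead coordinates of an ideal ``n_bp`` A-form duplex.

    Returns a mapping (pair index, bead key) -> xyz with bead keys as in
    :func:`ideal_pair_frame_coords`.  Strand 1 runs 5'->3' with
    increasing pair index; strand 2 antiparallel.
    """
    local = ideal_pair_frame_coords()
    out = {}
    for k in range(n_bp):
        rot, tr = pair_transform(k)
        for key, v in local.items():
            out[(k, key)] = rot @ v + tr
    return out


def _dist(a, b):
    return float(np.linalg.norm(a - b))


def _angle(a, b, c):
    u, v = a - b, c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosv, -1.0, 1.0)))


def signed_volume(center, a, b, c) -> float:
    """Signed volume (A^3) spanned by the vectors center->a, center->b,
    center->c; flips sign under mirror inversion."""
    u = a - center
    v = b - center
    w = c - center
    return float(np.dot(u, np.cross(v, w)))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral of four points, radians in (-pi, pi]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def equilibrium_geometry() -> dict[str, float]:
    """Equilibrium bonded values measured on an ideal 5-bp duplex.

    All topology builders read their equilibrium values from this table,
    which makes the ideal helix the exact zero of the bonded potential.
    Keys ending in ``_deg``/``_rad`` are angles; others are lengths (A).
    """
    d = ideal_duplex_beads(5)
    k = 2  # interior pair; neighbors on both sides
    g = {}
    # intra-nucleotide and backbone bonds (strand 1 geometry; strand 2 is
    # identical by the pair C2 symmetry)
    g["bond_PS"] = _dist(d[(k, "P1")], d[(k, "S1")])
    g["bond_SB"] = _dist(d[(k, "S1")], d[(k, "B1")])
    g["bond_SP_next"] = _dist(d[(k, "S1")], d[(k + 1, "P1")])
    g["bond_BB_pair"] = _dist(d[(k, "B1")], d[(k, "B2")])
    g["bond_SS_pair"] = _dist(d[(k, "S1")], d[(k, "S2")])
    g["bond_MB"] = _dist(d[(k, "M")], d[(k, "B1")])
    # angles
    g["angle_PSB"] = _angle(d[(k, "P1")], d[(k, "S1")], d[(k, "B1")])
    g["angle_PSP"] = _angle(d[(k, "P1")], d[(k, "S1")], d[(k + 1, "P1")])
    g["angle_BSP"] = _angle(d[(k, "B1")], d[(k, "S1")], d[(k + 1, "P1")])
    g["angle_SPS"] = _angle(d[(k, "S1")], d[(k + 1, "P1")], d[(k + 1, "S1")])
    g["angle_SBB"] = _angle(d[(k, "S1")], d[(k, "B1")], d[(k, "B2")])
    # chirality at the sugar: signed volume of the three bonds leaving
    # S_i (to P_i, B_i, P_{i+1}); the mirror image has -V0
    g["improper_V"] = signed_volume(
        d[(k, "S1")], d[(k, "P1")], d[(k, "B1")], d[(k + 1, "P1")]
    )
    # helical backbone dihedrals
    g["dihedral_PSPS"] = dihedral_angle(
        d[(k, "P1")], d[(k, "S1")], d[(k + 1, "P1")], d[(k + 1, "S1")]
    )
    g["dihedral_SPSP"] = dihedral_angle(
        d[(k, "S1")], d[(k + 1, "P1")], d[(k + 1, "S1")], d[(k + 2, "P1")]
    )
    return g
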