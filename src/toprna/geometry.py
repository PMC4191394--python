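"""Helix reference frames, interhelical Euler angles, RMSD and centers
of mass.

Frame convention (documented so orientation statistics are reproducible
run to run): the frame z-axis is the mean rotation axis of the Kabsch
rotations between consecutive base-pair bead sets, signed to point
5'->3' along strand 1; the origin is the projection of the reference
(first) base pair's centroid onto the axis; the x-axis is the
axis-perpendicular component of the vector from the origin to the
reference pair's S-bead midpoint.  Euler angles (alpha_h, beta_h,
gamma_h) are the intrinsic Z-Y-Z decomposition of the rotation carrying
the H1 frame onto the H2 frame: alpha_h and gamma_h are twists about
the two helix axes, beta_h the interhelical bend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .secstruct_topology import BeadTopology, Helix


class DegenerateGeometryError(ValueError):
    """Coordinates too degenerate to define a helix frame."""


@dataclass(frozen=True)
class HelixFrame:
    """Right-handed orthonormal triad attached to one helix."""

    origin: np.ndarray
    axes: np.ndarray  # 3x3, columns = x, y, z unit vectors

    def __post_init__(self):
        a = self.axes
        if not np.allclose(a.T @ a, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")


@dataclass(frozen=True)
class EulerTriple:
    """Interhelical orientation: alpha_h, gamma_h in [0, 360), beta_h in
    [0, 180] (degrees).  At beta_h ~ 0 or 180 only the twist sum
    (difference) is identifiable; it is folded into alpha_h and gamma_h
    is set to 0."""

    alpha: float
    beta: float
    gamma: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])


def _pair_bead_sets(topology: BeadTopology, helix: Helix) -> list[list[int]]:
    sets = []
    for (i, j) in helix.pairs:
        beads = list(topology.residue_beads(i)) + list(topology.residue_beads(j))
        m = topology.m_bead_of_pair.get((i, j))
        if m is not None:
            beads.append(m)
        sets.append(beads)
    return sets


def kabsch_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rotation R minimizing ||(B - Bc) - R (A - Ac)||."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    H = Ac.T @ Bc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def fit_helix_frame(
    coords: np.ndarray,
    topology: BeadTopology,
    helix: Helix | str,
    ref_pair: int = 0,
) -> HelixFrame:
    """Fit the reference frame of one helix from snapshot coordinates.

    ``ref_pair`` selects which base pair anchors the origin and x-axis
    (0 = first pair of the helix, -1 = last); deterministic for fixed
    input with no sign flips between near-identical snapshots.
    """
    if isinstance(helix, str):
        ss = topology.secondary_structure
        helix = next(h for h in ss.helices if h.name == helix)
    if len(helix.pairs) < 2:
        raise DegenerateGeometryError("helix needs >= 2 base pairs")

    sets = _pair_bead_sets(topology, helix)
    clouds = [coords[idx] for idx in sets]
    cents = np.array([c.mean(axis=0) for c in clouds])

    axes = []
    for k in range(len(clouds) - 1):
        R = kabsch_rotation(clouds[k], clouds[k + 1])
        rv = Rotation.from_matrix(R).as_rotvec()
        nrm = np.linalg.norm(rv)
        if nrm < 1e-10:
            continue
        ax = rv / nrm
        if np.dot(ax, cents[k + 1] - cents[k]) < 0:
            ax = -ax
        axes.append(ax)
    if not axes:
        raise DegenerateGeometryError("no usable inter-pair rotations")
    z = np.mean(axes, axis=0)
    nz = np.linalg.norm(z)
    if nz < 1e-8:
        raise DegenerateGeometryError("ill-defined helix axis")
    z = z / nz

    m = cents.mean(axis=0)
    c_ref = cents[ref_pair]
    origin = m + np.dot(c_ref - m, z) * z

    i, j = helix.pairs[ref_pair]
    s_mid = 0.5 * (
        coords[topology.bead_index(i, "S")] + coords[topology.bead_index(j, "S")]
    )
    v = s_mid - origin
    x = v - np.dot(v, z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-8:
        raise DegenerateGeometryError("reference S midpoint lies on the axis")
    x = x / nx
    y = np.cross(z, x)
    return HelixFrame(origin=origin, axes=np.column_stack([x, y, z]))


GIMBAL_TOL_DEG = 1e-6


def euler_angles(frame_h1: HelixFrame, frame_h2: HelixFrame) -> EulerTriple:
    """Z-Y-Z Euler angles carrying the H1 frame onto the H2 frame."""
    R = frame_h1.axes.T @ frame_h2.axes
    return euler_from_matrix(R)


def euler_from_matrix(R: np.ndarray) -> EulerTriple:
    import warnings

    with warnings.catch_warnings():
        # at beta ~ 0/180 scipy warns about gimbal lock; the
        # canonicalization below handles that case explicitly
        warnings.simplefilter("ignore", UserWarning)
        a, b, c = Rotation.from_matrix(R).as_euler("ZYZ", degrees=True)
    if b < GIMBAL_TOL_DEG:
        return EulerTriple((a + c) % 360.0, 0.0, 0.0)
    if b > 180.0 - GIMBAL_TOL_DEG:
        return EulerTriple((a - c) % 360.0, 180.0, 0.0)
    return EulerTriple(a % 360.0, b, c % 360.0)


def euler_to_matrix(t: EulerTriple) -> np.ndarray:
    return Rotation.from_euler(
        "ZYZ", [t.alpha, t.beta, t.gamma], degrees=True
    ).as_matrix()


def kabsch_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    selection: np.ndarray | list[int] | None = None,
) -> float:
    """Minimal RMSD over rigid superposition (A); symmetric in inputs."""
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if selection is not None:
        A = A[np.asarray(selection)]
        B = B[np.asarray(selection)]
    if A.shape != B.shape:
        raise ValueError("selections must have equal size")
    if len(A) < 3:
        raise ValueError("need >= 3 points")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    R = kabsch_rotation(A, B)
    diff = Bc - Ac @ R.T
    return float(np.sqrt((diff ** 2).sum() / len(A)))


def pairwise_rmsd_matrix(
    coords: np.ndarray, selection: np.ndarray | list[int] | None = None
) -> np.ndarray:
    """Symmetric matrix of pairwise Kabsch RMSDs over snapshots."""
    n = len(coords)
    sel = None if selection is None else np.asarray(selection)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = kabsch_rmsd(coords[i], coords[j], sel)
    return out


def center_of_mass(
    coords: np.ndarray,
    topology: BeadTopology,
    residues,
) -> np.ndarray:
    """Mass-weighted center of the P/S/B beads of ``residues`` (1-based)."""
    idx = []
    for r in residues:
        idx.extend(topology.residue_beads(r))
    if not idx:
        raise ValueError("empty selection")
    idx = np.array(idx)
    m = topology.mass[idx]
    return (coords[idx] * m[:, None]).sum(axis=0) / m.sum()


def write_cg_pdb(coords: np.ndarray, topology: BeadTopology, path) -> None:
    """Write one coarse snapshot as a PDB (beads as pseudo-atoms, one
    residue per nucleotide, M beads on the first residue of their pair).
    """
    lines = []
    serial = 1
    for idx in range(topology.n_beads):
        kind = topology.bead_kind[idx]
        res = int(topology.bead_resid[idx])
        base = topology.sequence[res - 1]
        x, y, z = coords[idx]
        lines.append(
            f"ATOM  {serial:5d} {kind:>3s}  {base:>2s} A{res:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
        )
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
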