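"""Orientation-space coverage, mutual information and center-of-mass
correlations over an ensemble.

Coverage discretizes interhelical Euler triples on an equal-width grid:
36 x 18 x 36 bins at 10 degrees and 6 x 3 x 6 = 108 bins at 60 degrees
per helix pair (beta bins are equal width in beta, which is what makes
108 the per-pair count on the 60-degree grid); the joint 9D space of
three helices measured against a common reference has denominator
108^3.  Mutual information between two orientation triples uses
45-degree histograms with the first-order finite-sample bias
subtracted, in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cg_engine import Ensemble
from .geometry import center_of_mass, euler_angles, fit_helix_frame

TRNA_STEMS = ("A-stem", "D-stem", "AC-stem", "T-stem")
DEFAULT_REFERENCE_STEM = "AC-stem"


def grid_bin_counts(bin_deg: float) -> tuple[int, int, int]:
    """Bins along (alpha, beta, gamma) for an equal-width grid."""
    na = int(round(360.0 / bin_deg))
    nb = int(round(180.0 / bin_deg))
    return na, nb, na


def grid_size(bin_deg: float) -> int:
    na, nb, ng = grid_bin_counts(bin_deg)
    return na * nb * ng


def _bin_codes(angles: np.ndarray, bin_deg: float) -> np.ndarray:
    """Flat bin index per triple; beta = 180 folds into the top bin."""
    na, nb, ng = grid_bin_counts(bin_deg)
    a = np.floor(angles[:, 0] / bin_deg).astype(np.int64) % na
    b = np.minimum(
        np.floor(angles[:, 1] / bin_deg).astype(np.int64), nb - 1
    )
    g = np.floor(angles[:, 2] / bin_deg).astype(np.int64) % ng
    return (a * nb + b) * ng + g


def ensemble_euler_angles(
    ensemble: Ensemble, h1: str, h2: str
) -> np.ndarray:
    """(n_snap, 3) Euler triples of helix ``h2`` relative to ``h1``."""
    topo = ensemble.topology
    out = np.empty((ensemble.n_snapshots, 3))
    for s in range(ensemble.n_snapshots):
        f1 = fit_helix_frame(ensemble.coords[s], topo, h1)
        f2 = fit_helix_frame(ensemble.coords[s], topo, h2)
        out[s] = euler_angles(f1, f2).as_array()
    return out


def euler_table(ensemble: Ensemble, pairs=None) -> pd.DataFrame:
    """Long-format per-snapshot Euler angles for the given helix pairs
    (default: every pair of tRNA stems, H1 listed first)."""
    if pairs is None:
        stems = [
            h.name for h in ensemble.topology.secondary_structure.helices
            if len(h.pairs) >= 2
        ]
        pairs = [
            (stems[i], stems[j])
            for i in range(len(stems))
            for j in range(i + 1, len(stems))
        ]
    frames = []
    for h1, h2 in pairs:
        ang = ensemble_euler_angles(ensemble, h1, h2)
        frames.append(pd.DataFrame({
            "snapshot": np.arange(len(ang)),
            "h1": h1,
            "h2": h2,
            "alpha": ang[:, 0],
            "beta": ang[:, 1],
            "gamma": ang[:, 2],
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CoverageResult:
    """Fraction of the orientation grid visited by an ensemble."""

    label: str
    bin_deg: float
    unique_bins: int
    denominator: int
    ratio_9d_3x3d: float | None = None

    @property
    def fraction(self) -> float:
        return self.unique_bins / self.denominator


def coverage_3d(
    source, h1: str | None = None, h2: str | None = None,
    bin_deg: float = 10.0,
) -> CoverageResult:
    """3D orientation coverage of one helix pair.

    ``source`` is an :class:`Ensemble` (with ``h1``/``h2`` helix names)
    or a precomputed (n, 3) array of Euler triples in degrees.
    """
    if isinstance(source, Ensemble):
        angles = ensemble_euler_angles(source, h1, h2)
        label = f"{h1}/{h2}"
    else:
        angles = np.asarray(source, dtype=float)
        label = f"{h1}/{h2}" if h1 else "angles"
    if len(angles) == 0:
        raise ValueError("need at least one snapshot")
    codes = _bin_codes(angles, bin_deg)
    return CoverageResult(
        label=label,
        bin_deg=bin_deg,
        unique_bins=len(np.unique(codes)),
        denominator=grid_size(bin_deg),
    )


def coverage_9d(
    source,
    reference: str = DEFAULT_REFERENCE_STEM,
    bin_deg: float = 60.0,
) -> CoverageResult:
    """Joint 9D coverage of three helices against a common reference.

    ``source`` is an Ensemble with >= 4 helices, or a sequence of three
    (n, 3) angle arrays.  Also reports the ratio of the 9D fraction to
    the product of the three 3D fractions on the same grid: the ratio
    is 1 when helix orientations are independent and < 1 when they are
    correlated (or undersampled).
    """
    if isinstance(source, Ensemble):
        ss = source.topology.secondary_structure
        stems = [h.name for h in ss.helices if len(h.pairs) >= 2]
        others = [s for s in stems if s != reference]
        if reference not in stems or len(others) < 3:
            raise ValueError("need a reference helix plus three others")
        streams = [
            ensemble_euler_angles(source, reference, h) for h in others[:3]
        ]
        label = f"9D vs {reference}"
    else:
        streams = [np.asarray(a, dtype=float) for a in source]
        if len(streams) != 3:
            raise ValueError("need exactly three angle streams")
        label = "9D"
    per_pair = grid_size(bin_deg)
    codes = [_bin_codes(a, bin_deg) for a in streams]
    joint = (codes[0] * per_pair + codes[1]) * per_pair + codes[2]
    unique9 = len(np.unique(joint))
    frac9 = unique9 / per_pair ** 3
    prod3 = 1.0
    for c in codes:
        prod3 *= len(np.unique(c)) / per_pair
    return CoverageResult(
        label=label,
        bin_deg=bin_deg,
        unique_bins=unique9,
        denominator=per_pair ** 3,
        ratio_9d_3x3d=frac9 / prod3,
    )


@dataclass(frozen=True)
class MIResult:
    """Bias-corrected mutual information between two orientations."""

    mi: float               # bits (or nats if base_2 is False)
    mi_uncorrected: float
    bias: float
    n: int
    bin_deg: float
    corrected: bool | str
    populated_joint_bins: int

    @property
    def ratio_bins_to_points(self) -> float:
        return self.n / max(self.populated_joint_bins, 1)


def _plug_in_mi(cx, cy, per, n, log):
    joint = cx.astype(np.int64) * per + cy
    _, jc = np.unique(joint, return_counts=True)
    _, xc = np.unique(cx, return_counts=True)
    _, yc = np.unique(cy, return_counts=True)
    hx = -np.sum(xc / n * log(xc / n))
    hy = -np.sum(yc / n * log(yc / n))
    hxy = -np.sum(jc / n * log(jc / n))
    return hx + hy - hxy, len(jc), len(xc), len(yc)


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    bin_deg: float = 45.0,
    correct: bool | str = True,
    base_2: bool = True,
    n_surrogates: int = 30,
    surrogate_seed: int = 0,
) -> MIResult:
    """MI between two Euler-triple streams (each (n, 3), degrees).

    ``correct`` selects the finite-sample correction applied to the
    plug-in estimate on ``bin_deg`` joint/marginal histograms:

    * True / ``"analytic"`` -- subtract the first-order bias
      (B_XY - B_X - B_Y + 1) / (2 N ln b), with B the populated-bin
      counts.  Valid when samples are independent and there are
      several points per populated bin.
    * ``"shift"`` -- subtract the mean plug-in MI of circular-shift
      surrogates (y rolled by random offsets).  Rolling preserves each
      series' autocorrelation while destroying cross-correlation, so
      this is the appropriate null for the time-correlated snapshot
      streams short simulations produce.
    * False -- no correction.

    The corrected estimate is floored at 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(x) != len(y):
        raise ValueError("need two equal-length nonempty angle streams")
    n = len(x)
    cx = _bin_codes(x, bin_deg)
    cy = _bin_codes(y, bin_deg)
    per = grid_size(bin_deg)
    log = np.log2 if base_2 else np.log
    mi_plug, n_joint, n_x, n_y = _plug_in_mi(cx, cy, per, n, log)
    lnb = np.log(2.0) if base_2 else 1.0
    if correct == "shift":
        rng = np.random.default_rng(surrogate_seed)
        null = []
        for _ in range(n_surrogates):
            k = int(rng.integers(n // 10, n - n // 10))
            null.append(
                _plug_in_mi(cx, np.roll(cy, k), per, n, log)[0]
            )
        bias = float(np.mean(null))
    else:
        bias = (n_joint - n_x - n_y + 1) / (2.0 * n * lnb)
    mi = mi_plug - bias if correct else mi_plug
    return MIResult(
        mi=max(mi, 0.0),
        mi_uncorrected=mi_plug,
        bias=bias,
        n=n,
        bin_deg=bin_deg,
        corrected=correct,
        populated_joint_bins=n_joint,
    )


def orientation_mutual_information(
    ensemble: Ensemble,
    h1: str,
    pair: tuple[str, str],
    bin_deg: float = 45.0,
    correct: bool = True,
) -> MIResult:
    """MI between the orientations of two helices, both measured with
    respect to the common reference helix ``h1``."""
    h2, h3 = pair
    x = ensemble_euler_angles(ensemble, h1, h2)
    y = ensemble_euler_angles(ensemble, h1, h3)
    return mutual_information(x, y, bin_deg=bin_deg, correct=correct)


def mi_matrix(
    ensemble: Ensemble,
    reference: str = DEFAULT_REFERENCE_STEM,
    bin_deg: float = 45.0,
) -> pd.DataFrame:
    """MI (bits) between every pair of non-reference stems, measured
    against the common reference stem."""
    ss = ensemble.topology.secondary_structure
    stems = [h.name for h in ss.helices if len(h.pairs) >= 2]
    others = [s for s in stems if s != reference]
    streams = {
        h: ensemble_euler_angles(ensemble, reference, h) for h in others
    }
    rows = []
    for i in range(len(others)):
        for j in range(i + 1, len(others)):
            res = mutual_information(
                streams[others[i]], streams[others[j]], bin_deg=bin_deg
            )
            rows.append({
                "h2": others[i], "h3": others[j], "mi_bits": res.mi,
                "bias": res.bias, "n": res.n,
            })
    return pd.DataFrame(rows)


def com_correlation(
    ensemble: Ensemble, element_pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson R between element centers of mass across snapshots,
    reported per Cartesian component plus the maximum over components.
    Constant coordinate series yield NaN and are flagged."""
    topo = ensemble.topology
    elements = topo.secondary_structure.elements
    names = sorted({n for p in element_pairs for n in p})
    coms = {}
    for nm in names:
        coms[nm] = np.array([
            center_of_mass(c, topo, elements[nm]) for c in ensemble.coords
        ])
    if ensemble.n_snapshots < 3:
        raise ValueError("need >= 3 snapshots for correlations")
    rows = []
    for a, b in element_pairs:
        rs = []
        degenerate = False
        for c in range(3):
            xa, xb = coms[a][:, c], coms[b][:, c]
            if np.std(xa) < 1e-12 or np.std(xb) < 1e-12:
                rs.append(np.nan)
                degenerate = True
            else:
                rs.append(float(np.corrcoef(xa, xb)[0, 1]))
        rows.append({
            "element_a": a, "element_b": b,
            "r_x": rs[0], "r_y": rs[1], "r_z": rs[2],
            "r_max": np.nan if degenerate and np.all(np.isnan(rs))
            else float(np.nanmax(np.abs(rs))),
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)
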