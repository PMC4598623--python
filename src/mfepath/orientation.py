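"""Collective variables built on atom groups.

Implements the CV family used to coarse-grain a transporter's conformational
cycle: orientation quaternions of transmembrane helices, a substrate
z-coordinate along the membrane normal, a two-reference delta-RMSD, roll-axis
interhelical angles, and principal-component analysis of quaternion vector
parts (QPC).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegeneracyError, InputError
from .quaternion import (
    UnitQuaternion,
    best_fit_quaternion,
    best_fit_rmsd,
    _canonicalize,
)


@dataclass(frozen=True)
class AtomGroupFrame:
    """An ordered coordinate group (angstrom) for orientation/axis fits.

    For helices, the point order is assumed N-terminal to C-terminal; that
    ordering fixes the sign of the fitted roll axis.
    """

    label: str
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise InputError(f"group '{self.label}': coordinates must be (N, 3)")
        c = c.copy()
        c.setflags(write=False)
        object.__setattr__(self, "coords", c)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


def orientation_quaternion(frame: AtomGroupFrame,
                           reference: AtomGroupFrame) -> UnitQuaternion:
    """Best-fit orientation quaternion of *frame* relative to *reference*."""
    if frame.n_atoms != reference.n_atoms:
        raise InputError(
            f"group '{frame.label}': {frame.n_atoms} atoms vs "
            f"reference '{reference.label}': {reference.n_atoms}"
        )
    return best_fit_quaternion(frame.coords, reference.coords, frame.label)


def substrate_z(substrate_position, anchor: AtomGroupFrame,
                c_offset: float = 0.0) -> float:
    """Substrate position along the membrane normal, Z_P (angstrom).

    The z component of the vector from the anchor-group centroid (a chosen
    set of luminal C-alpha atoms) to the substrate atom, plus a constant
    offset ``c_offset`` that shifts the scale so Z_P approximately reads as
    the substrate height relative to the whole-protein center of mass.
    """
    p = np.asarray(substrate_position, dtype=float)
    if p.shape != (3,):
        raise InputError("substrate position must be a 3-vector")
    if anchor.n_atoms == 0:
        raise InputError("anchor group is empty")
    return float(p[2] - anchor.centroid[2] + c_offset)


def calibrate_z_offset(anchor_z: np.ndarray, com_z: np.ndarray) -> float:
    """Estimate the Z_P offset constant a posteriori.

    Given per-sample z coordinates of the anchor centroid and of the
    whole-protein center of mass, the offset is the mean of
    DeltaZ = z_anchor - z_com over the sample set, so that
    ``z_sub - z_anchor + C`` tracks ``z_sub - z_com`` on average.
    """
    anchor_z = np.asarray(anchor_z, dtype=float)
    com_z = np.asarray(com_z, dtype=float)
    if anchor_z.shape != com_z.shape or anchor_z.size == 0:
        raise InputError("anchor and center-of-mass series must match and be non-empty")
    return float(np.mean(anchor_z - com_z))


def delta_rmsd(frame: AtomGroupFrame, ref_a: AtomGroupFrame,
               ref_b: AtomGroupFrame) -> float:
    """Two-reference progress variable: RMSD(frame, A) - RMSD(frame, B).

    Both RMSDs are best-fit (centroid-removed, optimally rotated).  Negative
    values mean the frame is closer to reference A; the variable is
    antisymmetric under swapping the references.
    """
    if not (frame.n_atoms == ref_a.n_atoms == ref_b.n_atoms):
        raise InputError(
            f"atom counts differ: {frame.n_atoms}/{ref_a.n_atoms}/{ref_b.n_atoms}"
        )
    ra = best_fit_rmsd(frame.coords, ref_a.coords, frame.label)
    rb = best_fit_rmsd(frame.coords, ref_b.coords, frame.label)
    return float(ra - rb)


def roll_axis(helix: AtomGroupFrame) -> np.ndarray:
    """Dominant principal axis of a helix, oriented N->C.

    The axis is the eigenvector of the coordinate covariance with the
    largest eigenvalue, its sign fixed so the projection onto the
    end-to-end (last minus first point) vector is positive.
    """
    if helix.n_atoms < 4:
        raise InputError(f"helix '{helix.label}': need >= 4 points for an axis fit")
    x = helix.coords - helix.centroid
    cov = x.T @ x / helix.n_atoms
    w, v = np.linalg.eigh(cov)
    if w[-1] < 1e-12 or (w[-1] - w[-2]) < 1e-6 * w[-1]:
        raise DegeneracyError(
            f"helix '{helix.label}': principal axis degenerate (isotropic points)"
        )
    axis = v[:, -1]
    end_to_end = helix.coords[-1] - helix.coords[0]
    if axis @ end_to_end < 0:
        axis = -axis
    return axis


def interhelical_angle(helix_a: AtomGroupFrame, helix_b: AtomGroupFrame) -> float:
    """Angle between the N->C-oriented roll axes of two helices, in degrees.

    Lies in [0, 180]; antiparallel helices give 180.
    """
    a = roll_axis(helix_a)
    b = roll_axis(helix_b)
    return float(np.degrees(np.arccos(np.clip(a @ b, -1.0, 1.0))))


@dataclass
class QuaternionPCAResult:
    """Principal components of quaternion vector parts.

    ``components`` rows are orthonormal directions in the stacked
    vector-part space; ``variance_fractions`` are nonnegative and sum to 1;
    ``projections`` are the centered data expressed in the component basis.
    ``zero_variance`` flags a degenerate (all-identical) ensemble, in which
    case the numeric fields are None.
    """

    zero_variance: bool
    components: np.ndarray | None = None
    variance_fractions: np.ndarray | None = None
    projections: np.ndarray | None = None
    mean: np.ndarray | None = None


def quaternion_pca(ensemble: np.ndarray,
                   weights: np.ndarray | None = None) -> QuaternionPCAResult:
    """PCA of stacked quaternion vector parts across an ensemble.

    ``ensemble`` is (n_samples, d) with d = 3 x (number of quaternions),
    each row the concatenated vector parts of the orientation-quaternion
    set of one sample (quaternions taken on the canonical hemisphere, so
    the components are single-valued).  Optional nonnegative ``weights``
    give a weighted covariance (normalized to sum 1); the default is the
    unweighted estimator.
    """
    x = np.atleast_2d(np.asarray(ensemble, dtype=float))
    n, d = x.shape
    if n < 2:
        raise InputError("need at least 2 samples for PCA")
    if d % 3 != 0:
        raise InputError("dimension must be 3 x number of quaternions")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise InputError("weights must be nonnegative, one per sample")
        w = w / w.sum()
    mean = w @ x
    xc = x - mean
    cov = (xc * w[:, None]).T @ xc
    total = np.trace(cov)
    if total < 1e-24:
        return QuaternionPCAResult(zero_variance=True)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    comps = evecs[:, order].T
    # fix component sign deterministically: largest-|.| entry positive
    for row in comps:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1
    return QuaternionPCAResult(
        zero_variance=False,
        components=comps,
        variance_fractions=evals / evals.sum(),
        projections=xc @ comps.T,
        mean=mean,
    )


def stack_vector_parts(quaternion_sets: list[list[UnitQuaternion]]) -> np.ndarray:
    """Flatten per-sample quaternion sets into a PCA-ready (n, 3m) array."""
    rows = []
    for qs in quaternion_sets:
        rows.append(np.concatenate([q.vector for q in qs]))
    return np.asarray(rows)


def hemisphere_align(q_components: np.ndarray) -> np.ndarray:
    """Canonicalize rows of raw 4-component quaternion data (q0 >= 0)."""
    q = np.atleast_2d(np.asarray(q_components, dtype=float))
    if q.shape[1] != 4:
        raise InputError("expected rows of 4 quaternion components")
    return np.array([_canonicalize(row) for row in q])
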