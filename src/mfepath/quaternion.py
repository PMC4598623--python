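"""Orientation quaternions: best-fit rotations, geodesic distance, restraints.

The optimal rigid-body rotation superimposing a coordinate group onto a
reference is encoded as a unit quaternion Q = (q0, q1, q2, q3) =
(cos(theta/2), sin(theta/2) * n), with theta the rotation angle and n the
unit rotation axis.  Because Q and -Q represent the same rotation, all
operations here are invariant under sign flips, and quaternions are stored
on a canonical hemisphere (q0 >= 0; ties broken by the first nonzero
component being positive).

The angular separation between two orientations P and Q is measured as

    Omega(P, Q) = arccos(|P . Q|)  in [0, pi/2],

the geodesic arc on the quotient of the unit 3-sphere by the sign flip.
For small separations Omega^2 ~ |P - Q|^2, which is what makes Euclidean
operations on quaternion components (PCA, path metrics) meaningful near a
reference orientation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegeneracyError, InputError

#: clamp for |P.Q| when differentiating arccos, to avoid derivative blow-up
#: at Omega = 0 and Omega = pi/2
_DOT_EPS = 1e-12

_UNIT_TOL = 1e-9


def _canonicalize(q: np.ndarray) -> np.ndarray:
    """Map a quaternion to the canonical hemisphere (q0 >= 0)."""
    for c in q:
        if c > 0:
            return q
        if c < 0:
            return -q
    return q


@dataclass(frozen=True)
class UnitQuaternion:
    """A unit quaternion on the canonical hemisphere."""

    q0: float
    q1: float
    q2: float
    q3: float

    def __post_init__(self) -> None:
        q = np.array([self.q0, self.q1, self.q2, self.q3], dtype=float)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-6:
            raise InputError(f"quaternion norm {n} too far from 1")
        q = _canonicalize(q / n)
        object.__setattr__(self, "q0", float(q[0]))
        object.__setattr__(self, "q1", float(q[1]))
        object.__setattr__(self, "q2", float(q[2]))
        object.__setattr__(self, "q3", float(q[3]))

    @classmethod
    def from_array(cls, q) -> "UnitQuaternion":
        q = np.asarray(q, dtype=float)
        if q.shape != (4,):
            raise InputError("quaternion needs exactly 4 components")
        return cls(*q)

    @classmethod
    def identity(cls) -> "UnitQuaternion":
        return cls(1.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_axis_angle(cls, axis, angle: float) -> "UnitQuaternion":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise InputError("rotation axis must be nonzero")
        axis = axis / n
        h = 0.5 * angle
        return cls(np.cos(h), *(np.sin(h) * axis))

    def as_array(self) -> np.ndarray:
        return np.array([self.q0, self.q1, self.q2, self.q3])

    @property
    def vector(self) -> np.ndarray:
        """The vector (imaginary) part (q1, q2, q3)."""
        return np.array([self.q1, self.q2, self.q3])

    @property
    def angle(self) -> float:
        """Rotation angle theta in [0, pi]."""
        return 2.0 * np.arccos(np.clip(abs(self.q0), 0.0, 1.0))

    @property
    def axis(self) -> np.ndarray:
        """Unit rotation axis; arbitrary (x) for the identity rotation."""
        v = self.vector
        n = np.linalg.norm(v)
        if n < 1e-12:
            return np.array([1.0, 0.0, 0.0])
        return v / n

    def rotation_matrix(self) -> np.ndarray:
        """3x3 rotation matrix R such that rotated = R @ x."""
        q0, q1, q2, q3 = self.q0, self.q1, self.q2, self.q3
        return np.array(
            [
                [
                    q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3,
                    2 * (q1 * q2 - q0 * q3),
                    2 * (q1 * q3 + q0 * q2),
                ],
                [
                    2 * (q1 * q2 + q0 * q3),
                    q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3,
                    2 * (q2 * q3 - q0 * q1),
                ],
                [
                    2 * (q1 * q3 - q0 * q2),
                    2 * (q2 * q3 + q0 * q1),
                    q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3,
                ],
            ]
        )

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Rotate an (N, 3) coordinate array."""
        return np.asarray(coords, dtype=float) @ self.rotation_matrix().T

    def dot(self, other: "UnitQuaternion") -> float:
        return float(self.as_array() @ other.as_array())


def _check_unit(q: UnitQuaternion) -> np.ndarray:
    a = q.as_array()
    if abs(a @ a - 1.0) > 1e-6:
        raise InputError("non-unit quaternion")
    return a


def _centered(coords: np.ndarray, label: str) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise InputError(f"group '{label}': coordinates must be (N, 3)")
    if coords.shape[0] < 3:
        raise DegeneracyError(f"group '{label}': need at least 3 points")
    return coords - coords.mean(axis=0)


def _check_nondegenerate(coords: np.ndarray, label: str) -> None:
    # a rotation fit needs points spanning at least a plane: the centered
    # coordinate matrix must have two significant singular values
    s = np.linalg.svd(coords, compute_uv=False)
    if s[0] < 1e-10 or s[1] < 1e-8 * s[0]:
        raise DegeneracyError(
            f"group '{label}' is degenerate (coincident or collinear points)"
        )


def best_fit_quaternion(frame: np.ndarray, reference: np.ndarray,
                        label: str = "group") -> UnitQuaternion:
    """Optimal-rotation quaternion superimposing *reference* onto *frame*.

    Both coordinate sets are centered on their centroids; the returned
    quaternion Q is the minimum-RMSD rotation in the sense

        frame_centered  ~  R(Q) @ reference_centered .

    Uses the symmetric 4x4 key-matrix eigenvalue method: the quaternion is
    the eigenvector of the largest eigenvalue.
    """
    x = _centered(frame, label)
    y = _centered(reference, f"{label}(ref)")
    if x.shape[0] != y.shape[0]:
        raise InputError(
            f"group '{label}': {x.shape[0]} points vs reference {y.shape[0]}"
        )
    _check_nondegenerate(x, label)
    _check_nondegenerate(y, f"{label}(ref)")
    q, _ = _key_matrix_fit(x, y)
    return UnitQuaternion.from_array(q)


def _key_matrix_fit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Return (quaternion, largest eigenvalue) rotating y onto x.

    Inputs must be centered.  The largest eigenvalue lambda_max of the key
    matrix satisfies  sum|x|^2 + sum|y|^2 - 2*lambda_max = N * RMSD_min^2.
    """
    m = y.T @ x  # m[a, b] = sum_i y_i[a] * x_i[b]
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    w, v = np.linalg.eigh(key)
    return v[:, -1], float(w[-1])


def best_fit_rmsd(frame: np.ndarray, reference: np.ndarray,
                  label: str = "group") -> float:
    """Minimum RMSD between two coordinate sets over rigid rotations.

    Computed from the key-matrix top eigenvalue, after centroid removal.
    """
    x = _centered(frame, label)
    y = _centered(reference, f"{label}(ref)")
    if x.shape[0] != y.shape[0]:
        raise InputError(
            f"group '{label}': {x.shape[0]} points vs reference {y.shape[0]}"
        )
    _, lam = _key_matrix_fit(x, y)
    n = x.shape[0]
    msd = max((np.sum(x * x) + np.sum(y * y) - 2.0 * lam) / n, 0.0)
    return float(np.sqrt(msd))


def geodesic_distance(p: UnitQuaternion, q: UnitQuaternion) -> float:
    """Omega(P, Q) = arccos(|P . Q|), the geodesic separation in [0, pi/2].

    Symmetric and invariant under sign flip of either argument (the two
    quaternions of one physical rotation give the same distance).
    """
    a = _check_unit(p)
    b = _check_unit(q)
    return float(np.arccos(np.clip(abs(a @ b), 0.0, 1.0)))


def orientation_restraint(q: UnitQuaternion, qc: UnitQuaternion,
                          k: float) -> tuple[float, np.ndarray]:
    """Harmonic orientation restraint E = 1/2 k Omega(Q, Qc)^2.

    Returns (energy, gradient) where the gradient is with respect to the
    four components of Q, projected onto the tangent space of the unit
    sphere at Q (the radial direction does not change the orientation).
    The derivative factor 1/sqrt(1-d^2) is clamped via |d| in
    [eps, 1-eps], eps = 1e-12, so the gradient stays finite at Omega -> 0
    and Omega -> pi/2.
    """
    if k < 0:
        raise InputError("force constant must be nonnegative")
    a = _check_unit(q)
    c = _check_unit(qc)
    d = float(a @ c)
    omega = np.arccos(np.clip(abs(d), 0.0, 1.0))
    energy = 0.5 * k * omega * omega
    sgn = 1.0 if d >= 0 else -1.0
    ad = np.clip(abs(d), _DOT_EPS, 1.0 - _DOT_EPS)
    # dE/dQ = k * Omega * dOmega/dQ,  dOmega/dQ = -sgn(d)/sqrt(1-d^2) * Qc
    grad = -k * omega * sgn / np.sqrt(1.0 - ad * ad) * c
    grad = grad - (grad @ a) * a  # tangent projection
    return float(energy), grad
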