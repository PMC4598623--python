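"""String paths and Bezier equidistant reparametrization.

A :class:`StringPath` is an ordered set of image centers tracing a
transition pathway in CV space, open or cyclic.  Reparametrization treats
the centers as the control points of a single global Bezier curve
(evaluated by de Casteljau's algorithm), measures arc length by dense
evaluation with chord-length accumulation, and places N equidistant points
along it.  Closed paths use a closed Bezier obtained by duplicating the
wrap-around control point.

A raw-control-point Bezier does not interpolate its interior controls; the
string algorithms that use this routine recompute the centers from data
each iteration, which counteracts the curve's pull toward the control
polygon's interior.  For very long strings (N > 64) a piecewise cubic
spline mode is available (``mode="spline"``), flagged in the path
metadata; the global Bezier remains the default.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .cvspace import CVSpace
from .errors import DegeneracyError, InputError


@dataclass
class StringPath:
    """Ordered image centers along a (possibly cyclic) pathway."""

    centers: np.ndarray
    cyclic: bool = False
    space: CVSpace | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.shape[0] < 3:
            raise InputError("a string path needs at least 3 images")
        seg = np.linalg.norm(np.diff(self.centers, axis=0), axis=1)
        if np.any(seg == 0):
            raise InputError("consecutive image centers must be distinct")
        if self.space is None:
            self.space = CVSpace.euclidean(self.centers.shape[1])
        elif self.space.dim != self.centers.shape[1]:
            raise InputError("space dimension does not match centers")

    @property
    def n_images(self) -> int:
        return self.centers.shape[0]

    def scaled_centers(self) -> np.ndarray:
        return self.centers * self.space.scales

    def arc_lengths(self) -> np.ndarray:
        """Cumulative polyline arc length at each image (metric units)."""
        seg = np.linalg.norm(np.diff(self.scaled_centers(), axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def total_length(self) -> float:
        s = self.arc_lengths()
        if self.cyclic:
            return float(
                s[-1] + np.linalg.norm(
                    self.scaled_centers()[0] - self.scaled_centers()[-1]
                )
            )
        return float(s[-1])

    def mean_spacing(self) -> float:
        n_seg = self.n_images if self.cyclic else self.n_images - 1
        return self.total_length() / n_seg

    def displacement(self, other: "StringPath") -> tuple[float, float]:
        """(max, rms) per-image displacement in the CV metric."""
        if other.n_images != self.n_images:
            raise InputError("paths must have the same image count")
        d = self.space.distance(self.centers, other.centers)
        return float(np.max(d)), float(np.sqrt(np.mean(d * d)))


def _decasteljau(controls: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate a Bezier curve at parameters t; controls (m, d), t (k,)."""
    p = np.broadcast_to(controls[None], (t.size,) + controls.shape).copy()
    tt = t[:, None, None]
    while p.shape[1] > 1:
        p = (1.0 - tt) * p[:, :-1] + tt * p[:, 1:]
    return p[:, 0]


def _dense_curve(controls: np.ndarray, cyclic: bool, n_dense: int,
                 mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Densely evaluated curve and its cumulative chord length."""
    if mode == "bezier":
        ctrl = np.vstack([controls, controls[:1]]) if cyclic else controls
        t = np.linspace(0.0, 1.0, n_dense)
        pts = _decasteljau(ctrl, t)
    elif mode == "spline":
        m = controls.shape[0]
        if cyclic:
            x = np.arange(m + 1)
            cs = CubicSpline(x, np.vstack([controls, controls[:1]]),
                             bc_type="periodic")
            pts = cs(np.linspace(0.0, m, n_dense))
        else:
            cs = CubicSpline(np.arange(m), controls, bc_type="natural")
            pts = cs(np.linspace(0.0, m - 1, n_dense))
    else:
        raise InputError(f"unknown reparametrization mode '{mode}'")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return pts, np.concatenate([[0.0], np.cumsum(seg)])


def bezier_reparametrize(centers: np.ndarray, n_points: int,
                         cyclic: bool = False, n_dense: int = 4096,
                         mode: str = "bezier") -> np.ndarray:
    """N points equidistant in arc length along the curve through ``centers``.

    The centers are the raw control points of a single global Bezier
    (closed for cyclic paths).  Arc length is accumulated over ``n_dense``
    de Casteljau evaluations; open curves keep their endpoints exactly;
    cyclic curves return N points spaced L/N apart starting at the curve
    origin (the first point's nearest curve position).
    """
    c = np.atleast_2d(np.asarray(centers, dtype=float))
    if c.shape[0] < 2:
        raise InputError("need at least 2 control points")
    if n_points < 2:
        raise InputError("need at least 2 output points")
    seg = np.linalg.norm(np.diff(c, axis=0), axis=1)
    if np.any(seg == 0):
        raise DegeneracyError(
            "coincident consecutive control points collapse the curve"
        )
    pts, arc = _dense_curve(c, cyclic, n_dense, mode)
    total = arc[-1]
    if total <= 0:
        raise DegeneracyError("curve has zero length")
    if cyclic:
        targets = np.arange(n_points) * total / n_points
    else:
        targets = np.linspace(0.0, total, n_points)
    # invert the arc-length table
    idx = np.searchsorted(arc, targets, side="right") - 1
    idx = np.clip(idx, 0, arc.size - 2)
    frac = (targets - arc[idx]) / np.maximum(arc[idx + 1] - arc[idx], 1e-300)
    out = pts[idx] + frac[:, None] * (pts[idx + 1] - pts[idx])
    if not cyclic:
        out[0] = pts[0]
        out[-1] = pts[-1]
    return out


def reparametrized_path(path: StringPath, n_points: int | None = None,
                        mode: str = "bezier") -> StringPath:
    """Equidistant resampling of a path, preserving flags and space."""
    n = n_points or path.n_images
    new = bezier_reparametrize(
        path.centers * path.space.scales, n, cyclic=path.cyclic, mode=mode
    ) / path.space.scales
    meta = dict(path.metadata)
    if mode != "bezier":
        meta["reparametrization"] = mode
    return StringPath(new, cyclic=path.cyclic, space=path.space, metadata=meta)
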