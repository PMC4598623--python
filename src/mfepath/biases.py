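"""Bias potentials acting in CV space.

All biases evaluate vectorized over an ``(n, d)`` batch of points and expose
analytic gradients, so they can be added to any model surface during
propagation and re-evaluated cheaply during reweighting.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


class Bias:
    """Interface: energy(x) -> (n,), gradient(x) -> (n, d)."""

    def energy(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.energy(x)


def _batch(x) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


@dataclass
class HarmonicBias(Bias):
    """Isotropic (or per-dimension) harmonic restraint 1/2 k |x - c|^2.

    ``k`` may be a scalar or a per-dimension array; an optional diagonal
    ``scales`` array applies the CV metric before the quadratic form, i.e.
    U = 1/2 sum_i k_i (s_i (x_i - c_i))^2.
    """

    center: np.ndarray
    k: np.ndarray | float
    scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        d = self.center.shape[0]
        k = np.asarray(self.k, dtype=float)
        if k.ndim == 0:
            k = np.full(d, float(k))
        if k.shape != (d,) or np.any(k < 0):
            raise InputError("force constant must be a nonnegative scalar or (d,)")
        self.k = k
        if self.scales is not None:
            s = np.asarray(self.scales, dtype=float)
            if s.shape != (d,) or np.any(s <= 0):
                raise InputError("scales must be positive, shape (d,)")
            self.scales = s

    def _keff(self) -> np.ndarray:
        if self.scales is None:
            return self.k
        return self.k * self.scales**2

    def energy(self, x: np.ndarray) -> np.ndarray:
        x, single = _batch(x)
        dx = x - self.center
        e = 0.5 * np.sum(self._keff() * dx * dx, axis=1)
        return e[0] if single else e

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x, single = _batch(x)
        g = self._keff() * (x - self.center)
        return g[0] if single else g


@dataclass
class TubeBias(Bias):
    """Half-harmonic penalty beyond distance ``radius`` from a polyline path.

    Restrains samples to a transition tube: zero inside the tube, and
    1/2 k (d - radius)^2 outside, where d is the shortest distance to the
    piecewise-linear path through ``points`` (closed if ``cyclic``).
    """

    points: np.ndarray
    radius: float
    k: float
    cyclic: bool = False

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.points, dtype=float))
        if p.shape[0] < 2:
            raise InputError("tube path needs at least 2 points")
        if self.radius <= 0 or self.k < 0:
            raise InputError("tube radius must be positive, k nonnegative")
        if self.cyclic:
            p = np.vstack([p, p[:1]])
        self.points = p

    def _dist_and_dir(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = self.points[:-1]  # (m, d)
        ab = self.points[1:] - a  # (m, d)
        denom = np.sum(ab * ab, axis=1)  # (m,)
        ax = x[:, None, :] - a[None, :, :]  # (n, m, d)
        t = np.clip(np.einsum("nmd,md->nm", ax, ab) / denom, 0.0, 1.0)
        proj = a[None] + t[:, :, None] * ab[None]  # (n, m, d)
        diff = x[:, None, :] - proj
        d2 = np.sum(diff * diff, axis=2)
        j = np.argmin(d2, axis=1)
        idx = np.arange(x.shape[0])
        dmin = np.sqrt(d2[idx, j])
        dirn = diff[idx, j]
        with np.errstate(invalid="ignore", divide="ignore"):
            dirn = np.where(dmin[:, None] > 1e-12, dirn / dmin[:, None], 0.0)
        return dmin, dirn

    def energy(self, x: np.ndarray) -> np.ndarray:
        x, single = _batch(x)
        d, _ = self._dist_and_dir(x)
        exc = np.maximum(d - self.radius, 0.0)
        e = 0.5 * self.k * exc * exc
        return e[0] if single else e

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x, single = _batch(x)
        d, dirn = self._dist_and_dir(x)
        exc = np.maximum(d - self.radius, 0.0)
        g = self.k * exc[:, None] * dirn
        return g[0] if single else g


@dataclass
class CompositeBias(Bias):
    """Sum of component biases."""

    parts: list = field(default_factory=list)

    def energy(self, x: np.ndarray) -> np.ndarray:
        x, single = _batch(x)
        e = np.zeros(x.shape[0])
        for p in self.parts:
            e = e + p.energy(x)
        return e[0] if single else e

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x, single = _batch(x)
        g = np.zeros_like(x)
        for p in self.parts:
            g = g + p.gradient(x)
        return g[0] if single else g
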