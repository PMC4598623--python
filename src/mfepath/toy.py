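"""Analytic model landscapes and an overdamped-Langevin propagator.

The effective dynamics of a high-dimensional molecular system projected
onto a few collective variables is modelled as Brownian motion on an
effective potential G(zeta).  This module provides that world in
miniature: analytic surfaces with documented minima, saddles and valley
curves; an Euler-Maruyama propagator with pluggable bias potentials; direct
quadrature of reference free-energy profiles; and a generator of
Crooks-consistent Gaussian work distributions for the work-based
estimators.  Everything is seeded and runs in reduced units (k_B T = 1 at
beta = 1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biases import Bias
from .cvspace import CVSpace
from .errors import ConfigError, InputError, IntegrationError, NumericalError
from .samples import SampleSet


class PotentialSurface:
    """Analytic potential on R^d with vectorized energy and gradient."""

    name: str = "surface"
    dim: int = 1

    def energy(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _batch(self, x) -> tuple[np.ndarray, bool]:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return x[None, :], True
        return x, False

    def check_gradient(self, points: np.ndarray, h: float = 1e-6,
                       rtol: float = 1e-5) -> float:
        """Max relative mismatch between analytic and central-difference grad."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        g = self.gradient(pts)
        num = np.zeros_like(pts)
        for j in range(pts.shape[1]):
            dp = pts.copy()
            dm = pts.copy()
            dp[:, j] += h
            dm[:, j] -= h
            num[:, j] = (self.energy(dp) - self.energy(dm)) / (2 * h)
        scale = np.maximum(np.abs(num), 1.0)
        err = float(np.max(np.abs(g - num) / scale))
        if err > rtol:
            raise NumericalError(f"{self.name}: gradient mismatch {err:.2e}")
        return err


class DoubleWell1D(PotentialSurface):
    """U(x) = b ((x/a)^2 - 1)^2: minima at +-a, barrier height b at x = 0."""

    dim = 1

    def __init__(self, a: float = 1.0, barrier: float = 4.0) -> None:
        if a <= 0 or barrier <= 0:
            raise ConfigError("double_well_1d needs a > 0 and barrier > 0")
        self.a = a
        self.barrier = barrier
        self.name = "double_well_1d"
        self.minima = np.array([[-a], [a]])
        self.saddles = np.array([[0.0]])

    def energy(self, x):
        x, single = self._batch(x)
        u = self.barrier * ((x[:, 0] / self.a) ** 2 - 1.0) ** 2
        return u[0] if single else u

    def gradient(self, x):
        x, single = self._batch(x)
        g = np.empty_like(x)
        g[:, 0] = 4.0 * self.barrier * x[:, 0] / self.a**2 * ((x[:, 0] / self.a) ** 2 - 1.0)
        return g[0] if single else g


class CurvedValley2D(PotentialSurface):
    """A semicircular valley of radius R in the upper half-plane.

    U = 1/2 kappa_t (r - R)^2 + 1/2 kappa_d min(y, 0)^2.  The valley curve
    is the arc r = R, y >= 0, from (-R, 0) to (R, 0); the potential is flat
    along it, so the arc is exactly the minimum free-energy path.  The
    half-plane penalty kappa_d keeps the lower arc out of play.
    """

    dim = 2

    def __init__(self, radius: float = 1.0, kappa_t: float = 100.0,
                 kappa_d: float = 100.0) -> None:
        if radius <= 0 or kappa_t <= 0 or kappa_d < 0:
            raise ConfigError("curved_valley_2d needs radius, kappa_t > 0")
        self.radius = radius
        self.kappa_t = kappa_t
        self.kappa_d = kappa_d
        self.name = "curved_valley_2d"
        self.valley_length = np.pi * radius

    def valley(self, s: np.ndarray) -> np.ndarray:
        """Point on the valley arc at arc length s in [0, pi*R]."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        phi = np.pi - s / self.radius
        return np.stack(
            [self.radius * np.cos(phi), self.radius * np.sin(phi)], axis=-1
        )

    def _polar(self, x):
        r = np.sqrt(x[:, 0] ** 2 + x[:, 1] ** 2)
        return r

    def energy(self, x):
        x, single = self._batch(x)
        r = self._polar(x)
        u = 0.5 * self.kappa_t * (r - self.radius) ** 2
        u = u + 0.5 * self.kappa_d * np.minimum(x[:, 1], 0.0) ** 2
        return u[0] if single else u

    def gradient(self, x):
        x, single = self._batch(x)
        r = self._polar(x)
        g = np.zeros_like(x)
        safe = r > 1e-12
        coef = np.where(safe, self.kappa_t * (r - self.radius) / np.where(safe, r, 1.0), 0.0)
        g[:, 0] = coef * x[:, 0]
        g[:, 1] = coef * x[:, 1] + self.kappa_d * np.minimum(x[:, 1], 0.0)
        return g[0] if single else g


class CyclicChannels2D(PotentialSurface):
    """Two basins on a ring connected by two channels of unequal barriers.

    U = 1/2 kappa_r (r - R)^2 + V(theta),
    V(theta) = sin^2(theta) * (c0 + c1 sin(theta)),
    c0 = (b_high + b_low)/2, c1 = (b_high - b_low)/2.

    Basins sit at theta = 0 and pi (both at V = 0); the upper channel
    (through theta = pi/2) has barrier b_high, the lower (theta = 3pi/2)
    b_low.  With the defaults the two channels differ by 3.5 reduced
    units, a bound-state-lowered-barrier motif on a closed cycle.  For
    b_high < 3 b_low the four ring stationary points are the only ones.
    """

    dim = 2

    def __init__(self, radius: float = 1.0, kappa_r: float = 100.0,
                 barrier_low: float = 1.5, barrier_high: float = 5.0) -> None:
        if radius <= 0 or kappa_r <= 0:
            raise ConfigError("cyclic_channels_2d needs radius, kappa_r > 0")
        if not 0 < barrier_low <= barrier_high:
            raise ConfigError("need 0 < barrier_low <= barrier_high")
        self.radius = radius
        self.kappa_r = kappa_r
        self.barrier_low = barrier_low
        self.barrier_high = barrier_high
        self.c0 = 0.5 * (barrier_high + barrier_low)
        self.c1 = 0.5 * (barrier_high - barrier_low)
        self.name = "cyclic_channels_2d"
        r = radius
        self.minima = np.array([[r, 0.0], [-r, 0.0]])
        self.saddles = np.array([[0.0, r], [0.0, -r]])
        self.valley_length = 2 * np.pi * radius

    @property
    def barrier_gap(self) -> float:
        """Planted barrier-height difference between the two channels."""
        return self.barrier_high - self.barrier_low

    def valley(self, s: np.ndarray) -> np.ndarray:
        """Point on the ring at arc length s in [0, 2 pi R), from (R, 0)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        th = s / self.radius
        return np.stack([self.radius * np.cos(th), self.radius * np.sin(th)], axis=-1)

    def angular_potential(self, theta: np.ndarray) -> np.ndarray:
        st = np.sin(theta)
        return st * st * (self.c0 + self.c1 * st)

    def energy(self, x):
        x, single = self._batch(x)
        r = np.sqrt(x[:, 0] ** 2 + x[:, 1] ** 2)
        th = np.arctan2(x[:, 1], x[:, 0])
        u = 0.5 * self.kappa_r * (r - self.radius) ** 2 + self.angular_potential(th)
        return u[0] if single else u

    def gradient(self, x):
        x, single = self._batch(x)
        r = np.sqrt(x[:, 0] ** 2 + x[:, 1] ** 2)
        th = np.arctan2(x[:, 1], x[:, 0])
        st, ct = np.sin(th), np.cos(th)
        dv = ct * st * (2 * self.c0 + 3 * self.c1 * st)
        g = np.zeros_like(x)
        safe = r > 1e-12
        rs = np.where(safe, r, 1.0)
        rad = np.where(safe, self.kappa_r * (r - self.radius) / rs, 0.0)
        g[:, 0] = rad * x[:, 0] + np.where(safe, dv * (-x[:, 1] / rs**2), 0.0)
        g[:, 1] = rad * x[:, 1] + np.where(safe, dv * (x[:, 0] / rs**2), 0.0)
        return g[0] if single else g


_PRESETS = {
    "double_well_1d": DoubleWell1D,
    "curved_valley_2d": CurvedValley2D,
    "cyclic_channels_2d": CyclicChannels2D,
}


def preset_surface(name: str, **params) -> PotentialSurface:
    """Construct a named model surface (see class docstrings for geometry)."""
    try:
        cls = _PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown surface '{name}'; available: {sorted(_PRESETS)}"
        ) from None
    return cls(**params)


@dataclass
class BrownianConfig:
    """Overdamped-Langevin integration parameters (reduced units).

    ``diffusion`` may be a scalar or per-dimension array; ``noise_scale``
    multiplies the stochastic term (0 gives deterministic steepest-descent
    drift, the zero-temperature limit).  The seed is mandatory: all
    randomness flows from it.
    """

    timestep: float
    n_steps: int
    seed: int
    beta: float = 1.0
    diffusion: float | np.ndarray = 1.0
    stride: int = 1
    noise_scale: float = 1.0
    domain_guard: float = 1e6

    def __post_init__(self) -> None:
        if self.timestep <= 0 or self.beta <= 0:
            raise ConfigError("timestep and beta must be positive")
        if np.any(np.asarray(self.diffusion) <= 0):
            raise ConfigError("diffusion must be positive")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_steps < 1 or self.stride < 1:
            raise ConfigError("n_steps and stride must be >= 1")


def propagate(
    start: np.ndarray,
    surface: PotentialSurface,
    biases: list[Bias] | None,
    config: BrownianConfig,
    space: CVSpace | None = None,
    window_labels: np.ndarray | None = None,
) -> SampleSet:
    """Euler-Maruyama Brownian dynamics on surface + sum(biases).

    ``start`` is one point ``(d,)`` or a batch of walkers ``(m, d)``; all
    walkers advance in lockstep and are recorded every ``stride`` steps.
    Deterministic given the seed.  Walkers leaving ``|x| > domain_guard``
    abort with an integration error naming the step.
    """
    x = np.atleast_2d(np.asarray(start, dtype=float)).copy()
    m, d = x.shape
    if d != surface.dim:
        raise InputError(f"start dimension {d} != surface dim {surface.dim}")
    space = space or CVSpace.euclidean(d)
    biases = list(biases or [])
    labels = (
        np.zeros(m, dtype=int)
        if window_labels is None
        else np.asarray(window_labels, dtype=int)
    )
    rng = np.random.default_rng(config.seed)
    dt = config.timestep
    dvec = np.broadcast_to(np.asarray(config.diffusion, dtype=float), (d,))
    drift_coef = dvec * config.beta * dt
    noise_coef = config.noise_scale * np.sqrt(2.0 * dvec * dt)

    n_out = config.n_steps // config.stride
    out = np.empty((n_out, m, d))
    times = np.empty(n_out)
    k = 0
    for step in range(1, config.n_steps + 1):
        g = surface.gradient(x)
        for b in biases:
            g = g + b.gradient(x)
        x = x - drift_coef * g
        if config.noise_scale != 0.0:
            x = x + noise_coef * rng.standard_normal(size=(m, d))
        if np.any(np.abs(x) > config.domain_guard):
            bad = int(np.argmax(np.any(np.abs(x) > config.domain_guard, axis=1)))
            raise IntegrationError(
                f"walker {bad} left the domain guard at step {step}"
            )
        if step % config.stride == 0:
            out[k] = x
            times[k] = step * dt
            k += 1
    values = out.transpose(1, 0, 2).reshape(n_out * m, d)
    return SampleSet(
        space=space,
        times=np.tile(times, m),
        values=values,
        window=np.repeat(labels, n_out),
        replica=np.repeat(np.arange(m), n_out),
    )


def _profile_on_lines(surface, points, normals, beta, halfwidth, n_ortho):
    u = np.linspace(-halfwidth, halfwidth, n_ortho)
    pts = points[:, None, :] + u[None, :, None] * normals[:, None, :]
    e = surface.energy(pts.reshape(-1, surface.dim)).reshape(points.shape[0], n_ortho)
    emin = e.min(axis=1, keepdims=True)
    z = np.trapezoid(np.exp(-beta * (e - emin)), u, axis=1)
    return (emin[:, 0] - np.log(z) / beta)


def analytic_pmf(
    surface: PotentialSurface,
    beta: float = 1.0,
    *,
    grid: np.ndarray | None = None,
    axis: int | None = None,
    path: np.ndarray | None = None,
    ortho_halfwidth: float = 2.0,
    n_ortho: int = 801,
    rtol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference free-energy profile by direct quadrature, anchored at 0.

    Three modes: 1-D surfaces return the potential itself on ``grid``;
    2-D surfaces with ``axis`` integrate the Boltzmann factor over the
    orthogonal coordinate; 2-D surfaces with a ``path`` (an (m, 2) polyline)
    integrate over the local normal of each path point, yielding G(s).
    The quadrature is repeated at twice the resolution and must agree to
    ``rtol`` (Richardson-style self-check), else a numerical error reports
    the achieved tolerance.
    """
    if surface.dim == 1:
        if grid is None:
            raise InputError("grid required for 1-D profiles")
        g = surface.energy(np.asarray(grid, dtype=float)[:, None])
        return np.asarray(grid, dtype=float), g - g.min()
    if surface.dim != 2:
        raise InputError("analytic_pmf supports d <= 2 surfaces")

    if (axis is None) == (path is None):
        raise InputError("give exactly one of axis= or path= for 2-D surfaces")
    if axis is not None:
        if grid is None:
            raise InputError("grid required for axis profiles")
        grid = np.asarray(grid, dtype=float)
        points = np.zeros((grid.shape[0], 2))
        points[:, axis] = grid
        normals = np.zeros_like(points)
        normals[:, 1 - axis] = 1.0
        s_out = grid
    else:
        points = np.atleast_2d(np.asarray(path, dtype=float))
        if points.shape[0] < 2:
            raise InputError("path needs at least 2 points")
        tang = np.gradient(points, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        normals = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        s_out = np.concatenate([[0.0], np.cumsum(seg)])

    g1 = _profile_on_lines(surface, points, normals, beta, ortho_halfwidth, n_ortho)
    g2 = _profile_on_lines(surface, points, normals, beta, ortho_halfwidth, 2 * n_ortho - 1)
    g1 -= g1.min()
    g2 -= g2.min()
    err = float(np.max(np.abs(g1 - g2)))
    if err > rtol:
        raise NumericalError(
            f"quadrature self-check failed: resolutions differ by {err:.2e} > {rtol}"
        )
    return s_out, g2


def make_crooks_work_samples(dg: float, sigma: float, n_forward: int,
                             n_reverse: int, beta: float, seed: int):
    """Crooks-consistent Gaussian work distributions with known Delta G.

    Forward works ~ N(dg + beta sigma^2 / 2, sigma^2) and reverse works
    ~ N(-dg + beta sigma^2 / 2, sigma^2): the unique equal-variance
    Gaussian pair satisfying the Crooks fluctuation relation
    P_f(W) / P_r(-W) = exp(beta (W - dg)).
    """
    from .alchemy import WorkSet

    if sigma < 0:
        raise InputError("sigma must be nonnegative")
    if n_forward < 1 or n_reverse < 1:
        raise InputError("need at least one work value per direction")
    rng = np.random.default_rng(seed)
    dissip = 0.5 * beta * sigma**2
    wf = rng.normal(dg + dissip, sigma, size=n_forward)
    wr = rng.normal(-dg + dissip, sigma, size=n_reverse)
    return WorkSet(forward=wf, reverse=wr, beta=beta)
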