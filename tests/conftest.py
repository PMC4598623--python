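"""Shared fixtures: analytic surfaces and pre-built biased sample sets."""
from __future__ import annotations

import numpy as np
import pytest

from mfepath.biases import HarmonicBias
from mfepath.cvspace import CVSpace
from mfepath.samples import SampleSet
from mfepath.toy import BrownianConfig, PotentialSurface, propagate


class Harmonic1D(PotentialSurface):
    """U = 1/2 kappa x^2: every reweighting quantity has a closed form."""

    dim = 1
    name = "harmonic_1d"

    def __init__(self, kappa: float = 1.0) -> None:
        self.kappa = kappa

    def energy(self, x):
        x, single = self._batch(x)
        u = 0.5 * self.kappa * x[:, 0] ** 2
        return u[0] if single else u

    def gradient(self, x):
        x, single = self._batch(x)
        g = self.kappa * x
        return g[0] if single else g


class Flat(PotentialSurface):
    """Zero potential in d dimensions."""

    name = "flat"

    def __init__(self, dim: int = 1) -> None:
        self.dim = dim

    def energy(self, x):
        x, single = self._batch(x)
        u = np.zeros(x.shape[0])
        return u[0] if single else u

    def gradient(self, x):
        x, single = self._batch(x)
        g = np.zeros_like(x)
        return g[0] if single else g


def harmonic_window_data(
    kappa: float = 1.0,
    k: float = 4.0,
    centers: np.ndarray | None = None,
    samples_per_window: int = 10_000,
    seed: int = 2024,
    dt: float = 0.02,
    stride: int = 20,
) -> tuple[SampleSet, list[HarmonicBias], Harmonic1D]:
    """Umbrella windows on the 1-D harmonic surface, one replica each.

    Stride is chosen long against the relaxation time 1/(kappa + k) so
    retained samples are nearly independent.
    """
    if centers is None:
        centers = np.linspace(-2.5, 2.5, 11)
    surface = Harmonic1D(kappa)
    biases = [HarmonicBias(np.array([c]), k) for c in centers]
    start = (k * centers / (kappa + k))[:, None]  # biased-minimum starts
    n_win = centers.size

    # propagate all windows in lockstep; per-walker biases via combined force
    rng_cfg = BrownianConfig(
        timestep=dt, n_steps=samples_per_window * stride, seed=seed,
        stride=stride,
    )
    x = start.copy()
    rng = np.random.default_rng(seed)
    drift = rng_cfg.beta * dt
    noise = np.sqrt(2.0 * dt)
    n_out = samples_per_window
    vals = np.empty((n_out, n_win, 1))
    times = np.empty(n_out)
    j = 0
    cvec = centers[:, None]
    for step in range(1, rng_cfg.n_steps + 1):
        g = surface.gradient(x) + k * (x - cvec)
        x = x - drift * g + noise * rng.standard_normal(x.shape)
        if step % stride == 0:
            vals[j] = x
            times[j] = step * dt
            j += 1
    samples = SampleSet(
        space=CVSpace.euclidean(1),
        times=np.tile(times, n_win),
        values=vals.transpose(1, 0, 2).reshape(-1, 1),
        window=np.repeat(np.arange(n_win), n_out),
        replica=np.repeat(np.arange(n_win), n_out),
    )
    return samples, biases, surface


@pytest.fixture(scope="session")
def harmonic_beus():
    """11 umbrella windows x 10^4 near-independent samples on U = x^2/2."""
    return harmonic_window_data()


@pytest.fixture(scope="session")
def harmonic_surface():
    return Harmonic1D()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
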