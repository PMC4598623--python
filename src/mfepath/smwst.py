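"""String method with swarms of trajectories (SMwST).

An initial pathway, discretized into images, is refined iteratively: each
image runs several copies that are (1) equilibrated under a harmonic
restraint at the image center, (2) released for a short unbiased swarm,
after which (3) the image center moves to the mean swarm endpoint (the
drift estimate of the local free-energy gradient flow) and (4) the string
is reparametrized to equidistant images.  At convergence the string
approximates the most probable transition pathway.  Open strings keep
their endpoints pinned; cyclic strings are fully free.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .paths import StringPath, reparametrized_path
from .toy import BrownianConfig, PotentialSurface


@dataclass
class StringHistory:
    """Per-iteration displacement diagnostics of a string optimization."""

    max_displacement: np.ndarray
    rms_displacement: np.ndarray
    paths: list[StringPath] | None = None


def _swarm_iteration(centers, surface, copies, restrain_steps, swarm_steps,
                     k_restrain, config, rng):
    """One restrain/release cycle; returns mean swarm endpoints per image."""
    n, d = centers.shape
    walkers = np.repeat(centers, copies, axis=0)
    anchor = walkers.copy()
    dt = config.timestep
    dvec = np.broadcast_to(np.asarray(config.diffusion, dtype=float), (d,))
    drift = dvec * config.beta * dt
    noise = config.noise_scale * np.sqrt(2.0 * dvec * dt)

    for _ in range(restrain_steps):
        g = surface.gradient(walkers) + k_restrain * (walkers - anchor)
        walkers = walkers - drift * g
        if config.noise_scale != 0.0:
            walkers = walkers + noise * rng.standard_normal(walkers.shape)
    for _ in range(swarm_steps):
        g = surface.gradient(walkers)
        walkers = walkers - drift * g
        if config.noise_scale != 0.0:
            walkers = walkers + noise * rng.standard_normal(walkers.shape)
    return walkers.reshape(n, copies, d).mean(axis=1)


def run_smwst(path: StringPath, surface: PotentialSurface,
              copies_per_image: int, restrain_steps: int, swarm_steps: int,
              k_restrain: float, iterations: int, config: BrownianConfig,
              keep_history: bool = False
              ) -> tuple[StringPath, StringHistory]:
    """Iterative swarm-drift refinement of a string.

    Each iteration restarts every copy at its image center, equilibrates it
    under the restraint, releases the swarm, moves each center to its mean
    swarm endpoint, and reparametrizes the string to equidistant images.
    A path lying along an exact flat valley is a fixed point in the
    zero-noise limit.  Returns the final path and per-iteration max/RMS
    image displacements.
    """
    if copies_per_image < 1:
        raise InputError("need at least one copy per image")
    if surface.dim != path.centers.shape[1]:
        raise InputError("surface dimension does not match path")
    rng = np.random.default_rng(config.seed)
    current = path
    max_d, rms_d = [], []
    kept = [path] if keep_history else None
    for _ in range(iterations):
        new_centers = _swarm_iteration(
            current.centers, surface, copies_per_image, restrain_steps,
            swarm_steps, k_restrain, config, rng,
        )
        if not path.cyclic:
            new_centers[0] = path.centers[0]
            new_centers[-1] = path.centers[-1]
        candidate = StringPath(new_centers, cyclic=path.cyclic, space=path.space)
        candidate = reparametrized_path(candidate)
        if not path.cyclic:
            candidate.centers[0] = path.centers[0]
            candidate.centers[-1] = path.centers[-1]
        mx, rms = candidate.displacement(current)
        max_d.append(mx)
        rms_d.append(rms)
        current = candidate
        if keep_history:
            kept.append(current)
    history = StringHistory(
        max_displacement=np.asarray(max_d),
        rms_displacement=np.asarray(rms_d),
        paths=kept,
    )
    return current, history


def string_convergence(history: StringHistory, tol: float,
                       consecutive: int = 5) -> tuple[bool, int | None]:
    """Detect convergence: RMS displacement < tol for M consecutive iterations.

    Returns (converged, first iteration index at which the criterion was
    met), with iterations counted from 1.
    """
    rms = np.asarray(history.rms_displacement)
    if rms.size < 2:
        raise InputError("need at least 2 iterations to assess convergence")
    below = rms < tol
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= consecutive:
            return True, i - consecutive + 2
    return False, None


def default_convergence_tol(path: StringPath, fraction: float = 0.01) -> float:
    """Default tolerance: 1% of the mean inter-image spacing."""
    return fraction * path.mean_spacing()
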