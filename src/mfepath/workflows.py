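"""End-to-end studies on the built-in model landscapes.

These functions wire the pipeline stages together the way a production
analysis would: biased sampling -> reweighting -> path extraction ->
PMF/stiff-spring free energies -> uncertainty.  They double as worked
examples and as the recomputation backbone of the acceptance script.

Problem sizes default to desk-scale settings (tens of windows, 10^4-10^5
samples) chosen so each study finishes in minutes on one CPU while leaving
the statistical checks comfortably resolved.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beus import WindowLadder, run_beus
from .cvspace import CVSpace
from .paths import StringPath
from .phsm import run_phsm
from .reweight import (
    gibbs_reweight,
    project_pmf,
    sample_weights,
    state_free_energies,
    stiff_spring_correct,
    wham_block_bootstrap,
    wham_solve,
)
from .samples import SampleSet, WeightedEnsemble
from .smwst import run_smwst
from .toy import BrownianConfig, analytic_pmf, preset_surface
from .uncertainty import BlockScheme


def sample_harmonic_windows(
    kappa: float = 1.0,
    k: float = 4.0,
    centers: np.ndarray | None = None,
    samples_per_window: int = 10_000,
    seed: int = 0,
) -> tuple[SampleSet, list, float]:
    """Exact iid draws from harmonic umbrella windows on U = kappa x^2 / 2.

    The biased density of window c is the Gaussian
    N(kc/(kappa+k), 1/(beta(kappa+k))), so the window ensembles can be
    sampled exactly — the cleanest fixture for estimator-recovery checks,
    with no residual autocorrelation.  Returns (samples, biases, kappa).
    """
    from .biases import HarmonicBias

    if centers is None:
        centers = np.linspace(-2.5, 2.5, 11)
    rng = np.random.default_rng(seed)
    n = samples_per_window
    sd = 1.0 / np.sqrt(kappa + k)
    vals = np.concatenate([
        rng.normal(k * c / (kappa + k), sd, size=n) for c in centers
    ])
    ss = SampleSet(
        space=CVSpace.euclidean(1),
        times=np.tile(np.arange(n, dtype=float) + 1.0, centers.size),
        values=vals[:, None],
        window=np.repeat(np.arange(centers.size), n),
        replica=np.repeat(np.arange(centers.size), n),
    )
    biases = [HarmonicBias(np.array([c]), k) for c in centers]
    return ss, biases, kappa


def harmonic_f_closed_form(centers: np.ndarray, kappa: float = 1.0,
                           k: float = 4.0) -> np.ndarray:
    """Perturbed free energies of harmonic windows: Gaussian convolution.

    F(c) = kappa k / (kappa + k) c^2 / 2, anchored at the first window.
    """
    f = 0.5 * kappa * k / (kappa + k) * np.asarray(centers) ** 2
    return f - f[0]


@dataclass
class PMFRecovery:
    """Projected-PMF vs quadrature-reference comparison on one surface."""

    xi: np.ndarray
    g_est: np.ndarray
    g_ref: np.ndarray
    sigma: np.ndarray
    n_samples: int

    @property
    def max_sigma_deviation(self) -> float:
        """Max |G_est - G_ref| / sigma over occupied bins (shape-aligned)."""
        resid = self.g_est - self.g_ref
        resid = resid - np.average(resid, weights=1.0 / self.sigma**2)
        return float(np.max(np.abs(resid) / self.sigma))


def _arc_coordinate(values: np.ndarray, radius: float) -> np.ndarray:
    theta = np.mod(np.arctan2(values[:, 1], values[:, 0]), 2 * np.pi)
    return theta * radius


def pmf_recovery_study(surface_name: str, seed: int,
                       total_samples: int = 100_000) -> PMFRecovery:
    """BEUS sampling + reweighting + projection vs direct quadrature.

    The projection variable is the CV itself (1-D surfaces) or the
    arc-length coordinate along the documented valley (2-D surfaces); the
    reference profile comes from :func:`~mfepath.toy.analytic_pmf`.
    Per-bin sigma combines the effective-count multinomial error with a
    correlation margin.
    """
    beta = 1.0
    surface = preset_surface(surface_name)
    if surface_name == "double_well_1d":
        # window springs must out-stiffen the negative barrier curvature
        # (|U''(0)| = 8 b / a^2 = 32 here), else barrier windows are bistable
        # timestep keeps kappa_total*dt small: the Euler-Maruyama stationary
        # variance is inflated by 2/(2 - kappa dt), which would bias G
        n_win = 16
        ladder = WindowLadder(np.linspace(-1.45, 1.45, n_win)[:, None], 50.0)
        cfg = BrownianConfig(timestep=0.0015, seed=seed, stride=40,
                             n_steps=40 * (total_samples // n_win))
    elif surface_name == "curved_valley_2d":
        n_win = 20
        arc = np.linspace(0.05, surface.valley_length - 0.05, n_win)
        ladder = WindowLadder(surface.valley(arc), 30.0)
        cfg = BrownianConfig(timestep=0.002, seed=seed, stride=24,
                             n_steps=24 * (total_samples // n_win))
    elif surface_name == "cyclic_channels_2d":
        n_win = 24
        arc = np.linspace(0, surface.valley_length, n_win, endpoint=False)
        ladder = WindowLadder(surface.valley(arc), 30.0, cyclic=True)
        cfg = BrownianConfig(timestep=0.002, seed=seed, stride=24,
                             n_steps=24 * (total_samples // n_win))
    else:
        raise ValueError(surface_name)

    samples, _ = run_beus(ladder, surface, cfg, exchange_interval=200)
    f = wham_solve(samples, ladder.biases(), beta)
    weights = sample_weights(samples, ladder.biases(), f, beta)

    # the histogram estimator reports bin-averaged Boltzmann weight, so the
    # reference must be bin-averaged the same way (point values differ by
    # the full within-bin variation of G on steep profiles)
    fine_per_bin = 16

    def bin_average(g_fine: np.ndarray, n_bins: int) -> np.ndarray:
        boltz = np.exp(-beta * (g_fine - g_fine.min()))
        boltz = boltz.reshape(n_bins, fine_per_bin).mean(axis=1)
        return -np.log(boltz) / beta

    if surface.dim == 1:
        xi = samples.values[:, 0]
        lo, hi = np.percentile(xi, [0.5, 99.5])
        grid = np.linspace(lo, hi, 31)
        fine = np.linspace(lo, hi, 30 * fine_per_bin + 1)[:-1]
        fine = fine + 0.5 * (fine[1] - fine[0])
        _, g_fine = analytic_pmf(surface, beta, grid=fine)
        g_ref = bin_average(g_fine, 30)
    else:
        xi = _arc_coordinate(samples.values, surface.radius)
        if surface_name == "curved_valley_2d":
            lo, hi = np.percentile(xi, [1, 99])
        else:
            lo, hi = 0.0, surface.valley_length
        grid = np.linspace(lo, hi, 31)
        fine = np.linspace(lo, hi, 30 * fine_per_bin + 1)[:-1]
        fine = fine + 0.5 * (fine[1] - fine[0])
        _, g_fine = analytic_pmf(surface, beta, path=surface.valley(fine),
                                 ortho_halfwidth=0.6)
        g_ref = bin_average(g_fine, 30)

    pmf = project_pmf(weights, xi, beta, grid, occupancy_floor=25.0)
    ok = ~pmf.mask
    sigma = 2.0 / (beta * np.sqrt(pmf.occupancy[ok])) + 0.02
    g_est = pmf.g[ok]
    g_ref = np.asarray(g_ref)[ok] - np.asarray(g_ref)[ok].min()
    return PMFRecovery(xi=pmf.centers[0][ok], g_est=g_est, g_ref=g_ref,
                       sigma=sigma, n_samples=samples.n_samples)


def _path_tube_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Max over images of either path of the distance to the other polyline."""
    def one_way(p: np.ndarray, q: np.ndarray) -> float:
        dense = []
        for i in range(q.shape[0] - 1):
            t = np.linspace(0, 1, 40)[:, None]
            dense.append(q[i] + t * (q[i + 1] - q[i]))
        dense = np.vstack(dense)
        return float(max(
            np.min(np.linalg.norm(dense - c, axis=1)) for c in p
        ))

    return max(one_way(a, b), one_way(b, a))


def curved_valley_path_study(seed: int, n_images_phsm: int = 33,
                             n_images_smwst: int = 49,
                             total_samples: int = 72_000) -> dict:
    """PHSM (two initializations) and SMwST on the semicircular valley.

    Returns the converged paths, their maximum deviation from the analytic
    valley arc, and the PHSM-SMwST tube disagreement, all in reduced
    units.  The image counts trade off the global-Bezier corner-cutting
    bias (which shrinks with more images) against the data-edge pull on
    cells near the pinned endpoints (which grows as cells shrink below the
    sampling spill-over at the path ends).
    """
    surface = preset_surface("curved_valley_2d")
    n_win = 24
    arc = np.linspace(0.02, surface.valley_length - 0.02, n_win)
    ladder = WindowLadder(surface.valley(arc), 30.0)
    cfg = BrownianConfig(timestep=0.002, seed=seed, stride=10,
                         n_steps=10 * (total_samples // n_win))
    samples, _ = run_beus(ladder, surface, cfg, exchange_interval=200)
    f = wham_solve(samples, ladder.biases(), 1.0)
    weights = sample_weights(samples, ladder.biases(), f, 1.0)

    def chord(y: float, n: int) -> StringPath:
        pts = np.column_stack([np.linspace(-1, 1, n), np.full(n, y)])
        pts[0] = [-1.0, 0.0]
        pts[-1] = [1.0, 0.0]
        return StringPath(pts)

    phsm_low = run_phsm(weights, chord(0.05, n_images_phsm), r_c=np.inf,
                        max_iter=100, tol=1e-3)
    phsm_high = run_phsm(weights, chord(0.4, n_images_phsm), r_c=np.inf,
                         max_iter=100, tol=1e-3)

    smwst_cfg = BrownianConfig(timestep=0.002, n_steps=1, seed=seed + 1)
    smwst_path, _ = run_smwst(chord(0.01, n_images_smwst), surface,
                              copies_per_image=128, restrain_steps=100,
                              swarm_steps=8, k_restrain=100.0,
                              iterations=50, config=smwst_cfg)

    dense = surface.valley(np.linspace(0, surface.valley_length, 1200))

    def deviation(path: StringPath) -> float:
        return float(max(
            np.min(np.linalg.norm(dense - c, axis=1)) for c in path.centers
        ))

    return {
        "phsm_path": phsm_low.path,
        "phsm_path_alt": phsm_high.path,
        "smwst_path": smwst_path,
        "phsm_deviation": deviation(phsm_low.path),
        "phsm_deviation_alt": deviation(phsm_high.path),
        "smwst_deviation": deviation(smwst_path),
        "init_robustness": float(np.max(np.linalg.norm(
            phsm_low.path.centers - phsm_high.path.centers, axis=1
        ))),
        "phsm_smwst_agreement": _path_tube_distance(
            phsm_low.path.centers, smwst_path.centers
        ),
    }


@dataclass
class CyclicStudyResult:
    """Outputs of the closed-cycle two-channel free-energy pipeline."""

    g_along_path: np.ndarray
    g_errors: np.ndarray
    correction_max: float
    barrier_high: float
    barrier_low: float
    barrier_gap: float
    barrier_gap_error: float
    planted_gap: float
    phsm_deviation: float
    n_samples: int
    state_table: list


def cyclic_channel_study(seed: int, n_windows: int = 32,
                         samples_per_window: int = 2500,
                         n_boot: int = 40) -> CyclicStudyResult:
    """Full closed-cycle pipeline on the two-channel ring landscape.

    BEUS over a cyclic window ladder -> Bayesian (Gibbs) reweighting ->
    PHSM path extraction -> stiff-spring-corrected G(s) -> state/barrier
    table, with block-bootstrap errors on the free energies.  The figure of
    merit is the barrier-height difference between the two channels, to be
    compared with the planted value of the landscape.
    """
    beta = 1.0
    surface = preset_surface("cyclic_channels_2d")
    k = 40.0
    arc = np.linspace(0, surface.valley_length, n_windows, endpoint=False)
    ladder = WindowLadder(surface.valley(arc), k, cyclic=True)
    stride = 25
    cfg = BrownianConfig(timestep=0.002, seed=seed, stride=stride,
                         n_steps=stride * samples_per_window)
    samples, _ = run_beus(ladder, surface, cfg, exchange_interval=250)

    post = gibbs_reweight(samples, ladder.biases(), beta, n_draws=100,
                          burn_in=40, seed=seed + 1)
    weights = post.weighted_ensemble(samples)

    # PHSM on the reweighted cloud, initialized off the ring
    init = StringPath(1.15 * ladder.centers, cyclic=True)
    phsm = run_phsm(weights, init, r_c=np.inf, max_iter=60, tol=2e-3)
    dense = surface.valley(np.linspace(0, surface.valley_length, 1600))
    phsm_dev = float(max(
        np.min(np.linalg.norm(dense - c, axis=1))
        for c in phsm.path.centers
    ))

    # block-bootstrap errors on F, then stiff-spring correction to G(s)
    scheme = BlockScheme.build(samples.times, samples.replica,
                               block_duration=stride * cfg.timestep * (samples_per_window // 10))
    f_mean, f_sd = wham_block_bootstrap(samples, ladder.biases(), beta,
                                        scheme, n_boot=n_boot, seed=seed + 2)
    s_arc = arc.copy()
    from .reweight import PerturbedFreeEnergies

    g, corr = stiff_spring_correct(
        PerturbedFreeEnergies(f_mean, beta), s_arc, k, cyclic=True,
        total_length=surface.valley_length,
    )
    g = g - g.min()

    theta = arc / surface.radius
    upper = np.sin(theta) > 0.1
    lower = np.sin(theta) < -0.1
    basins = ~upper & ~lower
    i_hi = int(np.argmax(np.where(upper, g, -np.inf)))
    i_lo = int(np.argmax(np.where(lower, g, -np.inf)))
    i_min = int(np.argmin(np.where(basins, g, np.inf)))
    barrier_high = float(g[i_hi] - g[i_min])
    barrier_low = float(g[i_lo] - g[i_min])
    gap_err = float(np.hypot(f_sd[i_hi], f_sd[i_lo]))

    table = state_free_energies(
        g, f_sd,
        states={"basin_right": i_min},
        barriers={"TS_high": i_hi, "TS_low": i_lo},
    )
    return CyclicStudyResult(
        g_along_path=g,
        g_errors=f_sd,
        correction_max=float(corr.max()),
        barrier_high=barrier_high,
        barrier_low=barrier_low,
        barrier_gap=barrier_high - barrier_low,
        barrier_gap_error=gap_err,
        planted_gap=surface.barrier_gap,
        phsm_deviation=phsm_dev,
        n_samples=samples.n_samples,
        state_table=table,
    )
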