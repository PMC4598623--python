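"""Recovering unbiased statistics from window-biased samples.

Umbrella windows i = 0..N-1 with bias potentials U_i collect T_i samples
each.  Writing F_i for the perturbed free energy of window i (the free
energy of the system with bias U_i switched on), the binless self-consistent
(WHAM-family) equations are

    exp(-beta F_i) = sum_t exp(-beta U_i(z_t)) / D_t ,
    D_t = sum_j T_j exp(beta F_j - beta U_j(z_t)) ,

with the sum over all samples from all windows.  The unnormalized weight of
sample t in the unbiased ensemble is w_t = 1 / D_t.  A Bayesian alternative
draws {f_i = T_i exp(beta F_i)} and {w_t} from their Gamma full
conditionals with a Gibbs sampler, whose stationary point reproduces the
maximum-likelihood equations; posterior spread then quantifies estimator
uncertainty without overfitting.

PMFs in an arbitrary projection variable xi follow by kernel smoothing of
the weighted samples, G(xi) = -beta^{-1} ln sum_t w_t K(xi - xi_t).  When
the windows ride a 1-D path with stiff springs, the PMF along the path is
the perturbed free-energy profile plus an O(1/k) correction built from its
first two arc-length derivatives.

All accumulations run in log space (log-sum-exp); 100+-window problems
underflow otherwise.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .biases import Bias
from .errors import ConvergenceError, InputError, NumericalError
from .samples import SampleSet, WeightedEnsemble


@dataclass
class PerturbedFreeEnergies:
    """Per-window perturbed free energies F_i, anchored to F_0 = 0."""

    f: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 1 or self.f.size < 1:
            raise InputError("F must be a 1-D array")
        if not np.all(np.isfinite(self.f)):
            raise InputError("F must be finite")
        self.f = self.f - self.f[0]

    @property
    def n_windows(self) -> int:
        return self.f.size


def log_bias_matrix(biases: list[Bias], values: np.ndarray,
                    beta: float) -> np.ndarray:
    """L[i, t] = -beta U_i(z_t) for every window bias i and sample t."""
    return np.stack([-beta * b.energy(values) for b in biases])


def _log_denominator(log_l: np.ndarray, log_t: np.ndarray,
                     bf: np.ndarray) -> np.ndarray:
    """log D_t = logsumexp_i [ ln T_i + beta F_i - beta U_i(z_t) ]."""
    return logsumexp(log_l + (log_t + bf)[:, None], axis=0)


def _solve_weighted(log_l: np.ndarray, window: np.ndarray, beta: float,
                    tol: float, max_iter: int,
                    log_u: np.ndarray | None = None,
                    bf_init: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Fixed point of the (optionally sample-weighted) window equations.

    With per-sample weights u_t (log_u; zero weight = -inf), the effective
    counts are T~_j = sum_{t in j} u_t and

        exp(-beta F_i) = sum_t u_t e^{-beta U_i(z_t)} / D_t ,
        D_t = sum_j T~_j exp(beta F_j - beta U_j(z_t)) .

    Returns (beta*F, iterations).  Warm starts from ``bf_init``.
    """
    n_win = log_l.shape[0]
    if log_u is None:
        log_u = np.zeros(log_l.shape[1])
    log_t = np.array([
        logsumexp(log_u[window == i]) if np.any(window == i) else -np.inf
        for i in range(n_win)
    ])
    if np.any(~np.isfinite(log_t)):
        raise InputError(
            f"windows without (weighted) samples: "
            f"{np.nonzero(~np.isfinite(log_t))[0].tolist()}"
        )
    bf = np.zeros(n_win) if bf_init is None else bf_init.copy()
    log_lu = log_l + log_u[None, :]
    t_eff = np.exp(log_t)
    n_eff = t_eff.sum()

    # the self-consistent equations are the stationarity conditions of a
    # convex objective; L-BFGS reaches its neighborhood in tens of
    # gradient evaluations where plain fixed-point sweeps need thousands
    # (slow relaxation across long window ladders)
    def objective(c: np.ndarray) -> tuple[float, np.ndarray]:
        log_d = _log_denominator(log_l, log_t, c)
        val = float(np.sum(np.exp(log_u) * log_d) - t_eff @ c)
        # grad_i = sum_t u_t T_i e^{c_i - bU_i} / D_t - T_i
        grad = np.exp(
            log_t + c + logsumexp(log_lu - log_d[None, :], axis=1)
        ) - t_eff
        return val / n_eff, grad / n_eff

    from scipy.optimize import minimize

    res = minimize(objective, bf, jac=True, method="L-BFGS-B",
                   options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10})
    bf = res.x - res.x[0]
    # polish with fixed-point sweeps until the stated tolerance is met
    for it in range(1, max_iter + 1):
        log_d = _log_denominator(log_l, log_t, bf)
        bf_new = -logsumexp(log_lu - log_d[None, :], axis=1)
        bf_new -= bf_new[0]
        delta = np.max(np.abs(bf_new - bf))
        bf = bf_new
        if delta < beta * tol:
            return bf, it
    raise ConvergenceError(
        f"WHAM not converged after {max_iter} sweeps (residual {delta / beta:.2e})"
    )


def wham_solve(samples: SampleSet, biases: list[Bias], beta: float,
               tol: float = 1e-8, max_iter: int = 50000,
               return_iterations: bool = False):
    """Self-consistent solution of the binless window equations.

    Iterates the F_i update to a fixed point with ``|dF_i| < tol`` between
    sweeps, anchored at F_0 = 0.  Warns when some window collected no
    samples near any other window's bias (no overlap: the relative free
    energies of disconnected groups are then ill-conditioned).
    """
    n_win = len(biases)
    t_i = samples.window_counts(n_win)
    if np.any(t_i == 0):
        raise InputError(
            f"windows without samples: {np.nonzero(t_i == 0)[0].tolist()}"
        )
    log_l = log_bias_matrix(biases, samples.values, beta)
    _check_overlap(log_l, samples.window, n_win)
    bf, it = _solve_weighted(log_l, samples.window, beta, tol, max_iter)
    result = PerturbedFreeEnergies(bf / beta, beta)
    return (result, it) if return_iterations else result


def wham_block_bootstrap(samples: SampleSet, biases: list[Bias], beta: float,
                         scheme, n_boot: int = 50, bayesian: bool = True,
                         seed: int = 0, tol: float = 1e-7,
                         max_iter: int = 20000) -> tuple[np.ndarray, np.ndarray]:
    """Block-bootstrap uncertainty of the perturbed free energies.

    Each replicate reweights the time blocks (flat-Dirichlet weights in
    Bayesian mode, multinomial counts classically), re-solves the weighted
    window equations warm-started from the full-data solution, and records
    F.  Returns (mean, sd) over replicates, each anchored at F_0 = 0.
    Blocks respect the provided :class:`~mfepath.uncertainty.BlockScheme`.
    """
    n_win = len(biases)
    log_l = log_bias_matrix(biases, samples.values, beta)
    bf0, _ = _solve_weighted(log_l, samples.window, beta, tol, max_iter)
    rng = np.random.default_rng(seed)
    nb = scheme.n_blocks
    draws = np.empty((n_boot, n_win))
    for b in range(n_boot):
        if bayesian:
            bw = rng.dirichlet(np.ones(nb)) * nb
        else:
            bw = np.bincount(rng.integers(0, nb, nb), minlength=nb).astype(float)
        with np.errstate(divide="ignore"):
            log_u = np.log(bw)[scheme.block_ids]
        bf, _ = _solve_weighted(log_l, samples.window, beta, tol, max_iter,
                                log_u=log_u, bf_init=bf0)
        draws[b] = bf / beta
    return draws.mean(axis=0), draws.std(axis=0, ddof=1)


def _check_overlap(log_l: np.ndarray, window: np.ndarray, n_win: int) -> None:
    # window i overlaps j when samples collected in i have non-negligible
    # Boltzmann factor under bias j; warn on any window isolated from all others
    for i in range(n_win):
        mine = window == i
        others = np.delete(np.arange(n_win), i)
        if others.size == 0:
            continue
        rel = log_l[np.ix_(others, np.nonzero(mine)[0])] - np.max(
            log_l[:, mine], axis=0
        )
        if rel.size and np.max(rel) < -50.0:
            j = others[int(np.argmax(np.max(rel, axis=1)))]
            warnings.warn(
                f"windows {i} and {j} share no sampled region; "
                "free energies may be ill-conditioned",
                stacklevel=3,
            )
            return


def sample_weights(samples: SampleSet, biases: list[Bias],
                   f: PerturbedFreeEnergies, beta: float,
                   normalized: bool = True) -> WeightedEnsemble:
    """Per-sample unbiased weights w_t = 1 / sum_i T_i e^{beta F_i - beta U_i}."""
    n_win = len(biases)
    if f.n_windows != n_win:
        raise InputError("F count does not match bias count")
    t_i = samples.window_counts(n_win).astype(float)
    log_l = log_bias_matrix(biases, samples.values, beta)
    log_d = _log_denominator(log_l, np.log(t_i), beta * f.f)
    we = WeightedEnsemble(samples, -log_d)
    return we.normalize() if normalized else we


def iterative_solve(samples: SampleSet, biases: list[Bias], beta: float,
                    tol: float = 1e-8, max_iter: int = 50000
                    ) -> tuple[WeightedEnsemble, PerturbedFreeEnergies]:
    """Joint fixed point of the weight and free-energy equations.

    Alternates w_t <- 1/D_t and exp(-beta F_i) <- sum_t w_t e^{-beta U_i};
    the fixed point coincides with :func:`wham_solve` (an internal guard of
    the estimator family).
    """
    n_win = len(biases)
    t_i = samples.window_counts(n_win).astype(float)
    if np.any(t_i == 0):
        raise InputError("every window needs at least one sample")
    log_l = log_bias_matrix(biases, samples.values, beta)
    log_t = np.log(t_i)
    bf = np.zeros(n_win)
    for _ in range(max_iter):
        log_w = -_log_denominator(log_l, log_t, bf)
        bf_new = -logsumexp(log_l + log_w[None, :], axis=1)
        bf_new -= bf_new[0]
        if np.max(np.abs(bf_new - bf)) < beta * tol:
            bf = bf_new
            break
        bf = bf_new
    else:
        raise ConvergenceError(f"iterative solve not converged in {max_iter} sweeps")
    fpe = PerturbedFreeEnergies(bf / beta, beta)
    return sample_weights(samples, biases, fpe, beta), fpe


@dataclass
class GibbsPosterior:
    """Posterior draws from the Bayesian reweighting Gibbs sampler."""

    f_draws: np.ndarray  # (n_draws, n_windows), each anchored F_0 = 0
    mean_log_weights: np.ndarray  # posterior-mean normalized log-weights
    beta: float
    last_log_weights: np.ndarray | None = None

    @property
    def f_mean(self) -> np.ndarray:
        return self.f_draws.mean(axis=0)

    @property
    def f_sd(self) -> np.ndarray:
        return self.f_draws.std(axis=0, ddof=1)

    def free_energies(self) -> PerturbedFreeEnergies:
        return PerturbedFreeEnergies(self.f_mean, self.beta)

    def weighted_ensemble(self, samples: SampleSet) -> WeightedEnsemble:
        return WeightedEnsemble(samples, self.mean_log_weights, normalized=False).normalize()


def gibbs_reweight(samples: SampleSet, biases: list[Bias], beta: float,
                   n_draws: int = 200, burn_in: int = 50,
                   seed: int = 0) -> GibbsPosterior:
    """Gibbs sampler over per-sample weights and window partition functions.

    With f_i := T_i exp(beta F_i), the full conditionals are conjugate
    Gamma distributions,

        f_i | w  ~ Gamma(shape = T_i, rate = sum_t w_t e^{-beta U_i(z_t)}),
        w_t | f  ~ Gamma(shape = 1,  rate = sum_i f_i e^{-beta U_i(z_t)}),

    with the weights renormalized after every sweep.  Any single draw is an
    equally likely reconstruction; the posterior mean of F_i agrees with the
    self-consistent solution on well-sampled data, and the posterior spread
    is the estimator uncertainty.
    """
    n_win = len(biases)
    t_i = samples.window_counts(n_win).astype(float)
    if np.any(t_i == 0):
        raise InputError("every window needs at least one sample")
    rng = np.random.default_rng(seed)
    log_l = log_bias_matrix(biases, samples.values, beta)
    n = samples.n_samples
    log_w = np.full(n, -np.log(n))
    f_draws = np.empty((n_draws, n_win))
    mean_w = np.zeros(n)
    for sweep in range(burn_in + n_draws):
        # f_i | w : Gamma(T_i, rate_i), rate_i = sum_t w_t e^{-beta U_i}
        log_rate_i = logsumexp(log_l + log_w[None, :], axis=1)
        if not np.all(np.isfinite(log_rate_i)):
            raise NumericalError(f"non-finite Gamma rate at sweep {sweep}")
        # sample in log space: f = gamma(shape)/rate
        log_f = np.log(rng.gamma(shape=t_i)) - log_rate_i
        # w_t | f : Gamma(1, rate_t), rate_t = sum_i f_i e^{-beta U_i}
        log_rate_t = logsumexp(log_l + log_f[:, None], axis=0)
        log_w = np.log(rng.exponential(scale=1.0, size=n)) - log_rate_t
        log_w -= logsumexp(log_w)
        if sweep >= burn_in:
            bf = log_f - np.log(t_i)
            f_draws[sweep - burn_in] = (bf - bf[0]) / beta
            mean_w += np.exp(log_w)
    mean_w /= n_draws
    with np.errstate(divide="ignore"):
        mean_log_w = np.log(mean_w)
    return GibbsPosterior(
        f_draws=f_draws,
        mean_log_weights=mean_log_w,
        beta=beta,
        last_log_weights=log_w,
    )


@dataclass
class PMFGrid:
    """A PMF on a 1-D or 2-D grid, anchored to 0 at its occupied minimum.

    ``occupancy`` holds effective sample counts per bin; bins below the
    occupancy floor are masked (True in ``mask``) and carry NaN, never an
    extrapolated value.
    """

    centers: tuple[np.ndarray, ...]
    g: np.ndarray
    occupancy: np.ndarray
    mask: np.ndarray
    kernel: str = "histogram"

    @property
    def ndim(self) -> int:
        return len(self.centers)


def project_pmf(weights: WeightedEnsemble, xi: np.ndarray, beta: float,
                grid, kernel: str = "histogram",
                bandwidth: float | None = None,
                occupancy_floor: float = 1.0) -> PMFGrid:
    """PMF of an arbitrary projection variable xi from weighted samples.

    ``xi`` is (n,) for 1-D or (n, 2) for 2-D projections; ``grid`` is the
    bin-edge array (1-D) or a tuple of two edge arrays (2-D).  Kernels:
    ``histogram`` (top-hat bins; the PMF is the log of the weighted
    histogram) or ``gaussian`` (1-D only; Silverman bandwidth when not
    given).  Bins whose effective count (sum w)^2 / sum w^2 falls below
    ``occupancy_floor`` are masked with a warning: a kernel estimate is
    meaningless where the projected sampling has not converged.
    """
    w = weights.normalize().weights
    xi = np.asarray(xi, dtype=float)
    if xi.ndim == 1:
        xi = xi[:, None]
    n, d = xi.shape
    if n != w.size:
        raise InputError("xi must have one row per sample")
    if d not in (1, 2):
        raise InputError("only 1-D and 2-D projections supported")
    edges = (np.asarray(grid, dtype=float),) if d == 1 else tuple(
        np.asarray(g, dtype=float) for g in grid
    )
    if len(edges) != d:
        raise InputError("grid dimensionality does not match xi")
    centers = tuple(0.5 * (e[1:] + e[:-1]) for e in edges)

    hist_w, _ = np.histogramdd(xi, bins=edges, weights=w)
    hist_w2, _ = np.histogramdd(xi, bins=edges, weights=w * w)
    with np.errstate(divide="ignore", invalid="ignore"):
        occupancy = np.where(hist_w2 > 0, hist_w**2 / hist_w2, 0.0)
    mask = occupancy < occupancy_floor

    if kernel == "histogram":
        with np.errstate(divide="ignore"):
            g = -np.log(hist_w) / beta
    elif kernel == "gaussian":
        if d != 1:
            raise InputError("gaussian kernel implemented for 1-D projections")
        x = xi[:, 0]
        if bandwidth is None:
            n_eff = w.sum() ** 2 / np.sum(w * w)
            sd = np.sqrt(np.average((x - np.average(x, weights=w)) ** 2, weights=w))
            bandwidth = 1.06 * sd * n_eff ** (-0.2)  # Silverman rule
        c = centers[0][:, None]
        log_k = -0.5 * ((c - x[None, :]) / bandwidth) ** 2
        lw = np.log(np.maximum(w, 1e-300))
        g = (-logsumexp(log_k + lw[None, :], axis=1) / beta).reshape(
            occupancy.shape
        )
    else:
        raise InputError(f"unknown kernel '{kernel}'")

    if np.all(mask):
        raise InputError("no occupied bins above the occupancy floor")
    if np.any(mask & (hist_w > 0)):
        warnings.warn(
            f"{int(np.sum(mask & (hist_w > 0)))} bins below occupancy floor masked",
            stacklevel=2,
        )
    g = np.where(mask, np.nan, g)
    g = g - np.nanmin(g)
    return PMFGrid(centers=centers, g=g, occupancy=occupancy, mask=mask,
                   kernel=kernel)


def _path_derivatives(f: np.ndarray, s: np.ndarray,
                      cyclic: bool, total_length: float | None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivatives of F(s), central second-order.

    Open paths use one-sided differences at the ends; cyclic paths wrap
    (the seam gap taken from ``total_length`` or inferred from the mean
    spacing).
    """
    if cyclic:
        if total_length is None:
            total_length = s[-1] - s[0] + np.mean(np.diff(s))
        s_ext = np.concatenate([[s[0] - (total_length - (s[-1] - s[0]))], s,
                                [s[-1] + (total_length - (s[-1] - s[0]))]])
        f_ext = np.concatenate([[f[-1]], f, [f[0]]])
        d1 = np.gradient(f_ext, s_ext)[1:-1]
        d2 = np.gradient(np.gradient(f_ext, s_ext), s_ext)[1:-1]
    else:
        d1 = np.gradient(f, s)
        d2 = np.gradient(d1, s)
    return d1, d2


def stiff_spring_correct(f: PerturbedFreeEnergies, arc_lengths: np.ndarray,
                         k: float, cyclic: bool = False,
                         total_length: float | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """PMF along a path from perturbed free energies, to first order in 1/k.

    With windows of spring constant k riding a 1-D pathway, F(s) is the
    Gaussian smoothing of G(s) with variance 1/(beta k); inverting the
    smoothing to first order gives

        G(s) = F(s) + F'(s)^2 / (2k) - F''(s) / (2 beta k) .

    Returns (G at the images, per-image |correction|).  Report the
    correction magnitudes: the approximation is trustworthy only where they
    are small against the statistical error.
    """
    s = np.asarray(arc_lengths, dtype=float)
    fv = f.f
    if fv.size < 5:
        raise InputError("stiff-spring correction needs at least 5 images")
    if s.shape != fv.shape:
        raise InputError("arc lengths must match image count")
    if k <= 0:
        raise InputError("force constant must be positive")
    d1, d2 = _path_derivatives(fv, s, cyclic, total_length)
    corr = d1 * d1 / (2.0 * k) - d2 / (2.0 * f.beta * k)
    return fv + corr, np.abs(corr)


def find_extrema(g: np.ndarray, cyclic: bool = False
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local minima and maxima of a profile (plateau-safe)."""
    g = np.asarray(g, dtype=float)
    n = g.size
    if cyclic:
        prev = np.roll(g, 1)
        nxt = np.roll(g, -1)
        minima = np.nonzero((g < prev) & (g <= nxt))[0]
        maxima = np.nonzero((g > prev) & (g >= nxt))[0]
    else:
        inner = np.arange(1, n - 1)
        minima = inner[(g[inner] < g[inner - 1]) & (g[inner] <= g[inner + 1])]
        maxima = inner[(g[inner] > g[inner - 1]) & (g[inner] >= g[inner + 1])]
    return minima, maxima


def state_free_energies(g: np.ndarray, errors: np.ndarray | None,
                        states: dict[str, int],
                        barriers: dict[str, int] | None = None
                        ) -> list[dict]:
    """Pairwise state free-energy differences and barrier heights.

    ``states`` maps state names to image indices of free-energy minima;
    ``barriers`` maps transition-state names to their images.  Errors are
    combined in quadrature assuming independent per-image errors (identical
    indices are special-cased to zero).  Returns a list of rows with keys
    kind/from/to/value/error.
    """
    g = np.asarray(g, dtype=float)
    e = np.zeros_like(g) if errors is None else np.asarray(errors, dtype=float)
    if e.shape != g.shape:
        raise InputError("errors must align with the profile")
    for name, idx in {**states, **(barriers or {})}.items():
        if not 0 <= idx < g.size:
            raise InputError(f"index {idx} for '{name}' out of range")

    rows: list[dict] = []
    names = list(states)
    for a_pos, a in enumerate(names):
        for b in names[a_pos + 1:]:
            i, j = states[a], states[b]
            err = 0.0 if i == j else float(np.hypot(e[i], e[j]))
            rows.append({
                "kind": "delta_g", "from": a, "to": b,
                "value": float(g[j] - g[i]), "error": err,
            })
    for ts, jt in (barriers or {}).items():
        for a in names:
            i = states[a]
            err = 0.0 if i == jt else float(np.hypot(e[i], e[jt]))
            rows.append({
                "kind": "barrier", "from": a, "to": ts,
                "value": float(g[jt] - g[i]), "error": err,
            })
    return rows
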