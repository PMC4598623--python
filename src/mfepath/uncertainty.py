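"""Autocorrelation-aware error bars for correlated sampling data.

Correlated time series carry fewer independent samples than points: the
variance of a mean is inflated by the statistical inefficiency
g = 1 + 2 tau / tau_lag, with tau the integrated autocorrelation time of
the quantity and tau_lag the spacing of the analysed points.
Autocorrelation times are computed on continuous replica trajectories, not
on window-reconstructed series, which makes them an upper bound for the
per-window values.  Block bootstrapping (classical resampling or the
Bayesian variant with flat-Dirichlet block weights) propagates that
correlation into the error of any derived estimate; blocks never span
replica boundaries.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ConfigError, InputError


def autocorrelation_function(series: np.ndarray, max_lag: int | None = None
                             ) -> np.ndarray:
    """Normalized autocorrelation rho_k, k = 0..max_lag, via FFT."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        raise InputError("series too short")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return np.zeros((max_lag or n - 1) + 1)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f))[:n] / n
    rho = acov / acov[0]
    if max_lag is not None:
        rho = rho[: max_lag + 1]
    return rho


def autocorrelation_time(series: np.ndarray) -> float:
    """Integrated autocorrelation time tau (in lag units).

    tau = sum_{k>=1} rho_k, accumulated up to the first negative ACF
    estimate (adaptive window cutoff).  A constant series has tau = 0
    (zero-variance warning).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 100:
        raise InputError("need at least 100 points for an ACF estimate")
    if np.ptp(x) == 0:
        warnings.warn("zero-variance series: tau defined as 0", stacklevel=2)
        return 0.0
    rho = autocorrelation_function(x)
    neg = np.nonzero(rho[1:] < 0)[0]
    cut = (neg[0] + 1) if neg.size else rho.size
    return float(max(np.sum(rho[1:cut]), 0.0))


def statistical_inefficiency(tau: float, lag: float) -> float:
    """g = 1 + 2 tau / tau_lag >= 1: variance inflation of correlated means."""
    if tau < 0 or lag <= 0:
        raise InputError("need tau >= 0 and lag > 0")
    return 1.0 + 2.0 * tau / lag


@dataclass
class BlockScheme:
    """Partition of per-replica retained time into equal blocks."""

    block_ids: np.ndarray  # per-sample block index, contiguous 0..n_blocks-1
    n_blocks: int
    block_duration: float

    @classmethod
    def build(cls, times: np.ndarray, replica: np.ndarray,
              block_duration: float) -> "BlockScheme":
        """Assign samples to blocks of ``block_duration`` within each replica.

        The block duration must tile each replica's time span exactly
        (within half a sampling interval); blocks never span replicas.
        """
        times = np.asarray(times, dtype=float)
        replica = np.asarray(replica, dtype=int)
        if times.shape != replica.shape:
            raise InputError("times and replica labels must align")
        if block_duration <= 0:
            raise ConfigError("block duration must be positive")
        ids = np.empty(times.size, dtype=int)
        offset = 0
        for r in np.unique(replica):
            m = replica == r
            t = times[m]
            dt = np.min(np.diff(t)) if t.size > 1 else block_duration
            span = t[-1] - t[0] + dt
            k = span / block_duration
            if abs(k - round(k)) > 0.5 * dt / block_duration:
                raise ConfigError(
                    f"block duration {block_duration} does not divide replica {r} "
                    f"span {span}; truncate explicitly first"
                )
            k = int(round(k))
            local = np.minimum(((t - t[0]) / block_duration).astype(int), k - 1)
            ids[m] = offset + local
            offset += k
        return cls(block_ids=ids, n_blocks=offset, block_duration=block_duration)


def block_bootstrap(values: np.ndarray, scheme: BlockScheme,
                    estimator: Callable[[np.ndarray, np.ndarray], float | np.ndarray],
                    n_boot: int = 200, bayesian: bool = True, seed: int = 0,
                    base_weights: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap an estimator over time blocks: (replicate mean, sd).

    ``estimator(values, weights)`` reduces a weighted sample set to a
    scalar or array.  Classical mode resamples blocks with replacement;
    Bayesian mode draws block weights from a flat Dirichlet over blocks.
    ``base_weights`` (e.g. reweighting weights) multiply the block weights.
    Seeded and deterministic.
    """
    values = np.asarray(values, dtype=float)
    if scheme.n_blocks < 2:
        raise InputError("need at least 2 blocks to bootstrap")
    if values.shape[0] != scheme.block_ids.size:
        raise InputError("values must align with the block scheme")
    w0 = (np.ones(values.shape[0]) if base_weights is None
          else np.asarray(base_weights, dtype=float))
    rng = np.random.default_rng(seed)
    reps = []
    nb = scheme.n_blocks
    for _ in range(n_boot):
        if bayesian:
            bw = rng.dirichlet(np.ones(nb)) * nb
        else:
            counts = np.bincount(rng.integers(0, nb, nb), minlength=nb)
            bw = counts.astype(float)
        w = w0 * bw[scheme.block_ids]
        reps.append(estimator(values, w))
    reps = np.asarray(reps, dtype=float)
    return reps.mean(axis=0), reps.std(axis=0, ddof=1)


def weighted_mean_estimator(values: np.ndarray, weights: np.ndarray) -> float:
    """Plain weighted mean, the default bootstrap reduction."""
    s = weights.sum()
    if s == 0:
        return np.nan
    return float(np.sum(values * weights) / s)


def path_average(quantity: np.ndarray, image_labels: np.ndarray,
                 weights: np.ndarray | None = None,
                 g: float | np.ndarray = 1.0,
                 n_images: int | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-image mean of a quantity along a pathway, with inflated errors.

    Unweighted by default (the efficient estimator under stiff springs);
    pass reweighting ``weights`` for the Boltzmann-weighted version.  The
    returned error is the standard error of the mean inflated by sqrt(g),
    the statistical-inefficiency correction sigma^2 g / N.  Images with
    fewer than 2 samples are masked (NaN) with a warning.
    """
    q = np.asarray(quantity, dtype=float)
    lab = np.asarray(image_labels, dtype=int)
    if q.shape != lab.shape:
        raise InputError("quantity and image labels must align")
    n_img = int(lab.max()) + 1 if n_images is None else n_images
    g_arr = np.broadcast_to(np.asarray(g, dtype=float), (n_img,))
    if np.any(g_arr < 1.0):
        raise InputError("statistical inefficiency must be >= 1")
    w = np.ones_like(q) if weights is None else np.asarray(weights, dtype=float)
    means = np.full(n_img, np.nan)
    errs = np.full(n_img, np.nan)
    starved = []
    for i in range(n_img):
        m = lab == i
        if np.sum(m) < 2:
            starved.append(i)
            continue
        wi = w[m]
        qi = q[m]
        sw = wi.sum()
        mu = np.sum(wi * qi) / sw
        var = np.sum(wi * (qi - mu) ** 2) / sw
        n_eff = sw**2 / np.sum(wi * wi)
        means[i] = mu
        errs[i] = np.sqrt(var * g_arr[i] / n_eff)
    if starved:
        warnings.warn(f"images with <2 samples masked: {starved}", stacklevel=2)
    return means, errs
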