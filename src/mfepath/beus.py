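"""Bias-exchange umbrella sampling (BEUS) over a window ladder.

One replica runs per window; at regular intervals, neighboring windows
attempt to exchange their biases with the Metropolis criterion

    Delta = beta [ (U_i(z_j) + U_j(z_i)) - (U_i(z_i) + U_j(z_j)) ],
    P(accept) = min(1, e^{-Delta}),

which preserves each window's biased stationary distribution while letting
replicas diffuse through the ladder, decorrelating the orthogonal degrees
of freedom.  Exchange attempts alternate between even and odd neighbor
pairs; a cyclic ladder (a closed transition pathway) also exchanges across
the seam.  With the exchange interval set to infinity the scheme reduces
exactly to independent umbrella sampling.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biases import Bias, CompositeBias, HarmonicBias, TubeBias
from .cvspace import CVSpace
from .errors import ConfigError, InputError, IntegrationError
from .samples import SampleSet
from .toy import BrownianConfig, PotentialSurface


@dataclass
class WindowLadder:
    """Ordered umbrella windows along a (possibly cyclic) pathway.

    ``centers`` is (n_windows, d); ``k`` a scalar or per-window force
    constant.  An optional transition-tube restraint (half-harmonic beyond
    ``tube_radius`` from the polyline through the centers) keeps sampling
    near the pathway.
    """

    centers: np.ndarray
    k: np.ndarray | float
    cyclic: bool = False
    tube_radius: float | None = None
    tube_k: float = 0.0
    space: CVSpace | None = None

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        n, d = self.centers.shape
        if n < 2:
            raise InputError("a ladder needs at least 2 windows")
        gaps = np.linalg.norm(np.diff(self.centers, axis=0), axis=1)
        if self.cyclic:
            gaps = np.append(
                gaps, np.linalg.norm(self.centers[0] - self.centers[-1])
            )
        if np.any(gaps == 0):
            raise InputError("consecutive window centers must be distinct")
        k = np.asarray(self.k, dtype=float)
        if k.ndim == 0:
            k = np.full(n, float(k))
        if k.shape != (n,) or np.any(k <= 0):
            raise InputError("force constants must be positive, scalar or (n,)")
        self.k = k
        if self.space is None:
            self.space = CVSpace.euclidean(d)
        elif self.space.dim != d:
            raise InputError("space dimension does not match centers")

    @property
    def n_windows(self) -> int:
        return self.centers.shape[0]

    def bias(self, i: int) -> Bias:
        """The full bias of window i (harmonic + optional tube restraint)."""
        h = HarmonicBias(self.centers[i], self.k[i])
        if self.tube_radius is None:
            return h
        tube = TubeBias(self.centers, self.tube_radius,
                        self.tube_k or float(np.mean(self.k)), self.cyclic)
        return CompositeBias([h, tube])

    def biases(self) -> list[Bias]:
        return [self.bias(i) for i in range(self.n_windows)]

    def neighbor_pairs(self, parity: int) -> list[tuple[int, int]]:
        """Non-conflicting neighbor pairs of the given parity (0 or 1)."""
        n = self.n_windows
        pairs = [(i, i + 1) for i in range(parity, n - 1, 2)]
        if self.cyclic and (n - 1) % 2 == parity:
            pairs.append((n - 1, 0))
        return pairs


@dataclass
class ExchangeLog:
    """Record of every exchange attempt plus replica->window occupancy."""

    times: list = field(default_factory=list)
    pairs: list = field(default_factory=list)
    deltas: list = field(default_factory=list)
    accepted: list = field(default_factory=list)
    occupancy_times: list = field(default_factory=list)
    occupancy: list = field(default_factory=list)  # replica -> window snapshots

    def record(self, t: float, i: int, j: int, delta: float, acc: bool) -> None:
        self.times.append(t)
        self.pairs.append((i, j))
        self.deltas.append(delta)
        self.accepted.append(acc)

    def snapshot(self, t: float, replica_window: np.ndarray) -> None:
        self.occupancy_times.append(t)
        self.occupancy.append(replica_window.copy())

    @property
    def acceptance_rate(self) -> float:
        if not self.accepted:
            return float("nan")
        return float(np.mean(self.accepted))

    def occupancy_array(self) -> np.ndarray:
        return np.asarray(self.occupancy, dtype=int)


def exchange_attempt(state_i: np.ndarray, state_j: np.ndarray,
                     bias_i: Bias, bias_j: Bias, beta: float,
                     rng: np.random.Generator) -> tuple[bool, float]:
    """Metropolis bias-exchange between two neighboring windows.

    Returns (accepted, Delta); Delta <= 0 is always accepted.
    """
    delta = beta * (
        bias_i.energy(state_j) + bias_j.energy(state_i)
        - bias_i.energy(state_i) - bias_j.energy(state_j)
    )
    delta = float(delta)
    if delta <= 0:
        return True, delta
    return bool(rng.random() < np.exp(-delta)), delta


def run_beus(ladder: WindowLadder, surface: PotentialSurface,
             config: BrownianConfig, exchange_interval: float,
             start: np.ndarray | None = None
             ) -> tuple[SampleSet, ExchangeLog]:
    """Run BEUS with one replica per window.

    ``exchange_interval`` counts propagation steps between exchange epochs
    (``np.inf`` disables exchanges).  Samples are labelled by the window
    whose bias they were collected under; replica labels stay fixed, so the
    continuous replica trajectories are directly reconstructable.
    """
    n = ladder.n_windows
    d = ladder.centers.shape[1]
    if surface.dim != d:
        raise InputError("surface dimension does not match ladder")
    x = (ladder.centers.copy() if start is None
         else np.array(start, dtype=float))
    if x.shape != (n, d):
        raise InputError(f"start must be ({n}, {d}): one replica per window")
    if exchange_interval != np.inf and (
        exchange_interval < 1 or int(exchange_interval) != exchange_interval
    ):
        raise ConfigError("exchange interval must be a positive step count or inf")

    rng = np.random.default_rng(config.seed)
    dt = config.timestep
    dvec = np.broadcast_to(np.asarray(config.diffusion, dtype=float), (d,))
    drift = dvec * config.beta * dt
    noise = config.noise_scale * np.sqrt(2.0 * dvec * dt)

    tube = None
    if ladder.tube_radius is not None:
        tube = TubeBias(ladder.centers, ladder.tube_radius,
                        ladder.tube_k or float(np.mean(ladder.k)), ladder.cyclic)

    rep_window = np.arange(n)  # replica r currently holds window rep_window[r]
    log = ExchangeLog()
    log.snapshot(0.0, rep_window)

    n_out = config.n_steps // config.stride
    times = np.empty(n_out)
    vals = np.empty((n_out, n, d))
    wins = np.empty((n_out, n), dtype=int)
    k_out = 0
    parity = 0
    for step in range(1, config.n_steps + 1):
        c = ladder.centers[rep_window]
        kw = ladder.k[rep_window][:, None]
        g = surface.gradient(x) + kw * (x - c)
        if tube is not None:
            g = g + tube.gradient(x)
        x = x - drift * g
        if config.noise_scale != 0.0:
            x = x + noise * rng.standard_normal(size=(n, d))
        if np.any(np.abs(x) > config.domain_guard):
            bad = int(np.argmax(np.any(np.abs(x) > config.domain_guard, axis=1)))
            raise IntegrationError(
                f"replica {bad} (window {rep_window[bad]}) left the domain "
                f"guard at step {step}"
            )
        if step % config.stride == 0:
            times[k_out] = step * dt
            vals[k_out] = x
            wins[k_out] = rep_window
            k_out += 1
        if exchange_interval != np.inf and step % int(exchange_interval) == 0:
            window_rep = np.argsort(rep_window)  # window w -> replica
            for (wi, wj) in ladder.neighbor_pairs(parity):
                ri, rj = window_rep[wi], window_rep[wj]
                acc, delta = exchange_attempt(
                    x[ri], x[rj], ladder.bias(wi), ladder.bias(wj),
                    config.beta, rng,
                )
                log.record(step * dt, wi, wj, delta, acc)
                if acc:
                    rep_window[ri], rep_window[rj] = wj, wi
                    window_rep[wi], window_rep[wj] = rj, ri
            parity = 1 - parity
            log.snapshot(step * dt, rep_window)

    samples = SampleSet(
        space=ladder.space,
        times=np.tile(times, n),
        values=vals.transpose(1, 0, 2).reshape(n_out * n, d),
        window=wins.T.reshape(-1),
        replica=np.repeat(np.arange(n), n_out),
    )
    return samples, log


def accounting(n_replicas: int, t_total: float, t_discard: float,
               sample_interval: float, block_size: float
               ) -> tuple[int, int]:
    """Sample and block bookkeeping for a BEUS analysis.

    retained_samples = n_replicas * (t_total - t_discard) / sample_interval,
    n_blocks = n_replicas * (t_total - t_discard) / block_size.  Both
    intervals must divide the retained duration exactly; otherwise the
    caller must truncate explicitly.
    """
    if t_discard >= t_total:
        if t_discard == t_total:
            return 0, 0
        raise ConfigError("discard time exceeds total time")
    if n_replicas < 1 or sample_interval <= 0 or block_size <= 0:
        raise ConfigError("replicas and intervals must be positive")
    retained = t_total - t_discard
    for name, interval in (("sample_interval", sample_interval),
                           ("block_size", block_size)):
        ratio = retained / interval
        if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
            raise ConfigError(
                f"{name} {interval} does not divide retained duration "
                f"{retained}; choose an explicit truncation policy"
            )
    return (
        int(round(n_replicas * retained / sample_interval)),
        int(round(n_replicas * retained / block_size)),
    )
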