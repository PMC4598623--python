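"""Sample containers: window-labelled CV time series and weighted ensembles."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cvspace import CVSpace
from .errors import InputError


@dataclass
class SampleSet:
    """CV samples with time, replica and window provenance.

    ``values`` is an ``(n, d)`` array of CV points; ``times`` are strictly
    increasing within each replica; every sample carries exactly one window
    label (the bias it was collected under).
    """

    space: CVSpace
    times: np.ndarray
    values: np.ndarray
    window: np.ndarray
    replica: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.window = np.asarray(self.window, dtype=int)
        self.replica = np.asarray(self.replica, dtype=int)
        n = self.times.shape[0]
        if self.values.shape != (n, self.space.dim):
            raise InputError(
                f"values shape {self.values.shape} != ({n}, {self.space.dim})"
            )
        if self.window.shape != (n,) or self.replica.shape != (n,):
            raise InputError("window/replica labels must be 1-D of length n")
        for r in np.unique(self.replica):
            t = self.times[self.replica == r]
            if np.any(np.diff(t) <= 0):
                bad = t[1:][np.diff(t) <= 0][0]
                raise InputError(
                    f"times not strictly increasing in replica {r} near t={bad}"
                )

    @property
    def n_samples(self) -> int:
        return self.times.shape[0]

    def replicas(self) -> np.ndarray:
        return np.unique(self.replica)

    def replica_series(self, r: int) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) of one continuous replica trajectory."""
        m = self.replica == r
        return self.times[m], self.values[m]

    def window_samples(self, w: int) -> np.ndarray:
        return self.values[self.window == w]

    def window_counts(self, n_windows: int) -> np.ndarray:
        """Per-window sample counts T_i."""
        return np.bincount(self.window, minlength=n_windows)

    @classmethod
    def concatenate(cls, parts: list["SampleSet"]) -> "SampleSet":
        if not parts:
            raise InputError("nothing to concatenate")
        space = parts[0].space
        for p in parts[1:]:
            space.check_compatible(p.space)
        return cls(
            space=space,
            times=np.concatenate([p.times for p in parts]),
            values=np.concatenate([p.values for p in parts]),
            window=np.concatenate([p.window for p in parts]),
            replica=np.concatenate([p.replica for p in parts]),
        )


@dataclass
class WeightedEnsemble:
    """Samples with unnormalized statistical weights.

    Weights are stored in log space to survive 100+-window reweighting
    problems; ``weights`` exposes the (optionally normalized) linear values.
    """

    samples: SampleSet
    log_weights: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.log_weights = np.asarray(self.log_weights, dtype=float)
        if self.log_weights.shape != (self.samples.n_samples,):
            raise InputError("one log-weight per sample required")
        if np.any(np.isnan(self.log_weights)):
            raise InputError("log-weights must be finite or -inf")

    @property
    def weights(self) -> np.ndarray:
        w = np.exp(self.log_weights - np.max(self.log_weights))
        if self.normalized:
            return w / w.sum()
        return w

    def normalize(self) -> "WeightedEnsemble":
        from scipy.special import logsumexp

        lw = self.log_weights - logsumexp(self.log_weights)
        return WeightedEnsemble(self.samples, lw, normalized=True)
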