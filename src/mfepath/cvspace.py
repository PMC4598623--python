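"""Collective-variable space: named components with a diagonal metric.

A point in CV space is a plain float vector; :class:`CVSpace` carries the
component names and strictly positive metric scales that turn coordinate
differences into distances,

    d(a, b)^2 = sum_i [ s_i * (a_i - b_i) ]^2 .

The scales let heterogeneous components (quaternion components, an angstrom
z-coordinate, a delta-RMSD) share one Euclidean metric, prioritizing the
degrees of freedom that matter for path continuity.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass(frozen=True)
class CVSpace:
    """Names and metric scales of a collective-variable space."""

    names: tuple[str, ...]
    scales: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise InputError(f"duplicate CV component names: {names}")
        if len(names) == 0:
            raise InputError("CVSpace needs at least one component")
        scales = self.scales
        if scales is None:
            scales = np.ones(len(names))
        scales = np.asarray(scales, dtype=float)
        if scales.shape != (len(names),):
            raise InputError(
                f"scales shape {scales.shape} does not match {len(names)} names"
            )
        if not np.all(scales > 0):
            raise InputError("metric scales must be strictly positive")
        scales.setflags(write=False)
        object.__setattr__(self, "scales", scales)

    @property
    def dim(self) -> int:
        return len(self.names)

    def check_compatible(self, other: "CVSpace") -> None:
        if self.names != other.names:
            raise InputError(
                f"CV component names differ: {self.names} vs {other.names}"
            )

    def check_point(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.dim:
            raise InputError(
                f"point dimension {x.shape[-1]} does not match space dim {self.dim}"
            )
        return x

    def distance(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Metric distance between points (broadcasting over leading axes)."""
        a = self.check_point(a)
        b = self.check_point(b)
        d = (a - b) * self.scales
        return np.sqrt(np.sum(d * d, axis=-1))

    @classmethod
    def euclidean(cls, dim: int, prefix: str = "x") -> "CVSpace":
        """Unit-scale space with components ``x0..x{dim-1}``."""
        return cls(tuple(f"{prefix}{i}" for i in range(dim)))


@dataclass(frozen=True)
class CVVector:
    """A single named point in CV space."""

    space: CVSpace
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.space.check_point(np.atleast_1d(self.values)).copy()
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.space.names.index(name)])

    def distance(self, other: "CVVector") -> float:
        self.space.check_compatible(other.space)
        return float(self.space.distance(self.values, other.values))
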