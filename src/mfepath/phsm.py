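"""Post-hoc string method (PHSM): principal curves from weighted samples.

PHSM extracts an approximate minimum free-energy path from an *existing*
weighted sample set (e.g. reweighted umbrella-sampling data) instead of
running new simulations.  Starting from an initial string of N image
centers, each iteration

  (i)   assigns every sample to the Voronoi cell of its nearest image
        center in the CV metric, excluding samples farther than the tube
        cutoff r_c from every center (r_c sets the transition-tube
        thickness);
  (ii)  moves each center to the Boltzmann-weighted mean of its cell;
  (iii) reparametrizes the centers to N equidistant points along a Bezier
        curve.

Iterated to convergence, the string is a weighted principal curve: the
Boltzmann-averaged center of each perpendicular cell lies on (or near) the
curve.  Excluded samples are re-evaluated every iteration as the tube
moves.  Ties in the assignment break toward the lower image index.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .paths import StringPath, reparametrized_path
from .samples import SampleSet, WeightedEnsemble

EXCLUDED = -1


@dataclass
class TubeVoronoiAssignment:
    """Per-sample image label (or -1 for out-of-tube), with the cutoff used."""

    labels: np.ndarray
    r_c: float

    @property
    def n_excluded(self) -> int:
        return int(np.sum(self.labels == EXCLUDED))

    def cell(self, i: int) -> np.ndarray:
        return np.nonzero(self.labels == i)[0]


def assign_voronoi(samples: SampleSet, path: StringPath,
                   r_c: float = np.inf, chunk: int = 65536
                   ) -> TubeVoronoiAssignment:
    """Tube-restricted Voronoi assignment of samples to image centers.

    Distances use the CV-space metric (diagonal scales); a sample farther
    than ``r_c`` from every center is excluded.  Deterministic; exact ties
    go to the lower image index (np.argmin convention).
    """
    if samples.n_samples == 0:
        raise InputError("empty sample set")
    samples.space.check_compatible(path.space)
    if r_c <= 0:
        raise InputError("tube cutoff must be positive (np.inf allowed)")
    sc = samples.space.scales
    x = samples.values * sc
    c = path.centers * sc
    labels = np.empty(samples.n_samples, dtype=int)
    for lo in range(0, x.shape[0], chunk):
        xs = x[lo:lo + chunk]
        d2 = (
            np.sum(xs * xs, axis=1)[:, None]
            - 2.0 * xs @ c.T
            + np.sum(c * c, axis=1)[None, :]
        )
        # recompute the winning distance exactly to keep the tube cutoff sharp
        lab = np.argmin(d2, axis=1)
        dmin = np.linalg.norm(xs - c[lab], axis=1)
        lab[dmin > r_c] = EXCLUDED
        labels[lo:lo + chunk] = lab
    return TubeVoronoiAssignment(labels=labels, r_c=float(r_c))


def weighted_centers(weights: WeightedEnsemble,
                     assignment: TubeVoronoiAssignment,
                     n_images: int) -> tuple[np.ndarray, np.ndarray]:
    """Boltzmann-weighted mean of each Voronoi cell.

    Returns (centers (N, d), empty mask).  Empty cells are NaN in the
    output and flagged, never silently interpolated; the caller decides the
    fill policy.
    """
    w = weights.normalize().weights
    x = weights.samples.values
    lab = assignment.labels
    if lab.shape != (x.shape[0],):
        raise InputError("assignment does not match the sample set")
    centers = np.full((n_images, x.shape[1]), np.nan)
    empty = np.zeros(n_images, dtype=bool)
    for i in range(n_images):
        m = lab == i
        wi = w[m]
        if wi.size == 0 or wi.sum() == 0:
            empty[i] = True
            continue
        centers[i] = np.average(x[m], axis=0, weights=wi)
    if np.all(empty):
        raise InputError("all Voronoi cells are empty")
    return centers, empty


def _fill_empty(centers: np.ndarray, empty: np.ndarray,
                cyclic: bool) -> np.ndarray:
    """Empty cells interpolate between their bracketing filled neighbors.

    A single empty cell gets the midpoint of its two neighbors; runs of
    empty cells are spread linearly between the bracketing filled centers
    (index-proportional), which keeps consecutive centers distinct.  At
    open ends the nearest filled center's chain is extrapolated from the
    nearest two.
    """
    n = centers.shape[0]
    filled = np.nonzero(~empty)[0]
    out = centers.copy()
    for i in np.nonzero(empty)[0]:
        if cyclic:
            prev_candidates = filled[(filled - i) % n > 0]
            prev = prev_candidates[np.argmin((i - prev_candidates) % n)]
            nxt = filled[np.argmin((filled - i) % n)]
            gap = (nxt - prev) % n or n
            frac = ((i - prev) % n) / gap
        else:
            before = filled[filled < i]
            after = filled[filled > i]
            if before.size and after.size:
                prev, nxt = before[-1], after[0]
            elif after.size:  # run at the start: extrapolate inward pair
                prev, nxt = after[0], after[1] if after.size > 1 else after[0]
            else:
                prev = before[-2] if before.size > 1 else before[-1]
                nxt = before[-1]
            gap = max(nxt - prev, 1)
            frac = (i - prev) / gap
        out[i] = centers[prev] + frac * (centers[nxt] - centers[prev])
    return out


@dataclass
class PHSMResult:
    """Converged (or partial) PHSM string plus per-iteration diagnostics."""

    path: StringPath
    converged: bool
    n_iterations: int
    max_displacement: np.ndarray
    excluded_fraction: np.ndarray
    self_consistency_residual: float
    oscillation_detected: bool = False
    assignment: TubeVoronoiAssignment | None = None


def run_phsm(weights: WeightedEnsemble, initial_path: StringPath,
             r_c: float | None = None, max_iter: int = 100,
             tol: float | None = None, mode: str = "bezier",
             keep_assignment: bool = True) -> PHSMResult:
    """Iterate assign -> weighted centers -> reparametrize to convergence.

    Defaults: ``r_c`` is 3x the median nearest-neighbor center spacing
    (recomputed from the initial path); ``tol`` is 1e-3 of the mean
    inter-image spacing.  Convergence is max center displacement < tol;
    if the displacement is non-decreasing for 10 straight iterations an
    oscillation is reported and the partial result returned flagged.
    """
    samples = weights.samples
    path = initial_path
    n = path.n_images
    if r_c is None:
        r_c = 3.0 * _median_nn_spacing(path)
    if tol is None:
        tol = 1e-3 * path.mean_spacing()

    disps: list[float] = []
    excluded: list[float] = []
    converged = False
    oscillation = False
    assignment = None
    for it in range(1, max_iter + 1):
        assignment = assign_voronoi(samples, path, r_c)
        excluded.append(assignment.n_excluded / samples.n_samples)
        centers, empty = weighted_centers(weights, assignment, n)
        if np.any(empty):
            centers = _fill_empty(centers, empty, path.cyclic)
        if not path.cyclic:
            # an open string connects two *given* endpoints: pin them
            centers[0] = initial_path.centers[0]
            centers[-1] = initial_path.centers[-1]
        candidate = StringPath(centers, cyclic=path.cyclic, space=path.space,
                               metadata=dict(path.metadata))
        candidate = reparametrized_path(candidate, mode=mode)
        if not path.cyclic:
            candidate.centers[0] = initial_path.centers[0]
            candidate.centers[-1] = initial_path.centers[-1]
        mx, _ = candidate.displacement(path)
        disps.append(mx)
        path = candidate
        if mx < tol:
            converged = True
            break
        if len(disps) > 10 and np.all(np.diff(disps[-10:]) >= 0):
            oscillation = True
            warnings.warn(
                "PHSM displacement non-decreasing for 10 iterations; "
                "returning partial result",
                stacklevel=2,
            )
            break

    final_assignment = assign_voronoi(samples, path, r_c)
    residual = _self_consistency(weights, final_assignment, path)
    return PHSMResult(
        path=path,
        converged=converged,
        n_iterations=len(disps),
        max_displacement=np.asarray(disps),
        excluded_fraction=np.asarray(excluded),
        self_consistency_residual=residual,
        oscillation_detected=oscillation,
        assignment=final_assignment if keep_assignment else None,
    )


def _median_nn_spacing(path: StringPath) -> float:
    c = path.scaled_centers()
    seg = np.linalg.norm(np.diff(c, axis=0), axis=1)
    if path.cyclic:
        seg = np.append(seg, np.linalg.norm(c[0] - c[-1]))
    return float(np.median(seg))


def _self_consistency(weights: WeightedEnsemble,
                      assignment: TubeVoronoiAssignment,
                      path: StringPath) -> float:
    """Max metric distance of any cell's weighted mean from its center."""
    try:
        centers, empty = weighted_centers(weights, assignment, path.n_images)
    except InputError:
        return float("nan")
    ok = ~empty
    if not path.cyclic:
        ok[0] = ok[-1] = False  # pinned endpoints are not free cell means
    if not np.any(ok):
        return float("nan")
    d = path.space.distance(centers[ok], path.centers[ok])
    return float(np.max(d))


def nearest_sample_path(samples: SampleSet, path: StringPath
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per image, the index and time of the closest sample (ties: earliest).

    The selected samples reconstruct a representative trajectory along the
    string, e.g. to seed follow-up simulations.  Pure distance criterion;
    weights play no role.
    """
    if samples.n_samples == 0:
        raise InputError("empty sample set")
    samples.space.check_compatible(path.space)
    sc = samples.space.scales
    x = samples.values * sc
    order = np.argsort(samples.times, kind="stable")
    xo = x[order]
    idx = np.empty(path.n_images, dtype=int)
    for i, c in enumerate(path.centers * sc):
        d = np.linalg.norm(xo - c, axis=1)
        idx[i] = order[int(np.argmin(d))]  # argmin: earliest time on ties
    return idx, samples.times[idx]
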