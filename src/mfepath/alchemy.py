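"""Nonequilibrium alchemical free-energy estimators.

Bidirectional fast-growth thermodynamic integration (FGTI) produces
forward (state A -> B) and reverse (B -> A) nonequilibrium work samples.
Two estimators recover the free-energy difference from them:

* **BAR** — the Bennett acceptance ratio, the minimum-variance bidirectional
  estimator, solved self-consistently with its standard asymptotic
  (Fermi-function) variance expression;
* **CGI** — Crooks-Gaussian intersection: fit Gaussians to the forward and
  negated-reverse work distributions and take their intersection, with a
  replacement-bootstrap error.

A thermodynamic-cycle helper assembles relative binding and conformational
free energies of a point mutation from per-state transformation values for
the four corners of a transporter cycle (outward/inward-facing, apo/bound).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .errors import EstimationError, InputError

STATE_NAMES = ("OF_apo", "OF_bound", "IF_bound", "IF_apo")


@dataclass
class WorkSet:
    """Forward and reverse nonequilibrium work samples at inverse temperature beta.

    Sign convention: forward works W_f are the work done driving A -> B,
    reverse works W_r the work driving B -> A.  The Crooks relation reads
    P_f(W) / P_r(-W) = exp(beta (W - dG)).
    """

    forward: np.ndarray
    reverse: np.ndarray
    beta: float = 1.0

    def __post_init__(self) -> None:
        self.forward = np.atleast_1d(np.asarray(self.forward, dtype=float))
        self.reverse = np.atleast_1d(np.asarray(self.reverse, dtype=float))
        if self.forward.size == 0 or self.reverse.size == 0:
            raise InputError("both work directions must be non-empty")
        if not (np.all(np.isfinite(self.forward)) and np.all(np.isfinite(self.reverse))):
            raise InputError("work values must be finite")
        if self.beta <= 0:
            raise InputError("beta must be positive")

    def swapped(self) -> "WorkSet":
        """Exchange the roles of the two directions (dG -> -dG)."""
        return WorkSet(self.reverse.copy(), self.forward.copy(), self.beta)


def accumulate_work(dhdl: np.ndarray, schedule: np.ndarray) -> float:
    """FGTI work as a per-step rectangle sum W = sum_s (dH/dlambda)_s dlambda_s.

    ``schedule`` holds the coupling-parameter value at each step (same
    length as the dH/dlambda series, monotone); per-step increments are the
    successive differences, with the first step given the same width as the
    second (a uniform-schedule convention, exact for midpoint schedules).
    """
    dhdl = np.atleast_1d(np.asarray(dhdl, dtype=float))
    lam = np.atleast_1d(np.asarray(schedule, dtype=float))
    if dhdl.shape != lam.shape:
        raise InputError(
            f"series length {dhdl.shape[0]} != schedule length {lam.shape[0]}"
        )
    if dhdl.size == 1:
        raise InputError("need at least two steps to define increments")
    dl = np.diff(lam)
    if not (np.all(dl >= 0) or np.all(dl <= 0)):
        raise InputError("lambda schedule must be monotone")
    dlam = np.concatenate([[dl[0]], dl])
    return float(np.sum(dhdl * dlam))


def _bar_objective(dg: float, wf: np.ndarray, wr: np.ndarray, beta: float,
                   m_shift: float) -> float:
    # sum_F f(beta(W_f - dG) + lnNf/Nr) - sum_R f(beta(W_r + dG) - lnNf/Nr)
    xf = beta * (wf - dg) + m_shift
    xr = beta * (wr + dg) - m_shift
    return float(np.sum(expit(-xf)) - np.sum(expit(-xr)))


def bar_estimate(works: WorkSet) -> tuple[float, float]:
    """Bennett acceptance ratio: (dG, analytic standard error).

    dG solves the standard self-consistent BAR equation (bracketed
    root-finding, tolerance 1e-10).  The error is the asymptotic
    maximum-likelihood variance

        var(beta dG) = [ sum_i f_i (1 - f_i) ]^{-1} - 1/n_f - 1/n_r,

    with the Fermi factors evaluated at the solution over both work sets.
    A warning (with an overlap diagnostic) is issued when the forward and
    negated-reverse distributions barely overlap.
    """
    wf, wr, beta = works.forward, works.reverse, works.beta
    if wf.size < 2 or wr.size < 2:
        raise InputError("BAR needs at least 2 work values per direction")
    m_shift = np.log(wf.size / wr.size)
    lo = min(wf.min(), -wr.max()) - 1.0
    hi = max(wf.max(), -wr.min()) + 1.0
    flo = _bar_objective(lo, wf, wr, beta, m_shift)
    fhi = _bar_objective(hi, wf, wr, beta, m_shift)
    for _ in range(60):
        if flo * fhi <= 0:
            break
        span = hi - lo
        lo -= span
        hi += span
        flo = _bar_objective(lo, wf, wr, beta, m_shift)
        fhi = _bar_objective(hi, wf, wr, beta, m_shift)
    else:
        raise EstimationError("BAR root not bracketed")
    if flo == 0.0:
        dg = lo
    elif fhi == 0.0:
        dg = hi
    else:
        dg = brentq(
            _bar_objective, lo, hi, args=(wf, wr, beta, m_shift), xtol=1e-10
        )

    x_all = np.concatenate([beta * (wf - dg) + m_shift, beta * (wr + dg) - m_shift])
    f = expit(-x_all)
    denom = np.sum(f * (1.0 - f))
    overlap = denom / x_all.size
    if overlap < 1e-4:
        warnings.warn(
            f"poor forward/reverse work overlap (mean Fermi variance {overlap:.2e}); "
            "BAR error estimate unreliable",
            stacklevel=2,
        )
    var = 1.0 / denom - 1.0 / wf.size - 1.0 / wr.size
    err = np.sqrt(max(var, 0.0)) / beta
    return float(dg), float(err)


def _gaussian_intersection(mu_f: float, var_f: float, mu_r: float,
                           var_r: float,
                           var_tol: float = 1e-12) -> tuple[float, bool]:
    """Intersection of two Gaussian pdfs lying between the means.

    Returns (point, fallback_flag).  Variances equal within ``var_tol``
    (relative) give the midpoint; otherwise the quadratic root between the
    means is chosen, or, if no real root lies between them, the root
    nearest the midpoint (flagged).
    """
    mid = 0.5 * (mu_f + mu_r)
    if abs(var_f - var_r) <= var_tol * max(var_f, var_r):
        return mid, False
    a = 0.5 * (1.0 / var_r - 1.0 / var_f)
    b = mu_f / var_f - mu_r / var_r
    c = 0.5 * (mu_r**2 / var_r - mu_f**2 / var_f) + 0.5 * np.log(var_r / var_f)
    disc = b * b - 4 * a * c
    if disc < 0:
        return mid, True
    r1 = (-b + np.sqrt(disc)) / (2 * a)
    r2 = (-b - np.sqrt(disc)) / (2 * a)
    lo, hi = min(mu_f, mu_r), max(mu_f, mu_r)
    between = [r for r in (r1, r2) if lo <= r <= hi]
    if between:
        return min(between, key=lambda r: abs(r - mid)), False
    return min((r1, r2), key=lambda r: abs(r - mid)), True


def cgi_estimate(works: WorkSet, n_boot: int = 1000,
                 seed: int = 0) -> tuple[float, float]:
    """Crooks-Gaussian intersection: (dG, bootstrap standard error).

    Gaussians are fitted to the forward works and to the negated reverse
    works; dG is their pdf intersection between the means (the midpoint
    when the two sample variances are statistically indistinguishable —
    the quadratic intersection of two near-identical Gaussians is an
    unstable far root that would dominate the bootstrap).  The error is
    the standard deviation of the estimate over ``n_boot`` resamples with
    replacement, drawn independently for each direction.
    """
    wf = works.forward
    wrn = -works.reverse
    if wf.size < 2 or wrn.size < 2:
        raise InputError("CGI needs at least 2 work values per direction")
    # variances equal within sampling noise: |ln ratio| ~ sqrt(2/n) each
    var_tol = 3.0 * np.sqrt(2.0 / wf.size + 2.0 / wrn.size)

    def point(f: np.ndarray, r: np.ndarray) -> float:
        vf = max(f.var(ddof=1), 1e-300)
        vr = max(r.var(ddof=1), 1e-300)
        val, fell = _gaussian_intersection(f.mean(), vf, r.mean(), vr,
                                           var_tol=var_tol)
        if fell:
            warnings.warn("no Gaussian intersection between the means; "
                          "using nearest quadratic root", stacklevel=3)
        return val

    dg = point(wf, wrn)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_boot):
            bf = wf[rng.integers(0, wf.size, wf.size)]
            br = wrn[rng.integers(0, wrn.size, wrn.size)]
            boots[i] = point(bf, br)
    return float(dg), float(boots.std(ddof=1))


def jarzynski_estimate(works: WorkSet) -> float:
    """One-sided exponential-average estimate from the forward works only."""
    wf = works.forward
    beta = works.beta
    return float(-(logsumexp(-beta * wf) - np.log(wf.size)) / beta)


@dataclass
class CycleStates:
    """Per-state mutation free energies for the four transporter states.

    ``dg`` maps each of OF_apo, OF_bound, IF_bound, IF_apo to the
    wild-type -> mutant transformation free energy in that state;
    ``err`` carries the matching standard errors (>= 0).
    """

    dg: dict[str, float]
    err: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in STATE_NAMES if s not in self.dg]
        if missing:
            raise InputError(f"missing states: {missing}")
        if not self.err:
            self.err = {s: 0.0 for s in STATE_NAMES}
        if any(self.err.get(s, 0.0) < 0 for s in STATE_NAMES):
            raise InputError("errors must be nonnegative")


def cycle_ddg(states: CycleStates) -> dict[str, tuple[float, float]]:
    """Assemble relative binding/conformational free energies of a mutation.

    Returns a mapping with (value, error-in-quadrature) pairs:

    * ``ddg_binding_IF``  = dG(IF_bound) - dG(IF_apo)
    * ``ddg_binding_OF``  = dG(OF_bound) - dG(OF_apo)
    * ``ddg_conf_apo``    = dG(OF_apo)  - dG(IF_apo)
    * ``ddg_conf_bound``  = dG(OF_bound) - dG(IF_bound)

    These satisfy the cycle-closure identity
    ddg_binding_OF - ddg_binding_IF = ddg_conf_bound - ddg_conf_apo.
    """
    g = states.dg
    e = states.err

    def diff(a: str, b: str) -> tuple[float, float]:
        return (
            float(g[a] - g[b]),
            float(np.hypot(e.get(a, 0.0), e.get(b, 0.0))),
        )

    return {
        "ddg_binding_IF": diff("IF_bound", "IF_apo"),
        "ddg_binding_OF": diff("OF_bound", "OF_apo"),
        "ddg_conf_apo": diff("OF_apo", "IF_apo"),
        "ddg_conf_bound": diff("OF_bound", "IF_bound"),
    }
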