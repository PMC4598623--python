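# Methods

This note documents the models, estimators and numerical choices behind
mfepath, in the spirit of a methods appendix: what is computed, under what
assumptions, with which defaults, and where the edges are.

## Effective dynamics and the toy engine

The working assumption of the whole toolkit is that the slow dynamics of a
large molecular system can be projected onto a low-dimensional collective
variable (CV) space ζ, where it behaves as Brownian motion on an effective
potential G(ζ) — the potential of mean force (PMF) — with some diffusion
tensor.  The toy engine realizes exactly this model world: analytic
surfaces standing in for G, an Euler–Maruyama overdamped-Langevin
propagator

x_{n+1} = x_n − D β ∇U Δt + √(2 D Δt) ξ_n,

and quadrature oracles for the exact PMF.  Units are reduced (k_B T = 1 at
β = 1); diffusion is a per-dimension constant (a full position-dependent
tensor is out of scope).  The zero-noise limit (`noise_scale=0`) gives
deterministic steepest descent, used by the string-method fixed-point
tests.

**Integrator bias.**  Euler–Maruyama samples a stationary variance
inflated by 2/(2 − κΔt) for a harmonic mode of stiffness κ.  All shipped
studies choose Δt so that κ_total Δt ≲ 0.15 for the stiffest biased mode,
keeping this bias below the statistical resolution.  This is the binding
constraint on the default timesteps (e.g. 0.0015 for the double-well
study, whose windows must out-stiffen the |U″| = 32 barrier curvature).

**Landscapes.**  `double_well_1d` has minima at ±a and barrier b by
construction.  `curved_valley_2d` is a flat semicircular valley
½κ_t(r−R)² (plus a half-plane penalty keeping the lower arc out of play),
so the arc is exactly the minimum free-energy path — the oracle for the
string methods.  `cyclic_channels_2d` is a ring ½κ_r(r−R)² + V(θ) with
V(θ) = sin²θ (c₀ + c₁ sinθ): two basins at θ = 0, π joined by two channels
whose barriers differ by b_high − b_low (default 1.5 vs 5.0, a 3.5 k_BT
gap — the motif of a substrate-lowered transition barrier on a closed
thermodynamic cycle).  For b_high < 3 b_low the four ring stationary
points are the only ones.

## Orientation quaternions

The optimal rotation superimposing a centered coordinate group on a
centered reference is computed by the symmetric 4×4 key-matrix eigenvalue
method; the top eigenvector is the quaternion, and the top eigenvalue
gives the minimum RMSD without applying the rotation.  Quaternions are
stored on the canonical hemisphere (q₀ ≥ 0, ties broken by the first
nonzero component), which makes Euclidean operations on components
(metrics, PCA) single-valued; every consumer is nevertheless invariant
under sign flips (double-cover safety, property-tested).

Angular separation uses Ω(P, Q) = arccos |P·Q| throughout — the
implementation-level estimate of the geodesic — and the orientation
restraint is E = ½ k Ω².  Its gradient is returned projected onto the
tangent space of the unit sphere (the radial component does not change
the orientation and would otherwise mask the vanishing of the force at
Ω → 0); the arccos derivative is clamped via |P·Q| ∈ [ε, 1−ε], ε = 1e−12.
For Ω < 0.1 the small-angle surrogate ½k|P−Q|² agrees within 5% (the
chord–arc relation 2−2cosΩ = Ω²(1 − Ω²/12) bounds the relative gap by
Ω²/12).

Helix roll axes are dominant principal axes of the Cα covariance,
sign-fixed by a positive projection on the N→C end-to-end vector — without
that convention the interhelical angle is ambiguous between α and 180°−α.
Dual-reference quaternion pairs (one per end state) are treated as
independent CV components; no kink model is attempted.

## BEUS

One replica per window; neighbor pairs (alternating even/odd parity, and
across the seam for cyclic ladders) attempt bias exchanges with
Δ = β[(U_i(ζ_j) + U_j(ζ_i)) − (U_i(ζ_i) + U_j(ζ_j))], accepted with
min(1, e^(−Δ)).  Exchanges permute the replica→window assignment only, so
replica trajectories remain continuous — the property the
autocorrelation analysis relies on.  With the exchange interval set to
infinity the scheme is plain umbrella sampling, and the reweighted results
are invariant to exchanges within statistical error (tested).  An optional
transition-tube restraint (half-harmonic beyond a cutoff distance from the
window polyline) mirrors the practice of confining a substrate to a
cylinder around the permeation pathway.

## Reweighting

With T_i samples under bias U_i, the binless self-consistent equations

exp(−βF_i) = Σ_t exp(−βU_i(ζ_t)) / D_t,  D_t = Σ_j T_j exp(βF_j − βU_j(ζ_t))

define the perturbed free energies (anchored F₀ = 0) and the unnormalized
sample weights w_t = 1/D_t.  They are the stationarity conditions of a
convex objective, which is minimized by L-BFGS with an analytic gradient
and then polished by fixed-point sweeps to the stated tolerance — plain
iteration alone relaxes across long window ladders with a near-unit
contraction factor and can need thousands of sweeps.  All accumulations
are in log space (log-sum-exp); 150-window problems underflow otherwise.
An explicit alternating weights/free-energies iteration is also provided;
both routes agree to solver tolerance (tested).

**Bayesian route.**  Writing f_i = T_i exp(βF_i), the Gibbs sampler draws

f_i | w ~ Gamma(shape T_i, rate Σ_t w_t e^(−βU_i(ζ_t))),
w_t | f ~ Gamma(shape 1, rate Σ_i f_i e^(−βU_i(ζ_t))),

renormalizing the weights each sweep.  The stationary point of these
conditionals reproduces the maximum-likelihood equations, which is the
internal guard that this conjugate scheme is the right reading; posterior
means agree with the self-consistent solution within posterior spread on
all fixtures (tested), and the posterior standard deviation scales as
n^(−1/2).  Priors are improper flat (the shape parameters above carry all
the information).

**PMF projection.**  G(ξ) = −β⁻¹ ln Σ_t w_t K(ξ − ξ_t) on a grid, with a
top-hat (histogram) kernel by default and a Gaussian kernel (Silverman
bandwidth) for 1-D profiles.  Bins whose effective count
(Σw)²/Σw² falls below a floor are masked, never extrapolated — the
estimator is meaningless where the projected sampling has not converged.
Profiles are anchored to zero at the occupied minimum.  When a projected
estimate is compared against a pointwise reference, the reference must be
bin-averaged over the Boltzmann factor first: on steep profiles the
within-bin variation of G reaches several k_BT and a point-value
comparison fails for purely geometric reasons.

**Stiff springs.**  Windows of spring constant k riding a 1-D pathway
measure F(s), the Gaussian smoothing of G(s) with variance 1/(βk).
Inverting to first order in 1/k,

G(s) = F(s) + F′(s)²/(2k) − F″(s)/(2βk),

with second-order central differences (one-sided at open ends, wrapped for
cyclic paths; ≥5 images required).  The per-image |correction| is
reported so the user can check the approximation a posteriori — it should
be small against the statistical error.  On quadratic profiles the
corrected G matches the exact Gaussian deconvolution within 1% for
k/κ ≥ 100, and the correction magnitude scales as 1/k (both tested).

## String methods

**SMwST** iterates: equilibrate several copies per image under a harmonic
restraint at the image center, release them for a short unbiased swarm,
move each center to the mean swarm endpoint (the drift estimate), and
reparametrize the string to equidistant images.  Open strings pin both
endpoints; cyclic strings are free.  Convergence is declared when the RMS
image displacement stays below a tolerance (default 1% of the mean
inter-image spacing) for 5 consecutive iterations.  The drift standard
error scales as (copies)^(−1/2) (tested).

**PHSM** extracts a principal curve from an existing weighted sample set:
(i) tube-Voronoi assignment of samples to the nearest image center in the
CV metric (diagonal scales; samples farther than r_c from every center
are excluded and re-evaluated each iteration; ties go to the lower
index); (ii) Boltzmann-weighted cell means become the new centers (empty
cells interpolate between bracketing filled neighbors — never silently
retained); (iii) Bézier equidistant reparametrization.  Open strings pin
the two given endpoints, matching the method's definition as connecting
two given points; without pinning the string retracts tangentially along
the data cloud.  The default r_c is 3× the median nearest-neighbor center
spacing — appropriate once the string is near the data, but an initial
path far from the sampled tube should use a large or infinite r_c, or the
tube excludes the very data the string must move toward.

**Reparametrization.**  The cell centers are the raw control points of a
single global Bézier curve, evaluated by de Casteljau's algorithm, with
arc length accumulated over a dense evaluation; closed paths duplicate
the wrap-around control point.  A raw-control Bézier does not interpolate
its interior controls: for n points sampled from a curve of curvature
κ_c, the curve is pulled inward by ≈ κ_c·x(1−x)/(2n) in the curve
parameter (Bernstein approximation error) — about 0.04 reduced units for
33 images on the unit semicircle.  The data-driven center updates push
back each iteration, so the converged string sits within that bias of the
true valley; choosing ≥33 images keeps it inside the 0.05 tube used by
the recovery checks.  More images shrink this bias but shrink the end
cells too, letting sampling spill-over beyond pinned endpoints pull the
near-end images off the path; the default study sizes (33 images for
PHSM, 49 for SMwST on the semicircular valley) balance the two.  An
interpolating cubic-spline mode (`mode="spline"`, flagged in the path
metadata) avoids the corner-cutting entirely and is the practical choice
for very long strings (N > 64); the global Bézier remains the default.

## Uncertainty

Integrated autocorrelation times use an FFT autocorrelation with the
first-negative-crossing window cutoff, computed on continuous replica
trajectories (an upper bound for per-window times).  The statistical
inefficiency g = 1 + 2τ/τ_lag inflates the variance of any mean of
correlated points; path averages report sd·√(g/N) per image.  Block
bootstrapping partitions each replica's retained time into equal blocks
(never spanning replicas), then either resamples blocks with replacement
(classical) or draws flat-Dirichlet block weights (Bayesian, the
default); the free energies themselves are bootstrapped by re-solving the
sample-weighted self-consistent equations per replicate, warm-started
from the full-data solution.  On AR(1) fixtures, blocks much longer than
τ reproduce the inefficiency-corrected analytic error of the mean while
single-sample blocks underestimate it (tested).

## Work-based estimators

Fast-growth work is the per-step rectangle sum Σ (∂H/∂λ) Δλ over a
monotone switching schedule.  The Crooks-consistent Gaussian fixture
draws forward works from N(ΔG + βσ²/2, σ²) and reverse works from
N(−ΔG + βσ²/2, σ²) — the unique equal-variance pair satisfying the
fluctuation relation — so ΔG is known exactly.

**BAR** solves the standard self-consistent equation by bracketed
root-finding (tolerance 1e−10) and reports the asymptotic
maximum-likelihood variance [Σ f(1−f)]⁻¹ − 1/n_f − 1/n_r (Fermi factors
at the solution), with a warning when the work distributions barely
overlap.  **CGI** fits Gaussians to the forward and negated-reverse works
and intersects them: midpoint of means for equal variances, otherwise the
quadratic root between the means.  When the two sample variances are
statistically indistinguishable (|ln ratio| within ~3√(2/n_f + 2/n_r))
the midpoint branch is taken deliberately: the quadratic intersection of
two near-identical Gaussians is a far, noise-dominated root that would
otherwise dominate the bootstrap error.  If no real root lies between the
means, the root nearest the midpoint is used and flagged.  CGI equals BAR
exactly in the σ → 0 limit, and both recover the fixture ΔG within
combined errors across a parameter sweep (tested).

Cycle assembly takes per-state mutation free energies for the four
corners (OF/IF × apo/bound) and returns relative binding and
conformational ΔΔG values with errors in quadrature; the closure identity
ΔΔG_bind(OF) − ΔΔG_bind(IF) = ΔΔG_conf(bound) − ΔΔG_conf(apo) holds
algebraically and is asserted exactly.

## What the toy fixtures do and do not show

The synthetic generators emulate the *statistical* structure of the real
problem: window-biased correlated samples from a known stationary
distribution, path-shaped data clouds, Crooks-consistent bidirectional
work.  Passing tests therefore demonstrate estimator correctness —
recovery of planted free energies, paths, barriers, rates and error
magnitudes.  They do not exercise force-field physics, CV quality for a
real protein, metastability on rugged landscapes, or position-dependent
diffusion; conclusions about a specific molecular system still require
judgment about whether its slow degrees of freedom are captured by the
chosen CVs.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (identical seeds give
bit-identical sample sets).  Shipped study sizes — 11–24 windows with
10⁴ samples each for reweighting recovery, 10⁵ total samples for PMF
recovery, a 32-image closed cycle with 2,500 samples/window for the
end-to-end study, 40 bootstrap replicates — were chosen once as the
smallest sets that leave the statistical checks comfortably resolved;
each study completes in seconds to a few minutes on one CPU.
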