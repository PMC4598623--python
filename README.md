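# mfepath

**mfepath** is a toolkit for mapping the conformational free-energy
landscape of large-scale molecular transitions — the kind of problem posed
by secondary-transporter cycles, where a protein alternates between
inward-facing (IF) and outward-facing (OF) states with and without a bound
substrate.  It implements, end to end and at desk scale, an
enhanced-sampling methodology built from:

- **orientation-quaternion collective variables (CVs)**: the rigid-body
  orientation of a helix or domain relative to a reference structure,
  encoded as the best-fit unit quaternion *Q*, with the geodesic
  Ω(*P*, *Q*) = arccos |*P* · *Q*| as the distance between orientations
  and ½ *k* Ω² as the biasing restraint; plus a substrate z-coordinate,
  a two-reference ΔRMSD progress variable, interhelical roll-axis angles,
  and PCA of quaternion vector parts (QPC);
- **bias-exchange umbrella sampling (BEUS)**: umbrella windows along a
  (possibly cyclic) pathway whose biases are exchanged between neighbors
  with the Metropolis rule, so replicas diffuse through the ladder;
- **string methods**: SMwST (swarms of short trajectories iteratively
  restrained, released, and re-centered) and the *post-hoc* string method
  (PHSM), which extracts an approximate minimum free-energy path from an
  *existing* weighted sample set by iterated tube-Voronoi assignment,
  Boltzmann-weighted cell centers, and Bézier equidistant
  reparametrization;
- **reweighting**: the binless self-consistent (WHAM-family) equations for
  per-window perturbed free energies *F_i* and per-sample weights, a
  Bayesian Gibbs sampler with Gamma conditionals as the
  overfitting-resistant alternative, kernel projection of the PMF onto any
  CV, and the stiff-spring correction
  G(s) = F(s) + F′²/2k − F″/2βk along a path;
- **uncertainty**: integrated autocorrelation times, the statistical
  inefficiency g = 1 + 2τ/τ_lag, and (Bayesian) block bootstrapping;
- **nonequilibrium alchemistry**: fast-growth work accumulation, the
  Bennett acceptance ratio (BAR) with its analytic error, the
  Crooks-Gaussian intersection (CGI) with a replacement bootstrap, and
  thermodynamic-cycle ΔΔG assembly for relative binding/conformational
  free energies of a mutation.

Because all-atom simulations are out of reach of a test suite, the package
ships a **toy engine**: analytic model landscapes (a double well, a
semicircular valley, and a closed ring with two channels of unequal
barrier height) with an overdamped-Langevin propagator, quadrature PMF
oracles, and Crooks-consistent Gaussian work generators.  Every method can
therefore be validated against closed forms and planted parameters.

## Worked example

Recover the free-energy profile of a closed two-channel cycle — the toy
analogue of an IF↔OF transition with and without substrate, where one
channel's barrier is 3.5 k_BT lower than the other's:

```python
import numpy as np
from mfepath.workflows import cyclic_channel_study

res = cyclic_channel_study(seed=11)
print(f"high barrier  {res.barrier_high:.2f} kT")
print(f"low barrier   {res.barrier_low:.2f} kT")
print(f"gap           {res.barrier_gap:.2f} +- {res.barrier_gap_error:.2f} kT"
      f"  (planted {res.planted_gap})")
print(f"max stiff-spring correction {res.correction_max:.2f} kT")
```

which prints (seed 11):

```
high barrier  4.97 kT
low barrier   1.47 kT
gap           3.50 +- 0.09 kT  (planted 3.5)
max stiff-spring correction 0.29 kT
```

The study runs BEUS over a closed 32-image window ladder, reweights with
the Gibbs sampler, extracts the cycle pathway with PHSM, converts the
perturbed free energies to the PMF along the path with the stiff-spring
correction, and propagates block-bootstrap errors into the barrier table.
The recovered inter-channel gap (3.50 ± 0.09 k_BT) matches the planted
3.5 k_BT of the landscape.

A command-line interface mirrors the pipeline stages
(`mfep cv|toy|beus|smwst|phsm|reweight|err|alchemy`); run
`mfep --help` for the tour.

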