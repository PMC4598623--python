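"""Reweighting: WHAM fixed point, Gibbs posterior, PMFs, stiff springs."""
import numpy as np
import pytest

from mfepath.biases import HarmonicBias
from mfepath.cvspace import CVSpace
from mfepath.errors import InputError
from mfepath.reweight import (
    PerturbedFreeEnergies,
    find_extrema,
    gibbs_reweight,
    iterative_solve,
    project_pmf,
    sample_weights,
    state_free_energies,
    stiff_spring_correct,
    wham_solve,
)
from mfepath.samples import SampleSet, WeightedEnsemble

from conftest import harmonic_window_data

KAPPA, K = 1.0, 4.0
CENTERS = np.linspace(-2.5, 2.5, 11)


def analytic_f(centers, kappa=KAPPA, k=K):
    """Closed-form perturbed free energies of harmonic windows on 1/2 kx^2.

    F(c) = 1/2 * kappa k / (kappa + k) * c^2 + const (Gaussian convolution).
    """
    f = 0.5 * kappa * k / (kappa + k) * centers**2
    return f - f[0]


def make_uniform_samples(values_per_window, centers, seed=0):
    rng = np.random.default_rng(seed)
    vals, wins = [], []
    for i, c in enumerate(centers):
        v = rng.normal(c, 0.5, size=values_per_window)
        vals.append(v)
        wins.append(np.full(values_per_window, i))
    n = values_per_window
    return SampleSet(
        space=CVSpace.euclidean(1),
        times=np.tile(np.arange(n, dtype=float) + 1, centers.size),
        values=np.concatenate(vals)[:, None],
        window=np.concatenate(wins),
        replica=np.repeat(np.arange(centers.size), n),
    )


class TestWham:
    def test_identical_windows_give_equal_f(self):
        centers = np.zeros(3)
        ss = make_uniform_samples(500, centers)
        biases = [HarmonicBias(np.zeros(1), 1.0) for _ in range(3)]
        f = wham_solve(ss, biases, 1.0)
        assert np.allclose(f.f, 0.0, atol=1e-9)

    def test_flat_surface_symmetric_windows_equal_f(self):
        """Flat PMF: perturbed free energies differ only by the same integral."""
        rng = np.random.default_rng(3)
        centers = np.linspace(-1, 1, 5)
        n = 4000
        vals = np.concatenate(
            [rng.normal(c, np.sqrt(1.0 / 4.0), n) for c in centers]
        )
        ss = SampleSet(
            space=CVSpace.euclidean(1),
            times=np.tile(np.arange(n, dtype=float) + 1, 5),
            values=vals[:, None],
            window=np.repeat(np.arange(5), n),
            replica=np.repeat(np.arange(5), n),
        )
        biases = [HarmonicBias(np.array([c]), 4.0) for c in centers]
        f = wham_solve(ss, biases, 1.0)
        assert np.max(np.abs(f.f)) < 0.1  # equal within statistical error

    def test_harmonic_closed_form_within_3_se(self, harmonic_beus):
        """Gaussian-convolution closed form at 1e4 samples/window."""
        ss, biases, _ = harmonic_beus
        f = wham_solve(ss, biases, 1.0)
        expect = analytic_f(CENTERS)
        post = gibbs_reweight(ss, biases, 1.0, n_draws=120, burn_in=40,
                              seed=99)
        g_inflation = np.sqrt(3.0)  # residual correlation margin at stride 20
        se = np.maximum(post.f_sd, 1e-3) * g_inflation
        assert np.all(np.abs(f.f - expect) < 3 * se)

    def test_iterative_route_agrees(self, harmonic_beus):
        ss, biases, _ = harmonic_beus
        f1 = wham_solve(ss, biases, 1.0, tol=1e-10)
        _, f2 = iterative_solve(ss, biases, 1.0, tol=1e-10)
        assert np.max(np.abs(f1.f - f2.f)) < 1e-8

    def test_empty_window_rejected(self):
        ss = make_uniform_samples(10, np.array([0.0, 1.0]))
        biases = [HarmonicBias(np.array([c]), 1.0) for c in (0.0, 1.0, 5.0)]
        with pytest.raises(InputError):
            wham_solve(ss, biases, 1.0)

    def test_no_overlap_warns(self):
        ss = make_uniform_samples(200, np.array([0.0, 50.0]), seed=5)
        biases = [HarmonicBias(np.array([c]), 4.0) for c in (0.0, 50.0)]
        with pytest.warns(UserWarning, match="no sampled region"):
            wham_solve(ss, biases, 1.0, max_iter=100000)


class TestWeights:
    def test_single_window_center_samples_equal_weights(self):
        n = 50
        ss = SampleSet(
            space=CVSpace.euclidean(1),
            times=np.arange(n, dtype=float),
            values=np.zeros((n, 1)),
            window=np.zeros(n, dtype=int),
            replica=np.zeros(n, dtype=int),
        )
        biases = [HarmonicBias(np.zeros(1), 2.0)]
        f = wham_solve(ss, biases, 1.0)
        w = sample_weights(ss, biases, f, 1.0)
        assert np.allclose(w.weights, 1.0 / n)

    def test_window_duplication_invariance(self, harmonic_beus):
        """Splitting one window's samples into two identical windows does
        not change the weights."""
        ss, biases, _ = harmonic_beus
        f = wham_solve(ss, biases, 1.0)
        w1 = sample_weights(ss, biases, f, 1.0)
        # duplicate window 0's bias; relabel half of window 0 as window 11
        window2 = ss.window.copy()
        idx0 = np.nonzero(window2 == 0)[0]
        window2[idx0[: idx0.size // 2]] = len(biases)
        ss2 = SampleSet(ss.space, ss.times, ss.values, window2, ss.replica)
        biases2 = biases + [biases[0]]
        f2 = wham_solve(ss2, biases2, 1.0)
        w2 = sample_weights(ss2, biases2, f2, 1.0)
        assert np.max(np.abs(w1.weights - w2.weights)) < 1e-6 * w1.weights.max()

    def test_gauge_invariance_of_weights(self, harmonic_beus):
        """Shifting all F_i by a constant leaves weights unchanged exactly."""
        ss, biases, _ = harmonic_beus
        f = wham_solve(ss, biases, 1.0)
        w1 = sample_weights(ss, biases, f, 1.0)
        shifted = PerturbedFreeEnergies(f.f + 0.0, f.beta)
        shifted.f = f.f + 7.3  # bypass anchoring to test the gauge directly
        w2 = sample_weights(ss, biases, shifted, 1.0)
        assert np.allclose(w1.weights, w2.weights, rtol=1e-12)

    def test_weighted_histogram_recovers_boltzmann(self, harmonic_beus):
        """exp(-beta G) recovered within 3 sigma multinomial bands."""
        ss, biases, _ = harmonic_beus
        f = wham_solve(ss, biases, 1.0)
        w = sample_weights(ss, biases, f, 1.0)
        edges = np.linspace(-2, 2, 21)
        hist, _ = np.histogram(ss.values[:, 0], bins=edges, weights=w.weights)
        hist2, _ = np.histogram(ss.values[:, 0], bins=edges,
                                weights=w.weights**2)
        centers = 0.5 * (edges[1:] + edges[:-1])
        p = np.exp(-0.5 * centers**2)
        p = p / p.sum() * hist.sum()
        n_eff = np.where(hist2 > 0, hist**2 / hist2, 1.0)
        sigma = np.maximum(hist / np.sqrt(n_eff) * np.sqrt(3.0), 1e-6)
        assert np.all(np.abs(hist - p) < 3.5 * sigma)


class TestGibbs:
    def test_single_window_posterior_trivially_anchored(self):
        ss = make_uniform_samples(300, np.array([0.0]))
        biases = [HarmonicBias(np.zeros(1), 1.0)]
        post = gibbs_reweight(ss, biases, 1.0, n_draws=20, burn_in=5, seed=1)
        assert np.allclose(post.f_draws, 0.0)

    def test_posterior_mean_matches_wham(self, harmonic_beus):
        ss, biases, _ = harmonic_beus
        f = wham_solve(ss, biases, 1.0)
        post = gibbs_reweight(ss, biases, 1.0, n_draws=150, burn_in=50, seed=7)
        assert np.all(
            np.abs(post.f_mean - f.f) < 2 * np.maximum(post.f_sd, 1e-3)
        )

    def test_seed_invariance_of_posterior_mean(self, harmonic_beus):
        """Different seeds agree within combined Monte-Carlo error."""
        ss, biases, _ = harmonic_beus
        p1 = gibbs_reweight(ss, biases, 1.0, n_draws=100, burn_in=30, seed=1)
        p2 = gibbs_reweight(ss, biases, 1.0, n_draws=100, burn_in=30, seed=2)
        mc = (p1.f_sd + p2.f_sd) / np.sqrt(100) * 6 + 1e-3
        assert np.all(np.abs(p1.f_mean - p2.f_mean) < mc * 3)

    def test_posterior_sd_scales_inverse_sqrt_n(self):
        """Posterior sd ~ n^-1/2 across 1e3 -> 1e4 samples/window."""
        sds = []
        ns = [1000, 4000, 16000]
        for n in ns:
            ss, biases, _ = harmonic_window_data(
                samples_per_window=n, seed=300 + n,
                centers=np.linspace(-1.5, 1.5, 5),
            )
            post = gibbs_reweight(ss, biases, 1.0, n_draws=100, burn_in=30,
                                  seed=n)
            sds.append(np.mean(post.f_sd[1:]))
        slope = np.polyfit(np.log(ns), np.log(sds), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)


class TestProjectPMF:
    def test_uniform_weights_uniform_xi_flat(self):
        rng = np.random.default_rng(0)
        xi = rng.uniform(0, 1, size=200_000)
        ss = make_uniform_samples(10, np.array([0.0, 1.0]))
        we = WeightedEnsemble(
            SampleSet(
                space=CVSpace.euclidean(1),
                times=np.arange(xi.size, dtype=float),
                values=xi[:, None],
                window=np.zeros(xi.size, dtype=int),
                replica=np.zeros(xi.size, dtype=int),
            ),
            np.zeros(xi.size),
        ).normalize()
        pmf = project_pmf(we, xi, 1.0, np.linspace(0, 1, 11))
        assert np.nanmax(pmf.g) < 0.05

    def test_harmonic_projection_recovers_potential(self, harmonic_beus):
        ss, biases, _ = harmonic_beus
        f = wham_solve(ss, biases, 1.0)
        w = sample_weights(ss, biases, f, 1.0)
        grid = np.linspace(-2, 2, 25)
        pmf = project_pmf(w, ss.values[:, 0], 1.0, grid)
        cen = pmf.centers[0][~pmf.mask]
        expect = 0.5 * cen**2
        expect -= expect.min()
        resid = pmf.g[~pmf.mask] - expect
        sigma = 1.0 / np.sqrt(pmf.occupancy[~pmf.mask]) * np.sqrt(3.0)
        assert np.all(np.abs(resid - resid.mean()) < 3.5 * np.maximum(sigma, 0.02))

    def test_gaussian_kernel_close_to_histogram(self, harmonic_beus):
        ss, biases, _ = harmonic_beus
        f = wham_solve(ss, biases, 1.0)
        w = sample_weights(ss, biases, f, 1.0)
        grid = np.linspace(-1.5, 1.5, 16)
        ph = project_pmf(w, ss.values[:, 0], 1.0, grid, kernel="histogram")
        pg = project_pmf(w, ss.values[:, 0], 1.0, grid, kernel="gaussian")
        ok = ~ph.mask
        assert np.nanmax(np.abs(ph.g[ok] - pg.g[ok])) < 0.15

    def test_2d_histogram_masks_unoccupied(self, rng):
        xy = rng.normal(size=(5000, 2)) * 0.3
        ss = SampleSet(
            space=CVSpace.euclidean(2),
            times=np.arange(5000, dtype=float),
            values=xy,
            window=np.zeros(5000, dtype=int),
            replica=np.zeros(5000, dtype=int),
        )
        we = WeightedEnsemble(ss, np.zeros(5000)).normalize()
        with pytest.warns(UserWarning, match="occupancy floor"):
            pmf = project_pmf(
                we, xy, 1.0,
                (np.linspace(-3, 3, 20), np.linspace(-3, 3, 20)),
                occupancy_floor=2.0,
            )
        assert pmf.mask.any()
        assert np.all(np.isnan(pmf.g[pmf.mask]))
        assert np.nanmin(pmf.g) == pytest.approx(0.0)


class TestStiffSpring:
    def test_constant_f_zero_correction(self):
        f = PerturbedFreeEnergies(np.full(9, 2.0) * 0, 1.0)
        g, corr = stiff_spring_correct(f, np.linspace(0, 1, 9), k=100.0)
        assert np.allclose(corr, 0.0)
        assert np.allclose(g, f.f)

    @pytest.mark.parametrize("k", [100.0, 1000.0])
    def test_quadratic_deconvolution_closed_form(self, k):
        """G = 1/2 kappa s^2 with kappa = keff k/(k - keff), within 1%."""
        kappa = 1.0
        keff = kappa * k / (kappa + k)
        s = np.linspace(-2, 2, 41)
        f = PerturbedFreeEnergies(0.5 * keff * s**2, 1.0)
        g, _ = stiff_spring_correct(f, s, k)
        target = 0.5 * kappa * s**2
        g -= g.min()
        target -= target.min()
        m = target > 0.5
        assert np.max(np.abs(g - target)[m] / target[m]) < 0.01

    def test_correction_scales_as_inverse_k(self):
        s = np.linspace(-2, 2, 41)
        kappa = 1.0
        mags = []
        ks = [10.0, 100.0, 1000.0]
        for k in ks:
            keff = kappa * k / (kappa + k)
            f = PerturbedFreeEnergies(0.5 * keff * s**2, 1.0)
            _, corr = stiff_spring_correct(f, s, k)
            mags.append(corr.max())
        slope = np.polyfit(np.log(ks), np.log(mags), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.05)

    def test_cyclic_wrap_consistency(self):
        s = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        f = PerturbedFreeEnergies(np.cos(s), 1.0)
        g, corr = stiff_spring_correct(f, s, k=50.0, cyclic=True,
                                       total_length=2 * np.pi)
        # smooth periodic F: the correction must be smooth across the seam
        assert abs(corr[0] - corr[-1]) < 0.02

    def test_too_few_images_rejected(self):
        f = PerturbedFreeEnergies(np.zeros(4), 1.0)
        with pytest.raises(InputError):
            stiff_spring_correct(f, np.arange(4.0), 10.0)


class TestStateTable:
    def test_planted_minima_arithmetic(self):
        g = np.array([0.0, 1.0, 0.5, 2.5, 2.0])
        rows = state_free_energies(g, None, {"A": 0, "B": 4},
                                   barriers={"TS": 3})
        by = {(r["kind"], r["from"], r["to"]): r for r in rows}
        assert by[("delta_g", "A", "B")]["value"] == pytest.approx(2.0)
        assert by[("barrier", "A", "TS")]["value"] == pytest.approx(2.5)
        assert by[("barrier", "B", "TS")]["value"] == pytest.approx(0.5)

    def test_identical_indices_zero_error(self):
        g = np.zeros(5)
        e = np.full(5, 0.3)
        rows = state_free_energies(g, e, {"A": 2, "B": 2})
        assert rows[0]["value"] == 0.0
        assert rows[0]["error"] == 0.0

    def test_quadrature_error_combination(self):
        g = np.array([0.0, 1.0, 2.0])
        e = np.array([0.3, 0.0, 0.4])
        rows = state_free_energies(g, e, {"A": 0, "B": 2})
        assert rows[0]["error"] == pytest.approx(0.5)

    def test_extremum_finder_cyclic(self):
        s = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        g = np.sin(2 * s)
        minima, maxima = find_extrema(g, cyclic=True)
        assert minima.size == 2 and maxima.size == 2

    def test_out_of_range_index(self):
        with pytest.raises(InputError):
            state_free_energies(np.zeros(3), None, {"A": 5})
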