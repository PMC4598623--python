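"""Bezier reparametrization and swarm-of-trajectories string refinement."""
import numpy as np
import pytest

from mfepath.errors import DegeneracyError, InputError
from mfepath.paths import StringPath, bezier_reparametrize, reparametrized_path
from mfepath.smwst import (
    StringHistory,
    default_convergence_tol,
    run_smwst,
    string_convergence,
)
from mfepath.toy import BrownianConfig, preset_surface

from conftest import Flat


def gaps(points: np.ndarray, cyclic: bool = False) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if cyclic:
        seg = np.append(seg, np.linalg.norm(points[0] - points[-1]))
    return seg


class TestBezier:
    def test_collinear_controls_give_uniform_segment(self):
        ctrl = np.outer(np.array([0.0, 0.3, 1.0, 2.0]), [1.0, 2.0])
        out = bezier_reparametrize(ctrl, 7)
        # points on the line through the controls
        d = out[:, 1] - 2 * out[:, 0]
        assert np.max(np.abs(d)) < 1e-8
        g = gaps(out)
        assert np.max(np.abs(g - g.mean())) < 1e-8

    @staticmethod
    def _arc_positions(out: np.ndarray, dense: np.ndarray) -> np.ndarray:
        """Arc coordinate of each output point on a dense oracle curve."""
        arc = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
        )
        pos = []
        for p in out:
            j = int(np.argmin(np.linalg.norm(dense - p, axis=1)))
            pos.append(arc[j])
        return np.asarray(pos), arc[-1]

    def test_right_angle_quadratic_oracle(self):
        """Equal arc-length gaps checked against a dense quadrature oracle."""
        ctrl = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        out = bezier_reparametrize(ctrl, 5)
        # oracle: very dense de Casteljau evaluation of the same quadratic
        t = np.linspace(0, 1, 200_001)[:, None]
        dense = ((1 - t) ** 2) * ctrl[0] + 2 * (1 - t) * t * ctrl[1] + t**2 * ctrl[2]
        # output points must lie on the quadratic
        for p in out:
            assert np.min(np.linalg.norm(dense - p, axis=1)) < 1e-4
        pos, total = self._arc_positions(out, dense)
        assert np.max(np.abs(np.diff(pos) - total / 4)) < 1e-4

    def test_cyclic_square_closes_uniformly(self):
        ctrl = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        out = bezier_reparametrize(ctrl, 8, cyclic=True)
        # oracle: dense evaluation of the same closed Bezier
        from mfepath.paths import _decasteljau

        dense = _decasteljau(np.vstack([ctrl, ctrl[:1]]),
                             np.linspace(0, 1, 200_001))
        pos, total = self._arc_positions(out, dense)
        g = np.diff(np.append(pos, pos[0] + total))
        assert np.max(np.abs(g - total / 8)) < 1e-4

    def test_idempotent_on_collinear_controls(self):
        ctrl = np.outer(np.linspace(0, 1, 6), [1.0, -1.0])
        once = bezier_reparametrize(ctrl, 6)
        twice = bezier_reparametrize(once, 6)
        assert np.max(np.abs(once - twice)) < 1e-6

    def test_open_endpoints_preserved(self, rng):
        ctrl = rng.normal(size=(5, 3))
        out = bezier_reparametrize(ctrl, 9)
        assert np.allclose(out[0], ctrl[0], atol=1e-12)
        assert np.allclose(out[-1], ctrl[-1], atol=1e-12)

    def test_coincident_controls_rejected(self):
        ctrl = np.array([[0.0, 0], [0.0, 0], [1, 1]])
        with pytest.raises(DegeneracyError):
            bezier_reparametrize(ctrl, 4)

    def test_spline_mode_flagged_in_metadata(self):
        path = StringPath(np.column_stack([np.linspace(0, 1, 5),
                                           np.zeros(5)]))
        out = reparametrized_path(path, mode="spline")
        assert out.metadata.get("reparametrization") == "spline"


class TestStringPath:
    def test_arc_lengths_respect_metric_scales(self):
        from mfepath.cvspace import CVSpace

        space = CVSpace(("a", "b"), np.array([2.0, 1.0]))
        p = StringPath(np.array([[0, 0], [1, 0], [2, 0.0]]), space=space)
        assert p.arc_lengths()[-1] == pytest.approx(4.0)

    def test_displacement_uses_metric(self):
        from mfepath.cvspace import CVSpace

        space = CVSpace(("a",), np.array([3.0]))
        p1 = StringPath(np.array([[0.0], [1.0], [2.0]]), space=space)
        p2 = StringPath(np.array([[0.5], [1.5], [2.5]]), space=space)
        mx, rms = p1.displacement(p2)
        assert mx == pytest.approx(1.5)
        assert rms == pytest.approx(1.5)


class TestSMwST:
    def test_flat_valley_zero_noise_is_fixed_point(self):
        """Zero drift on a flat surface: centers are stationary."""
        path = StringPath(np.column_stack([np.linspace(0, 1, 8), np.zeros(8)]))
        cfg = BrownianConfig(timestep=0.01, n_steps=1, seed=1, noise_scale=0.0)
        final, hist = run_smwst(path, Flat(2), copies_per_image=2,
                                restrain_steps=10, swarm_steps=10,
                                k_restrain=1.0, iterations=3, config=cfg)
        assert np.max(hist.max_displacement) < 1e-8

    def test_chord_converges_into_curved_valley(self):
        """Straight chord relaxes into the semicircular valley (tube 0.05)."""
        cv = preset_surface("curved_valley_2d")
        chord = np.column_stack([np.linspace(-1, 1, 49), np.full(49, 0.01)])
        chord[0] = [-1, 0]
        chord[-1] = [1, 0]
        cfg = BrownianConfig(timestep=0.002, n_steps=1, seed=3)
        final, _ = run_smwst(StringPath(chord), cv, copies_per_image=128,
                             restrain_steps=100, swarm_steps=8,
                             k_restrain=100.0, iterations=50, config=cfg)
        valley = cv.valley(np.linspace(0, cv.valley_length, 800))
        dev = max(
            np.min(np.linalg.norm(valley - c, axis=1)) for c in final.centers
        )
        assert dev < 0.05

    def test_copy_scaling_halves_standard_error(self):
        """Doubling copies scales the drift SE as n^-1/2 (log-log slope -0.5)."""
        cv = preset_surface("curved_valley_2d")
        start = StringPath(cv.valley(np.linspace(0.05, cv.valley_length - 0.05, 9)))
        copies_list = [4, 16, 64]
        ses = []
        for copies in copies_list:
            drifts = []
            for seed in range(12):
                cfg = BrownianConfig(timestep=0.002, n_steps=1, seed=seed)
                final, _ = run_smwst(start, cv, copies_per_image=copies,
                                     restrain_steps=40, swarm_steps=5,
                                     k_restrain=100.0, iterations=1,
                                     config=cfg)
                drifts.append(final.centers[4] - start.centers[4])
            ses.append(np.std(np.asarray(drifts)[:, 1]))
        slope = np.polyfit(np.log(copies_list), np.log(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.15)

    def test_open_string_pins_endpoints(self):
        cv = preset_surface("curved_valley_2d")
        chord = np.column_stack([np.linspace(-1, 1, 9), np.full(9, 0.01)])
        path = StringPath(chord)
        cfg = BrownianConfig(timestep=0.002, n_steps=1, seed=5)
        final, _ = run_smwst(path, cv, copies_per_image=4, restrain_steps=20,
                             swarm_steps=5, k_restrain=50.0, iterations=3,
                             config=cfg)
        assert np.allclose(final.centers[0], chord[0])
        assert np.allclose(final.centers[-1], chord[-1])
        assert final.n_images == 9


class TestConvergence:
    def test_identical_paths_zero_displacement(self):
        p = StringPath(np.arange(6, dtype=float)[:, None])
        assert p.displacement(p) == (0.0, 0.0)

    def test_translation_displacement_uses_scale(self):
        from mfepath.cvspace import CVSpace

        space = CVSpace(("x",), np.array([2.0]))
        p1 = StringPath(np.arange(4, dtype=float)[:, None], space=space)
        p2 = StringPath(p1.centers + 0.1, space=space)
        mx, _ = p1.displacement(p2)
        assert mx == pytest.approx(0.2)

    def test_geometric_decay_detection_matches_hand_count(self):
        rms = 0.5 ** np.arange(12)  # falls below 1e-2 at iteration 8 (0-based 7)
        hist = StringHistory(max_displacement=rms, rms_displacement=rms)
        converged, at = string_convergence(hist, tol=1e-2, consecutive=3)
        assert converged
        # rms < 1e-2 first at index 7 (0.0078); 3 consecutive ends at index 9
        assert at == 8

    def test_not_converged(self):
        hist = StringHistory(
            max_displacement=np.ones(5), rms_displacement=np.ones(5)
        )
        converged, at = string_convergence(hist, tol=0.5)
        assert not converged and at is None

    def test_default_tol_is_percent_of_spacing(self):
        p = StringPath(np.linspace(0, 10, 11)[:, None])
        assert default_convergence_tol(p) == pytest.approx(0.01)

    def test_too_short_history_rejected(self):
        hist = StringHistory(np.array([0.1]), np.array([0.1]))
        with pytest.raises(InputError):
            string_convergence(hist, 0.1)
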