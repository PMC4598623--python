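"""Orientation quaternions: fits, geodesics, restraints, double-cover safety."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfepath.errors import DegeneracyError, InputError
from mfepath.quaternion import (
    UnitQuaternion,
    best_fit_quaternion,
    best_fit_rmsd,
    geodesic_distance,
    orientation_restraint,
)

REF4 = np.array(
    [[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [-1, -1, -1] / np.sqrt(3)]
)


def random_unit_quaternion(rng) -> UnitQuaternion:
    v = rng.normal(size=4)
    return UnitQuaternion.from_array(v / np.linalg.norm(v))


class TestBestFit:
    def test_identity_frame_gives_identity_rotation(self):
        q = best_fit_quaternion(REF4, REF4)
        assert np.allclose(q.as_array(), [1, 0, 0, 0], atol=1e-9)

    def test_forced_90_degree_rotation_about_z(self):
        rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        q = best_fit_quaternion(REF4 @ rz.T, REF4)
        assert np.allclose(
            q.as_array(), [np.sqrt(2) / 2, 0, 0, np.sqrt(2) / 2], atol=1e-9
        )

    def test_random_rotation_recovery(self, rng):
        """Recovered quaternion reproduces the planted rotation matrix.

        Oracle: apply the recovered rotation to the reference and compare
        coordinates with the rotated frame.
        """
        for _ in range(50):
            ref = rng.normal(size=(8, 3))
            q_true = random_unit_quaternion(rng)
            frame = q_true.apply(ref - ref.mean(0)) + rng.normal(size=3)
            q = best_fit_quaternion(frame, ref)
            assert np.allclose(
                q.rotation_matrix(), q_true.rotation_matrix(), atol=1e-8
            )
            fitted = q.apply(ref - ref.mean(0)) + frame.mean(0) - 0
            assert np.allclose(
                fitted - fitted.mean(0), frame - frame.mean(0), atol=1e-7
            )

    def test_mismatched_counts_rejected(self):
        with pytest.raises(InputError):
            best_fit_quaternion(REF4[:3], REF4)

    @pytest.mark.parametrize(
        "bad",
        [
            np.zeros((4, 3)),  # coincident
            np.outer(np.arange(4.0), [1.0, 2.0, 3.0]),  # collinear
        ],
    )
    def test_degenerate_groups_raise_named_error(self, bad):
        with pytest.raises(DegeneracyError, match="helixX"):
            best_fit_quaternion(bad, REF4, label="helixX")

    def test_rmsd_self_consistency(self, rng):
        """Eigenvalue RMSD equals the RMSD after applying the fitted rotation."""
        for _ in range(10):
            ref = rng.normal(size=(10, 3))
            frame = rng.normal(size=(10, 3))
            q = best_fit_quaternion(frame, ref)
            r = best_fit_rmsd(frame, ref)
            fc = frame - frame.mean(0)
            rc = q.apply(ref - ref.mean(0))
            direct = np.sqrt(np.mean(np.sum((fc - rc) ** 2, axis=1)))
            assert r == pytest.approx(direct, abs=1e-8)


class TestGeodesic:
    def test_zero_for_identical(self, rng):
        for _ in range(10):
            q = random_unit_quaternion(rng)
            assert geodesic_distance(q, q) == pytest.approx(0.0, abs=1e-7)

    def test_quarter_turn_closed_form(self):
        p = UnitQuaternion.identity()
        q = UnitQuaternion.from_axis_angle([0, 0, 1], np.pi / 2)
        assert geodesic_distance(p, q) == pytest.approx(np.pi / 4, abs=1e-12)

    def test_small_angle_matches_chord(self):
        """Omega^2 ~ |P - Q|^2 for small rotations."""
        p = UnitQuaternion.identity()
        q = UnitQuaternion.from_axis_angle([1, 0, 0], 0.02)
        omega = geodesic_distance(p, q)
        assert omega == pytest.approx(0.01, rel=1e-9)
        chord2 = np.sum((p.as_array() - q.as_array()) ** 2)
        # 2 - 2cos(Omega) = Omega^2 (1 - Omega^2/12): relative gap 8e-6 here
        assert chord2 == pytest.approx(omega**2, rel=1e-5)

    def test_sign_flip_invariance_and_symmetry(self, rng):
        for _ in range(50):
            p = random_unit_quaternion(rng)
            q = random_unit_quaternion(rng)
            d = geodesic_distance(p, q)
            assert 0.0 <= d <= np.pi / 2 + 1e-12
            assert geodesic_distance(q, p) == pytest.approx(d, abs=1e-12)
            neg = UnitQuaternion.from_array(-q.as_array())
            assert geodesic_distance(p, neg) == pytest.approx(d, abs=1e-12)

    def test_triangle_inequality_on_quotient(self, rng):
        """Pseudo-metric on the sign quotient: 1000 random triples."""
        for _ in range(1000):
            a, b, c = (random_unit_quaternion(rng) for _ in range(3))
            assert geodesic_distance(a, c) <= (
                geodesic_distance(a, b) + geodesic_distance(b, c) + 1e-9
            )


class TestRestraint:
    def test_zero_at_center(self, rng):
        q = random_unit_quaternion(rng)
        e, g = orientation_restraint(q, q, k=3.0)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(g, 0.0, atol=1e-5)

    def test_closed_form_energy(self):
        qc = UnitQuaternion.identity()
        q = UnitQuaternion.from_axis_angle([0, 1, 0], np.pi / 2)  # Omega=pi/4
        e, _ = orientation_restraint(q, qc, k=2.0)
        assert e == pytest.approx(np.pi**2 / 16, rel=1e-12)

    def test_small_angle_surrogate(self, rng):
        """1/2 k |P-Q|^2 approximates the energy within 5% when Omega < 0.1."""
        checked = 0
        while checked < 20:
            axis = rng.normal(size=3)
            angle = rng.uniform(0.01, 0.19)  # Omega = angle/2 < 0.1
            qc = random_unit_quaternion(rng)
            rot = UnitQuaternion.from_axis_angle(axis, angle)
            # compose: q = rot * qc (quaternion product)
            a, b = rot.as_array(), qc.as_array()
            prod = np.array([
                a[0] * b[0] - a[1:] @ b[1:],
                *(a[0] * b[1:] + b[0] * a[1:] + np.cross(a[1:], b[1:])),
            ])
            q = UnitQuaternion.from_array(prod)
            if geodesic_distance(q, qc) >= 0.1:
                continue
            k = rng.uniform(0.5, 5.0)
            e, _ = orientation_restraint(q, qc, k)
            chord = min(
                np.sum((q.as_array() - qc.as_array()) ** 2),
                np.sum((q.as_array() + qc.as_array()) ** 2),
            )
            assert e == pytest.approx(0.5 * k * chord, rel=0.05)
            checked += 1

    def test_gradient_matches_central_differences(self, rng):
        """Tangent-projected gradient vs finite differences on the sphere."""
        h = 1e-6
        for _ in range(20):
            q = random_unit_quaternion(rng)
            qc = random_unit_quaternion(rng)
            if geodesic_distance(q, qc) > 1.4:  # avoid the pi/2 clamp region
                continue
            k = 2.0
            _, g = orientation_restraint(q, qc, k)
            qa = q.as_array()
            for _ in range(3):
                t = rng.normal(size=4)
                t -= (t @ qa) * qa
                t /= np.linalg.norm(t)
                qp = (qa + h * t) / np.linalg.norm(qa + h * t)
                qm = (qa - h * t) / np.linalg.norm(qa - h * t)

                def energy(arr):
                    d = abs(arr @ qc.as_array())
                    return 0.5 * k * np.arccos(np.clip(d, 0, 1)) ** 2

                num = (energy(qp) - energy(qm)) / (2 * h)
                assert g @ t == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_double_cover_invariance(self, rng):
        q = random_unit_quaternion(rng)
        qc = random_unit_quaternion(rng)
        e1, _ = orientation_restraint(q, qc, 1.0)
        e2, _ = orientation_restraint(
            UnitQuaternion.from_array(-q.as_array()), qc, 1.0
        )
        assert e1 == pytest.approx(e2, abs=1e-12)


class TestGeodesicProperties:
    quat = st.tuples(*([st.floats(-1, 1, allow_nan=False)] * 4)).filter(
        lambda t: sum(x * x for x in t) > 0.01
    )

    @staticmethod
    def _unit(t):
        v = np.asarray(t)
        return UnitQuaternion.from_array(v / np.linalg.norm(v))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(p=quat, q=quat)
    def test_range_symmetry_and_double_cover(self, p, q):
        """Omega lies in [0, pi/2], is symmetric, and ignores sign flips."""
        pu, qu = self._unit(p), self._unit(q)
        d = geodesic_distance(pu, qu)
        assert 0.0 <= d <= np.pi / 2 + 1e-12
        assert geodesic_distance(qu, pu) == pytest.approx(d, abs=1e-12)
        # canonicalization renormalizes, and arccos amplifies bit-level
        # dot-product changes near d = 0 by 1/sin(d): allow 1e-9
        flipped = UnitQuaternion.from_array(-qu.as_array())
        assert geodesic_distance(pu, flipped) == pytest.approx(d, abs=1e-9)


class TestCanonicalHemisphere:
    def test_construction_canonicalizes(self):
        q = UnitQuaternion(-0.5, 0.5, 0.5, 0.5)
        assert q.q0 == pytest.approx(0.5)
        assert q.q1 == pytest.approx(-0.5)

    def test_q0_zero_tie_break(self):
        q = UnitQuaternion(0.0, -1.0, 0.0, 0.0)
        assert q.q1 == pytest.approx(1.0)

    def test_norm_enforced(self):
        with pytest.raises(InputError):
            UnitQuaternion(1.0, 1.0, 0.0, 0.0)
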