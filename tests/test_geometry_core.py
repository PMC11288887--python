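"""Rigid transforms, ideal helices, torsion round-trips, clash checks
and Kabsch superposition (with an independent quaternion oracle)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from rbldesign.geometry_core import (HelixParams, RigidTransform, SixDOF,
                                     all_torsions, apply, clash_check,
                                     compose, dihedral, helix_axis,
                                     make_ideal_helix, power,
                                     rebuild_from_torsions, rmsd_no_super,
                                     superpose_kabsch, torsions)
from rbldesign.structure_model import BackboneModel, Residue


def quaternion_superpose(mobile, ref):
    """Independent oracle: Horn's closed-form quaternion method."""
    P = mobile - mobile.mean(axis=0)
    Q = ref - ref.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    w, v = np.linalg.eigh(K)
    q = v[:, -1]                      # quaternion (w, x, y, z)
    R = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
    diff = P @ R.T - Q
    return float(np.sqrt((diff ** 2).sum() / len(P)))


def random_transform(rng):
    R = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()
    return RigidTransform(R, rng.normal(0, 5, 3))


class TestTransforms:
    def test_power_identity(self):
        t = power(RigidTransform.identity(), 5)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0, atol=1e-12)

    def test_half_turn_squared_is_identity(self):
        t = SixDOF(rz=180.0).to_transform()
        t2 = power(t, 2)
        np.testing.assert_allclose(t2.rotation, np.eye(3), atol=1e-9)

    def test_power_matches_sequential_application(self, rng):
        t = random_transform(rng)
        pts = rng.normal(0, 10, (20, 3))
        seq = pts
        for _ in range(3):
            seq = t.apply_points(seq)
        np.testing.assert_allclose(power(t, 3).apply_points(pts), seq,
                                   atol=1e-9)

    def test_compose_inverse_is_identity(self, rng):
        t = random_transform(rng)
        ti = compose(t, t.inverse())
        np.testing.assert_allclose(ti.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(ti.translation, 0, atol=1e-9)

    def test_sixdof_round_trip(self):
        d = SixDOF(tx=1.5, ty=-2, tz=3, rx=20, ry=-35, rz=110)
        back = SixDOF.from_transform(d.to_transform())
        for f in ("tx", "ty", "tz", "rx", "ry", "rz"):
            assert abs(getattr(back, f) - getattr(d, f)) < 1e-6

    def test_nonorthonormal_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_transforms_are_isometries(self, seed):
        rng = np.random.default_rng(seed)
        t = random_transform(rng)
        pts = rng.normal(0, 10, (15, 3))
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        moved = t.apply_points(pts)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=2)
        assert np.abs(d0 - d1).max() < 1e-9


class TestIdealHelix:
    def test_ca_spacing(self, ideal_helix14):
        ca = ideal_helix14.coords("CA")
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert abs(d.mean() - 3.8) < 0.1

    def test_rise_per_residue(self, ideal_helix14):
        ca = ideal_helix14.coords("CA")
        axis, _ = helix_axis(ca)
        rise = np.diff(ca @ axis).mean()
        assert abs(rise - 1.5) < 0.1

    def test_canonical_frame_axis_on_z(self, ideal_helix14):
        ca = ideal_helix14.coords("CA")
        axis, _ = helix_axis(ca)
        angle = math.degrees(math.acos(abs(axis @ [0, 0, 1])))
        assert angle < 0.5
        assert abs(ca[:, 2].min()) < 1e-6          # N-term at z = 0

    def test_radius_and_orientation_placement(self):
        h = make_ideal_helix(HelixParams(length=14, radius=10.0,
                                         orientation=90.0))
        ca = h.coords("CA")
        center = ca.mean(axis=0)
        # axis displaced to (0, 10) after the 90° rotation about z
        assert abs(center[0]) < 0.5
        assert abs(center[1] - 10.0) < 0.5

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_ideal_helix(HelixParams(length=2))


class TestTorsions:
    def test_ideal_helix_phi_psi(self, ideal_helix14):
        for i in range(1, 13):
            phi, psi, omega = torsions(ideal_helix14, i)
            assert abs(phi - (-57.0)) < 0.01
            assert abs(psi - (-47.0)) < 0.01
            assert abs(abs(omega) - 180.0) < 0.01

    def test_round_trip_on_hairpin(self, hairpin):
        rebuilt = rebuild_from_torsions(all_torsions(hairpin))
        _, rmsd = superpose_kabsch(rebuilt.coords("CA"), hairpin.coords("CA"))
        assert rmsd < 0.1

    def test_rebuilt_omega_fixed_at_180(self, hairpin):
        rebuilt = rebuild_from_torsions(all_torsions(hairpin))
        for i in range(len(rebuilt) - 1):
            omega = all_torsions(rebuilt)[i][2]
            assert abs(abs(omega) - 180.0) < 1e-6

    def test_rebuild_is_rigid_motion_covariant(self, hairpin, rng):
        t = random_transform(rng)
        moved = apply(t, hairpin)
        tor_a = all_torsions(hairpin)
        tor_b = all_torsions(moved)
        for a, b in zip(tor_a, tor_b):
            for x, y in zip(a, b):
                if not (math.isnan(x) or math.isnan(y)):
                    assert abs((x - y + 180.0) % 360.0 - 180.0) < 1e-6


class TestClash:
    def test_close_nonbonded_atoms_clash(self):
        r1 = Residue(index=1, atoms={"N": np.zeros(3),
                                     "CA": np.array([1.5, 0, 0]),
                                     "C": np.array([2.5, 1, 0]),
                                     "O": np.array([2.0, 2, 0])})
        r2 = Residue(index=2, atoms={"N": np.array([30.0, 0, 0]),
                                     "CA": np.array([1.0, 1.0, 0]),
                                     "C": np.array([31, 1, 0]),
                                     "O": np.array([32, 2, 0])})
        m = BackboneModel(residues=[r1, r2], breaks={0})
        assert clash_check(m)

    def test_ideal_helix_no_clash(self, ideal_helix14):
        assert not clash_check(ideal_helix14)
        # exhaustive oracle: all heavy-atom pairs ≥2 residues apart
        atoms = [(i, n, x) for i, r in enumerate(ideal_helix14.residues)
                 for n, x in r.atoms.items()]
        for i, n1, x1 in atoms:
            for j, n2, x2 in atoms:
                if j - i >= 2:
                    assert np.linalg.norm(x1 - x2) > 0.6 * (1.7 + 1.7) or \
                        np.linalg.norm(x1 - x2) > 2.04

    def test_clash_factor_configurable(self, ideal_helix14):
        # an absurdly large factor turns normal geometry into "clash"
        assert clash_check(ideal_helix14, factor=2.5)


class TestKabsch:
    def test_identical_sets_rmsd_zero(self, rng):
        pts = rng.normal(0, 10, (10, 3))
        _, rmsd = superpose_kabsch(pts, pts)
        assert rmsd < 1e-9

    def test_translated_copy_rmsd_zero(self, rng):
        pts = rng.normal(0, 10, (10, 3))
        _, rmsd = superpose_kabsch(pts, pts + [5.0, -3.0, 2.0])
        assert rmsd < 1e-9

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(0, 10, (10, 3))
            b = rng.normal(0, 10, (10, 3))
            _, r1 = superpose_kabsch(a, b)
            r2 = quaternion_superpose(a, b)
            assert abs(r1 - r2) < 1e-6

    def test_recovers_applied_transform(self, rng):
        pts = rng.normal(0, 10, (12, 3))
        t = random_transform(rng)
        moved = t.apply_points(pts)
        est, rmsd = superpose_kabsch(pts, moved)
        assert rmsd < 1e-9
        np.testing.assert_allclose(est.rotation, t.rotation, atol=1e-6)
        np.testing.assert_allclose(est.translation, t.translation, atol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            superpose_kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_sets_flagged(self):
        a = np.array([[float(i), 0, 0] for i in range(5)])
        with pytest.warns(UserWarning):
            superpose_kabsch(a, a + 1.0)
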