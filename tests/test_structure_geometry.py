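import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from permeakit.io_core import select
from permeakit.structure_geometry import (
    axis_angle,
    helix_rotation,
    kabsch_fit,
    membrane_thickness,
    pore_profile,
    rmsd_two_selection,
    rotation_about_axis,
)

from conftest import make_structure


def _ring_structure(specs, n=12, vdw=1.5):
    """Stacked rings of atoms: specs = [(z, rho), ...]."""
    coords, radii = [], []
    for z, rho in specs:
        a = 2 * np.pi * np.arange(n) / n
        coords.append(np.column_stack(
            [rho * np.cos(a), rho * np.sin(a), np.full(n, z)]))
        radii.append(np.full(n, vdw))
    return make_structure(np.vstack(coords), radii=np.concatenate(radii))


class TestKabsch:
    def test_identity_on_self(self, rng):
        pts = rng.normal(size=(15, 3))
        tf = kabsch_fit(pts, pts)
        assert np.max(np.abs(tf.rotation - np.eye(3))) < 1e-12
        assert np.max(np.abs(tf.translation)) < 1e-12

    def test_recovers_constructed_72_degrees(self, rng):
        pts = rng.normal(size=(20, 3)) * 5
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = rotation_about_axis(axis, 72.0)
        ref = pts @ R.T + [1.0, -2.0, 3.0]
        aa = axis_angle(kabsch_fit(pts, ref).rotation)
        assert abs(aa.angle_deg - 72.0) < 1e-8

    def test_agrees_with_scipy_oracle(self, rng):
        pts = rng.normal(size=(25, 3)) * 4
        ref = rng.normal(size=(25, 3)) * 4
        tf = kabsch_fit(pts, ref)
        rot, _ = Rotation.align_vectors(ref - ref.mean(0), pts - pts.mean(0))
        assert np.max(np.abs(tf.rotation - rot.as_matrix())) < 1e-10

    def test_mirror_still_proper_with_residual(self, rng):
        pts = rng.normal(size=(10, 3))
        mirrored = pts * [1, 1, -1]
        tf = kabsch_fit(pts, mirrored)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-10)
        assert np.sum((tf.apply(pts) - mirrored) ** 2) > 1e-3

    def test_degenerate_collinear_errors(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_fit(pts, pts + [0, 1, 0])

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_residual_is_global_minimum(self, rng):
        """No random rigid perturbation of the fit lowers the residual."""
        pts = rng.normal(size=(12, 3)) * 3
        ref = pts @ rotation_about_axis([0, 0, 1], 30.0).T + rng.normal(size=3)
        ref += rng.normal(size=ref.shape) * 0.2  # noisy correspondence
        tf = kabsch_fit(pts, ref)
        best = np.sum((tf.apply(pts) - ref) ** 2)
        for _ in range(100):
            ax = rng.normal(size=3)
            ax /= np.linalg.norm(ax)
            pert = rotation_about_axis(ax, rng.uniform(0.1, 5.0))
            rot = pert @ tf.rotation
            shift = tf.translation + rng.normal(size=3) * 0.05
            res = np.sum((pts @ rot.T + shift - ref) ** 2)
            assert res >= best - 1e-12


class TestAxisAngle:
    def test_identity_convention(self):
        aa = axis_angle(np.eye(3))
        assert aa.angle_deg == 0.0
        assert np.array_equal(aa.axis, [0.0, 0.0, 1.0])

    def test_stage_magnitude_about_z(self):
        aa = axis_angle(rotation_about_axis([0, 0, 1], 27.5))
        assert aa.angle_deg == pytest.approx(27.5, abs=1e-10)
        assert np.allclose(aa.axis, [0, 0, 1], atol=1e-12)

    def test_round_trip_thousand_rotations(self, rng):
        for _ in range(1000):
            a = rng.normal(size=3)
            a /= np.linalg.norm(a)
            theta = rng.uniform(1e-3, 180.0 - 1e-3)
            aa = axis_angle(rotation_about_axis(a, theta))
            if a[np.argmax(np.abs(a))] < 0:
                a = -a
            assert abs(aa.angle_deg - theta) < 1e-8
            assert np.linalg.norm(aa.axis - a) < 1e-8

    def test_non_orthogonal_errors(self):
        with pytest.raises(ValueError):
            axis_angle(np.eye(3) * 1.01)


class TestRMSDTwoSelection:
    def test_equals_classic_fitted_rmsd_when_selections_match(self, rng):
        n = 30
        ref = make_structure(rng.normal(size=(n, 3)) * 5, names=["CA"] * n)
        coords = (ref.coords @ rotation_about_axis([1, 1, 0], 20.0).T
                  + rng.normal(size=(n, 3)) * 0.3 + [2, 0, -1])
        r = rmsd_two_selection(coords, ref, "name CA", "name CA")
        tf = kabsch_fit(coords, ref.coords)
        classic = np.sqrt(np.mean(np.sum(
            (tf.apply(coords) - ref.coords) ** 2, axis=1)))
        assert r == pytest.approx(classic, abs=1e-12)

    def test_rigid_translation_gives_zero(self, rng):
        n = 20
        ref = make_structure(rng.normal(size=(n, 3)),
                             names=["CA"] * 10 + ["CB"] * 10)
        r = rmsd_two_selection(ref.coords + [3, 4, 5], ref,
                               "name CA", "name CB")
        assert r < 1e-9

    def test_displaced_domain_reads_two_angstroms(self, rng):
        """One domain shifted 2 Å along Z after fitting on the rest."""
        n = 40
        names = ["CA"] * n
        monomers = [0] * n
        resnums = list(range(1, n + 1))
        ref = make_structure(rng.normal(size=(n, 3)) * 6, names=names,
                             monomers=monomers, resnums=resnums)
        coords = ref.coords.copy()
        domain = select(ref, "resnum 31:40")
        coords[domain.indices] += [0.0, 0.0, 2.0]
        fit = "resnum 1:30"
        r_dom = rmsd_two_selection(coords, ref, fit, "resnum 31:40")
        r_rest = rmsd_two_selection(coords, ref, fit, fit)
        assert r_dom == pytest.approx(2.0, abs=1e-9)
        assert r_rest < 1e-9

    def test_count_mismatch_errors(self, rng):
        ref = make_structure(rng.normal(size=(5, 3)), names=["CA"] * 5)
        with pytest.raises(ValueError):
            rmsd_two_selection(np.zeros((4, 3)), ref, "name CA", "name CA")


class TestHelixRotation:
    def _helix(self, rng, n=20):
        t = np.arange(n)
        coords = np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * t])
        coords += rng.normal(size=3) * 0  # deterministic
        return make_structure(coords, names=["CA"] * n,
                              resnums=np.arange(1, n + 1), monomers=[0] * n)

    def test_identity_gives_zero_angles(self, rng):
        ref = self._helix(rng)
        out = helix_rotation(ref, ref, {"H": "name CA"})
        assert out["H"]["angle_deg"] < 1e-9

    def test_corkscrew_recovered(self, rng):
        """A helix rotated 16.3° about its own axis reads back 16.3°."""
        ref = self._helix(rng)
        axis_point = np.array([0.0, 0.0, 0.0])
        R = rotation_about_axis([0, 0, 1], 16.3)
        conf = ref.with_coords((ref.coords - axis_point) @ R.T + axis_point)
        out = helix_rotation(conf, ref, {"H": "name CA"})
        assert out["H"]["angle_deg"] == pytest.approx(16.3, abs=1e-6)
        # rotation about +Z is counterclockwise seen from +Z (periplasm)
        assert out["H"]["clockwise_from_periplasm"] is False
        conf2 = ref.with_coords((ref.coords) @ rotation_about_axis(
            [0, 0, -1], 16.3).T)
        out2 = helix_rotation(conf2, ref, {"H": "name CA"})
        assert out2["H"]["clockwise_from_periplasm"] is True

    def test_global_rotation_shifts_every_helix_equally(self, rng):
        """No global pre-fit: a whole-structure rotation appears in every
        per-helix angle, matching a brute-force recomputation."""
        n = 24
        coords = rng.normal(size=(n, 3)) * 8
        ref = make_structure(coords, names=["CA"] * n,
                             resnums=np.arange(1, n + 1), monomers=[0] * n)
        R = rotation_about_axis([1, 2, 3], 33.0)
        conf = ref.with_coords(ref.coords @ R.T)
        sels = {"A": "resnum 1:12", "B": "resnum 13:24"}
        out = helix_rotation(conf, ref, sels)
        for name, sel in sels.items():
            idx = select(ref, sel).indices
            tf = kabsch_fit(conf.coords[idx], ref.coords[idx])
            aa = axis_angle(tf.rotation)
            assert out[name]["angle_deg"] == pytest.approx(aa.angle_deg,
                                                           abs=1e-9)
            assert out[name]["angle_deg"] == pytest.approx(33.0, abs=1e-6)

    def test_selection_mismatch_errors(self, rng):
        ref = self._helix(rng)
        conf = make_structure(ref.coords[:10], names=["CA"] * 10,
                              resnums=np.arange(1, 11), monomers=[0] * 10)
        with pytest.raises(ValueError):
            helix_rotation(conf, ref, {"H": "name CA"})


class TestPoreProfile:
    def test_analytic_ring(self):
        st = _ring_structure([(0.0, 5.0)])
        p = pore_profile(st, (0.0, 0.0), step=1.0, r_max=10.0)
        assert p.radii[0] == pytest.approx(3.5, abs=0.05)

    def test_hourglass_single_bottleneck(self):
        st = _ring_structure([(-5, 8.0), (0, 3.0), (5, 8.0)])
        p = pore_profile(st, (-6, 6), step=1.0, r_max=10.0)
        assert len(p.bottlenecks) == 1
        z_b, r_b = p.bottlenecks[0]
        assert abs(z_b - 0.0) <= 1.0
        assert r_b == pytest.approx(1.5, abs=0.05)

    def test_double_constriction_two_bottlenecks(self):
        """The W-shaped profile of a twice-constricted channel."""
        st = _ring_structure([(-12, 9.0), (-6, 3.5), (0, 7.0),
                              (6, 3.0), (12, 9.0)])
        p = pore_profile(st, (-13, 13), step=1.0, r_max=10.0)
        assert len(p.bottlenecks) == 2
        zs = sorted(z for z, _ in p.bottlenecks)
        assert abs(zs[0] + 6) <= 1.0 and abs(zs[1] - 6) <= 1.0
        # oracle: dense 0.1 Å axial scan of the objective
        for z_b, r_b in p.bottlenecks:
            dense = min(
                self._axial(st, z) for z in np.arange(z_b - 1, z_b + 1, 0.1))
            assert r_b <= dense + 0.05

    @staticmethod
    def _axial(st, z):
        d = np.linalg.norm(st.coords - [0, 0, z], axis=1) - st.vdw_radius
        return float(d.min())

    def test_radii_shrink_as_atom_radius_grows(self):
        small = _ring_structure([(0.0, 5.0)], vdw=1.0)
        big = _ring_structure([(0.0, 5.0)], vdw=2.0)
        ps = pore_profile(small, (0, 0), step=1.0, r_max=10.0)
        pb = pore_profile(big, (0, 0), step=1.0, r_max=10.0)
        assert pb.radii[0] < ps.radii[0]

    def test_cylinder_profile_constant(self):
        st = _ring_structure([(z, 5.0) for z in range(-4, 5)])
        p = pore_profile(st, (-3, 3), step=1.0, r_max=10.0)
        assert np.max(p.radii) - np.min(p.radii) < 0.1

    def test_empty_slab_capped_and_flagged(self):
        st = make_structure(np.empty((0, 3)))
        p = pore_profile(st, (0, 2), step=1.0, r_max=10.0)
        assert np.all(p.radii == 10.0)
        assert np.all(p.capped)


class TestMembraneThickness:
    def test_marker_planes(self):
        st = make_structure([[0, 0, 9.0], [1, 0, 9.0],
                             [0, 0, -9.0], [1, 0, -9.0]],
                            resnames=["MKU", "MKU", "MKL", "MKL"])
        assert membrane_thickness(st, "resname MKU", "resname MKL") == 18.0

    def test_noisy_markers_average_out(self, rng):
        n = 200
        up = np.column_stack([rng.normal(size=n), rng.normal(size=n),
                              9.0 + rng.uniform(-0.5, 0.5, n)])
        lo = np.column_stack([rng.normal(size=n), rng.normal(size=n),
                              -9.0 + rng.uniform(-0.5, 0.5, n)])
        st = make_structure(np.vstack([up, lo]),
                            resnames=["MKU"] * n + ["MKL"] * n)
        t = membrane_thickness(st, "resname MKU", "resname MKL")
        assert t == pytest.approx(18.0, abs=0.1)

    def test_single_marker_per_leaflet(self):
        st = make_structure([[0, 0, 9.0], [0, 0, -9.0]],
                            resnames=["MKU", "MKL"])
        assert membrane_thickness(st, "resname MKU", "resname MKL") == 18.0

    def test_empty_selection_errors(self):
        st = make_structure([[0, 0, 9.0]], resnames=["MKU"])
        with pytest.raises(ValueError):
            membrane_thickness(st, "resname MKU", "resname MKL")
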