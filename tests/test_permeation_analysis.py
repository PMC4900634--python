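import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from permeakit.io_core import Trajectory
from permeakit.permeation_analysis import (
    DeltaZSeries,
    contact_number,
    delta_z,
    detect_crossings,
    geometric_center,
    ion_displacement,
    lipid_residue_groups,
    segment_stages,
    target_residue_groups,
)

from conftest import make_structure


def _traj(topo, frames, dt=1.0):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(structure=topo, frames=frames,
                      times=np.arange(frames.shape[0]) * dt)


class TestGeometricCenter:
    def test_single_point(self):
        assert np.array_equal(geometric_center([[1.0, 2.0, 3.0]]), [1, 2, 3])

    def test_symmetric_pair(self):
        assert np.array_equal(
            geometric_center([[1, 0, 0], [-1, 0, 0]]), [0, 0, 0])

    def test_translation_equivariance(self, rng):
        pts = rng.normal(size=(10, 3))
        v = np.array([3.0, -2.0, 7.0])
        assert np.allclose(geometric_center(pts + v),
                           geometric_center(pts) + v, atol=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            geometric_center(np.empty((0, 3)))


class TestDeltaZ:
    def _system(self):
        # 3 ligand beads + 5 ring atoms
        coords = np.vstack([np.zeros((3, 3)),
                            np.column_stack([np.cos(np.linspace(0, 2 * np.pi, 5,
                                                                endpoint=False)),
                                             np.sin(np.linspace(0, 2 * np.pi, 5,
                                                                endpoint=False)),
                                             np.zeros(5)])])
        return make_structure(
            coords,
            resnames=["LIG"] * 3 + ["LYS"] * 5,
            names=["L1", "L2", "L3"] + ["CA"] * 5,
            monomers=[-1] * 3 + list(range(5)),
            resnums=[1] * 3 + [106 + 136 * m for m in range(5)])

    def test_in_plane_is_zero(self):
        topo = self._system()
        traj = _traj(topo, [topo.coords])
        s = delta_z(traj, "resname LIG", "resnum 106 and name CA")
        assert s.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_intermediate_state_magnitude(self):
        """A ligand 25 Å above the ring reads ΔZ = +25 Å."""
        topo = self._system()
        fr = topo.coords.copy()
        fr[:3, 2] += 25.0
        s = delta_z(_traj(topo, [fr]), "resname LIG", "resnum 106 and name CA")
        assert s.values[0] == pytest.approx(25.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        topo = self._system()
        frames = rng.normal(size=(120, topo.n_atoms, 3)) * 10
        traj = _traj(topo, frames)
        s = delta_z(traj, "resname LIG", "resnum 106 and name CA")
        for f in range(traj.n_frames):
            zl = frames[f, :3, 2].sum() / 3.0
            zr = frames[f, 3:, 2].sum() / 5.0
            assert abs(s.values[f] - (zl - zr)) < 1e-9

    def test_rigid_translation_invariance_and_mirror_flip(self, rng):
        topo = self._system()
        frames = rng.normal(size=(20, topo.n_atoms, 3)) * 10
        s = delta_z(_traj(topo, frames), "resname LIG", "resnum 106 and name CA")
        shifted = delta_z(_traj(topo, frames + [1.0, -2.0, 5.0]),
                          "resname LIG", "resnum 106 and name CA")
        assert np.allclose(s.values, shifted.values, atol=1e-9)
        mirrored = delta_z(_traj(topo, frames * [1, 1, -1]),
                           "resname LIG", "resnum 106 and name CA")
        assert np.allclose(mirrored.values, -s.values, atol=1e-9)

    def test_empty_selection_errors(self):
        topo = self._system()
        with pytest.raises(ValueError, match="empty"):
            delta_z(_traj(topo, [topo.coords]), "resname ZZZ", "name CA")


def _crossings_oracle(values, z_upper, z_lower):
    """Independent two-state hysteresis automaton (count only)."""
    state, down, up = None, 0, 0
    for v in values:
        if v >= z_upper:
            if state == "low":
                up += 1
            state = "high"
        elif v <= z_lower:
            if state == "high":
                down += 1
            state = "low"
    return down, up


class TestDetectCrossings:
    def test_monotone_descent_single_event(self):
        s = DeltaZSeries(times=np.arange(41.0),
                         values=np.linspace(30, -10, 41))
        ev = detect_crossings(s, z_upper=10.0, z_lower=-5.0)
        assert len(ev) == 1 and ev[0]["direction"] == "down"

    def test_four_oscillations_four_downward_events(self):
        blocks = []
        for _ in range(4):
            blocks += [30.0] * 3 + [-10.0] * 3
        s = DeltaZSeries(times=np.arange(len(blocks), dtype=float),
                         values=np.array(blocks))
        ev = detect_crossings(s, z_upper=10.0, z_lower=-5.0)
        assert sum(e["direction"] == "down" for e in ev) == 4

    def test_hysteresis_blocks_shallow_dip(self):
        s = DeltaZSeries(times=np.arange(5.0),
                         values=np.array([30.0, 0.0, -4.9, 0.0, 30.0]))
        assert detect_crossings(s, z_upper=10.0, z_lower=-5.0) == []

    def test_event_endpoints_follow_definition(self):
        vals = np.array([30.0, 30.0, 5.0, 2.0, -10.0])
        s = DeltaZSeries(times=np.arange(5.0) * 2, values=vals)
        ev = detect_crossings(s, z_upper=10.0, z_lower=-5.0)
        assert ev == [{"t_start": 2.0, "t_end": 8.0, "direction": "down"}]

    def test_too_short_series_errors(self):
        s = DeltaZSeries(times=[0.0], values=[1.0])
        with pytest.raises(ValueError):
            detect_crossings(s, 10.0, -5.0)

    def test_thresholds_must_be_ordered(self):
        s = DeltaZSeries(times=[0.0, 1.0], values=[1.0, 2.0])
        with pytest.raises(ValueError):
            detect_crossings(s, -5.0, 10.0)

    @given(arrays(np.float64, st.integers(2, 60),
                  elements=st.floats(-40, 40)))
    @settings(max_examples=300)
    def test_counts_match_independent_automaton(self, values):
        s = DeltaZSeries(times=np.arange(len(values), dtype=float),
                         values=values)
        ev = detect_crossings(s, z_upper=10.0, z_lower=-5.0)
        down = sum(e["direction"] == "down" for e in ev)
        up = sum(e["direction"] == "up" for e in ev)
        assert (down, up) == _crossings_oracle(values, 10.0, -5.0)


class TestSegmentStages:
    def test_constant_series_single_stage(self):
        s = DeltaZSeries(times=np.arange(50.0), values=np.full(50, 7.0))
        stages = segment_stages(s, bands=[20.0, 0.0], min_dwell=0.0)
        assert len(stages) == 1
        assert stages[0]["dwell_ps"] == 50.0

    def test_plateau_dwells_recovered_exactly(self):
        """Four plateaus with dwells 0.72/8.8/0.8/0.4 ns at 4 ps frames."""
        dt = 4.0
        dwells_ns = [0.72, 8.8, 0.8, 0.4]
        plateaus = [40.0, 25.0, 0.0, -15.0]
        vals = np.concatenate([
            np.full(int(d * 1000 / dt), p)
            for d, p in zip(dwells_ns, plateaus)])
        s = DeltaZSeries(times=np.arange(len(vals)) * dt, values=vals)
        stages = segment_stages(s, bands=[30.0, 10.0, -5.0], min_dwell=0.0)
        assert len(stages) == 4
        assert [st_["dwell_ps"] for st_ in stages] == [
            pytest.approx(d * 1000) for d in dwells_ns]
        assert [st_["mean_delta_z"] for st_ in stages] == plateaus

    def test_one_frame_blip_absorbed(self):
        vals = np.concatenate([np.full(20, 25.0), [35.0], np.full(20, 25.0)])
        s = DeltaZSeries(times=np.arange(len(vals), dtype=float), values=vals)
        stages = segment_stages(s, bands=[30.0], min_dwell=2.0)
        assert len(stages) == 1

    def test_stage_union_covers_window(self, rng):
        vals = rng.uniform(-30, 50, 200)
        s = DeltaZSeries(times=np.arange(200.0) * 4, values=vals)
        stages = segment_stages(s, bands=[30.0, 0.0], min_dwell=20.0)
        assert stages[0]["t_start"] == 0.0
        for a, b in zip(stages, stages[1:]):
            assert a["t_end"] == b["t_start"]
        total = sum(st_["dwell_ps"] for st_ in stages)
        assert total == pytest.approx(200 * 4)

    def test_empty_bands_error(self):
        s = DeltaZSeries(times=np.arange(5.0), values=np.zeros(5))
        with pytest.raises(ValueError):
            segment_stages(s, bands=[], min_dwell=0.0)

    def test_energy_annotation(self):
        s = DeltaZSeries(times=np.arange(4.0), values=[40.0, 40.0, 0.0, 0.0])
        stages = segment_stages(s, energies=[1.0, 3.0, 5.0, 7.0],
                                bands=[20.0], min_dwell=0.0)
        assert stages[0]["mean_energy"] == 2.0
        assert stages[1]["mean_energy"] == 6.0


class TestIonDisplacement:
    def _ions(self, n=20):
        return make_structure(np.zeros((n, 3)), names=["K"] * n)

    def test_static_ions_zero(self):
        topo = self._ions()
        traj = _traj(topo, [topo.coords] * 5)
        out = ion_displacement(traj, np.arange(topo.n_atoms))
        assert out["mean"] == 0.0

    def test_uniform_shift_minus_six(self):
        topo = self._ions()
        frames = [topo.coords, topo.coords + [0, 0, -6.0]]
        out = ion_displacement(_traj(topo, frames), np.arange(topo.n_atoms))
        assert out["mean"] == pytest.approx(-6.0)

    def test_random_walk_matches_oracle(self, rng):
        topo = self._ions()
        frames = np.cumsum(rng.normal(size=(30, topo.n_atoms, 3)), axis=0)
        traj = _traj(topo, frames)
        out = ion_displacement(traj, np.arange(topo.n_atoms), window=(3, 25))
        expected = (frames[25, :, 2] - frames[3, :, 2]).mean()
        assert out["mean"] == pytest.approx(expected, abs=1e-12)
        out2 = ion_displacement(traj, np.arange(topo.n_atoms),
                                window=(3, 25), mode="mean")
        expected2 = (frames[3:26, :, 2].mean(axis=0) - frames[3, :, 2]).mean()
        assert out2["mean"] == pytest.approx(expected2, abs=1e-12)

    def test_window_outside_errors(self):
        topo = self._ions()
        traj = _traj(topo, [topo.coords] * 3)
        with pytest.raises(ValueError, match="window"):
            ion_displacement(traj, np.arange(topo.n_atoms), window=(0, 5))


class TestContactNumber:
    def _fixture(self, lipid_positions, resnames):
        """One 2-atom target residue plus 1-atom lipid residues."""
        coords = [[0.0, 0, 0], [2.0, 0, 0]] + list(lipid_positions)
        n_lip = len(lipid_positions)
        topo = make_structure(
            coords,
            resnames=["ASN", "ASN"] + resnames,
            monomers=[0, 0] + [-1] * n_lip,
            resnums=[103, 103] + list(range(1, n_lip + 1)))
        targets = {"N103": np.array([0, 1])}
        lipids = [(rn, np.array([2 + i])) for i, rn in enumerate(resnames)]
        return topo, targets, lipids

    def test_inclusive_boundary_at_threshold(self):
        # target center at (1,0,0); lipid residue center exactly 6.5 away
        topo, targets, lipids = self._fixture([[7.5, 0, 0]], ["PA"])
        cs = contact_number(_traj(topo, [topo.coords]), targets, lipids)
        assert cs.counts["N103"].iloc[0] == 1

    def test_polar_residues_not_counted(self):
        topo, targets, lipids = self._fixture([[2.0, 0, 0]], ["PC"])
        with pytest.raises(ValueError, match="hydrophobic"):
            contact_number(_traj(topo, [topo.coords]), targets, lipids)

    def test_no_contacts_average_zero(self):
        topo, targets, lipids = self._fixture([[50.0, 0, 0]], ["OL"])
        cs = contact_number(_traj(topo, [topo.coords] * 4), targets, lipids)
        assert cs.averages["N103"] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        positions = rng.uniform(-10, 10, (12, 3))
        resnames = ["PA", "OL", "PC"] * 4
        topo, targets, lipids = self._fixture(positions, resnames)
        frames = topo.coords + rng.normal(size=(100, topo.n_atoms, 3)) * 3
        traj = _traj(topo, frames)
        cs = contact_number(traj, targets, lipids, threshold=6.5)
        for f in range(100):
            x = frames[f]
            tc = x[[0, 1]].mean(axis=0)
            n = 0
            for rn, idx in lipids:
                if rn not in ("PA", "OL"):
                    continue
                d = np.linalg.norm(x[idx].mean(axis=0) - tc)
                if d <= 6.5:
                    n += 1
            assert cs.counts["N103"].iloc[f] == n
        assert cs.averages["N103"] == pytest.approx(
            cs.counts["N103"].mean(), abs=1e-12)

    def test_monotone_in_threshold(self, rng):
        positions = rng.uniform(-8, 8, (10, 3))
        resnames = ["PA"] * 10
        topo, targets, lipids = self._fixture(positions, resnames)
        traj = _traj(topo, [topo.coords] * 3)
        prev = None
        for thr in (4.0, 6.5, 9.0):
            cs = contact_number(traj, targets, lipids, threshold=thr)
            if prev is not None:
                assert (cs.counts["N103"] >= prev).all()
            prev = cs.counts["N103"]


class TestResidueGroups:
    def test_counterpart_targets_at_offsets(self, pentamer):
        groups = target_residue_groups(pentamer, 103)
        assert sorted(groups) == ["N103", "N239", "N375", "N511", "N647"]

    def test_lipid_groups_from_builder(self, demo_system):
        from permeakit.synthetic_system import LipidSpec, place_lipids
        st = place_lipids(demo_system, LipidSpec(n_lipids=5, rng_seed=0))
        groups = lipid_residue_groups(st)
        assert len(groups) == 15
        assert {rn for rn, _ in groups} == {"PA", "PC", "OL"}
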