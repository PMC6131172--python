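import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation
from scipy.stats import circmean, circstd

from confens.dihedrals import (
    HIS453_IN,
    HIS453_OUT,
    HIS453_STATES,
    AngularState,
    assign_states,
    backbone_dihedrals,
    circular_distance,
    circular_mean_sd,
    dihedral,
    dihedral_series,
    variability_profile,
)
from confens.errors import DegenerateGeometryError
from confens.synthetic import (
    DihedralSwitcherSpec,
    build_helical_peptide,
    generate_dihedral_series,
)


class TestDihedral:
    def test_planar_trans_is_180(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == pytest.approx(180.0)

    def test_planar_cis_is_0(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(
            0.0, abs=1e-12
        )

    @pytest.mark.parametrize("angle", [60.0, -60.0, 90.0, -179.0, 13.7])
    def test_constructed_rotation_about_axis(self, angle):
        # p4 built by rotating p1's image about the p2-p3 axis must read back
        # as exactly that torsion
        p1, p2, p3 = np.array([0.0, 1.5, 0]), np.zeros(3), np.array([2.0, 0, 0])
        rot = Rotation.from_rotvec(np.radians(angle) * np.array([1.0, 0, 0]))
        p4 = p3 + rot.apply([0.0, 1.5, 0.0])
        assert dihedral(p1, p2, p3, p4) == pytest.approx(angle, abs=1e-8)

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])

    def test_collinear_points_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            dihedral([-1, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_rigid_motion_invariance_and_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=2.0, size=(4, 3))
        try:
            base = dihedral(*pts)
        except DegenerateGeometryError:
            return
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(scale=5.0, size=3)
        moved = dihedral(*(pts @ R.T + t))
        reversed_ = dihedral(*pts[::-1])
        mirrored = dihedral(*(pts * np.array([1.0, 1.0, -1.0])))
        assert moved == pytest.approx(base, abs=1e-7)
        # the torsion reads the same from either chain end ...
        assert circular_distance(reversed_, base) < 1e-7
        # ... and flips sign under an improper (mirror) transformation
        assert circular_distance(mirrored, -base) < 1e-7


class TestBackboneDihedrals:
    def test_helical_roundtrip_within_half_degree(self):
        frame = build_helical_peptide(10, -57.0, -47.0)
        for dv in backbone_dihedrals(frame):
            if dv.value is None:
                continue
            expected = -57.0 if dv.angle_name == "phi" else -47.0
            assert dv.value == pytest.approx(expected, abs=0.5)

    def test_two_residue_chain_has_one_phi_one_psi(self):
        frame = build_helical_peptide(2, -57.0, -47.0)
        defined = [(d.residue_number, d.angle_name) for d in backbone_dihedrals(frame) if d.value is not None]
        assert defined == [(1, "psi"), (2, "phi")]

    def test_termini_marked_missing_not_fabricated(self):
        frame = build_helical_peptide(4, -57.0, -47.0)
        by_key = {
            (d.residue_number, d.angle_name): d for d in backbone_dihedrals(frame)
        }
        assert by_key[(1, "phi")].value is None
        assert "missing atom" in by_key[(1, "phi")].reason
        assert by_key[(4, "psi")].value is None

    def test_missing_carbon_flags_dependent_angles(self):
        frame = build_helical_peptide(7, -57.0, -47.0, first_residue=450)
        frame.atoms = [
            a
            for a in frame.atoms
            if not (a.residue_number == 455 and a.atom_name == "C")
        ]
        by_key = {
            (d.residue_number, d.angle_name): d.value
            for d in backbone_dihedrals(frame)
        }
        assert by_key[(455, "phi")] is None  # needs own C
        assert by_key[(455, "psi")] is None
        assert by_key[(456, "phi")] is None  # needs C of 455
        assert by_key[(454, "psi")] is not None  # unaffected
        assert by_key[(456, "psi")] is None  # 456 is now chain C-terminus... still has N457? no
        assert by_key[(454, "phi")] is not None

    def test_agrees_with_mdtraj(self, tmp_path):
        mdtraj = pytest.importorskip("mdtraj")
        from confens.structure_io import write_pdb

        frame = build_helical_peptide(8, -63.0, -42.0)
        path = write_pdb([frame], tmp_path / "helix.pdb")
        traj = mdtraj.load_pdb(str(path), standard_names=False)
        _, phis = mdtraj.compute_phi(traj)
        _, psis = mdtraj.compute_psi(traj)
        ours = {
            (d.residue_number, d.angle_name): d.value
            for d in backbone_dihedrals(frame)
            if d.value is not None
        }
        # mdtraj re-reads the fixed-width PDB in float32, so agreement is
        # limited by the 3-decimal coordinate precision
        np.testing.assert_allclose(
            np.degrees(phis[0]),
            [ours[(r, "phi")] for r in range(2, 9)],
            atol=0.2,
        )
        np.testing.assert_allclose(
            np.degrees(psis[0]),
            [ours[(r, "psi")] for r in range(1, 8)],
            atol=0.2,
        )


class TestCircularStats:
    def test_wraparound_symmetric_pair_means_zero(self):
        mean, _ = circular_mean_sd([10.0, 350.0])
        assert mean == pytest.approx(0.0, abs=1e-10)

    def test_constant_series(self):
        mean, sd = circular_mean_sd([143.0] * 5)
        assert mean == pytest.approx(143.0)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_uniform_angles_undefined(self):
        with pytest.raises(DegenerateGeometryError):
            circular_mean_sd([0.0, 90.0, 180.0, 270.0])

    def test_recovers_wrapped_gaussian_parameters(self):
        series, _ = generate_dihedral_series(
            DihedralSwitcherSpec(
                states=(AngularState("only", 143.0, 20.0),),
                n_frames=100_000,
                seed=5,
            )
        )
        mean, sd = circular_mean_sd(series.values)
        assert mean == pytest.approx(143.0, abs=0.5)
        assert sd == pytest.approx(20.0, abs=0.5)

    def test_matches_scipy_circular_statistics(self, rng):
        vals = rng.uniform(-180, 180, size=50) * 0.4 + 100.0
        mean, sd = circular_mean_sd(vals)
        assert mean == pytest.approx(
            circmean(vals, high=180, low=-180), abs=1e-8
        )
        assert sd == pytest.approx(circstd(vals, high=180, low=-180), abs=1e-8)

    @settings(max_examples=25, deadline=None)
    @given(
        delta=st.floats(-720, 720, allow_nan=False),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_rotation_equivariance(self, delta, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(40.0, 15.0, size=30)
        base, sd0 = circular_mean_sd(vals)
        shifted, sd1 = circular_mean_sd(vals + delta)
        assert circular_distance(shifted, base + delta) < 1e-6
        assert sd1 == pytest.approx(sd0, abs=1e-6)


class TestVariabilityProfile:
    def _models(self, psis_per_model, n_res=12, first=450):
        return [
            build_helical_peptide(n_res, -57.0, psi, first_residue=first)
            for psi in psis_per_model
        ]

    def test_identical_models_zero_iqr(self):
        models = self._models([[-47.0] * 12] * 4)
        prof = variability_profile(models)
        np.testing.assert_allclose(prof.phi_iqr[~np.isnan(prof.phi_iqr)], 0, atol=1e-8)
        np.testing.assert_allclose(prof.psi_iqr[~np.isnan(prof.psi_iqr)], 0, atol=1e-8)

    def test_two_models_differing_by_ten_degrees(self):
        base = np.full(12, -47.0)
        moved = base.copy()
        moved[5] += 10.0  # residue 455
        prof = variability_profile(self._models([base, moved]))
        idx = list(prof.residue_numbers).index(455)
        assert prof.psi_iqr[idx] == pytest.approx(10.0, abs=1e-6)

    def test_perturbed_window_carries_highest_psi_variability(self, rng):
        # 8-model ensemble with psi noise confined to residues 450-456
        models = []
        for _ in range(8):
            psis = np.full(30, -47.0)
            window = (np.arange(30) + 440 >= 450) & (np.arange(30) + 440 <= 456)
            psis[window] += rng.normal(scale=35.0, size=window.sum())
            models.append(build_helical_peptide(30, -57.0, psis, first_residue=440))
        prof = variability_profile(models)
        argmax = prof.residue_numbers[np.nanargmax(prof.psi_iqr)]
        assert 450 <= argmax <= 456

    def test_invariant_to_360_relabeling(self):
        # same geometry, so profiles must match regardless of angle aliasing
        base = np.full(8, 170.0)
        moved = base.copy()
        moved[3] = -175.0  # 15 deg away through the wrap
        prof = variability_profile(self._models([base, moved], n_res=8))
        idx = list(prof.residue_numbers).index(453)
        assert prof.psi_iqr[idx] == pytest.approx(15.0, abs=1e-6)


class TestAssignStates:
    def test_preset_values_map_to_named_states(self):
        res = assign_states(np.array([-28.0, 143.0, 90.0]), HIS453_STATES)
        assert res.labels == ["in", "out", "unassigned"]

    def test_tie_goes_to_first_listed_state(self):
        a = AngularState("a", 0.0, 10.0)
        b = AngularState("b", 20.0, 10.0)
        res = assign_states(np.array([10.0]), [a, b])
        assert res.labels == ["a"]

    def test_unassigned_gap_is_transparent_for_transitions(self):
        vals = np.array([143.0, 90.0, -28.0, -28.0, 90.0, 143.0])
        res = assign_states(vals, HIS453_STATES)
        assert res.n_transitions == 2
        assert res.transition_counts[("out", "in")] == 1
        assert res.transition_counts[("in", "out")] == 1

    def test_markov_chain_recovery(self):
        spec = DihedralSwitcherSpec(n_frames=10_000, seed=11)
        series, truth = generate_dihedral_series(spec)
        res = assign_states(series, HIS453_STATES)
        labels = np.array(res.labels)
        assigned = labels != "unassigned"
        accuracy = np.mean(labels[assigned] == truth[assigned])
        assert accuracy >= 0.95
        # transition count against the ground-truth switch count
        true_transitions = int(np.sum(truth[1:] != truth[:-1]))
        assert res.n_transitions == pytest.approx(true_transitions, rel=0.2)

    def test_his453_windows_do_not_capture_perpendicular_angles(self):
        res = assign_states(np.array([90.0, -90.0]), HIS453_STATES)
        assert res.labels == ["unassigned", "unassigned"]


class TestDihedralSeries:
    def test_series_extraction_across_frames(self):
        frames = [
            build_helical_peptide(5, -57.0, [-47.0, -47.0, psi, -47.0, -47.0])
            for psi in (-40.0, -45.0, -50.0)
        ]
        series = dihedral_series(frames, 3, "psi")
        np.testing.assert_allclose(series.values, [-40.0, -45.0, -50.0], atol=1e-8)
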