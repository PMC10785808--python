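"""Ensemble container, readers, superposition and B-factor export."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import alloscope as al
from alloscope.errors import (
    ConsistencyError,
    DegenerateFitError,
    FormatError,
    FormattingError,
    SelectionError,
)

from conftest import random_rigid_transform


def toy_ensemble(n_residues=5, n_frames=2, seed=0):
    rng = np.random.default_rng(seed)
    ref = al.make_reference_chain(n_residues)
    coords = ref[None] + rng.normal(0, 0.2, size=(n_frames, n_residues, 3))
    return al.TrajectoryEnsemble(coords, al.chain_atoms(n_residues))


class TestAtomRecord:
    def test_flags_inferred_from_name(self):
        ca = al.AtomRecord.infer(5, "GLY", "CA")
        assert ca.is_calpha and ca.is_backbone_heavy
        side = al.AtomRecord.infer(5, "LYS", "NZ")
        assert not side.is_backbone_heavy and not side.is_calpha
        assert al.AtomRecord.infer(5, "GLY", "O").is_backbone_heavy

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            al.AtomRecord(1, "GLY", "", "C")
        with pytest.raises(ValueError):
            al.AtomRecord(1, "GLY", "CA", "C", is_backbone_heavy=False, is_calpha=True)


class TestResidueIndexMap:
    def test_bijection(self):
        m = al.ResidueIndexMap((2, 5, 9))
        assert [m.to_internal(m.to_author(i)) for i in range(3)] == [0, 1, 2]
        with pytest.raises(KeyError):
            m.to_internal(3)

    def test_rejects_non_increasing(self):
        with pytest.raises(ValueError):
            al.ResidueIndexMap((2, 2, 3))


class TestEnsemble:
    def test_mismatched_atom_count_rejected(self):
        with pytest.raises(ConsistencyError):
            al.TrajectoryEnsemble(np.zeros((1, 3, 3)), al.chain_atoms(2))

    def test_empty_selection_rejected(self):
        ens = toy_ensemble()
        with pytest.raises(SelectionError):
            ens.select(lambda a: a.atom_name == "ZZ")

    def test_discard_initial_uses_frame_times(self):
        ens = toy_ensemble(n_frames=4)
        ens.frame_times = np.array([0.0, 5.0, 10.0, 15.0])
        kept = ens.discard_initial(5.0)
        assert kept.n_frames == 3 and kept.frame_times[0] == 5.0

    def test_concatenate_discards_per_replica(self):
        a = toy_ensemble(n_frames=4, seed=1)
        a.frame_times = np.arange(4.0)
        b = toy_ensemble(n_frames=4, seed=2)
        b.frame_times = np.arange(4.0)
        meta = al.concatenate([a, b], discard_initial_ps=2.0)
        assert meta.n_frames == 4  # two frames survive per replica


class TestReaders:
    def test_pdb_multimodel_roundtrip(self, tmp_path):
        ens = toy_ensemble(n_residues=3, n_frames=2)
        path = tmp_path / "two_models.pdb"
        path.write_text(ens.to_pdb_text())
        back = al.read_trajectory(path, "pdb_multimodel")
        assert (back.n_frames, back.n_atoms) == (2, 3)
        # PDB coordinate fields carry 0.001 A precision
        assert np.abs(back.coordinates - ens.coordinates).max() <= 1e-3

    def test_calpha_selection_keeps_one_atom_per_residue(self, tmp_path):
        ens = toy_ensemble(n_residues=5, n_frames=1)
        path = tmp_path / "chain.pdb"
        path.write_text(ens.to_pdb_text())
        back = al.read_trajectory(path, "pdb_multimodel", selection=lambda a: a.is_calpha)
        assert back.n_atoms == 5

    def test_model_with_missing_atom_is_inconsistent(self, tmp_path):
        ens = toy_ensemble(n_residues=3, n_frames=2)
        lines = ens.to_pdb_text().splitlines()
        # drop the last ATOM record of model 2
        drop = max(i for i, l in enumerate(lines) if l.startswith("ATOM"))
        path = tmp_path / "bad.pdb"
        path.write_text("\n".join(lines[:drop] + lines[drop + 1 :]) + "\n")
        with pytest.raises(ConsistencyError):
            al.read_trajectory(path, "pdb_multimodel")

    def test_unparseable_file_raises_format_error(self, tmp_path):
        path = tmp_path / "junk.csv"
        path.write_text("not,a,fixture\n1,2,3\n")
        with pytest.raises(FormatError):
            al.read_trajectory(path, "csv")
        with pytest.raises(FormatError):
            al.read_trajectory(path, "nonsense")

    def test_csv_roundtrip_preserves_coordinates(self, tmp_path):
        ens = toy_ensemble(n_residues=4, n_frames=3)
        path = tmp_path / "fixture.csv"
        ens.to_csv(path)
        back = al.read_trajectory(path, "csv")
        np.testing.assert_allclose(back.coordinates, ens.coordinates, atol=1e-12)
        assert back.residue_numbers.tolist() == ens.residue_numbers.tolist()


class TestKabsch:
    def test_identity(self):
        frame = toy_ensemble(6, 1).frame(0)
        fitted, rmsd = al.kabsch_superpose(frame, frame)
        assert rmsd < 1e-12
        np.testing.assert_allclose(fitted, frame, atol=1e-9)

    def test_removes_rigid_motion(self):
        frame = toy_ensemble(6, 1).frame(0)
        rot = Rotation.from_euler("z", 90, degrees=True)
        moved = rot.apply(frame) + np.array([5.0, 5.0, 5.0])
        fitted, rmsd = al.kabsch_superpose(moved, frame)
        assert rmsd < 1e-9
        np.testing.assert_allclose(fitted, frame, atol=1e-7)

    def test_matches_rotation_grid_search(self):
        """Optimal RMSD agrees with a brute-force search over rotations."""
        rng = np.random.default_rng(3)
        for _ in range(3):
            mobile = rng.uniform(-3, 3, size=(4, 3))
            reference = rng.uniform(-3, 3, size=(4, 3))
            _, rmsd = al.kabsch_superpose(mobile, reference)
            assert abs(rmsd - _grid_search_rmsd(mobile, reference)) < 1e-3

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_rmsd_invariant_under_rigid_pretransform_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-5, 5, size=(7, 3))
        y = rng.uniform(-5, 5, size=(7, 3))
        rot, shift = random_rigid_transform(rng)
        _, r_xy = al.kabsch_superpose(x, y)
        _, r_moved = al.kabsch_superpose(rot.apply(x) + shift, y)
        _, r_yx = al.kabsch_superpose(y, x)
        assert abs(r_xy - r_moved) < 1e-9
        assert abs(r_xy - r_yx) < 1e-9
        # fitting can only lower the fit-set RMSD
        raw = np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1)))
        assert r_xy <= raw + 1e-12

    def test_degenerate_fits_rejected(self):
        with pytest.raises(DegenerateFitError):
            al.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(DegenerateFitError):
            al.kabsch_superpose(line, line)


def _grid_search_rmsd(mobile, reference):
    """Brute-force minimum RMSD over rotations: a 6° Euler-angle grid over
    all of SO(3), then local refinement around the best few basins."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def batch_rmsd(angles):
        mats = Rotation.from_euler("zyz", angles).as_matrix()
        moved = np.einsum("kij,aj->kai", mats, mob)
        return np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=2), axis=1))

    coarse_axes = [
        np.arange(-180.0, 180.0, 6.0),
        np.arange(0.0, 180.0 + 1e-9, 6.0),  # zyz: b in [0, 180] covers SO(3)
        np.arange(-180.0, 180.0, 6.0),
    ]
    grid = np.array(np.meshgrid(*coarse_axes, indexing="ij")).reshape(3, -1).T
    vals = batch_rmsd(grid)
    best = np.inf
    for k in np.argsort(vals)[:5]:  # refine several basins, keep the lowest
        center, span = grid[k], 6.0
        for _ in range(3):
            axes = [np.linspace(c - span, c + span, 21) for c in center]
            sub = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
            sub_vals = batch_rmsd(sub)
            j = int(np.argmin(sub_vals))
            center, span = sub[j], span / 8
            best = min(best, float(sub_vals[j]))
    return best


class TestScoreExport:
    def test_score_lands_in_bfactor_field(self):
        ens = toy_ensemble(3, 1)
        sv = al.ScoreVector("DF", ens.residue_numbers, [1.0, 2.5, 0.0], "high_means_mobile")
        text = al.write_scores_to_pdb(ens.frame(0), ens.atoms, sv)
        fields = [l[60:66] for l in text.splitlines() if l.startswith("ATOM")]
        assert fields == ["  1.00", "  2.50", "  0.00"]

    def test_unscored_residue_filled_and_warned(self, caplog):
        ens = toy_ensemble(3, 1)
        sv = al.ScoreVector("DF", ens.residue_numbers[:2], [1.0, 2.0], "high_means_mobile")
        with caplog.at_level(logging.WARNING):
            text = al.write_scores_to_pdb(ens.frame(0), ens.atoms, sv)
        fields = [l[60:66] for l in text.splitlines() if l.startswith("ATOM")]
        assert fields[-1] == "  0.00"
        assert any("no score" in r.message for r in caplog.records)

    def test_roundtrip_through_pdb(self, tmp_path):
        ens = toy_ensemble(4, 1)
        values = [0.12, 3.45, 99.99, 7.0]
        sv = al.ScoreVector("ATD", ens.residue_numbers, values, "high_means_mobile")
        path = tmp_path / "scored.pdb"
        al.write_scores_to_pdb(ens.frame(0), ens.atoms, sv, path=path)
        fields = [
            float(l[60:66]) for l in path.read_text().splitlines() if l.startswith("ATOM")
        ]
        np.testing.assert_allclose(fields, values, atol=0.01)

    def test_unrepresentable_score_raises(self):
        ens = toy_ensemble(2, 1)
        sv = al.ScoreVector("DF", ens.residue_numbers, [1.0, 1e7], "high_means_mobile")
        with pytest.raises(FormattingError):
            al.write_scores_to_pdb(ens.frame(0), ens.atoms, sv)
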