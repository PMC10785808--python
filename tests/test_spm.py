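"""Shortest path map: clustering, correlation, contacts, path accumulation."""

import logging

import networkx as nx
import numpy as np
import pytest

import alloscope as al
from alloscope.errors import ConsistencyError, CorrelationRangeError
from alloscope.spm import CorrelationMatrix, _pairwise_ca_rmsd
from alloscope.synthetic import CA_SPACING

from oracles import enumerate_shortest_paths, random_connected_graph


def graph_with_correlations(edges_with_c, n, first_residue=2):
    """Build a contact graph + correlation matrix from explicit |C| values."""
    residues = tuple(range(first_residue, first_residue + n))
    g = nx.Graph(residue_numbers=residues)
    g.add_nodes_from(residues)
    corr = np.eye(n)
    for (i, j), c in edges_with_c.items():
        g.add_edge(residues[i], residues[j], mean_distance=5.0)
        corr[i, j] = corr[j, i] = c
    cm = CorrelationMatrix(corr, al.ResidueIndexMap(residues), np.zeros((n, 3)))
    return g, cm


class TestClusterReference:
    def test_single_frame_returns_itself(self, helix60):
        ens = al.TrajectoryEnsemble(helix60[None], al.chain_atoms(60))
        ref = al.reference_from_clustering(ens)
        np.testing.assert_array_equal(ref.frame, helix60)
        assert ref.cluster_sizes == {1: 1}

    def test_majority_conformer_wins(self):
        """70/30 mix of two rigid conformers: medoid sits in the majority one.

        Oracle: every frame is assigned brute-force to its nearest known
        conformer by superposed Cα RMSD.
        """
        a = al.make_reference_chain(12)
        b = al.make_reference_chain(12, rise=2.5, turn=100.0)
        rng = np.random.default_rng(21)
        frames = [a + rng.normal(0, 0.05, a.shape) for _ in range(14)]
        frames += [b + rng.normal(0, 0.05, b.shape) for _ in range(6)]
        order = rng.permutation(20)
        coords = np.stack(frames)[order]
        ens = al.TrajectoryEnsemble(coords, al.chain_atoms(12))
        ref = al.reference_from_clustering(ens, cutoff=1.0)
        d_a = al.kabsch_superpose(ref.frame, a)[1]
        d_b = al.kabsch_superpose(ref.frame, b)[1]
        assert d_a < d_b
        # brute-force assignment agrees the majority cluster is conformer a
        assignments = [
            al.kabsch_superpose(f, a)[1] < al.kabsch_superpose(f, b)[1]
            for f in coords
        ]
        assert sum(assignments) == 14

    def test_medoid_close_to_frame_average(self, helix60):
        spec = al.CovarianceSpec(blocks=(), sigma=0.1)
        ens = al.sample_equilibrium_ensemble(helix60, spec, 80, seed=9)
        ref = al.reference_from_clustering(ens, cutoff=2.0)
        _, rmsd = al.kabsch_superpose(ref.frame, ens.coordinates.mean(axis=0))
        assert rmsd < 0.3

    def test_max_frames_subsampling_still_returns_ensemble_frame(self, helix60):
        spec = al.CovarianceSpec(blocks=(), sigma=0.1)
        ens = al.sample_equilibrium_ensemble(helix60, spec, 50, seed=9)
        ref = al.reference_from_clustering(ens, cutoff=2.0, max_frames=10)
        np.testing.assert_array_equal(ref.frame, ens.coordinates[ref.frame_index])


class TestCorrelationMatrix:
    def test_diagonal_is_one_for_fluctuating_residues(self, make_block_ensemble):
        ens = make_block_ensemble(seed=4, n_frames=50)
        corr = al.correlation_matrix(ens, al.reference_from_clustering(ens))
        assert np.all(np.diag(corr.values) == 1.0)
        assert np.all(np.abs(corr.values) <= 1.0)

    def test_identical_and_opposite_displacements(self, helix60):
        rng = np.random.default_rng(0)
        coords = np.repeat(helix60[None], 30, axis=0)
        wiggle = rng.normal(0, 0.3, size=(30, 3))
        coords[:, 1] += wiggle
        coords[:, 4] += wiggle  # identical displacement
        coords[:, 7] -= wiggle  # exactly opposite
        ens = al.TrajectoryEnsemble(coords, al.chain_atoms(60))
        corr = al.correlation_matrix(ens, helix60, fit=False)
        assert corr.values[1, 4] == pytest.approx(1.0, abs=1e-12)
        assert corr.values[1, 7] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_residue_zeroed_with_warning(self, helix60, caplog):
        rng = np.random.default_rng(1)
        coords = np.repeat(helix60[None], 20, axis=0)
        coords[:, 1:] += rng.normal(0, 0.2, size=(20, 59, 3))  # residue 0 frozen
        ens = al.TrajectoryEnsemble(coords, al.chain_atoms(60))
        with caplog.at_level(logging.WARNING):
            corr = al.correlation_matrix(ens, helix60, fit=False)
        assert np.all(corr.values[0] == 0) and np.all(corr.values[:, 0] == 0)
        assert any("zero displacement variance" in r.message for r in caplog.records)


class TestContactGraph:
    def test_straight_chain_has_only_sequence_neighbours(self):
        chain = al.make_reference_chain(8, rise=CA_SPACING, turn=0.0)
        ens = al.TrajectoryEnsemble(chain[None], al.chain_atoms(8))
        g = al.contact_graph(ens, cutoff=6.0)
        expected = {(r, r + 1) for r in range(2, 9)}
        assert {tuple(sorted(e)) for e in g.edges} == expected

    def test_zero_cutoff_gives_empty_graph(self, helix60):
        ens = al.TrajectoryEnsemble(helix60[None], al.chain_atoms(60))
        assert al.contact_graph(ens, cutoff=0.0).number_of_edges() == 0

    def test_strict_inequality_at_boundary(self):
        def pair_at(mean_d):
            c = np.array([[[0.0, 0, 0], [mean_d - 1, 0, 0]], [[0, 0, 0], [mean_d + 1, 0, 0]]])
            return al.TrajectoryEnsemble(c, al.chain_atoms(2))

        assert al.contact_graph(pair_at(5.9)).number_of_edges() == 1
        assert al.contact_graph(pair_at(6.1)).number_of_edges() == 0
        assert al.contact_graph(pair_at(6.0)).number_of_edges() == 0  # strict


class TestSPMBuild:
    def test_perfect_correlation_gives_zero_length(self):
        g, cm = graph_with_correlations({(0, 1): 1.0, (1, 2): 0.5}, 3)
        res = al.spm_build(g, cm)
        e01 = res.edges.set_index(["residue_i", "residue_j"]).loc[(2, 3)]
        assert e01["length"] == 0.0

    def test_three_node_path_graph_by_enumeration(self):
        """A–B–C with both |C| = e^{-1}: 3 pair-paths, usages (2, 2), B visited once."""
        c = float(np.exp(-1))
        g, cm = graph_with_correlations({(0, 1): c, (1, 2): c}, 3)
        res = al.spm_build(g, cm)
        np.testing.assert_allclose(res.edges["length"], [1.0, 1.0], atol=1e-12)
        assert res.edges["usage"].tolist() == [2, 2]
        assert res.edges["normalized_weight"].tolist() == [1.0, 1.0]
        assert res.prominence.values.tolist() == [0.0, 1.0, 0.0]
        assert res.n_paths == 3 and res.unreachable_pairs == 0

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            g0 = random_connected_graph(rng, n)
            edges = {tuple(e): rng.uniform(0.05, 0.99) for e in g0.edges}
            g, cm = graph_with_correlations(edges, n)
            res = al.spm_build(g, cm)
            lengths = {e: -np.log(c) for e, c in edges.items()}
            oracle = enumerate_shortest_paths(g0, lengths)
            impl = {
                (r.residue_i - 2, r.residue_j - 2): r.usage
                for r in res.edges.itertuples()
            }
            assert impl == oracle["usage"]
            assert res.prominence.values.tolist() == [
                float(oracle["visits"][v]) for v in range(n)
            ]

    def test_isolated_node_counts_unreachable_pairs(self):
        g, cm = graph_with_correlations({(0, 1): 0.5}, 3)  # node 2 isolated
        res = al.spm_build(g, cm)
        assert res.unreachable_pairs == 2  # N-1 pairs involve the isolated node
        assert res.n_paths == 1

    def test_zero_correlation_edge_dropped_as_infinite(self):
        g, cm = graph_with_correlations({(0, 1): 0.0, (1, 2): 0.5}, 3)
        res = al.spm_build(g, cm)
        assert res.dropped_zero_correlation_edges == 1
        assert len(res.edges) == 1

    def test_correlation_above_one_raises(self):
        g, cm = graph_with_correlations({(0, 1): 0.5}, 2)
        cm.values[0, 1] = cm.values[1, 0] = 1.0 + 1e-6
        with pytest.raises(CorrelationRangeError):
            al.spm_build(g, cm)

    def test_residue_mismatch_raises(self):
        g, _ = graph_with_correlations({(0, 1): 0.5}, 2)
        _, cm3 = graph_with_correlations({(0, 1): 0.5}, 3)
        with pytest.raises(ConsistencyError):
            al.spm_build(g, cm3)

    def test_uniform_correlation_scaling_preserves_routes(self):
        """Scaling all |C| by γ adds −ln γ per edge; routes are unchanged
        on a fixture whose shortest routes all have equal hop counts."""
        rng = np.random.default_rng(5)
        n = 6
        g0 = nx.cycle_graph(n)
        edges = {tuple(sorted(e)): rng.uniform(0.6, 0.9) for e in g0.edges}
        g, cm = graph_with_correlations(edges, n)
        base = al.spm_build(g, cm)
        gamma = 0.5
        g2, cm2 = graph_with_correlations(
            {e: c * gamma for e, c in edges.items()}, n
        )
        scaled = al.spm_build(g2, cm2)
        np.testing.assert_allclose(
            scaled.edges["length"], base.edges["length"] - np.log(gamma), atol=1e-12
        )
        assert scaled.edges["usage"].tolist() == base.edges["usage"].tolist()

    def test_normalized_weights_in_unit_interval_with_max_one(self, block_pipeline):
        _, _, spm = block_pipeline
        used = spm.edges[spm.edges["usage"] > 0]
        assert used["normalized_weight"].max() == 1.0
        assert ((used["normalized_weight"] > 0) & (used["normalized_weight"] <= 1)).all()
        assert set(spm.thresholded_edges.index) <= set(spm.edges.index)

    def test_exports(self, tmp_path, block_pipeline):
        _, _, spm = block_pipeline
        spm.to_tsv(tmp_path / "spm.tsv")
        spm.to_graphml(tmp_path / "spm.graphml")
        spm.prominence.to_tsv(tmp_path / "prominence.tsv")
        g = nx.read_graphml(tmp_path / "spm.graphml")
        assert g.number_of_edges() == len(spm.edges)


def test_pairwise_rmsd_is_symmetric_zero_diagonal(helix60):
    spec = al.CovarianceSpec(blocks=(), sigma=0.2)
    ens = al.sample_equilibrium_ensemble(helix60, spec, 6, seed=2)
    m = _pairwise_ca_rmsd(ens.coordinates)
    assert np.allclose(m, m.T) and np.all(np.diag(m) == 0)
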