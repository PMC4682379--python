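"""Generator contracts: planted structure, expression moments, determinism."""

import numpy as np
import pytest

from coremark.synthetic import (
    generate_docking_scores,
    generate_ground_truth,
    make_candidate_network,
    simulate_expression,
)
from coremark.cocktail import multi_target_ligands, top_k_ligands


class TestGroundTruth:
    def test_exactly_perturbed_rows_differ(self):
        truth = generate_ground_truth(M=10, edge_density=0.2, n_cancers=1,
                                      core_size=2, specific_size=0,
                                      effect_size=0.5, seed=1)
        (cid,) = truth.A_cancer_per_type
        diff = truth.A_cancer_per_type[cid] - truth.A_normal
        changed = {truth.protein_ids[i] for i in np.nonzero(diff.any(axis=1))[0]}
        # rows of perturbed proteins change, and changes touch nothing else
        assert truth.perturbed_core <= changed
        untouched = changed - truth.perturbed_core
        for p in untouched:  # only via an edge shared with a perturbed protein
            i = truth.protein_ids.index(p)
            js = np.nonzero(diff[i])[0]
            assert all(truth.protein_ids[j] in truth.perturbed_core for j in js)

    def test_zero_effect_gives_identical_conditions(self):
        truth = generate_ground_truth(M=12, edge_density=0.25, n_cancers=2,
                                      core_size=2, specific_size=1,
                                      effect_size=0.0, seed=3)
        for A in truth.A_cancer_per_type.values():
            np.testing.assert_array_equal(A, truth.A_normal)

    def test_core_is_intersection_of_perturbed_sets(self):
        truth = generate_ground_truth(M=28, edge_density=0.2, n_cancers=4,
                                      core_size=5, specific_size=2, seed=5)
        per_cancer = [truth.perturbed_core | spec
                      for spec in truth.perturbed_specific.values()]
        assert frozenset.intersection(*per_cancer) == truth.perturbed_core
        assert len(truth.perturbed_core) == 5

    def test_stability_and_symmetry_invariants(self):
        truth = generate_ground_truth(M=20, edge_density=0.3, n_cancers=2,
                                      core_size=3, specific_size=2, seed=11)
        for A in [truth.A_normal, *truth.A_cancer_per_type.values()]:
            assert max(abs(np.linalg.eigvals(A))) < 1.0
            np.testing.assert_array_equal(A, A.T)
            assert not np.diag(A).any()

    @pytest.mark.parametrize("kwargs", [
        dict(M=0, edge_density=0.2, n_cancers=1, core_size=0),
        dict(M=10, edge_density=1.5, n_cancers=1, core_size=0),
        dict(M=10, edge_density=0.2, n_cancers=2, core_size=4, specific_size=4),
        dict(M=10, edge_density=0.001, n_cancers=1, core_size=0),
    ])
    def test_rejects_infeasible_requests(self, kwargs):
        with pytest.raises(ValueError):
            generate_ground_truth(**kwargs)


class TestSimulateExpression:
    def test_pure_noise_has_identity_covariance(self):
        expr = simulate_expression(np.zeros((6, 6)), 5000, 1.0, seed=2)
        cov = np.cov(expr.values)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 0.1
        assert np.abs(np.diag(cov) - 1.0).max() < 0.1

    def test_single_edge_correlation_matches_closed_form(self):
        A = np.zeros((2, 2))
        A[0, 1] = A[1, 0] = 0.5
        expr = simulate_expression(A, 5000, 1.0, seed=4)
        corr = np.corrcoef(expr.values)[0, 1]
        # closed form: corr of (I-A)^{-1} w components = 2a/(1+a^2) = 0.8
        assert corr > 0.5
        assert corr == pytest.approx(0.8, abs=0.03)

    def test_deterministic_under_seed(self):
        A = np.zeros((3, 3))
        a = simulate_expression(A, 50, 0.5, seed=9)
        b = simulate_expression(A, 50, 0.5, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_variance_converges_to_noise_level(self):
        expr = simulate_expression(np.zeros((4, 4)), 10_000, 0.7, seed=6)
        rel_err = np.abs(expr.values.var(axis=1) - 0.49) / 0.49
        assert rel_err.max() < 0.05

    def test_rejects_unstable_system_and_bad_noise(self):
        A = np.eye(2)[::-1] * 1.2  # spectral radius 1.2
        with pytest.raises(ValueError, match="spectral radius"):
            simulate_expression(A, 10, 1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_expression(np.zeros((2, 2)), 10, -1.0, seed=0)


class TestCandidateNetwork:
    def test_no_contamination_returns_true_edges(self):
        truth = generate_ground_truth(M=10, edge_density=0.3, n_cancers=1,
                                      core_size=0, specific_size=0, seed=7)
        cand, labels = make_candidate_network(truth, 0, seed=8)
        assert cand == truth.true_edges()
        assert all(labels.values())

    def test_count_conservation_and_label_partition(self):
        truth = generate_ground_truth(M=10, edge_density=0.3, n_cancers=1,
                                      core_size=0, specific_size=0, seed=7)
        cand, labels = make_candidate_network(truth, 10, seed=8)
        true_edges = truth.true_edges()
        assert len(cand) == len(true_edges) + 10
        assert {e for e, t in labels.items() if t} == true_edges
        assert {e for e, t in labels.items() if not t} == cand - true_edges

    def test_rejects_excess_false_positives(self):
        truth = generate_ground_truth(M=5, edge_density=0.3, n_cancers=1,
                                      core_size=0, specific_size=0, seed=7)
        non_edges = 10 - len(truth.true_edges())
        with pytest.raises(ValueError):
            make_candidate_network(truth, non_edges + 1, seed=0)


class TestDockingScores:
    def test_nothing_planted_yields_no_multi_target_drug(self):
        proteins = [f"P{i}" for i in range(5)]
        table, planted = generate_docking_scores(proteins, n_drugs=30,
                                                 n_multi_target=0, top_k=5, seed=1)
        assert planted == frozenset()
        assert multi_target_ligands(top_k_ligands(table, 5), 2) == {}

    def test_planted_drugs_are_recovered(self):
        proteins = [f"P{i}" for i in range(6)]
        table, planted = generate_docking_scores(proteins, n_drugs=40,
                                                 n_multi_target=3,
                                                 targets_per_multi=2,
                                                 top_k=5, seed=2)
        multi = multi_target_ligands(top_k_ligands(table, 5), 2)
        assert set(multi) == planted
        assert all(len(ps) == 2 for ps in multi.values())

    def test_scores_within_range_and_deterministic(self):
        proteins = ["A", "B", "C"]
        t1, _ = generate_docking_scores(proteins, 20, 2, 2, (50.0, 150.0), 4, seed=3)
        t2, _ = generate_docking_scores(proteins, 20, 2, 2, (50.0, 150.0), 4, seed=3)
        assert t1.frame.equals(t2.frame)
        assert t1.frame["score"].between(50.0, 150.0).all()
        counts = t1.frame.groupby("protein_id").size()
        assert (counts >= 4).all()

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            generate_docking_scores([], 10, 0, 2, (0, 1), seed=0)
        with pytest.raises(ValueError):
            generate_docking_scores(["A"], 10, 0, 2, (1.0, 1.0), seed=0)


def test_generator_outputs_serialize_identically(tmp_path):
    """Same seed => byte-identical files after a write/write round."""
    from coremark import io as cio
    for sub in ("a", "b"):
        d = tmp_path / sub
        d.mkdir()
        truth = generate_ground_truth(M=8, edge_density=0.3, n_cancers=1,
                                      core_size=2, specific_size=0, seed=13)
        cand, _ = make_candidate_network(truth, 3, seed=14)
        expr = simulate_expression(truth.A_normal, 20, 0.3, seed=15,
                                   protein_ids=truth.protein_ids)
        cio.write_edge_list(cand, d / "net.tsv")
        cio.write_expression(expr, d / "expr.tsv")
    for name in ("net.tsv", "expr.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
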