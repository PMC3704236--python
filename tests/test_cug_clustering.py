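import numpy as np
import pytest

from codonscape.bias_metrics import CodonCounts
from codonscape.cug_clustering import (
    ClusterModel,
    centered_heatmap_matrix,
    counts_matrix,
    fit_clusters,
    heatmap_order,
    null_B,
    pooled_family_frequencies,
    select_S,
    self_consistency,
    stability_B,
    _normalize_theta,
)
from codonscape.genetic_code import CODON_TO_AA, DEGENERACY, DEGENERATE_CODONS, FAMILIES


class TestFitClusters:
    def test_single_cluster_is_pooled_frequencies(self, sim_small_counts):
        X, ids = counts_matrix(sim_small_counts)
        m = fit_clusters(X, 1, seed=0, gene_ids=ids)
        pooled = pooled_family_frequencies(X)
        # pseudocount-smoothed theta approaches pooled frequencies
        assert np.allclose(m.theta[0], pooled, atol=5e-3)
        assert all(b == pytest.approx(1.0) for b in m.selfcons.values())
        assert m.B == pytest.approx(1.0)

    def test_recovers_planted_two_clusters_exactly(self, sim_small, sim_small_counts):
        from sklearn.metrics import adjusted_rand_score

        X, ids = counts_matrix(sim_small_counts)
        m = fit_clusters(X, 2, seed=3, gene_ids=ids)
        truth = [sim_small.truth["labels"][g] for g in ids]
        pred = [m.assignments[g] for g in ids]
        assert adjusted_rand_score(truth, pred) == pytest.approx(1.0)

    def test_duplicated_genes_get_identical_assignments(self, sim_small_counts):
        dup = [
            CodonCounts(f"{c.gene_id}_copy", dict(c.counts)) for c in sim_small_counts
        ]
        m = fit_clusters(sim_small_counts + dup, 2, seed=3)
        for c in sim_small_counts:
            assert (
                m.assignments[c.gene_id] == m.assignments[f"{c.gene_id}_copy"]
            )

    def test_deterministic_given_seed(self, sim_small_counts):
        m1 = fit_clusters(sim_small_counts, 2, seed=9)
        m2 = fit_clusters(sim_small_counts, 2, seed=9)
        assert m1.assignments == m2.assignments
        assert m1.log_likelihood == m2.log_likelihood

    def test_loglik_trace_non_decreasing(self, sim_small_counts):
        m = fit_clusters(sim_small_counts, 2, seed=3)
        trace = np.asarray(m.ll_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_needs_enough_genes(self, sim_small_counts):
        with pytest.raises(ValueError):
            fit_clusters(sim_small_counts[:2], 5, seed=0)


class TestSelfConsistency:
    def test_bg_in_unit_interval(self, sim_small_counts):
        m = fit_clusters(sim_small_counts, 2, seed=3)
        bg, B = self_consistency(m, sim_small_counts)
        assert np.all(bg > 0) and np.all(bg <= 1)
        assert 0 < B <= 1

    def test_duplicated_theta_gives_half(self, sim_small_counts):
        X, ids = counts_matrix(sim_small_counts)
        base = fit_clusters(X, 1, seed=0, gene_ids=ids)
        twin = ClusterModel(
            S=2,
            theta=np.vstack([base.theta[0], base.theta[0]]),
            weights=np.array([0.5, 0.5]),
            assignments={g: 0 for g in ids},
            selfcons={g: 0.5 for g in ids},
            log_likelihood=0.0,
        )
        bg, B = self_consistency(twin, X, gene_ids=ids)
        assert np.allclose(bg, 0.5)
        assert B == pytest.approx(0.5)


class TestModelSelection:
    def test_null_B_deterministic(self, sim_small_counts):
        X, _ = counts_matrix(sim_small_counts)
        a = null_B(X, 2, n_reps=2, seed=5, n_restarts=3)
        b = null_B(X, 2, n_reps=2, seed=5, n_restarts=3)
        assert a == b

    def test_null_below_real_when_structure_planted(self, sim_small_counts):
        X, _ = counts_matrix(sim_small_counts)
        b_real, _ = stability_B(X, 2, n_reps=3, seed=5, n_restarts=3)
        b_rand, _ = null_B(X, 2, n_reps=3, seed=5, n_restarts=3)
        assert b_rand < b_real

    def test_s_equals_one_has_unit_scores(self, sim_small_counts):
        X, _ = counts_matrix(sim_small_counts)
        assert stability_B(X, 1, n_reps=2, seed=1)[0] == 1.0
        assert null_B(X, 1, n_reps=2, seed=1)[0] == 1.0

    def test_select_recovers_planted_two(self, sim_small_counts):
        X, ids = counts_matrix(sim_small_counts)
        sel = select_S(X, range(1, 5), seed=7, n_reps=3, n_restarts=4, gene_ids=ids)
        assert sel.chosen_S == 2

    def test_null_genome_chooses_one_by_tie_rule(self, rng):
        # codons drawn from one shared distribution: Delta ~ 0 everywhere
        from codonscape.cug_clustering import resample_null_counts

        counts = []
        for i in range(80):
            c = {}
            for aa, fam in FAMILIES.items():
                if DEGENERACY[aa] < 2:
                    continue
                draws = rng.multinomial(12, np.ones(len(fam)) / len(fam))
                for codon, k in zip(fam, draws):
                    c[codon] = int(k)
            counts.append(CodonCounts(f"g{i}", c))
        X, ids = counts_matrix(counts)
        sel = select_S(X, range(1, 4), seed=11, n_reps=2, n_restarts=3, gene_ids=ids)
        assert sel.chosen_S == 1


class TestCenteredHeatmap:
    def test_uniform_cluster_column_is_zero(self, sim_small_counts):
        X, ids = counts_matrix(sim_small_counts)
        theta = _normalize_theta(np.ones((1, 61)))
        m = ClusterModel(
            S=1,
            theta=theta,
            weights=np.array([1.0]),
            assignments={g: 0 for g in ids},
            selfcons={g: 1.0 for g in ids},
            log_likelihood=0.0,
        )
        mat = centered_heatmap_matrix(m)
        assert np.allclose(mat.to_numpy(), 0.0)

    def test_exclusive_codon_endpoints(self):
        theta = _normalize_theta(np.ones((1, 61)))
        # all Val usage on GTT
        from codonscape.cug_clustering import _CODON_INDEX

        for c in FAMILIES["V"]:
            theta[0, _CODON_INDEX[c]] = 1.0 if c == "GTT" else 0.0
        m = ClusterModel(
            S=1,
            theta=theta,
            weights=np.array([1.0]),
            assignments={},
            selfcons={},
            log_likelihood=0.0,
        )
        mat = centered_heatmap_matrix(m)
        assert mat.loc["GTT", "CUG0"] == pytest.approx(1.0)
        for c in FAMILIES["V"]:
            if c != "GTT":
                assert mat.loc[c, "CUG0"] == pytest.approx(-1 / 3)

    def test_family_centered_values_sum_to_zero(self, sim_small_counts):
        m = fit_clusters(sim_small_counts, 2, seed=3)
        mat = centered_heatmap_matrix(m)
        for aa, fam in FAMILIES.items():
            if DEGENERACY[aa] < 2:
                continue
            d = DEGENERACY[aa]
            # sum over family of (p - 1/d) is zero, so centered values
            # weighted by (1 - 1/d) sum to zero as well
            col = mat.loc[list(fam)].to_numpy() * (1 - 1 / d)
            assert np.allclose(col.sum(axis=0), 0.0, atol=1e-9)

    def test_heatmap_order_is_permutation(self, sim_small_counts):
        m = fit_clusters(sim_small_counts, 2, seed=3)
        mat = centered_heatmap_matrix(m)
        ordered = heatmap_order(mat)
        assert sorted(ordered.index) == sorted(mat.index)
        assert set(ordered.columns) == set(mat.columns)
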