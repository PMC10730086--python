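"""DEG set algebra, trajectory clustering, enrichment and mode calls."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

import apexprof as ap
from apexprof.degmodes import fisher_greater_p


class TestLogTransform:
    @pytest.mark.parametrize("fpkm,expected", [(0.0, 0.0), (1.0, 1.0), (3.0, 2.0)])
    def test_known_values(self, fpkm, expected):
        assert ap.log_transform(fpkm) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ap.log_transform(-1.0)

    def test_dataframe_round_trip(self):
        df = pd.DataFrame({"a": [0.0, 3.0]}, index=["g1", "g2"])
        out = ap.log_transform(df)
        assert isinstance(out, pd.DataFrame)
        assert out.loc["g2", "a"] == pytest.approx(2.0)


class TestCallDegs:
    @staticmethod
    def _table(padj):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(padj))],
             "log2fc": np.zeros(len(padj)), "padj": padj}
        )

    def test_all_insignificant_gives_empty_set(self):
        assert ap.call_degs(self._table([1.0, 1.0, 1.0])) == frozenset()

    def test_threshold_one_keeps_everything(self):
        table = self._table([0.2, 0.9, 0.5])
        assert ap.call_degs(table, 1.0) == frozenset(table["gene_id"])

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            ap.call_degs(pd.DataFrame({"gene_id": ["g1"]}))

    def test_recovers_truth_regulated_genes(self):
        params = ap.ExpressionSimParams(n_background=400, n_gradual=50,
                                        n_ectopic=20, seed=2)
        tables, truth = ap.generate_contrast_tables(params)
        degs = ap.call_degs(tables["tfl1_13v7"], 0.05)
        regulated = set(truth.loc[truth["archetype"] != "background",
                                  "gene_id"])
        background = set(truth.loc[truth["archetype"] == "background",
                                   "gene_id"])
        recall = len(degs & regulated) / len(regulated)
        fpr = len(degs & background) / len(background)
        assert recall > 0.8
        assert fpr < 0.10


class TestSetAlgebra:
    def test_identical_sets_difference_empty(self):
        s = frozenset("abc")
        assert ap.genotype_specific_degs(s, s) == frozenset()

    def test_disjoint_sets_difference_unchanged(self):
        assert ap.genotype_specific_degs(frozenset("ab"), frozenset("cd")) == \
            frozenset("ab")

    def test_random_sets_match_membership_scan(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(200)]
        for _ in range(20):
            a = frozenset(g for g in universe if rng.random() < 0.3)
            b = frozenset(g for g in universe if rng.random() < 0.3)
            expected = frozenset(g for g in universe if g in a and g not in b)
            assert ap.genotype_specific_degs(a, b) == expected

    def test_equal_sets_partition_to_shared_only(self):
        s = frozenset("xyz")
        part = ap.partition_timepoints(s, s)
        assert part.only_a == frozenset() and part.only_b == frozenset()
        assert part.both == s

    @given(
        a=st.frozensets(st.integers(min_value=0, max_value=100)),
        b=st.frozensets(st.integers(min_value=0, max_value=100)),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partition_conserves_counts(self, a, b):
        part = ap.partition_timepoints(a, b)
        sizes = part.sizes()
        assert sizes["only_a"] + sizes["only_b"] + sizes["both"] == sizes["union"]
        assert part.only_a.isdisjoint(part.only_b)
        assert part.only_a.isdisjoint(part.both)
        assert part.only_b.isdisjoint(part.both)
        assert part.union == a | b


class TestFoldChangeMatrix:
    @staticmethod
    def _tables(values: dict[str, dict[str, float]]):
        out = {}
        for name, gene_vals in values.items():
            out[name] = pd.DataFrame(
                {"gene_id": list(gene_vals), "log2fc": list(gene_vals.values()),
                 "padj": 0.5}
            )
        return out

    def test_single_shared_gene(self):
        tables = self._tables({"t7": {"g1": 0.1}, "t10": {"g1": 2.0}})
        matrix, dropped = ap.build_fc_matrix(tables, ["g1"], ["t7", "t10"])
        assert matrix.shape == (1, 2)
        assert matrix.loc["g1", "t10"] == 2.0
        assert dropped == []

    def test_missing_gene_dropped_and_reported(self):
        tables = self._tables({"t7": {"g1": 0.0, "g2": 0.0}, "t10": {"g1": 1.0}})
        matrix, dropped = ap.build_fc_matrix(tables, ["g1", "g2"], ["t7", "t10"])
        assert dropped == ["g2"]
        assert list(matrix.index) == ["g1"]

    def test_row_order_invariance(self):
        tables = self._tables(
            {"t7": {"g1": 0.0, "g2": 1.0}, "t10": {"g1": 2.0, "g2": 3.0}}
        )
        shuffled = {k: v.iloc[::-1].reset_index(drop=True)
                    for k, v in tables.items()}
        m1, _ = ap.build_fc_matrix(tables, ["g1", "g2"], ["t7", "t10"])
        m2, _ = ap.build_fc_matrix(shuffled, ["g1", "g2"], ["t7", "t10"])
        assert m1.equals(m2)

    def test_noise_free_rows_equal_configured_trajectories(self):
        params = ap.ExpressionSimParams(n_background=0, n_gradual=4,
                                        n_ectopic=3, lfc_sd=0.0, seed=0)
        tables, truth = ap.generate_contrast_tables(params)
        order = ["cross_7", "cross_10", "cross_13"]
        matrix, _ = ap.build_fc_matrix(
            {k: tables[k] for k in order}, truth["gene_id"], order
        )
        ect = truth.loc[truth["archetype"] == "ectopic", "gene_id"]
        grad = truth.loc[truth["archetype"] == "gradual", "gene_id"]
        assert np.allclose(matrix.loc[ect], [0.0, 4.0, 2.0])
        assert np.allclose(matrix.loc[grad], [0.0, 0.5, 1.0])


def brute_force_merge_heights(X: np.ndarray) -> list[float]:
    """Exhaustive complete-linkage agglomeration oracle for tiny n."""
    D = squareform(pdist(X))
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = max(D[a, b] for a in clusters[i] for b in clusters[j])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return sorted(heights)


class TestClusterTrajectories:
    @staticmethod
    def _matrix(values, ids=None):
        values = np.asarray(values, dtype=float)
        ids = ids or [f"g{i}" for i in range(len(values))]
        return pd.DataFrame(values, index=pd.Index(ids, name="gene_id"),
                            columns=["t7", "t10", "t13"])

    def test_k1_single_cluster(self):
        matrix = self._matrix([[0, 1, 2], [3, 4, 5], [0, 0, 0]])
        out = ap.cluster_trajectories(matrix, k=1)
        assert set(out.labels) == {1}

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            ap.cluster_trajectories(self._matrix([[0, 0, 0]]), k=2)

    def test_two_archetypes_recovered_perfectly(self):
        rng = np.random.default_rng(0)
        grad = np.tile([0.0, 0.5, 1.0], (50, 1))
        ect = np.tile([0.0, 4.0, 2.0], (50, 1))
        matrix = self._matrix(np.vstack([grad, ect]))
        out = ap.cluster_trajectories(matrix, k=2)
        # labels come back on the lexicographically sorted gene index
        truth = [0 if int(g[1:]) < 50 else 1 for g in out.labels.index]
        assert adjusted_rand_score(truth, out.labels.to_numpy()) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_merge_heights_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        X = rng.normal(size=(n, 3))
        matrix = self._matrix(X)
        out = ap.cluster_trajectories(matrix, k=1)
        scipy_heights = sorted(out.linkage_matrix[:, 2])
        assert np.allclose(scipy_heights, brute_force_merge_heights(X),
                           atol=1e-9)

    def test_label_determinism_under_row_permutation(self):
        rng = np.random.default_rng(4)
        matrix = self._matrix(rng.normal(size=(12, 3)))
        out1 = ap.cluster_trajectories(matrix, k=3)
        out2 = ap.cluster_trajectories(matrix.iloc[::-1], k=3)
        assert out1.labels.sort_index().equals(out2.labels.sort_index())


class TestSummarizeClusters:
    def test_single_gene_cluster_mean_is_row(self):
        matrix = TestClusterTrajectories._matrix([[1.0, 2.0, 3.0]])
        out = ap.cluster_trajectories(matrix, k=1)
        summary = ap.summarize_clusters(out, matrix)
        assert summary.loc[1, "t10_mean"] == 2.0
        assert summary.loc[1, "n"] == 1

    def test_opposite_rows_average_to_constant(self):
        matrix = TestClusterTrajectories._matrix([[0, 1, 2], [2, 1, 0]])
        out = ap.cluster_trajectories(matrix, k=1)
        summary = ap.summarize_clusters(out, matrix)
        assert np.allclose(summary.loc[1, ["t7_mean", "t10_mean", "t13_mean"]],
                           1.0)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(9)
        matrix = TestClusterTrajectories._matrix(rng.normal(size=(20, 3)))
        out = ap.cluster_trajectories(matrix, k=4)
        summary = ap.summarize_clusters(out, matrix)
        for cluster in summary.index:
            members = matrix.loc[out.labels[out.labels == cluster].index]
            assert np.allclose(
                summary.loc[cluster, ["t7_mean", "t10_mean", "t13_mean"]],
                members.mean(axis=0),
            )


def hypergeom_tail_oracle(a, b, c, d):
    """P(X >= a) for the 2x2 table by explicit binomial-coefficient sums."""
    N, K, n = a + b + c + d, a + c, a + b
    total = math.comb(N, n)
    return sum(
        math.comb(K, k) * math.comb(N - K, n - k)
        for k in range(a, min(K, n) + 1)
    ) / total


class TestEnrichment:
    def test_worked_example_17_over_70(self):
        res = ap.enrichment_test(
            deg_set={"g1", "g2", "g3", "g4"},
            background_set={f"g{i}" for i in range(1, 9)},
            bound_set={"g1", "g2", "g3", "g5"},
        )
        # table [[3,1],[1,3]] -> (C(4,3)C(4,1)+C(4,4)C(4,0)) / C(8,4) = 17/70
        assert res.table().tolist() == [[3, 1], [1, 3]]
        assert res.p_value == pytest.approx(17 / 70)

    def test_deg_not_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            ap.enrichment_test({"gX"}, {"g1"}, set())

    def test_deg_equals_background_degenerate(self):
        res = ap.enrichment_test({"g1", "g2"}, {"g1", "g2"}, {"g1"})
        assert res.p_value == pytest.approx(1.0)
        assert res.continuity_corrected

    def test_zero_bound_overlap_p_from_oracle(self):
        res = ap.enrichment_test(
            deg_set={"g1", "g2"},
            background_set={f"g{i}" for i in range(1, 7)},
            bound_set={"g3", "g4"},
        )
        assert res.p_value == pytest.approx(hypergeom_tail_oracle(0, 2, 2, 2))

    def test_matches_scipy_fisher_exact(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            expected = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert fisher_greater_p(int(a), int(b), int(c), int(d)) == \
                pytest.approx(expected, abs=1e-12)

    def test_exhaustive_small_tables_match_oracle(self):
        for N in range(1, 15):
            for a in range(N + 1):
                for b in range(N - a + 1):
                    for c in range(N - a - b + 1):
                        d = N - a - b - c
                        assert fisher_greater_p(a, b, c, d) == pytest.approx(
                            hypergeom_tail_oracle(a, b, c, d), abs=1e-10
                        )


class TestClassifyModes:
    @staticmethod
    def _assignment(trajectories, sizes):
        labels = []
        rows = []
        for cluster, (traj, n) in enumerate(zip(trajectories, sizes), start=1):
            for i in range(n):
                labels.append((f"c{cluster}_g{i}", cluster))
                rows.append(traj)
        ids, labs = zip(*labels)
        matrix = pd.DataFrame(np.asarray(rows, dtype=float),
                              index=pd.Index(ids, name="gene_id"),
                              columns=["t7", "t10", "t13"])
        return ap.cluster_trajectories(matrix, k=len(trajectories)), matrix

    def test_paper_magnitude_trajectories_labelled(self):
        assignment, _ = self._assignment(
            [(0, 4, 2), (0, 0.5, 1), (0, 0, 0)], [6, 6, 6]
        )
        modes = ap.classify_modes(assignment)
        by_mode = {m: set(modes.index[modes["mode"] == m])
                   for m in modes["mode"].unique()}
        assert len(by_mode.get("ectopic", ())) == 1
        assert len(by_mode.get("gradual", ())) == 1
        assert len(by_mode.get("other", ())) == 1

    def test_tiny_clusters_not_classified(self):
        assignment, _ = self._assignment([(0, 4, 2), (0, 0.5, 1)], [2, 10])
        modes = ap.classify_modes(assignment, min_size=5)
        assert (modes["mode"] == "not_classified").sum() == 1
        assert modes.loc[modes["small"], "n"].iloc[0] == 2

    def test_mode_recovery_under_default_noise(self):
        """>=95% of truth-regulated genes land in a cluster classified with
        their archetype's mode, across 20 seeds at log2FC noise sd 0.3."""
        correct = 0
        total = 0
        for seed in range(20):
            params = ap.ExpressionSimParams(
                n_background=0, n_gradual=50, n_ectopic=50,
                lfc_sd=0.3, seed=seed,
            )
            tables, truth = ap.generate_contrast_tables(params)
            order = ["cross_7", "cross_10", "cross_13"]
            matrix, _ = ap.build_fc_matrix(
                {k: tables[k] for k in order}, truth["gene_id"], order
            )
            assignment = ap.cluster_trajectories(matrix, k=2)
            modes = ap.classify_modes(assignment, min_size=5)
            mode_of = {"gradual": "gradual", "ectopic": "ectopic"}
            truth_map = truth.set_index("gene_id")["archetype"]
            for gene, cluster in assignment.labels.items():
                total += 1
                if modes.loc[cluster, "mode"] == mode_of[truth_map[gene]]:
                    correct += 1
        assert correct / total >= 0.95
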