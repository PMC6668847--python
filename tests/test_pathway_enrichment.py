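"""Hypergeometric enrichment, ubiquity, clustering, false negatives."""
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from gemthresh import (
    cluster_pathways,
    false_negatives,
    fn_summary,
    hypergeom_pvalue,
    known_pair_categories,
    load_known_pairs,
    ubiquity,
)
from gemthresh.pathway_enrichment import enrichment_matrix


def _upper_tail_oracle(M, K, N, x):
    """Exact P(X >= x) by summing the combinatorial mass function."""
    denom = comb(M, N)
    total = 0
    for i in range(x, min(K, N) + 1):
        if N - i <= M - K:
            total += comb(K, i) * comb(M - K, N - i)
    return total / denom


class TestHypergeometric:
    def test_spec_worked_example(self):
        # M=20, K=5, N=10, all five pathway reactions drawn
        expected = comb(5, 5) * comb(15, 5) / comb(20, 10)
        assert hypergeom_pvalue(20, 5, 10, 5) == pytest.approx(expected)
        assert hypergeom_pvalue(20, 5, 10, 5) < 0.05

    def test_x_zero_gives_total_probability(self):
        assert hypergeom_pvalue(20, 5, 10, 0) == pytest.approx(1.0)

    def test_everything_active_degenerate_draw(self):
        # N = M forces x = K; P(X >= K) = 1
        assert hypergeom_pvalue(12, 4, 12, 4) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_scan(self):
        for M in range(1, 13):
            for K in range(M + 1):
                for N in range(M + 1):
                    for x in range(min(K, N) + 1):
                        assert hypergeom_pvalue(M, K, N, x) == pytest.approx(
                            _upper_tail_oracle(M, K, N, x), abs=1e-12
                        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(5, 6, 2, 0)


class TestEnrichmentMatrix:
    def _calls(self):
        # 6 reactions, 2 tissues; r5 has no data
        return pd.DataFrame(
            {
                "t1": [1, 1, 1, 0, 0, np.nan],
                "t2": [0, 0, 0, 1, 1, np.nan],
            },
            index=[f"r{i}" for i in range(6)],
        )

    def test_binary_and_population_excludes_no_data(self):
        pmap = {f"r{i}": ("pw1" if i < 3 else "pw2") for i in range(6)}
        e = enrichment_matrix(self._calls(), pmap, alpha=0.5)
        assert set(np.unique(e.to_numpy())) <= {0, 1}
        # with M=5: t1 active = {r0,r1,r2} = all of pw1 -> p = C(2,0)C(3,3)/C(5,3) = 0.1
        assert e.loc["pw1", "t1"] == 1 and e.loc["pw1", "t2"] == 0

    def test_empty_active_set_enriches_nothing(self):
        calls = pd.DataFrame({"t": [0, 0, 0]}, index=list("abc"))
        e = enrichment_matrix(calls, {"a": "p", "b": "p", "c": "q"})
        assert (e == 0).all().all()


class TestUbiquity:
    def test_row_sums(self):
        e = pd.DataFrame([[1, 0, 1, 0], [0, 0, 0, 0]], index=["p1", "p2"])
        u = ubiquity({"m1": e, "m2": e})
        assert u.loc["p1"].tolist() == [2, 2]
        assert u.loc["p2"].tolist() == [0, 0]

    def test_index_mismatch_rejected(self):
        a = pd.DataFrame([[1]], index=["p1"], columns=["t1"])
        b = pd.DataFrame([[1]], index=["p2"], columns=["t1"])
        with pytest.raises(ValueError, match="mismatch"):
            ubiquity({"m1": a, "m2": b})


class TestClusterPathways:
    def test_distant_singletons(self):
        u = pd.DataFrame(np.eye(5) * 100, index=[f"p{i}" for i in range(5)])
        labels = cluster_pathways(u, k=5)
        assert labels.nunique() == 5

    def test_duplicated_rows_co_cluster(self):
        u = pd.DataFrame(
            [[0, 0], [0, 0], [50, 50], [90, 0]], index=["a", "b", "c", "d"]
        )
        labels = cluster_pathways(u, k=3)
        assert labels["a"] == labels["b"]

    def test_merge_sequence_matches_hand_worked_linkage(self):
        """Complete linkage on 1-D points {0, 1, 10, 12, 30, 100}: merges at
        heights 1 ({0,1}), 2 ({10,12}), 12 ({0,1}+{10,12}), 30 (+{30}),
        100 (+{100}) — traced by hand."""
        pts = np.array([[0.0], [1.0], [10.0], [12.0], [30.0], [100.0]])
        z = linkage(pts, method="complete", metric="euclidean")
        assert z[:, 2].tolist() == [1.0, 2.0, 12.0, 30.0, 100.0]
        at3 = fcluster(z, t=3, criterion="maxclust")
        assert at3[0] == at3[1] == at3[2] == at3[3]  # {0,1,10,12} together
        assert len(set(at3)) == 3

    def test_k_larger_than_pathways_rejected(self):
        u = pd.DataFrame([[1], [2]], index=["a", "b"])
        with pytest.raises(ValueError):
            cluster_pathways(u, k=3)


class TestKnownPairs:
    def test_packaged_synthetic_table_loads(self):
        from importlib.resources import files

        path = files("gemthresh") / "data" / "known_pairs_synthetic.tsv"
        pairs = load_known_pairs(path)
        assert len(pairs) == 154
        assert set(pairs["category"]) == {
            "ubiquitous",
            "group-specific",
            "tissue-specific",
        }

    def test_category_definition_from_pair_counts(self):
        pairs = pd.DataFrame(
            {
                "pathway": ["a", "a", "b", "b", "b", *["c"] * 12],
                "tissue": [f"t{i}" for i in range(17)],
            }
        )
        cats = known_pair_categories(pairs)
        assert cats["a"] == "tissue-specific"
        assert cats["b"] == "group-specific"
        assert cats["c"] == "ubiquitous"

    def test_duplicate_pairs_rejected(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("pathway\ttissue\npw\tt1\npw\tt1\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_known_pairs(p)


class TestFalseNegatives:
    def _setup(self):
        e_good = pd.DataFrame(
            [[1, 1], [1, 0]], index=["p1", "p2"], columns=["t1", "t2"]
        )
        e_bad = pd.DataFrame(
            [[0, 0], [0, 0]], index=["p1", "p2"], columns=["t1", "t2"]
        )
        known = pd.DataFrame(
            {"pathway": ["p1", "p2", "zz"], "tissue": ["t1", "t2", "t1"]}
        )
        return e_good, e_bad, known

    def test_definition_and_unknown_ids_excluded(self):
        e_good, e_bad, known = self._setup()
        fn = false_negatives({"good": e_good, "bad": e_bad}, known)
        by_method = fn.groupby("method")["fn"].sum()
        assert by_method["good"] == 1  # p2 known in t2 but not enriched
        assert by_method["bad"] == 2
        assert "zz" not in set(fn["pathway"])  # unknown pathway excluded

    def test_all_ones_matrix_has_no_false_negatives(self):
        e = pd.DataFrame(np.ones((2, 2)), index=["p1", "p2"], columns=["t1", "t2"])
        known = pd.DataFrame({"pathway": ["p1"], "tissue": ["t2"]})
        assert false_negatives({"m": e}, known)["fn"].sum() == 0

    def test_fn_non_increasing_in_alpha(self, default_fixture, full_table):
        network, _, _, known = default_fixture
        pmap = network.subsystems()
        calls = full_table.loc["GM1-O2-local25"].T
        counts = []
        for alpha in (0.01, 0.05, 0.2, 0.5):
            e = enrichment_matrix(calls, pmap, alpha=alpha)
            counts.append(false_negatives({"m": e}, known)["fn"].sum())
        assert counts == sorted(counts, reverse=True)

    def test_cluster_grouping(self):
        e_good, _, known = self._setup()
        clusters = pd.Series([1, 2], index=["p1", "p2"])
        fn = false_negatives({"good": e_good}, known, clusters)
        summary = fn_summary(fn, by="cluster")
        assert summary.loc[2, "good"] == 1
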