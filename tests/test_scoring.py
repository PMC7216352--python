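"""Cluster extraction, C_score / DG_score and candidate ranking."""

import numpy as np
import pytest
from sklearn.base import clone

from cluscore import (
    BipartiteNetwork,
    ClusterAssociationScorer,
    c_score,
    dg_score,
    disease_cluster,
    gene_cluster,
    score_candidates,
    top_fraction,
)

from conftest import oracle_c_score, oracle_dg_score, random_bipartite


class TestClusters:
    @pytest.mark.parametrize(
        "gene,expected", [("g1", {"d1", "d2"}), ("g3", {"d2"})]
    )
    def test_disease_cluster_is_adjacency(self, t1, gene, expected):
        assert disease_cluster(t1, gene).members == frozenset(expected)

    @pytest.mark.parametrize(
        "disease,expected", [("d1", {"g1", "g2"}), ("d3", {"g2"})]
    )
    def test_gene_cluster_is_adjacency(self, t1, disease, expected):
        assert gene_cluster(t1, disease).members == frozenset(expected)

    def test_unknown_node_raises(self, t1):
        with pytest.raises(KeyError):
            disease_cluster(t1, "g9")
        with pytest.raises(KeyError):
            gene_cluster(t1, "d9")


class TestCScore:
    @pytest.mark.parametrize(
        "gene,disease,exclude,expected",
        [
            ("g3", "d1", False, 1),   # edges into {g1,g2} x {d2} = {(g1,d2)}
            ("g3", "d3", False, 0),   # empty cluster intersection
            ("g1", "d1", False, 3),   # known edge, all cluster edges counted
            ("g1", "d1", True, 2),    # direct edge excluded
        ],
    )
    def test_t1_values(self, t1, gene, disease, exclude, expected):
        assert c_score(t1, gene, disease, exclude) == expected

    def test_unknown_node_raises(self, t1):
        with pytest.raises(KeyError):
            c_score(t1, "g9", "d1")

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            net = random_bipartite(rng)
            genes = sorted(net.gene_neighbors)
            diseases = sorted(net.disease_neighbors)
            for _ in range(10):
                g = genes[rng.integers(len(genes))]
                d = diseases[rng.integers(len(diseases))]
                for exclude in (False, True):
                    assert c_score(net, g, d, exclude) == oracle_c_score(
                        net, g, d, exclude
                    )

    def test_role_symmetry_under_transposition(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            net = random_bipartite(rng)
            tr = net.transpose()
            for g in sorted(net.gene_neighbors)[:4]:
                for d in sorted(net.disease_neighbors)[:4]:
                    assert c_score(net, g, d) == c_score(tr, d, g)

    def test_adding_cluster_edge_increments_score_by_one(self, t1):
        # (g2, d2) connects gCluster(d1)={g1,g2} to dCluster(g3)... pick a
        # pair not incident to the added edge's effect on its own degrees:
        # score (g3, d1); add edge (g1, d2)? already present. Use (g2, d2):
        # g2 in gCluster(d1), d2 in dCluster(g3); neither endpoint is g3/d1.
        before_c = c_score(t1, "g3", "d1")
        before_dg = dg_score(t1, "g3", "d1")
        grown = BipartiteNetwork.from_edges(t1.edges() + [("g2", "d2")])
        assert c_score(grown, "g3", "d1") == before_c + 1
        bonus = 1.0 / grown.degree("g3") + 1.0 / grown.degree("d1")
        assert dg_score(grown, "g3", "d1") == pytest.approx(before_dg + bonus)


class TestDGScore:
    def test_t1_degree_weighting(self, t1):
        # deg(g3)=1, deg(d1)=2, c=1 -> (1 + 0.5) * 1
        assert dg_score(t1, "g3", "d1") == pytest.approx(1.5)

    def test_zero_c_score_gives_zero(self, t1):
        assert dg_score(t1, "g3", "d3") == 0.0

    def test_both_degree_one_doubles_c(self):
        net = BipartiteNetwork.from_edges([("g1", "d1"), ("g2", "d2")])
        # c(g1, d2): clusters {g2} x {d1}, no edge -> 0; use the known pair
        assert dg_score(net, "g1", "d1") == pytest.approx(2 * c_score(net, "g1", "d1"))

    def test_matches_oracle_and_bounds(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            net = random_bipartite(rng)
            genes = sorted(net.gene_neighbors)
            diseases = sorted(net.disease_neighbors)
            g = genes[rng.integers(len(genes))]
            d = diseases[rng.integers(len(diseases))]
            val = dg_score(net, g, d)
            assert val == pytest.approx(oracle_dg_score(net, g, d), abs=1e-12)
            assert 0.0 <= val <= 2 * c_score(net, g, d) + 1e-12


class TestScoreCandidates:
    def test_t1_all_non_edges_ranked(self, t1):
        frame = score_candidates(t1)
        assert len(frame) == 4
        got = list(zip(frame["gene"], frame["disease"], frame["dg_score"]))
        assert got == [
            ("g1", "d3", 1.5),  # tie with (g3,d1) broken by gene id
            ("g3", "d1", 1.5),
            ("g2", "d2", 1.0),
            ("g3", "d3", 0.0),
        ]
        assert list(frame["rank"]) == [1, 2, 3, 4]

    def test_table_route_matches_per_pair_route(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            net = random_bipartite(rng)
            frame = score_candidates(net)
            for row in frame.itertuples(index=False):
                assert row.c_score == c_score(net, row.gene, row.disease)
                assert row.dg_score == pytest.approx(
                    dg_score(net, row.gene, row.disease), abs=1e-12
                )

    def test_empty_candidate_list(self, t1):
        assert len(score_candidates(t1, candidates=[])) == 0

    def test_known_edge_candidate_rejected(self, t1):
        with pytest.raises(ValueError, match="known edges"):
            score_candidates(t1, candidates=[("g1", "d1")])

    def test_known_edges_scoreable_when_allowed(self, t1):
        frame = score_candidates(t1, candidates=[("g1", "d1")], allow_known=True)
        assert frame.loc[0, "c_score"] == 3
        frame_x = score_candidates(
            t1, candidates=[("g1", "d1")], allow_known=True, exclude_direct_edge=True
        )
        assert frame_x.loc[0, "c_score"] == 2

    def test_lncrna_candidate_restriction(self):
        net = BipartiteNetwork.from_edges(
            [("g1", "d1"), ("g2", "d2"), ("g1", "d2")],
            gene_class={"g1": "lncRNA", "g2": "protein_coding"},
        )
        frame = score_candidates(net, candidates="lncrna_non_edges")
        assert set(frame["gene"]) <= {"g1"}

    def test_unknown_candidate_node_raises(self, t1):
        with pytest.raises(KeyError):
            score_candidates(t1, candidates=[("g9", "d1")])


class TestTopFraction:
    def test_ceil_arithmetic(self, t1):
        frame = score_candidates(t1)  # 4 candidates
        assert len(top_fraction(frame, 0.25)) == 1
        assert len(top_fraction(frame, 0.26)) == 2
        assert len(top_fraction(frame, 1.0)) == 4

    def test_top_pair_is_highest_ranked(self, t1):
        top = top_fraction(score_candidates(t1), 0.25)
        assert (top.loc[0, "gene"], top.loc[0, "disease"]) == ("g1", "d3")

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_fraction(self, t1, bad):
        with pytest.raises(ValueError):
            top_fraction(score_candidates(t1), bad)


class TestEstimator:
    def test_fit_predict_roundtrip(self, t1):
        scorer = ClusterAssociationScorer().fit(t1.edges())
        assert scorer.predict([("g3", "d1")]) == pytest.approx([1.5])
        assert scorer.c_scores([("g1", "d1")]) == [3]

    def test_get_set_params_and_clone(self):
        scorer = ClusterAssociationScorer(exclude_direct_edge=True)
        assert scorer.get_params() == {"exclude_direct_edge": True}
        twin = clone(scorer)
        assert twin.get_params() == scorer.get_params()
        scorer.set_params(exclude_direct_edge=False)
        assert not scorer.exclude_direct_edge

    def test_unfitted_predict_raises(self):
        with pytest.raises(Exception, match="not fitted"):
            ClusterAssociationScorer().predict([("g1", "d1")])

    def test_rank_candidates_equals_function(self, t1):
        scorer = ClusterAssociationScorer().fit(t1)
        assert scorer.rank_candidates().equals(score_candidates(t1))
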