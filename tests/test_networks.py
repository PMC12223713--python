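"""PPI edge filtering, Spearman correlation, co-expression networks."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from protnet import (
    SimDesign,
    build_coexpression_network,
    clean_edge_table,
    filter_ppi_edges,
    largest_connected_component,
    normalize_total_signal,
    simulate_counts,
    spearman_correlation,
)


def edge_frame(rows):
    return pd.DataFrame(
        rows, columns=["protein_a", "protein_b", "combined_score", "database", "experimental"]
    )


class TestFilterPpiEdges:
    TABLE = edge_frame(
        [
            ("A", "B", 0.7, False, True),
            ("A", "C", 0.2, True, False),
            ("B", "C", 0.5, False, False),  # text-mining only
        ]
    )

    def test_score_and_evidence_at_06(self):
        g = filter_ppi_edges(self.TABLE, 0.6)
        assert set(g.edges()) == {("A", "B")}
        assert set(g.nodes()) == {"A", "B"}  # C dropped, no surviving edge

    def test_score_and_evidence_at_015(self):
        g = filter_ppi_edges(self.TABLE, 0.15)
        assert {tuple(sorted(e)) for e in g.edges()} == {("A", "B"), ("A", "C")}

    def test_duplicates_collapsed_max_score(self):
        t = edge_frame([("A", "B", 0.3, True, False), ("B", "A", 0.8, False, True)])
        cleaned = clean_edge_table(t)
        assert len(cleaned) == 1
        assert cleaned.loc[0, "combined_score"] == 0.8
        assert cleaned.loc[0, "database"] and cleaned.loc[0, "experimental"]

    def test_self_edges_dropped(self):
        t = edge_frame([("A", "A", 0.9, True, True), ("A", "B", 0.9, True, True)])
        g = filter_ppi_edges(t, 0.5)
        assert set(g.edges()) == {("A", "B")}

    def test_malformed_score_reports_row(self):
        t = edge_frame([("A", "B", 1.7, True, True)])
        with pytest.raises(ValueError, match="row"):
            filter_ppi_edges(t, 0.5)

    def test_monotone_in_score_min(self):
        rng = np.random.default_rng(3)
        rows = [
            (f"p{a}", f"p{b}", float(rng.random()), bool(rng.random() < 0.7), bool(rng.random() < 0.7))
            for a, b in itertools.combinations(range(12), 2)
        ]
        t = edge_frame(rows)
        previous = None
        for smin in (0.0, 0.25, 0.5, 0.75, 1.0):
            edges = {tuple(sorted(e)) for e in filter_ppi_edges(t, smin).edges()}
            if previous is not None:
                assert edges <= previous
            previous = edges


class TestLargestConnectedComponent:
    def test_picks_biggest(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("x", "y")])
        assert set(largest_connected_component(g).nodes()) == {"a", "b", "c", "d", "e"}

    def test_connected_identity(self):
        g = nx.path_graph(5)
        out = largest_connected_component(g)
        assert set(out.nodes()) == set(g.nodes())
        assert set(out.edges()) == set(g.edges())

    def test_tie_breaks_to_smallest_id(self):
        g = nx.Graph([("X", "Y"), ("Y", "Z"), ("A", "B"), ("B", "C")])
        assert set(largest_connected_component(g).nodes()) == {"A", "B", "C"}

    def test_empty_graph(self):
        assert largest_connected_component(nx.Graph()).number_of_nodes() == 0


class TestSpearmanCorrelation:
    def test_monotone_pairs(self):
        assert spearman_correlation([1, 2, 3, 4], [2, 4, 6, 8]).rho == pytest.approx(1.0)
        assert spearman_correlation([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_perfect_rho_reports_p_zero(self):
        assert spearman_correlation([1, 2, 3, 4], [2, 4, 6, 8]).p_value == 0.0

    def test_tied_ranks_oracle(self):
        # hand-ranked Pearson-of-ranks: y ranks (1.5, 1.5, 3.5, 3.5, 5)
        rec = spearman_correlation([1, 2, 3, 4, 5], [1, 1, 2, 2, 3])
        assert rec.rho == pytest.approx(0.9487, abs=1e-4)

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x, y = rng.integers(0, 30, size=(2, 9)).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rec = spearman_correlation(x, y)
            ref = st.spearmanr(x, y)
            assert rec.rho == pytest.approx(ref.statistic, abs=1e-12)
            assert rec.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_constant_vector_flagged_invalid(self):
        rec = spearman_correlation([1, 1, 1], [1, 2, 3])
        assert not rec.valid and np.isnan(rec.rho)

    def test_permutation_p_agrees_with_t_for_clear_signal(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        exact = spearman_correlation(x, y, method="permutation")
        approx = spearman_correlation(x, y)
        assert exact.rho == approx.rho
        assert exact.p_value == pytest.approx(approx.p_value, abs=0.05)

    def test_rho_p_double_threshold_nonbinding_at_n9(self):
        # at n = 9, |rho| >= 0.95 implies p well below 0.01 (t ~ 8.05)
        from protnet.networks import _spearman_p

        assert _spearman_p(0.95, 9) < 1e-4 < 0.01


class TestCoexpressionNetwork:
    def _matrix(self, data):
        counts = pd.DataFrame(data).T
        counts.columns = [f"s{i}" for i in range(counts.shape[1])]
        design = pd.DataFrame(
            {"condition": ["A"] * counts.shape[1], "batch": [1] * counts.shape[1],
             "replicate": range(1, counts.shape[1] + 1)},
            index=counts.columns,
        )
        from protnet import CountMatrix

        return CountMatrix(counts, design, normalized=True)

    def test_identical_profiles_one_edge(self):
        m = self._matrix({
            "a": [1, 2, 3, 4, 5, 6, 7, 8, 9],
            "b": [2, 4, 6, 8, 10, 12, 14, 16, 18],
            "c": [5, 1, 4, 2, 9, 3, 7, 8, 6],
        })
        g = build_coexpression_network(m, "A", core={"a", "b", "c"})
        assert set(map(tuple, map(sorted, g.edges()))) == {("a", "b")}
        assert g.edges[("a", "b")]["weight"] == pytest.approx(1.0)

    def test_below_threshold_no_edge(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
        y = np.array([1, 2, 3, 4, 5, 6, 7, 9, 8], dtype=float)  # one swap: rho ~ 0.983
        y2 = np.array([2, 1, 4, 3, 6, 5, 8, 7, 9], dtype=float)  # 4 swaps: rho = 14/15
        assert spearman_correlation(x, y2).rho == pytest.approx(14 / 15, abs=1e-12)
        m = self._matrix({"a": x, "b": y2})
        g = build_coexpression_network(m, "A", core={"a", "b"})
        assert g.number_of_edges() == 0

    def test_planted_block_recovered(self):
        m, truth = simulate_counts(
            SimDesign(n_proteins=120, seed=21), n_coexpr_blocks=1, coexpr_block_size=5
        )
        norm = normalize_total_signal(m)
        g = build_coexpression_network(norm, "Col-0")
        block = sorted(truth.coexpr_blocks[0])
        for a, b in itertools.combinations(block, 2):
            assert g.has_edge(a, b)

    def test_block_to_noise_leakage_is_rare(self):
        # chance |rho| >= 0.95 at n = 9 has probability ~3.5e-4 per pair; the
        # planted block should not leak edges at more than a few times that
        false_edges = pairs = 0
        for seed in range(10):
            m, truth = simulate_counts(
                SimDesign(n_proteins=150, seed=seed), n_coexpr_blocks=1
            )
            norm = normalize_total_signal(m)
            g = build_coexpression_network(norm, "Col-0")
            block = truth.coexpr_blocks[0]
            others = set(g.nodes()) - block
            pairs += len(block) * len(others)
            false_edges += sum(g.has_edge(a, b) for a in block for b in others)
        assert false_edges / pairs < 5e-3

    def test_invariant_under_monotone_transform(self):
        m, _ = simulate_counts(SimDesign(n_proteins=40, seed=2))
        norm = normalize_total_signal(m)
        g1 = build_coexpression_network(norm, "gun1")
        from protnet import CountMatrix

        squared = CountMatrix(norm.counts**2 + 1, norm.design, normalized=True)
        core = {p for p in norm.counts.index if (norm.counts.loc[p] > 0).all()}
        g2 = build_coexpression_network(squared, "gun1", core=core)
        e1 = {tuple(sorted(e)) for e in g1.edges()}
        e2 = {tuple(sorted(e)) for e in g2.edges()}
        assert e1 == e2

    def test_empty_core_errors(self, tiny_matrix):
        norm = normalize_total_signal(tiny_matrix)
        with pytest.raises(ValueError, match="core"):
            build_coexpression_network(norm, "A", core=set())
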