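"""Seed-pair betweenness, permutation null, FDR, and candidate selection."""

import itertools

import networkx as nx
import numpy as np
import pytest

from modulink.geneio import GeneSet, ValidationError, load_amd_genes, load_candidate_table
from modulink.prioritize import (
    BetweennessRecord,
    Interactome,
    annotate_candidates,
    permutation_fdr,
    permutation_null,
    read_interactome,
    seed_pair_betweenness,
    select_candidates,
)


def bruteforce_betweenness(graph: nx.Graph, seeds) -> dict:
    """Oracle: enumerate every geodesic per seed pair with networkx."""
    counts = {n: 0 for n in graph.nodes}
    present = [s for s in seeds if s in graph]
    for s, t in itertools.combinations(sorted(present), 2):
        if not nx.has_path(graph, s, t):
            continue
        for path in nx.all_shortest_paths(graph, s, t):
            for inner in path[1:-1]:
                counts[inner] += 1
    return counts


def _interactome(edges):
    return Interactome.from_edges(edges)


def _geneset(symbols):
    return GeneSet("seeds", frozenset(symbols))


class TestReadInteractome:
    def test_canonicalization(self, tmp_path):
        f = tmp_path / "e.tsv"
        f.write_text("a\tb\nb\ta\nc\tc\n")
        g = read_interactome(f)
        assert g.nodes == {"A", "B"}
        assert g.n_edges == 1

    def test_path_graph(self, path_graph_file):
        g = read_interactome(path_graph_file)
        assert (g.n_nodes, g.n_edges) == (6, 5)

    def test_malformed_line_rejected(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("a\tb\tc\n")
        with pytest.raises(ValidationError, match=":1:"):
            read_interactome(f)

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "none.tsv"
        f.write_text("# nothing\n")
        with pytest.raises(ValidationError, match="no edges"):
            read_interactome(f)


class TestSeedPairBetweenness:
    def test_path_graph_interior_nodes(self):
        g = _interactome([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        b = seed_pair_betweenness(g, _geneset({"A", "E"}))
        assert b == {"A": 0, "B": 1, "C": 1, "D": 1, "E": 0}

    def test_four_cycle_counts_both_geodesics(self):
        g = _interactome([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        b = seed_pair_betweenness(g, _geneset({"A", "C"}))
        assert b == {"A": 0, "B": 1, "C": 0, "D": 1}

    def test_star_hub_counts_every_leaf_pair(self):
        g = _interactome([("H", f"L{i}") for i in range(1, 5)])
        b = seed_pair_betweenness(g, _geneset({f"L{i}" for i in range(1, 5)}))
        assert b["H"] == 6  # one geodesic per each of the C(4,2) leaf pairs
        assert all(b[f"L{i}"] == 0 for i in range(1, 5))

    def test_disconnected_seed_pair_contributes_zero(self):
        g = _interactome([("A", "B"), ("C", "D")])
        b = seed_pair_betweenness(g, _geneset({"A", "C", "B"}))
        assert b == {"A": 0, "B": 0, "C": 0, "D": 0}

    def test_fewer_than_two_present_seeds_rejected(self):
        g = _interactome([("A", "B")])
        with pytest.raises(ValidationError, match=">= 2 seed genes"):
            seed_pair_betweenness(g, _geneset({"A", "ZZZ"}))

    def test_absent_seeds_dropped(self):
        g = _interactome([("A", "B"), ("B", "C")])
        b = seed_pair_betweenness(g, _geneset({"A", "C", "MISSING"}))
        assert b["B"] == 1

    def test_matches_bruteforce_on_random_graphs(self):
        """Oracle equivalence on 60 random graphs (the deep 200-graph sweep
        lives in the acceptance suite)."""
        rng = np.random.default_rng(42)
        for trial in range(60):
            n = int(rng.integers(4, 13))
            p = float(rng.uniform(0.2, 0.7))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
            if g.number_of_edges() == 0:
                continue
            k = int(rng.integers(2, n + 1))
            seeds = rng.choice(sorted(g.nodes), size=k, replace=False)
            expected = bruteforce_betweenness(g, seeds)
            got = seed_pair_betweenness(Interactome(g), _geneset(seeds))
            assert got == expected, f"trial {trial}"

    def test_conservation_per_pair(self):
        """Sum of interior counts equals sigma_st * (d(s,t) - 1) per pair."""
        g = nx.petersen_graph()
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        for s, t in [("N0", "N7"), ("N1", "N9"), ("N2", "N6")]:
            paths = list(nx.all_shortest_paths(g, s, t))
            interior_total = sum(len(p) - 2 for p in paths)
            b = seed_pair_betweenness(Interactome(g), _geneset({s, t}))
            assert sum(b.values()) == interior_total

    def test_relabeling_permutes_output(self):
        g = _interactome([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        relabeled = Interactome(nx.relabel_nodes(
            g.graph, {"A": "W", "B": "X", "C": "Y", "D": "Z"}))
        b1 = seed_pair_betweenness(g, _geneset({"A", "C"}))
        b2 = seed_pair_betweenness(relabeled, _geneset({"W", "Y"}))
        mapping = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
        assert {mapping[k]: v for k, v in b1.items()} == b2


class TestPermutationNull:
    def test_reproducible_from_seed(self):
        g = _interactome([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("A", "E")])
        n1 = permutation_null(g, 2, n_perm=20, rng_seed=7)
        n2 = permutation_null(g, 2, n_perm=20, rng_seed=7)
        assert all(np.array_equal(n1[k], n2[k]) for k in n1)

    def test_different_seeds_differ(self):
        g = _interactome([(f"N{i}", f"N{j}") for i in range(8) for j in range(i + 1, 8)
                          if (i + j) % 3 != 0])
        n1 = permutation_null(g, 3, n_perm=10, rng_seed=1)
        n2 = permutation_null(g, 3, n_perm=10, rng_seed=2)
        assert any(not np.array_equal(n1[k], n2[k]) for k in n1)

    def test_complete_graph_null_is_zero(self):
        g = _interactome([(f"N{i}", f"N{j}")
                          for i in range(5) for j in range(i + 1, 5)])
        null = permutation_null(g, 3, n_perm=10, rng_seed=0)
        assert all(np.all(v == 0) for v in null.values())

    def test_path_graph_middle_exceeds_ends(self):
        # exact expectation: node at position v is interior for v*(5-v) of
        # the 15 seed pairs, so middles (6/15) dominate ends (0)
        g = _interactome([(f"N{i}", f"N{i+1}") for i in range(5)])
        null = permutation_null(g, 2, n_perm=200, rng_seed=3)
        middle = (null["N2"].mean() + null["N3"].mean()) / 2
        ends = (null["N0"].mean() + null["N5"].mean()) / 2
        assert middle > ends
        assert ends == 0.0
        assert middle == pytest.approx(6 / 15, abs=0.1)

    def test_invalid_args_rejected(self):
        g = _interactome([("A", "B")])
        with pytest.raises(ValidationError):
            permutation_null(g, 5, n_perm=10, rng_seed=0)
        with pytest.raises(ValidationError):
            permutation_null(g, 2, n_perm=0, rng_seed=0)


class TestPermutationFdr:
    def _records(self, actual, null):
        return permutation_fdr(actual, {k: np.asarray(v) for k, v in null.items()})

    def test_printed_formula(self):
        null = [20, 20, 20] + [5] * 97  # 3 of 100 exceed the actual of 10
        [rec] = self._records({"G": 10}, {"G": null})
        assert rec.fdr == pytest.approx(0.03)
        assert rec.positive_perm_count == 100

    def test_actual_above_all_null(self):
        [rec] = self._records({"G": 10}, {"G": [0] * 50})
        assert rec.fdr == 0.0

    def test_strict_inequality_at_zero(self):
        [rec] = self._records({"G": 0}, {"G": [0] * 100})
        assert rec.fdr == 0.0
        assert rec.positive_perm_count == 0

    def test_gene_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            self._records({"G": 1}, {"H": [0]})

    def test_fdr_on_grid(self):
        recs = self._records({"A": 3, "B": 7},
                             {"A": [1, 5, 5, 2], "B": [9, 9, 9, 9]})
        for r in recs:
            assert r.fdr in {i / 4 for i in range(5)}


def _record(gene, b, fdr, pos, null_mean=None, n=100):
    """Build a consistent record with the requested statistics."""
    if null_mean is None:
        null_mean = pos * 1.0  # small positives
    n_over = round(fdr * n)
    over_val = b + 1
    # construct null values: n_over values above actual, rest low/zero
    base = []
    base += [over_val] * n_over
    remaining_pos = max(pos - n_over, 0)
    total = round(null_mean * n)
    spread = total - over_val * n_over
    if remaining_pos > 0:
        per = max(spread // remaining_pos, 1) if spread > 0 else 1
        vals = [min(per, b)] * remaining_pos
        base += vals
    base += [0] * (n - len(base))
    return BetweennessRecord(
        gene=gene, betweenness_actual=b, null_values=tuple(base[:n]),
        fdr=sum(v > b for v in base[:n]) / n,
        positive_perm_count=sum(v > 0 for v in base[:n]),
    )


class TestSelectCandidates:
    def test_each_filter_excludes_exactly_one(self):
        records = [
            _record("G1", 5123, 0.0, 10),
            _record("G2", 900, 0.0, 5),        # fails b_min
            _record("G3", 2000, 0.10, 5),      # fails fdr
            _record("G4", 2000, 0.0, 80, null_mean=500.0),  # fails hub rule
        ]
        table = select_candidates(records, b_min=1000, fdr_max=0.05, hub_max=50)
        assert list(table.frame["gene"]) == ["G1"]

    def test_positive_count_statistic_option(self):
        records = [
            _record("G1", 2000, 0.0, 80, null_mean=10.0),  # low mean, many positives
        ]
        assert len(select_candidates(records, hub_statistic="mean_null")) == 1
        assert len(select_candidates(records, hub_statistic="positive_count")) == 0

    def test_table_fixture_all_pass_betweenness_filter(self):
        table = load_candidate_table()
        records = [
            _record(g, int(b), 0.0, 0)
            for g, b in zip(table.frame["gene"], table.frame["betweenness"])
        ]
        selected = select_candidates(records, b_min=1000, fdr_max=0.05, hub_max=50)
        assert len(selected) == 42
        assert selected.frame.iloc[0]["gene"] == "ABCG5"

    def test_threshold_above_max_gives_empty_table(self):
        records = [_record("G1", 500, 0.0, 0)]
        assert len(select_candidates(records, b_min=10_000)) == 0

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        records = [
            _record(f"G{i}", int(rng.integers(0, 3000)),
                    float(rng.integers(0, 10)) / 100, int(rng.integers(0, 100)))
            for i in range(50)
        ]
        loose = select_candidates(records, b_min=500, fdr_max=0.2, hub_max=90)
        tight = select_candidates(records, b_min=1500, fdr_max=0.05, hub_max=40)
        assert set(tight.frame["gene"]) <= set(loose.frame["gene"])

    def test_no_null_filters_on_betweenness_only(self):
        records = [BetweennessRecord("G", 2000, (), None, 0)]
        table = select_candidates(records, b_min=1000)
        assert list(table.frame["gene"]) == ["G"]
        assert table.frame["fdr"].isna().all()


class TestAnnotateCandidates:
    def test_fixture_overlap_is_seven_named_genes(self):
        table = load_candidate_table()
        seeds = load_amd_genes()
        annotated, overlap = annotate_candidates(table, seeds)
        assert overlap == 7
        flagged = set(annotated.frame.loc[annotated.frame["is_seed"], "gene"])
        assert flagged == {"C3", "ELN", "TF", "FLT1", "CFH", "VEGFA", "FBLN5"}

    def test_disjoint_seed_set(self):
        table = load_candidate_table()
        _, overlap = annotate_candidates(table, GeneSet("x", frozenset({"NOPE"})))
        assert overlap == 0

    def test_candidates_subset_of_seeds(self):
        import pandas as pd

        from modulink.geneio import CandidateTable

        table = CandidateTable(pd.DataFrame({"gene": ["A", "B"],
                                             "betweenness": [3, 2]}))
        _, overlap = annotate_candidates(table, GeneSet("s", frozenset({"A", "B", "C"})))
        assert overlap == 2
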