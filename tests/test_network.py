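"""Network construction, candidate filtering, Relevance Index, ranking."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest

import sciseq
from sciseq.containers import EdgeList, ValidationError, annotation_for


def _edges(pairs):
    return EdgeList.from_pairs(pairs)


def _de_table(fc: dict[str, float]):
    genes = sorted(fc)
    vals = np.array([fc[g] for g in genes])
    return pd.DataFrame(
        {
            "fold_change": vals,
            "log2_fc": np.log2(vals),
            "is_significant": True,
            "direction": np.where(vals > 1, "up", "down"),
        },
        index=pd.Index(genes, name="gene"),
    )


def _ann(rows: dict[str, tuple[str, bool]]):
    return pd.DataFrame(
        {
            "location": [rows[g][0] for g in rows],
            "has_drug": [rows[g][1] for g in rows],
        },
        index=pd.Index(list(rows), name="gene"),
    )


class TestBuildNetwork:
    def test_two_focus_genes_one_edge(self):
        net = sciseq.build_network({"A", "B"}, _edges([("A", "B")]))
        assert set(net.nodes) == {"A", "B"}
        assert net.degree("A") == 1

    def test_first_neighbor_rule(self):
        net = sciseq.build_network({"A"}, _edges([("A", "C"), ("C", "D")]),
                                   include_neighbors=True)
        assert set(net.nodes) == {"A", "C"}

    def test_isolated_focus_nodes_dropped(self):
        net = sciseq.build_network({"A", "B", "X"}, _edges([("A", "B"), ("C", "D")]))
        assert set(net.nodes) == {"A", "B"}

    def test_no_focus_in_edges_errors(self):
        with pytest.raises(ValidationError):
            sciseq.build_network({"Z"}, _edges([("A", "B")]))

    def test_degrees_equal_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 15))
            pairs = [
                (f"n{a}", f"n{b}")
                for a in range(n)
                for b in range(a + 1, n)
                if rng.random() < 0.3
            ]
            if not pairs:
                continue
            focus = {f"n{i}" for i in range(n // 2)}
            try:
                net = sciseq.build_network(focus, _edges(pairs))
            except ValidationError:
                continue
            for node in net.nodes:
                expected = sum(
                    1
                    for a, b in set(map(lambda p: tuple(sorted(p)), pairs))
                    if (a == node and b in net.nodes)
                    or (b == node and a in net.nodes)
                )
                assert net.degree(node) == expected


class TestFilter:
    def test_cytoplasmic_without_drug_excluded(self):
        net = sciseq.build_network({"A", "B"}, _edges([("A", "B")]))
        table = sciseq.filter_candidates(
            net, _ann({"A": ("cytoplasm", False), "B": ("plasma_membrane", False)}),
            _de_table({"A": 10.0, "B": 10.0}),
        )
        assert not bool(table.loc["A", "passes_filter"])
        assert bool(table.loc["B", "passes_filter"])

    def test_drug_overrides_location(self):
        net = sciseq.build_network({"A", "B"}, _edges([("A", "B")]))
        table = sciseq.filter_candidates(
            net, _ann({"A": ("cytoplasm", True), "B": ("nucleus", False)}),
            _de_table({"A": 1.1, "B": 10.0}),
        )
        assert bool(table.loc["A", "passes_filter"])
        assert not bool(table.loc["B", "passes_filter"])

    def test_missing_annotation_defaults_permissively(self):
        net = sciseq.build_network({"A", "B"}, _edges([("A", "B")]))
        table = sciseq.filter_candidates(net, None, _de_table({"A": 10.0, "B": 10.0}))
        assert (table["location"] == "other").all()
        assert not table["passes_filter"].any()

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(1)
        locations = ["extracellular_space", "plasma_membrane", "cytoplasm",
                     "nucleus", "other"]
        genes = [f"g{i}" for i in range(40)]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]
                 if rng.random() < 0.15]
        net = sciseq.build_network(set(genes), _edges(pairs))
        for _ in range(25):
            ann = _ann({g: (locations[rng.integers(5)], bool(rng.random() < 0.3))
                        for g in genes})
            fcs = {g: float(2.0 ** rng.normal(0, 2)) for g in genes}
            table = sciseq.filter_candidates(net, ann, _de_table(fcs))
            for g in table.index:
                loc, drug = ann.loc[g, "location"], bool(ann.loc[g, "has_drug"])
                fc = fcs[g]
                expected = (
                    loc in ("plasma_membrane", "extracellular_space")
                    and (fc > 2 or fc < 0.5)
                ) or drug
                assert bool(table.loc[g, "passes_filter"]) == expected


class TestRelevanceIndex:
    def test_unit_fold_change_gives_zero(self):
        assert sciseq.relevance_index(1.0, 17) == 0.0

    def test_zero_degree_gives_zero(self):
        assert sciseq.relevance_index(123.0, 0) == 0.0

    def test_arithmetic(self):
        assert sciseq.relevance_index(4.0, 5, log_base=2) == pytest.approx(10.0)

    def test_non_positive_fold_change_errors(self):
        with pytest.raises(ValidationError):
            sciseq.relevance_index(0.0, 3)

    def test_base_change_preserves_order(self):
        rng = np.random.default_rng(2)
        fc = 2.0 ** rng.normal(0, 2, 30)
        deg = rng.integers(1, 20, 30)
        r2 = sciseq.relevance_index(fc, deg, 2)
        r10 = sciseq.relevance_index(fc, deg, 10)
        assert np.array_equal(np.argsort(-r2), np.argsort(-r10))


class TestRanking:
    def test_sort_and_tie_rules(self):
        cand = pd.DataFrame(
            {
                "fold_change": [1024.0, 8.0, 128.0],
                "connection_number": [1, 1, 1],
                "passes_filter": True,
            },
            index=pd.Index(["x", "y", "z"], name="gene"),
        )
        ranked = sciseq.rank_candidates(cand)
        assert list(ranked.index) == ["x", "z", "y"]
        cand_tied = pd.DataFrame(
            {
                "fold_change": [4.0, 4.0, 4.0],
                "connection_number": [2, 5, 2],
                "passes_filter": True,
            },
            index=pd.Index(["b", "c", "a"], name="gene"),
        )
        ranked = sciseq.rank_candidates(cand_tied)
        assert list(ranked.index) == ["c", "a", "b"]

    def test_monotone_in_degree_and_fold_change(self):
        base = pd.DataFrame(
            {
                "fold_change": [4.0, 4.0],
                "connection_number": [5, 5],
                "passes_filter": True,
            },
            index=pd.Index(["a", "b"], name="gene"),
        )
        bumped = base.copy()
        bumped.loc["b", "connection_number"] = 9
        assert list(sciseq.rank_candidates(bumped).index)[0] == "b"
        bumped2 = base.copy()
        bumped2.loc["b", "fold_change"] = 16.0
        assert list(sciseq.rank_candidates(bumped2).index)[0] == "b"

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(12)]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]
                 if rng.random() < 0.4]
        fcs = {g: float(2.0 ** rng.normal(0, 2)) for g in genes}
        ann = _ann({g: ("plasma_membrane", False) for g in genes})
        ranked = sciseq.prioritize(genes, _edges(pairs), ann, _de_table(fcs),
                                   include_neighbors=False)
        mapping = {g: f"Z{i:02d}" for i, g in enumerate(reversed(genes))}
        pairs2 = [(mapping[a], mapping[b]) for a, b in pairs]
        fcs2 = {mapping[g]: v for g, v in fcs.items()}
        ann2 = _ann({mapping[g]: ("plasma_membrane", False) for g in genes})
        ranked2 = sciseq.prioritize(
            [mapping[g] for g in genes], _edges(pairs2), ann2, _de_table(fcs2),
            include_neighbors=False,
        )
        assert [mapping[g] for g in ranked.index] == list(ranked2.index)


def hand_enumerated_framework(genes, pairs, ann_rows, fcs, focus):
    """Independent enumeration of build → filter → RI → rank (plain loops)."""
    adj = {}
    for a, b in pairs:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    keep = set()
    for g in focus:
        if g in adj:
            keep.add(g)
            keep |= adj[g]
    nodes = {g for g in keep
             if any(v in keep for v in adj.get(g, set()))}
    scored = []
    for g in sorted(nodes):
        deg = sum(1 for v in adj.get(g, set()) if v in nodes)
        loc, drug = ann_rows.get(g, ("other", False))
        fc = fcs.get(g, 1.0)
        passes = (loc in ("plasma_membrane", "extracellular_space")
                  and (fc > 2 or fc < 0.5)) or drug
        if passes:
            ri = abs(np.log2(fc)) * deg
            scored.append((-ri, -deg, g))
    scored.sort()
    return [g for _, _, g in scored]


class TestFullFramework:
    # 12-node worked instance: two hubs, a drug-rescued cytoplasmic gene,
    # an excluded high-FC nuclear gene, and grown-in neighbors
    GENES = list("ABCDEFGHIJKL")
    PAIRS = [
        ("A", "B"), ("A", "C"), ("A", "D"), ("A", "E"), ("A", "F"),
        ("B", "C"), ("B", "G"), ("C", "H"), ("D", "I"), ("E", "J"),
        ("K", "L"),
    ]
    ANN = {
        "A": ("plasma_membrane", False),
        "B": ("extracellular_space", False),
        "C": ("cytoplasm", True),
        "D": ("nucleus", False),
        "E": ("plasma_membrane", False),
        "F": ("other", False),
        "G": ("plasma_membrane", False),
        "H": ("cytoplasm", False),
        "I": ("plasma_membrane", False),
        "J": ("extracellular_space", False),
        "K": ("plasma_membrane", False),
        "L": ("plasma_membrane", False),
    }
    FCS = {
        "A": 8.0, "B": 4.0, "C": 16.0, "D": 32.0, "E": 0.25, "F": 2.5,
        "G": 1.5, "H": 3.0, "I": 2.1, "J": 6.0, "K": 64.0, "L": 0.1,
    }
    FOCUS = ["A", "B", "E", "K"]

    def test_equals_hand_enumeration(self):
        expected = hand_enumerated_framework(
            self.GENES, self.PAIRS, self.ANN, self.FCS, self.FOCUS
        )
        ranked = sciseq.prioritize(
            self.FOCUS, _edges(self.PAIRS), _ann(self.ANN), _de_table(self.FCS),
            include_neighbors=True,
        )
        assert list(ranked.index) == expected
        # frozen expected ordering for this instance, from the enumeration:
        # A: deg 5 (B,C,D,E,F all in), |log2 8|*5 = 15
        # K: deg 1, |log2 64| = 6 ;  C: drug, deg 3 (A,B,H), 4*3 = 12
        assert expected[0] == "A"
        assert "D" not in expected  # nuclear, no drug: filtered out
        assert "C" in expected      # cytoplasmic but druggable
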