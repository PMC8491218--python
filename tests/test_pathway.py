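"""Network expansion: traversal semantics, alias handling, audit rules."""

import numpy as np
import pandas as pd
import pytest

from pesig.io import AliasMap, ExpressionMatrix, InteractionNetwork
from pesig.pathway import (
    CONDITIONS,
    Condition,
    expand,
    parent_child_pairs,
    run_conditions,
    substitute_aliases,
    verify_associations,
)


def chain_fixture(b_correlated: bool):
    """A - B - C chain; A curated. B's correlation with GI50 is switchable."""
    rng = np.random.default_rng(3)
    n = 30
    gi50 = rng.uniform(3, 6.5, n)
    z = (gi50 - gi50.mean()) / gi50.std()

    def planted():
        e = rng.normal(size=n)
        w = e - (e @ z) / (z @ z) * z
        return 7.0 + 0.98 * z + np.sqrt(1 - 0.98**2) * (w / w.std())

    rows = {
        "A": planted(),
        "B": planted() if b_correlated else 7.0 + rng.normal(size=n),
        "C": planted(),
    }
    matrix = ExpressionMatrix(
        pd.DataFrame(rows.values(), index=list(rows),
                     columns=[f"S{i}" for i in range(n)])
    )
    network = InteractionNetwork.from_edges(
        [("A", "int", "B"), ("B", "int", "C")]
    )
    return matrix, network, gi50


def bfs_oracle(seeds, network, passing: set, max_depth: int) -> dict:
    """Plain BFS through passing genes only; returns gene -> distance."""
    dist = {}
    frontier = [g for g in seeds if g in passing]
    for g in seeds:
        dist[g] = 0
    out = {g: 0 for g in frontier}
    for d in range(1, max_depth + 1):
        nxt = []
        for g in frontier:
            for nb in network.neighbors(g):
                if nb in dist:
                    continue
                dist[nb] = d
                if nb in passing:
                    out[nb] = d
                    nxt.append(nb)
        frontier = nxt
    return out


class TestSubstituteAliases:
    def test_mapped_alias_replaced_and_logged(self):
        aliases = AliasMap.from_pairs([("DBP", "GC")])
        out, report = substitute_aliases(["DBP", "TP53"], aliases)
        assert out == ["GC", "TP53"]
        assert report["substitutions"] == {"DBP": "GC"}
        assert report["unmapped"] == ["TP53"]

    def test_all_approved_identity(self):
        aliases = AliasMap.from_pairs([("DBP", "GC")])
        out, report = substitute_aliases(["GC", "BRCA1"], aliases)
        assert out == ["GC", "BRCA1"]
        assert report["substitutions"] == {}

    def test_colliding_aliases_deduplicated(self):
        aliases = AliasMap.from_pairs([("OLD1", "GC"), ("OLD2", "GC")])
        out, report = substitute_aliases(["OLD1", "OLD2"], aliases)
        assert out == ["GC"]
        assert report["duplicates"] == ["GC"]


class TestVerifyAssociations:
    @pytest.fixture()
    def toy_net(self):
        # mirrors the documented alias-corruption case: GC is wired to
        # HNF1A/CYP27B1 but never to CNN1 or CA3
        return InteractionNetwork.from_edges(
            [("GC", "int", "HNF1A"), ("GC", "int", "CYP27B1"),
             ("HNF1A", "int", "PIK3R3")]
        )

    def test_absent_edge_removed(self, toy_net):
        retained, removed = verify_associations(
            [("GC", "CNN1"), ("GC", "CA3")], toy_net
        )
        assert retained == [] and removed == [("GC", "CNN1"), ("GC", "CA3")]

    def test_present_edge_retained(self, toy_net):
        retained, removed = verify_associations(
            [("GC", "HNF1A"), ("GC", "CYP27B1")], toy_net
        )
        assert removed == []
        assert retained == [("GC", "HNF1A"), ("GC", "CYP27B1")]

    def test_empty_pairs(self, toy_net):
        assert verify_associations([], toy_net) == ([], [])


class TestExpand:
    def test_depth_zero_output_subset_of_seeds(self, small_panel, small_network):
        q = expand(
            small_panel.curated, small_network.network, small_panel.expression,
            None, small_panel.responses.gi50.to_numpy(), CONDITIONS[2],
        )
        assert set(q.entries) <= set(small_panel.curated)
        assert all(e.node_distance == 0 for e in q.entries.values())

    def test_chain_recruited_through_passing_intermediate(self):
        matrix, network, gi50 = chain_fixture(b_correlated=True)
        q = expand(["A"], network, matrix, None, gi50, Condition("t", 2, 20.0))
        assert set(q.entries) == {"A", "B", "C"}
        assert q.entries["C"].node_distance == 2
        assert q.entries["C"].parents == ["B"]

    def test_traversal_through_failing_gene_forbidden(self):
        matrix, network, gi50 = chain_fixture(b_correlated=False)
        q = expand(["A"], network, matrix, None, gi50, Condition("t", 2, 20.0))
        assert "B" not in q.entries and "C" not in q.entries
        assert "B" in q.audit  # scored, failed, dead end

    def test_matches_bfs_oracle_on_random_fixture(self, small_panel, small_network):
        from pesig.mfa import angle_pass, angle_table

        gi50 = small_panel.responses.gi50.to_numpy()
        cond = CONDITIONS[6]
        # oracle passing set: every expression gene whose GE angle passes
        all_genes = sorted(set(small_panel.expression.feature_ids))
        records, _ = angle_table(small_panel.expression, None, gi50, all_genes)
        passing = {r.gene for r in records if angle_pass(r, cond.theta)}
        expected = bfs_oracle(
            small_panel.curated, small_network.network, passing, cond.max_depth
        )
        q = expand(
            small_panel.curated, small_network.network, small_panel.expression,
            None, gi50, cond,
        )
        got = {g: e.node_distance for g, e in q.entries.items()}
        # oracle may list network-only symbols with no expression data
        expected = {
            g: d for g, d in expected.items()
            if small_panel.expression.has_feature(g)
        }
        assert got == expected

    def test_parentage_validity(self, small_panel, small_network):
        q = expand(
            small_panel.curated, small_network.network, small_panel.expression,
            None, small_panel.responses.gi50.to_numpy(), CONDITIONS[6],
        )
        for gene, entry in q.entries.items():
            if entry.node_distance == 0:
                continue
            assert entry.parents, f"{gene} has no parents"
            for parent in entry.parents:
                assert small_network.network.has_edge(parent, gene)
                assert q.entries[parent].node_distance == entry.node_distance - 1
                assert q.entries[parent].passed

    def test_minimum_distance_assignment(self):
        # A curated; D reachable at distance 1 (A-D) and 2 (A-B-D): keep 1
        matrix, _, gi50 = chain_fixture(b_correlated=True)
        extra = matrix.data.copy()
        extra.loc["D"] = extra.loc["C"]
        matrix = ExpressionMatrix(extra)
        network = InteractionNetwork.from_edges(
            [("A", "int", "B"), ("B", "int", "D"), ("A", "int", "D")]
        )
        q = expand(["A"], network, matrix, None, gi50, Condition("t", 2, 20.0))
        assert q.entries["D"].node_distance == 1

    def test_no_passing_seed_gives_empty_set(self, small_panel, small_network):
        q = expand(
            small_panel.noise_genes[:3], small_network.network,
            small_panel.expression, None,
            small_panel.responses.gi50.to_numpy(), CONDITIONS[6],
        )
        assert q.entries == {}

    def test_alias_substitution_before_traversal(self):
        matrix, _, gi50 = chain_fixture(b_correlated=True)
        network = InteractionNetwork.from_edges(
            [("A", "int", "OLDB"), ("OLDB", "int", "C")]
        )
        aliases = AliasMap.from_pairs([("OLDB", "B"), ("OLDA", "A")])
        q = expand(["OLDA"], network, matrix, None, gi50,
                   Condition("t", 2, 20.0), aliases=aliases)
        assert set(q.entries) == {"A", "B", "C"}

    def test_seed_alias_audit_pairs_verified(self, small_panel, small_network):
        q = expand(
            small_panel.curated, small_network.network, small_panel.expression,
            None, small_panel.responses.gi50.to_numpy(), CONDITIONS[6],
        )
        pairs = parent_child_pairs(q)
        retained, removed = verify_associations(pairs, small_network.network)
        assert removed == []  # every recruitment is edge-backed
        assert set(retained) == set(pairs)


@pytest.fixture(scope="module")
def all_sets(small_panel, small_network):
    return run_conditions(
        small_panel.curated, small_network.network, small_panel.expression,
        small_panel.copy_number, small_panel.responses.gi50.to_numpy(),
    )


class TestRunConditions:
    def test_configuration_of_six_conditions(self):
        assert {(c.max_depth, c.theta) for c in CONDITIONS.values()} == {
            (0, 10.0), (0, 20.0), (1, 10.0), (1, 20.0), (2, 10.0), (2, 20.0)
        }

    def test_threshold_monotonicity(self, all_sets):
        for narrow, wide in [(1, 2), (3, 4), (5, 6)]:
            assert set(all_sets[narrow].entries) <= set(all_sets[wide].entries)

    def test_depth_monotonicity(self, all_sets):
        for shallow, deep in [(1, 3), (3, 5), (2, 4), (4, 6)]:
            assert set(all_sets[shallow].entries) <= set(all_sets[deep].entries)

    def test_determinism(self, small_panel, small_network, all_sets):
        again = run_conditions(
            small_panel.curated, small_network.network, small_panel.expression,
            small_panel.copy_number, small_panel.responses.gi50.to_numpy(),
        )
        for cid in CONDITIONS:
            assert set(again[cid].entries) == set(all_sets[cid].entries)
            for g in again[cid].entries:
                assert (
                    again[cid].entries[g].node_distance
                    == all_sets[cid].entries[g].node_distance
                )
                assert again[cid].entries[g].parents == all_sets[cid].entries[g].parents
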