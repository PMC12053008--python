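"""Bridge enumeration, centrality, jointness and the two-of-three rule."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metabridge.bridge_analysis import (
    degree_centrality,
    find_bridge_pathways,
    is_selected,
    jointness_score,
    select_candidates,
)
from metabridge.mgm_network import NetworkModel

from conftest import WORKED_PATHWAYS


class TestWorkedExample:
    """The printed 11-adjacency network: 6 pathways over 5 metabolites."""

    def test_pathway_enumeration(self, worked_network):
        pathways = find_bridge_pathways(worked_network)
        triples = {(p.risk_factor, p.metabolite, p.symptom) for p in pathways}
        assert triples == WORKED_PATHWAYS
        assert len(pathways) == 6
        assert len({p.metabolite for p in pathways}) == 5
        # six pathways span 12 per-pathway metabolite-phenotype pairs
        assert sum(2 for _ in pathways) == 12

    def test_roster_mirrors_full_network_dimensions(self, worked_network):
        roles = worked_network.nodes["role"]
        assert (roles == "symptom").sum() == 21
        assert (roles == "metabolite").sum() == 52
        assert (roles == "risk_factor").sum() == 3
        assert len(worked_network.nodes) == 76

    def test_jointness_hand_count(self, worked_network):
        jointness = jointness_score(worked_network)
        expected = {"creatinine": 2, "omega_3_fa": 1, "glucose": 1, "albumin": 1, "citrate": 1}
        for m, j in expected.items():
            assert jointness[m] == j
        assert sum(jointness.values()) == 6


def toy_network(n_rf=1, n_met=2, n_sym=3, edges=None):
    nodes = (
        [(f"rf{i}", "risk_factor") for i in range(n_rf)]
        + [(f"m{i}", "metabolite") for i in range(n_met)]
        + [(f"s{i}", "symptom") for i in range(n_sym)]
    )
    return NetworkModel.from_edges(nodes, edges or [])


class TestPathways:
    def test_no_metabolite_symptom_edges_gives_empty(self):
        net = toy_network(edges=[("m0", "rf0", 0.5)])
        assert find_bridge_pathways(net) == []

    def test_fully_connected_toy_matches_brute_force(self):
        edges = [(f"m{i}", other, 0.1) for i in range(2) for other in ["rf0", "s0", "s1", "s2"]]
        net = toy_network(edges=edges)
        pathways = {(p.risk_factor, p.metabolite, p.symptom) for p in find_bridge_pathways(net)}
        brute = {
            ("rf0", m, s)
            for m, s in itertools.product(["m0", "m1"], ["s0", "s1", "s2"])
            if net.weight(m, "rf0") and net.weight(m, s)
        }
        assert pathways == brute
        assert len(pathways) == 6

    def test_ordering_is_lexicographic(self):
        edges = [("m1", "rf0", 0.1), ("m1", "s1", 0.1), ("m0", "rf0", 0.1), ("m0", "s0", 0.1)]
        pathways = find_bridge_pathways(toy_network(edges=edges))
        keys = [(p.risk_factor, p.metabolite, p.symptom) for p in pathways]
        assert keys == sorted(keys)

    def test_missing_roles_error(self):
        import pandas as pd

        net = NetworkModel.from_edges(
            pd.DataFrame({"name": ["a", "b"], "role": ["covariate", "covariate"],
                          "type": ["gaussian", "gaussian"]}),
            [],
        )
        with pytest.raises(ValueError, match="role"):
            find_bridge_pathways(net)


class TestDegree:
    def test_isolated_metabolite_zero(self):
        assert degree_centrality(toy_network())["m0"] == 0

    def test_complete_metabolite_graph(self):
        n = 10
        nodes = [(f"m{i}", "metabolite") for i in range(n)]
        edges = [(f"m{i}", f"m{j}", 0.1) for i in range(n) for j in range(i + 1, n)]
        net = NetworkModel.from_edges(nodes, edges)
        assert all(d == n - 1 for d in degree_centrality(net).values())

    def test_random_sparse_graph_matches_recount(self):
        rng = np.random.default_rng(0)
        nodes = [(f"m{i}", "metabolite") for i in range(8)] + [("s0", "symptom")]
        edges = []
        for i in range(8):
            for j in range(i + 1, 8):
                if rng.random() < 0.3:
                    edges.append((f"m{i}", f"m{j}", rng.normal()))
        net = NetworkModel.from_edges(nodes, edges)
        deg = degree_centrality(net)
        for i in range(8):
            brute = sum(1 for a, b, w in edges if w != 0 and f"m{i}" in (a, b))
            assert deg[f"m{i}"] == brute

    def test_full_scope_counts_phenotype_edges(self):
        net = toy_network(edges=[("m0", "rf0", 0.2), ("m0", "s0", 0.2), ("m0", "m1", 0.2)])
        assert degree_centrality(net, scope="metabolite")["m0"] == 1
        assert degree_centrality(net, scope="full")["m0"] == 3


class TestJointness:
    def test_one_sided_connection_is_zero(self):
        net = toy_network(edges=[("m0", "s0", 0.4), ("m0", "s1", 0.4)])
        assert jointness_score(net)["m0"] == 0

    def test_bipartite_attachment_product(self):
        # 2 risk factors x 3 symptoms fully attached -> 6 bridged pairs
        nodes = (
            [("rf0", "risk_factor"), ("rf1", "risk_factor"), ("m", "metabolite")]
            + [(f"s{i}", "symptom") for i in range(3)]
        )
        edges = [("m", x, 0.2) for x in ["rf0", "rf1", "s0", "s1", "s2"]]
        net = NetworkModel.from_edges(nodes, edges)
        assert jointness_score(net)["m"] == 6

    def test_pathway_count_equals_jointness_sum(self, worked_network):
        pathways = find_bridge_pathways(worked_network)
        assert len(pathways) == sum(jointness_score(worked_network).values())

    def test_weighted_variant_uses_min_edge(self):
        net = toy_network(edges=[("m0", "rf0", 0.5), ("m0", "s0", -0.2)])
        assert jointness_score(net, weighted=True)["m0"] == pytest.approx(0.2)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 2)), max_size=6, unique=True),
           st.data())
    def test_edge_removal_never_increases_jointness(self, attachments, data):
        # metabolite attached to a random set of phenotypes; dropping any
        # edge cannot raise any jointness score
        edges = []
        for rf, s in attachments:
            edges.append(("m0", f"rf{rf}", 0.3))
            edges.append(("m0", f"s{s}", 0.3))
        edges = list({(a, b): (a, b, 0.3) for a, b, _ in edges}.values())
        net = toy_network(n_rf=2, n_met=1, n_sym=3, edges=edges)
        base = jointness_score(net)
        if not edges:
            return
        drop = data.draw(st.integers(0, len(edges) - 1))
        reduced = toy_network(n_rf=2, n_met=1, n_sym=3,
                              edges=[e for k, e in enumerate(edges) if k != drop])
        shrunk = jointness_score(reduced)
        assert all(shrunk[m] <= base[m] for m in base)

    def test_jointness_bounded_by_degree_product(self, worked_network):
        jointness = jointness_score(worked_network)
        for m in jointness:
            i = worked_network.index_of(m)
            rf_deg = sum(
                worked_network.adjacency[i, worked_network.index_of(r)] != 0
                for r in worked_network.nodes_by_role("risk_factor")
            )
            sym_deg = sum(
                worked_network.adjacency[i, worked_network.index_of(s)] != 0
                for s in worked_network.nodes_by_role("symptom")
            )
            assert jointness[m] <= rf_deg * sym_deg


class TestSelection:
    def test_truth_table(self):
        # exhaustive 3^3 enumeration of the two-of-three rule
        for verdicts in itertools.product(["pass", "semi", "fail"], repeat=3):
            n_ok = sum(v != "fail" for v in verdicts)
            n_pass = sum(v == "pass" for v in verdicts)
            assert is_selected(verdicts) == (n_ok >= 2 and n_pass >= 1)

    def test_select_candidates_table(self):
        import pandas as pd

        table = pd.DataFrame(
            [
                {"metabolite": "m_all_pass", "degree": 1, "jointness": 2,
                 "stability_verdict": "pass", "permutation_verdict": "pass", "robustness_verdict": "pass"},
                {"metabolite": "m_all_fail", "degree": 0, "jointness": 1,
                 "stability_verdict": "fail", "permutation_verdict": "fail", "robustness_verdict": "fail"},
                {"metabolite": "m_pass_semi", "degree": 2, "jointness": 3,
                 "stability_verdict": "pass", "permutation_verdict": "semi", "robustness_verdict": "fail"},
                {"metabolite": "m_two_semi", "degree": 0, "jointness": 1,
                 "stability_verdict": "semi", "permutation_verdict": "semi", "robustness_verdict": "fail"},
            ]
        )
        selected = select_candidates(table)
        assert selected == ["m_pass_semi", "m_all_pass"]  # jointness-desc ranking

    def test_missing_verdict_errors(self):
        import pandas as pd

        table = pd.DataFrame(
            [{"metabolite": "m", "stability_verdict": "pass",
              "permutation_verdict": None, "robustness_verdict": "pass"}]
        )
        with pytest.raises(ValueError, match="permutation_verdict"):
            select_candidates(table)
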