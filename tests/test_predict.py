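import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem
from rdkit.Chem.Descriptors import ExactMolWt

from pathseer.core_data import (
    EnzymeAssociation,
    ReactionRule,
    TranscriptAnnotation,
    ValidationError,
)
from pathseer.predict import (
    GHOST,
    MEASURED,
    MassSignatureNode,
    apply_rule,
    admissible_rules,
    attach_enzyme_support,
    build_network,
    default_hierarchy,
    insert_ghosts,
    iterate_prediction,
    longest_path,
    match_mass_pairs,
    predict_pathways,
    substructure_prescreen,
    to_dag,
)
from pathseer.rules import build_transition_index


def _rule(rule_id, transition, smarts="[cH:1]>>[c:1]O", direction="both", pfams=("PF1",)):
    return ReactionRule(
        rule_id=rule_id,
        smarts=smarts,
        substrate_mass=100.0,
        product_mass=100.0 + transition,
        mass_transition=transition,
        direction=direction,
        enzyme_associations=tuple(
            EnzymeAssociation(p, "1.1.1.1", "strict", "Plantae") for p in pfams
        ),
    )


def _node(node_id, mass, feature=None, structures=()):
    return MassSignatureNode(
        node_id=node_id,
        kind=MEASURED,
        mass=mass,
        source_feature=feature or node_id.rsplit("@", 1)[0],
        structures=tuple(structures),
    )


HYDROX = _rule("hydrox", 15.9949)


class TestMatchMassPairs:
    def test_hydroxylation_pair_both_orientations(self):
        nodes = [_node("fA@180.0634", 180.0634), _node("fB@196.0583", 196.0583)]
        idx = build_transition_index([HYDROX])
        pairs = match_mass_pairs(nodes, idx, tol_da=0.002)
        got = set(zip(pairs.substrate_node, pairs.product_node, pairs.direction))
        assert got == {
            ("fA@180.0634", "fB@196.0583", "forward"),
            ("fB@196.0583", "fA@180.0634", "reverse"),
        }

    def test_unexplained_difference_gives_no_pair(self):
        nodes = [_node("fA@100.0", 100.0), _node("fB@107.0", 107.0)]
        pairs = match_mass_pairs(nodes, build_transition_index([HYDROX]), tol_da=0.002)
        assert len(pairs) == 0

    def test_zero_tolerance_exact_difference(self):
        # masses chosen exactly representable so the difference is exact
        rule = _rule("plus16", 16.0)
        nodes = [_node("fA@100.0", 100.0), _node("fB@116.0", 116.0)]
        pairs = match_mass_pairs(nodes, build_transition_index([rule]), tol_da=0.0)
        assert len(pairs) == 2  # forward + reverse orientation


class TestInsertGhosts:
    def test_double_hydroxylation_bridged(self):
        nodes = [_node("fA@180.0634", 180.0634), _node("fC@212.0532", 212.0532)]
        idx = build_transition_index([HYDROX])
        pairs = match_mass_pairs(nodes, idx, tol_da=0.002)
        assert len(pairs) == 0
        extended, ghosts = insert_ghosts(pairs, nodes, idx, mode="auto", tol_da=0.002)
        assert len(ghosts) == 1
        assert ghosts[0].kind == GHOST
        assert ghosts[0].mass == pytest.approx(196.0583, abs=2e-3)
        chain = set(zip(extended.substrate_node, extended.product_node))
        assert ("fA@180.0634", ghosts[0].node_id) in chain
        assert (ghosts[0].node_id, "fC@212.0532") in chain

    def test_mode_off_is_identity(self):
        nodes = [_node("fA@180.0634", 180.0634), _node("fC@212.0532", 212.0532)]
        idx = build_transition_index([HYDROX])
        pairs = match_mass_pairs(nodes, idx, tol_da=0.002)
        out, ghosts = insert_ghosts(pairs, nodes, idx, mode="off")
        assert ghosts == []
        pd.testing.assert_frame_equal(out, pairs)

    def test_ghost_mass_obeys_anchor_plus_transition(self):
        rng = np.random.default_rng(0)
        rules = [HYDROX, _rule("methyl", 14.01565), _rule("desat", -2.01565)]
        idx = build_transition_index(rules)
        masses = sorted(rng.uniform(150, 400, 8))
        nodes = [_node(f"f{i}@{m:.4f}", round(m, 4)) for i, m in enumerate(masses)]
        pairs = match_mass_pairs(nodes, idx, tol_da=0.002)
        extended, ghosts = insert_ghosts(pairs, nodes, idx, mode="always", tol_da=0.002)
        by_id = {n.node_id: n for n in nodes + ghosts}
        transitions = {r.mass_transition for r in rules} | {-r.mass_transition for r in rules}
        for row in extended.itertuples(index=False):
            diff = by_id[row.product_node].mass - by_id[row.substrate_node].mass
            assert min(abs(diff - t) for t in transitions) <= 0.002 + 1e-4


class TestAttachEnzymeSupport:
    NETWORK = pd.DataFrame(
        {
            "transcript_id": ["t_des", "t_other", "t_weak"],
            "feature_id": ["fA", "fA", "fB"],
            "weight": [0.9, 0.8, 0.4],
        }
    )
    ANNOS = [
        TranscriptAnnotation("t_des", ("PF_desat",), "tailoring"),
        TranscriptAnnotation("t_weak", ("PF_desat",), "tailoring"),
        TranscriptAnnotation("t_other", ("PF_unrelated",), "other"),
    ]

    @staticmethod
    def _pairs():
        return pd.DataFrame(
            [
                {
                    "substrate_node": "fA@100.0000",
                    "product_node": "fB@97.9844",
                    "rule_id": "desat",
                    "direction": "forward",
                    "transition": -2.01565,
                }
            ]
        )

    def test_matching_pfam_retained_with_max_support(self):
        rules = {"desat": _rule("desat", -2.01565, pfams=("PF_desat",))}
        out = attach_enzyme_support(
            self._pairs(), self.NETWORK, self.ANNOS, rules, cluster_restrict=False
        )
        assert len(out) == 1
        assert out.loc[0, "support_transcripts"] == "t_des;t_weak"
        assert out.loc[0, "edge_support"] == pytest.approx(0.9)

    def test_unrelated_pfam_dropped(self):
        rules = {"desat": _rule("desat", -2.01565, pfams=("PF_nothing",))}
        out = attach_enzyme_support(
            self._pairs(), self.NETWORK, self.ANNOS, rules, cluster_restrict=False
        )
        assert len(out) == 0

    def test_cluster_restriction_requires_co_clustering(self):
        from pathseer.cluster import FEATURE, TRANSCRIPT, FunctionalCluster

        rules = {"desat": _rule("desat", -2.01565, pfams=("PF_desat",))}
        outside = FunctionalCluster(
            1, frozenset({(TRANSCRIPT, "t_other"), (FEATURE, "fA")})
        )
        out = attach_enzyme_support(
            self._pairs(), self.NETWORK, self.ANNOS, rules,
            clusters=[outside], cluster_restrict=True,
        )
        assert len(out) == 0
        inside = FunctionalCluster(
            1, frozenset({(TRANSCRIPT, "t_des"), (FEATURE, "fA")})
        )
        out = attach_enzyme_support(
            self._pairs(), self.NETWORK, self.ANNOS, rules,
            clusters=[inside], cluster_restrict=True,
        )
        assert len(out) == 1
        assert out.loc[0, "support_transcripts"] == "t_des"


STRUCTURES_20 = [
    "c1ccccc1", "Oc1ccccc1", "Cc1ccccc1", "Nc1ccccc1", "c1ccncc1",
    "OCC1OC(O)C(O)C(O)C1O", "O=C1CC(c2ccc(O)cc2)Oc2cc(O)cc(O)c21",
    "CCCCCC", "CCCCCCO", "CC(=O)O", "OC(=O)c1ccccc1", "Oc1ccccc1O",
    "C=Cc1ccccc1", "CCCCCCCCc1ccccc1", "CCN", "c1ccc2[nH]ccc2c1",
    "c1ccoc1", "C1CCCCC1", "OC1CCCCC1", "NC(Cc1ccccc1)C(=O)O",
]

_TEMPLATE_POOL = [
    ("[cH:1]>>[c:1]O", 15.994915),
    ("[CH2:1][CH2:2]>>[CH:1]=[CH:2]", -2.015650),
    ("[OX2H:1]>>[O:1]C", 14.015650),
    ("[OX2H:1]>>[O:1]C(C)=O", 42.010565),
    ("[NX3;H2:1]>>[N:1]C(C)=O", 42.010565),
    ("[CX4;H2:1][OX2H1:2]>>[CX3:1]=[OX1:2]", -2.015650),
]

RULES_30 = [
    _rule(f"r{i:02d}", _TEMPLATE_POOL[i % 6][1], smarts=_TEMPLATE_POOL[i % 6][0])
    for i in range(30)
]


class TestSubstructurePrescreen:
    def test_benzene_gates_nitrogen_keys(self):
        keys = substructure_prescreen(["c1ccccc1"])["c1ccccc1"]
        assert "N" not in keys and "C-N" not in keys and "N=C-N" not in keys
        assert {"C", "c_arom", "c:c", "benzene"} <= keys

    def test_parent_gate_blocks_untested_children(self):
        # glucose has no aromatic carbon, so no aromatic-rooted key may pass
        keys = substructure_prescreen(["OCC1OC(O)C(O)C(O)C1O"])["OCC1OC(O)C(O)C(O)C1O"]
        assert not {"c_arom", "c:c", "benzene", "phenol_OH"} & keys
        assert {"C", "O", "C-O", "O-H"} <= keys

    def test_empty_structure_list(self):
        assert substructure_prescreen([]) == {}

    def test_unparseable_smiles_skipped(self):
        out = substructure_prescreen(["not_a_smiles", "CC"])
        assert set(out) == {"CC"}

    def test_prescreened_application_equals_brute_force(self):
        """The divide-and-conquer gate must introduce no false negatives:
        on 20 structures x 30 rules, rules that survive the prescreen and
        produce a product are exactly the rules that produce a product."""
        hierarchy = default_hierarchy()
        pres = substructure_prescreen(STRUCTURES_20, hierarchy)
        for smi in STRUCTURES_20:
            brute = {r.rule_id for r in RULES_30 if apply_rule(smi, r)}
            screened = {
                r.rule_id
                for r in admissible_rules(smi, RULES_30, pres, hierarchy)
                if apply_rule(smi, r)
            }
            assert screened == brute, smi


class TestApplyRule:
    def test_benzene_hydroxylation_gives_phenol(self):
        rule = _rule("hydrox", 15.994915)
        assert apply_rule("c1ccccc1", rule) == ["Oc1ccccc1"]

    def test_naringenin_2_hydroxylation(self):
        naringenin = "O=C1CC(c2ccc(O)cc2)Oc2cc(O)cc(O)c21"
        rule = _rule(
            "f2h",
            15.994915,
            smarts="[O;R:1][CH1:2]([c:3])[CH2:4]>>[O;R:1][C:2](O)([c:3])[CH2:4]",
        )
        products = apply_rule(naringenin, rule)
        expected = Chem.MolToSmiles(
            Chem.MolFromSmiles("O=C1CC(O)(c2ccc(O)cc2)Oc2cc(O)cc(O)c21")
        )
        assert expected in products

    def test_non_matching_template_empty(self):
        desat = _rule("desat", -2.01565, smarts="[CH2:1][CH2:2]>>[CH:1]=[CH:2]")
        assert apply_rule("CC", desat) == []  # ethane: CH3 groups only

    def test_products_conserve_mass(self):
        for rule in RULES_30[:6]:
            for smi in STRUCTURES_20:
                sub_mass = ExactMolWt(Chem.MolFromSmiles(smi))
                for prod in apply_rule(smi, rule):
                    pmass = ExactMolWt(Chem.MolFromSmiles(prod))
                    assert abs(pmass - sub_mass - rule.mass_transition) <= 0.005


def _graph(edges):
    g = nx.MultiDiGraph()
    for u, v, sup in edges:
        g.add_edge(u, v, key=f"{u}-{v}", rule_id=f"{u}-{v}", edge_support=sup)
    return g


class TestToDag:
    def test_triangle_back_edge_removed(self):
        g = _graph([("A", "B", 0.9), ("B", "C", 0.8), ("C", "A", 0.7)])
        dag = to_dag(g, "A")
        assert nx.is_directed_acyclic_graph(dag.graph)
        assert not dag.graph.has_edge("C", "A")
        assert dag.graph.has_edge("A", "B") and dag.graph.has_edge("B", "C")

    def test_chain_unchanged(self):
        g = _graph([("A", "B", 0.5), ("B", "C", 0.5)])
        dag = to_dag(g, "A")
        assert sorted(dag.graph.edges(keys=False)) == [("A", "B"), ("B", "C")]

    def test_reciprocal_equidistant_weakest_removed(self):
        g = _graph(
            [("R", "X", 0.9), ("R", "Y", 0.9), ("X", "Y", 0.6), ("Y", "X", 0.4)]
        )
        dag = to_dag(g, "R")
        assert dag.graph.has_edge("X", "Y")
        assert not dag.graph.has_edge("Y", "X")

    def test_missing_root_errors(self):
        with pytest.raises(ValidationError):
            to_dag(_graph([("A", "B", 0.5)]), "Z")

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        edges=st.lists(
            st.tuples(
                st.integers(0, 7), st.integers(0, 7), st.floats(0.01, 1.0)
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_output_always_acyclic_and_root_reachable(self, edges):
        g = nx.MultiDiGraph()
        g.add_node("n0")
        for i, (u, v, sup) in enumerate(edges):
            if u == v:
                continue
            g.add_edge(f"n{u}", f"n{v}", key=f"e{i}", edge_support=round(sup, 3))
        dag = to_dag(g, "n0")
        assert nx.is_directed_acyclic_graph(dag.graph)
        for n in dag.graph:
            assert n == "n0" or nx.has_path(dag.graph, "n0", n)


class TestLongestPath:
    def test_chain_of_four(self):
        dag = to_dag(_graph([("A", "B", 1), ("B", "C", 1), ("C", "D", 1)]), "A")
        pw = longest_path(dag)
        assert pw.nodes == ("A", "B", "C", "D")
        assert len(pw) == 3

    def test_longer_branch_wins(self):
        dag = to_dag(
            _graph(
                [("R", "a", 1), ("a", "b", 1),
                 ("R", "x", 1), ("x", "y", 1), ("y", "z", 1)]
            ),
            "R",
        )
        assert longest_path(dag).nodes == ("R", "x", "y", "z")

    def test_support_breaks_length_ties(self):
        dag = to_dag(
            _graph(
                [("R", "a1", 0.9), ("a1", "a2", 0.9),
                 ("R", "b1", 0.5), ("b1", "b2", 0.5)]
            ),
            "R",
        )
        pw = longest_path(dag)
        assert pw.nodes == ("R", "a1", "a2")
        assert pw.total_support == pytest.approx(1.8)

    def test_two_rooted_predictions(self):
        g = _graph([("A", "B", 0.9), ("B", "C", 0.8)])
        forward, reverse = predict_pathways(g, "A")
        assert forward.nodes == ("A", "B", "C")
        assert reverse.nodes[-1] == "C"


class TestIteratePrediction:
    @staticmethod
    def _chain_setup():
        from pathseer.fixtures import generate_pathway_chain

        structures, rules = generate_pathway_chain(3, seed=5)
        masses = [round(ExactMolWt(Chem.MolFromSmiles(s)), 4) for s in structures]
        nodes = [
            _node(f"f{i}@{m:.4f}", m, structures=[structures[i]] if i == 0 else ())
            for i, m in enumerate(masses)
        ]
        return structures, rules, nodes

    def test_round_limit_controls_recovery_depth(self):
        structures, rules, nodes = self._chain_setup()
        base = nx.MultiDiGraph()
        one = iterate_prediction(base, nodes, rules, rounds=1)
        full = iterate_prediction(base, nodes, rules, rounds=3)
        assert one.number_of_edges() == 1
        assert full.number_of_edges() == 3
        pw = longest_path(to_dag(full, nodes[0].node_id))
        assert pw.nodes == tuple(n.node_id for n in nodes)

    def test_monotone_in_rounds(self):
        structures, rules, nodes = self._chain_setup()
        base = nx.MultiDiGraph()
        sizes = [
            iterate_prediction(base, nodes, rules, rounds=k).number_of_edges()
            for k in (1, 2, 3, 4)
        ]
        assert sizes == sorted(sizes)
        assert sizes[2] == sizes[3]  # fixpoint after the chain is complete


class TestBuildNetwork:
    def test_chained_pairs_counts(self):
        edges = pd.DataFrame(
            [
                {"substrate_node": a, "product_node": b, "rule_id": f"r{i}",
                 "direction": "forward", "transition": 1.0,
                 "support_transcripts": "t", "edge_support": 0.5}
                for i, (a, b) in enumerate([("n1", "n2"), ("n2", "n3"), ("n3", "n4")])
            ]
        )
        nodes = [_node(n, 100.0 + i) for i, n in enumerate(["n1", "n2", "n3", "n4"])]
        g = build_network(edges, nodes)
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 3

    def test_parallel_edges_for_distinct_rules(self):
        edges = pd.DataFrame(
            [
                {"substrate_node": "n1", "product_node": "n2", "rule_id": r,
                 "direction": "forward", "transition": 1.0,
                 "support_transcripts": "t", "edge_support": 0.5}
                for r in ("ruleA", "ruleB")
            ]
        )
        nodes = [_node("n1", 100.0), _node("n2", 101.0)]
        g = build_network(edges, nodes)
        assert g.number_of_edges(u="n1", v="n2") == 2
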