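"""Ontology parsing, closures, information content, term scoring, bridging."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenomatch as pm
from helpers import (
    brute_force_mica_score,
    make_ontology,
    nx_ancestors,
    random_dag_edges,
)

OBO_SMALL = """\
format-version: 1.2

[Term]
id: X:0000001
name: root

[Term]
id: X:0000002
name: child-a
is_a: X:0000001 ! root

[Term]
id: X:0000003
name: child-b
is_a: X:0000001
"""


class TestLoadObo:
    def test_small_fixture(self, tmp_path):
        p = tmp_path / "small.obo"
        p.write_text(OBO_SMALL)
        ont = pm.load_obo(str(p), species="x")
        assert len(ont) == 3
        assert ont.root == "X:0000001"
        assert ont.ancestors("X:0000002") == {"X:0000002", "X:0000001"}
        assert ont.label("X:0000002") == "child-a"

    def test_obsolete_terms_are_dropped(self, tmp_path):
        p = tmp_path / "obs.obo"
        p.write_text(
            OBO_SMALL
            + "\n[Term]\nid: X:0000004\nis_a: X:0000002\nis_obsolete: true\n"
        )
        ont = pm.load_obo(str(p))
        assert "X:0000004" not in ont
        assert len(ont) == 3

    def test_missing_id_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.obo"
        p.write_text("[Term]\nid: A:1\n\n[Term]\nname: anonymous\n")
        with pytest.raises(pm.OntologyError, match="line 4"):
            pm.load_obo(str(p))

    def test_multi_root_gets_synthetic_root(self, tmp_path):
        p = tmp_path / "two_roots.obo"
        p.write_text("[Term]\nid: A:1\n\n[Term]\nid: A:2\n")
        ont = pm.load_obo(str(p))
        assert ont.root == pm.ontology.SYNTHETIC_ROOT_ID
        assert ont.ancestors("A:1") == {"A:1", ont.root}

    def test_roundtrip_through_write_obo(self, tmp_path):
        p = tmp_path / "small.obo"
        p.write_text(OBO_SMALL)
        ont = pm.load_obo(str(p), species="x")
        out = tmp_path / "out.obo"
        pm.write_obo(ont, str(out))
        again = pm.load_obo(str(out), species="x")
        assert again.terms == ont.terms

    def test_matches_obonet_on_random_obo(self, tmp_path):
        """Independent parse: obonet + networkx reachability as oracle."""
        import networkx as nx
        import obonet

        rng = np.random.default_rng(5)
        edges = random_dag_edges(rng, 40)
        ont = make_ontology(edges)
        p = tmp_path / "rand.obo"
        pm.write_obo(ont, str(p))
        g = obonet.read_obo(str(p))
        assert set(g.nodes) == set(ont.terms)
        for t in g.nodes:
            # obonet edges point child -> parent for is_a
            oracle = {t} | nx.descendants(g, t)
            assert ont.ancestors(t) == oracle


class TestAncestors:
    def test_root_is_self_closure(self, chain_ontology):
        assert chain_ontology.ancestors("root") == {"root"}

    def test_chain(self, chain_ontology):
        assert chain_ontology.ancestors("b") == {"b", "a", "root"}

    def test_diamond(self):
        ont = make_ontology(
            {"a": [], "b": ["a"], "c": ["a"], "d": ["b", "c"]}
        )
        assert ont.ancestors("d") == {"d", "b", "c", "a"}

    def test_unknown_term_is_error(self, chain_ontology):
        with pytest.raises(pm.OntologyError, match="nope"):
            pm.ancestors(chain_ontology, "nope")

    def test_cycle_is_hard_error(self):
        with pytest.raises(pm.OntologyError, match="cycle"):
            make_ontology({"a": ["b"], "b": ["a"]})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_closure_equals_brute_force_reachability(self, seed):
        rng = np.random.default_rng(seed)
        edges = random_dag_edges(rng, 200)
        ont = make_ontology(edges)
        for t in edges:
            assert ont.ancestors(t) == nx_ancestors(edges, t)


class TestInformationContent:
    @pytest.fixture()
    def corpus_ontology(self):
        return make_ontology(
            {"r": [], "a": ["r"], "b": ["r"], "a1": ["a"], "a2": ["a"]}
        )

    def test_root_ic_is_zero(self, corpus_ontology):
        ic = pm.information_content(
            corpus_ontology,
            [("e1", {"a1"}), ("e2", {"a2"}), ("e3", {"b"}), ("e4", {"a"})],
        )
        assert ic.ic["r"] == 0.0
        assert ic.corpus_size == 4

    def test_singleton_leaf_ic(self, corpus_ontology):
        ic = pm.information_content(
            corpus_ontology,
            [("e1", {"a1"}), ("e2", {"a"}), ("e3", {"b"}), ("e4", {"b"})],
        )
        assert ic.ic["a1"] == pytest.approx(-math.log(1 / 4))

    def test_unused_terms_absent(self, corpus_ontology):
        ic = pm.information_content(corpus_ontology, [("e1", {"a1"})])
        assert "b" not in ic
        assert "a2" not in ic

    def test_empty_corpus_is_error(self, corpus_ontology):
        with pytest.raises(pm.OntologyError, match="empty"):
            pm.information_content(corpus_ontology, [])

    def test_counts_and_ic_monotone_along_edges(self):
        rng = np.random.default_rng(7)
        edges = random_dag_edges(rng, 60)
        ont = make_ontology(edges)
        terms = sorted(edges)
        annotations = [
            (f"e{i}", set(rng.choice(terms, size=3, replace=False)))
            for i in range(25)
        ]
        ic = pm.information_content(ont, annotations)
        for child, parents in edges.items():
            for p in parents:
                if child in ic and p in ic:
                    assert ic.counts[p] >= ic.counts[child]
                    assert ic.ic[p] <= ic.ic[child] + 1e-12


class TestSimJaccard:
    def test_identity(self, chain_ontology):
        assert pm.sim_jaccard(chain_ontology, "b", "b") == 1.0

    def test_chain_parent_child(self, chain_ontology):
        assert pm.sim_jaccard(chain_ontology, "a", "b") == pytest.approx(2 / 3)

    def test_siblings_under_root(self):
        ont = make_ontology({"r": [], "a": ["r"], "b": ["r"]})
        assert pm.sim_jaccard(ont, "a", "b") == pytest.approx(1 / 3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), data=st.data())
    def test_bounds_and_symmetry(self, seed, data):
        rng = np.random.default_rng(seed)
        edges = random_dag_edges(rng, 25)
        ont = make_ontology(edges)
        terms = sorted(edges)
        t1 = data.draw(st.sampled_from(terms))
        t2 = data.draw(st.sampled_from(terms))
        s = pm.sim_jaccard(ont, t1, t2)
        assert 0.0 <= s <= 1.0
        assert s == pm.sim_jaccard(ont, t2, t1)
        assert pm.sim_jaccard(ont, t1, t1) == 1.0


class TestTermPairScore:
    def test_self_score_is_sqrt_ic(self):
        ont = make_ontology({"r": [], "a": ["r"], "a1": ["a"]})
        ic = pm.information_content(
            ont, [("e1", {"a1"}), ("e2", {"r"})] + [(f"n{i}", {"a"}) for i in range(6)]
        )
        assert pm.term_pair_score(ont, ic, "a1", "a1") == pytest.approx(
            math.sqrt(ic.ic["a1"])
        )

    def test_siblings_with_zero_ic_root_score_zero(self):
        ont = make_ontology({"r": [], "a": ["r"], "b": ["r"]})
        ic = pm.information_content(ont, [("e1", {"a"}), ("e2", {"b"})])
        assert pm.term_pair_score(ont, ic, "a", "b") == 0.0

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_equals_brute_force_mica_oracle(self, seed):
        rng = np.random.default_rng(seed)
        edges = random_dag_edges(rng, 30)
        ont = make_ontology(edges)
        terms = sorted(edges)
        annotations = [
            (f"e{i}", set(rng.choice(terms, size=2, replace=False)))
            for i in range(15)
        ]
        ic = pm.information_content(ont, annotations)
        for _ in range(50):
            t1, t2 = rng.choice(terms, size=2, replace=True)
            expected = brute_force_mica_score(edges, ic.ic, t1, t2)
            assert pm.term_pair_score(ont, ic, t1, t2) == pytest.approx(
                expected, abs=1e-12
            )


class TestBridge:
    @pytest.fixture()
    def bridge_world(self):
        human = make_ontology(
            {"H:r": [], "H:a": ["H:r"], "H:a1": ["H:a"], "H:a2": ["H:a"],
             "H:b": ["H:r"]},
            species="human",
        )
        model = make_ontology(
            {"M:r": [], "M:a": ["M:r"], "M:a1": ["M:a"], "M:a2": ["M:a"],
             "M:b": ["M:r"]},
            species="mouse",
        )
        entries = {"H:r": {"M:r"}, "H:a": {"M:a"}, "H:a1": {"M:a1"},
                   "H:b": {"M:b"}}
        return human, model, entries

    def test_exact_entry(self, bridge_world):
        human, model, entries = bridge_world
        bridge = pm.BridgeMap("human", "mouse", entries, human, model)
        assert pm.bridge_term(bridge, human, "H:a1") == {("M:a1", pm.EXACT)}

    def test_one_step_fallback(self, bridge_world):
        human, model, entries = bridge_world
        bridge = pm.BridgeMap("human", "mouse", entries, human, model)
        # H:a2 has no entry; its parent H:a maps to M:a
        assert pm.bridge_term(bridge, human, "H:a2") == {
            ("M:a", pm.ANCESTOR_FALLBACK)
        }

    def test_fallback_reaches_root_when_nothing_else_mapped(self, bridge_world):
        human, model, _ = bridge_world
        bridge = pm.BridgeMap(
            "human", "mouse", {"H:r": {"M:r"}}, human, model
        )
        assert pm.bridge_term(bridge, human, "H:a1") == {
            ("M:r", pm.ANCESTOR_FALLBACK)
        }

    def test_deleting_entry_falls_back_to_ancestor_image(self, bridge_world):
        """Removing a term's equivalence must redirect to its ancestor's
        image, never to an unrelated branch."""
        human, model, entries = bridge_world
        without = {k: v for k, v in entries.items() if k != "H:a1"}
        bridge = pm.BridgeMap("human", "mouse", without, human, model)
        image = pm.bridge_term(bridge, human, "H:a1")
        assert image == {("M:a", pm.ANCESTOR_FALLBACK)}
        assert all(t in model.ancestors("M:a1") for t, _ in image)

    def test_unmapped_root_is_load_error(self, bridge_world):
        human, model, entries = bridge_world
        entries = {k: v for k, v in entries.items() if k != "H:r"}
        with pytest.raises(pm.OntologyError, match="root"):
            pm.BridgeMap("human", "mouse", entries, human, model)

    def test_tsv_roundtrip(self, bridge_world, tmp_path):
        human, model, entries = bridge_world
        bridge = pm.BridgeMap("human", "mouse", entries, human, model)
        p = tmp_path / "bridge.tsv"
        pm.write_bridge(bridge, str(p))
        again = pm.load_bridge(str(p), human, model)
        assert again.exact == bridge.exact
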