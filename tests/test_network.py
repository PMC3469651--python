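"""Parsing, multiset algebra, stoichiometry and reactive-subset reduction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import orgcycle as oc
from orgcycle.network import ParseError, Reaction


class TestParsing:
    def test_readback(self):
        net = oc.parse_network("r1: a -> b\nr2: b -> c")
        assert net.species == ("a", "b", "c")
        assert [r.id for r in net.reactions] == ["r1", "r2"]

    def test_inflow_empty_lhs(self):
        net = oc.parse_network("r1: 0 -> a")
        assert net.reactions[0].lhs == {}
        assert net.reactions[0].rhs == {"a": 1}

    def test_multiplicities_and_comments(self):
        net = oc.parse_network("# header\nr1: 2 a + b -> 3 c  # trailing\n")
        r = net.reactions[0]
        assert r.lhs == {"a": 2, "b": 1}
        assert r.rhs == {"c": 3}

    def test_repeated_species_accumulates(self):
        net = oc.parse_network("r1: a + a -> b")
        assert net.reactions[0].lhs == {"a": 2}

    def test_malformed_line_reports_number(self):
        with pytest.raises(ParseError, match="line 2"):
            oc.parse_network("r1: a -> b\nr2 a -> b")

    def test_duplicate_reaction_id_rejected(self):
        with pytest.raises(oc.NetworkError, match="duplicate"):
            oc.parse_network("r1: a -> b\nr1: b -> a")

    def test_both_sides_empty_rejected(self):
        with pytest.raises(ParseError):
            oc.parse_network("r1: 0 -> 0")

    def test_round_trip_identity(self, fig1):
        again = oc.parse_network(oc.write_network(fig1))
        assert again == fig1

    def test_reversible_parse_and_split(self):
        net = oc.parse_network("r1: a + b <-> c")
        assert net.reactions[0].reversible
        split = oc.split_reversible(net)
        assert [r.id for r in split.reactions] == ["r1_fwd", "r1_rev"]
        fwd, rev = split.reactions
        assert fwd.lhs == rev.rhs == {"a": 1, "b": 1}
        assert fwd.rhs == rev.lhs == {"c": 1}
        assert fwd.reversible_origin == rev.reversible_origin == "r1"

    def test_split_is_identity_without_reversibles(self, toy_chain):
        assert oc.split_reversible(toy_chain) is toy_chain


class TestSupportProduct:
    @pytest.mark.parametrize(
        "line,expected",
        [
            ("r: a + 2 b -> c", {"a", "b"}),
            ("r: 0 -> a", set()),
            ("r: a -> 2 a", {"a"}),
        ],
    )
    def test_support(self, line, expected):
        net = oc.parse_network(line)
        assert oc.support(net.reactions[0]) == expected

    @pytest.mark.parametrize(
        "line,expected",
        [
            ("r: a -> b + b", {"b"}),  # a set, never the multiset {b, b}
            ("r: a -> 0", set()),
            ("r: a -> a + b", {"a", "b"}),
        ],
    )
    def test_product(self, line, expected):
        net = oc.parse_network(line)
        assert oc.product(net.reactions[0]) == expected

    @given(scale=st.integers(min_value=1, max_value=20))
    def test_support_invariant_under_multiplicity_scaling(self, scale):
        base = Reaction("r", {"a": 1, "b": 2}, {"c": 1})
        scaled = Reaction("r", {"a": scale, "b": 2 * scale}, {"c": 1})
        assert base.support == scaled.support


class TestApplicableReactions:
    def test_support_containment(self, toy_chain):
        assert [r.id for r in oc.applicable_reactions(toy_chain, {"a"})] == ["r1"]
        assert [r.id for r in oc.applicable_reactions(toy_chain, {"a", "b", "c"})] == [
            "r1",
            "r2",
        ]

    def test_empty_set_gets_only_inflows(self, toy_inflow):
        assert [r.id for r in oc.applicable_reactions(toy_inflow, set())] == ["r1"]

    def test_unknown_species_rejected(self, toy_chain):
        with pytest.raises(oc.NetworkError, match="unknown species"):
            oc.applicable_reactions(toy_chain, {"z"})

    @given(seed=st.integers(0, 10**6), data=st.data())
    def test_monotone_in_the_species_set(self, seed, data):
        net = oc.random_network(n_species=5, n_reactions=6, seed=seed)
        species = sorted(net.species_set)
        X = frozenset(data.draw(st.sets(st.sampled_from(species))))
        Y = X | frozenset(data.draw(st.sets(st.sampled_from(species))))
        rx = {r.id for r in oc.applicable_reactions(net, X)}
        ry = {r.id for r in oc.applicable_reactions(net, Y)}
        assert rx <= ry


class TestStoichiometry:
    def test_simple_column(self):
        net = oc.parse_network("r: a -> 2 b")
        sm = oc.stoichiometric_matrix(net)
        assert sm.matrix.tolist() == [[-1], [2]]

    def test_catalyst_nets_to_zero(self):
        net = oc.parse_network("r: a + x -> a + y")
        sm = oc.stoichiometric_matrix(net)
        col = dict(zip(sm.species, sm.matrix[:, 0]))
        assert col == {"a": 0, "x": -1, "y": 1}

    def test_toy_decay_matrix(self, toy_decay):
        sm = oc.stoichiometric_matrix(toy_decay)
        assert sm.species == ("a", "b")
        assert sm.matrix.tolist() == [[-1, 1], [1, -2]]

    @given(seed=st.integers(0, 10**6))
    def test_reversible_pairs_have_negated_columns(self, seed):
        net = oc.random_network(n_species=4, n_reactions=5, seed=seed)
        # mark every reaction reversible, then split
        rev = oc.ReactionNetwork(
            species=net.species,
            reactions=tuple(
                oc.Reaction(r.id, dict(r.lhs), dict(r.rhs), reversible=True)
                for r in net.reactions
            ),
        )
        sm = oc.stoichiometric_matrix(oc.split_reversible(rev))
        cols = {rid: sm.matrix[:, j] for j, rid in enumerate(sm.reaction_ids)}
        for r in net.reactions:
            np.testing.assert_array_equal(
                cols[f"{r.id}_fwd"], -cols[f"{r.id}_rev"]
            )


class TestReactiveSubset:
    def test_chain_fully_reactive(self, toy_chain):
        X = {"a", "b", "c"}
        assert oc.largest_reactive_subset(toy_chain, X) == X

    def test_untouched_species_dropped(self):
        net = oc.parse_network("r1: a -> b\nr2: c -> c + a")  # c present but unused in X
        assert oc.largest_reactive_subset(net, {"c"}) == {"c"}  # self-catalytic
        net2 = oc.parse_network("r1: a -> b")
        # c is not even a species of net2
        net3 = oc.ReactionNetwork(species=("a", "b", "c"), reactions=net2.reactions)
        assert oc.largest_reactive_subset(net3, {"c"}) == frozenset()

    def test_template_every_subset_reactive(self, case1):
        # every template species has a unary decay outlet, so any subset
        # is already its own largest reactive subset
        for X in ({"w"}, {"s", "f"}, case1.species_set):
            assert oc.largest_reactive_subset(case1, X) == frozenset(X)

    @given(seed=st.integers(0, 10**6), data=st.data())
    def test_idempotent_and_monotone(self, seed, data):
        net = oc.random_network(n_species=5, n_reactions=6, seed=seed)
        species = sorted(net.species_set)
        X = frozenset(data.draw(st.sets(st.sampled_from(species))))
        Y = X | frozenset(data.draw(st.sets(st.sampled_from(species))))
        rx = oc.largest_reactive_subset(net, X)
        assert oc.largest_reactive_subset(net, rx) == rx
        assert rx <= oc.largest_reactive_subset(net, Y)


class TestSBML:
    def _write_sbml(self, tmp_path, stoich_b=2.0):
        import libsbml

        doc = libsbml.SBMLDocument(3, 2)
        model = doc.createModel()
        comp = model.createCompartment()
        comp.setId("cell")
        comp.setConstant(True)
        for sid in ("A", "B", "E"):
            sp = model.createSpecies()
            sp.setId(sid)
            sp.setCompartment("cell")
            sp.setConstant(False)
            sp.setBoundaryCondition(False)
            sp.setHasOnlySubstanceUnits(False)
        rx = model.createReaction()
        rx.setId("v1")
        rx.setReversible(True)
        ref = rx.createReactant()
        ref.setSpecies("A")
        ref.setStoichiometry(1.0)
        ref.setConstant(True)
        ref = rx.createProduct()
        ref.setSpecies("B")
        ref.setStoichiometry(stoich_b)
        ref.setConstant(True)
        mod = rx.createModifier()
        mod.setSpecies("E")
        path = tmp_path / "net.xml"
        path.write_text(libsbml.writeSBMLToString(doc))
        return path

    def test_species_reactions_and_modifier_as_catalyst(self, tmp_path):
        net = oc.read_sbml(str(self._write_sbml(tmp_path)))
        assert net.species == ("A", "B", "E")
        (r,) = net.reactions
        assert r.lhs == {"A": 1, "E": 1}
        assert r.rhs == {"B": 2, "E": 1}
        assert r.reversible
        split = oc.split_reversible(net)
        assert len(split.reactions) == 2

    def test_non_integer_stoichiometry_scaled_with_warning(self, tmp_path):
        path = self._write_sbml(tmp_path, stoich_b=0.5)
        with pytest.warns(UserWarning, match="scaled by 2"):
            net = oc.read_sbml(str(path))
        (r,) = net.reactions
        assert r.lhs == {"A": 2, "E": 2}
        assert r.rhs == {"B": 1, "E": 2}

    def test_strict_rejects_non_integer(self, tmp_path):
        path = self._write_sbml(tmp_path, stoich_b=0.5)
        with pytest.raises(oc.NetworkError, match="non-integer"):
            oc.read_sbml(str(path), strict=True)
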