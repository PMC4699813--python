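"""Network reading, flattening, feedback removal, compression, AND expansion."""

import itertools
import math

import numpy as np
import pytest

from fuzzyhep.pkn import (
    BooleanGate,
    PKNError,
    PriorNetwork,
    Species,
    Transition,
    compress,
    expand_and_gates,
    flatten_boolean_gates,
    read_annotations,
    read_sif,
    remove_feedback,
    write_sif,
)

from helpers import all_clamp_patterns, boolean_network_eval, random_dag


class TestReadSif:
    def test_two_line_chain(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("IL6\t1\tJAK\nJAK\t1\tSTAT3\n")
        net = read_sif(p)
        assert set(net.species) == {"IL6", "JAK", "STAT3"}
        assert net.transitions == {
            Transition("IL6", "JAK", 1),
            Transition("JAK", "STAT3", 1),
        }

    def test_invalid_relation_token_names_line(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A foo B\n")
        with pytest.raises(PKNError, match="line 1"):
            read_sif(p)

    def test_duplicate_lines_collapse(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A 1 B\nA 1 B\n")
        assert len(read_sif(p).transitions) == 1

    def test_contradictory_duplicate_retained_with_warning(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A 1 B\nA -1 B\n")
        with pytest.warns(UserWarning, match="contradictory"):
            net = read_sif(p)
        assert len(net.transitions) == 2

    def test_word_relations_and_comments(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("# header\nA activates B\nB inhibits C  # trailing\n")
        net = read_sif(p)
        assert Transition("A", "B", 1) in net.transitions
        assert Transition("B", "C", -1) in net.transitions

    def test_write_read_roundtrip(self, tmp_path, rng):
        net = random_dag(rng)
        p = tmp_path / "net.sif"
        write_sif(net, p)
        assert read_sif(p).transitions == net.transitions


class TestFlatten:
    @pytest.mark.parametrize(
        "gate, expected",
        [
            (  # AND(A, NOT B) -> C
                BooleanGate((("A", False), ("B", True)), "C"),
                {Transition("A", "C", 1), Transition("B", "C", -1)},
            ),
            (  # OR(A, B) -> C
                BooleanGate((("A", False), ("B", False)), "C"),
                {Transition("A", "C", 1), Transition("B", "C", 1)},
            ),
            (  # NOT A -> B
                BooleanGate((("A", True),), "B"),
                {Transition("A", "B", -1)},
            ),
        ],
    )
    def test_gates_become_signed_transitions(self, gate, expected):
        assert flatten_boolean_gates([gate]).transitions == expected

    def test_zero_input_gate_rejected(self):
        with pytest.raises(PKNError, match="zero inputs"):
            flatten_boolean_gates([BooleanGate((), "C")])

    def test_idempotent_on_flat_networks(self, rng):
        net = random_dag(rng)
        gates = [BooleanGate(((t.source, t.sign < 0),), t.target) for t in net.transitions]
        assert flatten_boolean_gates(gates).transitions == net.transitions


class TestRemoveFeedback:
    def _two_cycle(self):
        net = PriorNetwork()
        for n in "AB":
            net.add_species(n)
        net.add_transition("A", "B", 1)
        net.add_transition("B", "A", 1)
        return net

    def test_explicit_removal_list(self):
        net = self._two_cycle()
        out, deleted = remove_feedback(net, [Transition("B", "A", 1)])
        assert out.transitions == {Transition("A", "B", 1)}
        assert deleted == [Transition("B", "A", 1)]

    def test_listed_transition_absent_raises(self):
        with pytest.raises(PKNError, match="absent"):
            remove_feedback(self._two_cycle(), [Transition("A", "C", 1)])

    def test_acyclic_input_identity_under_auto(self, rng):
        net = random_dag(rng)
        out, deleted = remove_feedback(net, "auto")
        assert deleted == []
        assert out.transitions == net.transitions

    def test_three_cycle_auto_single_deletion(self):
        net = PriorNetwork()
        for n in "ABC":
            net.add_species(n)
        edges = [("A", "B"), ("B", "C"), ("C", "A")]
        for s, t in edges:
            net.add_transition(s, t, 1)
        # oracle: every single-edge deletion of a 3-cycle yields a DAG
        for s, t in edges:
            trial = net.copy()
            trial.transitions.discard(Transition(s, t, 1))
            assert trial.is_acyclic()
        out, deleted = remove_feedback(net, "auto")
        assert len(deleted) == 1
        assert out.is_acyclic()
        # deterministic lexicographic tie-break among equally good edges
        assert deleted[0] == Transition("A", "B", 1)


def _annotated_chain(mid_measured: bool, sign2: int = 1):
    net = PriorNetwork()
    net.add_species(Species("A", role="signaling", perturbable=True))
    net.add_species(Species("B", role="signaling", measured=mid_measured))
    net.add_species(Species("C", role="gene", measured=True))
    net.add_transition("A", "B", 1)
    net.add_transition("B", "C", sign2)
    return net


class TestCompress:
    def test_passthrough_sign_product(self):
        net = _annotated_chain(mid_measured=False, sign2=-1)
        out, removed = compress(net)
        assert removed == ["B"]
        assert out.transitions == {Transition("A", "C", -1)}

    def test_measured_species_retained(self):
        net = _annotated_chain(mid_measured=True)
        out, removed = compress(net)
        assert removed == []
        assert out.transitions == net.transitions

    def test_requires_acyclic(self):
        net = PriorNetwork()
        for n in "AB":
            net.add_species(n)
        net.add_transition("A", "B", 1)
        net.add_transition("B", "A", 1)
        with pytest.raises(PKNError, match="acyclic"):
            compress(net)

    def test_steady_state_equivalence_on_random_dags(self):
        """Measured steady states are identical pre/post compression for
        every exhaustive clamp pattern (independent recursive oracle)."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            net = random_dag(rng, n_species=8)
            out, _ = compress(net)
            for clamps in all_clamp_patterns(net):
                before = boolean_network_eval(net, clamps)
                after = boolean_network_eval(out, clamps)
                for m in net.measured():
                    assert before[m] == after[m]


class TestExpandAndGates:
    def _fan_in(self, d: int) -> PriorNetwork:
        net = PriorNetwork()
        net.add_species("T")
        for i in range(d):
            net.add_species(f"S{i}")
            net.add_transition(f"S{i}", "T", 1 if i % 2 == 0 else -1)
        return net

    @pytest.mark.parametrize("d, max_and, expected", [(2, 2, 3), (3, 2, 6), (1, 2, 1)])
    def test_gate_counts(self, d, max_and, expected):
        assert len(expand_and_gates(self._fan_in(d), max_and)) == expected

    @pytest.mark.parametrize("d", range(1, 7))
    @pytest.mark.parametrize("max_and", [1, 2, 3])
    def test_counting_formula_matches_enumeration(self, d, max_and):
        space = expand_and_gates(self._fan_in(d), max_and)
        expected = d + sum(math.comb(d, j) for j in range(2, min(d, max_and) + 1))
        assert len(space) == expected
        # every single incoming transition appears as a one-input gate
        singles = {g.inputs[0] for g in space.gates if g.kind == "single"}
        assert len(singles) == d
        # AND inputs have distinct sources, sizes in 2..max_and
        for g in space.gates:
            if g.kind == "AND":
                sources = [s for s, _ in g.inputs]
                assert 2 <= len(sources) <= max_and
                assert len(set(sources)) == len(sources)

    def test_invalid_max_and_size(self):
        with pytest.raises(PKNError):
            expand_and_gates(self._fan_in(2), 0)

    def test_signs_preserved_in_and_gates(self):
        space = expand_and_gates(self._fan_in(2), 2)
        (and_gate,) = [g for g in space.gates if g.kind == "AND"]
        assert dict(and_gate.inputs) == {"S0": 1, "S1": -1}


class TestAnnotations:
    def test_read_annotations_applies_flags(self, tmp_path):
        net = PriorNetwork()
        for n in ("IL6", "G"):
            net.add_species(n)
        net.add_transition("IL6", "G", 1)
        p = tmp_path / "ann.csv"
        p.write_text(
            "name,role,measured,perturbable,constitutive\n"
            "IL6,stimulus,False,False,False\nG,gene,True,False,False\n"
        )
        out = read_annotations(net, p)
        assert out.species["IL6"].role == "stimulus"
        assert out.species["G"].measured

    def test_unknown_species_rejected(self, tmp_path):
        net = PriorNetwork()
        net.add_species("A")
        p = tmp_path / "ann.csv"
        p.write_text(
            "name,role,measured,perturbable,constitutive\nB,gene,True,False,False\n"
        )
        with pytest.raises(PKNError, match="unknown species"):
            read_annotations(net, p)


def test_topological_order_asserts_acyclicity(rng):
    net = random_dag(rng)
    order = net.topological_order()
    pos = {n: i for i, n in enumerate(order)}
    for t in net.transitions:
        assert pos[t.source] < pos[t.target]
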