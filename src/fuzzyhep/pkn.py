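"""Prior knowledge networks: reading, flattening, feedback removal, compression.

A prior knowledge network (PKN) is a signed directed graph over biological
species: cytokines/stimuli, signaling intermediates, transcription factors and
regulated genes.  Activating influences carry sign +1, inhibiting influences
sign -1.  The PKN is the hypothesis space for fuzzy-logic model training: after
feedback removal it must be acyclic, and after compression it contains only
species that are measured, perturbable, designated stimuli/constitutive
regulators, or required so that the compressed graph predicts the same measured
steady states as the original.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

__all__ = [
    "Species",
    "Transition",
    "PriorNetwork",
    "BooleanGate",
    "read_sif",
    "write_sif",
    "read_annotations",
    "flatten_boolean_gates",
    "remove_feedback",
    "compress",
    "expand_and_gates",
    "boolean_steady_state",
]

ROLES = {"stimulus", "signaling", "transcription_factor", "gene", "complex", "unknown"}

_ACTIVATING_TOKENS = {"1", "+1", "activates"}
_INHIBITING_TOKENS = {"-1", "inhibits"}


class PKNError(ValueError):
    """Structural or parse error in a prior knowledge network."""


@dataclass
class Species:
    """A network node with its experimental annotations.

    ``measured`` marks readouts (here: genes with expression data),
    ``perturbable`` marks nodes that an experimental clamp can fix (stimuli,
    inhibitor targets), ``constitutive`` marks regulators with basal activity 1
    in the absence of inputs (e.g. hepatocyte nuclear factors).
    """

    name: str
    role: str = "unknown"
    measured: bool = False
    perturbable: bool = False
    constitutive: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PKNError(f"unknown species role {self.role!r} for {self.name!r}")


@dataclass(frozen=True, order=True)
class Transition:
    """A signed directed influence ``source -> target``."""

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise PKNError(f"transition sign must be +1 or -1, got {self.sign!r}")


@dataclass
class PriorNetwork:
    """Species plus signed transitions; the raw hypothesis space."""

    species: dict[str, Species] = field(default_factory=dict)
    transitions: set[Transition] = field(default_factory=set)

    # -- construction -----------------------------------------------------
    def add_species(self, species: Species | str) -> Species:
        if isinstance(species, str):
            species = Species(species)
        existing = self.species.get(species.name)
        if existing is None:
            self.species[species.name] = species
            return species
        return existing

    def add_transition(self, source: str, target: str, sign: int) -> Transition:
        for name in (source, target):
            if name not in self.species:
                raise PKNError(f"transition endpoint {name!r} is not a declared species")
        t = Transition(source, target, sign)
        self.transitions.add(t)
        return t

    def copy(self) -> "PriorNetwork":
        return PriorNetwork(
            species={n: replace(s) for n, s in self.species.items()},
            transitions=set(self.transitions),
        )

    # -- views ------------------------------------------------------------
    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.species)
        for t in self.transitions:
            g.add_edge(t.source, t.target, sign=t.sign)
        return g

    def incoming(self, target: str) -> list[Transition]:
        return sorted(t for t in self.transitions if t.target == target)

    def outgoing(self, source: str) -> list[Transition]:
        return sorted(t for t in self.transitions if t.source == source)

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def topological_order(self) -> list[str]:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise PKNError("network contains feedback loops; run remove_feedback first")
        # lexicographic tie-break makes the order, and everything derived
        # from it, deterministic
        return list(nx.lexicographical_topological_sort(nx.DiGraph(g)))

    def stimuli(self) -> list[str]:
        return sorted(n for n, s in self.species.items() if s.role == "stimulus")

    def measured(self) -> list[str]:
        return sorted(n for n, s in self.species.items() if s.measured)

    def perturbable(self) -> list[str]:
        return sorted(n for n, s in self.species.items() if s.perturbable)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_sif(path) -> PriorNetwork:
    """Read a SIF file: one ``source relation target`` triple per line.

    Relations may be ``1``/``-1`` or ``activates``/``inhibits``; fields are
    separated by tabs or whitespace; ``#`` starts a comment.  Duplicate lines
    collapse (set semantics); a contradictory duplicate (same pair, both
    signs) is retained with a warning — both hypotheses stay in play and the
    training step decides.
    """
    net = PriorNetwork()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) != 3:
                raise PKNError(f"{path}: line {lineno}: expected 'source relation target', got {line!r}")
            source, rel, target = parts
            if rel in _ACTIVATING_TOKENS:
                sign = +1
            elif rel in _INHIBITING_TOKENS:
                sign = -1
            else:
                raise PKNError(f"{path}: line {lineno}: invalid relation token {rel!r}")
            net.add_species(source)
            net.add_species(target)
            opposite = Transition(source, target, -sign)
            if opposite in net.transitions:
                warnings.warn(
                    f"{path}: line {lineno}: contradictory duplicate transition "
                    f"{source}->{target}; both signs retained",
                    stacklevel=2,
                )
            net.add_transition(source, target, sign)
    return net


def write_sif(net: PriorNetwork, path) -> None:
    with open(path, "w") as fh:
        for t in sorted(net.transitions):
            fh.write(f"{t.source}\t{t.sign}\t{t.target}\n")


def read_annotations(net: PriorNetwork, path) -> PriorNetwork:
    """Apply a species annotation CSV (columns: name,role,measured,perturbable,constitutive)."""
    table = pd.read_csv(path)
    required = {"name", "role", "measured", "perturbable", "constitutive"}
    missing = required - set(table.columns)
    if missing:
        raise PKNError(f"annotation file {path} lacks columns {sorted(missing)}")
    net = net.copy()
    for row in table.itertuples(index=False):
        name = str(row.name)
        if name not in net.species:
            raise PKNError(f"annotation for unknown species {name!r}")
        net.species[name] = Species(
            name,
            role=str(row.role),
            measured=bool(row.measured),
            perturbable=bool(row.perturbable),
            constitutive=bool(row.constitutive),
        )
    return net


def write_annotations(net: PriorNetwork, path) -> None:
    rows = [
        {
            "name": s.name,
            "role": s.role,
            "measured": s.measured,
            "perturbable": s.perturbable,
            "constitutive": s.constitutive,
        }
        for s in (net.species[n] for n in sorted(net.species))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gate flattening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanGate:
    """A gated influence: inputs (with optional negation) -> output.

    Used only as input to :func:`flatten_boolean_gates`; the gate type (AND /
    OR / NOT) is irrelevant for flattening and is therefore not recorded.
    """

    inputs: tuple[tuple[str, bool], ...]  # (species, negated)
    output: str


def flatten_boolean_gates(boolean_spec: list[BooleanGate]) -> PriorNetwork:
    """Flatten a gated network into simple signed transitions.

    Each gate input becomes one transition to the gate's output: negated
    inputs become inhibiting (-1), plain inputs activating (+1).  The gate
    structure itself is discarded; AND hypotheses are re-introduced later by
    :func:`expand_and_gates`.
    """
    net = PriorNetwork()
    for gate in boolean_spec:
        if not gate.inputs:
            raise PKNError(f"gate feeding {gate.output!r} has zero inputs")
        net.add_species(gate.output)
        for name, negated in gate.inputs:
            net.add_species(name)
            net.add_transition(name, gate.output, -1 if negated else +1)
    return net


# ---------------------------------------------------------------------------
# Feedback removal
# ---------------------------------------------------------------------------

def remove_feedback(
    net: PriorNetwork,
    removal_list: list[Transition] | str = "auto",
) -> tuple[PriorNetwork, list[Transition]]:
    """Delete transitions until the network is acyclic.

    With an explicit ``removal_list`` exactly those transitions are deleted
    (each must exist).  With policy ``"auto"`` cycles are broken greedily: in
    each round the transition lying on the most simple cycles is deleted, ties
    resolved lexicographically by (source, target, sign).  Returns the acyclic
    network and the list of deleted transitions.
    """
    net = net.copy()
    deleted: list[Transition] = []
    if removal_list != "auto":
        for t in removal_list:
            if t not in net.transitions:
                raise PKNError(f"listed transition {t} absent from network")
            net.transitions.discard(t)
            deleted.append(t)
        if not net.is_acyclic():
            raise PKNError("network still cyclic after removing the listed transitions")
        return net, deleted

    while True:
        g = nx.DiGraph()
        g.add_nodes_from(net.species)
        for t in net.transitions:
            g.add_edge(t.source, t.target)
        cycles = list(nx.simple_cycles(g))
        if not cycles:
            break
        counts: dict[tuple[str, str], int] = {}
        for cyc in cycles:
            for u, v in zip(cyc, cyc[1:] + cyc[:1]):
                counts[(u, v)] = counts.get((u, v), 0) + 1
        best = max(sorted(counts), key=lambda e: counts[e])
        # ties resolved by the sorted() above: max() keeps the first maximum
        best = min((e for e in counts if counts[e] == counts[best]))
        for t in sorted(net.transitions):
            if (t.source, t.target) == best:
                net.transitions.discard(t)
                deleted.append(t)
        if not deleted:  # pragma: no cover - unreachable safety net
            raise PKNError("auto feedback removal failed to make progress")
    return net, deleted


# ---------------------------------------------------------------------------
# Boolean steady state (used by compression verification)
# ---------------------------------------------------------------------------

def boolean_steady_state(net: PriorNetwork, clamps: dict[str, int]) -> dict[str, int]:
    """Boolean-limit steady state of an acyclic PKN.

    Each incoming transition acts as one literal (negated for sign -1) and a
    species is the OR of its incoming literals; species without inputs are 1
    if constitutive, else 0.  Clamped species take their clamp value
    regardless of inputs.  This is the limit of the fuzzy semantics for steep
    transfer functions and binary clamps.
    """
    state: dict[str, int] = {}
    incoming: dict[str, list[Transition]] = {n: [] for n in net.species}
    for t in net.transitions:
        incoming[t.target].append(t)
    for name in net.topological_order():
        if name in clamps:
            state[name] = int(clamps[name])
            continue
        ins = incoming[name]
        if not ins:
            state[name] = 1 if net.species[name].constitutive else 0
            continue
        state[name] = int(
            any(state[t.source] if t.sign > 0 else 1 - state[t.source] for t in ins)
        )
    return state


def _clampable(net: PriorNetwork) -> list[str]:
    names = {n for n, s in net.species.items() if s.perturbable or s.role == "stimulus"}
    return sorted(names)


def _measured_states_equal(
    a: PriorNetwork, b: PriorNetwork, clampable: list[str], measured: list[str]
) -> bool:
    for bits in itertools.product((0, 1), repeat=len(clampable)):
        clamps = dict(zip(clampable, bits))
        sa = boolean_steady_state(a, clamps)
        sb = boolean_steady_state(b, clamps)
        if any(sa[m] != sb[m] for m in measured):
            return False
    return True


# ---------------------------------------------------------------------------
# Compression
# ---------------------------------------------------------------------------

def compress(
    net: PriorNetwork,
    verify: bool | str = "auto",
    max_verify_patterns: int = 256,
) -> tuple[PriorNetwork, list[str]]:
    """Remove species that are neither measured nor perturbed.

    Unobserved sinks are dropped outright.  Pass-through species are removed
    by rewiring every (U -> S, S -> V) pair to U -> V with the product sign.
    A species is retained ("necessary for logical consistency") when removal
    is not guaranteed to preserve measured steady states:

    * fan-in > 1 combined with fan-out > 1 (it feeds distinct gate contexts),
    * fan-in > 1 with an inhibiting outgoing transition (OR of inputs would
      have to distribute over a negation),
    * removal would create contradictory duplicate transitions between the
      same pair of species.

    With ``verify`` enabled (the default, whenever the number of exhaustive
    clamp patterns is at most ``max_verify_patterns``) every removal is
    additionally checked against Boolean-limit steady-state equivalence at the
    measured species and reverted if equivalence fails.

    Returns the compressed network and the names of removed species.
    """
    if not net.is_acyclic():
        raise PKNError("compress expects an acyclic network")
    current = net.copy()
    clampable = _clampable(net)
    measured = net.measured()
    do_verify = verify is True or (
        verify == "auto" and 2 ** len(clampable) <= max_verify_patterns
    )
    removed: list[str] = []
    changed = True
    while changed:
        changed = False
        for name in sorted(current.species):
            sp = current.species[name]
            if sp.measured or sp.perturbable or sp.constitutive or sp.role == "stimulus":
                continue
            ins = current.incoming(name)
            outs = current.outgoing(name)
            if outs and not _passthrough_safe(ins, outs):
                continue
            if not ins and outs:
                # an unobserved constant-off source: removal would silently
                # change its targets' gate spaces, so keep it
                continue
            candidate = current.copy()
            del candidate.species[name]
            candidate.transitions -= set(ins) | set(outs)
            conflict = False
            for ti in ins:
                for to in outs:
                    new = Transition(ti.source, to.target, ti.sign * to.sign)
                    if Transition(new.source, new.target, -new.sign) in candidate.transitions:
                        conflict = True
                    candidate.transitions.add(new)
            if conflict:
                continue
            if do_verify and not _measured_states_equal(current, candidate, clampable, measured):
                continue  # retained: equivalence oracle vetoed the rule
            current = candidate
            removed.append(name)
            changed = True
    return current, removed


def _passthrough_safe(ins: list[Transition], outs: list[Transition]) -> bool:
    if not ins or not outs:
        return True  # pure sink (or isolated); no rewiring happens
    if len(ins) > 1 and len(outs) > 1:
        return False
    if len(ins) > 1 and any(t.sign < 0 for t in outs):
        # OR(in literals) feeding a negated contribution is not expressible
        # as a rewiring under OR-of-single-gates semantics
        return False
    return True


# ---------------------------------------------------------------------------
# AND-gate expansion
# ---------------------------------------------------------------------------

def expand_and_gates(net: PriorNetwork, max_and_size: int = 2):
    """Expand an acyclic PKN into the candidate gate space.

    Every incoming transition of every target yields a one-input gate, and
    every combination of 2..max_and_size incoming transitions with distinct
    sources yields an AND-gate hypothesis.  Multiple gates on one target are
    combined by OR (max) during simulation.
    """
    from .fuzzy_engine import Gate, GateSpace  # deferred: avoids import cycle

    if max_and_size < 1:
        raise PKNError("max_and_size must be >= 1")
    if not net.is_acyclic():
        raise PKNError("expand_and_gates expects an acyclic network")
    gates: list[Gate] = []
    for target in net.topological_order():
        ins = net.incoming(target)
        for t in ins:
            gates.append(Gate(target=target, inputs=((t.source, t.sign),), kind="single"))
        for size in range(2, min(len(ins), max_and_size) + 1):
            for combo in itertools.combinations(ins, size):
                if len({t.source for t in combo}) < size:
                    continue
                gates.append(
                    Gate(
                        target=target,
                        inputs=tuple((t.source, t.sign) for t in combo),
                        kind="AND",
                    )
                )
    return GateSpace(gates=gates, max_and_size=max_and_size, network=net)
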