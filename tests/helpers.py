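"""Independent oracles and random-structure generators used across tests.

Everything here is deliberately written from first principles (recursion,
enumeration, direct formulas) and independent of the library code paths it is
used to check.
"""

from __future__ import annotations

import itertools

import numpy as np

from fuzzyhep.fuzzy_engine import Condition, FuzzyModel, Gate, TransferParams
from fuzzyhep.pkn import PriorNetwork, Species


# ---------------------------------------------------------------------------
# Boolean oracles
# ---------------------------------------------------------------------------

def boolean_model_eval(model: FuzzyModel, clamps: dict[str, int]) -> dict[str, int]:
    """Brute-force Boolean evaluation of a fuzzy model's gate structure.

    AND gates are conjunctions of signed literals, multiple gates disjoin;
    clamps override; gate-free species fall back to their constitutive level
    (thresholded at 0.5).  Evaluated by recursion with memoization.
    """
    gates_by_target: dict[str, list[Gate]] = {}
    for g in model.gates:
        gates_by_target.setdefault(g.target, []).append(g)
    memo: dict[str, int] = {}

    def value(name: str) -> int:
        if name in memo:
            return memo[name]
        if name in clamps:
            memo[name] = int(clamps[name])
            return memo[name]
        gates = gates_by_target.get(name, [])
        if not gates:
            memo[name] = int(model.constitutive.get(name, 0.0) >= 0.5)
            return memo[name]
        result = 0
        for g in gates:
            term = 1
            for source, sign in g.inputs:
                lit = value(source)
                if sign < 0:
                    lit = 1 - lit
                term = term and lit
            result = result or term
        memo[name] = int(result)
        return memo[name]

    return {name: value(name) for name in model.network.species}


def boolean_network_eval(net: PriorNetwork, clamps: dict[str, int]) -> dict[str, int]:
    """Boolean steady state of a raw PKN: OR over incoming signed literals."""
    incoming: dict[str, list] = {n: [] for n in net.species}
    for t in net.transitions:
        incoming[t.target].append(t)
    memo: dict[str, int] = {}

    def value(name: str) -> int:
        if name in memo:
            return memo[name]
        if name in clamps:
            memo[name] = int(clamps[name])
            return memo[name]
        ins = incoming[name]
        if not ins:
            memo[name] = 1 if net.species[name].constitutive else 0
            return memo[name]
        memo[name] = int(
            any(
                (value(t.source) if t.sign > 0 else 1 - value(t.source))
                for t in ins
            )
        )
        return memo[name]

    return {name: value(name) for name in net.species}


def all_clamp_patterns(net: PriorNetwork, limit: int = 6):
    """All binary clamp assignments over stimuli + perturbable species."""
    clampable = sorted(
        n for n, s in net.species.items() if s.perturbable or s.role == "stimulus"
    )
    assert len(clampable) <= limit, "too many clampable species for exhaustion"
    for bits in itertools.product((0, 1), repeat=len(clampable)):
        yield dict(zip(clampable, bits))


def clamps_to_condition(clamps: dict[str, int], name: str = "c") -> Condition:
    stimuli = {s: float(v) for s, v in clamps.items() if v == 1}
    inhibited = {s for s, v in clamps.items() if v == 0}
    return Condition.make(name, stimuli, inhibited)


# ---------------------------------------------------------------------------
# Random structures
# ---------------------------------------------------------------------------

def random_dag(rng: np.random.Generator, n_species: int = 8, edge_prob: float = 0.35,
               n_measured: int = 3, n_perturbable: int = 2) -> PriorNetwork:
    """A random annotated DAG: edges only from lower to higher index."""
    net = PriorNetwork()
    names = [f"S{i}" for i in range(n_species)]
    for name in names:
        net.add_species(Species(name, role="signaling"))
    for i in range(n_species):
        for j in range(i + 1, n_species):
            if rng.random() < edge_prob:
                net.add_transition(names[i], names[j], int(rng.choice([-1, 1])))
    # keep the graph rooted in a single stimulus so exhaustive clamp
    # enumeration stays small
    for j in range(1, n_species):
        if not net.incoming(names[j]):
            i = int(rng.integers(0, j))
            net.add_transition(names[i], names[j], int(rng.choice([-1, 1])))
    sources = [n for n in names if not net.incoming(n)]
    for s in sources:
        net.species[s].role = "stimulus"
    non_sources = [n for n in names if n not in sources]
    rng.shuffle(non_sources)
    for n in non_sources[:n_perturbable]:
        net.species[n].perturbable = True
    sinkish = sorted(non_sources[n_perturbable:], key=lambda n: -len(net.incoming(n)))
    for n in sinkish[:n_measured]:
        net.species[n].measured = True
    return net


def random_model(rng: np.random.Generator, net: PriorNetwork,
                 steep: bool = True) -> FuzzyModel:
    """Random active-gate selection over a DAG, with steep or random transfers."""
    from fuzzyhep.pkn import expand_and_gates

    space = expand_and_gates(net, max_and_size=2)
    gates = []
    for target, candidates in space.by_target().items():
        n_active = int(rng.integers(0, min(len(candidates), 2) + 1))
        idx = rng.choice(len(candidates), size=n_active, replace=False)
        for i in idx:
            p = (
                TransferParams(0.5, 10.0)
                if steep
                else TransferParams(float(rng.choice([0.3, 0.5, 0.8])), float(rng.choice([2, 4])))
            )
            gates.append(candidates[int(i)].with_params(p))
    return FuzzyModel(network=net, gates=gates)


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------

def brute_ranks(x: np.ndarray) -> np.ndarray:
    """Midranks computed by sorting, independent of scipy."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def brute_spearman(x, y) -> float:
    """Pearson correlation of midranks (the Spearman definition)."""
    rx, ry = brute_ranks(np.asarray(x, float)), brute_ranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def upgma_reference(points: np.ndarray):
    """Exhaustive UPGMA agglomeration: returns merge heights (sorted sizes).

    Clusters merge at the unweighted average pairwise distance between their
    members; at each step the globally closest pair merges.  Returns the
    sorted list of merge heights, which identifies the dendrogram up to
    leaf-order ambiguity.
    """
    clusters = [[i] for i in range(len(points))]

    def dist(a, b):
        return float(
            np.mean([np.linalg.norm(points[i] - points[j]) for i in a for j in b])
        )

    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted(heights)
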