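"""Constrained fuzzy-logic evaluation: transfer functions, gates, steady states.

Species states live in [0, 1].  An input species x feeds a gate through a
normalized Hill transfer function

    f(x) = x^n * (1 + k^n) / (x^n + k^n)

which satisfies f(0) = 0 and f(1) = 1 for every gain k in (0, 1] and exponent
n >= 1, so a fully active input always transmits full activity.  Inhibiting
inputs contribute 1 - f(x) (invert after transfer): a gene whose only input is
an inhibiting transition from a silent pathway therefore rests at 1, which is
the control-state behavior of downregulated detoxification genes.  AND gates
take the min of their input contributions, multiple gates on one target
combine by OR = max.  Stimuli and inhibitors are clamps: they fix a species'
state regardless of its gates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pkn import PriorNetwork

__all__ = [
    "TransferParams",
    "Gate",
    "GateSpace",
    "FuzzyModel",
    "Condition",
    "DEFAULT_K_GRID",
    "DEFAULT_N_GRID",
    "transfer",
    "simulate",
    "score_mse",
]

# Discrete training grids for the transfer-function parameters.  The genetic
# algorithm only ever assigns values from these sets.
DEFAULT_K_GRID: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
DEFAULT_N_GRID: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 6.0)


class EngineError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class TransferParams:
    """Normalized-Hill parameters: gain k in (0, 1], exponent n >= 1."""

    k: float
    n: float

    def __post_init__(self) -> None:
        if not (0.0 < self.k <= 1.0):
            raise EngineError(f"gain k must be in (0, 1], got {self.k}")
        if self.n < 1.0:
            raise EngineError(f"Hill exponent n must be >= 1, got {self.n}")


def transfer(x, p: TransferParams):
    """Normalized Hill transfer f(x) = x^n (1 + k^n) / (x^n + k^n).

    Strictly increasing on [0, 1] with f(0) = 0 and f(1) = 1.  Accepts scalars
    or numpy arrays.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise EngineError("transfer input state outside [0, 1]")
    kn = p.k**p.n
    xn = x**p.n
    out = xn * (1.0 + kn) / (xn + kn)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Gate:
    """A logical term feeding ``target``.

    ``inputs`` is a tuple of (source species, sign); ``params`` when set is a
    per-input tuple of :class:`TransferParams` (training assigns one (k, n)
    pair per gate, replicated over its inputs).  ``kind`` is ``"single"`` or
    ``"AND"``; AND gates have >= 2 inputs with distinct sources.
    """

    target: str
    inputs: tuple[tuple[str, int], ...]
    kind: str = "single"
    params: tuple[TransferParams, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("single", "AND"):
            raise EngineError(f"unknown gate kind {self.kind!r}")
        if self.kind == "AND":
            if len(self.inputs) < 2:
                raise EngineError("AND gate needs >= 2 inputs")
            if len({s for s, _ in self.inputs}) < len(self.inputs):
                raise EngineError("AND gate inputs must have distinct sources")
        if self.kind == "single" and len(self.inputs) != 1:
            raise EngineError("single gate has exactly one input")
        if self.params is not None and len(self.params) != len(self.inputs):
            raise EngineError("params must align with inputs")

    def key(self) -> tuple:
        """Structural identity, ignoring transfer parameters."""
        return (self.target, self.kind, tuple(sorted(self.inputs)))

    def with_params(self, p: TransferParams) -> "Gate":
        return Gate(self.target, self.inputs, self.kind, tuple(p for _ in self.inputs))


@dataclass
class GateSpace:
    """All candidate gates expanded from a PKN (see pkn.expand_and_gates)."""

    gates: list[Gate]
    max_and_size: int
    network: PriorNetwork

    def __len__(self) -> int:
        return len(self.gates)

    def by_target(self) -> dict[str, list[Gate]]:
        grouped: dict[str, list[Gate]] = {}
        for g in self.gates:
            grouped.setdefault(g.target, []).append(g)
        return grouped


@dataclass
class FuzzyModel:
    """A concrete model: active, parameterized gates over a PKN."""

    network: PriorNetwork
    gates: list[Gate]
    constitutive: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        transitions = {(t.source, t.target, t.sign) for t in self.network.transitions}
        for g in self.gates:
            for source, sign in g.inputs:
                if (source, g.target, sign) not in transitions:
                    raise EngineError(
                        f"gate input {source}->{g.target} (sign {sign:+d}) is not a network transition"
                    )
        if not self.constitutive:
            self.constitutive = {
                n: 1.0 for n, s in self.network.species.items() if s.constitutive
            }

    def gate_keys(self) -> set[tuple]:
        return {g.key() for g in self.gates}

    def active_transitions(self) -> set[tuple[str, str, int]]:
        return {(s, g.target, sign) for g in self.gates for s, sign in g.inputs}

    def n_parameters(self) -> int:
        """Scalar parameter count: one (k, n) pair per active gate input."""
        return 2 * sum(len(g.inputs) for g in self.gates)


@dataclass(frozen=True)
class Condition:
    """An experimental condition: stimulus levels plus inhibitor clamps (to 0)."""

    name: str
    stimuli: tuple[tuple[str, float], ...] = ()
    inhibited: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        stim = dict(self.stimuli)
        overlap = set(stim) & set(self.inhibited)
        if overlap:
            raise EngineError(f"species both stimulated and inhibited: {sorted(overlap)}")

    @classmethod
    def make(cls, name: str, stimuli: dict[str, float] | None = None,
             inhibited=()) -> "Condition":
        return cls(
            name=name,
            stimuli=tuple(sorted((stimuli or {}).items())),
            inhibited=frozenset(inhibited),
        )

    def clamps(self) -> dict[str, float]:
        clamps = {s: float(v) for s, v in self.stimuli}
        clamps.update({s: 0.0 for s in self.inhibited})
        return clamps


_DEFAULT_PARAMS = TransferParams(0.5, 3.0)


def simulate(model: FuzzyModel, cond: Condition) -> dict[str, float]:
    """Steady state of the model under a condition's clamps.

    Species are evaluated in topological order.  Clamped species take their
    clamp value; otherwise a species is the max (OR) over its active gates'
    outputs, each gate output being the min (AND) of its inputs'
    contributions; with no active gate the species falls back to its
    constitutive baseline (default 0).  Gates without assigned parameters use
    a default mid-grid transfer (k=0.5, n=3).
    """
    clamps = cond.clamps()
    gates_by_target: dict[str, list[Gate]] = {}
    for g in model.gates:
        gates_by_target.setdefault(g.target, []).append(g)
    state: dict[str, float] = {}
    for name in model.network.topological_order():
        if name in clamps:
            state[name] = clamps[name]
            continue
        outputs = []
        for g in gates_by_target.get(name, ()):
            params = g.params or tuple(_DEFAULT_PARAMS for _ in g.inputs)
            contribs = []
            for (source, sign), p in zip(g.inputs, params):
                fx = transfer(state[source], p)
                contribs.append(fx if sign > 0 else 1.0 - fx)
            outputs.append(min(contribs))
        state[name] = max(outputs) if outputs else model.constitutive.get(name, 0.0)
    return state


def score_mse(model: FuzzyModel, design, data) -> float:
    """Mean squared error of model predictions against normalized tables.

    ``design`` is a list of :class:`Condition`; ``data`` a list of
    per-donor :class:`fuzzyhep.normalize.NormalizedTable`.  The mean runs over
    every non-missing (gene, condition, donor) cell; missing cells contribute
    to neither numerator nor denominator.
    """
    predictions = {c.name: simulate(model, c) for c in design}
    sq_sum = 0.0
    n_cells = 0
    for table in data:
        values = table.values
        for gene in values.index:
            if gene not in model.network.species:
                raise EngineError(f"measured gene {gene!r} absent from model network")
            for cond in design:
                if cond.name not in values.columns:
                    continue
                y = values.at[gene, cond.name]
                if y != y:  # NaN = missing
                    continue
                sq_sum += (predictions[cond.name][gene] - float(y)) ** 2
                n_cells += 1
    if n_cells == 0:
        raise EngineError("no non-missing cells to score against")
    return sq_sum / n_cells
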