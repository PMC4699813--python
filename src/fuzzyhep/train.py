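"""Genetic-algorithm calibration, model reduction, families and consensus.

A candidate model is encoded as one integer locus per candidate gate: 0 means
the gate is off, any other value indexes a discrete (k, n) grid for the gate's
transfer function(s).  Fitness is the negative mean squared error between the
simulated steady states and the normalized data, pooled over all donors'
non-missing cells.  After optimization, gates whose removal costs little MSE
are pruned greedily up to a selection threshold; repeating
optimization + reduction with different seeds yields a model family whose
per-element frequencies form the consensus network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .fuzzy_engine import (
    DEFAULT_K_GRID,
    DEFAULT_N_GRID,
    Condition,
    FuzzyModel,
    Gate,
    GateSpace,
    TransferParams,
)

__all__ = [
    "GAHyperparams",
    "ModelFamily",
    "ReductionCurvePoint",
    "ConsensusNetwork",
    "ga_optimize",
    "reduce_model",
    "fit_family",
    "consensus_network",
    "reduction_curve",
    "gate_label",
]


class TrainError(ValueError):
    pass


class UnidentifiableError(TrainError):
    """No measured species lies downstream of any perturbed species."""


@dataclass(frozen=True)
class GAHyperparams:
    population_size: int = 50
    max_generations: int = 500
    stall_generations: int = 100
    mutation_rate: float = 0.05
    elitism: int = 1
    tournament_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise TrainError("population_size must be >= 2")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise TrainError("mutation_rate must be in [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise TrainError("elitism must be in [0, population_size)")


def gate_label(key: tuple) -> str:
    """Stable human-readable identity of a gate, e.g. ``GENE=AND[ERK:-1,NFKB:-1]``."""
    target, kind, inputs = key
    body = ",".join(f"{s}:{sign:+d}" for s, sign in inputs)
    return f"{target}={kind}[{body}]"


# ---------------------------------------------------------------------------
# Compiled evaluation problem
# ---------------------------------------------------------------------------

class CompiledProblem:
    """Vectorized steady-state + MSE evaluation for genome arrays.

    Conditions are evaluated as one numpy vector per species, and donor data
    are pre-aggregated to per-(gene, condition) sufficient statistics, so a
    fitness call costs one pass over the species in topological order.
    Numerically identical to fuzzy_engine.simulate / score_mse.
    """

    def __init__(self, space: GateSpace, design: list[Condition], data,
                 k_grid=DEFAULT_K_GRID, n_grid=DEFAULT_N_GRID,
                 param_options=None):
        if not space.gates:
            raise TrainError("empty gate space")
        net = space.network
        self.space = space
        self.design = list(design)
        self.order = net.topological_order()
        self.index = {name: i for i, name in enumerate(self.order)}
        n_species, n_cond = len(self.order), len(self.design)

        self.const = np.zeros((n_species, n_cond))
        for name, sp in net.species.items():
            if sp.constitutive:
                self.const[self.index[name], :] = 1.0
        self.clamp_mask = np.zeros((n_species, n_cond), dtype=bool)
        self.clamp_val = np.zeros((n_species, n_cond))
        for c_idx, cond in enumerate(self.design):
            for name, level in cond.clamps().items():
                if name in self.index:
                    i = self.index[name]
                    self.clamp_mask[i, c_idx] = True
                    self.clamp_val[i, c_idx] = level

        if param_options is None:
            self.grid = [
                TransferParams(k, n) for k, n in itertools.product(k_grid, n_grid)
            ]
            param_options = [
                [tuple(p for _ in g.inputs) for p in self.grid] for g in space.gates
            ]
        else:
            self.grid = None
        # per gate, per option: list of (src_index, sign, k^n, n)
        self.gate_opts: list[list[list[tuple[int, int, float, float]]]] = []
        self.gates_of: dict[int, list[int]] = {}
        for j, g in enumerate(space.gates):
            opts = []
            for params in param_options[j]:
                opts.append(
                    [
                        (self.index[src], sign, p.k**p.n, p.n)
                        for (src, sign), p in zip(g.inputs, params)
                    ]
                )
            self.gate_opts.append(opts)
            self.gates_of.setdefault(self.index[g.target], []).append(j)
        self.n_options = [len(o) for o in self.gate_opts]
        self.n_loci = len(space.gates)

        # sufficient statistics of the data per (gene, condition)
        genes: list[str] = []
        for t in data:
            for gene in t.values.index:
                if gene not in genes:
                    genes.append(gene)
        unknown = [g for g in genes if g not in self.index]
        if unknown:
            raise TrainError(f"measured genes absent from network: {unknown}")
        self.genes = genes
        cond_pos = {c.name: i for i, c in enumerate(self.design)}
        n_genes = len(genes)
        self.n_gc = np.zeros((n_genes, n_cond))
        self.s_gc = np.zeros((n_genes, n_cond))
        self.ss_gc = np.zeros((n_genes, n_cond))
        for t in data:
            for col in t.values.columns:
                if col not in cond_pos:
                    continue
                c = cond_pos[col]
                for gi, gene in enumerate(genes):
                    if gene not in t.values.index:
                        continue
                    y = t.values.at[gene, col]
                    if y != y:
                        continue
                    y = float(y)
                    self.n_gc[gi, c] += 1.0
                    self.s_gc[gi, c] += y
                    self.ss_gc[gi, c] += y * y
        self.n_cells = float(self.n_gc.sum())
        if self.n_cells == 0:
            raise TrainError("no non-missing cells to score against")
        self.gene_rows = np.array([self.index[g] for g in genes])
        self._cache: dict[bytes, float] = {}

    # -- evaluation -------------------------------------------------------
    def predict(self, genome: np.ndarray) -> np.ndarray:
        """Steady states of the measured genes (genes x conditions)."""
        states = np.empty_like(self.const)
        for i in range(len(self.order)):
            acc = None
            for j in self.gates_of.get(i, ()):
                v = int(genome[j])
                if v == 0:
                    continue
                out = None
                for src, sign, kn, n in self.gate_opts[j][v - 1]:
                    x = states[src]
                    xn = x**n
                    fx = xn * (1.0 + kn) / (xn + kn)
                    c = fx if sign > 0 else 1.0 - fx
                    out = c if out is None else np.minimum(out, c)
                acc = out if acc is None else np.maximum(acc, out)
            row = self.const[i] if acc is None else acc
            mask = self.clamp_mask[i]
            states[i] = np.where(mask, self.clamp_val[i], row)
        return states[self.gene_rows]

    def mse(self, genome: np.ndarray) -> float:
        key = genome.astype(np.int32).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        p = self.predict(genome)
        total = float((self.n_gc * p * p - 2.0 * p * self.s_gc + self.ss_gc).sum())
        val = max(total, 0.0) / self.n_cells
        self._cache[key] = val
        return val

    def n_parameters(self, genome: np.ndarray) -> int:
        return 2 * sum(
            len(self.space.gates[j].inputs) for j in range(self.n_loci) if genome[j] > 0
        )

    def to_model(self, genome: np.ndarray) -> FuzzyModel:
        gates = []
        for j, g in enumerate(self.space.gates):
            v = int(genome[j])
            if v == 0:
                continue
            if self.grid is not None:
                gates.append(g.with_params(self.grid[v - 1]))
            else:
                gates.append(g)
        return FuzzyModel(network=self.space.network, gates=gates)

    def genome_of(self, model: FuzzyModel) -> np.ndarray:
        """Inverse of to_model for grid-parameterized models."""
        genome = np.zeros(self.n_loci, dtype=np.int32)
        keys = {g.key(): j for j, g in enumerate(self.space.gates)}
        grid_pos = {p: v + 1 for v, p in enumerate(self.grid or ())}
        for g in model.gates:
            j = keys.get(g.key())
            if j is None:
                raise TrainError(f"model gate {gate_label(g.key())} not in space")
            if self.grid is None or g.params is None:
                genome[j] = 1
            else:
                genome[j] = grid_pos.get(g.params[0], 1)
        return genome


def _check_identifiable(space: GateSpace, design: list[Condition]) -> None:
    net = space.network
    clamped = set()
    for cond in design:
        clamped |= {s for s, _ in cond.stimuli} | set(cond.inhibited)
    g = nx.DiGraph()
    g.add_nodes_from(net.species)
    g.add_edges_from((t.source, t.target) for t in net.transitions)
    measured = set(net.measured())
    for s in clamped & set(net.species):
        if measured & nx.descendants(g, s):
            return
    raise UnidentifiableError(
        "unidentifiable: no measured species lies downstream of any perturbed species"
    )


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

def _ga_genome(problem: CompiledProblem, hp: GAHyperparams) -> tuple[np.ndarray, float]:
    rng = np.random.default_rng(hp.seed)
    n_opts = np.asarray(problem.n_options)
    pop = rng.integers(0, n_opts + 1, size=(hp.population_size, problem.n_loci))
    # seed one fully-active individual: plateaus where a gate and all of its
    # downstream consumers are jointly off are then escapable by pruning
    pop[0] = (n_opts + 1) // 2
    fitness = np.array([problem.mse(ind) for ind in pop])
    best_idx = int(np.argmin(fitness))
    best, best_mse = pop[best_idx].copy(), float(fitness[best_idx])
    stall = 0
    for _ in range(hp.max_generations):
        order = np.argsort(fitness, kind="stable")
        new_pop = [pop[i].copy() for i in order[: hp.elitism]]
        while len(new_pop) < hp.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, hp.population_size, size=hp.tournament_size)
                parents.append(pop[contenders[np.argmin(fitness[contenders])]])
            mask = rng.random(problem.n_loci) < 0.5
            child = np.where(mask, parents[0], parents[1])
            mut = rng.random(problem.n_loci) < hp.mutation_rate
            if mut.any():
                child = child.copy()
                child[mut] = rng.integers(0, n_opts[mut] + 1)
            new_pop.append(child)
        pop = np.array(new_pop)
        fitness = np.array([problem.mse(ind) for ind in pop])
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_mse - 1e-12:
            best, best_mse = pop[gen_best].copy(), float(fitness[gen_best])
            stall = 0
        else:
            stall += 1
            if stall >= hp.stall_generations:
                break
    return _local_descent(problem, best, best_mse)


def _local_descent(problem: CompiledProblem, genome: np.ndarray, mse: float):
    """Deterministic single-locus polish: move each locus to its best value
    while that strictly improves the fit.  Guarantees the returned genome is
    one-locus locally optimal, which the GA's uniform mutation alone does not
    (switching one gate off is a 1-in-|grid| proposal)."""
    genome = genome.copy()
    improved = True
    while improved:
        improved = False
        for j in range(problem.n_loci):
            best_v, best_m = int(genome[j]), mse
            trial = genome.copy()
            for v in range(problem.n_options[j] + 1):
                if v == int(genome[j]):
                    continue
                trial[j] = v
                m = problem.mse(trial)
                if m < best_m - 1e-15:
                    best_v, best_m = v, m
            if best_v != int(genome[j]):
                genome[j] = best_v
                mse = best_m
                improved = True
    return genome, mse


def ga_optimize(
    space: GateSpace,
    design: list[Condition],
    data,
    hp: GAHyperparams,
    k_grid=DEFAULT_K_GRID,
    n_grid=DEFAULT_N_GRID,
    problem: CompiledProblem | None = None,
) -> tuple[FuzzyModel, float]:
    """Fit gate selection and transfer parameters by a genetic algorithm.

    The fitness is the negative pooled MSE; the run stops after
    ``stall_generations`` without improvement or at ``max_generations``.
    Identical seeds give identical results.
    """
    _check_identifiable(space, design)
    if problem is None:
        problem = CompiledProblem(space, design, data, k_grid, n_grid)
    genome, mse = _ga_genome(problem, hp)
    return problem.to_model(genome), mse


# ---------------------------------------------------------------------------
# Reduction
# ---------------------------------------------------------------------------

def _reduce_genome(
    problem: CompiledProblem, genome: np.ndarray, threshold: float
) -> tuple[np.ndarray, float]:
    genome = genome.copy()
    original = problem.mse(genome)
    current = original
    while True:
        best_j, best_mse = None, None
        for j in range(problem.n_loci):
            if genome[j] == 0:
                continue
            trial = genome.copy()
            trial[j] = 0
            m = problem.mse(trial)
            if best_mse is None or m < best_mse - 1e-15:
                best_j, best_mse = j, m
        if best_j is None or best_mse - original > threshold:
            return genome, current
        genome[best_j] = 0
        current = best_mse


def reduce_model(
    model: FuzzyModel,
    design: list[Condition],
    data,
    threshold: float = 0.01,
) -> FuzzyModel:
    """Greedily remove gates while the cumulative MSE increase stays within threshold.

    At each step the gate whose removal yields the smallest MSE is removed
    (ties by gate order), as long as MSE(reduced) - MSE(original) <= threshold.
    The bound final_mse <= original_mse + threshold holds by construction.
    """
    if threshold < 0:
        raise TrainError("threshold must be >= 0")
    if not model.gates:
        return model
    space = GateSpace(gates=list(model.gates), max_and_size=0, network=model.network)
    problem = CompiledProblem(
        space, design, data, param_options=[[g.params or _default_params(g)] for g in model.gates]
    )
    genome = np.ones(problem.n_loci, dtype=np.int32)
    reduced, _ = _reduce_genome(problem, genome, threshold)
    return FuzzyModel(
        network=model.network,
        gates=[g for j, g in enumerate(model.gates) if reduced[j] > 0],
        constitutive=dict(model.constitutive),
    )


def _default_params(g: Gate):
    p = TransferParams(0.5, 3.0)
    return tuple(p for _ in g.inputs)


# ---------------------------------------------------------------------------
# Model families
# ---------------------------------------------------------------------------

@dataclass
class ModelFamily:
    """Independently optimized + reduced models with consensus frequencies."""

    models: list[tuple[FuzzyModel, float]]
    n_runs: int
    threshold: float
    seed: int
    consensus_gates: dict[tuple, float] = field(default_factory=dict)
    consensus_transitions: dict[tuple[str, str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.models) != self.n_runs:
            raise TrainError("family must hold exactly n_runs models")
        if not self.consensus_gates:
            self._compute_consensus()

    def _compute_consensus(self) -> None:
        gate_counts: dict[tuple, int] = {}
        trans_counts: dict[tuple[str, str, int], int] = {}
        for model, _ in self.models:
            for key in model.gate_keys():
                gate_counts[key] = gate_counts.get(key, 0) + 1
            for t in model.active_transitions():
                trans_counts[t] = trans_counts.get(t, 0) + 1
        self.consensus_gates = {k: c / self.n_runs for k, c in gate_counts.items()}
        self.consensus_transitions = {k: c / self.n_runs for k, c in trans_counts.items()}

    def mean_mse(self) -> float:
        return float(np.mean([m for _, m in self.models]))

    def mean_parameters(self) -> float:
        return float(np.mean([model.n_parameters() for model, _ in self.models]))


def fit_family(
    space: GateSpace,
    design: list[Condition],
    data,
    hp: GAHyperparams,
    n_runs: int = 100,
    threshold: float = 0.01,
    k_grid=DEFAULT_K_GRID,
    n_grid=DEFAULT_N_GRID,
) -> ModelFamily:
    """Optimize + reduce ``n_runs`` times; run r uses seed ``hp.seed + r``."""
    if n_runs < 1:
        raise TrainError("n_runs must be >= 1")
    _check_identifiable(space, design)
    problem = CompiledProblem(space, design, data, k_grid, n_grid)
    models = []
    for r in range(n_runs):
        genome, _ = _ga_genome(problem, replace(hp, seed=hp.seed + r))
        reduced, mse = _reduce_genome(problem, genome, threshold)
        models.append((problem.to_model(reduced), mse))
    return ModelFamily(models=models, n_runs=n_runs, threshold=threshold, seed=hp.seed)


@dataclass
class ConsensusNetwork:
    """Transitions retained in at least ``min_frequency`` of the family's models."""

    network: "object"  # PriorNetwork
    weights: dict[tuple[str, str, int], float]
    min_frequency: float


def consensus_network(family: ModelFamily, min_frequency: float = 0.30) -> ConsensusNetwork:
    """Frequency-filtered consensus: keep transitions with frequency >= cutoff."""
    from .pkn import PriorNetwork, Species, Transition

    if not family.models:
        raise TrainError("empty model family")
    base = family.models[0][0].network
    net = PriorNetwork()
    weights = {}
    for (source, target, sign), freq in sorted(family.consensus_transitions.items()):
        if freq < min_frequency:
            continue
        for name in (source, target):
            if name not in net.species:
                sp = base.species.get(name)
                net.add_species(
                    Species(name, sp.role, sp.measured, sp.perturbable, sp.constitutive)
                    if sp
                    else name
                )
        net.add_transition(source, target, sign)
        weights[(source, target, sign)] = freq
    return ConsensusNetwork(network=net, weights=weights, min_frequency=min_frequency)


# ---------------------------------------------------------------------------
# Reduction curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReductionCurvePoint:
    threshold: float
    mean_mse: float
    mean_parameters: float


def reduction_curve(
    space: GateSpace,
    design: list[Condition],
    data,
    hp: GAHyperparams,
    thresholds: list[float],
    n_runs: int = 10,
    k_grid=DEFAULT_K_GRID,
    n_grid=DEFAULT_N_GRID,
) -> list[ReductionCurvePoint]:
    """Mean MSE and parameter count of the family as the threshold varies.

    The GA runs are shared across thresholds: each optimized genome is
    re-reduced per threshold, which is how the trade-off curve is meant to be
    read (the optimization itself is threshold-independent).
    """
    if list(thresholds) != sorted(thresholds):
        raise TrainError("thresholds must be sorted ascending")
    _check_identifiable(space, design)
    problem = CompiledProblem(space, design, data, k_grid, n_grid)
    genomes = [_ga_genome(problem, replace(hp, seed=hp.seed + r))[0] for r in range(n_runs)]
    points = []
    for t in thresholds:
        mses, params = [], []
        for genome in genomes:
            reduced, mse = _reduce_genome(problem, genome, t)
            mses.append(mse)
            params.append(problem.n_parameters(reduced))
        points.append(
            ReductionCurvePoint(
                threshold=float(t),
                mean_mse=float(np.mean(mses)),
                mean_parameters=float(np.mean(params)),
            )
        )
    return points
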