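"""GA calibration, reduction, model families, consensus, reduction curve."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fuzzyhep import serialize
from fuzzyhep.fuzzy_engine import (
    Condition,
    FuzzyModel,
    Gate,
    TransferParams,
    score_mse,
    simulate,
)
from fuzzyhep.normalize import NormalizationScheme, NormalizedTable
from fuzzyhep.pkn import PriorNetwork, Species, expand_and_gates
from fuzzyhep.train import (
    CompiledProblem,
    GAHyperparams,
    ModelFamily,
    TrainError,
    UnidentifiableError,
    consensus_network,
    fit_family,
    ga_optimize,
    reduce_model,
    reduction_curve,
)


def _norm(values: pd.DataFrame, donor="D1") -> NormalizedTable:
    return NormalizedTable(
        values=values,
        donor_id=donor,
        scheme=NormalizationScheme(4.0, {g: 0.5 for g in values.index}),
    )


def _two_gene_problem():
    """Two genes driven by one stimulus at graded levels: parameters matter."""
    net = PriorNetwork()
    net.add_species(Species("IL6", role="stimulus"))
    for g in ("G1", "G2"):
        net.add_species(Species(g, role="gene", measured=True))
        net.add_transition("IL6", g, 1)
    space = expand_and_gates(net, 2)
    design = [
        Condition.make(f"lvl{i}", {"IL6": x}) for i, x in enumerate([0.25, 0.5, 0.75, 1.0])
    ]
    truth = FuzzyModel(
        net,
        [
            Gate("G1", (("IL6", 1),), params=(TransferParams(0.4, 2.0),)),
            Gate("G2", (("IL6", 1),), params=(TransferParams(0.8, 6.0),)),
        ],
    )
    frame = pd.DataFrame(
        {c.name: {g: simulate(truth, c)[g] for g in ("G1", "G2")} for c in design}
    )
    return space, design, [_norm(frame)]


class TestCompiledProblem:
    def test_matches_reference_scorer_on_benchmark(self, toy_benchmark, rng):
        truth, _, norm, space = toy_benchmark
        problem = CompiledProblem(space, truth.design, norm)
        for _ in range(10):
            genome = rng.integers(0, np.asarray(problem.n_options) + 1)
            model = problem.to_model(genome)
            assert problem.mse(genome) == pytest.approx(
                score_mse(model, truth.design, norm), abs=1e-12
            )

    def test_genome_roundtrip(self, toy_benchmark, rng):
        truth, _, norm, space = toy_benchmark
        problem = CompiledProblem(space, truth.design, norm)
        genome = rng.integers(0, np.asarray(problem.n_options) + 1)
        back = problem.genome_of(problem.to_model(genome))
        assert (back == genome).all()


class TestGAOptimize:
    def test_same_seed_same_result(self, toy_benchmark, quick_hp):
        truth, _, norm, space = toy_benchmark
        a = ga_optimize(space, truth.design, norm, quick_hp)
        b = ga_optimize(space, truth.design, norm, quick_hp)
        assert a[1] == b[1]
        assert serialize.model_to_dict(a[0]) == serialize.model_to_dict(b[0])

    def test_matches_exhaustive_search_single_gate(self, quick_hp):
        """With one candidate gate the GA must equal brute force over all genomes."""
        space, design, data = _two_gene_problem()
        space.gates = [g for g in space.gates if g.target == "G1"]
        problem = CompiledProblem(space, design, data)
        brute = min(
            problem.mse(np.array([v])) for v in range(problem.n_options[0] + 1)
        )
        _, mse = ga_optimize(space, design, data, quick_hp, problem=problem)
        assert mse == pytest.approx(brute, abs=1e-12)

    def test_matches_exhaustive_search_two_gates(self, quick_hp):
        """Full enumeration of the 46^2 genome space as the oracle."""
        space, design, data = _two_gene_problem()
        problem = CompiledProblem(space, design, data)
        brute = min(
            problem.mse(np.array(genome))
            for genome in itertools.product(
                range(problem.n_options[0] + 1), range(problem.n_options[1] + 1)
            )
        )
        _, mse = ga_optimize(space, design, data, quick_hp, problem=problem)
        assert mse == pytest.approx(brute, abs=1e-12)
        assert mse == pytest.approx(0.0, abs=1e-12)  # truth is inside the grid

    def test_noise_free_roundtrip_reaches_truth(self, quick_hp):
        space, design, data = _two_gene_problem()
        model, mse = ga_optimize(space, design, data, quick_hp)
        assert mse <= 1e-4

    def test_unidentifiable_design_rejected(self):
        space, _, data = _two_gene_problem()
        design = [Condition.make("nothing")]
        with pytest.raises(UnidentifiableError):
            ga_optimize(space, design, data, GAHyperparams(seed=0))


class TestReduceModel:
    def _model_and_data(self):
        net = PriorNetwork()
        net.add_species(Species("IL6", role="stimulus"))
        net.add_species(Species("G", role="gene", measured=True))
        net.add_transition("IL6", "G", 1)
        p = (TransferParams(0.5, 4.0),)
        model = FuzzyModel(
            net,
            [Gate("G", (("IL6", 1),), params=p), Gate("G", (("IL6", 1),), params=p)],
        )
        design = [Condition.make("off", {"IL6": 0.0}), Condition.make("on", {"IL6": 1.0})]
        data = [_norm(pd.DataFrame({"off": {"G": 0.0}, "on": {"G": 1.0}}))]
        return model, design, data

    def test_duplicate_gate_removed_at_zero_threshold(self):
        model, design, data = self._model_and_data()
        reduced = reduce_model(model, design, data, threshold=0.0)
        assert len(reduced.gates) == 1
        assert score_mse(reduced, design, data) == pytest.approx(
            score_mse(model, design, data), abs=1e-15
        )

    def test_zero_threshold_keeps_needed_gates(self):
        model, design, data = self._model_and_data()
        reduced = reduce_model(model, design, data, threshold=0.0)
        # a second pass has nothing left to remove
        again = reduce_model(reduced, design, data, threshold=0.0)
        assert len(again.gates) == 1

    def test_infinite_threshold_empties_the_model(self):
        model, design, data = self._model_and_data()
        reduced = reduce_model(model, design, data, threshold=np.inf)
        assert reduced.gates == []
        assert np.isfinite(score_mse(reduced, design, data))

    def test_reduction_bound_holds_on_benchmark_runs(self, toy_benchmark, quick_hp):
        """MSE(reduced) - MSE(optimized) <= threshold, for every run."""
        truth, _, norm, space = toy_benchmark
        threshold = 0.01
        for seed in range(5):
            hp = GAHyperparams(seed=seed, population_size=40, stall_generations=40)
            model, mse_opt = ga_optimize(space, truth.design, norm, hp)
            reduced = reduce_model(model, truth.design, norm, threshold=threshold)
            mse_red = score_mse(reduced, truth.design, norm)
            assert mse_red <= mse_opt + threshold + 1e-12
            assert len(reduced.gates) <= len(model.gates)

    def test_negative_threshold_rejected(self):
        model, design, data = self._model_and_data()
        with pytest.raises(TrainError):
            reduce_model(model, design, data, threshold=-0.1)


def _family_of(models_gates, net) -> ModelFamily:
    models = [
        (FuzzyModel(network=net, gates=gates), 0.0) for gates in models_gates
    ]
    return ModelFamily(models=models, n_runs=len(models), threshold=0.01, seed=0)


class TestModelFamily:
    @pytest.fixture()
    def small_net(self):
        net = PriorNetwork()
        for name, role in [("A", "stimulus"), ("B", "signaling"), ("G", "gene")]:
            net.add_species(Species(name, role=role, measured=(name == "G")))
        net.add_transition("A", "G", 1)
        net.add_transition("B", "G", -1)
        return net

    def test_consensus_frequencies_are_counts_over_runs(self, small_net):
        ga = Gate("G", (("A", 1),))
        gb = Gate("G", (("B", -1),))
        family = _family_of([[ga], [ga, gb], [ga], [gb]], small_net)
        assert family.consensus_gates[ga.key()] == 0.75
        assert family.consensus_gates[gb.key()] == 0.5
        assert family.consensus_transitions[("A", "G", 1)] == 0.75

    def test_mean_parameters_counts_scalars_per_input(self, small_net):
        ga = Gate("G", (("A", 1),))
        gb = Gate("G", (("B", -1),))
        family = _family_of([[ga], [ga, gb]], small_net)
        # (2 + 4) / 2 scalars: one (k, n) pair per active gate input
        assert family.mean_parameters() == 3.0

    def test_consensus_network_threshold_is_inclusive(self, small_net):
        ga = Gate("G", (("A", 1),))
        gb = Gate("G", (("B", -1),))
        # A->G in 3/10 runs (exactly at cutoff), B->G in 2/10 (below)
        family = _family_of([[ga]] * 3 + [[gb]] * 2 + [[]] * 5, small_net)
        cons = consensus_network(family, min_frequency=0.30)
        assert ("A", "G", 1) in cons.weights
        assert cons.weights[("A", "G", 1)] == pytest.approx(0.3)
        assert ("B", "G", -1) not in cons.weights

    def test_consensus_of_empty_family_raises(self, small_net):
        family = ModelFamily(models=[], n_runs=0, threshold=0.01, seed=0)
        with pytest.raises(TrainError):
            consensus_network(family)

    def test_family_fit_is_seed_reproducible_byte_for_byte(self, toy_benchmark):
        truth, _, norm, space = toy_benchmark
        hp = GAHyperparams(seed=5, population_size=30, stall_generations=20)
        fam1 = fit_family(space, truth.design, norm, hp, n_runs=2)
        fam2 = fit_family(space, truth.design, norm, hp, n_runs=2)
        a = serialize.dumps(serialize.family_to_dict(fam1))
        b = serialize.dumps(serialize.family_to_dict(fam2))
        assert a == b

    def test_family_serialization_roundtrip(self, toy_benchmark):
        truth, _, norm, space = toy_benchmark
        hp = GAHyperparams(seed=5, population_size=30, stall_generations=20)
        fam = fit_family(space, truth.design, norm, hp, n_runs=2)
        back = serialize.family_from_dict(serialize.family_to_dict(fam))
        assert serialize.dumps(serialize.family_to_dict(back)) == serialize.dumps(
            serialize.family_to_dict(fam)
        )


def test_reduction_curve_zero_threshold_matches_unreduced_family(toy_benchmark):
    truth, _, norm, space = toy_benchmark
    hp = GAHyperparams(seed=2, population_size=30, stall_generations=20)
    points = reduction_curve(space, truth.design, norm, hp, [0.0, 0.05], n_runs=2)
    # at threshold 0 only non-increasing removals are allowed, so the curve's
    # first point can never exceed the unreduced family mean MSE
    mses = []
    for r in range(2):
        _, mse = ga_optimize(
            space, truth.design, norm,
            GAHyperparams(seed=2 + r, population_size=30, stall_generations=20),
        )
        mses.append(mse)
    assert points[0].mean_mse <= float(np.mean(mses)) + 1e-12
    assert points[1].mean_parameters <= points[0].mean_parameters
    assert points[1].mean_mse >= points[0].mean_mse - 1e-12


def test_reduction_curve_requires_sorted_thresholds(toy_benchmark):
    truth, _, norm, space = toy_benchmark
    with pytest.raises(TrainError):
        reduction_curve(space, truth.design, norm, GAHyperparams(seed=0), [0.1, 0.0])
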