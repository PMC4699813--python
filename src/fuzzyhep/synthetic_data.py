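"""Ground-truth models and noisy multi-donor perturbation datasets.

The generator emulates the statistical structure of cytokine-perturbation
qPCR experiments in primary hepatocytes: a stimulus feeding three druggable
signaling branches (JAK/STAT-like, MAPK-like, PI3K/NF-kB-like) that converge
on a nuclear-receptor hub controlling a panel of mostly downregulated
detoxification genes, plus a few strongly induced acute-phase genes.  From a
sampled ground-truth fuzzy model it manufactures linear fold changes by
inverting the Hill normalization, then applies per-donor log2 random effects,
multiplicative lognormal noise, and random missing cells.

The default generator settings are the study conditions every downstream
benchmark uses: 5 donors, the 9-condition inhibitor design, multiplicative
noise CV 0.2, donor effect SD 0.25 (log2), missing rate 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fuzzy_engine import (
    DEFAULT_K_GRID,
    DEFAULT_N_GRID,
    Condition,
    FuzzyModel,
    TransferParams,
    simulate,
)
from .normalize import MeasurementTable, CtTable, inverse_hill
from .pkn import PriorNetwork, Species, expand_and_gates

__all__ = [
    "SyntheticTruth",
    "paper_design",
    "make_benchmark_pkn",
    "sample_truth",
    "emit_dataset",
    "emit_ct",
    "recovery_summary",
    "RecoverySummary",
]

CLIP_EPS = 1e-3  # clip Boolean-ish states away from {0,1} before inverting the Hill


def paper_design() -> list[Condition]:
    """The 9-condition perturbation design.

    Control; IL-6 alone; IL-6 plus single inhibition of STAT3, PI3K or MAPK;
    IL-6 plus the two tolerated double inhibitions (STAT3+MAPK, PI3K+MAPK; the
    STAT3+PI3K combination is absent by design); and two inhibitor-only
    vehicle controls.  Inhibitors clamp their targets to 0, the stimulus
    clamps IL6 to 1.
    """
    mk = Condition.make
    return [
        mk("control"),
        mk("IL6", {"IL6": 1.0}),
        mk("IL6_STAT3i", {"IL6": 1.0}, {"STAT3"}),
        mk("IL6_PI3Ki", {"IL6": 1.0}, {"PI3K"}),
        mk("IL6_MAPKi", {"IL6": 1.0}, {"MAPK"}),
        mk("IL6_STAT3i_MAPKi", {"IL6": 1.0}, {"STAT3", "MAPK"}),
        mk("IL6_PI3Ki_MAPKi", {"IL6": 1.0}, {"PI3K", "MAPK"}),
        mk("STAT3i", {}, {"STAT3"}),
        mk("MAPKi", {}, {"MAPK"}),
    ]


# Gene panel of the paper-scale benchmark, grouped by regulatory input.
# The nuclear-receptor hub dominates, as it does in hepatic DMET regulation.
_HUB_GENES = (
    "CYP1A2", "CYP2A6", "CYP2B6", "CYP2C8", "CYP2C9", "CYP2C19", "CYP2D6",
    "CYP3A4", "CYP7A1", "ABCB11", "ABCC2", "SLCO1B1", "SLC22A1", "UGT1A1",
    "UGT2B7", "GSTA2", "NAT1", "NAT2", "TPMT", "FMO3",
)
_GR_GENES = ("ABCG2", "GSTM1")
_NFKB_GENES = ("ABCB1", "SLC10A1")
_HNF_GENES = ("SULT1A1",)
_DUAL_GENES = ("SLC22A7", "CES1")
_APR_GENES = ("CRP", "SAA1", "SOCS3")


def make_benchmark_pkn(scale: str = "toy") -> PriorNetwork:
    """Build the annotated benchmark PKN at ``toy`` or ``paper`` scale.

    Toy: 1 stimulus, 3 perturbable pathway nodes, 2 transcription-factor
    nodes, 4 genes (10 species).  Paper: 1 stimulus, 3 perturbable pathway
    branches of depth 2-3, a TF layer (nuclear-receptor hub, NF-kB-like,
    HNF-like, GR-like) and 30 measured genes wired predominantly through the
    hub.  Both are acyclic by construction.
    """
    net = PriorNetwork()

    def sp(name, role, **kw):
        net.add_species(Species(name, role=role, **kw))

    if scale == "toy":
        sp("IL6", "stimulus")
        for node in ("STAT3", "PI3K", "MAPK"):
            sp(node, "signaling", perturbable=True)
            net.add_transition("IL6", node, +1)
        sp("RXRNR", "complex")
        sp("NFKB", "transcription_factor")
        net.add_transition("MAPK", "RXRNR", -1)
        net.add_transition("PI3K", "RXRNR", -1)
        net.add_transition("PI3K", "NFKB", +1)
        for gene in ("DMET1", "DMET2"):
            sp(gene, "gene", measured=True)
            net.add_transition("RXRNR", gene, +1)
        sp("DMET3", "gene", measured=True)
        net.add_transition("NFKB", "DMET3", -1)
        sp("APR1", "gene", measured=True)
        net.add_transition("STAT3", "APR1", +1)
        return net

    if scale != "paper":
        raise ValueError(f"unknown benchmark scale {scale!r}")

    sp("IL6", "stimulus")
    for node in ("JAK", "SHP2", "RAS", "ERK", "AKT"):
        sp(node, "signaling")
    for node in ("STAT3", "PI3K", "MAPK"):
        sp(node, "signaling", perturbable=True)
    sp("RXRNR", "complex")
    sp("NFKB", "transcription_factor")
    sp("GR", "transcription_factor")
    sp("HNF4A", "transcription_factor")
    edges = [
        ("IL6", "JAK", +1), ("JAK", "STAT3", +1),
        ("IL6", "SHP2", +1), ("SHP2", "RAS", +1), ("RAS", "MAPK", +1),
        ("MAPK", "ERK", +1),
        ("SHP2", "PI3K", +1), ("PI3K", "AKT", +1), ("AKT", "NFKB", +1),
        ("ERK", "RXRNR", -1), ("NFKB", "RXRNR", -1),
        ("ERK", "GR", -1), ("NFKB", "HNF4A", -1),
    ]
    for s, t, sign in edges:
        net.add_transition(s, t, sign)
    for gene in _HUB_GENES + _GR_GENES + _NFKB_GENES + _HNF_GENES + _DUAL_GENES + _APR_GENES:
        sp(gene, "gene", measured=True)
    for gene in _HUB_GENES:
        net.add_transition("RXRNR", gene, +1)
    for gene in _GR_GENES:
        net.add_transition("GR", gene, +1)
    for gene in _NFKB_GENES:
        net.add_transition("NFKB", gene, -1)
    for gene in _HNF_GENES:
        net.add_transition("HNF4A", gene, +1)
    for gene in _DUAL_GENES:
        net.add_transition("GR", gene, +1)
        net.add_transition("NFKB", gene, -1)
    for gene in _APR_GENES:
        net.add_transition("STAT3", gene, +1)
    return net


@dataclass
class SyntheticTruth:
    """A ground-truth model plus the noise model that generated its data."""

    model: FuzzyModel
    design: list[Condition]
    noise_cv: float = 0.2
    donor_sd: float = 0.25
    missing_rate: float = 0.05
    seed: int = 0
    gene_midpoints: dict[str, float] = field(default_factory=dict)
    gene_directions: dict[str, str] = field(default_factory=dict)
    leaky_stat3_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.donor_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


def sample_truth(
    net: PriorNetwork,
    seed: int,
    design: list[Condition] | None = None,
    max_and_size: int = 2,
    noise_cv: float = 0.2,
    donor_sd: float = 0.25,
    missing_rate: float = 0.05,
    up_midpoint: float = 8.0,
    gene_effect_sd: float = 0.5,
    leaky_stat3_residual: float = 0.0,
    k_grid=DEFAULT_K_GRID,
    n_grid=DEFAULT_N_GRID,
) -> SyntheticTruth:
    """Sample a ground-truth model: one active gate per target, grid parameters.

    The true fold-change midpoint of each measured gene follows from its
    simulated response: genes whose state falls under the stimulus get the
    down-gene midpoint 0.5, induced genes get ``up_midpoint`` (large, so their
    emitted fold changes look like acute-phase inductions).  Each gene's
    midpoint is additionally jittered by a log2-normal factor of SD
    ``gene_effect_sd``, giving genes individual effect sizes the way real
    expression panels have them.  Identical seeds give identical truths.
    """
    if design is None:
        design = paper_design()
    rng = np.random.default_rng([int(seed), 0x5EED])
    space = expand_and_gates(net, max_and_size)
    by_target = space.by_target()
    gates = []
    for target in sorted(by_target):
        candidates = by_target[target]
        gate = candidates[int(rng.integers(len(candidates)))]
        params = TransferParams(
            float(k_grid[int(rng.integers(len(k_grid)))]),
            float(n_grid[int(rng.integers(len(n_grid)))]),
        )
        gates.append(gate.with_params(params))
    model = FuzzyModel(network=net, gates=gates)

    control = next(c for c in design if not c.stimuli and not c.inhibited)
    stimulated = next(c for c in design if c.stimuli and not c.inhibited)
    s_ctrl = simulate(model, control)
    s_stim = simulate(model, stimulated)
    midpoints, directions = {}, {}
    for gene in net.measured():
        if s_stim[gene] < s_ctrl[gene]:
            base, directions[gene] = 0.5, "down"
        elif s_stim[gene] > s_ctrl[gene]:
            base, directions[gene] = float(up_midpoint), "up"
        else:  # unresponsive gene: treat as a down-gene for emission
            base, directions[gene] = 0.5, "down"
        jitter = float(np.exp2(np.clip(rng.normal(0.0, gene_effect_sd), -1.2, 1.2)))
        midpoints[gene] = base * jitter
    return SyntheticTruth(
        model=model,
        design=list(design),
        noise_cv=noise_cv,
        donor_sd=donor_sd,
        missing_rate=missing_rate,
        seed=int(seed),
        gene_midpoints=midpoints,
        gene_directions=directions,
        leaky_stat3_residual=leaky_stat3_residual,
    )


def _true_states(truth: SyntheticTruth) -> pd.DataFrame:
    genes = truth.model.network.measured()
    cols = {}
    for cond in truth.design:
        state = simulate(truth.model, cond)
        if truth.leaky_stat3_residual > 0 and "STAT3" in cond.inhibited and cond.stimuli:
            # leaky inhibition: strongly STAT3-driven genes keep residual output
            for g in genes:
                if truth.gene_directions.get(g) == "up":
                    state[g] = max(state[g], truth.leaky_stat3_residual)
        cols[cond.name] = [state[g] for g in genes]
    return pd.DataFrame(cols, index=genes)


def emit_dataset(truth: SyntheticTruth, n_donors: int = 5, h: float = 4.0) -> list[MeasurementTable]:
    """Manufacture per-donor fold-change tables from the truth.

    Simulated states are clipped to [eps, 1-eps] and pushed through the
    inverse Hill curve with each gene's true midpoint; a per-(donor, gene)
    log2-normal random effect and per-cell multiplicative lognormal noise
    (coefficient of variation ``noise_cv``) are applied; cells go missing
    independently with probability ``missing_rate``.  The control column is
    exactly 1 wherever present (it is its own calibrator), so noise is not
    applied to it.
    """
    rng = np.random.default_rng([truth.seed, 0xDA7A])
    states = _true_states(truth)
    genes, conds = list(states.index), list(states.columns)
    control = next(c.name for c in truth.design if not c.stimuli and not c.inhibited)
    v = np.clip(states.to_numpy(dtype=float), CLIP_EPS, 1.0 - CLIP_EPS)
    m = np.array([truth.gene_midpoints[g] for g in genes])
    fc = inverse_hill(v, 1.0, h) * m[:, None]  # inverse Hill is linear in m
    ctrl_idx = conds.index(control)
    fc[:, ctrl_idx] = 1.0
    sigma = math.sqrt(math.log1p(truth.noise_cv**2))
    tables = []
    for d in range(n_donors):
        donor_effect = np.exp2(rng.normal(0.0, truth.donor_sd, size=len(genes)))
        noise = np.exp(rng.normal(0.0, sigma, size=fc.shape))
        observed = fc * donor_effect[:, None] * noise
        observed[:, ctrl_idx] = 1.0
        missing = rng.random(fc.shape) < truth.missing_rate
        observed = np.where(missing, np.nan, observed)
        tables.append(
            MeasurementTable(
                pd.DataFrame(observed, index=genes, columns=conds),
                donor_id=f"D{d + 1}",
                control_condition=control,
            )
        )
    return tables


def emit_ct(
    tables: list[MeasurementTable],
    baseline_ct: dict[str, float] | float = 24.0,
    ref_ct: float = 20.0,
    reference_gene: str = "GAPDH",
) -> CtTable:
    """Convert fold-change tables back into a raw Ct table (with a flat reference).

    Ct(gene, sample) = baseline(gene) - log2(fc); the reference gene sits at a
    constant ``ref_ct``, so the ddCt pipeline reproduces the fold changes
    exactly.
    """
    rows: dict[str, dict[str, float]] = {}
    sheet_rows = []
    for t in tables:
        for cond in t.fold_changes.columns:
            sample = f"{t.donor_id}__{cond}"
            sheet_rows.append({"sample": sample, "donor": t.donor_id, "condition": cond})
            for gene in t.fold_changes.index:
                base = baseline_ct[gene] if isinstance(baseline_ct, dict) else float(baseline_ct)
                fcv = t.fold_changes.at[gene, cond]
                rows.setdefault(gene, {})[sample] = (
                    np.nan if fcv != fcv else base - math.log2(float(fcv))
                )
            rows.setdefault(reference_gene, {})[sample] = float(ref_ct)
    values = pd.DataFrame(rows).T
    sheet = pd.DataFrame(sheet_rows).set_index("sample")
    control = tables[0].control_condition or "control"
    return CtTable(
        values=values,
        sample_sheet=sheet,
        reference_gene=reference_gene,
        calibrator_condition=control,
    )


@dataclass
class RecoverySummary:
    """How well a fitted family recovered a known ground truth."""

    n_true_gates: int
    recovered_fraction: float  # true gates with frequency >= true_freq
    max_spurious_frequency: float
    spurious_in_consensus: int  # spurious gates at/above the display cutoff
    consensus_size: int
    true_frequencies: dict[tuple, float]
    spurious_frequencies: dict[tuple, float]


def recovery_summary(family, truth: SyntheticTruth, true_freq: float = 0.8,
                     cutoff: float = 0.30) -> RecoverySummary:
    """Compare family consensus gate frequencies against the truth's gates."""
    true_keys = truth.model.gate_keys()
    freqs = family.consensus_gates
    true_f = {k: freqs.get(k, 0.0) for k in true_keys}
    spurious_f = {k: f for k, f in freqs.items() if k not in true_keys}
    consensus = {k: f for k, f in freqs.items() if f >= cutoff}
    return RecoverySummary(
        n_true_gates=len(true_keys),
        recovered_fraction=sum(f >= true_freq for f in true_f.values()) / len(true_keys),
        max_spurious_frequency=max(spurious_f.values(), default=0.0),
        spurious_in_consensus=sum(k not in true_keys for k in consensus),
        consensus_size=len(consensus),
        true_frequencies=true_f,
        spurious_frequencies=spurious_f,
    )
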