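"""JSON/CSV serialization of networks, gate spaces, models, families, designs.

All JSON documents carry a ``schema_version`` and are written with sorted
keys, so identical objects serialize byte-identically (used to assert seed
reproducibility of whole model families).
"""

from __future__ import annotations

import json

import pandas as pd

from .fuzzy_engine import Condition, FuzzyModel, Gate, GateSpace, TransferParams
from .pkn import PriorNetwork, Species, Transition

SCHEMA_VERSION = 1

__all__ = [
    "network_to_dict", "network_from_dict",
    "gatespace_to_dict", "gatespace_from_dict",
    "model_to_dict", "model_from_dict",
    "family_to_dict", "family_from_dict",
    "dumps", "read_design_csv", "write_design_csv",
    "read_fc_csv", "write_fc_csv",
]


def dumps(obj: dict) -> str:
    return json.dumps(obj, sort_keys=True, indent=1)


# -- networks ---------------------------------------------------------------

def network_to_dict(net: PriorNetwork) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "species": [
            {
                "name": s.name,
                "role": s.role,
                "measured": s.measured,
                "perturbable": s.perturbable,
                "constitutive": s.constitutive,
            }
            for s in (net.species[n] for n in sorted(net.species))
        ],
        "transitions": [
            {"source": t.source, "target": t.target, "sign": t.sign}
            for t in sorted(net.transitions)
        ],
    }


def network_from_dict(d: dict) -> PriorNetwork:
    net = PriorNetwork()
    for s in d["species"]:
        net.add_species(
            Species(s["name"], s["role"], s["measured"], s["perturbable"], s["constitutive"])
        )
    for t in d["transitions"]:
        net.add_transition(t["source"], t["target"], int(t["sign"]))
    return net


# -- gates ------------------------------------------------------------------

def _gate_to_dict(g: Gate) -> dict:
    d = {
        "target": g.target,
        "kind": g.kind,
        "inputs": [{"source": s, "sign": sign} for s, sign in g.inputs],
    }
    if g.params is not None:
        d["params"] = [{"k": p.k, "n": p.n} for p in g.params]
    return d


def _gate_from_dict(d: dict) -> Gate:
    params = d.get("params")
    return Gate(
        target=d["target"],
        inputs=tuple((i["source"], int(i["sign"])) for i in d["inputs"]),
        kind=d["kind"],
        params=tuple(TransferParams(p["k"], p["n"]) for p in params) if params else None,
    )


def gatespace_to_dict(space: GateSpace) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "max_and_size": space.max_and_size,
        "network": network_to_dict(space.network),
        "gates": [_gate_to_dict(g) for g in space.gates],
    }


def gatespace_from_dict(d: dict) -> GateSpace:
    return GateSpace(
        gates=[_gate_from_dict(g) for g in d["gates"]],
        max_and_size=int(d["max_and_size"]),
        network=network_from_dict(d["network"]),
    )


# -- models and families ----------------------------------------------------

def model_to_dict(model: FuzzyModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "network": network_to_dict(model.network),
        "gates": [_gate_to_dict(g) for g in sorted(model.gates, key=lambda g: g.key())],
        "constitutive": dict(sorted(model.constitutive.items())),
    }


def model_from_dict(d: dict) -> FuzzyModel:
    return FuzzyModel(
        network=network_from_dict(d["network"]),
        gates=[_gate_from_dict(g) for g in d["gates"]],
        constitutive={k: float(v) for k, v in d["constitutive"].items()},
    )


def family_to_dict(family) -> dict:
    from .train import gate_label

    return {
        "schema_version": SCHEMA_VERSION,
        "n_runs": family.n_runs,
        "threshold": family.threshold,
        "seed": family.seed,
        "models": [
            {"mse": mse, "model": model_to_dict(model)} for model, mse in family.models
        ],
        "consensus_gates": {
            gate_label(k): f for k, f in sorted(family.consensus_gates.items())
        },
        "consensus_transitions": {
            f"{s}->{t}:{sign:+d}": f
            for (s, t, sign), f in sorted(family.consensus_transitions.items())
        },
    }


def family_from_dict(d: dict):
    from .train import ModelFamily

    return ModelFamily(
        models=[(model_from_dict(m["model"]), float(m["mse"])) for m in d["models"]],
        n_runs=int(d["n_runs"]),
        threshold=float(d["threshold"]),
        seed=int(d["seed"]),
    )


# -- designs and fold-change tables -----------------------------------------

def write_design_csv(design: list[Condition], path) -> None:
    rows = []
    for c in design:
        rows.append(
            {
                "condition": c.name,
                "stimuli": ";".join(f"{s}={v:g}" for s, v in c.stimuli),
                "inhibited": ";".join(sorted(c.inhibited)),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_design_csv(path) -> list[Condition]:
    table = pd.read_csv(path, keep_default_na=False)
    design = []
    for row in table.itertuples(index=False):
        stimuli = {}
        if row.stimuli:
            for part in str(row.stimuli).split(";"):
                name, _, level = part.partition("=")
                stimuli[name.strip()] = float(level) if level else 1.0
        inhibited = [p.strip() for p in str(row.inhibited).split(";") if p.strip()]
        design.append(Condition.make(str(row.condition), stimuli, inhibited))
    return design


def write_fc_csv(table, path) -> None:
    """MeasurementTable (or NormalizedTable) values to CSV, NA for missing."""
    frame = getattr(table, "fold_changes", None)
    if frame is None:
        frame = table.values
    frame.to_csv(path, index_label="gene", na_rep="NA")


def read_fc_csv(path, donor_id: str, control_condition: str = "control"):
    from .normalize import MeasurementTable

    frame = pd.read_csv(path, index_col="gene", na_values=["NA"])
    return MeasurementTable(frame, donor_id=donor_id, control_condition=control_condition)
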