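"""Bundled example inputs.

The hepatic prior knowledge network here is a curated, approximate
transcription of a published IL-6 signaling + gene-regulation pathway figure:
it is meant as a realistic worked example for the preprocessing pipeline, not
as an authoritative reference network.
"""

from importlib import resources

from ..pkn import PriorNetwork, Transition, read_annotations, read_sif

__all__ = ["load_hepatic_pkn", "load_hepatic_feedback_removals"]


def _path(name: str):
    return resources.files(__package__) / name


def load_hepatic_pkn() -> PriorNetwork:
    """The bundled hepatic IL-6 network with its species annotations applied."""
    with resources.as_file(_path("hepatic_pkn.sif")) as p:
        net = read_sif(p)
    with resources.as_file(_path("hepatic_annotations.csv")) as p:
        return read_annotations(net, p)


def load_hepatic_feedback_removals() -> list[Transition]:
    """The explicit feedback transitions deleted before modeling."""
    import pandas as pd

    with resources.as_file(_path("hepatic_feedback_removals.csv")) as p:
        table = pd.read_csv(p)
    return [Transition(r.source, r.target, int(r.sign)) for r in table.itertuples(index=False)]
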