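"""Fold-change computation (ddCt) and Hill normalization into [0, 1].

qPCR Ct values are converted to linear fold changes with the comparative
ddCt method: dCt = Ct(target) - Ct(reference gene) per sample, ddCt =
dCt(sample) - dCt(calibrator), FC = 2^(-ddCt).  Fold changes are then mapped
into [0, 1] with a Hill curve

    v = fc^h / (m^h + fc^h)

whose midpoint m is chosen per gene class so that the untreated control
(fc = 1) lands near the model's resting state: m = 0.5 for genes
downregulated by the stimulus (control maps to ~0.94), m = 2 for weakly
induced genes (control maps to ~0.06), and m = half the mean stimulated fold
change for strongly induced acute-phase genes.  The Hill coefficient is h = 4
for all genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CtTable",
    "MeasurementTable",
    "NormalizationScheme",
    "NormalizedTable",
    "delta_delta_ct",
    "assign_midpoints",
    "hill_normalize",
    "inverse_hill",
    "normalize_tables",
]


class NormalizeError(ValueError):
    pass


@dataclass
class CtTable:
    """Raw qPCR cycle-threshold values.

    ``values``: genes x samples Ct numbers (NaN = failed well).
    ``sample_sheet``: DataFrame indexed by sample with columns ``donor`` and
    ``condition``.  ``reference_gene`` must be a row of ``values``;
    ``calibrator_condition`` names the control treatment.
    """

    values: pd.DataFrame
    sample_sheet: pd.DataFrame
    reference_gene: str
    calibrator_condition: str = "control"

    def __post_init__(self) -> None:
        if self.reference_gene not in self.values.index:
            raise NormalizeError(f"reference gene {self.reference_gene!r} not in Ct table")
        present = self.values.to_numpy()
        if np.any(np.nan_to_num(present, nan=1.0) <= 0):
            raise NormalizeError("Ct values must be positive")
        missing = set(self.values.columns) - set(self.sample_sheet.index)
        if missing:
            raise NormalizeError(f"samples without sheet entry: {sorted(missing)}")


@dataclass
class MeasurementTable:
    """Linear fold changes (vs control) for one donor; NaN marks missing cells."""

    fold_changes: pd.DataFrame  # genes x conditions
    donor_id: str
    control_condition: str | None = "control"

    def __post_init__(self) -> None:
        vals = self.fold_changes.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise NormalizeError(f"donor {self.donor_id}: fold changes must be positive")


@dataclass
class NormalizationScheme:
    """Per-gene Hill midpoints and the shared Hill coefficient."""

    h: float
    m_per_gene: dict[str, float]
    direction_per_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.h < 1.0:
            raise NormalizeError(f"Hill coefficient h must be >= 1, got {self.h}")
        for gene, m in self.m_per_gene.items():
            if m <= 0:
                raise NormalizeError(f"midpoint m must be positive (gene {gene!r})")


@dataclass
class NormalizedTable:
    """The [0, 1] image of a MeasurementTable under its scheme."""

    values: pd.DataFrame  # genes x conditions, in [0, 1]; NaN = missing
    donor_id: str
    scheme: NormalizationScheme


def delta_delta_ct(ct: CtTable) -> list[MeasurementTable]:
    """ddCt fold changes, one MeasurementTable per donor.

    A sample whose reference-gene Ct is missing is flagged missing for all its
    genes rather than fabricated.  The calibrator column is exactly 1 for
    every gene by construction.
    """
    sheet = ct.sample_sheet
    if ct.calibrator_condition not in set(sheet["condition"]):
        raise NormalizeError(
            f"calibrator condition {ct.calibrator_condition!r} absent from sample sheet"
        )
    genes = [g for g in ct.values.index if g != ct.reference_gene]
    ref = ct.values.loc[ct.reference_gene]
    dct = ct.values.loc[genes].sub(ref, axis=1)  # NaN ref -> NaN whole sample
    tables = []
    for donor in sorted(sheet["donor"].unique()):
        donor_samples = sheet.index[sheet["donor"] == donor]
        cal_samples = [
            s for s in donor_samples if sheet.at[s, "condition"] == ct.calibrator_condition
        ]
        if not cal_samples:
            raise NormalizeError(f"donor {donor!r} has no calibrator sample")
        cal = dct[cal_samples].mean(axis=1)
        fc = pd.DataFrame(index=genes, dtype=float)
        for sample in donor_samples:
            cond = sheet.at[sample, "condition"]
            fc[cond] = np.power(2.0, -(dct[sample] - cal))
        if ct.calibrator_condition in fc.columns:
            present = fc[ct.calibrator_condition].notna()
            fc.loc[present, ct.calibrator_condition] = 1.0
        tables.append(
            MeasurementTable(fc, donor_id=str(donor), control_condition=ct.calibrator_condition)
        )
    return tables


def assign_midpoints(
    data: list[MeasurementTable],
    il6_condition: str = "IL6",
    strong_up_cutoff: float = 4.0,
    h: float = 4.0,
    overrides: dict[str, float] | None = None,
) -> NormalizationScheme:
    """Classify genes by their mean stimulated fold change and assign midpoints.

    Per gene, the mean fold change under the stimulus condition across donors
    (missing cells excluded) determines the class: mean < 1 -> downregulated,
    m = 0.5; 1 <= mean < ``strong_up_cutoff`` -> weakly induced, m = 2;
    mean >= cutoff -> strongly induced, m = mean / 2.  ``overrides`` pins
    individual genes to explicit midpoints (direction "override").
    """
    genes: list[str] = []
    for t in data:
        for g in t.fold_changes.index:
            if g not in genes:
                genes.append(g)
    for t in data:
        if il6_condition not in t.fold_changes.columns:
            raise NormalizeError(
                f"donor {t.donor_id}: stimulus condition {il6_condition!r} missing"
            )
    m_per_gene: dict[str, float] = {}
    direction: dict[str, str] = {}
    unmeasured = []
    for gene in genes:
        vals = [
            float(t.fold_changes.at[gene, il6_condition])
            for t in data
            if gene in t.fold_changes.index
            and t.fold_changes.at[gene, il6_condition] == t.fold_changes.at[gene, il6_condition]
        ]
        if overrides and gene in overrides:
            m_per_gene[gene] = float(overrides[gene])
            direction[gene] = "override"
            continue
        if not vals:
            unmeasured.append(gene)
            continue
        mean_fc = float(np.mean(vals))
        if mean_fc < 1.0:
            m_per_gene[gene], direction[gene] = 0.5, "down"
        elif mean_fc < strong_up_cutoff:
            m_per_gene[gene], direction[gene] = 2.0, "up"
        else:
            m_per_gene[gene], direction[gene] = mean_fc / 2.0, "up"
    if unmeasured:
        raise NormalizeError(f"genes missing in all donors: {unmeasured}")
    return NormalizationScheme(h=h, m_per_gene=m_per_gene, direction_per_gene=direction)


def hill_normalize(fc, m: float, h: float):
    """Map a linear fold change into [0, 1]: v = fc^h / (m^h + fc^h)."""
    if m <= 0:
        raise NormalizeError(f"midpoint m must be positive, got {m}")
    if h < 1:
        raise NormalizeError(f"Hill coefficient h must be >= 1, got {h}")
    fc = np.asarray(fc, dtype=float)
    if np.any(fc[~np.isnan(fc)] < 0):
        raise NormalizeError("fold changes must be >= 0")
    out = fc**h / (m**h + fc**h)
    return float(out) if out.ndim == 0 else out


def inverse_hill(v, m: float, h: float):
    """Invert hill_normalize: fc = m * (v / (1 - v))^(1/h), for v in (0, 1)."""
    if m <= 0 or h < 1:
        raise NormalizeError("require m > 0 and h >= 1")
    v = np.asarray(v, dtype=float)
    if np.any((v <= 0.0) | (v >= 1.0)):
        raise NormalizeError("inverse_hill defined on open interval (0, 1); clip first")
    out = m * (v / (1.0 - v)) ** (1.0 / h)
    return float(out) if out.ndim == 0 else out


def normalize_tables(
    data: list[MeasurementTable], scheme: NormalizationScheme
) -> list[NormalizedTable]:
    """Apply the per-gene Hill normalization to every donor table."""
    out = []
    for t in data:
        missing_m = [g for g in t.fold_changes.index if g not in scheme.m_per_gene]
        if missing_m:
            raise NormalizeError(f"no midpoint assigned for genes: {missing_m}")
        m = np.array([scheme.m_per_gene[g] for g in t.fold_changes.index])
        fc = t.fold_changes.to_numpy(dtype=float)
        values = fc**scheme.h / (m[:, None] ** scheme.h + fc**scheme.h)
        out.append(
            NormalizedTable(
                values=pd.DataFrame(
                    values, index=t.fold_changes.index, columns=t.fold_changes.columns
                ),
                donor_id=t.donor_id,
                scheme=scheme,
            )
        )
    return out
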