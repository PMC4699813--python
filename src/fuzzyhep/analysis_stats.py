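"""Descriptive and validation statistics for the perturbation analysis.

Hierarchical clustering of log2 fold changes (average linkage, Euclidean
metric) for heat-map ordering; Spearman rank correlation between two
treatment arms' per-gene mean log2 fold changes (the knock-down-versus-
cytokine validation); family-prediction-versus-data tables; and pooled
two-sample t-tests.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .fuzzy_engine import simulate

__all__ = [
    "ClusterResult",
    "ValidationReport",
    "cluster_log2fc",
    "spearman_validation",
    "prediction_vs_data",
    "grouped_ttest",
    "linkage_to_newick",
]


class StatsError(ValueError):
    pass


@dataclass
class ClusterResult:
    """Row/column orders and linkages from hierarchical clustering."""

    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray  # scipy linkage matrices (merge heights in
    col_linkage: np.ndarray  # Euclidean distance units)
    matrix: pd.DataFrame  # input matrix reordered by (row_order, col_order)


def _pairwise_complete_pdist(x: np.ndarray) -> np.ndarray:
    """Condensed Euclidean distances; missing cells handled pairwise-complete.

    Each pair's squared distance over shared cells is rescaled by
    total/shared so distances stay comparable across missingness patterns.
    """
    n, p = x.shape
    out = np.empty(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(x[i]) & ~np.isnan(x[j])
            s = int(shared.sum())
            if s == 0:
                raise StatsError(f"rows {i} and {j} share no observed cells")
            d2 = float(((x[i, shared] - x[j, shared]) ** 2).sum()) * (p / s)
            out[idx] = math.sqrt(d2)
            idx += 1
    return out


def cluster_log2fc(table: pd.DataFrame) -> ClusterResult:
    """Average-linkage (UPGMA) clustering of rows and columns of a log2FC matrix.

    Rows and columns are clustered independently on Euclidean distances;
    all-missing rows/columns are dropped with a warning.  The scipy
    agglomeration is deterministic for a given distance matrix.
    """
    table = table.astype(float)
    empty_rows = table.index[table.isna().all(axis=1)]
    empty_cols = table.columns[table.isna().all(axis=0)]
    if len(empty_rows) or len(empty_cols):
        warnings.warn(
            f"dropping all-missing rows {list(empty_rows)} / columns {list(empty_cols)}",
            stacklevel=2,
        )
        table = table.drop(index=empty_rows, columns=empty_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise StatsError("need at least 2 rows and 2 columns to cluster")
    row_z = hierarchy.linkage(_pairwise_complete_pdist(table.to_numpy()), method="average")
    col_z = hierarchy.linkage(_pairwise_complete_pdist(table.to_numpy().T), method="average")
    row_order = [table.index[i] for i in hierarchy.leaves_list(row_z)]
    col_order = [table.columns[i] for i in hierarchy.leaves_list(col_z)]
    return ClusterResult(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_z,
        col_linkage=col_z,
        matrix=table.loc[row_order, col_order],
    )


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(z)

    def render(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


@dataclass
class ValidationReport:
    """Spearman comparison of two arms' per-gene mean log2 fold changes."""

    r_s: float
    n: int
    p: float
    pairs: pd.DataFrame  # per-gene (arm_a, arm_b) mean log2FC, listwise complete
    method: str = "t-approximation"


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, observed: float) -> float:
    n = len(xr)
    count, total = 0, 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(xr, yr[list(perm)])[0, 1]
        total += 1
        if abs(r) >= abs(observed) - 1e-12:
            count += 1
    return count / total


def spearman_validation(
    fc_a: pd.Series, fc_b: pd.Series, exact_max_n: int = 8
) -> ValidationReport:
    """Spearman rank correlation between two per-gene mean log2FC vectors.

    Pairs are listwise-complete over the shared genes; ties get midranks.
    The two-tailed p-value uses the exact permutation distribution for
    n <= ``exact_max_n`` and the t-approximation
    t = r_s * sqrt((n - 2) / (1 - r_s^2)) otherwise.
    """
    pairs = pd.DataFrame({"arm_a": fc_a, "arm_b": fc_b}).dropna()
    n = len(pairs)
    if n < 3:
        raise StatsError(f"need >= 3 shared genes, got {n}")
    a, b = pairs["arm_a"].to_numpy(), pairs["arm_b"].to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise StatsError("zero variance in one arm; Spearman undefined")
    r_s, p_t = stats.spearmanr(a, b)
    r_s = float(r_s)
    if n <= exact_max_n:
        p = _exact_spearman_p(stats.rankdata(a), stats.rankdata(b), r_s)
        method = "exact permutation"
    else:
        p, method = float(p_t), "t-approximation"
    return ValidationReport(r_s=r_s, n=n, p=p, pairs=pairs, method=method)


def prediction_vs_data(family, design, data) -> pd.DataFrame:
    """Family predictions against donor-aggregated normalized data.

    One row per (gene, condition): the mean prediction over the family's
    models, the mean and standard deviation of the normalized data across
    donors (missing cells excluded), and the absolute deviation.  Rows are
    sorted by deviation, largest first, to surface systematic misfits.
    """
    genes: list[str] = []
    for t in data:
        for g in t.values.index:
            if g not in genes:
                genes.append(g)
    cond_names = [c.name for c in design]
    pred = pd.DataFrame(0.0, index=genes, columns=cond_names)
    for model, _ in family.models:
        for cond in design:
            state = simulate(model, cond)
            for g in genes:
                pred.at[g, cond.name] += state[g]
    pred /= len(family.models)
    rows = []
    for g in genes:
        for cond in cond_names:
            vals = [
                float(t.values.at[g, cond])
                for t in data
                if g in t.values.index
                and cond in t.values.columns
                and t.values.at[g, cond] == t.values.at[g, cond]
            ]
            if not vals:
                continue
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            rows.append(
                {
                    "gene": g,
                    "condition": cond,
                    "prediction": float(pred.at[g, cond]),
                    "data_mean": mean,
                    "data_sd": sd,
                    "abs_deviation": abs(float(pred.at[g, cond]) - mean),
                    "n_donors": len(vals),
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values("abs_deviation", ascending=False, kind="stable").reset_index(drop=True)


def grouped_ttest(treated, control, welch: bool = False) -> tuple[float, float]:
    """Two-sample two-tailed t-test; returns (t, p).

    Pooled-variance by default; Welch with ``welch=True``.  Degenerate arms
    (zero pooled variance) raise rather than fabricate a p-value.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(treated) < 2 or len(control) < 2:
        raise StatsError("need >= 2 replicates per arm")
    if np.var(treated, ddof=1) == 0 and np.var(control, ddof=1) == 0:
        raise StatsError("zero pooled variance; t-test undefined")
    t, p = stats.ttest_ind(treated, control, equal_var=not welch)
    return float(t), float(p)
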