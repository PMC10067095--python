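"""Cluster-marker discovery and correlation-network analysis.

Given the two subtypes, a volcano screen flags proteins whose cluster-1 /
cluster-2 geometric-mean fold change exceeds the threshold (strictly more
than 2 by default) at MWW p strictly below alpha.  Protein co-regulation
is then mapped by correlating all protein pairs (Pearson on log2 values
by default), controlling the false discovery rate with Benjamini-Hochberg,
and extracting the network of pairs below the FDR cutoff (1e-4 by
default, positive correlations only).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AbundanceMatrix
from .screening import mww_test

__all__ = [
    "VolcanoResult",
    "CorrelationNetwork",
    "volcano_screen",
    "correlation_matrix",
    "bh_adjust",
    "build_network",
    "fisher_exact_2x2",
]


@dataclasses.dataclass
class VolcanoResult:
    """Per-protein fold change / p-value screen between two clusters."""

    table: pd.DataFrame  # fold_change, log2_fold_change, p, flag
    fc_threshold: float
    alpha: float

    @property
    def up(self) -> list[str]:
        return list(self.table.index[self.table["flag"] == "up"])

    @property
    def down(self) -> list[str]:
        return list(self.table.index[self.table["flag"] == "down"])

    def summary(self) -> str:
        return (
            f"Volcano screen (FC > {self.fc_threshold:g}, p < {self.alpha:g}): "
            f"{len(self.up)} up, {len(self.down)} down, "
            f"{int((self.table['flag'] == 'ns').sum())} ns"
        )


def volcano_screen(
    m: AbundanceMatrix | pd.DataFrame,
    labels: pd.Series,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> VolcanoResult:
    """Flag proteins differing between cluster 1 and cluster 2.

    Fold change is the ratio of geometric means (cluster 1 over
    cluster 2); p-values come from the MWW test, consistent with the
    screening stage.  Both thresholds are strict: a protein at fold
    change exactly 2 is *not* flagged ("more than two").
    """
    data = m.data if isinstance(m, AbundanceMatrix) else m
    if data.isna().any().any():
        raise ValueError("volcano screen requires a complete (imputed) matrix")
    labels = labels.loc[[s for s in data.columns if s in labels.index]]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("labels must define exactly two clusters")
    ids1 = labels.index[labels == groups[0]]
    ids2 = labels.index[labels == groups[1]]
    if len(ids1) < 2 or len(ids2) < 2:
        raise ValueError("each cluster needs at least 2 samples")
    v1 = data[ids1].to_numpy()
    v2 = data[ids2].to_numpy()
    fc = np.exp(np.mean(np.log(v1), axis=1) - np.mean(np.log(v2), axis=1))
    pvals = np.array([mww_test(v1[i], v2[i]).p for i in range(data.shape[0])])
    flag = np.where(
        (fc > fc_threshold) & (pvals < alpha),
        "up",
        np.where((fc < 1.0 / fc_threshold) & (pvals < alpha), "down", "ns"),
    )
    table = pd.DataFrame(
        {
            "fold_change": fc,
            "log2_fold_change": np.log2(fc),
            "p": pvals,
            "flag": flag,
        },
        index=data.index.rename("protein"),
    )
    return VolcanoResult(table=table, fc_threshold=fc_threshold, alpha=alpha)


def correlation_matrix(
    m: AbundanceMatrix | pd.DataFrame, method: str = "pearson_log2"
) -> pd.DataFrame:
    """Correlations for all unordered protein pairs.

    ``pearson_log2`` computes Pearson r on log2 abundances (log-normal
    data; the conventional scale) with the two-sided t-transform p-value;
    ``spearman`` uses rank correlation.  Pairs involving a zero-variance
    protein are marked not computable (NaN).

    Returns a table with columns ``protein_a, protein_b, r, p``.
    """
    data = m.data if isinstance(m, AbundanceMatrix) else m
    if data.isna().any().any():
        raise ValueError("correlation analysis requires a complete matrix")
    n = data.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    X = data.to_numpy()
    if method == "pearson_log2":
        if (X <= 0).any():
            raise ValueError("pearson_log2 requires positive values")
        L = np.log2(X)
        sd = L.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(L)
        df = n - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt(df / np.clip(1 - r**2, 1e-300, None))
        p = 2 * stats.t.sf(np.abs(t), df)
        p[np.isclose(np.abs(r), 1.0)] = 0.0
    elif method == "spearman":
        sd = X.std(axis=1)
        r, p = stats.spearmanr(X.T)
        r = np.atleast_2d(r)
        p = np.atleast_2d(p)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    degenerate = sd == 0
    iu = np.triu_indices(data.shape[0], k=1)
    ids = data.index.to_numpy()
    bad = degenerate[iu[0]] | degenerate[iu[1]]
    r_pairs = r[iu].astype(float)
    p_pairs = np.clip(p[iu].astype(float), 0.0, 1.0)
    r_pairs[bad] = np.nan
    p_pairs[bad] = np.nan
    return pd.DataFrame(
        {
            "protein_a": ids[iu[0]],
            "protein_b": ids[iu[1]],
            "r": r_pairs,
            "p": p_pairs,
        }
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Order-preserving with the input; NaN entries (not-computable tests)
    propagate as NaN and do not enter the adjustment.
    """
    pvals = np.asarray(pvals, dtype=float)
    mask = ~np.isnan(pvals)
    if ((pvals[mask] < 0) | (pvals[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(pvals.shape, np.nan)
    if mask.sum():
        q[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
    return q


@dataclasses.dataclass
class CorrelationNetwork:
    """FDR-thresholded correlation network.

    ``edges`` has columns ``protein_a, protein_b, r, p, q``; ``nodes``
    are the endpoints of kept edges; focus proteins with no surviving
    edge are reported separately as ``isolated_focus``.
    """

    edges: pd.DataFrame
    nodes: list[str]
    isolated_focus: list[str]
    q_threshold: float
    positive_only: bool

    def graph(self):
        """The network as a networkx Graph with r/q edge attributes."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edges.iterrows():
            g.add_edge(row["protein_a"], row["protein_b"], r=row["r"], q=row["q"])
        return g

    def summary(self) -> str:
        return (
            f"Correlation network (q < {self.q_threshold:g}"
            + (", positive only" if self.positive_only else "")
            + f"): {len(self.nodes)} nodes, {len(self.edges)} edges"
            + (f", {len(self.isolated_focus)} isolated focus proteins"
               if self.isolated_focus else "")
        )


def build_network(
    pairs: pd.DataFrame,
    q_threshold: float = 1e-4,
    positive_only: bool = True,
    focus: Iterable[str] | None = None,
) -> CorrelationNetwork:
    """Extract the network of pairs below the FDR threshold.

    ``pairs`` must carry ``protein_a, protein_b, r`` and either ``q`` or
    ``p`` (q is computed by BH if absent).  With ``focus`` given, only
    edges touching a focus protein are kept, and focus proteins left
    without edges are listed as isolated.
    """
    pairs = pairs.copy()
    if "q" not in pairs.columns:
        pairs["q"] = bh_adjust(pairs["p"].to_numpy())
    keep = pairs["q"] < q_threshold
    if positive_only:
        keep &= pairs["r"] > 0
    if focus is not None:
        focus = set(focus)
        keep &= pairs["protein_a"].isin(focus) | pairs["protein_b"].isin(focus)
    edges = pairs.loc[keep.fillna(False)].reset_index(drop=True)
    nodes = sorted(set(edges["protein_a"]) | set(edges["protein_b"]))
    isolated = sorted(focus - set(nodes)) if focus is not None else []
    return CorrelationNetwork(
        edges=edges,
        nodes=nodes,
        isolated_focus=isolated,
        q_threshold=q_threshold,
        positive_only=positive_only,
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
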