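"""Pearson correlation network over differential metabolites; hub-degree candidates.

Edges connect feature pairs whose squared Pearson correlation meets the
threshold (default r^2 >= 0.4, i.e. |r| >= 0.632; an ``absolute`` mode
thresholds |r| >= 0.4 instead, since the literature convention is written
ambiguously).  Correlations use pairwise-complete samples.  Candidate
biomarkers are the best-connected nodes: ranked by degree, ties broken by
mean |r| of incident edges, then feature ID.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["build_network", "select_candidates", "edge_list"]


def build_network(
    dem_matrix: pd.DataFrame,
    threshold: float = 0.4,
    mode: str = "squared",
    eligible: list[str] | None = None,
    min_pairs: int = 3,
) -> nx.Graph:
    """Correlation network over the (optionally restricted) DEM matrix.

    ``mode="squared"`` keeps edges with r^2 >= threshold; ``mode="absolute"``
    keeps |r| >= threshold.  Nodes carry a ``degree``-synchronized size
    attribute; edges carry ``r`` and ``sign``.  Constant features have
    undefined correlations and end up isolated (warned).
    """
    if mode not in ("squared", "absolute"):
        raise ValueError(f"mode must be 'squared' or 'absolute', got {mode!r}")
    m = dem_matrix[eligible] if eligible is not None else dem_matrix
    const = m.columns[m.std(ddof=0) == 0]
    if len(const):
        warnings.warn(f"constant feature(s) have undefined correlations: {list(const)}")
    corr = m.corr(method="pearson", min_periods=min_pairs)
    g = nx.Graph()
    g.add_nodes_from(m.columns)
    cols = list(m.columns)
    r = corr.to_numpy()
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            rij = r[i, j]
            if not np.isfinite(rij):
                continue
            stat = rij**2 if mode == "squared" else abs(rij)
            if stat >= threshold:
                g.add_edge(cols[i], cols[j], r=float(rij), sign=1 if rij >= 0 else -1)
    for node in g.nodes:
        g.nodes[node]["size"] = g.degree[node]
    return g


def select_candidates(net: nx.Graph, top_n: int | None = None, degree_quantile: float = 0.75) -> list[str]:
    """Best-connected nodes: degree desc, ties by mean |r| of incident edges, then ID.

    Default returns every node strictly above the ``degree_quantile`` of the
    degree distribution (isolated graphs give an empty list); ``top_n``
    overrides with a fixed count.
    """
    degrees = dict(net.degree)
    if not degrees or max(degrees.values()) == 0:
        return []

    def mean_abs_r(node: str) -> float:
        rs = [abs(d["r"]) for _, _, d in net.edges(node, data=True)]
        return float(np.mean(rs)) if rs else 0.0

    ranked = sorted(degrees, key=lambda f: (-degrees[f], -mean_abs_r(f), f))
    if top_n is not None:
        return ranked[:top_n]
    cut = float(np.quantile(list(degrees.values()), degree_quantile))
    return [f for f in ranked if degrees[f] > cut and degrees[f] > 0]


def edge_list(net: nx.Graph) -> pd.DataFrame:
    """Edges as a (feature_a, feature_b, r) frame, and implicitly the node degrees."""
    return pd.DataFrame(
        [{"feature_a": a, "feature_b": b, "r": d["r"]} for a, b, d in net.edges(data=True)]
    )
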