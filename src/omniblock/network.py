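"""Block-level partial-correlation (Gaussian graphical model) network.

The correlation matrix of the block composite scores is shrunk toward the
identity with the analytic variance-minimizing intensity (Schafer-Strimmer),
inverted, and rescaled to partial correlations.  Edges are tested, kept at a
permissive p threshold, and the resulting undirected graph is scored with
unnormalized shortest-path betweenness centrality and exported as GraphML /
SIF text / CSV tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data import OmniblockError, ValidationError

__all__ = [
    "PartialCorrNetwork",
    "partial_correlations",
    "build_network",
    "betweenness",
    "export_graph",
]


@dataclass
class PartialCorrNetwork:
    graph: nx.Graph
    pcor: pd.DataFrame
    p_values: pd.DataFrame
    shrinkage: float
    node_attrs: pd.DataFrame | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


def _shrinkage_intensity(Z: np.ndarray) -> float:
    """Analytic variance-minimizing shrinkage of off-diagonal correlations.

    ``lambda* = sum var(r_ij) / sum r_ij^2`` over i < j, computed from the
    standardized data, clamped to [0, 1].
    """
    n, g = Z.shape
    W = np.einsum("ki,kj->kij", Z, Z)  # n x g x g products
    wbar = W.mean(axis=0)
    r = wbar * n / (n - 1)
    var_r = n / ((n - 1) ** 3) * np.sum((W - wbar[None]) ** 2, axis=0)
    iu = np.triu_indices(g, k=1)
    denom = float(np.sum(r[iu] ** 2))
    if denom <= 0:
        return 1.0
    lam = float(np.sum(var_r[iu]) / denom)
    return min(max(lam, 0.0), 1.0)


def partial_correlations(
    scores: pd.DataFrame | np.ndarray, names: list[str] | None = None
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Shrinkage partial correlations of the samples x blocks score matrix.

    Returns ``(pcor, lambda, p_values)``.  The correlation matrix is shrunk
    as ``(1 - lambda) R + lambda I`` (guaranteed positive definite for
    ``lambda > 0``), inverted to the precision matrix ``Omega``, and scaled:
    ``pcor_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)``.  Edge p-values come
    from the t statistic ``r sqrt(df / (1 - r^2))`` with ``df = n - G``
    degrees of freedom when positive, otherwise from a Fisher-z normal
    approximation with ``n - 3`` effective observations.
    """
    if isinstance(scores, pd.DataFrame):
        names = list(scores.columns)
        X = scores.to_numpy(dtype=float)
    else:
        X = np.asarray(scores, dtype=float)
        if names is None:
            names = [f"v{j + 1}" for j in range(X.shape[1])]
    n, g = X.shape
    if n < 3:
        raise ValidationError("need at least 3 samples")
    if g < 2:
        raise ValidationError("need at least 2 blocks")
    sd = X.std(axis=0, ddof=1)
    const = [names[j] for j in range(g) if not sd[j] > 0]
    if const:
        raise OmniblockError(f"constant block score column(s): {const}")
    Z = (X - X.mean(axis=0)) / sd
    lam = _shrinkage_intensity(Z)
    R = np.corrcoef(X, rowvar=False)
    R_sh = (1.0 - lam) * R
    np.fill_diagonal(R_sh, 1.0)
    omega = np.linalg.inv(R_sh)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = np.clip((pcor + pcor.T) / 2.0, -1 + 1e-12, 1 - 1e-12)
    np.fill_diagonal(pcor, 1.0)

    df = n - 2 - (g - 2)
    pvals = np.ones((g, g))
    iu = np.triu_indices(g, k=1)
    r = pcor[iu]
    if df > 0:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        z = np.arctanh(r) * np.sqrt(max(n - 3, 1))
        p = 2.0 * stats.norm.sf(np.abs(z))
    pvals[iu] = p
    pvals[(iu[1], iu[0])] = p
    np.fill_diagonal(pvals, 0.0)
    idx = pd.Index(names)
    return (
        pd.DataFrame(pcor, index=idx, columns=idx),
        lam,
        pd.DataFrame(pvals, index=idx, columns=idx),
    )


def build_network(
    pcor: pd.DataFrame,
    p_values: pd.DataFrame,
    p_threshold: float = 0.25,
    shrinkage: float = float("nan"),
    node_attrs: pd.DataFrame | None = None,
) -> PartialCorrNetwork:
    """Threshold edges at ``p <= p_threshold``; isolated nodes are retained."""
    if not (0 < p_threshold <= 1):
        raise ValidationError("p_threshold must lie in (0, 1]")
    g = nx.Graph()
    names = list(pcor.columns)
    g.add_nodes_from(names)
    if node_attrs is not None:
        for node in names:
            if node in node_attrs.index:
                for key, val in node_attrs.loc[node].items():
                    g.nodes[node][key] = float(val) if isinstance(val, (int, float, np.floating)) else val
    P = p_values.to_numpy()
    R = pcor.to_numpy()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if P[i, j] <= p_threshold:
                g.add_edge(
                    names[i], names[j],
                    pcor=float(R[i, j]), p=float(P[i, j]),
                    sign=1 if R[i, j] >= 0 else -1,
                )
    return PartialCorrNetwork(graph=g, pcor=pcor, p_values=p_values,
                              shrinkage=shrinkage, node_attrs=node_attrs)


def betweenness(network: PartialCorrNetwork | nx.Graph) -> pd.Series:
    """Unnormalized shortest-path betweenness g(v) on the unweighted graph.

    ``g(v) = sum_{s != v != t} sigma_st(v) / sigma_st`` over unordered pairs,
    with ``sigma`` counting all shortest paths; disconnected pairs contribute
    zero.
    """
    g = network.graph if isinstance(network, PartialCorrNetwork) else network
    bc = nx.betweenness_centrality(g, normalized=False, weight=None)
    return pd.Series(bc, name="betweenness")


def export_graph(network: PartialCorrNetwork, path: str | Path) -> tuple[Path, Path]:
    """Write GraphML plus a SIF-style text file; returns both paths.

    The SIF relation is ``pp`` (positive partial correlation) or ``pn``
    (negative); isolated nodes appear as single-column rows.
    """
    path = Path(path)
    graphml = path.with_suffix(".graphml")
    sif = path.with_suffix(".sif")
    g = network.graph.copy()
    bc = betweenness(network)
    for node in g.nodes:
        g.nodes[node]["betweenness"] = float(bc[node])
    nx.write_graphml(g, graphml)
    lines = []
    isolated = set(g.nodes)
    for u, v, attrs in sorted(g.edges(data=True)):
        rel = "pp" if attrs.get("sign", 1) >= 0 else "pn"
        lines.append(f"{u}\t{rel}\t{v}")
        isolated.discard(u)
        isolated.discard(v)
    lines.extend(sorted(isolated))
    sif.write_text("\n".join(lines) + ("\n" if lines else ""))
    return graphml, sif
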