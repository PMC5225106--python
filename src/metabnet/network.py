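"""Correlation-based metabolite networks and their comparison.

Within each sample group (genotype x condition), every metabolite pair
is scored by Pearson correlation; pairs passing strict |r| and BH-FDR
thresholds become undirected edges.  Networks are summarized by edge
count, average node degree 2E/n, and a density convention E/(n(n-1))
— half the standard undirected density, the convention under which the
published group summaries are internally consistent; the standard form
is available behind a flag.  Two networks over the same feature
universe are compared by edge intersection and by the symmetric
difference network (SDN), whose edges live in exactly one source and
carry its tag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import NormalizedTable
from .univariate import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationNetwork",
    "NetworkProperties",
    "SymmetricDifferenceNetwork",
    "correlation_matrix",
    "build_network",
    "network_properties",
    "intersect_networks",
    "symmetric_difference",
    "write_edge_list",
]


def correlation_matrix(
    table: NormalizedTable,
    group: tuple[str, str] | None = None,
    timepoint: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Pairwise Pearson r and two-sided p within one sample group.

    ``group`` is a (genotype, condition) pair; by default both
    timepoints and all replicates are pooled, ``timepoint`` restricts
    to one.  Zero-variance features are excluded with a warning; their
    correlations are undefined, never treated as r = 0.  Returns
    (r matrix, p matrix, n samples).  p comes from the exact null
    distribution of r via t = r sqrt(n-2)/sqrt(1-r^2); |r| = 1 gives
    p = 0 exactly.
    """
    meta = table.metadata
    mask = pd.Series(True, index=meta.index)
    if group is not None:
        genotype, condition = group
        mask &= meta["genotype"].astype(str) == str(genotype)
        mask &= meta["condition"].astype(str) == str(condition)
        if not mask.any():
            raise ValueError(f"group {group!r} absent from metadata")
    if timepoint is not None:
        mask &= meta["timepoint"].astype(str) == str(timepoint)
    samples = meta.index[mask]
    n = len(samples)
    if n < 4:
        raise ValueError(f"group has {n} samples; need >= 4 for meaningful p-values")

    values = table.values.loc[samples]
    sds = values.std(axis=0, ddof=1)
    constant = list(values.columns[(sds == 0) | sds.isna()])
    if constant:
        logger.warning("excluding %d zero-variance feature(s) in group %s: %s",
                       len(constant), group, constant)
        values = values.drop(columns=constant)

    r = np.corrcoef(values.to_numpy(dtype=float), rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0 - 1e-12] = 0.0
    np.fill_diagonal(p, 0.0)
    cols = values.columns
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
        n,
    )


@dataclass
class CorrelationNetwork:
    """Undirected network of significant metabolite correlations.

    Nodes are features with at least one significant edge (isolated
    features are not nodes).  Edge attributes: r, p, q.
    """

    label: str
    graph: nx.Graph
    r_min: float = 0.9
    q_max: float = 0.05
    n_samples: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted((str(u), str(v)))) for u, v in self.graph.edges}

    def edges_frame(self) -> pd.DataFrame:
        """Edge list in deterministic lexicographic order."""
        rows = [
            {"node1": a, "node2": b, **self.graph.edges[a, b]}
            for a, b in sorted(self.edge_set())
        ]
        cols = ["node1", "node2", "r", "p", "q"]
        return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def build_network(
    r: pd.DataFrame,
    p: pd.DataFrame,
    label: str = "",
    r_min: float = 0.9,
    q_max: float = 0.05,
    n_samples: int = 0,
) -> CorrelationNetwork:
    """Threshold a correlation matrix into a network.

    BH-FDR is computed over all p(p-1)/2 feature pairs of this matrix
    (the family is one group's matrix, not all groups); edges require
    strictly |r| > r_min and q < q_max.
    """
    if not 0.0 <= r_min < 1.0:
        raise ValueError("r_min must lie in [0, 1)")
    if not 0.0 < q_max <= 1.0:
        raise ValueError("q_max must lie in (0, 1]")
    features = list(r.columns)
    iu = np.triu_indices(len(features), k=1)
    r_flat = r.to_numpy()[iu]
    p_flat = p.to_numpy()[iu]
    # pairs with undefined r (NaN from zero variance upstream) are excluded
    defined = np.isfinite(r_flat)
    q_flat = np.full_like(p_flat, np.nan)
    if defined.any():
        q_flat[defined] = bh_fdr(p_flat[defined])
    keep = defined & (np.abs(r_flat) > r_min) & (q_flat < q_max)

    g = nx.Graph()
    for k in np.flatnonzero(keep):
        a, b = features[iu[0][k]], features[iu[1][k]]
        g.add_edge(a, b, r=float(r_flat[k]), p=float(p_flat[k]), q=float(q_flat[k]))
    return CorrelationNetwork(
        label=label, graph=g, r_min=r_min, q_max=q_max, n_samples=n_samples
    )


@dataclass(frozen=True)
class NetworkProperties:
    """Summary counts and the derived degree/density statistics."""

    n_nodes: int
    n_edges: int
    average_degree: float
    density: float
    standard_density: float

    @classmethod
    def from_counts(
        cls, n_nodes: int, n_edges: int, paper_convention: bool = True
    ) -> "NetworkProperties":
        """Properties from raw (n, E) counts.

        ``density`` follows the E/(n(n-1)) convention by default; the
        standard undirected 2E/(n(n-1)) is always reported alongside.
        No simple-graph bound on E is enforced here so published count
        pairs can be summarized as printed.
        """
        n, e = int(n_nodes), int(n_edges)
        if n <= 0:
            logger.warning("empty network; reporting zero properties")
            return cls(0, e, 0.0, 0.0, 0.0)
        avg = 2.0 * e / n
        denom = n * (n - 1)
        half = e / denom if denom else 0.0
        std = 2.0 * e / denom if denom else 0.0
        return cls(n, e, avg, half if paper_convention else std, std)


def network_properties(net: CorrelationNetwork) -> NetworkProperties:
    """Average degree 2E/n and density E/(n(n-1)) of a built network."""
    return NetworkProperties.from_counts(net.n_nodes, net.n_edges)


def intersect_networks(a: CorrelationNetwork, b: CorrelationNetwork) -> CorrelationNetwork:
    """Edges present in both networks, annotated with r from each source."""
    g = nx.Graph()
    for u, v in sorted(a.edge_set() & b.edge_set()):
        g.add_edge(u, v, r_a=a.graph.edges[u, v]["r"], r_b=b.graph.edges[u, v]["r"],
                   r=(a.graph.edges[u, v]["r"] + b.graph.edges[u, v]["r"]) / 2.0,
                   p=max(a.graph.edges[u, v]["p"], b.graph.edges[u, v]["p"]),
                   q=max(a.graph.edges[u, v]["q"], b.graph.edges[u, v]["q"]))
    return CorrelationNetwork(
        label=f"{a.label}&{b.label}", graph=g,
        r_min=max(a.r_min, b.r_min), q_max=min(a.q_max, b.q_max),
        n_samples=min(a.n_samples, b.n_samples),
    )


@dataclass
class SymmetricDifferenceNetwork:
    """Edges present in exactly one of two compared networks.

    Each edge carries the label of its source network; a node is
    "specific" to a source when every one of its SDN edges carries that
    source's tag.
    """

    label_a: str
    label_b: str
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_specific_to(self, label: str) -> int:
        return sum(1 for _, _, s in self.graph.edges(data="source") if s == label)

    def nodes_specific_to(self, label: str) -> int:
        return sum(
            1
            for node in self.graph.nodes
            if all(s == label for _, _, s in self.graph.edges(node, data="source"))
        )

    @property
    def edge_ratio(self) -> float:
        """Ratio of B-specific to A-specific edge counts (the '1 : x')."""
        ea = self.edges_specific_to(self.label_a)
        eb = self.edges_specific_to(self.label_b)
        return eb / ea if ea else float("inf")

    def node_tallies(self) -> pd.DataFrame:
        """Per-node counts of source-tagged SDN edges."""
        rows = []
        for node in sorted(self.graph.nodes, key=str):
            sources = [s for _, _, s in self.graph.edges(node, data="source")]
            rows.append(
                {
                    "node": node,
                    f"edges_{self.label_a}": sources.count(self.label_a),
                    f"edges_{self.label_b}": sources.count(self.label_b),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            f"edges_{self.label_a}": self.edges_specific_to(self.label_a),
            f"edges_{self.label_b}": self.edges_specific_to(self.label_b),
            f"nodes_{self.label_a}": self.nodes_specific_to(self.label_a),
            f"nodes_{self.label_b}": self.nodes_specific_to(self.label_b),
            "edge_ratio": self.edge_ratio,
        }


def symmetric_difference(
    a: CorrelationNetwork, b: CorrelationNetwork
) -> SymmetricDifferenceNetwork:
    """XOR of two edge sets with source tags and summary counts."""
    ea, eb = a.edge_set(), b.edge_set()
    g = nx.Graph()
    for u, v in sorted(ea - eb):
        g.add_edge(u, v, source=a.label, **{k: a.graph.edges[u, v][k] for k in ("r", "p", "q") if k in a.graph.edges[u, v]})
    for u, v in sorted(eb - ea):
        g.add_edge(u, v, source=b.label, **{k: b.graph.edges[u, v][k] for k in ("r", "p", "q") if k in b.graph.edges[u, v]})
    return SymmetricDifferenceNetwork(label_a=a.label, label_b=b.label, graph=g)


def write_edge_list(net: CorrelationNetwork | SymmetricDifferenceNetwork,
                    path: str | Path, delimiter: str = "\t") -> None:
    """Edge list TSV in deterministic order; SDNs include the source tag."""
    if isinstance(net, SymmetricDifferenceNetwork):
        rows = [
            {"node1": u, "node2": v, **net.graph.edges[u, v]}
            for u, v in sorted(
                tuple(sorted((str(x), str(y)))) for x, y in net.graph.edges
            )
        ]
        frame = pd.DataFrame(rows, columns=["node1", "node2", "r", "p", "q", "source"])
    else:
        frame = net.edges_frame()
    frame.to_csv(path, sep=delimiter, index=False)


def write_graphml(net: CorrelationNetwork | SymmetricDifferenceNetwork,
                  path: str | Path) -> None:
    """GraphML export suitable for Cytoscape import."""
    nx.write_graphml(net.graph, str(path))
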