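"""Network construction, degree statistics, power-law fit, hubs and export.

The tissue network is a simple undirected graph whose nodes carry a consensus
regulation class (Up / Down / Mixed / NotDE).  Hubs are ranked by degree;
"key hubs" additionally have many differentially expressed neighbours.  The
degree distribution P(k) is fitted with a power law P(k) ~ k^-alpha, by
default via least squares of log10 P(k) on log10 k (a discrete maximum-
likelihood estimator is available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from lxml import etree

from .integration import Edge

REGULATION_CLASSES = ("Up", "Down", "Mixed", "NotDE")


@dataclass
class TissueNetwork:
    """Simple undirected graph with per-node regulation classes."""

    graph: nx.Graph = field(repr=False)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes())

    @property
    def edges(self) -> set[Edge]:
        return {tuple(sorted(e)) for e in self.graph.edges()}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def regulation(self, gene: str) -> str:
        return self.graph.nodes[gene]["regulation"]


@dataclass
class PowerLawFit:
    alpha: float
    fit_method: str
    k_range: tuple[int, int]
    r_squared: float | None = None


@dataclass(frozen=True)
class HubRecord:
    protein: str
    n_neighbours: int
    n_deg_neighbours: int
    n_up: int
    n_down: int
    n_mixed: int


def build_graph(
    edges: set[Edge] | list[Edge],
    consensus_classes: dict[str, str] | None = None,
    supports: dict[Edge, int] | None = None,
) -> TissueNetwork:
    """Build the tissue network from deduplicated edges.

    Nodes are all endpoint genes; each carries its consensus class (``NotDE``
    when absent from the consensus table).  Optional per-edge dataset-support
    counts are stored as the ``support`` edge attribute.
    """
    consensus_classes = consensus_classes or {}
    g = nx.Graph()
    for a, b in sorted(tuple(sorted(e)) for e in edges):
        attrs = {}
        if supports is not None:
            attrs["support"] = int(supports.get((a, b), 0))
        g.add_edge(a, b, **attrs)
    for node in g.nodes():
        cls = consensus_classes.get(node, "NotDE")
        if cls not in REGULATION_CLASSES:
            raise ValueError(f"unknown regulation class {cls!r} for {node}")
        g.nodes[node]["regulation"] = cls
    return TissueNetwork(graph=g)


def degree_distribution(network: TissueNetwork) -> dict[int, float]:
    """Fraction of nodes having each observed degree (sums to 1)."""
    if network.n_nodes == 0:
        raise ValueError("empty network")
    degrees = [d for _, d in network.graph.degree()]
    counts: dict[int, int] = {}
    for d in degrees:
        counts[d] = counts.get(d, 0) + 1
    n = len(degrees)
    return {k: counts[k] / n for k in sorted(counts)}


def fit_power_law(distribution: dict[int, float], method: str = "loglog_ls") -> PowerLawFit:
    """Fit P(k) ~ k^-alpha to a degree distribution.

    ``loglog_ls``: ordinary least squares of log10 P(k) on log10 k over the
    nonzero-frequency degrees k >= 1; alpha is the negated slope.
    ``discrete_mle``: the discrete Hill-type maximum-likelihood estimator
    alpha = 1 + n / sum(ln(k_i / (k_min - 0.5))), weighted by frequencies.
    """
    points = {k: p for k, p in distribution.items() if k >= 1 and p > 0}
    if len(points) < 3:
        raise ValueError("need at least 3 distinct degrees with nonzero frequency")
    ks = np.array(sorted(points), dtype=float)
    ps = np.array([points[int(k)] for k in ks])
    if method == "loglog_ls":
        x = np.log10(ks)
        y = np.log10(ps)
        slope, _intercept = np.polyfit(x, y, 1)
        yhat = np.polyval(np.polyfit(x, y, 1), x)
        ss_res = float(((y - yhat) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        alpha = -float(slope)
    elif method == "discrete_mle":
        kmin = ks.min()
        w = ps / ps.sum()
        denom = float((w * np.log(ks / (kmin - 0.5))).sum())
        alpha = 1.0 + 1.0 / denom if denom > 0 else np.inf
        r2 = None
    else:
        raise ValueError(f"unknown fit method {method!r}")
    return PowerLawFit(
        alpha=alpha,
        fit_method=method,
        k_range=(int(ks.min()), int(ks.max())),
        r_squared=r2,
    )


def neighbour_deg_profile(network: TissueNetwork, protein: str) -> HubRecord:
    """Degree plus regulation-class tallies over a protein's neighbours."""
    if protein not in network.graph:
        raise KeyError(f"unknown protein {protein!r}")
    tallies = {"Up": 0, "Down": 0, "Mixed": 0}
    neighbours = list(network.graph.neighbors(protein))
    for nb in neighbours:
        cls = network.regulation(nb)
        if cls in tallies:
            tallies[cls] += 1
    return HubRecord(
        protein=protein,
        n_neighbours=len(neighbours),
        n_deg_neighbours=sum(tallies.values()),
        n_up=tallies["Up"],
        n_down=tallies["Down"],
        n_mixed=tallies["Mixed"],
    )


def rank_hubs(network: TissueNetwork, top_n: int | None = 50) -> list[HubRecord]:
    """Hub records in decreasing degree order (ties broken by symbol)."""
    if network.n_nodes == 0:
        raise ValueError("empty network")
    records = [neighbour_deg_profile(network, p) for p in network.nodes]
    records.sort(key=lambda r: (-r.n_neighbours, r.protein))
    return records if top_n is None else records[:top_n]


def select_key_hubs(
    records: list[HubRecord], *, min_neighbours: int = 27, min_degs: int = 7
) -> list[HubRecord]:
    """Hubs with many neighbours AND many DEGs among them."""
    return [
        r
        for r in records
        if r.n_neighbours >= min_neighbours and r.n_deg_neighbours >= min_degs
    ]


def extract_subnetwork(network: TissueNetwork, hub: str) -> TissueNetwork:
    """Induced subgraph on the hub and its immediate neighbours."""
    if hub not in network.graph:
        raise KeyError(f"unknown hub {hub!r}")
    nodes = {hub} | set(network.graph.neighbors(hub))
    return TissueNetwork(graph=network.graph.subgraph(nodes).copy())


def topology_summary(network: TissueNetwork, fit: PowerLawFit | None = None) -> dict:
    """Node/edge counts and the two per-node edge statistics.

    ``edges_per_node`` is |E|/|N| and ``mean_degree`` is 2|E|/|N| — distinct
    statistics that are easy to conflate when describing a network.
    """
    n, e = network.n_nodes, network.n_edges
    out = {
        "nodes": n,
        "edges": e,
        "edges_per_node": e / n if n else float("nan"),
        "mean_degree": 2 * e / n if n else float("nan"),
    }
    if fit is not None:
        out["power_law_alpha"] = fit.alpha
        out["power_law_method"] = fit.fit_method
    return out


def hub_table(records: list[HubRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein": r.protein,
                "neighbours": r.n_neighbours,
                "degs": r.n_deg_neighbours,
                "up_degs": r.n_up,
                "down_degs": r.n_down,
                "mixed_degs": r.n_mixed,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# export / import


def export_graph(network: TissueNetwork, path: str | Path, format: str = "graphml") -> None:
    """Write the network with its ``regulation`` node attribute.

    GraphML via networkx; XGMML (the Cytoscape exchange format) via lxml.
    Nodes and edges are emitted in sorted order so re-export is byte-stable.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        for node in network.nodes:
            g.add_node(node, regulation=network.regulation(node))
        for a, b in sorted(network.edges):
            g.add_edge(a, b, **network.graph.edges[a, b])
        nx.write_graphml(g, path)
    elif format == "xgmml":
        root = etree.Element(
            "graph",
            attrib={"label": "tissue-network", "directed": "0"},
            nsmap={None: "http://www.cs.rpi.edu/XGMML"},
        )
        for node in network.nodes:
            el = etree.SubElement(root, "node", attrib={"id": node, "label": node})
            etree.SubElement(
                el,
                "att",
                attrib={"name": "regulation", "type": "string",
                        "value": network.regulation(node)},
            )
        for a, b in sorted(network.edges):
            etree.SubElement(
                root, "edge", attrib={"source": a, "target": b, "label": f"{a}-{b}"}
            )
        etree.ElementTree(root).write(
            str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
        )
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_graph(path: str | Path, format: str = "graphml") -> TissueNetwork:
    """Parse a previously exported network back (round-trip counterpart)."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        g = nx.Graph(g)
        for node in g.nodes():
            g.nodes[node].setdefault("regulation", "NotDE")
        # networkx may read numeric-looking attrs; normalise edge attrs
        for _a, _b, attrs in g.edges(data=True):
            if "support" in attrs:
                attrs["support"] = int(attrs["support"])
        return TissueNetwork(graph=g)
    if format == "xgmml":
        tree = etree.parse(str(path))
        ns = {"x": "http://www.cs.rpi.edu/XGMML"}
        g = nx.Graph()
        for node in tree.findall("x:node", ns):
            attrs = {
                att.get("name"): att.get("value")
                for att in node.findall("x:att", ns)
            }
            g.add_node(node.get("id"), regulation=attrs.get("regulation", "NotDE"))
        for edge in tree.findall("x:edge", ns):
            g.add_edge(edge.get("source"), edge.get("target"))
        return TissueNetwork(graph=g)
    raise ValueError(f"unknown import format {format!r}")
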