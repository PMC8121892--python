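"""Fluvial network representation and along-network distances.

A river network is an undirected weighted graph (usually a dendritic tree)
of sampling sites and confluence nodes, with edge lengths in km and a
single designated outlet. All spatial quantities in the analysis —
pairwise site distances and distance to the outlet — are shortest-path
lengths along the channel network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd


class NetworkError(ValueError):
    """The network violates a structural requirement."""


@dataclass
class RiverNetwork:
    """Weighted site/confluence graph with one outlet.

    ``graph`` is an undirected networkx graph whose edges carry a
    ``length_km`` weight (> 0). ``outlet`` names the most-downstream node.
    Optional per-node attributes (altitude, width, river name) ride on the
    graph's node data.
    """

    graph: nx.Graph
    outlet: str
    site_attrs: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.outlet not in self.graph:
            raise NetworkError(f"outlet {self.outlet!r} is not a network node")
        if self.graph.number_of_nodes() and not nx.is_connected(self.graph):
            raise NetworkError("network is not connected")
        for u, v, data in self.graph.edges(data=True):
            if data.get("length_km", 0) <= 0:
                raise NetworkError(f"edge ({u!r}, {v!r}) has non-positive length")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def is_tree(self) -> bool:
        return nx.is_tree(self.graph)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        outlet: str,
        site_attrs: pd.DataFrame | None = None,
    ) -> "RiverNetwork":
        g = nx.Graph()
        for u, v, length in edges:
            g.add_edge(str(u), str(v), length_km=float(length))
        return cls(graph=g, outlet=str(outlet), site_attrs=site_attrs)

    @classmethod
    def from_csv(cls, edge_path: str | Path, node_path: str | Path | None = None) -> "RiverNetwork":
        """Load from an edge-list CSV (from_node,to_node,length_km).

        ``node_path`` optionally supplies per-node attributes with an
        ``is_outlet`` column flagging exactly one node; without it the
        edge file must carry an ``outlet`` column naming the outlet on
        every row.
        """
        edges = pd.read_csv(edge_path, dtype={"from_node": str, "to_node": str})
        attrs = None
        if node_path is not None:
            attrs = pd.read_csv(node_path, dtype={"node": str}).set_index("node")
            flagged = attrs.index[attrs["is_outlet"].astype(bool)].tolist()
            if len(flagged) != 1:
                raise NetworkError(f"expected exactly one outlet, got {flagged}")
            outlet = flagged[0]
        elif "outlet" in edges.columns:
            outlet = str(edges["outlet"].iloc[0])
        else:
            raise NetworkError("no node file and no outlet column in edge list")
        net = cls.from_edges(
            edges[["from_node", "to_node", "length_km"]].itertuples(index=False),
            outlet=outlet,
            site_attrs=attrs,
        )
        if attrs is not None:
            for node, row in attrs.iterrows():
                net.graph.nodes[node].update(row.to_dict())
        return net

    def to_csv(self, edge_path: str | Path, node_path: str | Path | None = None) -> None:
        rows = [
            {"from_node": u, "to_node": v, "length_km": d["length_km"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(edge_path, index=False)
        if node_path is not None:
            attrs = self.site_attrs
            if attrs is None:
                attrs = pd.DataFrame(index=pd.Index(self.nodes, name="node"))
            attrs = attrs.copy()
            attrs["is_outlet"] = [n == self.outlet for n in attrs.index]
            attrs.reset_index(names="node").to_csv(node_path, index=False)


def network_distance_matrix(net: RiverNetwork, sites: Sequence[str]) -> pd.DataFrame:
    """Symmetric matrix of along-network shortest-path distances (km)."""
    missing = [s for s in sites if s not in net.graph]
    if missing:
        raise NetworkError(f"sites not in network: {missing}")
    n = len(sites)
    mat = np.zeros((n, n))
    for i, s in enumerate(sites):
        lengths = nx.single_source_dijkstra_path_length(net.graph, s, weight="length_km")
        for j, t in enumerate(sites):
            mat[i, j] = lengths[t]
    mat = (mat + mat.T) / 2.0  # exact symmetry despite float summation order
    np.fill_diagonal(mat, 0.0)
    return pd.DataFrame(mat, index=list(sites), columns=list(sites))


def distance_to_outlet(net: RiverNetwork, sites: Sequence[str]) -> pd.Series:
    """Along-network distance (km) from each site to the outlet."""
    missing = [s for s in sites if s not in net.graph]
    if missing:
        raise NetworkError(f"sites not in network: {missing}")
    lengths = nx.single_source_dijkstra_path_length(net.graph, net.outlet, weight="length_km")
    return pd.Series([lengths[s] for s in sites], index=list(sites), name="distance_km")
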