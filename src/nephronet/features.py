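"""Graph feature engineering on perturbation networks.

Each patient's perturbation network is summarised at three levels:

* node level — the degree of every indicator node (F features);
* subgraph level — diameter of the largest connected component and the
  average clustering coefficient (2 features);
* global level — number of non-isolated nodes, number of edges, number of
  connected components among non-isolated nodes, and edge density
  (4 features).

With the default 40-indicator schema this yields exactly 46 named attributes
per patient; for an F-indicator schema the catalog length is F + 6.

Degenerate conventions keep every vector finite: an empty graph has diameter
0, density 0 and component count 0; nodes with degree < 2 contribute 0 to
the average clustering coefficient, which is averaged over all F nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .networks import SampleNetwork

LEVELS = ("node", "subgraph", "global")


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    level: str
    computation: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown feature level {self.level!r}")


@dataclass(frozen=True)
class FeatureCatalog:
    descriptors: tuple[FeatureDescriptor, ...]

    def __post_init__(self) -> None:
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def __len__(self) -> int:
        return len(self.descriptors)


def default_catalog(indicator_names: list[str]) -> FeatureCatalog:
    """F node degrees + 2 subgraph + 4 global summaries (46 for F=40)."""
    descriptors = [
        FeatureDescriptor(f"degree_{n}", "node", "degree") for n in indicator_names
    ]
    descriptors += [
        FeatureDescriptor("lcc_diameter", "subgraph", "diameter"),
        FeatureDescriptor("avg_clustering", "subgraph", "clustering"),
        FeatureDescriptor("n_nodes_nonisolated", "global", "node_count"),
        FeatureDescriptor("n_edges", "global", "edge_count"),
        FeatureDescriptor("n_components", "global", "component_count"),
        FeatureDescriptor("edge_density", "global", "density"),
    ]
    return FeatureCatalog(tuple(descriptors))


def extract_features(net: SampleNetwork, catalog: FeatureCatalog | None = None) -> pd.Series:
    """The named feature vector of one patient's perturbation network."""
    catalog = catalog or default_catalog(net.names)
    expected = {f"degree_{n}" for n in net.names}
    have = {d.name for d in catalog.descriptors if d.computation == "degree"}
    if have != expected:
        raise ValueError("catalog node features do not match the network schema")

    adj = net.adjacency
    f = len(net.names)
    degrees = adj.sum(axis=1).astype(float)
    n_edges = float(degrees.sum() / 2)
    g = net.graph()

    nonisolated = [n for n, d in g.degree() if d > 0]
    if nonisolated:
        sub = g.subgraph(nonisolated)
        components = list(nx.connected_components(sub))
        largest = max(components, key=len)
        diameter = float(nx.diameter(g.subgraph(largest))) if len(largest) > 1 else 0.0
        n_components = float(len(components))
    else:
        diameter = 0.0
        n_components = 0.0
    # clustering over all F nodes; degree<2 nodes contribute 0
    avg_clustering = float(np.mean(list(nx.clustering(g).values()))) if f else 0.0
    density = n_edges / (f * (f - 1) / 2) if f > 1 else 0.0

    values: dict[str, float] = {}
    for d in catalog.descriptors:
        if d.computation == "degree":
            values[d.name] = degrees[net.names.index(d.name[len("degree_"):])]
        elif d.computation == "diameter":
            values[d.name] = diameter
        elif d.computation == "clustering":
            values[d.name] = avg_clustering
        elif d.computation == "node_count":
            values[d.name] = float(len(nonisolated))
        elif d.computation == "edge_count":
            values[d.name] = n_edges
        elif d.computation == "component_count":
            values[d.name] = n_components
        elif d.computation == "density":
            values[d.name] = density
        else:
            raise ValueError(f"unknown computation tag {d.computation!r}")
    out = pd.Series(values, name=net.patient_id)[catalog.names]
    if not np.isfinite(out.to_numpy()).all():
        raise ValueError("non-finite feature encountered")
    return out


def feature_matrix(nets: list[SampleNetwork],
                   catalog: FeatureCatalog | None = None) -> pd.DataFrame:
    """Patients x features matrix over a list of perturbation networks."""
    if not nets:
        raise ValueError("no networks supplied")
    catalog = catalog or default_catalog(nets[0].names)
    return pd.DataFrame([extract_features(net, catalog) for net in nets])


def ego_network(net: SampleNetwork, hub: str, radius: int = 1) -> nx.Graph:
    """Induced subgraph on nodes within graph distance ``radius`` of ``hub``."""
    if hub not in net.names:
        raise KeyError(f"unknown hub indicator {hub!r}")
    return nx.ego_graph(net.graph(), hub, radius=radius)


def aggregate_cluster_network(
    nets: list[SampleNetwork], labels: pd.Series | dict
) -> dict[int, pd.DataFrame]:
    """Per-cluster edge-frequency networks.

    For each cluster, the weight of edge (i, j) is the fraction of that
    cluster's patients whose perturbation network contains the edge.
    Returns a dict mapping cluster label to an edge table with columns
    ``node_i, node_j, weight`` (only edges with weight > 0).
    """
    labels = pd.Series(labels)
    by_cluster: dict[int, list[SampleNetwork]] = {}
    for net in nets:
        if net.patient_id not in labels.index:
            raise KeyError(f"no cluster label for patient {net.patient_id}")
        by_cluster.setdefault(int(labels[net.patient_id]), []).append(net)
    for lbl in labels.unique():
        if int(lbl) not in by_cluster:
            raise ValueError(f"cluster {lbl} has no patients with networks")

    out: dict[int, pd.DataFrame] = {}
    for lbl, members in sorted(by_cluster.items()):
        names = members[0].names
        counts = np.zeros_like(members[0].adjacency, dtype=float)
        for net in members:
            if net.names != names:
                raise ValueError("networks must share one schema")
            counts += net.adjacency
        freq = counts / len(members)
        rows, cols = np.where(np.triu(freq, k=1) > 0)
        out[lbl] = pd.DataFrame({
            "node_i": [names[i] for i in rows],
            "node_j": [names[j] for j in cols],
            "weight": freq[rows, cols],
        })
    return out
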