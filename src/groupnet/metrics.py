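"""SRI-weighted network construction and the per-node metric suite.

The network view of an association matrix keeps an undirected edge for
every dyad whose SRI exceeds a threshold (default 0: any observed
association is a tie) with the SRI as edge weight.  Metric conventions:

* degree — binarized tie count (number of associates);
* eigenvector centrality — principal eigenvector of the *weighted*
  adjacency matrix, rescaled so the maximum node scores 1;
* betweenness centrality — unnormalized shortest-path pair counts, with
  geodesic length defined as the **sum of SRI weights** along the path
  (the sociogram convention used here); a conventional 1/weight
  distance is available via ``distance="inverse"``;
* clustering coefficient — unweighted local clustering on the
  binarized network; nodes with fewer than two ties are undefined (NaN)
  and excluded from species means;
* density — realized fraction of the n(n-1)/2 possible ties;
* average path length — mean weighted geodesic over reachable pairs.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .association import AssociationMatrix
from .observation import IndividualRecord, ValidationError

METRICS = ("degree", "eigenvector", "betweenness", "clustering")

_DISTANCE_MODES = ("weight", "inverse")


def build_network(
    matrix: AssociationMatrix,
    roster: Sequence[IndividualRecord] | None = None,
    threshold: float = 0.0,
) -> nx.Graph:
    """Threshold an association matrix into an annotated weighted graph.

    Edge rule: SRI strictly greater than ``threshold``.  All roster
    individuals appear as nodes even when isolated.
    """
    if threshold < 0:
        raise ValidationError("edge threshold must be non-negative")
    net = nx.Graph(threshold=threshold)
    attrs = {r.id: r for r in roster} if roster is not None else {}
    for ident in matrix.ids:
        rec = attrs.get(ident)
        if rec is not None:
            net.add_node(ident, species=rec.species, sex=rec.sex, group=rec.group)
        elif matrix.species is not None:
            net.add_node(ident, species=matrix.species[ident])
        else:
            net.add_node(ident)
    for a, b, value in matrix.dyads():
        if value > threshold:
            net.add_edge(a, b, weight=float(value))
    return net


def density(net: nx.Graph) -> float:
    """Fraction of possible ties present."""
    if net.number_of_nodes() < 2:
        raise ValidationError("density needs at least two nodes")
    return nx.density(net)


def degree_centrality(net: nx.Graph) -> dict[str, int]:
    """Binarized tie count per node."""
    return {node: int(deg) for node, deg in net.degree()}


def eigenvector_centrality(net: nx.Graph) -> dict[str, float]:
    """Principal eigenvector of the weighted adjacency, max scaled to 1.

    Computed on the full matrix; in a disconnected network the dominant
    component carries the mass and other components score near 0.
    """
    nodes = list(net.nodes)
    if not nodes:
        raise ValidationError("eigenvector centrality needs a non-empty network")
    adj = nx.to_numpy_array(net, nodelist=nodes, weight="weight")
    if not adj.any():
        warnings.warn("all-zero adjacency; eigenvector centrality is all zeros")
        return {node: 0.0 for node in nodes}
    eigvals, eigvecs = np.linalg.eigh(adj)
    vec = np.abs(eigvecs[:, int(np.argmax(eigvals))])
    vec /= vec.max()
    return {node: float(v) for node, v in zip(nodes, vec)}


def _distance_graph(net: nx.Graph, distance: str) -> nx.Graph:
    if distance not in _DISTANCE_MODES:
        raise ValidationError(f"distance must be one of {_DISTANCE_MODES}")
    work = net.copy()
    for _, _, data in work.edges(data=True):
        w = float(data["weight"])
        data["length"] = w if distance == "weight" else 1.0 / w
    return work


def betweenness_centrality(net: nx.Graph, distance: str = "weight") -> dict[str, float]:
    """Unnormalized betweenness with weighted geodesics.

    Equally short paths share credit equally (standard Brandes
    accounting); endpoints are not counted.
    """
    work = _distance_graph(net, distance)
    bc = nx.betweenness_centrality(work, normalized=False, weight="length")
    return {node: float(v) for node, v in bc.items()}


def clustering_coefficient(net: nx.Graph) -> dict[str, float]:
    """Unweighted local clustering; NaN for nodes with degree < 2."""
    raw = nx.clustering(net)
    return {
        node: (float(raw[node]) if deg >= 2 else float("nan"))
        for node, deg in net.degree()
    }


@dataclasses.dataclass(frozen=True)
class PathLengthSummary:
    mean: float
    sd: float
    n_pairs: int
    n_unreachable: int


def average_path_length(
    net: nx.Graph,
    subset: Sequence[str] | None = None,
    distance: str = "weight",
) -> PathLengthSummary:
    """Mean and sample SD of weighted geodesic lengths over node pairs.

    With ``subset`` given, pairs (i, j) with i in the subset and j any
    other node are averaged.  Unreachable pairs are excluded and counted.
    """
    work = _distance_graph(net, distance)
    lengths = dict(nx.all_pairs_dijkstra_path_length(work, weight="length"))
    nodes = list(net.nodes)
    chosen = set(subset) if subset is not None else set(nodes)
    unknown = chosen - set(nodes)
    if unknown:
        raise ValidationError(f"subset ids not in network: {sorted(unknown)}")
    values = []
    unreachable = 0
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if a not in chosen and b not in chosen:
                continue
            if b in lengths[a]:
                values.append(lengths[a][b])
            else:
                unreachable += 1
    if not values:
        raise ValidationError("no reachable pairs for average path length")
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return PathLengthSummary(float(arr.mean()), sd, arr.size, unreachable)


def node_metrics(net: nx.Graph, distance: str = "weight") -> pd.DataFrame:
    """Per-node metric table: degree, eigenvector, betweenness, clustering.

    Node attributes (species, sex, group) are carried along when present.
    """
    deg = degree_centrality(net)
    eig = eigenvector_centrality(net)
    bet = betweenness_centrality(net, distance=distance)
    clu = clustering_coefficient(net)
    rows = []
    for node, data in net.nodes(data=True):
        rows.append(
            {
                "id": node,
                "species": data.get("species"),
                "sex": data.get("sex"),
                "group": data.get("group"),
                "degree": deg[node],
                "eigenvector": eig[node],
                "betweenness": bet[node],
                "clustering": clu[node],
            }
        )
    return pd.DataFrame(rows).set_index("id")


def species_summary(metrics: pd.DataFrame, group_by: str = "species") -> pd.DataFrame:
    """Mean and sample SD per metric per species.

    Clustering means skip nodes with undefined (NaN) clustering.  The
    layout mirrors a per-species results table: one row per species,
    mean and sd columns for each of the four metrics.
    """
    if metrics[group_by].isna().any():
        raise ValidationError(f"every node needs a {group_by!r} label")
    out = {}
    for label, sub in metrics.groupby(group_by, sort=True):
        row = {}
        row["n"] = len(sub)
        for metric in METRICS:
            vals = sub[metric].dropna().to_numpy(dtype=float)
            row[f"{metric}_mean"] = float(vals.mean()) if vals.size else float("nan")
            row[f"{metric}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[label] = row
    df = pd.DataFrame(out).T
    df.index.name = group_by
    df["n"] = df["n"].astype(int)
    return df
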