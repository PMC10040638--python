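"""Co-occurrence networks and driver-taxon detection between disease states.

A per-group network is built by thresholding pairwise Spearman associations
between taxa (BH-adjusted significance plus an absolute-correlation floor).
Candidate *driver* taxa between a control network (benign polyps) and a case
network (stage-1 tumors) are nodes of the common sub-network whose
neighborhood rewires strongly — a neighbor-shift (NESH-style) score — and
whose shortest-path betweenness increases from control to case.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = [
    "GroupNetwork", "build_network", "common_subnetwork", "nesh_scores",
    "betweenness_change", "score_drivers", "identify_drivers",
    "write_edges", "read_edges",
]


@dataclass
class GroupNetwork:
    """Undirected co-occurrence graph for one sample group.

    Nodes are the prevalence-retained taxa (isolated nodes allowed); edges
    carry ``weight`` (signed association) and ``p_adj``.
    """

    group: str
    graph: nx.Graph

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    def neighbors(self, node) -> set:
        if node not in self.graph:
            raise InputError(f"node {node!r} absent from {self.group} network")
        return set(self.graph.neighbors(node))


def build_network(
    profile: pd.DataFrame,
    group: str = "",
    method: str = "spearman",
    min_prevalence: float = 0.3,
    rho_threshold: float = 0.6,
    correction: str = "BH",
    alpha: float = 0.05,
) -> GroupNetwork:
    """Build one group's co-occurrence network from its abundance profile.

    ``profile`` is samples x taxa for that group only.  Taxa present in
    fewer than ``min_prevalence`` of samples are dropped; an edge requires
    |Spearman rho| >= ``rho_threshold`` and BH-adjusted p <= ``alpha``
    (p from the t approximation).  Requires >= 5 samples.
    """
    if method != "spearman":
        raise InputError(f"unsupported association method {method!r}")
    n = profile.shape[0]
    if n < 5:
        raise InputError("association networks need at least 5 samples per group")
    prevalence = (profile > 0).mean(axis=0)
    keep = profile.columns[prevalence >= min_prevalence]
    sub = profile[keep].to_numpy(dtype=float)
    g = nx.Graph()
    g.add_nodes_from(keep)
    if len(keep) >= 2:
        rho, p = stats.spearmanr(sub)
        if np.ndim(rho) == 0:  # exactly two columns -> scalars
            rho = np.array([[1.0, rho], [rho, 1.0]])
            p = np.array([[0.0, p], [p, 0.0]])
        iu = np.triu_indices(len(keep), k=1)
        pvals = p[iu]
        # constant columns yield NaN correlations; treat as no association
        valid = np.isfinite(pvals)
        p_adj = np.full(len(pvals), np.nan)
        if valid.any():
            p_adj[valid] = multipletests(pvals[valid], method="fdr_bh")[1]
        for (i, j), r, q in zip(zip(*iu), rho[iu], p_adj):
            if np.isfinite(r) and abs(r) >= rho_threshold and q <= alpha:
                g.add_edge(keep[i], keep[j], weight=float(r), p_adj=float(q))
    return GroupNetwork(group=group, graph=g)


@dataclass
class CommonSubnetwork:
    nodes: set                      # node-set intersection
    control_edges: set              # induced edges, per network
    case_edges: set
    control_boundary: set           # outside nodes adjacent to the common set
    case_boundary: set


def common_subnetwork(control: GroupNetwork, case: GroupNetwork) -> CommonSubnetwork:
    """Intersect node sets and report each network's induced edges.

    Nodes outside the intersection but directly adjacent to it are flagged
    per network (the "boundary" of the common sub-network).
    """
    nodes = control.nodes & case.nodes

    def induced(net: GroupNetwork) -> set:
        return {
            frozenset((u, v))
            for u, v in net.graph.edges
            if u in nodes and v in nodes
        }

    def boundary(net: GroupNetwork) -> set:
        out = set()
        for u, v in net.graph.edges:
            if (u in nodes) != (v in nodes):
                out.add(v if u in nodes else u)
        return out

    return CommonSubnetwork(
        nodes=nodes,
        control_edges=induced(control),
        case_edges=induced(case),
        control_boundary=boundary(control),
        case_boundary=boundary(case),
    )


def nesh_scores(control: GroupNetwork, case: GroupNetwork, nodes) -> pd.Series:
    """Neighbor-shift score per node, in [0, 2].

    With A the control neighbors and B the case neighbors:
    ``score = (1 - |A∩B|/|A∪B|) + |B\\A|/|A∪B|`` — the Jaccard distance
    between neighborhoods plus the case-gained fraction, 0 when both
    neighborhoods are empty.  An unchanged nonempty neighborhood scores 0;
    a fully case-gained one scores 2.
    """
    out = {}
    for node in nodes:
        a = control.neighbors(node)
        b = case.neighbors(node)
        union = a | b
        if not union:
            out[node] = 0.0
            continue
        jacc = len(a & b) / len(union)
        gained = len(b - a) / len(union)
        out[node] = (1.0 - jacc) + gained
    return pd.Series(out, name="nesh_score")


def betweenness_change(control: GroupNetwork, case: GroupNetwork,
                       nodes) -> pd.DataFrame:
    """Normalized shortest-path betweenness in each full group network.

    Computed on the unweighted thresholded graphs; ``increased`` is a strict
    case-over-control comparison.
    """
    b_control = nx.betweenness_centrality(control.graph, normalized=True)
    b_case = nx.betweenness_centrality(case.graph, normalized=True)
    rows = []
    for node in nodes:
        bc = b_control.get(node, 0.0)
        bk = b_case.get(node, 0.0)
        rows.append((node, bc, bk, bk > bc))
    return pd.DataFrame(
        rows, columns=["taxon", "betweenness_control", "betweenness_case",
                       "increased"]
    ).set_index("taxon")


def score_drivers(control: GroupNetwork, case: GroupNetwork) -> pd.DataFrame:
    """Per-common-node driver records: neighborhoods, NESH, betweenness.

    Community membership (greedy modularity on the case network) is attached
    for reporting.
    """
    common = common_subnetwork(control, case)
    nodes = sorted(common.nodes)
    if not nodes:
        return pd.DataFrame(
            columns=["n_neighbors_control", "n_neighbors_case", "nesh_score",
                     "betweenness_control", "betweenness_case", "increased",
                     "community"]
        )
    nesh = nesh_scores(control, case, nodes)
    btw = betweenness_change(control, case, nodes)
    communities = nx.algorithms.community.greedy_modularity_communities(case.graph)
    comm_of = {}
    for ci, members in enumerate(communities):
        for m in members:
            comm_of[m] = ci
    records = pd.DataFrame(index=pd.Index(nodes, name="taxon"))
    records["n_neighbors_control"] = [len(control.neighbors(n)) for n in nodes]
    records["n_neighbors_case"] = [len(case.neighbors(n)) for n in nodes]
    records["nesh_score"] = nesh.loc[nodes]
    records[["betweenness_control", "betweenness_case", "increased"]] = btw.loc[
        nodes, ["betweenness_control", "betweenness_case", "increased"]
    ]
    records["community"] = [comm_of.get(n, -1) for n in nodes]
    return records


def identify_drivers(records: pd.DataFrame,
                     score_quantile: float = 0.90) -> pd.DataFrame:
    """Flag drivers: NESH at/above the score quantile AND increased betweenness."""
    if records.empty:
        out = records.copy()
        out["driver"] = pd.Series(dtype=bool)
        return out
    threshold = float(np.quantile(records["nesh_score"], score_quantile))
    out = records.copy()
    out["nesh_threshold"] = threshold
    out["driver"] = (out["nesh_score"] >= threshold) & out["increased"].astype(bool)
    return out


def write_edges(path, network: GroupNetwork) -> None:
    rows = [
        (u, v, d.get("weight", np.nan), d.get("p_adj", np.nan))
        for u, v, d in network.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "p_adj"]).to_csv(
        path, sep="\t", index=False
    )


def read_edges(path, group: str = "") -> GroupNetwork:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(row["node_a"], row["node_b"], weight=row["weight"],
                   p_adj=row["p_adj"])
    return GroupNetwork(group=group, graph=g)
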