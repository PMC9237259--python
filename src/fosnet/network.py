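"""Interregional correlation networks, thresholding, centralities, and hubs.

A per-group functional network is the region x region matrix of cross-animal
correlations of c-Fos activity. Graphs are obtained by strict thresholding
(signed r > tau by default; absolute mode is available); node degree is the
binary count of supra-threshold edges and betweenness is unweighted
shortest-path betweenness on the binarized graph. Hubs are regions that
jointly satisfy a degree floor (>= 5) and a betweenness rank criterion
(top 10 of 30 regions, i.e. the top third), with boundary ties included.

Two correlation backends are provided. The default is plain Pearson (or
Spearman) across the animals of one group. The alternative is a
mean-centered task partial-least-squares (PLS) decomposition of the
group-mean deviation matrix, with permutation tests on the singular values
and within-group bootstrap salience ratios; its derived network correlates
the regions' rank-limited LV reconstructions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import MOTOR_REGIONS, CohortMatrix, ValidationError
from .stats import pearson_matrix

__all__ = [
    "CorrelationNetwork",
    "ThresholdedGraph",
    "PLSResult",
    "interregional_correlation",
    "pls_lv_correlation",
    "threshold_network",
    "degree_centrality",
    "betweenness_centrality",
    "edge_betweenness",
    "identify_hubs",
    "hub_overlap",
    "motor_subnetwork",
    "ego_network",
]


@dataclass
class CorrelationNetwork:
    """Symmetric region x region correlation weights for one group."""

    group: str
    regions: list[str]
    weights: pd.DataFrame
    method: str = "pearson"
    n_animals: int = 0

    def __post_init__(self) -> None:
        w = self.weights
        if list(w.index) != self.regions or list(w.columns) != self.regions:
            raise ValidationError("weights not aligned to the region list")
        arr = w.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, equal_nan=True, atol=1e-12):
            raise ValidationError("weights must be symmetric")
        if np.nanmax(np.abs(arr)) > 1 + 1e-9:
            raise ValidationError("|weights| must not exceed 1")

    def weight(self, a: str, b: str) -> float:
        return float(self.weights.at[a, b])

    def restrict(self, regions: Sequence[str]) -> "CorrelationNetwork":
        missing = [r for r in regions if r not in self.regions]
        if missing:
            raise ValidationError(f"regions absent from network: {missing}")
        sub = self.weights.loc[list(regions), list(regions)]
        return CorrelationNetwork(group=self.group, regions=list(regions),
                                  weights=sub, method=self.method,
                                  n_animals=self.n_animals)


@dataclass
class ThresholdedGraph:
    """Graph after applying an edge threshold; isolated nodes are retained."""

    graph: nx.Graph
    tau: float
    mode: str = "signed"
    group: str = ""
    n_missing_pairs: int = 0

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> list[tuple[str, str, float]]:
        return [(u, v, float(d["weight"]))
                for u, v, d in sorted(self.graph.edges(data=True))]


@dataclass
class PLSResult:
    """Mean-centered task-PLS decomposition with resampling diagnostics.

    ``singular_values`` are non-increasing; ``perm_p[i]`` is the permutation
    probability that a label-shuffled singular value meets or exceeds the
    observed one; ``bootstrap_ratio`` (region x LV) is salience mean / SD
    over within-group bootstrap resamples; ``saliences`` are the region
    weights (right singular vectors) and ``scores`` the per-animal LV
    projections.
    """

    singular_values: np.ndarray
    perm_p: np.ndarray
    saliences: pd.DataFrame
    bootstrap_ratio: pd.DataFrame
    scores: pd.DataFrame
    n_perm: int
    n_boot: int


def interregional_correlation(
    cohort: CohortMatrix,
    group: str,
    method: str = "pearson",
) -> CorrelationNetwork:
    """Region x region correlation of activity across one group's animals.

    Zero-variance regions produce NaN weights for their pairs (reported, not
    zeroed) with a warning naming the region.
    """
    if method not in {"pearson", "spearman"}:
        raise ValidationError(f"unsupported method {method!r}")
    act = cohort.activity(group)
    if len(act) < 3:
        raise ValidationError(
            f"group {group!r} has {len(act)} animals; need at least 3"
        )
    flat = [r for r in cohort.regions if act[r].std() == 0.0]
    if flat:
        warnings.warn(
            f"zero-variance region(s) {flat} in group {group!r}: their "
            "correlations are undefined and reported as missing",
            UserWarning, stacklevel=2,
        )
    w = act.corr(method=method)
    arr = w.to_numpy()
    np.fill_diagonal(arr, 1.0)
    w = pd.DataFrame(arr, index=w.index, columns=w.columns)
    return CorrelationNetwork(group=group, regions=list(cohort.regions),
                              weights=w, method=method, n_animals=len(act))


def _group_mean_deviation(x: np.ndarray, labels: np.ndarray,
                          groups: list) -> np.ndarray:
    means = np.stack([x[labels == g].mean(axis=0) for g in groups])
    return means - x.mean(axis=0)


def pls_lv_correlation(
    cohort: CohortMatrix,
    groups: Sequence[str] | None = None,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    group: str | None = None,
) -> tuple[PLSResult, CorrelationNetwork]:
    """Task PLS across groups plus a derived interregional network.

    The group-mean deviation matrix (groups x regions, grand-mean centered)
    is decomposed by SVD; each latent variable pairs a group contrast with a
    region salience pattern. Permutation p-values shuffle group labels;
    bootstrap ratios resample animals within groups with sign alignment to
    the observed saliences. The derived network holds Pearson correlations
    between the regions' rank-(k) LV reconstructions across animals of one
    group (default: all animals pooled), tagged ``method='pls_lv'``.
    """
    if n_perm < 100 or n_boot < 100:
        raise ValidationError("n_perm and n_boot must be at least 100")
    group_list = list(groups) if groups is not None else list(cohort.groups)
    group_list = [g for g in group_list if (cohort.data["group"] == g).any()]
    if len(group_list) < 2:
        raise ValidationError("PLS needs at least two non-empty groups")
    x = cohort.activity().to_numpy(dtype=float)
    labels = cohort.data["group"].to_numpy()
    keep = np.isin(labels, group_list)
    x, labels = x[keep], labels[keep]
    regions = list(cohort.regions)
    rng = np.random.default_rng(seed)

    m = _group_mean_deviation(x, labels, group_list)
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    k = min(len(group_list) - 1, len(regions))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    v = vt.T  # regions x k saliences

    # permutation test on singular values
    exceed = np.zeros(k)
    for _ in range(n_perm):
        perm_labels = rng.permutation(labels)
        sp = np.linalg.svd(
            _group_mean_deviation(x, perm_labels, group_list),
            compute_uv=False,
        )[:k]
        exceed += sp >= s
    perm_p = (1.0 + exceed) / (1.0 + n_perm)

    # within-group bootstrap of saliences, sign-aligned per LV
    boot = np.zeros((n_boot, len(regions), k))
    group_idx = {g: np.flatnonzero(labels == g) for g in group_list}
    for b in range(n_boot):
        take = np.concatenate([
            rng.choice(idx, size=idx.size, replace=True)
            for idx in group_idx.values()
        ])
        xb, lb = x[take], labels[take]
        _, _, vbt = np.linalg.svd(
            _group_mean_deviation(xb, lb, group_list), full_matrices=False
        )
        vb = vbt[:k].T
        signs = np.sign(np.einsum("rk,rk->k", v, vb))
        signs[signs == 0] = 1.0
        boot[b] = vb * signs
    boot_sd = boot.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(boot_sd > 0, boot.mean(axis=0) / boot_sd, 0.0)

    scores = x @ v  # animals x k brain scores
    lv_cols = [f"LV{i + 1}" for i in range(k)]
    result = PLSResult(
        singular_values=s,
        perm_p=perm_p,
        saliences=pd.DataFrame(v, index=regions, columns=lv_cols),
        bootstrap_ratio=pd.DataFrame(ratio, index=regions, columns=lv_cols),
        scores=pd.DataFrame(scores, index=cohort.data.index[keep],
                            columns=lv_cols),
        n_perm=n_perm,
        n_boot=n_boot,
    )

    # derived network: correlate rank-k reconstructions of region activity
    if group is not None:
        sel = labels == group
        tag_group = group
    else:
        sel = np.ones(len(labels), dtype=bool)
        tag_group = "+".join(group_list)
    xc = x[sel] - x[sel].mean(axis=0)
    recon = (xc @ v) @ v.T
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.corrcoef(recon, rowvar=False)
    w = np.clip(w, -1.0, 1.0)
    np.fill_diagonal(w, 1.0)
    net = CorrelationNetwork(
        group=tag_group, regions=regions,
        weights=pd.DataFrame(w, index=regions, columns=regions),
        method="pls_lv", n_animals=int(sel.sum()),
    )
    return result, net


def threshold_network(
    network: CorrelationNetwork,
    tau: float,
    mode: str = "signed",
) -> ThresholdedGraph:
    """Binarize a correlation network with the strict rule weight > tau.

    ``signed`` keeps edges with r > tau; ``absolute`` keeps |r| > tau. Every
    region stays as a node even when isolated. NaN weights are skipped and
    counted in ``n_missing_pairs``.
    """
    if not 0.0 < tau < 1.0:
        raise ValidationError(f"tau must lie in (0, 1), got {tau}")
    if mode not in {"signed", "absolute"}:
        raise ValidationError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    g = nx.Graph()
    for region in network.regions:
        g.add_node(region)
    missing = 0
    arr = network.weights.to_numpy(dtype=float)
    for i, a in enumerate(network.regions):
        for j in range(i + 1, len(network.regions)):
            w = arr[i, j]
            if np.isnan(w):
                missing += 1
                continue
            value = abs(w) if mode == "absolute" else w
            if value > tau:
                g.add_edge(a, network.regions[j], weight=float(w))
    return ThresholdedGraph(graph=g, tau=tau, mode=mode, group=network.group,
                            n_missing_pairs=missing)


def degree_centrality(
    graph: ThresholdedGraph, weighted: bool = False
) -> dict[str, float]:
    """Edge count per node (default) or summed |weight| strength."""
    g = graph.graph
    if weighted:
        return {node: float(sum(abs(d["weight"]) for _, _, d in
                                g.edges(node, data=True)))
                for node in g.nodes}
    return {node: int(deg) for node, deg in g.degree()}


def betweenness_centrality(
    graph: ThresholdedGraph, weighted: bool = False
) -> dict[str, float]:
    """Unnormalized shortest-path betweenness on the binarized graph.

    Each unordered node pair contributes once. With ``weighted=True``,
    shortest paths use the distance 1 - r instead of hop count.
    """
    g = graph.graph
    if weighted:
        dist = nx.Graph()
        dist.add_nodes_from(g.nodes)
        dist.add_weighted_edges_from(
            (u, v, 1.0 - d["weight"]) for u, v, d in g.edges(data=True)
        )
        bc = nx.betweenness_centrality(dist, normalized=False, weight="weight")
    else:
        bc = nx.betweenness_centrality(g, normalized=False)
    return {node: float(val) for node, val in bc.items()}


def edge_betweenness(graph: ThresholdedGraph) -> dict[tuple[str, str], float]:
    """Unnormalized shortest-path betweenness per edge."""
    bc = nx.edge_betweenness_centrality(graph.graph, normalized=False)
    return {tuple(sorted(edge)): float(val) for edge, val in bc.items()}


def _min_rank_desc(values: pd.Series) -> pd.Series:
    return values.rank(method="min", ascending=False).astype(int)


def identify_hubs(
    graph: ThresholdedGraph,
    degree_min: int = 5,
    betweenness_top_k: int = 10,
) -> pd.DataFrame:
    """Joint degree/betweenness hub report for every node.

    A region qualifies on degree when its edge count is at least
    ``degree_min``, and on betweenness when its descending min-rank is within
    ``betweenness_top_k`` (ties at the boundary are all included). A hub
    satisfies both. Columns: degree, betweenness, degree_rank,
    betweenness_rank, degree_qualified, betweenness_qualified, hub.
    """
    if graph.graph.number_of_nodes() == 0:
        raise ValidationError("graph has no nodes")
    deg = pd.Series(degree_centrality(graph), name="degree")
    btw = pd.Series(betweenness_centrality(graph), name="betweenness")
    report = pd.concat([deg, btw], axis=1)
    report["degree_rank"] = _min_rank_desc(report["degree"])
    report["betweenness_rank"] = _min_rank_desc(report["betweenness"])
    report["degree_qualified"] = report["degree"] >= degree_min
    report["betweenness_qualified"] = report["betweenness_rank"] <= betweenness_top_k
    report["hub"] = report["degree_qualified"] & report["betweenness_qualified"]
    report.index.name = "region"
    return report


def hub_overlap(
    degree_qualified: Sequence[str] | frozenset,
    betweenness_qualified: Sequence[str] | frozenset,
) -> set[str]:
    """Regions qualifying on both criteria (the Venn-diagram intersection)."""
    return set(degree_qualified) & set(betweenness_qualified)


def motor_subnetwork(
    network: CorrelationNetwork,
    tau: float = 0.5,
    regions: Sequence[str] = MOTOR_REGIONS,
) -> ThresholdedGraph:
    """Threshold the network restricted to the motor-circuit regions."""
    missing = [r for r in regions if r not in network.regions]
    if missing:
        raise ValidationError(f"motor region(s) missing from network: {missing}")
    return threshold_network(network.restrict(regions), tau=tau, mode="signed")


def ego_network(graph: ThresholdedGraph, center: str = "M1") -> ThresholdedGraph:
    """Seed-centered subgraph with centralities computed on the full graph.

    Returns the subgraph induced by the center and its direct neighbors.
    Node betweenness and edge betweenness are computed on the *full* graph
    first and attached as ``betweenness`` attributes, so the seed view keeps
    whole-network context.
    """
    g = graph.graph
    if center not in g:
        raise ValidationError(f"unknown center region {center!r}")
    node_btw = betweenness_centrality(graph)
    edge_btw = edge_betweenness(graph)
    members = [center] + sorted(g.neighbors(center))
    sub = g.subgraph(members).copy()
    for node in sub.nodes:
        sub.nodes[node]["betweenness"] = node_btw[node]
    for u, v in sub.edges:
        sub.edges[u, v]["betweenness"] = edge_btw[tuple(sorted((u, v)))]
    return ThresholdedGraph(graph=sub, tau=graph.tau, mode=graph.mode,
                            group=graph.group)
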