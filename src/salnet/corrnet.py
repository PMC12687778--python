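"""Kendall-tau saliency correlation networks across brain regions.

Pipeline: pairwise tau-b between region-saliency columns (across subjects,
severity groups pooled) -> significance filter (p < alpha, default 0.01)
and tau threshold -> graph with per-node degrees -> top-edge tables, a
seeded spring layout whose edge attraction grows with tau (so an edge's
rest length tracks 1 - tau), hub rankings swept over tau thresholds
0.1–0.6, and composition statistics (within-lobe, per-lobe, hemisphere and
cortico-subcortical fractions).

The tau variant is tau-b (tie-corrected).  Significance is exact for small
samples (<= 9 subjects: full permutation enumeration) and the tie-corrected
normal approximation otherwise.  Only positive correlations pass the
default filter (tau > threshold); an absolute-value mode is available.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .core import RegionSaliencyMatrix, ValidationError

__all__ = [
    "CorrelationEdge", "CorrelationGraph", "kendall_tau",
    "pairwise_region_correlations", "filter_edges", "top_edges",
    "spring_layout", "hub_ranking", "composition_stats",
    "DEFAULT_THRESHOLDS",
]

logger = logging.getLogger(__name__)

#: The tau-threshold sweep: 0.1–0.6 in steps of 0.1 (divisor 6 in averaged
#: summaries).  A 0.0 threshold can be requested explicitly.
DEFAULT_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)

EXACT_P_MAX_N = 9


@dataclass(frozen=True)
class CorrelationEdge:
    region_a: int
    region_b: int
    tau: float
    p: float

    def __post_init__(self) -> None:
        if self.region_a >= self.region_b:
            raise ValidationError("edges are stored with region_a < region_b")


def _tau_b(x: np.ndarray, y: np.ndarray) -> float:
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic)


def _exact_p(x: np.ndarray, y: np.ndarray, tau_obs: float) -> float:
    """Two-sided exact permutation p-value for tau-b (small n only)."""
    n = len(x)
    perms = np.array(list(itertools.permutations(range(n))))
    yp = y[perms]  # (n!, n)
    i, j = np.triu_indices(n, k=1)
    sx = np.sign(x[j] - x[i])
    sy = np.sign(yp[:, j] - yp[:, i])
    num = (sx[None, :] * sy).sum(axis=1).astype(float)
    n0 = n * (n - 1) / 2
    tx = n0 - np.count_nonzero(sx)
    ty = n0 - np.count_nonzero(sy[0])  # tie pattern is permutation-invariant
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    if denom == 0:
        return float("nan")
    taus = num / denom
    return float(np.mean(np.abs(taus) >= abs(tau_obs) - 1e-12))


def kendall_tau(x, y):
    """Tie-corrected Kendall tau-b with a two-sided significance.

    For n <= 9 the p-value is an exact enumeration over all permutations of
    ``y``; beyond that, the tie-corrected normal approximation.  Constant
    inputs have no defined rank correlation: returns ``(nan, nan)`` with a
    warning so callers can exclude the pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("kendall_tau expects two equal-length 1D vectors")
    if len(x) < 3:
        raise ValidationError("kendall_tau requires length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("kendall_tau requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Kendall tau undefined", UserWarning,
                      stacklevel=2)
        return float("nan"), float("nan")
    if len(x) <= EXACT_P_MAX_N:
        tau = _tau_b(x, y)
        return tau, _exact_p(x, y, tau)
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _scope_ids(matrix: RegionSaliencyMatrix, scope: str):
    if matrix.regions is None:
        raise ValidationError("matrix carries no region table; scope unavailable")
    cort = set(matrix.regions.loc[matrix.regions["is_cortical"], "region_id"])
    ids = list(matrix.region_ids)
    if scope == "cortical-cortical":
        keep = [i for i in ids if i in cort]
        return keep, lambda a, b: True
    if scope == "cortical-subcortical":
        return ids, lambda a, b: (a in cort) != (b in cort) or (a not in cort and b not in cort)
    if scope == "all":
        return ids, lambda a, b: True
    raise ValidationError(f"unknown scope {scope!r}")


def pairwise_region_correlations(matrix: RegionSaliencyMatrix,
                                 scope: str = "cortical-cortical"):
    """One tau-b edge per unordered region pair in scope, across subjects.

    High and low severity subjects are pooled (controls, if present in the
    matrix, participate as well only when explicitly included upstream; the
    pipeline passes scored subjects).  Constant columns are skipped with a
    logged warning.

    Scopes: ``cortical-cortical`` (the default cross-regional analysis),
    ``cortical-subcortical`` (cortico-subcortical plus subcortico-
    subcortical pairs), ``all``.
    """
    if matrix.values.shape[0] < 3:
        raise ValidationError("pairwise correlations require >= 3 subjects")
    ids, pair_ok = _scope_ids(matrix, scope)
    pos = {r: i for i, r in enumerate(matrix.region_ids)}
    cols = {r: matrix.values[:, pos[r]] for r in ids}
    constant = {r for r in ids if np.ptp(cols[r]) == 0}
    for r in constant:
        logger.warning("region %s has constant saliency; its pairs are skipped", r)
    edges = []
    n = matrix.values.shape[0]
    use_exact = n <= EXACT_P_MAX_N
    for a, b in itertools.combinations(ids, 2):
        if a in constant or b in constant or not pair_ok(a, b):
            continue
        if use_exact:
            tau, p = kendall_tau(cols[a], cols[b])
        else:
            res = stats.kendalltau(cols[a], cols[b], variant="b", method="asymptotic")
            tau, p = float(res.statistic), float(res.pvalue)
        edges.append(CorrelationEdge(int(min(a, b)), int(max(a, b)), tau, p))
    return edges


@dataclass
class CorrelationGraph:
    """Significance- and threshold-filtered region graph."""

    graph: nx.Graph
    alpha: float
    tau_threshold: float

    @property
    def degrees(self) -> dict:
        return {n: d for n, d in self.graph.degree()}

    @property
    def edges(self):
        return [CorrelationEdge(min(a, b), max(a, b), d["tau"], d["p"])
                for a, b, d in self.graph.edges(data=True)]

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def filter_edges(edges: Sequence[CorrelationEdge], alpha: float = 0.01,
                 tau_threshold: float = 0.4,
                 matrix: Optional[RegionSaliencyMatrix] = None,
                 absolute: bool = False) -> CorrelationGraph:
    """Keep edges with p < alpha and tau > threshold; recompute degrees.

    Nodes are all regions of ``matrix`` (so isolated regions keep degree 0)
    when a matrix is given, else the regions incident to surviving edges.
    ``absolute=True`` thresholds |tau| instead (negative correlations kept).
    """
    if not 0.0 <= tau_threshold <= 1.0:
        raise ValidationError("tau_threshold must be in [0, 1]")
    G = nx.Graph()
    if matrix is not None and matrix.regions is not None:
        for _, row in matrix.regions.iterrows():
            if row["region_id"] in set(matrix.region_ids):
                G.add_node(int(row["region_id"]),
                           hemisphere=row["hemisphere"], lobe=row["lobe"],
                           is_cortical=bool(row["is_cortical"]),
                           network=row["network"], name=row["name"])
    for e in edges:
        stat = abs(e.tau) if absolute else e.tau
        if e.p < alpha and stat > tau_threshold:
            G.add_edge(e.region_a, e.region_b, tau=e.tau, p=e.p)
    return CorrelationGraph(graph=G, alpha=alpha, tau_threshold=tau_threshold)


def top_edges(edges: Sequence[CorrelationEdge], n: int = 500):
    """The n largest-tau edges, deterministically tie-broken.

    Sort key: tau descending, then p ascending, then (region_a, region_b).
    If fewer than n edges exist, all are returned (logged).
    """
    ranked = sorted(edges, key=lambda e: (-e.tau, e.p, e.region_a, e.region_b))
    if len(ranked) < n:
        logger.info("top_edges: only %d edges available (requested %d)",
                    len(ranked), n)
    return ranked[:n]


def spring_layout(graph: CorrelationGraph, seed: int = 0) -> dict:
    """Seeded force-directed layout; high-tau edges pull nodes together.

    The attraction weight of an edge is its tau (clipped positive), so the
    realised edge length tracks 1 - tau and well-connected regions drift to
    the centre.  Returns {node: (x, y)}; node degree doubles as marker size.
    """
    G = graph.graph
    if G.number_of_nodes() == 0:
        raise ValidationError("cannot lay out an empty graph")
    H = nx.Graph()
    H.add_nodes_from(G.nodes)
    for a, b, d in G.edges(data=True):
        H.add_edge(a, b, attraction=max(d["tau"], 1e-6))
    # scale=None keeps raw equilibrium coordinates, so realised distances
    # remain comparable across graphs (strong edges genuinely sit shorter)
    pos = nx.spring_layout(H, weight="attraction", seed=seed, scale=None)
    return {n: (float(x), float(y)) for n, (x, y) in pos.items()}


def hub_ranking(matrix: RegionSaliencyMatrix,
                edges: Optional[Sequence[CorrelationEdge]] = None,
                thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                top_n: int = 50, alpha: float = 0.01,
                scope: str = "cortical-cortical"):
    """Per-threshold top-n hub tables plus the threshold-averaged ranking.

    For each threshold: degree per region in the filtered graph; the top_n
    regions by degree (ties: higher mean tau of incident edges first, then
    region id).  The averaged table sums each region's degrees over the
    per-threshold top-n tables it appears in and divides by the *number of
    thresholds* (6 for the default sweep), then re-ranks.
    """
    thresholds = tuple(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValidationError("thresholds must be strictly increasing")
    if edges is None:
        edges = pairwise_region_correlations(matrix, scope=scope)
    scoped_ids, _ = _scope_ids(matrix, scope)
    per_threshold = {}
    summed = {}
    for thr in thresholds:
        g = filter_edges(edges, alpha=alpha, tau_threshold=thr, matrix=None)
        deg = {int(r): 0 for r in scoped_ids}
        deg.update(dict(g.graph.degree()))
        mean_tau = {}
        for node in g.graph.nodes:
            taus = [d["tau"] for _, _, d in g.graph.edges(node, data=True)]
            mean_tau[node] = float(np.mean(taus)) if taus else 0.0
        ranked = sorted(deg, key=lambda r: (-deg[r], -mean_tau.get(r, 0.0), r))[:top_n]
        per_threshold[thr] = [
            {"region_id": int(r), "degree": int(deg[r]),
             "mean_tau": mean_tau.get(r, 0.0)}
            for r in ranked
        ]
        for row in per_threshold[thr]:
            summed[row["region_id"]] = summed.get(row["region_id"], 0) + row["degree"]
    divisor = len(thresholds)
    averaged = [
        {"region_id": int(r), "average_degree": s / divisor}
        for r, s in summed.items()
    ]
    averaged.sort(key=lambda row: (-row["average_degree"], row["region_id"]))
    return {"per_threshold": per_threshold, "averaged": averaged[:top_n],
            "divisor": divisor}


def composition_stats(graph: CorrelationGraph) -> dict:
    """Edge-composition fractions of a filtered graph.

    * ``within_lobe_fraction``: edges joining two regions of the same lobe
      *and* hemisphere, over all edges;
    * ``lobe_fractions``: per (hemisphere, lobe) share of within-lobe edges
      relative to all edges;
    * ``hemisphere_fractions``: shares of edges lying within L, within R,
      or crossing;
    * ``subcortical_attachment``: among edges touching a subcortical
      region, the shares attached to LH cortex, RH cortex, or staying
      within the subcortical set (meaningful on the cortical-subcortical
      scope graph).

    An empty graph yields ``None`` fractions (undefined, not zero).
    """
    G = graph.graph
    edges = list(G.edges)
    out = {"n_edges": len(edges), "within_lobe_fraction": None,
           "lobe_fractions": {}, "hemisphere_fractions": None,
           "subcortical_attachment": None}
    if not edges:
        return out
    need = {"hemisphere", "lobe", "is_cortical"}
    for n, d in G.nodes(data=True):
        if not need <= set(d):
            raise ValidationError(
                f"node {n} lacks hemisphere/lobe attributes required for "
                "composition statistics"
            )
    attr = dict(G.nodes(data=True))
    same_lobe = 0
    lobe_counts = {}
    hemi_counts = {"L": 0, "R": 0, "cross": 0}
    for a, b in edges:
        da, db = attr[a], attr[b]
        if da["hemisphere"] == db["hemisphere"] and da["lobe"] == db["lobe"]:
            same_lobe += 1
            key = (da["hemisphere"], da["lobe"])
            lobe_counts[key] = lobe_counts.get(key, 0) + 1
        if da["hemisphere"] == db["hemisphere"] and da["hemisphere"] in ("L", "R"):
            hemi_counts[da["hemisphere"]] += 1
        else:
            hemi_counts["cross"] += 1
    n = len(edges)
    out["within_lobe_fraction"] = same_lobe / n
    out["lobe_fractions"] = {f"{h}-{l}": c / n for (h, l), c in sorted(lobe_counts.items())}
    out["hemisphere_fractions"] = {k: v / n for k, v in hemi_counts.items()}

    sub_edges = [(a, b) for a, b in edges
                 if not attr[a]["is_cortical"] or not attr[b]["is_cortical"]]
    if sub_edges:
        counts = {"L": 0, "R": 0, "subcortical": 0}
        for a, b in sub_edges:
            da, db = attr[a], attr[b]
            if not da["is_cortical"] and not db["is_cortical"]:
                counts["subcortical"] += 1
            else:
                cort = da if da["is_cortical"] else db
                if cort["hemisphere"] in counts:
                    counts[cort["hemisphere"]] += 1
        m = len(sub_edges)
        out["subcortical_attachment"] = {k: v / m for k, v in counts.items()}
    return out
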