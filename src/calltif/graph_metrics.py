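"""Evaluation and connectome-analysis computations.

Structure recovery is scored as binary classification over edges: the
directed protocol treats all n^2 ordered pairs (self-loops included) as
candidates; the adjacency protocol first collapses truth and prediction to
undirected graphs and scores the n(n-1)/2 unordered pairs.

Also here: normalized degree / causal flow, subnetwork aggregation,
group average and intersection graphs, functional (correlation) graphs, and
per-lag unique-edge contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SummaryGraph
from .lagged_design import TimeSeriesPanel

__all__ = [
    "EvaluationReport",
    "NodePartition",
    "evaluate",
    "degree_and_flow",
    "subnetwork_graph",
    "group_average",
    "group_intersection",
    "functional_graph",
    "lag_contribution",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Precision/recall/F1 under the directed and adjacency protocols."""

    precision_directed: float
    recall_directed: float
    f1_directed: float
    precision_adjacency: float
    recall_adjacency: float
    f1_adjacency: float
    counts_directed: tuple[int, int, int, int]   # TP, FP, FN, TN
    counts_adjacency: tuple[int, int, int, int]

    def to_dict(self) -> dict:
        d = {
            "precision_directed": self.precision_directed,
            "recall_directed": self.recall_directed,
            "f1_directed": self.f1_directed,
            "precision_adjacency": self.precision_adjacency,
            "recall_adjacency": self.recall_adjacency,
            "f1_adjacency": self.f1_adjacency,
        }
        for proto, counts in (
            ("directed", self.counts_directed),
            ("adjacency", self.counts_adjacency),
        ):
            for name, c in zip(("tp", "fp", "fn", "tn"), counts):
                d[f"{name}_{proto}"] = c
        return d


class NodePartition:
    """Mapping node label -> (subnetwork, hemisphere); every node exactly once."""

    def __init__(self, assignments: dict[str, tuple[str, str]]) -> None:
        self.assignments = dict(assignments)

    def subnetwork_of(self, label: str) -> str:
        return self.assignments[label][0]

    def subnetworks(self) -> list[str]:
        seen: dict[str, None] = {}
        for sub, _ in self.assignments.values():
            seen.setdefault(sub, None)
        return list(seen)

    def validate_against(self, labels: list[str]) -> None:
        missing = [x for x in labels if x not in self.assignments]
        if missing:
            raise ValueError(f"partition missing nodes: {missing}")


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


def _as_binary(graph) -> np.ndarray:
    a = graph.adjacency if isinstance(graph, SummaryGraph) else graph
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    return (a != 0).astype(np.int8)


def evaluate(truth, predicted) -> EvaluationReport:
    """Score ``predicted`` against ``truth`` as binary edge classification."""
    t = _as_binary(truth)
    p = _as_binary(predicted)
    if t.shape != p.shape:
        raise ValueError(
            f"node-set mismatch: truth has {t.shape[0]} nodes, "
            f"predicted has {p.shape[0]}"
        )
    # directed: all n^2 ordered pairs, self-loops included
    tp = int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    tn = int(np.sum((t == 0) & (p == 0)))
    prec_d, rec_d, f1_d = _prf(tp, fp, fn)

    # adjacency: undirected collapse, upper triangle (no self pairs)
    tu = ((t + t.T) > 0).astype(np.int8)
    pu = ((p + p.T) > 0).astype(np.int8)
    iu = np.triu_indices(t.shape[0], k=1)
    tuv, puv = tu[iu], pu[iu]
    tp_a = int(np.sum((tuv == 1) & (puv == 1)))
    fp_a = int(np.sum((tuv == 0) & (puv == 1)))
    fn_a = int(np.sum((tuv == 1) & (puv == 0)))
    tn_a = int(np.sum((tuv == 0) & (puv == 0)))
    prec_a, rec_a, f1_a = _prf(tp_a, fp_a, fn_a)

    return EvaluationReport(
        precision_directed=prec_d,
        recall_directed=rec_d,
        f1_directed=f1_d,
        precision_adjacency=prec_a,
        recall_adjacency=rec_a,
        f1_adjacency=f1_a,
        counts_directed=(tp, fp, fn, tn),
        counts_adjacency=(tp_a, fp_a, fn_a, tn_a),
    )


def degree_and_flow(graph) -> tuple[np.ndarray, np.ndarray]:
    """Per-node normalized degree and causal flow.

    degree_i = (sum_j G[i,j] + sum_j G[j,i]) / N;
    flow_i   = (sum_j G[i,j] - sum_j G[j,i]) / N  (out minus in).
    Weighted graphs use weighted sums.  Flows always sum to zero.
    """
    a = graph.adjacency if isinstance(graph, SummaryGraph) else np.asarray(graph)
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    n = a.shape[0]
    out_sum = a.sum(axis=1)
    in_sum = a.sum(axis=0)
    return (out_sum + in_sum) / n, (out_sum - in_sum) / n


def subnetwork_graph(
    graph,
    partition: NodePartition,
    node_labels: list[str] | None = None,
    threshold: float | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Aggregate a node-level digraph into a weighted subnetwork digraph.

    W[a, b] = (# node pairs u in a, v in b, u != v, with edge u -> v) divided
    by the number of possible such pairs: |a|*|b| for a != b and
    |a|*(|a|-1) for a = b (self-loops excluded from the diagonal norm).
    Weights below ``threshold`` (if given) are zeroed.
    """
    adj = _as_binary(graph)
    if node_labels is None:
        if isinstance(graph, SummaryGraph):
            node_labels = graph.node_labels
        else:
            raise ValueError("node_labels required for a bare adjacency matrix")
    partition.validate_against(list(node_labels))
    subs = partition.subnetworks()
    members = {
        s: [k for k, lbl in enumerate(node_labels)
            if partition.subnetwork_of(lbl) == s]
        for s in subs
    }
    for s, mem in members.items():
        if not mem:
            raise ValueError(f"empty subnetwork {s!r}")
    n_sub = len(subs)
    w = np.zeros((n_sub, n_sub))
    for ai, a in enumerate(subs):
        for bi, b in enumerate(subs):
            ma, mb = members[a], members[b]
            count = sum(
                int(adj[u, v]) for u in ma for v in mb if u != v
            )
            possible = (len(ma) * (len(ma) - 1) if ai == bi
                        else len(ma) * len(mb))
            w[ai, bi] = count / possible if possible else 0.0
    if threshold is not None:
        w[w < threshold] = 0.0
    return w, subs


def _stacked(graphs) -> np.ndarray:
    mats = []
    labels = None
    for g in graphs:
        if isinstance(g, SummaryGraph):
            if labels is not None and g.node_labels != labels:
                raise ValueError("graphs have mismatched node labels")
            labels = g.node_labels
        mats.append(_as_binary(g))
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError("graphs have mismatched node sets")
    return np.stack(mats)


def group_average(graphs) -> np.ndarray:
    """Entrywise mean of binary graphs: per-edge presence probability."""
    return _stacked(graphs).mean(axis=0)


def group_intersection(graphs) -> np.ndarray:
    """Entrywise AND: edges present in every graph."""
    return _stacked(graphs).all(axis=0).astype(np.int8)


def functional_graph(panel: TimeSeriesPanel, alpha: float = 0.01) -> np.ndarray:
    """Binary undirected graph of significant Pearson correlations.

    Sessions are concatenated; an edge is placed between two nodes iff the
    two-sided t-test p-value of their correlation is < ``alpha``.  Constant
    nodes receive no edges (with a warning).
    """
    x = panel.values
    n_t, n = x.shape
    if n_t < 3:
        raise ValueError("need at least 3 time points")
    sd = x.std(axis=0)
    constant = sd < 1e-12
    if np.any(constant):
        warnings.warn(
            "constant node(s) receive no functional edges: "
            + ", ".join(np.array(panel.node_labels)[constant]),
            stacklevel=2,
        )
    xs = (x - x.mean(axis=0)) / np.where(constant, 1.0, sd)
    r = (xs.T @ xs) / n_t
    np.clip(r, -1.0, 1.0, out=r)
    dof = n_t - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / np.maximum(1.0 - r**2, 0.0))
    pv = 2.0 * stats.t.sf(np.abs(t), dof)
    pv = np.where(np.isinf(t), 0.0, pv)
    adj = (pv < alpha).astype(np.int8)
    np.fill_diagonal(adj, 0)
    adj[constant, :] = 0
    adj[:, constant] = 0
    return np.maximum(adj, adj.T)


def lag_contribution(summary: SummaryGraph) -> np.ndarray:
    """Percentage of summary edges attributable to exactly one lag, per lag.

    Entry tau is 100 * (# edges whose provenance is exactly {tau}) / (total
    edges).  Multi-lag edges count toward no single lag, so the entries sum
    to at most 100.
    """
    prov = summary.lag_provenance
    total = int(summary.adjacency.sum())
    n_lags = prov.shape[2]
    if total == 0:
        warnings.warn("empty summary graph; lag contributions are all zero",
                      stacklevel=2)
        return np.zeros(n_lags)
    counts = prov.sum(axis=2)
    shares = np.empty(n_lags)
    for tau in range(n_lags):
        only = np.sum(prov[:, :, tau] & (counts == 1))
        shares[tau] = 100.0 * only / total
    return shares
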