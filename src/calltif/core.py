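"""Summary-graph construction: corrected thresholding, contemporaneous
orientation, and the OR-collapse across lags.

Pipeline (:func:`run_calltif`)::

    panel -> lagged design -> CI tests -> threshold -> orient lag-0 -> collapse

The per-test threshold is derived from the prescribed overall type-I bound
``alpha`` by the cross-lag correction

    alpha_level = alpha / ((tau_max + 1) * 2**tau_max)

whose correction factor ``(tau_max + 1) * 2**tau_max`` replaces the plain
``tau_max + 1`` of a Bonferroni correction.  The derivation (uniform edge
prior, non-negative dependence of edge absence across lags) lives in the
project docs; only the resulting formula is code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ci_engine import EdgeTensor, test_all_pairs
from .lagged_design import TimeSeriesPanel, build_lagged_design

__all__ = [
    "ThresholdPolicy",
    "SummaryGraph",
    "LaggedEdgeSet",
    "corrected_alpha",
    "correction_factor",
    "threshold_edges",
    "orient_contemporaneous",
    "collapse_summary",
    "run_calltif",
]


def correction_factor(tau_max: int) -> int:
    """The cross-lag multiple-comparison correction factor (tau_max + 1) * 2**tau_max."""
    if tau_max < 0:
        raise ValueError("tau_max must be non-negative")
    return (tau_max + 1) * 2**tau_max


def corrected_alpha(alpha_overall: float, tau_max: int) -> float:
    """Per-test significance threshold bounding the summary-edge type-I error.

    ``alpha_overall / ((tau_max + 1) * 2**tau_max)``; at tau_max = 0 this is
    the identity.
    """
    if not 0.0 < alpha_overall < 1.0:
        raise ValueError("alpha_overall must lie in (0, 1)")
    return alpha_overall / correction_factor(tau_max)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Per-test threshold policy: corrected from an overall bound, or manual."""

    alpha_overall: float
    tau_max: int
    alpha_level: float = field(init=False)
    mode: str = "corrected"
    alpha_level_override: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_overall < 1.0:
            raise ValueError("alpha_overall must lie in (0, 1)")
        if self.tau_max < 0:
            raise ValueError("tau_max must be non-negative")
        if self.mode not in ("corrected", "manual"):
            raise ValueError("mode must be 'corrected' or 'manual'")
        if self.mode == "manual":
            if self.alpha_level_override is None:
                raise ValueError("manual mode requires alpha_level_override")
            if not 0.0 < self.alpha_level_override < 1.0:
                raise ValueError("alpha_level_override must lie in (0, 1)")
            level = self.alpha_level_override
        else:
            level = corrected_alpha(self.alpha_overall, self.tau_max)
        object.__setattr__(self, "alpha_level", level)


@dataclass
class LaggedEdgeSet:
    """Thresholded edges of the extended time-lagged graph.

    ``lagged`` holds directed (i, j, tau) triples with tau >= 1 (self-edges
    allowed); ``contemporaneous_pairs`` holds undirected lag-0 marks in
    canonical (i < j) form; ``contemporaneous_directed`` is filled by
    :func:`orient_contemporaneous`.
    """

    lagged: set[tuple[int, int, int]] = field(default_factory=set)
    contemporaneous_pairs: set[tuple[int, int]] = field(default_factory=set)
    contemporaneous_directed: set[tuple[int, int]] = field(default_factory=set)
    n_nodes: int = 0
    oriented: bool = False


@dataclass
class SummaryGraph:
    """Directed summary graph with per-edge strength and per-lag provenance.

    ``adjacency[i, j] = 1`` means edge i -> j (self-loops allowed).
    ``strength[i, j]`` is the minimum p-value across contributing lags
    (1.0 where there is no edge).  ``lag_provenance[i, j, tau]`` marks the
    lags whose test produced the edge.
    """

    adjacency: np.ndarray
    strength: np.ndarray
    lag_provenance: np.ndarray
    node_labels: list[str]
    alpha_level: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def tau_max(self) -> int:
        return self.lag_provenance.shape[2] - 1

    def edge_count(self) -> int:
        return int(self.adjacency.sum())

    def density(self) -> float:
        """Edge density over the n^2 candidate positions (self-loops included)."""
        n = self.n_nodes
        return float(self.adjacency.sum()) / (n * n)


def threshold_edges(tensor: EdgeTensor, policy: ThresholdPolicy) -> LaggedEdgeSet:
    """Keep every test with ``pval < alpha_level`` (strict; ties excluded).

    Lag-0 survivors become undirected canonical (i < j) pair marks; lagged
    survivors are directed triples.
    """
    if policy.tau_max != tensor.tau_max:
        raise ValueError(
            f"policy tau_max = {policy.tau_max} does not match tensor "
            f"tau_max = {tensor.tau_max}"
        )
    level = policy.alpha_level
    n = tensor.n_nodes
    edges = LaggedEdgeSet(n_nodes=n)
    for tau in range(1, tensor.tau_max + 1):
        hits = np.argwhere(tensor.pval[:, :, tau] < level)
        edges.lagged.update((int(i), int(j), tau) for i, j in hits)
    p0 = tensor.pval[:, :, 0]
    for i in range(n):
        for j in range(i + 1, n):
            if p0[i, j] < level:
                edges.contemporaneous_pairs.add((i, j))
    return edges


def orient_contemporaneous(edges: LaggedEdgeSet) -> LaggedEdgeSet:
    """Resolve each undirected lag-0 mark using the lagged edges of the pair.

    No lagged edge in either direction -> both directions (reciprocal pair);
    lagged edges in one direction only -> that direction; both directions
    lagged -> both.
    """
    for i, j in edges.contemporaneous_pairs:
        if not (0 <= i < j < edges.n_nodes):
            raise ValueError(f"malformed contemporaneous mark ({i}, {j})")
        fwd = any(e[0] == i and e[1] == j for e in edges.lagged)
        rev = any(e[0] == j and e[1] == i for e in edges.lagged)
        if fwd == rev:  # neither or both lagged directions
            edges.contemporaneous_directed.add((i, j))
            edges.contemporaneous_directed.add((j, i))
        elif fwd:
            edges.contemporaneous_directed.add((i, j))
        else:
            edges.contemporaneous_directed.add((j, i))
    edges.oriented = True
    return edges


def collapse_summary(
    edges: LaggedEdgeSet,
    tensor: EdgeTensor,
    alpha_level: float,
    node_labels: list[str] | None = None,
) -> SummaryGraph:
    """OR the directed lagged edges across lags into the summary graph.

    Strength is the minimum p-value over contributing lags; lag-0
    contributions use the symmetric lag-0 p-value for whichever direction(s)
    the orientation step emitted.
    """
    if not edges.oriented:
        raise ValueError("orient_contemporaneous must run before collapse_summary")
    n = edges.n_nodes
    tau_max = tensor.tau_max
    provenance = np.zeros((n, n, tau_max + 1), dtype=bool)
    for i, j, tau in edges.lagged:
        provenance[i, j, tau] = True
    for i, j in edges.contemporaneous_directed:
        provenance[i, j, 0] = True
    adjacency = provenance.any(axis=2).astype(np.int8)
    strength = np.ones((n, n))
    for i, j in np.argwhere(adjacency):
        contributing = np.flatnonzero(provenance[i, j])
        strength[i, j] = float(np.min(tensor.pval[i, j, contributing]))
    labels = node_labels or tensor.node_labels or [str(k) for k in range(n)]
    return SummaryGraph(
        adjacency=adjacency,
        strength=strength,
        lag_provenance=provenance,
        node_labels=list(labels),
        alpha_level=alpha_level,
    )


def run_calltif(
    panel: TimeSeriesPanel,
    tau_max: int = 3,
    alpha_overall: float = 0.01,
    alpha_level_override: float | None = None,
    standardize: bool = True,
) -> tuple[SummaryGraph, EdgeTensor]:
    """Full pipeline from panel to summary graph; deterministic given the panel."""
    try:
        design = build_lagged_design(panel, tau_max, standardize=standardize)
    except ValueError as exc:
        raise ValueError(f"lagged design construction failed: {exc}") from exc
    try:
        tensor = test_all_pairs(design)
    except ValueError as exc:
        raise ValueError(f"conditional-independence testing failed: {exc}") from exc
    tensor.node_labels = list(panel.node_labels)
    policy = ThresholdPolicy(
        alpha_overall=alpha_overall,
        tau_max=tau_max,
        mode="manual" if alpha_level_override is not None else "corrected",
        alpha_level_override=alpha_level_override,
    )
    edges = threshold_edges(tensor, policy)
    edges = orient_contemporaneous(edges)
    graph = collapse_summary(
        edges, tensor, policy.alpha_level, node_labels=list(panel.node_labels)
    )
    return graph, tensor
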