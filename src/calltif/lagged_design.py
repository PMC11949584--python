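"""Time-series data model and construction of the aligned lagged design matrix.

A :class:`TimeSeriesPanel` holds one or more contiguous recording sessions of
the same set of named nodes.  :func:`build_lagged_design` turns a panel into
the matrix of lagged copies ``X_k(t - s)`` for ``s = 0 .. tau_max`` that every
conditional-independence test downstream consumes.  Lagging never crosses a
session boundary: each session contributes its own block of rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TimeSeriesPanel",
    "LaggedVariable",
    "LaggedDesign",
    "build_lagged_design",
]


@dataclass(frozen=True)
class LaggedVariable:
    """A column identity in the lagged design: node ``node_index`` at lag ``lag``.

    Lag 0 is the contemporaneous copy ``X_i(t)``; lag ``s`` is ``X_i(t - s)``.
    """

    node_index: int
    lag: int

    def __post_init__(self) -> None:
        if self.node_index < 0:
            raise ValueError("node_index must be non-negative")
        if self.lag < 0:
            raise ValueError("lag must be non-negative")


class TimeSeriesPanel:
    """Observed node-by-time measurements for one or more sessions.

    Parameters
    ----------
    values
        Real matrix, time points x nodes.  No missing/non-finite entries.
    node_labels
        Unique column labels, one per node.
    tr_seconds
        Sampling interval (repetition time) in seconds.
    session_boundaries
        Start row index of each session, strictly increasing, first element 0.
        Defaults to a single session.
    """

    def __init__(
        self,
        values: np.ndarray,
        node_labels: Sequence[str],
        tr_seconds: float = 1.0,
        session_boundaries: Sequence[int] | None = None,
        panel_id: str = "panel",
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (time x nodes)")
        if not np.all(np.isfinite(values)):
            raise ValueError("panel values contain non-finite entries")
        labels = [str(x) for x in node_labels]
        if len(labels) != values.shape[1]:
            raise ValueError(
                f"{len(labels)} node labels for {values.shape[1]} columns"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique")
        if tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if session_boundaries is None:
            session_boundaries = [0]
        bounds = [int(b) for b in session_boundaries]
        if not bounds or bounds[0] != 0:
            raise ValueError("session_boundaries must start at row 0")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("session_boundaries must be strictly increasing")
        if bounds[-1] >= values.shape[0]:
            raise ValueError("session boundary beyond last row")
        self.values = values
        self.node_labels = labels
        self.tr_seconds = float(tr_seconds)
        self.session_boundaries = bounds
        self.panel_id = panel_id

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_sessions(self) -> int:
        return len(self.session_boundaries)

    def session_slices(self) -> list[slice]:
        """Row slices of the individual sessions, in order."""
        stops = list(self.session_boundaries[1:]) + [self.n_timepoints]
        return [slice(b, s) for b, s in zip(self.session_boundaries, stops)]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TimeSeriesPanel(id={self.panel_id!r}, T={self.n_timepoints}, "
            f"N={self.n_nodes}, sessions={self.n_sessions}, TR={self.tr_seconds}s)"
        )


@dataclass
class LaggedDesign:
    """Aligned lagged design matrix: usable time points x N*(tau_max + 1) columns.

    Row *r* at session-local time *t* holds, in the column mapped to
    ``(k, s)``, the panel value of node *k* at time *t - s*.
    """

    matrix: np.ndarray
    column_map: list[LaggedVariable]
    n_nodes: int
    tau_max: int
    source_panel_id: str = "panel"
    standardized: bool = False
    constant_columns: list[int] = field(default_factory=list)

    @property
    def n_effective(self) -> int:
        return self.matrix.shape[0]

    def column_index(self, node_index: int, lag: int) -> int:
        """Position of variable ``(node_index, lag)`` in the matrix."""
        # layout: lag-major blocks, node-minor within each lag
        return lag * self.n_nodes + node_index

    def lagged_columns(self) -> np.ndarray:
        """Indices of all columns with lag >= 1, in layout order."""
        return np.arange(self.n_nodes, self.n_nodes * (self.tau_max + 1))

    def contemporaneous_columns(self) -> np.ndarray:
        """Indices of the lag-0 columns, one per node."""
        return np.arange(self.n_nodes)


def build_lagged_design(
    panel: TimeSeriesPanel,
    tau_max: int,
    standardize: bool = True,
) -> LaggedDesign:
    """Construct the stacked per-session lagged design at maximum lag ``tau_max``.

    Each session of length ``L`` contributes ``L - tau_max`` rows; rows never
    mix values across a session boundary.  With ``standardize=True`` each
    *panel* column is z-scored per session before lagging (constant columns
    are centered only and recorded in ``constant_columns``).

    Raises
    ------
    ValueError
        If ``tau_max < 0`` or any session is too short (length must exceed
        ``tau_max + 1``).
    """
    if tau_max < 0:
        raise ValueError("tau_max must be non-negative")
    n = panel.n_nodes
    constant_nodes: set[int] = set()
    blocks: list[np.ndarray] = []
    for s_idx, sl in enumerate(panel.session_slices()):
        seg = panel.values[sl]
        length = seg.shape[0]
        if length <= tau_max + 1:
            raise ValueError(
                f"session {s_idx} has length {length}; need more than "
                f"tau_max + 1 = {tau_max + 1} time points"
            )
        if standardize:
            seg = seg - seg.mean(axis=0)
            sd = seg.std(axis=0, ddof=1)
            const = sd < 1e-12
            constant_nodes.update(np.flatnonzero(const).tolist())
            sd = np.where(const, 1.0, sd)
            seg = seg / sd
        rows = length - tau_max
        block = np.empty((rows, n * (tau_max + 1)))
        for lag in range(tau_max + 1):
            block[:, lag * n : (lag + 1) * n] = seg[tau_max - lag : length - lag]
        blocks.append(block)
    column_map = [
        LaggedVariable(node_index=k, lag=lag)
        for lag in range(tau_max + 1)
        for k in range(n)
    ]
    const_cols = sorted(
        lag * n + k for k in constant_nodes for lag in range(tau_max + 1)
    )
    if const_cols:
        warnings.warn(
            "constant node column(s) left centered only (not scaled): "
            + ", ".join(panel.node_labels[c % n] for c in sorted(constant_nodes)),
            stacklevel=2,
        )
    return LaggedDesign(
        matrix=np.vstack(blocks),
        column_map=column_map,
        n_nodes=n,
        tau_max=tau_max,
        source_panel_id=panel.panel_id,
        standardized=standardize,
        constant_columns=const_cols,
    )
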