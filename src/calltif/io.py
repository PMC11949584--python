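"""File formats: delimited time-series panels, summary-graph dialects,
edge-tensor tables, and run manifests.

Panels are TSV (default) or CSV with a header row of node labels and one row
per time point; multiple files are stacked as separate sessions.  A summary
graph is written as both an edge-list CSV (source_label, target_label,
strength_pval, lags) and a dense labeled 0/1 adjacency CSV; the pair
round-trips losslessly.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ci_engine import EdgeTensor
from .core import SummaryGraph
from .lagged_design import TimeSeriesPanel

__all__ = [
    "read_panel",
    "write_panel",
    "write_graph",
    "read_graph",
    "write_edge_tensor",
    "write_manifest",
]

logger = logging.getLogger("calltif")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError(f"{path}: empty table")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any() and not df[col].isna().any():
            row = int(bad.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric cell at row {row}, column {col!r}"
            )
        if df[col].isna().any():
            row = int(df[col].isna().idxmax())
            raise ValueError(f"{path}: missing value at row {row}, column {col!r}")
        df[col] = bad
    return df


def read_panel(
    paths: Sequence[str | Path],
    tr_seconds: float = 1.0,
    panel_id: str | None = None,
) -> TimeSeriesPanel:
    """Read one panel from one or more session files (first file fixes column order)."""
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input files given")
    frames = []
    ref_cols: list[str] | None = None
    for path in paths:
        df = _read_table(path)
        cols = [str(c) for c in df.columns]
        if ref_cols is None:
            ref_cols = cols
        elif cols != ref_cols:
            if sorted(cols) != sorted(ref_cols):
                raise ValueError(
                    f"{path}: header mismatch with {paths[0]} "
                    f"({sorted(set(ref_cols) ^ set(cols))})"
                )
            logger.warning("%s: columns permuted; realigned by label", path)
            df = df[ref_cols]
        frames.append(df.to_numpy(dtype=float))
    boundaries = np.cumsum([0] + [f.shape[0] for f in frames[:-1]]).tolist()
    return TimeSeriesPanel(
        # C-order so that downstream reductions sum in the same order as for
        # an in-memory panel (bit-identical rebuild guarantee)
        values=np.ascontiguousarray(np.vstack(frames)),
        node_labels=ref_cols,
        tr_seconds=tr_seconds,
        session_boundaries=boundaries,
        panel_id=panel_id or paths[0].stem,
    )


def write_panel(panel: TimeSeriesPanel, path: str | Path) -> None:
    """Write a single-session view of the panel (TSV or CSV by extension)."""
    path = Path(path)
    pd.DataFrame(panel.values, columns=panel.node_labels).to_csv(
        path, sep=_sep_for(path), index=False
    )


def write_graph(graph: SummaryGraph, out_dir: str | Path, stem: str = "summary") -> dict:
    """Write edge-list and adjacency CSVs; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, j in np.argwhere(graph.adjacency):
        lags = np.flatnonzero(graph.lag_provenance[i, j])
        rows.append(
            (
                graph.node_labels[i],
                graph.node_labels[j],
                graph.strength[i, j],
                ";".join(str(int(tau)) for tau in lags),
            )
        )
    edge_path = out_dir / f"{stem}_edges.csv"
    pd.DataFrame(
        rows, columns=["source_label", "target_label", "strength_pval", "lags"]
    ).to_csv(edge_path, index=False)
    adj_path = out_dir / f"{stem}_adjacency.csv"
    pd.DataFrame(
        graph.adjacency, index=graph.node_labels, columns=graph.node_labels
    ).to_csv(adj_path)
    meta_path = out_dir / f"{stem}_meta.json"
    meta_path.write_text(
        json.dumps(
            {"alpha_level": graph.alpha_level, "tau_max": graph.tau_max},
            indent=2,
        )
    )
    return {"edges": str(edge_path), "adjacency": str(adj_path),
            "meta": str(meta_path)}


def read_graph(out_dir: str | Path, stem: str = "summary") -> SummaryGraph:
    """Reconstruct a SummaryGraph written by :func:`write_graph`."""
    out_dir = Path(out_dir)
    adj_df = pd.read_csv(out_dir / f"{stem}_adjacency.csv", index_col=0)
    labels = [str(c) for c in adj_df.columns]
    if [str(r) for r in adj_df.index] != labels:
        raise ValueError("adjacency CSV row labels do not match column labels")
    meta = json.loads((out_dir / f"{stem}_meta.json").read_text())
    n = len(labels)
    tau_max = int(meta["tau_max"])
    adjacency = adj_df.to_numpy(dtype=np.int8)
    strength = np.ones((n, n))
    provenance = np.zeros((n, n, tau_max + 1), dtype=bool)
    index = {lbl: k for k, lbl in enumerate(labels)}
    edges = pd.read_csv(out_dir / f"{stem}_edges.csv", dtype=str)
    for _, row in edges.iterrows():
        try:
            i, j = index[str(row["source_label"])], index[str(row["target_label"])]
        except KeyError as exc:
            raise ValueError(f"unknown node label in edge list: {exc}") from exc
        strength[i, j] = float(row["strength_pval"])
        if isinstance(row["lags"], str) and row["lags"]:
            for tau in row["lags"].split(";"):
                provenance[i, j, int(tau)] = True
    rebuilt = provenance.any(axis=2).astype(np.int8)
    if not np.array_equal(rebuilt, adjacency):
        raise ValueError("edge list and adjacency CSV disagree")
    return SummaryGraph(
        adjacency=adjacency,
        strength=strength,
        lag_provenance=provenance,
        node_labels=labels,
        alpha_level=float(meta["alpha_level"]),
    )


def write_edge_tensor(tensor: EdgeTensor, path: str | Path) -> None:
    tensor.to_frame().to_csv(path, index=False)


def write_manifest(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_adjacency(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a labeled dense adjacency CSV (or an unlabeled square matrix)."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    try:
        mat = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric adjacency") from exc
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: adjacency must be square, got {mat.shape}")
    return mat, [str(c) for c in df.columns]


def read_partition(path: str | Path):
    """Read a node partition CSV: node_label, subnetwork, hemisphere."""
    from .graph_metrics import NodePartition

    df = pd.read_csv(path, dtype=str)
    required = {"node_label", "subnetwork", "hemisphere"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"partition file must have columns {sorted(required)}"
        )
    if df["node_label"].duplicated().any():
        dup = df.loc[df["node_label"].duplicated(), "node_label"].iloc[0]
        raise ValueError(f"node {dup!r} mapped more than once")
    return NodePartition(
        {
            str(r.node_label): (str(r.subnetwork), str(r.hemisphere))
            for r in df.itertuples()
        }
    )
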