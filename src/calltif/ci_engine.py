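"""Partial-correlation conditional-independence tests over the lagged design.

Every test is of the form rho(X, Y | Z): Pearson correlation of the residuals
of X and Y after least-squares projection onto [1, Z], with a two-sided
t-test of rho = 0 at dof = n - |Z| - 2.

:func:`test_all_pairs` runs the full battery: every lagged source
``X_i(t - tau)``, tau in [1, tau_max], against every contemporaneous target
``X_j(t)``, conditioned on *all* lagged variables except the tested source
itself; and every contemporaneous pair ``X_i(t), X_j(t)`` conditioned on all
lagged variables.  No contemporaneous variable is ever conditioned on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .lagged_design import LaggedDesign

__all__ = ["EdgeTensor", "partial_correlation", "test_all_pairs"]


@dataclass
class EdgeTensor:
    """Per-(source, target, lag) partial correlations and p-values.

    ``rho[i, j, tau]`` tests ``X_i(t - tau)`` against ``X_j(t)``.  The tau = 0
    slices are symmetric; the tau = 0 diagonal (a variable against itself) is
    undefined and stored as NaN.
    """

    rho: np.ndarray
    pval: np.ndarray
    dof_lagged: int
    dof_contemporaneous: int
    n_effective: int
    node_labels: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.rho.shape[0]

    @property
    def tau_max(self) -> int:
        return self.rho.shape[2] - 1

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: source, target, lag, rho, pval, dof."""
        n, _, n_lags = self.rho.shape
        labels = self.node_labels or [str(i) for i in range(n)]
        rows = []
        for tau in range(n_lags):
            dof = self.dof_contemporaneous if tau == 0 else self.dof_lagged
            for i in range(n):
                for j in range(n):
                    if tau == 0 and i == j:
                        continue
                    rows.append(
                        (labels[i], labels[j], tau,
                         self.rho[i, j, tau], self.pval[i, j, tau], dof)
                    )
        return pd.DataFrame(
            rows, columns=["source", "target", "lag", "rho", "pval", "dof"]
        )


def _orthonormal_basis(z: np.ndarray, warn_label: str | None = None):
    """Orthonormal basis of col-span(z) via pivoted QR; returns (Q, rank).

    Rank-deficient inputs are handled by projecting onto the span of an
    independent column subset (the projection itself is unchanged).
    """
    q, r, _ = sla.qr(z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(z.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < z.shape[1] and warn_label is not None:
        warnings.warn(
            f"rank-deficient conditioning set in {warn_label}: "
            f"{z.shape[1] - rank} redundant column(s) dropped; dof adjusted",
            stacklevel=3,
        )
    return q[:, :rank], rank


def _corr_pval(rho: np.ndarray, dof: int) -> np.ndarray:
    """Two-sided p-value of the t-statistic rho * sqrt(dof / (1 - rho^2))."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(dof / np.maximum(1.0 - rho**2, 0.0))
    pv = 2.0 * stats.t.sf(np.abs(t), dof)
    return np.where(np.isinf(t) | (np.abs(rho) >= 1.0), 0.0, pv)


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    conditioning: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """Sample partial correlation of ``x`` and ``y`` given ``conditioning``.

    Both series are residualized on ``[1, conditioning]`` by least squares;
    the Pearson correlation of the residuals is tested two-sided against
    zero with ``dof = n - |Z| - 2`` (|Z| = effective rank of the
    conditioning set).

    Returns
    -------
    (rho, pval, dof)
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("x and y must have the same length")
    if conditioning is None:
        conditioning = np.empty((n, 0))
    z = np.asarray(conditioning, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if z.shape[0] != n:
        raise ValueError("conditioning must have the same row count as x and y")
    zi = np.column_stack([np.ones(n), z])
    q, rank = _orthonormal_basis(zi, warn_label="partial_correlation"
                                 if z.shape[1] + 1 > 0 else None)
    n_z = rank - 1  # effective conditioning size, intercept excluded
    dof = n - n_z - 2
    if dof < 1:
        raise ValueError(
            f"insufficient degrees of freedom: n = {n}, |Z| = {n_z}; "
            f"need n >= {n_z + 3}"
        )
    rx = x - q @ (q.T @ x)
    ry = y - q @ (q.T @ y)
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0.0:
        raise ValueError("residual of x or y is identically zero")
    rho = float(np.dot(rx, ry) / denom)
    pval = float(_corr_pval(np.array(rho), dof))
    return rho, pval, dof


def _residual_correlations(
    q: np.ndarray, x: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """Correlations of x with each target column, all residualized on span(q)."""
    rx = x - q @ (q.T @ x)
    rt = targets - q @ (q.T @ targets)
    nx = np.linalg.norm(rx)
    nt = np.linalg.norm(rt, axis=0)
    denom = nx * nt
    denom = np.where(denom == 0.0, np.nan, denom)
    return (rx @ rt) / denom


def test_all_pairs(design: LaggedDesign) -> EdgeTensor:
    """Run every momentary conditional-independence test on ``design``.

    For tau >= 1 (including i = j), ``X_i(t - tau)`` vs ``X_j(t)`` given all
    lagged variables minus the tested source; for tau = 0 and i != j,
    ``X_i(t)`` vs ``X_j(t)`` given all lagged variables.
    """
    n_obs = design.n_effective
    n = design.n_nodes
    tau_max = design.tau_max
    m = n * tau_max  # number of lagged variables
    contemp = design.matrix[:, design.contemporaneous_columns()]
    lagged = design.matrix[:, design.lagged_columns()]
    ones = np.ones((n_obs, 1))

    if n_obs - m - 2 < 1:
        raise ValueError(
            f"n_effective = {n_obs} too small for conditioning set of size "
            f"{m}; need at least {m + 3} usable rows"
        )

    rho = np.full((n, n, tau_max + 1), np.nan)
    pval = np.full((n, n, tau_max + 1), np.nan)

    # contemporaneous block: condition on all lagged variables
    q_full, rank_full = _orthonormal_basis(
        np.column_stack([ones, lagged]), warn_label="lag-0 tests"
    )
    dof0 = n_obs - (rank_full - 1) - 2
    if dof0 < 1:
        raise ValueError("insufficient dof for lag-0 tests")
    resid0 = contemp - q_full @ (q_full.T @ contemp)
    norms = np.linalg.norm(resid0, axis=0)
    denom = np.outer(norms, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        r0 = (resid0.T @ resid0) / denom
    np.fill_diagonal(r0, np.nan)
    rho[:, :, 0] = r0
    pval[:, :, 0] = _corr_pval(r0, dof0)
    for i in range(n):
        pval[i, i, 0] = np.nan

    # lagged tests: drop the tested source from the conditioning set
    dof_lag = n_obs - (m - 1) - 2 if m > 0 else n_obs - 2
    for tau in range(1, tau_max + 1):
        for i in range(n):
            col = (tau - 1) * n + i  # position of (i, tau) within `lagged`
            x = lagged[:, col]
            others = np.delete(lagged, col, axis=1)
            q, rank = _orthonormal_basis(
                np.column_stack([ones, others]),
                warn_label=f"test ({i} -> *, lag {tau})",
            )
            dof = n_obs - (rank - 1) - 2
            if dof < 1:
                raise ValueError(
                    f"insufficient dof for test (source {i}, lag {tau})"
                )
            r = _residual_correlations(q, x, contemp)
            if np.any(np.isnan(r)):
                bad = int(np.flatnonzero(np.isnan(r))[0])
                raise ValueError(
                    f"degenerate residual in test (source {i}, target {bad}, "
                    f"lag {tau})"
                )
            rho[i, :, tau] = r
            pval[i, :, tau] = _corr_pval(r, dof)

    return EdgeTensor(
        rho=rho,
        pval=pval,
        dof_lagged=dof_lag,
        dof_contemporaneous=dof0,
        n_effective=n_obs,
        node_labels=None,
    )
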