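"""Synthetic BOLD generation with known ground-truth digraphs.

The generative chain mirrors the standard resting-state benchmark recipe:
a signed digraph A drives linear neural dynamics

    dz/dt = sigma * A z + C u

with per-node Poisson impulse inputs (C = I), the neural states are pushed
through the Balloon-Windkessel hemodynamic model, and the resulting BOLD is
decimated to the scanner TR.  A stationary VAR generator is also provided as
a cheap oracle for unit tests of the discovery pipeline.

Hemodynamic parameter defaults follow the conventional DCM values
(kappa = 0.65 /s, gamma = 0.41 /s, tau = 0.98 s, alpha = 0.32, rho = 0.34,
v0 = 0.02, k1 = 7 rho, k2 = 2, k3 = 2 rho - 0.2); all are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lagged_design import TimeSeriesPanel

__all__ = [
    "GroundTruthModel",
    "HemodynamicParams",
    "make_random_cyclic_graph",
    "simulate_neural",
    "balloon_windkessel",
    "sample_bold",
    "simulate_var",
    "simulate_bold_panel",
]

_DIVERGENCE_BOUND = 1e6


@dataclass
class HemodynamicParams:
    """Balloon-Windkessel parameters (rates in 1/s, times in s)."""

    kappa: float = 0.65       # vasodilatory signal decay
    gamma: float = 0.41       # flow-dependent elimination
    tau: float = 0.98         # hemodynamic transit time
    alpha_grubb: float = 0.32 # vessel stiffness exponent
    rho_oxy: float = 0.34     # resting oxygen extraction fraction
    v0: float = 0.02          # resting blood-volume fraction

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "alpha_grubb", "rho_oxy", "v0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("alpha_grubb", "rho_oxy", "v0"):
            if not getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    @property
    def k1(self) -> float:
        return 7.0 * self.rho_oxy

    @property
    def k2(self) -> float:
        return 2.0

    @property
    def k3(self) -> float:
        return 2.0 * self.rho_oxy - 0.2


@dataclass
class GroundTruthModel:
    """Signed ground-truth digraph plus the dynamics/sampling parameters.

    ``adjacency_signed[i, j] != 0`` means a ground-truth edge i -> j; the
    diagonal holds the (negative) self-decay.  The continuous system
    ``dz/dt = sigma * A^T z + u`` must be stable (all eigenvalues of
    sigma * A in the open left half-plane; eigenvalues of A and A^T agree).
    """

    adjacency_signed: np.ndarray
    sigma: float = 1.0
    poisson_rate: float = 0.5
    # kept small so the hemodynamic states stay in their positive basin
    impulse_amplitude: float = 0.15
    dt_seconds: float = 0.01
    duration_seconds: float = 600.0
    tr_seconds: float = 1.2
    seed: int = 0
    hemodynamics: HemodynamicParams = field(default_factory=HemodynamicParams)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency_signed, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency_signed must be square")
        self.adjacency_signed = a
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.dt_seconds <= 0 or self.duration_seconds <= 0:
            raise ValueError("dt and duration must be positive")
        ratio = self.tr_seconds / self.dt_seconds
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("dt_seconds must divide tr_seconds")
        eig = np.linalg.eigvals(self.sigma * a)
        if np.max(eig.real) >= 0:
            raise ValueError(
                "unstable dynamics: sigma * A has an eigenvalue with "
                f"non-negative real part (max Re = {np.max(eig.real):.4g})"
            )

    @property
    def n_nodes(self) -> int:
        return self.adjacency_signed.shape[0]

    @property
    def binary_truth(self) -> np.ndarray:
        """0/1 edge pattern, self-loops included (nonzero diagonal decay)."""
        return (self.adjacency_signed != 0).astype(np.int8)


def make_random_cyclic_graph(
    n_nodes: int,
    density: float,
    bidirectional_fraction: float = 0.3,
    weight_range: tuple[float, float] = (0.3, 0.8),
    self_decay: float = -1.0,
    seed: int = 0,
    sigma: float = 1.0,
    sign_policy: str = "random",
    max_resamples: int = 200,
    **model_kwargs,
) -> GroundTruthModel:
    """Draw a random signed digraph with the requested expected density.

    ``density`` is the expected fraction of the n*(n-1) ordered off-diagonal
    positions that carry an edge.  A ``bidirectional_fraction`` of connected
    node pairs is made reciprocal (2-cycles).  Off-diagonal weights are drawn
    uniformly from ``weight_range`` with sign per ``sign_policy`` ('random',
    'positive' or 'negative'); the diagonal is ``self_decay``.  Matrices are
    rejection-resampled until ``sigma * A`` is stable.
    """
    if not 0.0 <= density < 1.0:
        raise ValueError("density must lie in [0, 1)")
    if not 0.0 <= bidirectional_fraction <= 1.0:
        raise ValueError("bidirectional_fraction must lie in [0, 1]")
    if self_decay >= 0:
        raise ValueError("self_decay must be negative")
    if sign_policy not in ("random", "positive", "negative"):
        raise ValueError("sign_policy must be random/positive/negative")
    lo, hi = weight_range
    if not 0 < lo <= hi:
        raise ValueError("weight_range must be positive and ordered")
    # a connected pair contributes (1 + b) ordered edges on average, so the
    # pair-connection probability solving E[edges] = density * n(n-1) is:
    p_pair = min(1.0, 2.0 * density / (1.0 + bidirectional_fraction))
    rng = np.random.default_rng(seed)
    for _ in range(max_resamples):
        a = np.zeros((n_nodes, n_nodes))
        np.fill_diagonal(a, self_decay)
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() >= p_pair:
                    continue
                w1 = rng.uniform(lo, hi)
                w2 = rng.uniform(lo, hi)
                if sign_policy == "random":
                    w1 *= rng.choice([-1.0, 1.0])
                    w2 *= rng.choice([-1.0, 1.0])
                elif sign_policy == "negative":
                    w1, w2 = -w1, -w2
                if rng.random() < bidirectional_fraction:
                    a[i, j], a[j, i] = w1, w2
                elif rng.random() < 0.5:
                    a[i, j] = w1
                else:
                    a[j, i] = w1
        if np.max(np.linalg.eigvals(sigma * a).real) < 0:
            return GroundTruthModel(
                adjacency_signed=a, sigma=sigma, seed=seed, **model_kwargs
            )
    raise RuntimeError(
        f"no stable adjacency found in {max_resamples} resamples; "
        "reduce weight_range or density, or strengthen self_decay"
    )


def simulate_neural(
    model: GroundTruthModel, z_init: np.ndarray | None = None
) -> np.ndarray:
    """Euler-integrate dz/dt = sigma * A^T z + u with Poisson impulse inputs.

    ``A[i, j]`` is the influence of node i on node j, so the state update
    uses ``A^T z``.  Each node receives an independent Poisson event stream
    of the model's rate; an event adds ``impulse_amplitude`` to that node's
    state (a delta input integrated over one step).  Returns the state
    trajectory (time steps x nodes).
    """
    rng = np.random.default_rng(model.seed)
    n = model.n_nodes
    dt = model.dt_seconds
    n_steps = int(round(model.duration_seconds / dt))
    coupling = model.sigma * model.adjacency_signed.T
    z = np.zeros(n) if z_init is None else np.asarray(z_init, dtype=float).copy()
    out = np.empty((n_steps, n))
    counts = rng.poisson(model.poisson_rate * dt, size=(n_steps, n))
    impulses = model.impulse_amplitude * counts
    for t in range(n_steps):
        z = z + dt * (coupling @ z) + impulses[t]
        if np.max(np.abs(z)) > _DIVERGENCE_BOUND:
            raise RuntimeError(
                f"neural simulation diverged at step {t} "
                f"(|z| > {_DIVERGENCE_BOUND:g}); dynamics unstable at this dt"
            )
        out[t] = z
    return out


def _integrate_bw(z: np.ndarray, p: HemodynamicParams, dt: float) -> np.ndarray:
    n_steps, n = z.shape
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    inv_alpha = 1.0 / p.alpha_grubb
    bold = np.empty((n_steps, n))
    for t in range(n_steps):
        ds = z[t] - p.kappa * s - p.gamma * (f - 1.0)
        df = s
        dv = (f - v**inv_alpha) / p.tau
        dq = (f * (1.0 - (1.0 - p.rho_oxy) ** (1.0 / f)) / p.rho_oxy
              - q * v ** (inv_alpha - 1.0)) / p.tau
        s = s + dt * ds
        f = f + dt * df
        v = v + dt * dv
        q = q + dt * dq
        if np.any(f <= 0) or np.any(v <= 0) or np.any(q <= 0):
            raise FloatingPointError(
                f"hemodynamic state positivity violated at step {t}"
            )
        bold[t] = p.v0 * (
            p.k1 * (1.0 - q) + p.k2 * (1.0 - q / v) + p.k3 * (1.0 - v)
        )
    return bold


def balloon_windkessel(
    z: np.ndarray, params: HemodynamicParams | None = None, dt: float = 0.01
) -> np.ndarray:
    """Map neural states to BOLD through the Balloon-Windkessel model.

    Per node: ds/dt = z - kappa*s - gamma*(f-1); df/dt = s;
    tau*dv/dt = f - v^(1/alpha);
    tau*dq/dt = f*(1-(1-rho)^(1/f))/rho - q*v^(1/alpha - 1);
    BOLD = v0*(k1*(1-q) + k2*(1-q/v) + k3*(1-v)).

    Resting input (z = 0) stays at the s=0, f=v=q=1 fixed point and yields a
    zero baseline.  If a state positivity violation occurs, the integration
    is retried once at half the step (sub-stepping), then fails.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("neural states contain non-finite values")
    if params is None:
        params = HemodynamicParams()
    try:
        return _integrate_bw(z, params, dt)
    except FloatingPointError:
        # one retry on a twice-finer grid (inputs held piecewise constant)
        z_fine = np.repeat(z, 2, axis=0)
        bold_fine = _integrate_bw(z_fine, params, dt / 2.0)
        return bold_fine[1::2]


def sample_bold(
    bold: np.ndarray,
    dt_seconds: float,
    tr_seconds: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    node_labels: list[str] | None = None,
) -> TimeSeriesPanel:
    """Decimate a dt-grid BOLD matrix to the TR grid, add measurement noise."""
    bold = np.asarray(bold, dtype=float)
    ratio = tr_seconds / dt_seconds
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("tr_seconds must be a multiple of dt_seconds")
    step = int(round(ratio))
    sampled = bold[step - 1 :: step].copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sampled += rng.normal(0.0, noise_sd, size=sampled.shape)
    labels = node_labels or [f"node{i}" for i in range(bold.shape[1])]
    return TimeSeriesPanel(
        values=sampled, node_labels=labels, tr_seconds=tr_seconds
    )


def simulate_bold_panel(
    model: GroundTruthModel,
    noise_sd: float = 0.0,
    node_labels: list[str] | None = None,
) -> TimeSeriesPanel:
    """End-to-end convenience: neural dynamics -> hemodynamics -> TR sampling."""
    z = simulate_neural(model)
    bold = balloon_windkessel(z, model.hemodynamics, model.dt_seconds)
    return sample_bold(
        bold,
        dt_seconds=model.dt_seconds,
        tr_seconds=model.tr_seconds,
        noise_sd=noise_sd,
        seed=model.seed + 1,  # decouple measurement noise from input stream
        node_labels=node_labels,
    )


def simulate_var(
    coefficients: np.ndarray,
    innovation_cov: np.ndarray,
    t_points: int,
    seed: int = 0,
    burn_in: int = 200,
    node_labels: list[str] | None = None,
    tr_seconds: float = 1.0,
) -> TimeSeriesPanel:
    """Draw a stationary VAR(p) path.

    ``coefficients`` has shape (p, N, N) with ``coefficients[s-1][i, j]`` the
    effect of ``X_i(t - s)`` on ``X_j(t)``.  The companion-form spectral
    radius must be < 1.  Ground truth for discovery is the nonzero
    coefficient pattern plus lag-0 dependence from off-diagonal innovation
    covariance.
    """
    coefficients = np.atleast_3d(np.asarray(coefficients, dtype=float))
    if coefficients.ndim != 3 or coefficients.shape[1] != coefficients.shape[2]:
        raise ValueError("coefficients must have shape (p, N, N)")
    p, n, _ = coefficients.shape
    cov = np.asarray(innovation_cov, dtype=float)
    if cov.shape != (n, n):
        raise ValueError("innovation_cov must be N x N")
    # companion matrix uses the (target x source) convention: B_s = A_s^T
    companion = np.zeros((n * p, n * p))
    for s in range(p):
        companion[:n, s * n : (s + 1) * n] = coefficients[s].T
    if p > 1:
        companion[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    radius = np.max(np.abs(np.linalg.eigvals(companion)))
    if radius >= 1.0:
        raise ValueError(
            f"nonstationary VAR: companion spectral radius {radius:.4f} >= 1"
        )
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov)
    total = burn_in + t_points
    eps = rng.standard_normal((total, n)) @ chol.T
    x = np.zeros((total, n))
    for t in range(total):
        acc = eps[t].copy()
        for s in range(1, p + 1):
            if t - s >= 0:
                acc += coefficients[s - 1].T @ x[t - s]
        x[t] = acc
    labels = node_labels or [f"node{i}" for i in range(n)]
    return TimeSeriesPanel(
        values=x[burn_in:], node_labels=labels, tr_seconds=tr_seconds
    )
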