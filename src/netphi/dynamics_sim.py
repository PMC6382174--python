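"""Time-series simulators on structural networks.

Two dynamics drive the validation experiments:

* stochastic coupled Rossler oscillators — each node runs the chaotic
  Rossler system (a = 0.2, b = 0.2, c = 9) with its own intrinsic frequency
  w ~ Normal(10, 0.1), Gaussian noise of amplitude d = 750 injected into the
  y equation, and diffusive x-coupling of strength sigma through the graph
  Laplacian; weakly coupled, the recorded y components are approximately
  multivariate normal;
* stable VAR(1) processes — a linear benchmark whose stationary covariances
  are known analytically.

The synchronizability interval for the Rossler x-coupling comes from the
master stability function: sigma * lambda must lie in (0.186, 4.614) for
every nonzero Laplacian eigenvalue lambda, giving the bounds
0.186/lambda_2 and 4.614/lambda_max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .connectome_gen import WeightedGraph
from .exceptions import (
    DegenerateGraphError,
    DivergenceError,
    InvalidArgumentError,
)
from .gaussian_model import TimeSeries
from .graph_metrics import laplacian_matrix

__all__ = [
    "RosslerParams",
    "master_stability_coupling",
    "simulate_rossler",
    "simulate_var",
]

#: Master-stability constants for x-coupled Rossler oscillators.
MSF_LOWER_CONST = 0.186
MSF_UPPER_CONST = 4.614

_BLOWUP_LIMIT = 1e6


@dataclass(frozen=True)
class RosslerParams:
    """Stochastic Rossler oscillator parameters (dimensionless)."""

    a: float = 0.2
    b: float = 0.2
    c: float = 9.0
    w_mean: float = 10.0
    w_sd: float = 0.1
    d: float = 750.0          # noise amplitude (y equation)
    sigma: float = 0.1        # coupling strength
    dt: float = 1e-3          # Euler integration step
    n_points: int = 25_000    # recorded samples after burn-in
    burn_in: int = 5_000      # discarded initial integration steps
    record_every: int = 50    # integration steps per recorded sample
    seed: int = 0
    ito_noise: bool = False   # scale noise by sqrt(dt) instead of dt

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        if self.sigma < 0:
            raise InvalidArgumentError("sigma must be non-negative")
        if self.n_points < 100:
            raise InvalidArgumentError("n_points must be >= 100")
        if self.record_every < 1:
            raise InvalidArgumentError("record_every must be >= 1")


def master_stability_coupling(
    graph: WeightedGraph,
) -> tuple[float, float, float]:
    """Coupling bounds (lower, upper, midpoint) from the master stability
    function: 0.186/lambda_2 and 4.614/lambda_max over the Laplacian
    spectrum (eigenvalues ascending, lambda_2 the Fiedler value)."""
    L = laplacian_matrix(graph)
    eigvals = np.sort(np.linalg.eigvalsh(0.5 * (L + L.T)))
    lambda2 = eigvals[1]
    lambda_max = eigvals[-1]
    if lambda2 <= 1e-10 * max(1.0, lambda_max):
        raise DegenerateGraphError(
            "graph is disconnected (Fiedler eigenvalue ~ 0); "
            "no synchronizing coupling exists"
        )
    lower = MSF_LOWER_CONST / lambda2
    upper = MSF_UPPER_CONST / lambda_max
    if lower > upper:
        warnings.warn(
            f"network is unsynchronizable: sigma_lower={lower:.4g} exceeds "
            f"sigma_upper={upper:.4g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(lower), float(upper), float(0.5 * (lower + upper))


@njit(cache=True)
def _rossler_chunk(
    x, y, z, w, deg, indptr, indices, edge_w,
    a, b, c, sigma, dt, noise_scale, eta,
    out, step0, burn_in, record_every,
):  # pragma: no cover - exercised through simulate_rossler
    n = x.size
    steps = eta.shape[0]
    for k in range(steps):
        for i in range(n):
            acc = deg[i] * x[i]
            for e in range(indptr[i], indptr[i + 1]):
                acc -= edge_w[e] * x[indices[e]]
            dx = -w[i] * y[i] - z[i] - sigma * acc
            dy = w[i] * x[i] + a * y[i]
            dz = b + (x[i] - c) * z[i]
            x[i] = x[i] + dt * dx
            y[i] = y[i] + dt * dy + noise_scale * eta[k, i]
            z[i] = z[i] + dt * dz
        step = step0 + k
        if step >= burn_in and (step - burn_in) % record_every == 0:
            row = (step - burn_in) // record_every
            if row < out.shape[0]:
                for i in range(n):
                    out[row, i] = y[i]


def simulate_rossler(graph: WeightedGraph, params: RosslerParams) -> TimeSeries:
    """Euler-integrate coupled stochastic Rossler oscillators on a graph.

    Per integration step (state x, y, z per oscillator, Laplacian
    coefficients g)::

        x += dt * (-w*y - z - sigma * (g @ x))
        y += dt * ( w*x + a*y) + d * eta * dt
        z += dt * ( b + (x - c)*z )

    with eta i.i.d. standard normal.  Initial states are uniform in
    [-1, 1]^3; ``burn_in`` steps are discarded and the y component recorded
    every ``record_every`` steps afterwards until ``n_points`` samples are
    collected.  Identical seeds give bitwise-identical output; any state
    magnitude above 1e6 (or a non-finite state) raises a divergence error
    naming the step.
    """
    if graph.n < 2:
        raise InvalidArgumentError("need at least 2 oscillators")
    n = graph.n
    rng = np.random.default_rng(params.seed)
    W = graph.weights
    deg = W.sum(axis=1)
    # adjacency in CSR form for the sparse Laplacian mat-vec in the kernel
    rows, cols = np.nonzero(W)
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, rows + 1, 1)
    indptr = np.cumsum(indptr)
    edge_w = W[rows, cols]
    indices = cols.astype(np.int64)

    w = rng.normal(params.w_mean, params.w_sd, size=n)
    x = rng.uniform(-1.0, 1.0, size=n)
    y = rng.uniform(-1.0, 1.0, size=n)
    z = rng.uniform(-1.0, 1.0, size=n)

    dt = params.dt
    noise_scale = params.d * (np.sqrt(dt) if params.ito_noise else dt)
    total = params.burn_in + params.n_points * params.record_every
    out = np.empty((params.n_points, n))

    chunk = 16384
    step = 0
    with np.errstate(over="ignore", invalid="ignore"):
        while step < total:
            block = min(chunk, total - step)
            eta = rng.standard_normal((block, n))
            _rossler_chunk(
                x, y, z, w, deg, indptr, indices, edge_w,
                params.a, params.b, params.c, params.sigma, dt, noise_scale,
                eta, out, step, params.burn_in, params.record_every,
            )
            step += block
            extent = np.array([np.abs(x).max(), np.abs(y).max(), np.abs(z).max()])
            if not np.all(np.isfinite(extent)) or extent.max() > _BLOWUP_LIMIT:
                raise DivergenceError(
                    f"Rossler integration diverged by step {step}", step=step
                )
    return TimeSeries(data=out)


def simulate_var(
    graph: WeightedGraph,
    coupling: float,
    n_points: int,
    seed: int = 0,
    self_coupling: float = 0.2,
    spectral_radius_cap: float = 0.9,
) -> TimeSeries:
    """Simulate a stable VAR(1) process coupled through a graph.

    The coefficient matrix is ``self_coupling * I + coupling * (W / degree)``
    (rows of the adjacency normalized by node degree), rescaled to spectral
    radius ``spectral_radius_cap`` if it exceeds it — stationarity by
    construction.  Innovations are i.i.d. standard normal.
    """
    if coupling < 0:
        raise InvalidArgumentError("coupling must be non-negative")
    n = graph.n
    W = graph.weights
    deg = W.sum(axis=1)
    norm = np.where(deg > 0, deg, 1.0)
    A = self_coupling * np.eye(n) + coupling * (W / norm[:, None])
    radius = np.max(np.abs(np.linalg.eigvals(A)))
    if radius == 0:
        raise InvalidArgumentError(
            "coefficient matrix is zero; nothing to simulate"
        )
    if radius > spectral_radius_cap:
        A = A * (spectral_radius_cap / radius)
    rng = np.random.default_rng(seed)
    burn = 1000
    data = np.zeros((n_points + burn, n))
    e = rng.standard_normal((n_points + burn, n))
    state = np.zeros(n)
    for t in range(n_points + burn):
        state = A @ state + e[t]
        data[t] = state
    return TimeSeries(data=data[burn:])
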