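"""Geometric integrated information across a bipartition.

Integrated information is the minimized Kullback-Leibler divergence between
the full Gaussian transition model of a system and a "disconnected" model in
which each part's present depends only on its own past, i.e. the regression
matrix A' is block-diagonal with respect to the partition.  For fixed A' the
optimal disconnected residual covariance is

    Sigma_E' = Sigma_E + (A - A') Sigma_past (A - A')^T

which profiles the residual covariance out of the search: the objective
reduces to

    Phi(A') = 1/2 * log2( det Sigma_E' / det Sigma_E )   [bits]

minimized over the within-block entries of A' with a smooth quasi-Newton
method (analytic gradient).  The normalization K is the smaller of the two
sub-communities' Gaussian entropies; the minimum information bipartition
(MIB) minimizes Phi/K.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize

from .exceptions import InvalidArgumentError, NotPositiveDefiniteError
from .gaussian_model import (
    GaussianTransitionModel,
    TimeSeries,
    _chol_logdet,
    fit_transition_model,
    gaussian_entropy,
)

__all__ = [
    "Bipartition",
    "PhiOptions",
    "PhiResult",
    "phi_g",
    "normalization_K",
    "normalized_phi",
    "select_time_lag",
]

logger = logging.getLogger("netphi.phi_core")

_LN2 = float(np.log(2.0))

#: Partitions whose smaller-side entropy falls below this (in bits) are
#: flagged invalid rather than risking division by ~0.
K_SAFEGUARD_BITS = 1e-6

#: Floating-point phi more negative than this signals optimizer failure.
NEGATIVE_PHI_TOL = 1e-6

#: Problems with at most this many free A' entries use the exact-Hessian
#: Newton path; larger ones fall back to L-BFGS (Hessian solves scale as the
#: cube of the parameter count).
_NEWTON_PARAM_CAP = 400


@dataclass(frozen=True, order=True)
class Bipartition:
    """A two-way split of channel indices, stored in canonical form.

    Canonical form: both groups sorted ascending, and ``group1`` is the group
    containing the lowest channel index (the labels 1/2 carry no meaning).
    """

    group1: tuple[int, ...]
    group2: tuple[int, ...]

    def __init__(self, group1, group2):
        g1 = tuple(sorted(int(i) for i in group1))
        g2 = tuple(sorted(int(i) for i in group2))
        if not g1 or not g2:
            raise InvalidArgumentError("both groups must be non-empty")
        if set(g1) & set(g2):
            raise InvalidArgumentError("groups must be disjoint")
        if len(set(g1)) != len(g1) or len(set(g2)) != len(g2):
            raise InvalidArgumentError("duplicate channel index in a group")
        if g2[0] < g1[0]:
            g1, g2 = g2, g1
        object.__setattr__(self, "group1", g1)
        object.__setattr__(self, "group2", g2)

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(sorted(self.group1 + self.group2))

    @property
    def n_channels(self) -> int:
        return len(self.group1) + len(self.group2)

    def validate_for(self, n: int) -> None:
        if self.channels != tuple(range(n)):
            raise InvalidArgumentError(
                f"partition channels {self.channels} do not cover 0..{n - 1}"
            )

    def labels(self, n: int | None = None) -> np.ndarray:
        """0/1 membership vector over the channel set."""
        if n is None:
            n = self.n_channels
        self.validate_for(n)
        out = np.zeros(n, dtype=int)
        out[list(self.group2)] = 1
        return out

    @classmethod
    def from_labels(cls, labels) -> "Bipartition":
        labels = np.asarray(labels)
        idx = np.arange(labels.size)
        vals = np.unique(labels)
        if vals.size != 2:
            raise InvalidArgumentError(
                f"labels must take exactly 2 values, got {vals.size}"
            )
        return cls(idx[labels == vals[0]], idx[labels == vals[1]])

    def to_json_dict(self) -> dict:
        return {"group1": list(self.group1), "group2": list(self.group2)}

    @classmethod
    def from_json_dict(cls, d: dict) -> "Bipartition":
        return cls(d["group1"], d["group2"])


@dataclass(frozen=True)
class PhiOptions:
    """Optimizer settings for the disconnected-model fit."""

    tol: float = 1e-8          # gradient-norm convergence threshold
    ftol: float = 1e-12        # per-iteration objective-decrease threshold
    max_iter: int = 1000
    k_safeguard_bits: float = K_SAFEGUARD_BITS


@dataclass(frozen=True)
class PhiResult:
    """Integrated information across one bipartition, with diagnostics."""

    phi_bits: float
    K_bits: float
    normalized_phi: float
    partition: Bipartition
    A_prime: np.ndarray = field(compare=False, repr=False)
    Sigma_Eprime: np.ndarray = field(compare=False, repr=False)
    iterations: int = 0
    final_grad_norm: float = np.nan
    converged: bool = True
    valid: bool = True

    def to_json_dict(self) -> dict:
        return {
            "phi_bits": self.phi_bits,
            "K_bits": self.K_bits,
            "normalized_phi": self.normalized_phi,
            "normalized_phi_units": "bits (normalized)",
            "partition": self.partition.to_json_dict(),
            "A_prime": self.A_prime.tolist(),
            "Sigma_Eprime": self.Sigma_Eprime.tolist(),
            "iterations": self.iterations,
            "final_grad_norm": self.final_grad_norm,
            "converged": self.converged,
            "valid": self.valid,
        }


def _block_mask(partition: Bipartition, n: int) -> np.ndarray:
    """Boolean mask of the within-block entries of A'."""
    labels = partition.labels(n)
    return labels[:, None] == labels[None, :]


@njit(cache=True)
def _chol_flag(M):
    """Cholesky factor with a success flag instead of an exception."""
    n = M.shape[0]
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            s = M[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return L, False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return L, True


@njit(cache=True)
def _chol_solve_vec(L, b):
    n = L.shape[0]
    x = b.copy()
    for i in range(n):
        for k in range(i):
            x[i] -= L[i, k] * x[k]
        x[i] /= L[i, i]
    for i in range(n - 1, -1, -1):
        for k in range(i + 1, n):
            x[i] -= L[k, i] * x[k]
        x[i] /= L[i, i]
    return x


@njit(cache=True)
def _phi_newton(A, S, SE, free_i, free_j, theta0, logdet_SE, gtol, ftol, maxiter):
    """Damped-Newton minimization of the KL objective over free A' entries.

    Uses the analytic Hessian
    H[(i,j),(k,l)] = G_ik (S - S D^T G D S)_lj - B_il B_kj  (B = G D S),
    with Levenberg damping when H is not positive definite and a
    backtracking line search; quadratic convergence makes it far cheaper
    than quasi-Newton for the small systems of exhaustive MIB searches.
    Returns (theta, f, iterations, grad_max, converged).
    """  # pragma: no cover - exercised through phi_g
    n = A.shape[0]
    p = free_i.size
    theta = theta0.copy()
    f_prev = np.inf
    f = np.inf
    gmax = np.inf
    converged = False
    it = 0
    D = np.empty((n, n))
    for it in range(1, maxiter + 1):
        for i in range(n):
            for j in range(n):
                D[i, j] = A[i, j]
        for a in range(p):
            D[free_i[a], free_j[a]] -= theta[a]
        M = SE + D @ S @ D.T
        M = 0.5 * (M + M.T)
        LM, ok = _chol_flag(M)
        if not ok:
            break
        logdet_M = 0.0
        for i in range(n):
            logdet_M += 2.0 * np.log(LM[i, i])
        f = 0.5 * (logdet_M - logdet_SE)
        G = np.linalg.inv(M)
        G = 0.5 * (G + G.T)
        B = G @ D @ S
        grad = np.empty(p)
        gmax = 0.0
        for a in range(p):
            grad[a] = -B[free_i[a], free_j[a]]
            if abs(grad[a]) > gmax:
                gmax = abs(grad[a])
        if gmax <= gtol or (f_prev - f) < ftol and it > 1:
            converged = gmax <= gtol or abs(f_prev - f) < ftol
            break
        f_prev = f
        C = S @ D.T @ B
        SmC = S - 0.5 * (C + C.T)
        H = np.empty((p, p))
        for a in range(p):
            ia, ja = free_i[a], free_j[a]
            for b in range(a, p):
                ib, jb = free_i[b], free_j[b]
                h = G[ia, ib] * SmC[jb, ja] - B[ia, jb] * B[ib, ja]
                H[a, b] = h
                H[b, a] = h
        # Levenberg damping until the (possibly indefinite) Hessian factors
        lam = 0.0
        base = 0.0
        for a in range(p):
            base += H[a, a]
        base = max(base / p, 1e-12)
        delta = np.zeros(p)
        solved = False
        for _attempt in range(40):
            Hd = H.copy()
            for a in range(p):
                Hd[a, a] += lam
            LH, okH = _chol_flag(Hd)
            if okH:
                delta = _chol_solve_vec(LH, -grad)
                solved = True
                break
            lam = base * 1e-8 if lam == 0.0 else lam * 10.0
        if not solved:
            break
        # backtracking line search (Armijo)
        slope = 0.0
        for a in range(p):
            slope += grad[a] * delta[a]
        if slope >= 0.0:
            delta = -grad
            slope = -(grad @ grad)
        t = 1.0
        accepted = False
        for _ls in range(40):
            theta_new = theta + t * delta
            for i in range(n):
                for j in range(n):
                    D[i, j] = A[i, j]
            for a in range(p):
                D[free_i[a], free_j[a]] -= theta_new[a]
            Mn = SE + D @ S @ D.T
            Mn = 0.5 * (Mn + Mn.T)
            Ln, okn = _chol_flag(Mn)
            if okn:
                ld = 0.0
                for i in range(n):
                    ld += 2.0 * np.log(Ln[i, i])
                f_new = 0.5 * (ld - logdet_SE)
                if f_new <= f + 1e-4 * t * slope:
                    theta = theta_new
                    accepted = True
                    break
            t *= 0.5
        if not accepted:
            break
    return theta, f, it, gmax, converged


@njit(cache=True)
def _phi_objective(theta, A, S, SE, free_idx, logdet_SE):
    """KL objective (nats) and gradient over the free entries of A'.

    f = 1/2 (ln det(SE + D S D^T) - ln det SE) with D = A - A',
    grad wrt the free entries of A' = -(M^{-1} D S)[free].
    """  # pragma: no cover - exercised through phi_g
    n = A.shape[0]
    D = A.copy().reshape(-1)
    for k in range(free_idx.size):
        D[free_idx[k]] -= theta[k]
    D = D.reshape(n, n)
    M = SE + D @ S @ D.T
    M = 0.5 * (M + M.T)
    L = np.linalg.cholesky(M)
    logdet_M = 0.0
    for i in range(n):
        logdet_M += 2.0 * np.log(L[i, i])
    f = 0.5 * (logdet_M - logdet_SE)
    Z = (np.linalg.solve(M, D) @ S).reshape(-1)
    grad = np.empty(free_idx.size)
    for k in range(free_idx.size):
        grad[k] = -Z[free_idx[k]]
    return f, grad


def phi_g(
    model: GaussianTransitionModel,
    partition: Bipartition,
    opts: PhiOptions | None = None,
) -> PhiResult:
    """Geometric integrated information, in bits, across ``partition``.

    Minimizes ``1/2 log2 det(Sigma_E + (A-A') Sigma_past (A-A')^T) -
    1/2 log2 det(Sigma_E)`` over block-constrained A', starting from the
    block-diagonal part of A (with one restart from zeros on failure).  The
    returned value never exceeds the objective at the initialization point.
    """
    if opts is None:
        opts = PhiOptions()
    n = model.n_channels
    partition.validate_for(n)

    A = model.A
    S = model.Sigma_past
    SE = 0.5 * (model.Sigma_E + model.Sigma_E.T)
    # PD checks double as the domain guard for the whole computation.
    logdet_SE = _chol_logdet(SE, "Sigma_E")
    _chol_logdet(S, "Sigma_past")

    mask = _block_mask(partition, n)
    free_idx = np.flatnonzero(mask.reshape(-1))
    A_c = np.ascontiguousarray(A)
    S_c = np.ascontiguousarray(S)
    SE_c = np.ascontiguousarray(SE)

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        return _phi_objective(theta, A_c, S_c, SE_c, free_idx, logdet_SE)

    free_i = (free_idx // n).astype(np.int64)
    free_j = (free_idx % n).astype(np.int64)
    use_newton = free_idx.size <= _NEWTON_PARAM_CAP

    def run(theta0: np.ndarray):
        """One optimizer pass; returns (theta, f, iterations, converged)."""
        if use_newton:
            theta, _f, nit, _gmax, conv = _phi_newton(
                A_c, S_c, SE_c, free_i, free_j,
                np.ascontiguousarray(theta0, dtype=float),
                logdet_SE, opts.tol, opts.ftol, opts.max_iter,
            )
            f, _ = objective(theta)
            return theta, float(f), int(nit), bool(conv)
        res = minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={
                "gtol": opts.tol,
                "ftol": opts.ftol,
                "maxiter": opts.max_iter,
                "maxcor": 20,
            },
        )
        # a stalled line search means no further objective decrease is
        # attainable, which satisfies the decrease-based stopping rule
        stalled = "ABNORMAL" in str(res.message)
        return (
            np.asarray(res.x),
            float(res.fun),
            int(res.nit),
            bool(res.success or stalled),
        )

    theta_init = A[mask]
    f_init, _ = objective(theta_init)
    theta_star, f_star, iterations, converged = run(theta_init)
    if not converged:
        retry = run(np.zeros_like(theta_init))
        if retry[1] < f_star:
            theta_star, f_star, iterations, converged = retry
        else:
            converged = converged or retry[3]
    if not converged:
        warnings.warn(
            "phi_g optimizer reached its iteration cap without convergence",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning(
            "phi_g did not converge (partition %s)", partition.to_json_dict()
        )

    # Never report worse than the starting point.
    if f_star > f_init:
        theta_star, f_star, iterations = theta_init, f_init, 0
    grad = objective(theta_star)[1]

    phi_bits = f_star / _LN2
    if phi_bits < 0.0:
        if phi_bits > -NEGATIVE_PHI_TOL:
            phi_bits = 0.0
        else:
            raise NotPositiveDefiniteError(
                f"phi optimization produced {phi_bits:.3e} bits < 0; "
                "optimizer failure"
            )

    A_prime = np.zeros((n, n))
    A_prime[mask] = theta_star
    D = A - A_prime
    Sigma_Eprime = SE + D @ S @ D.T
    Sigma_Eprime = 0.5 * (Sigma_Eprime + Sigma_Eprime.T)

    K_bits, K_valid = _normalization_K_checked(
        S, partition, opts.k_safeguard_bits
    )
    normalized = phi_bits / K_bits if K_valid else np.nan

    return PhiResult(
        phi_bits=phi_bits,
        K_bits=K_bits,
        normalized_phi=normalized,
        partition=partition,
        A_prime=A_prime,
        Sigma_Eprime=Sigma_Eprime,
        iterations=iterations,
        final_grad_norm=float(np.max(np.abs(grad))) if np.size(grad) else 0.0,
        converged=converged,
        valid=K_valid,
    )


def _normalization_K_checked(
    Sigma_past: np.ndarray, partition: Bipartition, safeguard: float
) -> tuple[float, bool]:
    n = Sigma_past.shape[0]
    partition.validate_for(n)
    entropies = []
    for group in (partition.group1, partition.group2):
        idx = np.asarray(group)
        entropies.append(gaussian_entropy(Sigma_past[np.ix_(idx, idx)]))
    K = float(min(entropies))
    return K, K > safeguard


def normalization_K(
    Sigma_past: np.ndarray,
    partition: Bipartition,
    safeguard: float = K_SAFEGUARD_BITS,
) -> float:
    """Entropy normalization: min over the two groups of the Gaussian entropy
    of that group's marginal past covariance, in bits.

    Raises if a marginal block is not positive definite.  Values at or below
    ``safeguard`` indicate an invalid partition for normalized phi; callers
    that must not divide by ~0 should use :func:`normalized_phi`, which flags
    such partitions instead.
    """
    K, _ = _normalization_K_checked(Sigma_past, partition, safeguard)
    return K


def normalized_phi(
    model: GaussianTransitionModel,
    partition: Bipartition,
    opts: PhiOptions | None = None,
) -> PhiResult:
    """Phi across ``partition`` together with its entropy-normalized value."""
    return phi_g(model, partition, opts)


def select_time_lag(
    ts: TimeSeries,
    lags,
    search: str = "brute",
    opts: PhiOptions | None = None,
    seed: int = 0,
    **search_kwargs,
) -> tuple[int, "pd.DataFrame"]:
    """Choose the lag that maximizes integrated information across the MIB.

    For each candidate lag the full model is fitted, the MIB is found by the
    chosen search (``brute`` or ``spectral``) and phi across it recorded;
    the returned ``tau_star`` maximizes phi with ties broken toward the
    smallest lag.  Returns the lag and a per-lag table with an
    ``all_near_zero`` flag set when every phi is below 0.01 bits (no
    temporal integration at any lag).
    """
    import pandas as pd

    from . import partition_search

    lags = [int(ell) for ell in lags]
    if not lags:
        raise InvalidArgumentError("lag list is empty")
    if search not in ("brute", "spectral"):
        raise InvalidArgumentError(f"unknown search method {search!r}")

    rows = []
    for lag in lags:
        model = fit_transition_model(ts, lag)
        if search == "brute":
            result = partition_search.brute_force_mib(model, opts)
        else:
            result = partition_search.spectral_mib(
                ts, lag, opts, seed=seed, **search_kwargs
            )
        best = result.best
        rows.append(
            {
                "tau": lag,
                "phi_bits": best.phi_bits,
                "normalized_phi": best.normalized_phi,
                "partition": best.partition.to_json_dict(),
            }
        )
    table = pd.DataFrame(rows)
    all_near_zero = bool((table["phi_bits"] < 0.01).all())
    table.attrs["all_near_zero"] = all_near_zero
    if all_near_zero:
        warnings.warn(
            "integrated information is below 0.01 bits at every candidate "
            "lag; the selected lag is not meaningful",
            RuntimeWarning,
            stacklevel=2,
        )
    # idxmax returns the first maximizer; sorting by tau first makes the
    # tie-break toward the smallest lag explicit.
    order = table.sort_values("tau").reset_index(drop=True)
    tau_star = int(order.loc[order["phi_bits"].idxmax(), "tau"])
    return tau_star, table
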