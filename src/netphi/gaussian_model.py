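"""Gaussian transition models of multivariate time series.

The present of an n-channel signal is modelled as a linear function of its
past at lag ``tau``::

    X_t = A X_{t-tau} + E

where ``A`` is found from the normal equation
``A = Sigma_cross @ inv(Sigma_past)`` and the residual covariance
``Sigma_E = Sigma_present - A @ Sigma_cross.T`` equals the conditional
covariance of the present given the past.  For (approximately) Gaussian
signals this "full model" captures every spatiotemporal dependency that
integrated information is computed from.

All entropies and information quantities are in bits (base-2 logarithms).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ConditioningError,
    DegenerateDataError,
    InvalidArgumentError,
    NotPositiveDefiniteError,
)

__all__ = [
    "TimeSeries",
    "GaussianTransitionModel",
    "lagged_covariances",
    "fit_transition_model",
    "gaussian_entropy",
    "mutual_information_time",
    "read_timeseries",
    "write_timeseries",
]

#: Condition-number cap above which Sigma_past is refused (no silent ridge).
CONDITION_CAP = 1e12

#: Symmetric matrices are declared PSD if their smallest eigenvalue exceeds
#: -PSD_TOL * max(1, largest eigenvalue).
PSD_TOL = 1e-8

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class TimeSeries:
    """An m x n matrix of real-valued observations (rows = time points)."""

    data: np.ndarray
    channel_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise InvalidArgumentError("time series data must be a 2-D matrix")
        m, n = data.shape
        if m < 2 or n < 2:
            raise InvalidArgumentError(
                f"need at least 2 time points and 2 channels, got shape {data.shape}"
            )
        if not np.all(np.isfinite(data)):
            raise InvalidArgumentError("time series contains non-finite values")
        object.__setattr__(self, "data", data)
        if self.channel_labels is not None:
            labels = tuple(str(c) for c in self.channel_labels)
            if len(labels) != n:
                raise InvalidArgumentError(
                    f"{len(labels)} channel labels for {n} channels"
                )
            object.__setattr__(self, "channel_labels", labels)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class GaussianTransitionModel:
    """The fitted "full model" of a time series at lag ``tau``.

    Holds the lagged covariance structure, the regression matrix ``A`` and
    the residual covariance ``Sigma_E``.
    """

    tau: int
    Sigma_past: np.ndarray
    Sigma_present: np.ndarray
    Sigma_cross: np.ndarray
    A: np.ndarray
    Sigma_E: np.ndarray
    n_pairs: int = 0
    channel_labels: tuple[str, ...] | None = field(default=None, compare=False)

    @property
    def n_channels(self) -> int:
        return self.A.shape[0]

    @classmethod
    def from_var_coefficients(
        cls, A: np.ndarray, Sigma_noise: np.ndarray | None = None, tau: int = 1
    ) -> "GaussianTransitionModel":
        """Analytic model of a stationary VAR(1) process ``x_t = A x_{t-1} + e``.

        The stationary covariance solves the discrete Lyapunov equation
        ``Sigma = A Sigma A' + Sigma_noise``; lagged covariances follow from
        ``Cov(x_t, x_{t-tau}) = A^tau Sigma``.  Useful for constructing exact
        ground-truth models without simulation.
        """
        from scipy.linalg import solve_discrete_lyapunov

        A = np.asarray(A, dtype=float)
        n = A.shape[0]
        if A.shape != (n, n):
            raise InvalidArgumentError("A must be square")
        if np.max(np.abs(np.linalg.eigvals(A))) >= 1.0:
            raise InvalidArgumentError("VAR coefficient matrix is not stable")
        if Sigma_noise is None:
            Sigma_noise = np.eye(n)
        Sigma_noise = np.asarray(Sigma_noise, dtype=float)
        Sigma = solve_discrete_lyapunov(A, Sigma_noise)
        Sigma = 0.5 * (Sigma + Sigma.T)
        A_tau = np.linalg.matrix_power(A, tau)
        Sigma_cross = A_tau @ Sigma
        A_eff = np.linalg.solve(Sigma.T, Sigma_cross.T).T
        Sigma_E = Sigma - A_eff @ Sigma_cross.T
        Sigma_E = 0.5 * (Sigma_E + Sigma_E.T)
        return cls(
            tau=tau,
            Sigma_past=Sigma,
            Sigma_present=Sigma.copy(),
            Sigma_cross=Sigma_cross,
            A=A_eff,
            Sigma_E=Sigma_E,
            n_pairs=0,
        )


def _symmetrize(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def _check_psd(M: np.ndarray, name: str) -> None:
    w = np.linalg.eigvalsh(M)
    if w[0] < -PSD_TOL * max(1.0, abs(w[-1])):
        raise NotPositiveDefiniteError(
            f"{name} is not positive semidefinite (min eigenvalue {w[0]:.3e})"
        )


def lagged_covariances(
    ts: TimeSeries, tau: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample covariances of the aligned (past, present) pairs at lag ``tau``.

    Pairs are (x_{t-tau}, x_t) for t = tau+1 .. m, i.e. ``m - tau`` pairs.
    Each channel is demeaned over its own aligned window and covariances are
    normalized by (number of pairs - 1).

    Returns
    -------
    (Sigma_past, Sigma_present, Sigma_cross)
        ``Sigma_cross[i, j] = Cov(x_t[i], x_{t-tau}[j])``.
    """
    m = ts.n_timepoints
    if not isinstance(tau, (int, np.integer)) or tau < 1 or tau > m - 2:
        raise InvalidArgumentError(
            f"lag tau={tau} outside the valid range [1, {m - 2}] for m={m}"
        )
    past = ts.data[: m - tau]
    present = ts.data[tau:]
    k = m - tau

    for name, block in (("past", past), ("present", present)):
        var = block.var(axis=0, ddof=1)
        # relative floor so a constant channel is caught despite the
        # rounding residue its mean subtraction leaves behind
        floor = 1e-18 * (1.0 + np.abs(block).max(axis=0) ** 2)
        if np.any(var <= floor):
            ch = int(np.argmax(var <= floor))
            label = (
                ts.channel_labels[ch] if ts.channel_labels is not None else str(ch)
            )
            raise DegenerateDataError(
                f"channel {label} has zero variance in the {name} window"
            )

    past_c = past - past.mean(axis=0)
    present_c = present - present.mean(axis=0)
    denom = k - 1
    Sigma_past = _symmetrize(past_c.T @ past_c / denom)
    Sigma_present = _symmetrize(present_c.T @ present_c / denom)
    Sigma_cross = present_c.T @ past_c / denom
    return Sigma_past, Sigma_present, Sigma_cross


def fit_transition_model(ts: TimeSeries, tau: int) -> GaussianTransitionModel:
    """Fit the Gaussian full model at lag ``tau`` via the normal equation."""
    Sigma_past, Sigma_present, Sigma_cross = lagged_covariances(ts, tau)
    cond = np.linalg.cond(Sigma_past)
    if not np.isfinite(cond) or cond > CONDITION_CAP:
        raise ConditioningError(
            f"Sigma_past is ill-conditioned (condition number {cond:.3e} "
            f"exceeds cap {CONDITION_CAP:.0e}); no ridge is applied silently",
            condition_number=float(cond),
        )
    # A = Sigma_cross @ inv(Sigma_past), solved without forming the inverse.
    A = np.linalg.solve(Sigma_past.T, Sigma_cross.T).T
    Sigma_E = _symmetrize(Sigma_present - A @ Sigma_cross.T)
    _check_psd(Sigma_E, "residual covariance Sigma_E")
    return GaussianTransitionModel(
        tau=int(tau),
        Sigma_past=Sigma_past,
        Sigma_present=Sigma_present,
        Sigma_cross=Sigma_cross,
        A=A,
        Sigma_E=Sigma_E,
        n_pairs=ts.n_timepoints - int(tau),
        channel_labels=ts.channel_labels,
    )


def _chol_logdet(Sigma: np.ndarray, name: str) -> float:
    """log-determinant (natural log) via Cholesky; raises if not PD."""
    try:
        L = np.linalg.cholesky(_symmetrize(np.asarray(Sigma, dtype=float)))
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError(f"{name} is not positive definite") from None
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def gaussian_entropy(Sigma: np.ndarray) -> float:
    """Differential entropy of a Gaussian with covariance ``Sigma``, in bits.

    H = 1/2 * log2((2*pi*e)^n * det Sigma).  Block-diagonal covariances give
    the sum of their blocks' entropies.
    """
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    n = Sigma.shape[0]
    logdet = _chol_logdet(Sigma, "Sigma")
    return 0.5 * (n * np.log(2.0 * np.pi * np.e) + logdet) / _LN2


def mutual_information_time(model: GaussianTransitionModel) -> float:
    """Total mutual information between past and present, in bits.

    I(X_t ; X_{t-tau}) = 1/2 * log2(det Sigma_present / det Sigma_E) — the
    upper bound that integrated information can never exceed.
    """
    ld_present = _chol_logdet(model.Sigma_present, "Sigma_present")
    ld_E = _chol_logdet(model.Sigma_E, "Sigma_E")
    return 0.5 * (ld_present - ld_E) / _LN2


# ---------------------------------------------------------------------------
# Delimited-text I/O

def read_timeseries(path_or_buffer, delimiter: str | None = None) -> TimeSeries:
    """Read a time series from delimited text (rows = time points).

    A single header row of channel labels is detected automatically.
    The delimiter is sniffed between comma and tab/whitespace when not given.
    """
    if isinstance(path_or_buffer, (str,)) or hasattr(path_or_buffer, "read"):
        df = pd.read_csv(
            path_or_buffer,
            sep=delimiter if delimiter is not None else None,
            engine="python",
            header=None,
            comment="#",
        )
    else:
        raise InvalidArgumentError("expected a path or file-like object")
    first = df.iloc[0]
    has_header = not all(
        isinstance(v, (int, float, np.integer, np.floating))
        or str(v).replace(".", "").replace("-", "").replace("e", "").replace("+", "").isdigit()
        for v in first
    )
    try:
        first.astype(float)
        has_header = False
    except (ValueError, TypeError):
        has_header = True
    if has_header:
        labels = tuple(str(v) for v in first)
        data = df.iloc[1:].astype(float).to_numpy()
        return TimeSeries(data=data, channel_labels=labels)
    return TimeSeries(data=df.astype(float).to_numpy())


def write_timeseries(ts: TimeSeries, path, delimiter: str = ",") -> None:
    """Write a time series as delimited text with an optional label header."""
    if isinstance(path, (str,)):
        handle: io.TextIOBase = open(path, "w")
        close = True
    else:
        handle, close = path, False
    try:
        if ts.channel_labels is not None:
            handle.write(delimiter.join(ts.channel_labels) + "\n")
        np.savetxt(handle, ts.data, delimiter=delimiter, fmt="%.10g")
    finally:
        if close:
            handle.close()
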