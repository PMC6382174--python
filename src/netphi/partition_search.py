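"""Search for the minimum information bipartition (MIB).

Small systems are searched exhaustively: every one of the 2^(n-1) - 1
unordered bipartitions is scored by normalized integrated information and
the minimizer returned.  For large systems that search is intractable, so
the spectral method shrinks it to a fixed candidate grid: the Pearson
correlation matrix of the data is mapped to non-negative edge weights by a
power adjacency transform w = ((r+1)/2)^beta over 10 log-spaced beta values
(plus the raw correlation matrix with negative entries floored at zero),
each matrix is thresholded at 199 percentile cutoffs (0 to 0.99 in steps of
0.005), and normalized-cut spectral clustering bipartitions each of the
11 x 199 = 2189 thresholded graphs.  Normalized phi is then evaluated only
on the deduplicated candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from sklearn.metrics import rand_score

from .connectome_gen import WeightedGraph
from .exceptions import (
    DegenerateGraphError,
    InvalidArgumentError,
)
from .gaussian_model import GaussianTransitionModel, TimeSeries, fit_transition_model
from .phi_core import Bipartition, PhiOptions, PhiResult, phi_g

__all__ = [
    "CandidateSet",
    "MIBSearchResult",
    "enumerate_bipartitions",
    "brute_force_mib",
    "power_adjacency",
    "threshold_at_percentile",
    "spectral_bipartition",
    "ncut_value",
    "candidate_partitions",
    "spectral_mib",
    "rand_index",
    "read_square_matrix",
    "write_square_matrix",
]

#: enumerate_bipartitions refuses beyond this (2^24 partitions).
ENUMERATION_CAP = 25

#: brute_force_mib refuses beyond this many channels.
BRUTE_FORCE_CAP = 18


@dataclass(frozen=True)
class CandidateSet:
    """Deduplicated spectral candidate partitions with provenance.

    Each entry of ``candidates`` is ``(Bipartition, provenance)`` where the
    provenance dict records the source matrix ("raw" or its beta value) and
    the percentile cutoff that produced the partition first.
    """

    candidates: tuple[tuple[Bipartition, dict], ...]
    n_generated: int
    n_unique: int
    n_skipped: int = 0

    def partitions(self) -> list[Bipartition]:
        return [p for p, _ in self.candidates]


@dataclass(frozen=True)
class MIBSearchResult:
    best: PhiResult
    method: str
    n_evaluated: int
    n_skipped_invalid: int = 0
    table: pd.DataFrame | None = field(default=None, compare=False, repr=False)

    def to_json_dict(self) -> dict:
        out = {
            "best": self.best.to_json_dict(),
            "method": self.method,
            "n_evaluated": self.n_evaluated,
            "n_skipped_invalid": self.n_skipped_invalid,
        }
        if self.table is not None:
            tbl = self.table.copy()
            tbl["partition"] = tbl["partition"].map(
                lambda p: p.to_json_dict() if isinstance(p, Bipartition) else p
            )
            out["candidates"] = tbl.to_dict(orient="records")
        return out


def enumerate_bipartitions(n: int) -> Iterator[Bipartition]:
    """Yield every unordered bipartition of channels 0..n-1 exactly once.

    Channel 0 is pinned to group1, so group2 ranges over the non-empty
    subsets of {1, .., n-1}: 2^(n-1) - 1 canonical partitions.
    """
    if n < 2 or n > ENUMERATION_CAP:
        raise InvalidArgumentError(
            f"n={n} outside the supported range [2, {ENUMERATION_CAP}]"
        )
    rest = list(range(1, n))
    for mask in range(1, 2 ** (n - 1)):
        group2 = [rest[b] for b in range(n - 1) if mask >> b & 1]
        group1 = [0] + [rest[b] for b in range(n - 1) if not mask >> b & 1]
        yield Bipartition(group1, group2)


def _evaluate_partitions(model, partitions, opts, provenance=None):
    """Score normalized phi on each partition; returns (rows, best_result)."""
    from .phi_core import _normalization_K_checked

    if opts is None:
        opts = PhiOptions()
    rows = []
    best: PhiResult | None = None
    best_key = None
    n_skipped = 0
    for idx, part in enumerate(partitions):
        K, valid = _normalization_K_checked(
            model.Sigma_past, part, opts.k_safeguard_bits
        )
        if not valid:
            n_skipped += 1
            rows.append(
                {
                    "partition": part,
                    "phi_bits": np.nan,
                    "K_bits": K,
                    "normalized_phi": np.nan,
                    "valid": False,
                    "provenance": provenance[idx] if provenance else None,
                }
            )
            continue
        result = phi_g(model, part, opts)
        rows.append(
            {
                "partition": part,
                "phi_bits": result.phi_bits,
                "K_bits": result.K_bits,
                "normalized_phi": result.normalized_phi,
                "valid": True,
                "provenance": provenance[idx] if provenance else None,
            }
        )
        # ties: smaller phi_bits, then earlier (lexicographic / provenance)
        key = (result.normalized_phi, result.phi_bits, result.partition.group1)
        if best_key is None or key < best_key:
            best, best_key = result, key
    return rows, best, n_skipped


def brute_force_mib(
    model: GaussianTransitionModel, opts: PhiOptions | None = None
) -> MIBSearchResult:
    """Exhaustive MIB search: the ground truth for small systems."""
    n = model.n_channels
    if n > BRUTE_FORCE_CAP:
        raise InvalidArgumentError(
            f"brute-force search is capped at {BRUTE_FORCE_CAP} channels "
            f"(got {n}); use spectral_mib for larger systems"
        )
    rows, best, n_skipped = _evaluate_partitions(
        model, enumerate_bipartitions(n), opts
    )
    if best is None:
        raise DegenerateGraphError(
            "every bipartition was excluded by the entropy safeguard"
        )
    return MIBSearchResult(
        best=best,
        method="brute",
        n_evaluated=len(rows) - n_skipped,
        n_skipped_invalid=n_skipped,
        table=pd.DataFrame(rows),
    )


def power_adjacency(corr: np.ndarray, beta: float) -> WeightedGraph:
    """Map correlations to edge weights w_ij = ((r_ij + 1)/2)^beta.

    Perfect correlation maps to weight 1, perfect anticorrelation to 0; the
    diagonal is zeroed.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise InvalidArgumentError("correlation matrix must be square")
    if beta < 1:
        raise InvalidArgumentError("beta must be >= 1")
    if np.any(np.abs(corr) > 1 + 1e-9):
        raise InvalidArgumentError("correlation entries must lie in [-1, 1]")
    r = np.clip(0.5 * (corr + corr.T), -1.0, 1.0)
    W = ((r + 1.0) / 2.0) ** beta
    np.fill_diagonal(W, 0.0)
    return WeightedGraph(weights=W)


def threshold_at_percentile(graph: WeightedGraph, pct: float) -> WeightedGraph:
    """Zero every weight strictly below the pct quantile of the off-diagonal
    upper-triangle weights.  pct = 0 returns the graph unchanged."""
    if not 0.0 <= pct <= 0.99:
        raise InvalidArgumentError("percentile must lie in [0, 0.99]")
    W = graph.weights
    iu = np.triu_indices(graph.n, k=1)
    cutoff = np.quantile(W[iu], pct)
    out = np.where(W < cutoff, 0.0, W)
    np.fill_diagonal(out, 0.0)
    return WeightedGraph(weights=out, modules=graph.modules)


def _kmeans_two(points: np.ndarray, seed: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic 2-means: seeded random first center, farthest-point
    second center, then Lloyd iterations to convergence."""
    rng = np.random.default_rng(seed)
    n = points.shape[0]
    c0 = points[int(rng.integers(n))]
    d0 = np.linalg.norm(points - c0, axis=1)
    c1 = points[int(np.argmax(d0))]
    centers = np.stack([c0, c1])
    labels = np.full(n, -1, dtype=int)
    for _iteration in range(max_iter):
        dists = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2)
        new_labels = np.argmin(dists, axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(2):
            if np.any(labels == c):
                centers[c] = points[labels == c].mean(axis=0)
    return labels


def spectral_bipartition(graph: WeightedGraph, seed: int = 0) -> Bipartition:
    """Spectral normalized-cut bipartition of a weighted graph.

    Takes the eigenvectors of the 2 smallest eigenvalues of the graph
    Laplacian L = D - W and 2-means clusters the rows (deterministic
    farthest-point initialization from ``seed``).  Following the
    splitting-point selection of the Ncut method, the sweep cuts along the
    Fiedler ordering are also scored, the partition with the smallest Ncut
    value is kept and polished by greedy single-node moves; a sign split of
    the Fiedler vector backs up a degenerate clustering.
    """
    W = graph.weights
    n = graph.n
    if n < 2:
        raise InvalidArgumentError("spectral bipartition requires >= 2 nodes")
    if not np.any(W > 0):
        raise DegenerateGraphError("all-zero weight matrix")
    L = np.diag(W.sum(axis=1)) - W
    eigvals, eigvecs = np.linalg.eigh(0.5 * (L + L.T))
    U = eigvecs[:, :2]
    fiedler = eigvecs[:, 1]

    candidates: list[np.ndarray] = []
    # a few deterministic k-means restarts guard against a poor farthest-
    # point initialization on weakly structured graphs
    for restart, sub_seed in enumerate(
        np.random.SeedSequence(seed).generate_state(4)
    ):
        labels = _kmeans_two(U, int(sub_seed))
        if labels.min() == labels.max():
            if restart > 0:
                continue
            labels = (fiedler > 0).astype(int)
            if labels.min() == labels.max():
                labels = (fiedler > np.median(fiedler)).astype(int)
            if labels.min() == labels.max():  # constant Fiedler vector
                labels = np.zeros(n, dtype=int)
                labels[n // 2:] = 1
        candidates.append(labels)
    order = np.argsort(fiedler, kind="stable")
    sweep = np.empty(n, dtype=int)
    for cut_at in range(1, n):
        sweep[:] = 1
        sweep[order[:cut_at]] = 0
        candidates.append(sweep.copy())

    best_labels, best_val = None, np.inf
    for cand in candidates:
        part_val = _ncut_from_labels(W, cand)
        if part_val < best_val - 1e-12:
            best_labels, best_val = cand, part_val
    best_labels = _refine_ncut(W, best_labels)
    return Bipartition.from_labels(best_labels)


def _refine_ncut(W: np.ndarray, labels: np.ndarray, max_passes: int = 10) -> np.ndarray:
    """Greedy single-node moves that strictly decrease the Ncut value.

    Polishes the spectral relaxation's rounding; moves that would empty a
    side are not considered.
    """
    labels = labels.copy()
    deg = W.sum(axis=1)
    side = labels == labels[0]  # boolean side-A membership
    vol_a = deg[side].sum()
    vol_b = deg[~side].sum()
    cut = W[np.ix_(np.flatnonzero(side), np.flatnonzero(~side))].sum()

    def value(c, va, vb):
        ta = c / va if va > 0 else 0.0
        tb = c / vb if vb > 0 else 0.0
        return ta + tb

    current = value(cut, vol_a, vol_b)
    n = labels.size
    for _ in range(max_passes):
        improved = False
        for i in range(n):
            in_a = side[i]
            if (side.sum() == 1 and in_a) or ((~side).sum() == 1 and not in_a):
                continue
            w_same = float(W[i] @ side) if in_a else float(W[i] @ ~side)
            w_other = deg[i] - w_same
            new_cut = cut - w_other + w_same
            if in_a:
                new_va, new_vb = vol_a - deg[i], vol_b + deg[i]
            else:
                new_va, new_vb = vol_a + deg[i], vol_b - deg[i]
            new_val = value(new_cut, new_va, new_vb)
            if new_val < current - 1e-12:
                side[i] = not in_a
                cut, vol_a, vol_b, current = new_cut, new_va, new_vb, new_val
                improved = True
        if not improved:
            break
    return np.where(side, 0, 1)


def _ncut_from_labels(W: np.ndarray, labels: np.ndarray) -> float:
    a = labels == labels[0]
    cut = W[np.ix_(np.flatnonzero(a), np.flatnonzero(~a))].sum()
    assoc_a = W[a, :].sum()
    assoc_b = W[~a, :].sum()
    term_a = cut / assoc_a if assoc_a > 0 else 0.0
    term_b = cut / assoc_b if assoc_b > 0 else 0.0
    return term_a + term_b


def ncut_value(graph: WeightedGraph, partition: Bipartition) -> float:
    """Normalized cut: cut(A,B)/assoc(A,V) + cut(A,B)/assoc(B,V).

    Zero iff no positive weight crosses the partition; a side with zero
    association contributes 0 (isolated side convention).
    """
    partition.validate_for(graph.n)
    W = graph.weights
    a = list(partition.group1)
    b = list(partition.group2)
    cut = W[np.ix_(a, b)].sum()
    assoc_a = W[a, :].sum()
    assoc_b = W[b, :].sum()
    term_a = cut / assoc_a if assoc_a > 0 else 0.0
    term_b = cut / assoc_b if assoc_b > 0 else 0.0
    return float(term_a + term_b)


def candidate_partitions(
    corr: np.ndarray,
    seed: int = 0,
    n_beta: int = 10,
    pct_step: float = 0.005,
    pct_max: float = 0.99,
) -> CandidateSet:
    """Generate the spectral candidate grid from a correlation matrix.

    Source matrices: ``n_beta`` power-adjacency transforms with beta
    log-spaced on [1, 10], plus the raw correlation matrix with negative
    entries floored at 0.  Each source is thresholded at every percentile in
    {0, pct_step, .., pct_max} and spectrally bipartitioned.  Defaults give
    the full 11 x 199 = 2189-candidate grid; degenerate thresholds (all-zero
    graph or unusable clustering) are counted as skipped.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1] or corr.shape[0] < 3:
        raise InvalidArgumentError("need a square correlation matrix with n >= 3")
    betas = np.logspace(0.0, 1.0, n_beta)
    sources: list[tuple[str, WeightedGraph]] = [
        (f"beta={b:.6g}", power_adjacency(corr, b)) for b in betas
    ]
    raw = np.clip(0.5 * (corr + corr.T), -1.0, 1.0)
    raw = np.where(raw < 0, 0.0, raw)
    np.fill_diagonal(raw, 0.0)
    sources.append(("raw", WeightedGraph(weights=raw)))

    n_steps = int(np.floor(pct_max / pct_step + 1e-9)) + 1
    pcts = np.round(np.arange(n_steps) * pct_step, 10)
    pcts = pcts[pcts <= pct_max + 1e-9]
    n_generated = len(sources) * len(pcts)

    seen: dict[tuple, tuple[Bipartition, dict]] = {}
    n_skipped = 0
    for source_name, source_graph in sources:
        for pct in pcts:
            try:
                thresholded = threshold_at_percentile(source_graph, float(pct))
                part = spectral_bipartition(thresholded, seed)
            except DegenerateGraphError:
                n_skipped += 1
                continue
            key = (part.group1, part.group2)
            if key not in seen:
                seen[key] = (
                    part,
                    {"source": source_name, "percentile": float(pct)},
                )
    candidates = tuple(seen.values())
    return CandidateSet(
        candidates=candidates,
        n_generated=n_generated,
        n_unique=len(candidates),
        n_skipped=n_skipped,
    )


def spectral_mib(
    ts: TimeSeries,
    tau: int,
    opts: PhiOptions | None = None,
    seed: int = 0,
    model: GaussianTransitionModel | None = None,
    n_beta: int = 10,
    pct_step: float = 0.005,
    pct_max: float = 0.99,
) -> MIBSearchResult:
    """Approximate MIB via the spectral candidate grid.

    Builds the Pearson correlation matrix of the time series, generates the
    candidate partitions, fits the transition model once (or reuses a
    pre-fitted one) and scores normalized phi on each unique candidate.
    """
    corr = np.corrcoef(ts.data, rowvar=False)
    cset = candidate_partitions(
        corr, seed=seed, n_beta=n_beta, pct_step=pct_step, pct_max=pct_max
    )
    if model is None:
        model = fit_transition_model(ts, tau)
    parts = [p for p, _ in cset.candidates]
    provenance = [prov for _, prov in cset.candidates]
    rows, best, n_skipped = _evaluate_partitions(model, parts, opts, provenance)
    if best is None:
        raise DegenerateGraphError(
            "every spectral candidate was excluded by the entropy safeguard"
        )
    return MIBSearchResult(
        best=best,
        method="spectral",
        n_evaluated=len(rows) - n_skipped,
        n_skipped_invalid=n_skipped,
        table=pd.DataFrame(rows),
    )


def rand_index(p1: Bipartition, p2: Bipartition) -> float:
    """Fraction of channel pairs on whose co-assignment the two partitions
    agree; 1 iff the partitions are identical up to group labels."""
    if p1.channels != p2.channels:
        raise InvalidArgumentError("partitions cover different channel sets")
    n = p1.n_channels
    return float(rand_score(p1.labels(n), p2.labels(n)))


# ---------------------------------------------------------------------------
# Delimited square-matrix I/O (correlation matrices, weighted graphs)

def read_square_matrix(path) -> np.ndarray:
    """Read a delimited (whitespace/comma) square matrix from text."""
    try:
        M = np.loadtxt(path, delimiter=",")
    except ValueError:
        M = np.loadtxt(path)
    M = np.atleast_2d(M)
    if M.shape[0] != M.shape[1]:
        raise InvalidArgumentError(f"matrix in {path!r} is not square: {M.shape}")
    return M


def write_square_matrix(M: np.ndarray, path, delimiter: str = ",") -> None:
    np.savetxt(path, np.asarray(M, dtype=float), delimiter=delimiter, fmt="%.10g")
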