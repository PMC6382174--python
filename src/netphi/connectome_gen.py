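"""Synthetic structural networks.

Three generator families drive the validation experiments:

* brain-like "Hebbian" connectomes — modular random graphs whose degree
  sequence is redistributed by a rich-get-richer rule, yielding the modular
  structure, rich cross-module connectivity and right-skewed (log-normal-ish)
  degree distributions characteristic of real connectomes;
* structurally cut networks — a brain-like network severed into two halves,
  which pins the minimum information bipartition onto the cut;
* Watts-Strogatz ring lattices with probabilistic rewiring, spanning the
  regular-to-random spectrum of global efficiency and modularity.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .exceptions import (
    GenerationFailureError,
    InvalidArgumentError,
)
from .phi_core import Bipartition

__all__ = [
    "WeightedGraph",
    "ConnectomeConfig",
    "brain_like_network",
    "cut_in_half",
    "watts_strogatz",
    "read_edgelist",
    "write_edgelist",
]

_RETRY_CAP = 100


@dataclass(frozen=True)
class WeightedGraph:
    """Symmetric non-negative adjacency with zero diagonal."""

    weights: np.ndarray
    modules: tuple[int, ...] | None = None
    binary: bool = False

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise InvalidArgumentError("weights must be a square matrix")
        if not np.all(np.isfinite(W)):
            raise InvalidArgumentError("weights contain non-finite values")
        if np.any(W < 0):
            raise InvalidArgumentError("weights must be non-negative")
        if not np.array_equal(W, W.T):
            raise InvalidArgumentError("weights must be exactly symmetric")
        if np.any(np.diag(W) != 0):
            raise InvalidArgumentError("diagonal must be exactly zero")
        if self.binary and not np.isin(W, (0.0, 1.0)).all():
            raise InvalidArgumentError("binary graph has weights outside {0, 1}")
        object.__setattr__(self, "weights", W)
        if self.modules is not None:
            mods = tuple(int(m) for m in self.modules)
            if len(mods) != W.shape[0]:
                raise InvalidArgumentError("one module label per node required")
            object.__setattr__(self, "modules", mods)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        return nx.from_numpy_array(self.weights)

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())


@dataclass(frozen=True)
class ConnectomeConfig:
    """Parameters of the brain-like generator.

    Defaults follow the generating rules of the validation study: module
    count ceil(ln n); within-module edge probability 4.5/s for module size
    s >= 4 (else 4/s); cross-module probability 3.3/(s*M) (else 3.75/(s*M),
    s = mean size of the two modules, M = module count); Hebbian percentile
    0.38; ceiling degree Z = (n + ln n)/7.
    """

    n: int
    seed: int = 0
    hebbian_percentile: float = 0.38
    p_int_large: float = 4.5
    p_int_small: float = 4.0
    p_ext_large: float = 3.3
    p_ext_small: float = 3.75
    small_module_size: int = 4
    retry_cap: int = _RETRY_CAP

    def __post_init__(self):
        if self.n < 10:
            raise InvalidArgumentError("brain-like generator requires n >= 10")
        if not 0 < self.hebbian_percentile < 1:
            raise InvalidArgumentError("hebbian_percentile must lie in (0, 1)")

    @property
    def module_count(self) -> int:
        return math.ceil(math.log(self.n))

    @property
    def degree_ceiling(self) -> float:
        return (self.n + math.log(self.n)) / 7.0


def _logistic(c, c0, s, Z):
    return 1.0 + (Z - 1.0) / (1.0 + np.exp(-(c - c0) / s))


def _fit_sigmoid(x: np.ndarray, y: np.ndarray, Z: float):
    """Least-squares 3-parameter logistic through the (x, y) target profile."""
    c0_init = float(np.median(x))
    s_init = max((x[-1] - x[0]) / 8.0, 0.5)
    try:
        with warnings.catch_warnings():
            # short plateau profiles make the covariance inestimable, which
            # is irrelevant here — only the fitted curve is used
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _logistic,
                x.astype(float),
                y.astype(float),
                p0=[c0_init, s_init, Z],
                maxfev=20000,
            )
        c0, s, Zf = popt
        if s <= 0 or not np.isfinite([c0, s, Zf]).all():
            raise RuntimeError
    except (RuntimeError, ValueError):
        c0, s, Zf = c0_init, s_init, Z
    return lambda c: _logistic(np.asarray(c, dtype=float), c0, s, Zf)


def _hebbian_target_profile(q: int, f: int, Z: float):
    """Build the (x, y) degree-remapping profile.

    x spans [q-1, f+5].  y is 1 on a head plateau (the punished low-degree
    regime, capped at floor(f/4) entries but never reaching degrees at or
    above the 38th-percentile threshold q), Z on a tail plateau covering
    degrees f..f+5 (the rewarded hubs), with a linear ramp in between.
    Confining the punish plateau below q and anchoring the reward plateau at
    the observed maximum degree keeps the redistribution from collapsing the
    whole degree sequence to ~1, which disconnects every draw.
    """
    x = np.arange(q - 1, f + 6)
    l = x.size
    n_head = max(1, min(f // 4, int(np.sum(x < q))))
    n_tail = max(1, min(6, l - n_head - 1))
    n_ramp = l - n_head - n_tail
    y = np.concatenate(
        [
            np.ones(n_head),
            np.linspace(1.0, Z, n_ramp + 2)[1:-1] if n_ramp > 0 else np.empty(0),
            np.full(n_tail, Z),
        ]
    )
    return x, y


def _cast_edges(rng: np.random.Generator, modules: np.ndarray, cfg: ConnectomeConfig):
    n = cfg.n
    M = cfg.module_count
    sizes = np.bincount(modules, minlength=M).astype(float)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if modules[i] == modules[j]:
                s = sizes[modules[i]]
                coef = cfg.p_int_large if s >= cfg.small_module_size else cfg.p_int_small
                p = coef / s
            else:
                s = 0.5 * (sizes[modules[i]] + sizes[modules[j]])
                coef = cfg.p_ext_large if s >= cfg.small_module_size else cfg.p_ext_small
                p = coef / (s * M)
            if rng.random() < min(p, 1.0):
                W[i, j] = W[j, i] = 1.0
    return W


def _hebbian_redistribute(rng: np.random.Generator, W: np.ndarray, cfg: ConnectomeConfig):
    n = cfg.n
    degrees = W.sum(axis=1).astype(int)
    f = int(degrees.max())
    if f < 2:
        return W  # too sparse for a meaningful profile; retry loop will catch
    q = max(int(np.quantile(degrees, cfg.hebbian_percentile)), 1)
    # hub ceiling never below the observed max degree, else small networks
    # (where (n + ln n)/7 ~ 2) lose their hubs entirely
    Z = max(cfg.degree_ceiling, float(f))
    x, y = _hebbian_target_profile(q, f, Z)
    S = _fit_sigmoid(x, y, Z)
    targets = np.maximum(np.rint(S(W.sum(axis=1))).astype(int), 1)
    for i in rng.permutation(n):
        deg = int(W[i].sum())
        want = int(targets[i])
        if deg < want:
            candidates = np.flatnonzero((W[i] == 0) & (np.arange(n) != i))
            add = rng.choice(
                candidates, size=min(want - deg, candidates.size), replace=False
            )
            W[i, add] = W[add, i] = 1.0
        elif deg > want:
            neighbours = np.flatnonzero(W[i] > 0)
            drop = rng.choice(neighbours, size=deg - want, replace=False)
            W[i, drop] = W[drop, i] = 0.0
    return W


def brain_like_network(cfg: ConnectomeConfig) -> WeightedGraph:
    """Generate a connected, modular, Hebbian-redistributed binary network.

    Nodes are assigned to ceil(ln n) modules uniformly at random, edges cast
    with module-size-dependent probabilities, and every node's degree pulled
    toward a fitted sigmoid of its provisional degree (rich get richer, poor
    get pruned).  Regenerates (fresh sub-seed) until connected, up to the
    retry cap.
    """
    root = np.random.SeedSequence(cfg.seed)
    for attempt_seed in root.spawn(cfg.retry_cap):
        rng = np.random.default_rng(attempt_seed)
        modules = rng.integers(cfg.module_count, size=cfg.n)
        # every module must be populated for the size-based probabilities
        if np.unique(modules).size < cfg.module_count:
            short = np.setdiff1d(np.arange(cfg.module_count), modules)
            swap = rng.choice(cfg.n, size=short.size, replace=False)
            modules[swap] = short
        W = _cast_edges(rng, modules, cfg)
        if W.sum() == 0:
            continue
        W = _hebbian_redistribute(rng, W, cfg)
        graph = WeightedGraph(weights=W, modules=tuple(modules), binary=True)
        if graph.is_connected():
            return graph
    raise GenerationFailureError(
        f"no connected network within {cfg.retry_cap} attempts (seed {cfg.seed})"
    )


def cut_in_half(cfg: ConnectomeConfig) -> tuple[WeightedGraph, Bipartition]:
    """A brain-like network severed into two internally connected halves.

    Whole modules are assigned to the halves as evenly as possible (module
    order shuffled by the seed), every cross-half edge is deleted, and the
    result is regenerated until both halves are internally connected.  The
    returned bipartition is the ground-truth cut: its integrated information
    converges to zero with infinite data.
    """
    if cfg.n % 2 != 0:
        raise InvalidArgumentError("cut networks require an even node count")
    root = np.random.SeedSequence((cfg.seed, 0x5EED))
    for k, attempt_seed in enumerate(root.spawn(cfg.retry_cap)):
        rng = np.random.default_rng(attempt_seed)
        sub = ConnectomeConfig(
            n=cfg.n,
            seed=int(rng.integers(2**31)),
            hebbian_percentile=cfg.hebbian_percentile,
            retry_cap=cfg.retry_cap,
        )
        try:
            graph = brain_like_network(sub)
        except GenerationFailureError:
            continue
        modules = np.asarray(graph.modules)
        order = rng.permutation(cfg.module_count)
        half_a: list[int] = []
        half_b: list[int] = []
        for m in order:
            members = np.flatnonzero(modules == m).tolist()
            if len(half_a) <= len(half_b):
                half_a.extend(members)
            else:
                half_b.extend(members)
        if not half_a or not half_b:
            continue
        W = graph.weights.copy()
        W[np.ix_(half_a, half_b)] = 0.0
        W[np.ix_(half_b, half_a)] = 0.0
        G = nx.from_numpy_array(W)
        if nx.is_connected(G.subgraph(half_a)) and nx.is_connected(
            G.subgraph(half_b)
        ):
            cut = Bipartition(half_a, half_b)
            return (
                WeightedGraph(weights=W, modules=graph.modules, binary=True),
                cut,
            )
    raise GenerationFailureError(
        f"no valid cut network within {cfg.retry_cap} attempts (seed {cfg.seed})"
    )


def watts_strogatz(n: int, k: int, p: float, seed: int = 0) -> WeightedGraph:
    """Connected Watts-Strogatz small-world graph.

    Ring lattice of ``n`` nodes each joined to its ``k`` nearest neighbours;
    every lattice edge is rewired with probability ``p`` to a uniformly
    random non-duplicate, non-self target (edge count conserved).
    Regenerated until connected.
    """
    if k % 2 != 0 or k <= 0 or k >= n:
        raise InvalidArgumentError("mean degree k must be even with 0 < k < n")
    if not 0.0 <= p <= 1.0:
        raise InvalidArgumentError("rewiring probability p must lie in [0, 1]")
    try:
        G = nx.connected_watts_strogatz_graph(n, k, p, tries=_RETRY_CAP, seed=seed)
    except nx.NetworkXError as exc:
        raise GenerationFailureError(
            f"no connected Watts-Strogatz graph within {_RETRY_CAP} tries "
            f"(n={n}, k={k}, p={p}, seed={seed})"
        ) from exc
    W = nx.to_numpy_array(G, nodelist=range(n))
    return WeightedGraph(weights=W, binary=True)


# ---------------------------------------------------------------------------
# Edge-list I/O (0-based node ids, optional module-label sidecar)

def write_edgelist(graph: WeightedGraph, path: str, modules_path: str | None = None):
    with open(path, "w") as fh:
        fh.write(f"# nodes: {graph.n}\n")
        rows, cols = np.nonzero(np.triu(graph.weights))
        for i, j in zip(rows, cols):
            w = graph.weights[i, j]
            if graph.binary:
                fh.write(f"{i} {j}\n")
            else:
                fh.write(f"{i} {j} {w:.10g}\n")
    if modules_path is not None and graph.modules is not None:
        with open(modules_path, "w") as fh:
            json.dump({"modules": list(graph.modules)}, fh)


def read_edgelist(path: str, modules_path: str | None = None) -> WeightedGraph:
    n = None
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "nodes:" in line:
                    n = int(line.split("nodes:")[1])
                continue
            parts = line.split()
            i, j = int(parts[0]), int(parts[1])
            w = float(parts[2]) if len(parts) > 2 else 1.0
            edges.append((i, j, w))
    if n is None:
        n = 1 + max(max(i, j) for i, j, _ in edges)
    W = np.zeros((n, n))
    binary = True
    for i, j, w in edges:
        W[i, j] = W[j, i] = w
        binary = binary and w in (0.0, 1.0)
    modules = None
    if modules_path is not None:
        with open(modules_path) as fh:
            modules = tuple(json.load(fh)["modules"])
    return WeightedGraph(weights=W, modules=modules, binary=binary)
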