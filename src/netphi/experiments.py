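"""Validation experiments: orchestration, seeding and reporting.

Three protocols probe the spectral MIB search end to end:

* small-network validation — brain-like oscillator networks small enough
  for an exhaustive MIB search; counts how often the spectral candidate
  grid attains the brute-force minimum of normalized phi;
* cut-network validation — large networks whose MIB is forced by severing
  them in half; measures how close the spectral partition's normalized phi
  comes to the ground-truth cut's, and their Rand index;
* structure sweep — Watts-Strogatz networks across the rewiring-probability
  grid; correlates (non-normalized) phi across the spectral MIB with global
  efficiency and with modularity Q.

A master seed deterministically derives per-network child seeds through a
numpy SeedSequence, so reports are bit-reproducible given (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.stats import spearmanr

from . import __version__ as _version
from .connectome_gen import ConnectomeConfig, WeightedGraph, brain_like_network, cut_in_half, watts_strogatz
from .dynamics_sim import RosslerParams, master_stability_coupling, simulate_rossler, simulate_var
from .exceptions import NetphiError
from .gaussian_model import fit_transition_model
from .graph_metrics import global_efficiency, modularity_newman
from .partition_search import brute_force_mib, rand_index, spectral_mib
from .phi_core import PhiOptions, normalized_phi

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_small_validation",
    "run_cut_validation",
    "run_structure_sweep",
    "default_p_grid",
]

logger = logging.getLogger("netphi.experiments")

#: Spectral phi counts as attaining the brute-force minimum below this
#: difference (both searches score partitions with the same estimator, so a
#: true match is exact to rounding).
MATCH_TOL = 1e-9


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared configuration for the three validation experiments."""

    experiment: str = "small_validation"
    network_sizes: tuple[int, ...] = (14, 16)
    networks_per_size: int = 50
    n_points: int = 25_000
    tau: int = 1
    sigma_rule: str | float = "msf_mid"   # "msf_mid" or a fixed value
    dynamics: str = "rossler"             # "rossler" or "var"
    record_every: int = 50                # integration steps per sample
    var_coupling: float = 0.6
    master_seed: int = 0
    # spectral candidate grid (defaults give the full 2189-candidate grid)
    n_beta: int = 10
    pct_step: float = 0.005
    pct_max: float = 0.99
    # phi optimizer tolerances (gradient norm, per-iteration decrease)
    opt_tol: float = 1e-8
    opt_ftol: float = 1e-12
    # Watts-Strogatz sweep settings
    ws_mean_degree: int = 6
    p_grid: tuple[float, ...] | None = None

    def child_seeds(self, count: int) -> list[int]:
        ss = np.random.SeedSequence(self.master_seed)
        return [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(count)]


@dataclass(frozen=True)
class ExperimentReport:
    """Per-network records plus aggregates recomputable from them."""

    experiment: str
    records: tuple[dict, ...]
    aggregates: dict
    config: dict
    n_failed: int = 0
    version: str = field(default=_version)

    def to_json_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "version": self.version,
            "config": self.config,
            "n_failed": self.n_failed,
            "records": list(self.records),
            "aggregates": self.aggregates,
        }

    def write_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def default_p_grid() -> tuple[float, ...]:
    """The rewiring-probability grid: 10 log-spaced values in [0.001, 0.1]
    followed by 9 linearly spaced values in (0.1, 1]."""
    log_part = np.logspace(np.log10(0.001), np.log10(0.1), 10)
    lin_part = np.linspace(0.1, 1.0, 10)[1:]
    return tuple(np.concatenate([log_part, lin_part]).tolist())


def _sigma_for(graph: WeightedGraph, cfg: ExperimentConfig) -> float:
    if cfg.sigma_rule != "msf_mid":
        return float(cfg.sigma_rule)
    if graph.is_connected():
        return master_stability_coupling(graph)[2]
    # cut networks: intersect the per-component synchronization intervals
    import networkx as nx

    lowers, uppers = [], []
    G = nx.from_numpy_array(graph.weights)
    for comp in nx.connected_components(G):
        idx = sorted(comp)
        if len(idx) < 2:
            continue
        sub = WeightedGraph(weights=graph.weights[np.ix_(idx, idx)])
        lo, hi, _ = master_stability_coupling(sub)
        lowers.append(lo)
        uppers.append(hi)
    if not lowers:
        raise NetphiError("no component large enough for a coupling bound")
    return 0.5 * (max(lowers) + min(uppers))


def _simulate(graph: WeightedGraph, cfg: ExperimentConfig, seed: int):
    if cfg.dynamics == "rossler":
        params = RosslerParams(
            sigma=_sigma_for(graph, cfg),
            n_points=cfg.n_points,
            record_every=cfg.record_every,
            seed=seed,
        )
        return simulate_rossler(graph, params)
    if cfg.dynamics == "var":
        return simulate_var(graph, cfg.var_coupling, cfg.n_points, seed=seed)
    raise NetphiError(f"unknown dynamics {cfg.dynamics!r}")


def _spectral_kwargs(cfg: ExperimentConfig) -> dict:
    return {
        "n_beta": cfg.n_beta,
        "pct_step": cfg.pct_step,
        "pct_max": cfg.pct_max,
    }


def run_small_validation(cfg: ExperimentConfig) -> ExperimentReport:
    """Spectral vs brute-force MIB on small brain-like networks."""
    if max(cfg.network_sizes) > 18:
        raise NetphiError("small validation requires network sizes <= 18")
    opts = PhiOptions(tol=cfg.opt_tol, ftol=cfg.opt_ftol)
    jobs = [(size, k) for size in cfg.network_sizes for k in range(cfg.networks_per_size)]
    seeds = cfg.child_seeds(len(jobs))
    records, n_failed = [], 0
    for (size, k), seed in zip(jobs, seeds):
        try:
            graph = brain_like_network(ConnectomeConfig(n=size, seed=seed))
            ts = _simulate(graph, cfg, seed)
            model = fit_transition_model(ts, cfg.tau)
            brute = brute_force_mib(model, opts)
            spectral = spectral_mib(
                ts, cfg.tau, opts, seed=seed, model=model, **_spectral_kwargs(cfg)
            )
        except NetphiError as exc:
            logger.warning("network (n=%d, seed=%d) failed: %s", size, seed, exc)
            n_failed += 1
            continue
        diff = spectral.best.normalized_phi - brute.best.normalized_phi
        records.append(
            {
                "size": size,
                "seed": seed,
                "brute_normalized_phi": brute.best.normalized_phi,
                "spectral_normalized_phi": spectral.best.normalized_phi,
                "normalized_phi_difference": diff,
                "exact_match": bool(diff <= MATCH_TOL),
                "rand_index": rand_index(
                    brute.best.partition, spectral.best.partition
                ),
                "brute_partition": brute.best.partition.to_json_dict(),
                "spectral_partition": spectral.best.partition.to_json_dict(),
            }
        )
    diffs = [r["normalized_phi_difference"] for r in records]
    aggregates = {
        "n_networks": len(records),
        "n_exact_match": int(sum(r["exact_match"] for r in records)),
        "match_fraction": float(np.mean([r["exact_match"] for r in records]))
        if records
        else np.nan,
        "mean_difference": float(np.mean(diffs)) if diffs else np.nan,
        "mean_rand_index": float(np.mean([r["rand_index"] for r in records]))
        if records
        else np.nan,
    }
    return ExperimentReport(
        experiment="small_validation",
        records=tuple(records),
        aggregates=aggregates,
        config=asdict(cfg),
        n_failed=n_failed,
    )


def run_cut_validation(cfg: ExperimentConfig) -> ExperimentReport:
    """Spectral MIB vs the ground-truth structural cut on severed networks."""
    opts = PhiOptions(tol=cfg.opt_tol, ftol=cfg.opt_ftol)
    jobs = [(size, k) for size in cfg.network_sizes for k in range(cfg.networks_per_size)]
    seeds = cfg.child_seeds(len(jobs))
    records, n_failed = [], 0
    for (size, k), seed in zip(jobs, seeds):
        try:
            graph, cut = cut_in_half(ConnectomeConfig(n=size, seed=seed))
            ts = _simulate(graph, cfg, seed)
            model = fit_transition_model(ts, cfg.tau)
            spectral = spectral_mib(
                ts, cfg.tau, opts, seed=seed, model=model, **_spectral_kwargs(cfg)
            )
            cut_result = normalized_phi(model, cut, opts)
        except NetphiError as exc:
            logger.warning("cut network (n=%d, seed=%d) failed: %s", size, seed, exc)
            n_failed += 1
            continue
        ri = rand_index(spectral.best.partition, cut)
        records.append(
            {
                "size": size,
                "seed": seed,
                "spectral_normalized_phi": spectral.best.normalized_phi,
                "cut_normalized_phi": cut_result.normalized_phi,
                "cut_phi_bits": cut_result.phi_bits,
                "abs_difference": abs(
                    spectral.best.normalized_phi - cut_result.normalized_phi
                ),
                "rand_index": ri,
                "rand_above_0.8": bool(ri > 0.8),
                "spectral_partition": spectral.best.partition.to_json_dict(),
                "cut_partition": cut.to_json_dict(),
            }
        )
    aggregates = {
        "n_networks": len(records),
        "mean_abs_difference": float(
            np.mean([r["abs_difference"] for r in records])
        )
        if records
        else np.nan,
        "n_rand_above_0.8": int(sum(r["rand_above_0.8"] for r in records)),
        "fraction_rand_above_0.8": float(
            np.mean([r["rand_above_0.8"] for r in records])
        )
        if records
        else np.nan,
        "mean_rand_index": float(np.mean([r["rand_index"] for r in records]))
        if records
        else np.nan,
    }
    return ExperimentReport(
        experiment="cut_validation",
        records=tuple(records),
        aggregates=aggregates,
        config=asdict(cfg),
        n_failed=n_failed,
    )


def run_structure_sweep(cfg: ExperimentConfig) -> ExperimentReport:
    """Phi across the spectral MIB vs global efficiency and modularity on
    Watts-Strogatz networks over the rewiring-probability grid."""
    opts = PhiOptions(tol=cfg.opt_tol, ftol=cfg.opt_ftol)
    p_grid = cfg.p_grid if cfg.p_grid is not None else default_p_grid()
    size = cfg.network_sizes[0]
    jobs = [(p, k) for p in p_grid for k in range(cfg.networks_per_size)]
    seeds = cfg.child_seeds(len(jobs))
    records, n_failed = [], 0
    for (p, k), seed in zip(jobs, seeds):
        try:
            graph = watts_strogatz(size, cfg.ws_mean_degree, float(p), seed=seed)
            ts = _simulate(graph, cfg, seed)
            spectral = spectral_mib(
                ts, cfg.tau, opts, seed=seed, **_spectral_kwargs(cfg)
            )
            efficiency = global_efficiency(graph)
            Q, _labels = modularity_newman(graph)
        except NetphiError as exc:
            logger.warning("sweep network (p=%.4g, seed=%d) failed: %s", p, seed, exc)
            n_failed += 1
            continue
        records.append(
            {
                "p": float(p),
                "seed": seed,
                "phi_bits": spectral.best.phi_bits,
                "normalized_phi": spectral.best.normalized_phi,
                "global_efficiency": efficiency,
                "modularity_Q": Q,
                "spectral_partition": spectral.best.partition.to_json_dict(),
            }
        )
    phi = [r["phi_bits"] for r in records]
    eff = [r["global_efficiency"] for r in records]
    mod = [r["modularity_Q"] for r in records]
    if len(records) >= 3:
        rho_eff, p_eff = spearmanr(phi, eff)
        rho_mod, p_mod = spearmanr(phi, mod)
    else:
        rho_eff = p_eff = rho_mod = p_mod = np.nan
    aggregates = {
        "n_networks": len(records),
        "spearman_phi_efficiency": float(rho_eff),
        "spearman_phi_efficiency_p": float(p_eff),
        "spearman_phi_modularity": float(rho_mod),
        "spearman_phi_modularity_p": float(p_mod),
    }
    return ExperimentReport(
        experiment="structure_sweep",
        records=tuple(records),
        aggregates=aggregates,
        config=asdict(cfg),
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# Preset configurations

def desk_scale_config(experiment: str, master_seed: int = 0) -> ExperimentConfig:
    """Reduced-scale presets that reproduce each validation experiment's
    headline statistic on a single CPU in minutes.

    * ``small_validation`` — 10 brain-like 14-node oscillator networks,
      25,000 samples, full 2189-candidate grid.
    * ``cut_validation`` — 10 severed 50-node networks, 50,000 samples.
    * ``structure_sweep`` — 5 Watts-Strogatz networks (50 nodes, mean
      degree 6) per rewiring probability over the 19-value grid, fixed
      coupling 0.25, coarse candidate grid.
    """
    if experiment == "small_validation":
        return ExperimentConfig(
            experiment="small_validation",
            network_sizes=(14,),
            networks_per_size=10,
            n_points=25_000,
            record_every=100,
            master_seed=master_seed,
        )
    if experiment == "cut_validation":
        return ExperimentConfig(
            experiment="cut_validation",
            network_sizes=(50,),
            networks_per_size=10,
            n_points=50_000,
            record_every=100,
            n_beta=4,
            pct_step=0.02,
            opt_tol=1e-5,
            opt_ftol=1e-9,
            master_seed=master_seed,
        )
    if experiment == "structure_sweep":
        return ExperimentConfig(
            experiment="structure_sweep",
            network_sizes=(50,),
            networks_per_size=5,
            n_points=25_000,
            record_every=50,
            sigma_rule=0.25,
            n_beta=3,
            pct_step=0.05,
            opt_tol=1e-5,
            opt_ftol=1e-9,
            master_seed=master_seed,
        )
    raise NetphiError(f"unknown experiment {experiment!r}")


def paper_scale_config(experiment: str, master_seed: int = 0) -> ExperimentConfig:
    """Full-scale presets matching the published validation protocols
    (50 networks per size / per p; hours of compute)."""
    if experiment == "small_validation":
        return ExperimentConfig(
            experiment="small_validation",
            network_sizes=(14, 16),
            networks_per_size=50,
            n_points=25_000,
            record_every=100,
            master_seed=master_seed,
        )
    if experiment == "cut_validation":
        return ExperimentConfig(
            experiment="cut_validation",
            network_sizes=(50, 100, 150, 200, 250, 300),
            networks_per_size=40,
            n_points=100_000,
            record_every=100,
            master_seed=master_seed,
        )
    if experiment == "structure_sweep":
        return ExperimentConfig(
            experiment="structure_sweep",
            network_sizes=(100,),
            networks_per_size=50,
            n_points=25_000,
            record_every=50,
            sigma_rule=0.25,
            master_seed=master_seed,
        )
    raise NetphiError(f"unknown experiment {experiment!r}")


_RUNNERS = {
    "small_validation": run_small_validation,
    "cut_validation": run_cut_validation,
    "structure_sweep": run_structure_sweep,
}


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Dispatch a configuration to its runner."""
    try:
        return _RUNNERS[cfg.experiment](cfg)
    except KeyError:
        raise NetphiError(f"unknown experiment {cfg.experiment!r}") from None
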