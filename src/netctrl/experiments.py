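"""Reproducible simulation protocols over synthetic network ensembles.

Each protocol sweeps one factor of the low-dimensional control problem —
projection dimension ``r``, target size, final-state dispersion, eigenmap
selection scheme, topology, Euler resolution, state configuration or network
size — over an ensemble of independently generated networks, holding the
reference parameters (rho = 1e-4, tf = 1, dt = 0.01, xf ~ N(1, 10),
betweenness-ranked drivers) fixed elsewhere.  Results come back as a tidy
long-format table, one row per (network, factor combination), fully
determined by the configuration's master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .centrality import make_target
from .control import ControlTask, optimal_input
from .generators import HMSWParams, generate_network, sample_state_pair
from .graph_spectral import (
    WeightedNetwork,
    betweenness_ranking,
    eigendecompose,
    build_projector,
    laplacian,
    stabilize,
)

__all__ = ["ExperimentConfig", "run_experiment", "one_way_anova_f", "network_seed"]

PROTOCOLS = (
    "precision_vs_r",
    "target_size_sweep",
    "sigma_sweep",
    "selection_scheme",
    "topology_compare",
    "dt_sweep",
    "state_config",
    "size_sweep",
)


@dataclass(frozen=True)
class ExperimentConfig:
    """One protocol run: ensemble size, factor grids and control parameters."""

    protocol: str
    n_networks: int = 100
    model: str = "hmsw"
    network_params: dict = field(default_factory=dict)
    driver_counts: tuple[int, ...] = (1, 8, 64)
    r_grid: tuple[int, ...] = (4, 16, 64, 256)
    rho: float = 1e-4
    tf: float = 1.0
    dt: float = 0.01
    mu_f: float = 1.0
    sigma_f: float = 10.0
    sigma_grid: tuple[float, ...] = (0.1, 0.5, 1.0, 5.0, 10.0)
    dt_grid: tuple[float, ...] = (0.001, 0.01, 0.1)
    size_grid: tuple[int, ...] = (64, 128, 256)
    selection_mode: str = "magnitude"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}; choose from {PROTOCOLS}")
        for name in ("driver_counts", "r_grid", "sigma_grid", "dt_grid", "size_grid"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")


def network_seed(master_seed: int, index: int) -> int:
    """Deterministic per-network seed derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def _solve(system, drivers, projector, pair, rho, tf, dt):
    task = ControlTask(
        system=system,
        drivers=tuple(int(d) for d in drivers),
        projector=projector,
        x0=pair.x0,
        xf=pair.xf,
        rho=rho,
        tf=tf,
        dt=dt,
    )
    return optimal_input(task)


def _hmsw_params(config: ExperimentConfig, n: int | None = None) -> HMSWParams:
    params = dict(config.network_params)
    if n is not None:
        params["n"] = n
        params["levels"] = int(np.log2(n // params.get("initial_cluster_size", 2))) + 1
    return HMSWParams(**params)


def _gen(config: ExperimentConfig, seed: int, model: str | None = None, n: int | None = None):
    model = model or config.model
    if model == "hmsw":
        return generate_network("hmsw", _hmsw_params(config, n), seed)
    params = dict(config.network_params)
    if n is not None:
        params["n"] = n
    return generate_network(model, params, seed)


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Execute a protocol; returns a tidy long-format results table.

    Columns always include ``network``, ``seed``, the swept factor columns,
    and the metrics ``delta`` (precision), ``eta`` (representativeness),
    ``accuracy`` (their sum) and ``energy``.  Rows for infeasible factor
    combinations (e.g. ``r`` exceeding a target size) are skipped.
    """
    rows: list[dict] = []
    for i in range(config.n_networks):
        seed = network_seed(config.master_seed, i)
        if config.protocol == "size_sweep":
            for n in config.size_grid:
                _run_single_network(config, i, seed, rows, n=n)
        elif config.protocol == "topology_compare":
            for model in ("hmsw", "er", "ba"):
                _run_single_network(config, i, seed, rows, model=model)
        else:
            _run_single_network(config, i, seed, rows)
    return pd.DataFrame(rows)


def _run_single_network(config, index, seed, rows, model=None, n=None):
    gen = _gen(config, seed, model=model, n=n)
    net = gen.network
    basis = eigendecompose(laplacian(net))
    system = stabilize(net)
    ranking = betweenness_ranking(net)
    base = {"network": index, "seed": seed}
    if model is not None:
        base["model"] = model
    if n is not None:
        base["n"] = net.n

    proto = config.protocol
    if proto in ("precision_vs_r", "topology_compare", "size_sweep", "dt_sweep"):
        pair = sample_state_pair(net.n, "gaussian", seed, mu_f=config.mu_f, sigma_f=config.sigma_f)
        dts = config.dt_grid if proto == "dt_sweep" else (config.dt,)
        for k in config.driver_counts:
            if k > net.n:
                continue
            drivers = ranking[:k]
            for r in config.r_grid:
                if r > net.n:
                    continue
                proj = build_projector(basis, r, config.selection_mode, pair.xf)
                for dt in dts:
                    sol = _solve(system, drivers, proj, pair, config.rho, config.tf, dt)
                    rows.append(
                        {**base, "n_drivers": k, "r": r, "dt": dt, **_metrics(sol)}
                    )
    elif proto in ("sigma_sweep", "selection_scheme"):
        modes = ("magnitude", "lambda") if proto == "selection_scheme" else (config.selection_mode,)
        for sigma in config.sigma_grid:
            pair = sample_state_pair(net.n, "gaussian", seed, mu_f=config.mu_f, sigma_f=sigma)
            for k in config.driver_counts:
                drivers = ranking[:k] if k < net.n else np.arange(net.n)
                for r in config.r_grid:
                    if r > net.n:
                        continue
                    for mode in modes:
                        proj = build_projector(basis, r, mode, pair.xf)
                        sol = _solve(system, drivers, proj, pair, config.rho, config.tf, config.dt)
                        rows.append(
                            {
                                **base,
                                "sigma_f": sigma,
                                "n_drivers": k,
                                "r": r,
                                "mode": mode,
                                **_metrics(sol),
                            }
                        )
    elif proto == "target_size_sweep":
        pair = sample_state_pair(net.n, "gaussian", seed, mu_f=config.mu_f, sigma_f=config.sigma_f)
        modules = gen.modules(8)
        order = np.arange(8)
        for n_modules in range(1, 9):
            target_nodes = np.where(np.isin(modules, order[:n_modules]))[0]
            m = target_nodes.size
            r = min(min(config.r_grid), m)
            target = make_target(net, target_nodes, r, mode="magnitude", reference_state=pair.xf)
            in_mask = np.isin(ranking, target_nodes)
            inside = ranking[in_mask][:1]
            outside = ranking[~in_mask][:1]
            for side, drivers in (("internal", inside), ("external", outside)):
                if drivers.size == 0:
                    continue
                sol = _solve(system, drivers, target, pair, config.rho, config.tf, config.dt)
                rows.append(
                    {**base, "target_size": m, "r": r, "driver_side": side, **_metrics(sol)}
                )
    elif proto == "state_config":
        modules = gen.modules(8)
        for cfg_name in ("uniform_modular", "constant_gaussian"):
            if cfg_name == "uniform_modular":
                pair = sample_state_pair(net.n, "uniform_modular", seed, modules=modules)
            else:
                pair = sample_state_pair(net.n, "gaussian", seed, mu_f=4.5, sigma_f=2.4)
            for k in config.driver_counts:
                drivers = ranking[:k]
                for r in config.r_grid:
                    if r > net.n:
                        continue
                    proj = build_projector(basis, r, config.selection_mode, pair.xf)
                    sol = _solve(system, drivers, proj, pair, config.rho, config.tf, config.dt)
                    rows.append(
                        {
                            **base,
                            "state_config": cfg_name,
                            "n_drivers": k,
                            "r": r,
                            **_metrics(sol),
                        }
                    )
    else:  # pragma: no cover - guarded by ExperimentConfig validation
        raise ValueError(f"unhandled protocol {proto!r}")


def _metrics(sol) -> dict:
    delta = sol.precision
    eta = sol.representativeness
    acc = delta + eta if delta is not None and eta is not None else None
    return {"delta": delta, "eta": eta, "accuracy": acc, "energy": sol.energy}


def one_way_anova_f(groups: Sequence[Sequence[float]]) -> tuple[float, int, int]:
    """One-way ANOVA F statistic with its degrees of freedom.

    ``F = (SSB / (k - 1)) / (SSW / (N - k))``.  Zero within-group variance
    with non-zero between-group variance yields ``F = inf``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need at least 2 groups with at least 2 observations each")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    grand = float(np.concatenate(groups).mean())
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0.0:
        f = float("inf") if ssb > 0 else 0.0
    else:
        f = float(scipy.stats.f_oneway(*groups).statistic)
    return f, df_b, df_w
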