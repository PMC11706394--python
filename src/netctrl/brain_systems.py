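"""System-level aggregation of control centralities.

Connectome nodes come labelled with a functional system (VIS, SMN, DAN, ...)
and a hemisphere.  Aggregating per-node low-dimensional control centralities
over those labels yields interpretable system-scale quantities: how easily a
system is controlled (system controllability), whether it is driven from
within or without (self- vs external regulation), which hemisphere dominates
its self-regulation (lateralization index phi), and a directed system-by-
system meta-graph of who drives whom, summarised by geometric means and an
out-minus-in control unbalance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .centrality import POSITIVITY_TOL, GramianEngine, GramianScore, make_target
from .graph_spectral import WeightedNetwork, laplacian

__all__ = [
    "NodePartition",
    "MetaGraph",
    "SystemMetrics",
    "system_metrics",
    "lateralization_index",
    "build_metagraph",
    "hemisphere_control",
    "correlate_centrality",
]


@dataclass(frozen=True)
class NodePartition:
    """Per-node system and hemisphere labels (plus optional 3-D coordinates)."""

    system_label: tuple[str, ...]
    hemisphere: tuple[str, ...]
    coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        systems = tuple(str(s) for s in self.system_label)
        hemis = tuple(str(h) for h in self.hemisphere)
        if len(systems) != len(hemis):
            raise ValueError("system and hemisphere label lists differ in length")
        if any(not s for s in systems) or any(not h for h in hemis):
            raise ValueError("labels must be non-empty")
        bad = set(hemis) - {"L", "R"}
        if bad:
            raise ValueError(f"hemisphere labels must be 'L' or 'R', got {sorted(bad)}")
        object.__setattr__(self, "system_label", systems)
        object.__setattr__(self, "hemisphere", hemis)
        if self.coordinates is not None:
            coords = np.asarray(self.coordinates, dtype=float)
            if coords.shape != (len(systems), 3):
                raise ValueError("coordinates must be (n, 3)")
            object.__setattr__(self, "coordinates", coords)

    @property
    def n(self) -> int:
        return len(self.system_label)

    @property
    def systems(self) -> tuple[str, ...]:
        """Distinct system labels in order of first appearance."""
        return tuple(dict.fromkeys(self.system_label))

    def nodes_of_system(self, system: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.system_label) if s == system])

    def nodes_of_hemisphere(self, hemi: str) -> np.ndarray:
        return np.array([i for i, h in enumerate(self.hemisphere) if h == hemi])


@dataclass(frozen=True)
class MetaGraph:
    """Directed system-by-system control map.

    ``weights[i, j]`` is the geometric-mean centrality of drivers in system
    ``i`` when targeting system ``j``; ``unbalance`` is each system's
    out-minus-in strength with self-loops excluded (so it sums to zero).
    """

    systems: tuple[str, ...]
    weights: np.ndarray
    unbalance: np.ndarray
    excluded_scores: int = 0


@dataclass(frozen=True)
class SystemMetrics:
    """Aggregated control metrics for one targeted system.

    Any quantity whose driver set is empty is ``None`` (reported missing,
    never silently zero).
    """

    target_system: str
    system_controllability: float | None
    self_regulation: float | None
    external_regulation: float | None
    log_ratio: float | None
    best_inside_driver: int | None
    best_outside_driver: int | None


def system_metrics(
    scores: list[GramianScore] | dict[int, float],
    partition: NodePartition,
    target_system: str,
) -> SystemMetrics:
    """Aggregate per-driver centralities for one target system.

    System controllability is the mean over all candidate drivers,
    self-regulation the mean over drivers inside the target, external
    regulation the mean over drivers outside; their ratio is reported
    log10-transformed.  Best drivers are the argmax inside and outside.
    """
    if isinstance(scores, dict):
        per_driver = {int(d): float(v) for d, v in scores.items()}
    else:
        per_driver = {s.driver: s.lambda_min_eig for s in scores}
    inside_nodes = set(partition.nodes_of_system(target_system).tolist())
    inside = {d: v for d, v in per_driver.items() if d in inside_nodes}
    outside = {d: v for d, v in per_driver.items() if d not in inside_nodes}
    overall = float(np.mean(list(per_driver.values()))) if per_driver else None
    self_reg = float(np.mean(list(inside.values()))) if inside else None
    ext_reg = float(np.mean(list(outside.values()))) if outside else None
    log_ratio = None
    if self_reg is not None and ext_reg is not None and self_reg > 0 and ext_reg > 0:
        log_ratio = math.log10(self_reg / ext_reg)
    best_in = max(inside, key=inside.get) if inside else None
    best_out = max(outside, key=outside.get) if outside else None
    return SystemMetrics(
        target_system=target_system,
        system_controllability=overall,
        self_regulation=self_reg,
        external_regulation=ext_reg,
        log_ratio=log_ratio,
        best_inside_driver=best_in,
        best_outside_driver=best_out,
    )


def lateralization_index(zeta_r: float, zeta_l: float) -> float | None:
    """Lateralization ``phi = (zeta_R - zeta_L) / (zeta_R + zeta_L)`` in [-1, 1].

    Contrasts right- vs left-hemisphere self-regulation; +1 means fully
    right-lateralized.  Undefined (``None``) when both inputs are zero.
    """
    if zeta_r < 0 or zeta_l < 0:
        raise ValueError("zeta values must be nonnegative")
    total = zeta_r + zeta_l
    if total == 0:
        return None
    return (zeta_r - zeta_l) / total


def build_metagraph(
    network: WeightedNetwork,
    partition: NodePartition,
    r: int = 5,
    engine: GramianEngine | None = None,
) -> MetaGraph:
    """Directed meta-graph of geometric-mean control centralities.

    For each ordered system pair ``(i, j)`` the weight is the geometric mean
    over drivers in ``i`` of their centrality when targeting ``j`` (target
    built from system ``j``'s subnetwork Laplacian at dimension ``r``).
    Non-positive centralities (at or below the positivity tolerance) cannot
    enter a geometric mean; they are excluded and counted.
    """
    if engine is None:
        engine = GramianEngine(network)
    systems = partition.systems
    k = len(systems)
    weights = np.zeros((k, k))
    excluded = 0
    targets = {}
    for j, sysj in enumerate(systems):
        nodes_j = partition.nodes_of_system(sysj)
        targets[j] = make_target(network, nodes_j, min(r, len(nodes_j)), mode="lambda")
    for i, sysi in enumerate(systems):
        drivers = partition.nodes_of_system(sysi)
        for j in range(k):
            vals = []
            for d in drivers:
                lam = engine.score(int(d), targets[j]).lambda_min_eig
                if lam > POSITIVITY_TOL:
                    vals.append(lam)
                else:
                    excluded += 1
            weights[i, j] = float(scipy.stats.gmean(vals)) if vals else 0.0
    off = weights - np.diag(np.diag(weights))
    unbalance = off.sum(axis=1) - off.sum(axis=0)
    return MetaGraph(systems=systems, weights=weights, unbalance=unbalance, excluded_scores=excluded)


def hemisphere_control(
    network: WeightedNetwork,
    partition: NodePartition,
    r: int = 5,
    system: str | None = None,
    engine: GramianEngine | None = None,
) -> dict[str, float | None]:
    """Ipsi- and contralateral control capacity of the two hemispheres.

    Each hemisphere's full node set is a target (its own subnetwork
    Laplacian); ipsilateral control is the mean centrality of a hemisphere's
    nodes targeting their own hemisphere, contralateral the mean targeting
    the other.  ``system`` restricts the driver nodes to one functional
    system (targets stay whole-hemisphere).

    Returns ``{"ipsi_L", "ipsi_R", "contra_LtoR", "contra_RtoL"}``.
    """
    left = partition.nodes_of_hemisphere("L")
    right = partition.nodes_of_hemisphere("R")
    if left.size == 0 or right.size == 0:
        raise ValueError("both hemispheres must be non-empty")
    if engine is None:
        engine = GramianEngine(network)
    targets = {
        "L": make_target(network, left, min(r, left.size), mode="lambda"),
        "R": make_target(network, right, min(r, right.size), mode="lambda"),
    }
    drivers = {"L": left, "R": right}
    if system is not None:
        sys_nodes = set(partition.nodes_of_system(system).tolist())
        drivers = {h: np.array([d for d in drivers[h] if d in sys_nodes]) for h in drivers}

    def _mean(driver_set: np.ndarray, tgt: str) -> float | None:
        if driver_set.size == 0:
            return None
        return float(
            np.mean([engine.score(int(d), targets[tgt]).lambda_min_eig for d in driver_set])
        )

    return {
        "ipsi_L": _mean(drivers["L"], "L"),
        "ipsi_R": _mean(drivers["R"], "R"),
        "contra_LtoR": _mean(drivers["L"], "R"),
        "contra_RtoL": _mean(drivers["R"], "L"),
    }


def correlate_centrality(
    network: WeightedNetwork,
    scores: dict[int, float],
    covariate: str,
    target_nodes=None,
    partition: NodePartition | None = None,
) -> tuple[float, float]:
    """Pearson correlation between per-driver centrality and a node covariate.

    Covariates: ``"topological_distance"`` (sum of shortest-path lengths from
    the driver to every target node), ``"euclidean_distance"`` (same with
    straight-line distances; needs coordinates) or ``"node_strength"`` (sum
    of the driver's link weights).  Returns ``(r, p)``.
    """
    import networkx as nx

    drivers = sorted(scores)
    vals = np.array([scores[d] for d in drivers])
    if covariate == "node_strength":
        strength = network.degree()
        cov = strength[drivers]
    elif covariate == "topological_distance":
        if target_nodes is None:
            raise ValueError("topological_distance requires target_nodes")
        g = nx.from_numpy_array(network.adjacency)
        weights = network.adjacency[network.adjacency > 0]
        kw = {}
        if weights.size and not np.all(weights == 1.0):
            for _, _, dd in g.edges(data=True):
                dd["length"] = 1.0 / dd["weight"]
            kw["weight"] = "length"
        cov = np.array(
            [
                sum(
                    nx.shortest_path_length(g, int(d), int(j), **kw)
                    for j in target_nodes
                    if int(j) != int(d)
                )
                for d in drivers
            ],
            dtype=float,
        )
    elif covariate == "euclidean_distance":
        if partition is None or partition.coordinates is None:
            raise ValueError("euclidean_distance requires a partition with coordinates")
        if target_nodes is None:
            raise ValueError("euclidean_distance requires target_nodes")
        coords = partition.coordinates
        cov = np.array(
            [
                float(np.linalg.norm(coords[list(target_nodes)] - coords[int(d)], axis=1).sum())
                for d in drivers
            ]
        )
    else:
        raise ValueError(f"unknown covariate {covariate!r}")
    if np.ptp(cov) == 0:
        raise ValueError("covariate has zero variance; correlation undefined")
    r, p = scipy.stats.pearsonr(vals, cov)
    return float(r), float(p)
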