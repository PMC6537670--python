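"""Rho-statistic dating of network nodes.

rho is the multiplicity-weighted mean number of mutations separating a set
of tip haplotypes from a designated ancestral node. Under a molecular clock
its expectation is mu * L * t, so t = rho / (mu * L) generations, converted
to calendar time via the generation interval. The standard error follows
the per-edge tip-count estimator used with haplotype networks:

    sigma^2 = (1/n^2) * sum_over_edges (tips through edge)^2 * edge length

where n is the total tip multiplicity and an edge "carries" the tips whose
geodesic to the dated node traverses it. rho and sigma are only defined on
tree-like neighbourhoods: a reticulation on any tip path is an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .haplotype_network import HaploNetwork


@dataclass(frozen=True)
class DatingConfig:
    """Clock parameters: mutation rate per site per generation, sites used, years per generation."""

    mu: float
    L_sites: float
    generation_years: float

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.L_sites <= 0 or self.generation_years <= 0:
            raise ValueError("mu, L_sites and generation_years must all be positive")


@dataclass
class DatingResult:
    node: str
    n_tips: int
    rho: float
    sigma: float
    t_years: float
    t_sd_years: float


def _tip_paths(net: HaploNetwork, tips: Sequence[str], node: str) -> dict[str, list[str]]:
    g = net.graph
    if node not in g:
        raise KeyError(f"node {node!r} not in network")
    paths: dict[str, list[str]] = {}
    for tip in tips:
        if tip not in g:
            raise KeyError(f"tip {tip!r} not in network")
        gens = nx.all_shortest_paths(g, tip, node, weight="length")
        first = next(gens)
        try:
            next(gens)
        except StopIteration:
            paths[tip] = first
        else:
            raise ValueError(
                f"ambiguous geodesic between {tip!r} and {node!r} (reticulation on path)"
            )
    return paths


def _multiplicity(net: HaploNetwork, tip: str) -> int:
    m = net.graph.nodes[tip]["multiplicity"]
    return max(int(m), 1)  # a median used as a tip counts once


def rho_statistic(net: HaploNetwork, tips: Sequence[str], node: str) -> float:
    """Multiplicity-weighted mean path length from the tips to the node."""
    paths = _tip_paths(net, tips, node)
    total_w = sum(_multiplicity(net, t) for t in tips)
    if total_w == 0:
        raise ValueError("no tips")
    acc = 0.0
    for tip, path in paths.items():
        length = sum(net.graph.edges[a, b]["length"] for a, b in zip(path, path[1:]))
        acc += _multiplicity(net, tip) * length
    return acc / total_w


def sigma_rho(net: HaploNetwork, tips: Sequence[str], node: str) -> float:
    """Standard error of rho from the subtree spanning the tips and the node."""
    paths = _tip_paths(net, tips, node)
    n = sum(_multiplicity(net, t) for t in tips)
    edge_tips: dict[tuple[str, str], int] = {}
    for tip, path in paths.items():
        w = _multiplicity(net, tip)
        for a, b in zip(path, path[1:]):
            key = (min(a, b), max(a, b))
            edge_tips[key] = edge_tips.get(key, 0) + w
    var = sum(
        (count ** 2) * net.graph.edges[e]["length"] for e, count in edge_tips.items()
    ) / (n ** 2)
    return var ** 0.5


def rho_to_years(rho: float, sigma: float, cfg: DatingConfig, node: str = "", n_tips: int = 0) -> DatingResult:
    """Convert a rho estimate to calendar years: T = rho / (mu * L) * g."""
    scale = cfg.generation_years / (cfg.mu * cfg.L_sites)
    return DatingResult(
        node=node,
        n_tips=n_tips,
        rho=rho,
        sigma=sigma,
        t_years=rho * scale,
        t_sd_years=sigma * scale,
    )


def date_node(net: HaploNetwork, tips: Sequence[str], node: str, cfg: DatingConfig) -> DatingResult:
    rho = rho_statistic(net, tips, node)
    sigma = sigma_rho(net, tips, node)
    n = sum(_multiplicity(net, t) for t in tips)
    return rho_to_years(rho, sigma, cfg, node=node, n_tips=n)
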