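"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library routines they check: path
enumeration works on a plain adjacency dict by recursion, betweenness is
accumulated from the enumerated shortest paths.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from allopath.synthetic import (PlantedCovariance, ToyChannelSpec,
                                generate_toy_channel, generate_trajectory)
from allopath.trajectory import extract_node_series, load_system


# ---------------------------------------------------------------------------
# brute-force graph oracles (independent of networkx algorithms)


def enumerate_simple_paths(adj: dict, source, target):
    """Yield (path, weight) over all simple paths via explicit recursion."""
    path = [source]
    seen = {source}

    def rec(u, w):
        if u == target:
            yield list(path), w
            return
        for v, wv in adj[u].items():
            if v not in seen:
                seen.add(v)
                path.append(v)
                yield from rec(v, w + wv)
                path.pop()
                seen.remove(v)

    yield from rec(source, 0.0)


def graph_to_adj(G) -> dict:
    adj: dict = {n: {} for n in G.nodes}
    for u, v, d in G.edges(data=True):
        adj[u][v] = d["weight"]
        adj[v][u] = d["weight"]
    return adj


def brute_force_min_path(G, sources, sinks, tol=1e-9):
    """(d_min, lexicographically smallest co-minimal path) by enumeration."""
    adj = graph_to_adj(G)
    best = math.inf
    candidates = []
    for s in sources:
        for t in sinks:
            for p, w in enumerate_simple_paths(adj, s, t):
                if w < best - tol:
                    best = w
                    candidates = [p]
                elif abs(w - best) <= tol:
                    candidates.append(p)
    if not candidates:
        return math.inf, None
    candidates.sort(key=lambda p: tuple(str(n) for n in p))
    return best, candidates[0]


def brute_force_betweenness(G, tol=1e-9) -> dict:
    """Normalized weighted betweenness by exhaustive shortest-path counting.

    Matches the undirected convention: for each unordered pair (s, t) the
    fraction of minimal-weight paths through an interior node v, scaled by
    2 / ((n-1)(n-2)).
    """
    adj = graph_to_adj(G)
    nodes = list(G.nodes)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    for i in range(n):
        for j in range(i + 1, n):
            s, t = nodes[i], nodes[j]
            paths = list(enumerate_simple_paths(adj, s, t))
            if not paths:
                continue
            wmin = min(w for _, w in paths)
            shortest = [p for p, w in paths if abs(w - wmin) <= tol]
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in shortest if v in p)
                bc[v] += through / len(shortest)
    if n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        bc = {v: val * scale for v, val in bc.items()}
    return bc


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def toy_spec() -> ToyChannelSpec:
    return ToyChannelSpec()


@pytest.fixture(scope="session")
def toy_channel(toy_spec):
    return generate_toy_channel(toy_spec)


@pytest.fixture(scope="session")
def planted_cov(toy_spec) -> PlantedCovariance:
    # the planted chain spans subunit A
    return PlantedCovariance(
        path_nodes=tuple(range(toy_spec.residues_per_subunit)), rho_path=0.9)


@pytest.fixture(scope="session")
def toy_trajectory(toy_channel, planted_cov):
    return generate_trajectory(toy_channel, planted_cov, n_frames=500, seed=11)


@pytest.fixture(scope="session")
def toy_node_series(toy_trajectory):
    system = load_system(None, universe=toy_trajectory.to_universe())
    return extract_node_series(system)
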