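"""Random-matrix-theory co-occurrence networks and topological node roles.

The correlation threshold for network construction is chosen where the
nearest-neighbor spacing distribution (NNSD) of the thresholded correlation
matrix's eigenvalues transitions from the Gaussian orthogonal ensemble
(Wigner surmise, level repulsion: correlated system-wide structure) to
Poisson (uncorrelated spectrum: only modular, real associations survive).
Degree-preserving Maslov-Sneppen rewiring provides the null ensemble, and
nodes are classified by within-module degree z-score (Zi) and participation
coefficient (Pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, DomainError, NoTransitionError

#: Topological-role thresholds (standard convention).
ZI_HUB = 2.5
PI_CONNECTOR = 0.62

DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.30, 0.955, 0.02), 2)


# ---------------------------------------------------------------------------
# OTU prevalence filter and correlations


def prevalence_filter(
    abundance: pd.DataFrame, min_present: int = 10, n_samples: int = 12
) -> pd.DataFrame:
    """Keep OTUs (rows) present (count > 0) in at least ``min_present`` samples.

    ``n_samples`` documents the expected design width; a mismatch with the
    actual number of columns raises, catching mis-shaped inputs early.
    """
    if n_samples is not None and abundance.shape[1] != n_samples:
        raise DomainError(
            f"expected {n_samples} sample columns, got {abundance.shape[1]}"
        )
    present = (abundance > 0).sum(axis=1)
    return abundance.loc[present >= min_present]


def correlation_matrix(abundance: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between OTU rows across sample columns.

    Missing values are excluded pairwise; constant rows yield NaN
    correlations which are treated as 0 (no evidence of association).
    """
    corr = abundance.T.corr(method="pearson")
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


# ---------------------------------------------------------------------------
# Spectral unfolding and the NNSD


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale == 0:
        return 1.0
    return 0.9 * scale * n ** (-0.2)


def nnsd(eigenvalues: np.ndarray, bandwidth: float | None = None) -> np.ndarray:
    """Unit-mean nearest-neighbor spacings of an unfolded spectrum.

    The spectrum is unfolded with a Gaussian-broadened cumulative spectral
    density (bandwidth by Silverman's rule unless given), which maps the
    eigenvalues onto a uniform density so their spacings are comparable to
    the Wigner/Poisson reference distributions.
    """
    ev = np.sort(np.asarray(eigenvalues, dtype=float))
    n = ev.size
    if n < 50:
        raise DomainError(f"need >= 50 eigenvalues for stable unfolding, got {n}")
    h = bandwidth if bandwidth is not None else _silverman_bandwidth(ev)
    if h <= 0:
        raise DegenerateInputError("degenerate spectrum: zero unfolding bandwidth")
    # unfolded positions: N * smoothed CDF evaluated at each eigenvalue
    z = (ev[:, None] - ev[None, :]) / h
    unfolded = n * stats.norm.cdf(z).mean(axis=1)
    s = np.diff(np.sort(unfolded))
    mean = s.mean()
    if mean == 0:
        raise DegenerateInputError("degenerate spectrum: all spacings zero")
    return s / mean


def wigner_surmise_pdf(s: np.ndarray) -> np.ndarray:
    """GOE Wigner surmise: p(s) = (π/2) s exp(-π s²/4)."""
    s = np.asarray(s, dtype=float)
    return 0.5 * np.pi * s * np.exp(-0.25 * np.pi * s**2)


def wigner_surmise_cdf(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    return 1.0 - np.exp(-0.25 * np.pi * s**2)


def poisson_spacing_pdf(s: np.ndarray) -> np.ndarray:
    """Poisson (uncorrelated-spectrum) spacings: p(s) = exp(-s)."""
    return np.exp(-np.asarray(s, dtype=float))


def _binned_chi2(spacings: np.ndarray, cdf, n_bins: int = 10) -> float:
    """χ² distance between observed spacings and a reference distribution.

    Bins cover [0, 3] plus an overflow bin; expected masses come from the
    reference CDF.
    """
    edges = np.linspace(0.0, 3.0, n_bins)
    edges = np.append(edges, np.inf)
    obs, _ = np.histogram(spacings, bins=edges)
    cdf_vals = np.append(cdf(edges[:-1]), 1.0)
    expected = np.diff(cdf_vals) * spacings.size
    expected = np.maximum(expected, 1e-9)
    return float(((obs - expected) ** 2 / expected).sum())


def spacing_distances(spacings: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """(distance to Poisson, distance to Wigner) for a spacing sample."""
    d_poisson = _binned_chi2(spacings, lambda s: 1.0 - np.exp(-s), n_bins)
    d_wigner = _binned_chi2(spacings, wigner_surmise_cdf, n_bins)
    return d_poisson, d_wigner


def rmt_threshold_scan(
    corr: pd.DataFrame,
    grid: np.ndarray = DEFAULT_THRESHOLD_GRID,
    n_bins: int = 10,
    min_eigenvalues: int = 50,
) -> float:
    """Choose the correlation threshold at the GOE→Poisson transition.

    For each threshold, entries with \\|r\\| below it are zeroed, rows left
    without any off-diagonal entry are dropped, and the NNSD of the
    remaining matrix is scored by binned χ² distance against the Poisson
    and Wigner references.  Returns the smallest grid threshold whose
    spectrum is Poisson-closer and stays so at every larger threshold.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise DomainError("threshold grid must be ascending")
    values = corr.values
    if not np.allclose(values, values.T, atol=1e-10):
        raise DomainError("correlation matrix must be symmetric")

    verdict: list[bool | None] = []  # True=Poisson-closer; None=unusable spectrum
    endpoint_fits: dict[float, tuple[float, float]] = {}
    for t in grid:
        m = values.copy()
        m[np.abs(m) < t] = 0.0
        off = m - np.diag(np.diag(m))
        keep = np.abs(off).sum(axis=1) > 0
        m = m[np.ix_(keep, keep)]
        if m.shape[0] < min_eigenvalues:
            verdict.append(None)
            continue
        ev = np.linalg.eigvalsh(m)
        try:
            s = nnsd(ev)
        except DegenerateInputError:
            verdict.append(None)
            continue
        d_p, d_w = spacing_distances(s, n_bins)
        endpoint_fits[float(t)] = (d_p, d_w)
        verdict.append(d_p < d_w)

    chosen = None
    for i, t in enumerate(grid):
        tail = [v for v in verdict[i:] if v is not None]
        if verdict[i] is True and tail and all(tail):
            chosen = float(t)
            break
    if chosen is None:
        lo = endpoint_fits.get(float(grid[0]))
        hi = endpoint_fits.get(float(grid[-1]))
        raise NoTransitionError(
            "no GOE→Poisson transition found on the grid "
            f"(fits at endpoints: {grid[0]}→{lo}, {grid[-1]}→{hi})"
        )
    return chosen


# ---------------------------------------------------------------------------
# Network construction, nulls, and node roles


def build_network(corr: pd.DataFrame, threshold: float) -> nx.Graph:
    """Undirected network of OTU pairs with \\|r\\| >= threshold (no self-edges).

    Nodes without any suprathreshold association are excluded.  Edge weights
    carry the signed correlation.
    """
    g = nx.Graph()
    ids = list(corr.index)
    values = corr.values
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            r = values[i, j]
            if abs(r) >= threshold:
                g.add_edge(ids[i], ids[j], weight=float(r))
    return g


def maslov_sneppen(
    network: nx.Graph, n_swaps: int | None = None, seed: int = 0
) -> nx.Graph:
    """Degree-preserving random rewiring (repeated double-edge swaps).

    Self-loops and multi-edges are rejected by construction.  If no legal
    swap can be found (e.g. a star graph) the input is returned unchanged
    with a warning.  The degree sequence is asserted identical on exit.
    """
    if network.number_of_edges() < 2:
        raise DomainError("need at least 2 edges to rewire")
    rewired = network.copy()
    if n_swaps is None:
        n_swaps = 10 * network.number_of_edges()
    try:
        nx.double_edge_swap(
            rewired, nswap=n_swaps, max_tries=100 * n_swaps, seed=seed
        )
    except nx.NetworkXException:
        # too few nodes, or swap attempts exhausted (e.g. a star graph):
        # the degree sequence is preserved either way
        warnings.warn(
            "Maslov-Sneppen rewiring found few or no legal swaps; "
            "returning the graph with its degree sequence intact",
            stacklevel=2,
        )
    assert sorted(d for _, d in rewired.degree()) == sorted(
        d for _, d in network.degree()
    ), "degree sequence changed during rewiring"
    return rewired


@dataclass(frozen=True)
class NodeRole:
    node: str
    degree: int
    module: int
    zi: float  # NaN for isolated nodes / singleton modules
    pi: float
    role: str


def detect_modules(network: nx.Graph) -> dict[str, int]:
    """Greedy modularity maximization (deterministic)."""
    communities = nx.algorithms.community.greedy_modularity_communities(network)
    assignment: dict[str, int] = {}
    for m, nodes in enumerate(communities):
        for node in nodes:
            assignment[node] = m
    return assignment


def zi_pi(
    network: nx.Graph, module_assignment: dict[str, int] | None = None
) -> list[NodeRole]:
    """Within-module degree z-score and participation coefficient per node.

    Zi = (k_i,within - mean within-degree of the module) / sd; modules whose
    within-degrees have zero spread give Zi = 0, singleton modules and
    isolated nodes give Zi = NaN.  Pi = 1 - Σ_m (k_i,m / k_i)².  Roles:
    ``module hub`` (Zi >= 2.5), ``connector`` (Pi >= 0.62), ``network hub``
    (both), else ``peripheral``.  Invariant to module relabeling.
    """
    if module_assignment is None:
        module_assignment = detect_modules(network)
    nodes = list(network.nodes)
    within_degree = {
        v: sum(1 for u in network[v] if module_assignment[u] == module_assignment[v])
        for v in nodes
    }
    by_module: dict[int, list[int]] = {}
    for v in nodes:
        by_module.setdefault(module_assignment[v], []).append(within_degree[v])

    roles: list[NodeRole] = []
    for v in nodes:
        k = network.degree(v)
        m = module_assignment[v]
        member_wd = by_module[m]
        if k == 0 or len(member_wd) < 2:
            zi = float("nan")
        else:
            mu = float(np.mean(member_wd))
            sd = float(np.std(member_wd))
            zi = (within_degree[v] - mu) / sd if sd > 0 else 0.0
        if k == 0:
            pi = 0.0
        else:
            per_module: dict[int, int] = {}
            for u in network[v]:
                mu_mod = module_assignment[u]
                per_module[mu_mod] = per_module.get(mu_mod, 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in per_module.values())
        is_hub = not np.isnan(zi) and zi >= ZI_HUB
        is_conn = pi >= PI_CONNECTOR
        if is_hub and is_conn:
            role = "network hub"
        elif is_hub:
            role = "module hub"
        elif is_conn:
            role = "connector"
        else:
            role = "peripheral"
        roles.append(NodeRole(v, k, m, zi, pi, role))
    return roles


def roles_frame(roles: list[NodeRole]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in roles]).set_index("node")


def edge_frame(network: nx.Graph) -> pd.DataFrame:
    rows = [
        {"node_a": a, "node_b": b, "r": d.get("weight", np.nan)}
        for a, b, d in network.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "r"])
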