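"""Binary and weighted graph metrics with random-surrogate normalisation.

Measures follow the standard connectome conventions: node degree / strength
(K), clustering coefficient (C; Onnela geometric-mean triangle formula on
max-normalised weights in the weighted case), characteristic path length
(L; inverse-weight edge lengths in the weighted case, disconnected pairs
excluded from the average), Louvain modularity (Q), and small-worldness
sigma = N-C / N-L where N- denotes normalisation by the mean over
degree-preserving rewired surrogates.

Every weighted measure reduces exactly to its binary counterpart when all
surviving weights equal 1 — the "bridge invariant" that the test suite
exercises across the full threshold sweep.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._utils import derive_seed
from .exceptions import DegenerateInputError, InvalidArgumentError
from .network import ThresholdedGraph
from .synthetic import SensorLayout

logger = logging.getLogger(__name__)


def _adj(g: ThresholdedGraph | np.ndarray) -> tuple[np.ndarray, bool]:
    if isinstance(g, ThresholdedGraph):
        return g.adjacency, g.mode == "weighted"
    a = np.asarray(g, dtype=float)
    return a, bool(np.any((a != 0) & (a != 1)))


def degree(g: ThresholdedGraph | np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node degree (binary) or strength (weighted) and its mean."""
    a, weighted = _adj(g)
    vec = a.sum(axis=1) if weighted else (a != 0).sum(axis=1).astype(float)
    return vec, float(vec.mean())


def clustering(g: ThresholdedGraph | np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficient and its mean.

    Binary: fraction of closed neighbour pairs. Weighted: geometric-mean
    triangle intensity on weights rescaled by the graph maximum,
    C_i = sum_{jh} (w_ij w_ih w_jh)^(1/3) / (k_i (k_i - 1)); nodes with
    degree < 2 have C_i = 0.
    """
    a, weighted = _adj(g)
    pattern = (a != 0).astype(float)
    k = pattern.sum(axis=1)
    if weighted:
        mx = a.max()
        s = np.cbrt(a / mx) if mx > 0 else a
        tri = np.diagonal(s @ s @ s)
    else:
        tri = np.diagonal(pattern @ pattern @ pattern)
    denom = k * (k - 1)
    vec = np.divide(tri, denom, out=np.zeros_like(denom, dtype=float), where=denom > 0)
    return vec, float(vec.mean())


def char_path_length(g: ThresholdedGraph | np.ndarray) -> float:
    """Average shortest-path length over all ordered reachable node pairs.

    Weighted graphs use edge lengths 1/w (stronger connections are
    shorter). Disconnected pairs are excluded from the average and their
    count logged; a graph with no finite off-diagonal path at all is
    degenerate.
    """
    a, weighted = _adj(g)
    n = a.shape[0]
    if weighted:
        lengths = np.zeros_like(a)
        nz = a != 0
        lengths[nz] = 1.0 / a[nz]
        d = shortest_path(csr_matrix(lengths), method="D", directed=False)
    else:
        d = shortest_path(csr_matrix(a), method="D", directed=False, unweighted=True)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_disconnected = int(off.sum() - finite.sum())
    if finite.sum() == 0:
        raise DegenerateInputError("fully disconnected graph has no path length")
    if n_disconnected:
        logger.info("char_path_length: excluded %d disconnected ordered pairs", n_disconnected)
    return float(d[finite].mean())


def _to_nx(a: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(a.shape[0]))
    iu, ju = np.nonzero(np.triu(a, k=1))
    G.add_weighted_edges_from((int(i), int(j), float(a[i, j])) for i, j in zip(iu, ju))
    return G


def modularity(
    g: ThresholdedGraph | np.ndarray, seed: int, restarts: int = 10
) -> tuple[float, list[set[int]]]:
    """Louvain modularity: best Q over seeded restarts and its partition."""
    a, _ = _adj(g)
    G = _to_nx(a)
    if G.number_of_edges() == 0:
        raise DegenerateInputError("modularity requires at least one edge")
    best_q, best_part = -np.inf, None
    for r in range(restarts):
        part = nx.community.louvain_communities(
            G, weight="weight", resolution=1.0, seed=derive_seed(seed, "louvain", r)
        )
        q = nx.community.modularity(G, part, weight="weight")
        if q > best_q:
            best_q, best_part = q, part
    return float(best_q), [set(c) for c in best_part]


@dataclass(frozen=True)
class SurrogateNormalized:
    """Clustering and path length normalised by a rewired-surrogate ensemble."""

    nc: float
    nl: float
    c_raw: float
    l_raw: float
    c_surrogate_mean: float
    l_surrogate_mean: float
    n_surrogates: int

    @property
    def sigma(self) -> float:
        return self.nc / self.nl


def _rewired_surrogate(a: np.ndarray, weighted: bool, rewire_seed: int,
                       weight_rng: np.random.Generator) -> np.ndarray:
    """One surrogate. The rewiring stream is independent of the
    weight-shuffling stream so binary and weighted surrogates share the
    identical rewired topology for the same seed (bridge invariant)."""
    G = _to_nx((a != 0).astype(float))
    m = G.number_of_edges()
    try:
        nx.double_edge_swap(G, nswap=10 * m, max_tries=200 * m, seed=rewire_seed)
        topo = nx.to_numpy_array(G, nodelist=range(a.shape[0]))
    except (nx.NetworkXError, nx.NetworkXAlgorithmError) as exc:
        warnings.warn(f"degree-preserving rewiring failed ({exc}); "
                      "falling back to weight-shuffle-only surrogates")
        topo = (a != 0).astype(float)
    if not weighted:
        return topo
    iu, ju = np.nonzero(np.triu(topo, k=1))
    w_iu, w_ju = np.nonzero(np.triu(a, k=1))
    weights = a[w_iu, w_ju].copy()
    weight_rng.shuffle(weights)
    out = np.zeros_like(a)
    out[iu, ju] = weights[: len(iu)]
    out[ju, iu] = out[iu, ju]
    return out


def surrogate_normalize(
    g: ThresholdedGraph | np.ndarray, n_surrogates: int = 50, seed: int = 0
) -> SurrogateNormalized:
    """Normalise C and L by their means over degree-preserving surrogates.

    Surrogates rewire the binary topology with double-edge swaps (degree
    sequence preserved); weighted graphs additionally shuffle the surviving
    weights over the rewired topology.
    """
    if n_surrogates < 1:
        raise InvalidArgumentError("n_surrogates must be >= 1")
    a, weighted = _adj(g)
    _, c = clustering(g)
    l = char_path_length(g)
    cs, ls = [], []
    for i in range(n_surrogates):
        s = _rewired_surrogate(
            a, weighted, rewire_seed=derive_seed(seed, "rewire", i),
            weight_rng=np.random.default_rng(derive_seed(seed, "weights", i)))
        cs.append(clustering(s)[1])
        ls.append(char_path_length(s))
    c_mean, l_mean = float(np.mean(cs)), float(np.mean(ls))
    return SurrogateNormalized(
        nc=c / c_mean if c_mean > 0 else np.nan,
        nl=l / l_mean if l_mean > 0 else np.nan,
        c_raw=c, l_raw=l, c_surrogate_mean=c_mean, l_surrogate_mean=l_mean,
        n_surrogates=n_surrogates,
    )


def small_worldness(g: ThresholdedGraph | np.ndarray, seed: int = 0,
                    n_surrogates: int = 50) -> float:
    """sigma = N-C / N-L; > 1 indicates small-world topology."""
    return surrogate_normalize(g, n_surrogates=n_surrogates, seed=seed).sigma


def regional_means(vector: np.ndarray, layout: SensorLayout) -> dict[str, float]:
    """Mean of a node-level metric within each scalp region."""
    vector = np.asarray(vector, dtype=float)
    if len(vector) != layout.n_channels:
        raise InvalidArgumentError("vector length does not match layout")
    regions = np.asarray(layout.region)
    return {r: float(vector[regions == r].mean()) for r in sorted(set(regions))}
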