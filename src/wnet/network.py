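"""Matrix normalisation, proportional thresholding and edge-distance profiles.

Proportional thresholding (PT%) retains the strongest PT% of the possible
off-diagonal edges; a "weighted" graph keeps the surviving weights, a
"binary" graph sets them to 1. The retained edge count is
k = round(PT/100 * n(n-1)/2), with ties at the cut broken deterministically
by the lowest (row, column) index.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .connectivity import ConnectivityMatrix
from .exceptions import DegenerateInputError, InvalidArgumentError
from .synthetic import SensorLayout

#: Edge-length ranges in mm (left-closed, right-open except the last bin,
#: interpreted from the printed integer boundaries <57 / 57-114 / 115-170 /
#: 171-227).
DISTANCE_RANGES: dict[str, tuple[float, float]] = {
    "very_short": (0.0, 57.0),
    "short": (57.0, 115.0),
    "long": (115.0, 171.0),
    "very_long": (171.0, 227.0),
}


@dataclass(frozen=True)
class ThresholdedGraph:
    """A proportionally thresholded connectivity graph."""

    adjacency: np.ndarray
    mode: str  # "binary" | "weighted"
    pt_percent: float
    labels: tuple[str, ...]
    source: ConnectivityMatrix | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.adjacency[iu, ju]))

    def edge_set(self) -> set[tuple[int, int]]:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        on = self.adjacency[iu, ju] != 0
        return set(zip(iu[on].tolist(), ju[on].tolist()))


@dataclass(frozen=True)
class DistanceProfile:
    """Mean connectivity and edge counts per inter-electrode distance range."""

    mean_wpli: dict[str, float]
    counts: dict[str, int]

    def __post_init__(self):
        if set(self.mean_wpli) != set(DISTANCE_RANGES) or set(self.counts) != set(DISTANCE_RANGES):
            raise InvalidArgumentError("profile must cover all four distance ranges")


def normalize_weights(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Divide all weights by the matrix's maximum connectivity value.

    Puts every matrix on a [0, 1] scale with max 1, removing group-level
    differences in overall connectivity strength before weighted metrics
    are computed. Rank order of entries is preserved.
    """
    mx = m.wpli.max()
    if mx <= 0:
        raise DegenerateInputError("all-zero connectivity matrix cannot be normalized")
    return replace(m, wpli=m.wpli / mx)


def proportional_threshold(
    m: ConnectivityMatrix | np.ndarray,
    pt_percent: float,
    mode: str = "weighted",
) -> ThresholdedGraph:
    """Keep the strongest pt_percent% of off-diagonal edges."""
    if not 0 < pt_percent <= 100:
        raise InvalidArgumentError(f"pt_percent must be in (0, 100], got {pt_percent}")
    if mode not in ("binary", "weighted"):
        raise InvalidArgumentError(f"mode must be 'binary' or 'weighted', got {mode!r}")
    if isinstance(m, ConnectivityMatrix):
        w, labels, source = m.wpli, m.labels, m
    else:
        w = np.asarray(m, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or not np.allclose(w, w.T, atol=1e-9):
            raise InvalidArgumentError("matrix must be square symmetric")
        labels, source = tuple(f"n{i}" for i in range(w.shape[0])), None
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    n_possible = len(vals)
    k = int(np.floor(pt_percent / 100.0 * n_possible + 0.5))
    adj = np.zeros_like(w)
    if k > 0:
        # stable sort on (-weight, row, col): ties at the cut go to the
        # lowest (row, column) index
        order = np.lexsort((ju, iu, -vals))
        keep = order[:k]
        kept = vals[keep] if mode == "weighted" else np.ones(k)
        adj[iu[keep], ju[keep]] = kept
        adj[ju[keep], iu[keep]] = kept
    return ThresholdedGraph(adjacency=adj, mode=mode, pt_percent=float(pt_percent),
                            labels=labels, source=source)


def pt_sweep(
    m: ConnectivityMatrix | np.ndarray,
    pt_lo: float = 3,
    pt_hi: float = 60,
    step: float = 1,
    mode: str = "weighted",
) -> list[ThresholdedGraph]:
    """Threshold at every PT% level of the grid (default 3..60%, 58 levels)."""
    if pt_lo > pt_hi:
        raise InvalidArgumentError("pt_lo must be <= pt_hi")
    levels = np.arange(pt_lo, pt_hi + step / 2, step)
    return [proportional_threshold(m, float(pt), mode=mode) for pt in levels]


def mean_wpli(m: ConnectivityMatrix) -> float:
    """Arithmetic mean connectivity over all (upper-triangle) edges."""
    n = m.n_channels
    if n < 2:
        raise InvalidArgumentError("need at least 2 channels")
    iu, ju = np.triu_indices(n, k=1)
    return float(m.wpli[iu, ju].mean())


def distance_profile(m: ConnectivityMatrix, layout: SensorLayout) -> DistanceProfile:
    """Bin edges by inter-electrode Euclidean distance; mean WPLI per bin."""
    if tuple(layout.labels) != tuple(m.labels):
        raise InvalidArgumentError("layout labels do not match matrix labels")
    d = layout.pairwise_distances()
    iu, ju = np.triu_indices(m.n_channels, k=1)
    dist, vals = d[iu, ju], m.wpli[iu, ju]
    if np.any(dist > DISTANCE_RANGES["very_long"][1]):
        warnings.warn("edge distance exceeds 227 mm; assigned to the 'very_long' range")
    means, counts = {}, {}
    last_name = list(DISTANCE_RANGES)[-1]
    for name, (lo, hi) in DISTANCE_RANGES.items():
        if name == last_name:
            sel = dist >= lo  # closed on the right; out-of-range edges land here
        else:
            sel = (dist >= lo) & (dist < hi)
        counts[name] = int(sel.sum())
        means[name] = float(vals[sel].mean()) if sel.any() else float("nan")
    return DistanceProfile(mean_wpli=means, counts=counts)
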