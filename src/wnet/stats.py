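"""Between-group statistics for connectivity and network measures.

Covers the full inferential chain used on threshold-averaged measures:
Kruskal-Wallis omnibus tests followed by pairwise two-tailed Mann-Whitney U
post hocs under Holm-Bonferroni control; the Mack-Skillings rank test for a
group effect across threshold-level blocks; a network-based statistic (NBS)
that controls family-wise error over connected components of
supra-threshold edges by permutation; per-distance-range comparisons; a
mixed-design (region within-subject x group between-subject) ANOVA gate for
regional measures; and uncorrected Spearman correlations against clinical
scores.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from ._utils import rng_for
from .connectivity import ConnectivityMatrix
from .exceptions import InvalidArgumentError
from .network import DISTANCE_RANGES, DistanceProfile


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_raw: float
    p_adjusted: float
    correction: str  # "none" | "holm" | "bonferroni"
    comparison: tuple = ()
    alpha: float = 0.05
    extras: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_adjusted < self.alpha


@dataclass(frozen=True)
class NbsResult:
    components: list  # list of edge-index lists [(i, j), ...]
    component_labels: list  # same edges as label pairs
    component_sizes: list  # edge counts
    component_p: list
    threshold: float
    n_perm: int
    stat_matrix: np.ndarray
    null_max_sizes: np.ndarray


def _as_groups(groups, min_per_group=2):
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise InvalidArgumentError("need at least 2 groups")
    for i, g in enumerate(gs):
        if len(g) < min_per_group:
            raise InvalidArgumentError(f"group {i} has fewer than {min_per_group} values")
    return gs


def kruskal_wallis(groups, labels=None, alpha: float = 0.05) -> StatResult:
    """Kruskal-Wallis H with average-rank tie correction; chi-square p."""
    gs = _as_groups(groups)
    if np.ptp(np.concatenate(gs)) == 0:
        # every observation tied: no evidence against the null
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*gs)
    return StatResult(statistic=float(h), p_raw=float(p), p_adjusted=float(p),
                      correction="none",
                      comparison=tuple(labels) if labels is not None else (),
                      alpha=alpha)


def _mwu(a, b):
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    exact = len(a) <= 8 and len(b) <= 8 and len(np.unique(pooled)) == len(pooled)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def mann_whitney_posthoc(groups, labels=None, comparisons=None,
                         alpha: float = 0.05) -> list[StatResult]:
    """All-pairs two-tailed Mann-Whitney U with Holm step-down correction.

    Exact p for small tie-free samples (both n <= 8), normal approximation
    with tie and continuity correction otherwise.
    """
    gs = _as_groups(groups)
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(gs))]
    pairs = list(comparisons) if comparisons is not None else list(combinations(range(len(gs)), 2))
    raw = []
    stat = []
    for i, j in pairs:
        u, p = _mwu(gs[i], gs[j])
        stat.append(u)
        raw.append(p)
    adj = holm_adjust(raw)
    return [
        StatResult(statistic=stat[k], p_raw=raw[k], p_adjusted=adj[k],
                   correction="holm", comparison=(labels[i], labels[j]), alpha=alpha)
        for k, (i, j) in enumerate(pairs)
    ]


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def mack_skillings(values, groups, blocks, alpha: float = 0.05) -> StatResult:
    """Mack-Skillings rank test for a group effect across blocks.

    The block-design generalisation of the Friedman test that allows
    replication: observations are ranked within each block (average ranks
    for ties), group rank sums are centred against their within-block
    expectation and scaled by 1/(N_block + 1), and the quadratic form
    against the exact finite-population within-block covariance is referred
    to chi-square with (n_groups - 1) degrees of freedom. Reduces to
    Friedman for one observation per group per block.
    """
    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(groups).ravel()
    blocks = np.asarray(blocks).ravel()
    if not len(values) == len(groups) == len(blocks):
        raise InvalidArgumentError("values, groups and blocks must align")
    glabels = np.unique(groups)
    blabels = np.unique(blocks)
    k = len(glabels)
    if k < 2:
        raise InvalidArgumentError("need at least 2 groups")
    d = np.zeros(k)
    cov = np.zeros((k, k))
    for b in blabels:
        sel = blocks == b
        r = sps.rankdata(values[sel])
        gb = groups[sel]
        n_i = len(r)
        var = r.var()  # population variance of realised ranks (handles ties)
        scale = 1.0 / (n_i + 1)
        n_ij = np.array([(gb == g).sum() for g in glabels])
        if np.any(n_ij == 0):
            g_missing = glabels[np.argmin(n_ij)]
            raise InvalidArgumentError(f"block {b!r} has no observation for group {g_missing!r}")
        rsum = np.array([r[gb == g].sum() for g in glabels])
        d += scale * (rsum - n_ij * r.mean())
        if n_i > 1 and var > 0:
            c = -np.outer(n_ij, n_ij) * var / (n_i - 1)
            np.fill_diagonal(c, n_ij * var * (n_i - n_ij) / (n_i - 1))
            cov += scale**2 * c
    stat = float(d @ np.linalg.pinv(cov) @ d) if np.any(cov) else 0.0
    p = float(sps.chi2.sf(stat, df=k - 1))
    return StatResult(statistic=stat, p_raw=p, p_adjusted=p, correction="none",
                      comparison=tuple(glabels.tolist()), alpha=alpha,
                      extras={"df": k - 1, "n_blocks": len(blabels)})


def _edge_data(matrices) -> tuple[np.ndarray, tuple, tuple[np.ndarray, np.ndarray]]:
    mats = [m.wpli if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
            for m in matrices]
    n = mats[0].shape[0]
    labels = (matrices[0].labels if isinstance(matrices[0], ConnectivityMatrix)
              else tuple(f"n{i}" for i in range(n)))
    iu, ju = np.triu_indices(n, k=1)
    return np.stack([m[iu, ju] for m in mats]), labels, (iu, ju)


def _edge_stat_f(data: np.ndarray, labels: np.ndarray, glabels: np.ndarray) -> np.ndarray:
    """Vectorised one-way ANOVA F per edge (subjects x edges data)."""
    grand = data.mean(axis=0)
    ssb = np.zeros(data.shape[1])
    ssw = np.zeros(data.shape[1])
    for g in glabels:
        sub = data[labels == g]
        m = sub.mean(axis=0)
        ssb += len(sub) * (m - grand) ** 2
        ssw += ((sub - m) ** 2).sum(axis=0)
    df1 = len(glabels) - 1
    df2 = data.shape[0] - len(glabels)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / (ssw / df2)
    return np.nan_to_num(f, nan=0.0, posinf=np.inf)


def _edge_stat_t(data: np.ndarray, labels: np.ndarray, glabels: np.ndarray) -> np.ndarray:
    """Pooled-variance one-tailed t per edge (first group > second group)."""
    a, b = data[labels == glabels[0]], data[labels == glabels[1]]
    na, nb = len(a), len(b)
    sp = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp * (1 / na + 1 / nb))
    return np.nan_to_num(t, nan=0.0)


def _max_component(supra: np.ndarray, iu, ju, n_nodes: int):
    """Connected components of the supra-threshold edge graph; returns
    (component edge-index lists, sizes) sorted by size descending."""
    if not supra.any():
        return [], []
    adj = csr_matrix(
        (np.ones(int(supra.sum())), (iu[supra], ju[supra])), shape=(n_nodes, n_nodes))
    n_comp, node_comp = connected_components(adj + adj.T, directed=False)
    edge_comp = node_comp[iu[supra]]
    comps, sizes = [], []
    eidx = np.flatnonzero(supra)
    for c in np.unique(edge_comp):
        edges = eidx[edge_comp == c]
        if len(edges):
            comps.append(edges)
            sizes.append(len(edges))
    order = np.argsort(sizes)[::-1]
    return [comps[o] for o in order], [sizes[o] for o in order]


def nbs(matrices, design, stat: str = "F", threshold: float = 8.0,
        n_perm: int = 5000, seed: int = 0) -> NbsResult:
    """Network-based statistic: permutation FWER control over connected
    components of supra-threshold edges.

    Per edge, an across-subject statistic (one-way F across groups, or
    pooled one-tailed t for two groups) is computed; edges exceeding the
    component-forming threshold are collected into connected components and
    each component's family-wise p is the permutation probability of a null
    maximum component (edge-count) at least as large.
    """
    if threshold <= 0:
        raise InvalidArgumentError("threshold must be positive")
    data, labels, (iu, ju) = _edge_data(matrices)
    design = np.asarray(design)
    glabels = np.unique(design)
    for g in glabels:
        if (design == g).sum() < 2:
            raise InvalidArgumentError(f"group {g!r} has fewer than 2 subjects")
    if stat == "F":
        edge_stat = _edge_stat_f
    elif stat == "t_onetail":
        if len(glabels) != 2:
            raise InvalidArgumentError("t_onetail requires exactly 2 groups")
        edge_stat = _edge_stat_t
    else:
        raise InvalidArgumentError(f"unknown stat {stat!r}")
    n_nodes = len(labels)
    obs = edge_stat(data, design, glabels)
    supra = obs > threshold
    if supra.mean() > 0.5:
        warnings.warn("more than 50% of edges exceed the NBS threshold; "
                      "the component-forming threshold is likely too lenient")
    comps, sizes = _max_component(supra, iu, ju, n_nodes)
    rng = rng_for(seed, "nbs")
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(design)
        s = edge_stat(data, perm, glabels) > threshold
        _, null_sizes = _max_component(s, iu, ju, n_nodes)
        null_max[p] = max(null_sizes) if null_sizes else 0
    pvals = [float((1 + np.sum(null_max >= s)) / (n_perm + 1)) for s in sizes]
    return NbsResult(
        components=[[(int(iu[e]), int(ju[e])) for e in c] for c in comps],
        component_labels=[[(labels[iu[e]], labels[ju[e]]) for e in c] for c in comps],
        component_sizes=sizes, component_p=pvals, threshold=threshold,
        n_perm=n_perm,
        stat_matrix=_square(obs, iu, ju, n_nodes),
        null_max_sizes=null_max,
    )


def _square(vals, iu, ju, n):
    m = np.zeros((n, n))
    m[iu, ju] = vals
    m[ju, iu] = vals
    return m


def distance_range_tests(profiles: list[DistanceProfile], groups,
                         alpha: float = 0.05) -> dict:
    """Per-distance-range group comparisons: Kruskal-Wallis with Holm over
    the four ranges, pairwise Mann-Whitney with Holm over the pairs."""
    groups = np.asarray(groups)
    if len(profiles) != len(groups):
        raise InvalidArgumentError("profiles and groups must align")
    glabels = np.unique(groups)
    out = {}
    omnibus_raw = []
    for rng_name in DISTANCE_RANGES:
        vals = np.array([p.mean_wpli[rng_name] for p in profiles])
        per_group = [vals[groups == g] for g in glabels]
        kw = kruskal_wallis(per_group, labels=glabels, alpha=alpha)
        post = mann_whitney_posthoc(per_group, labels=glabels, alpha=alpha)
        out[rng_name] = {"omnibus": kw, "posthoc": post}
        omnibus_raw.append(kw.p_raw)
    adj = holm_adjust(omnibus_raw)
    for rng_name, p_adj in zip(DISTANCE_RANGES, adj):
        kw = out[rng_name]["omnibus"]
        out[rng_name]["omnibus"] = StatResult(
            statistic=kw.statistic, p_raw=kw.p_raw, p_adjusted=float(p_adj),
            correction="holm", comparison=kw.comparison, alpha=alpha)
    return out


def region_group_gate(regional: pd.DataFrame, alpha: float = 0.05,
                      correction: str | None = None) -> dict:
    """Mixed-design ANOVA gate for regional measures.

    `regional` is long-format with columns subject, group, region, value.
    A repeated-measures ANOVA with region as the within-subject factor and
    group between subjects is run first; only when the region x group
    interaction is significant are per-region Kruskal-Wallis (+ Mann-Whitney
    post hoc) tests performed, Holm-corrected over the four regions.
    Sphericity is assumed by default; pass correction="gg" for a
    Greenhouse-Geisser corrected interaction p.
    """
    import pingouin as pg

    required = {"subject", "group", "region", "value"}
    if not required.issubset(regional.columns):
        raise InvalidArgumentError(f"regional table needs columns {sorted(required)}")
    counts = regional.groupby("subject")["region"].nunique()
    if counts.nunique() != 1:
        raise InvalidArgumentError("missing region cells for some subjects")
    aov = pg.mixed_anova(data=regional, dv="value", within="region",
                         subject="subject", between="group", correction=correction == "gg")
    inter = aov[aov["Source"] == "Interaction"].iloc[0]
    p_col = "p_GG_corr" if correction == "gg" and "p_GG_corr" in aov.columns \
        and np.isfinite(inter.get("p_GG_corr", np.nan)) else "p_unc"
    p_inter = float(inter[p_col])
    result = {"anova": aov, "interaction_F": float(inter["F"]),
              "interaction_p": p_inter, "gate_passed": p_inter < alpha,
              "per_region": {}}
    if not result["gate_passed"]:
        return result
    glabels = np.unique(regional["group"])
    raw = []
    for region, sub in regional.groupby("region"):
        per_group = [sub.loc[sub["group"] == g, "value"].to_numpy() for g in glabels]
        kw = kruskal_wallis(per_group, labels=glabels, alpha=alpha)
        post = mann_whitney_posthoc(per_group, labels=glabels, alpha=alpha)
        result["per_region"][region] = {"omnibus": kw, "posthoc": post}
        raw.append((region, kw))
    adj = holm_adjust([kw.p_raw for _, kw in raw])
    for (region, kw), p_adj in zip(raw, adj):
        result["per_region"][region]["omnibus"] = StatResult(
            statistic=kw.statistic, p_raw=kw.p_raw, p_adjusted=float(p_adj),
            correction="holm", comparison=kw.comparison, alpha=alpha)
    return result


def clinical_correlations(measures: pd.DataFrame, clinical: pd.DataFrame,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Uncorrected Spearman correlations between network measures and
    clinical scores, per (group, band, measure, score).

    `measures` is long-format (subject_id, group, band, measure, value);
    `clinical` is wide (subject_id, group, one column per score). Rows with
    fewer than 5 paired observations are flagged unstable.
    """
    need = {"subject_id", "group", "band", "measure", "value"}
    if not need.issubset(measures.columns):
        raise InvalidArgumentError(f"measures table needs columns {sorted(need)}")
    score_cols = [c for c in clinical.columns if c not in ("subject_id", "group")]
    rows = []
    for (group, band, measure), sub in measures.groupby(["group", "band", "measure"]):
        merged = sub.merge(clinical[["subject_id"] + score_cols], on="subject_id")
        for score in score_cols:
            paired = merged[["value", score]].dropna()
            n = len(paired)
            if n >= 2 and paired["value"].nunique() > 1 and paired[score].nunique() > 1:
                rho, p = sps.spearmanr(paired["value"], paired[score])
            else:
                rho, p = np.nan, np.nan
            rows.append({"group": group, "band": band, "measure": measure,
                         "score": score, "rho": float(rho), "p": float(p),
                         "n": n, "correction": "uncorrected", "unstable": n < 5,
                         "significant": bool(p < alpha) if np.isfinite(p) else False})
    return pd.DataFrame(rows)
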