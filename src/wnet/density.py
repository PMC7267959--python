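"""Dependence of network measures on the proportional-threshold level.

Three complementary quantifications:

1. Spearman rank correlation between a metric curve and the PT% grid, with
   a permutation (bootstrap) null of 5,000 shuffles; a correlation is
   significant when it falls in the outer 2.5% of either null tail.
2. A three-parameter power-law fit, value = scale * t^exponent + offset,
   with t = PT%/100 in (0, 1].
3. A closed-form comparison of the first derivatives of the binary and
   weighted fits: the sub-interval of (0, 1] where the weighted measure's
   slope magnitude is below the binary one, i.e. where
   (m n t^(n-1)) / (f g t^(g-1)) < 1 with (f, g) binary and (m, n) weighted
   power-law coefficients. Since the ratio is (mn/fg) t^(n-g), the boundary
   is t* = (f g / (m n))^(1/(n-g)) and the direction follows sign(n - g).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._utils import rng_for
from .exceptions import DegenerateInputError, FitFailureError, InvalidArgumentError
from .metrics import char_path_length, clustering, degree, modularity, small_worldness
from .network import ThresholdedGraph


@dataclass(frozen=True)
class MetricCurve:
    """One network measure evaluated across the PT% sweep."""

    pt_levels: np.ndarray
    values: np.ndarray
    metric: str = ""
    mode: str = ""
    band: str = ""
    subject: str = ""

    def __post_init__(self):
        if len(self.pt_levels) != len(self.values):
            raise InvalidArgumentError("pt_levels and values must have equal length")
        if np.any(np.diff(self.pt_levels) <= 0):
            raise InvalidArgumentError("pt_levels must be strictly increasing")

    @property
    def mean(self) -> float:
        """Threshold-averaged measure (the scalar used in group tests)."""
        return float(np.mean(self.values))


@dataclass(frozen=True)
class PowerLawFit:
    """value = scale * t^exponent + offset on t = PT%/100 in (0, 1]."""

    scale: float
    exponent: float
    offset: float
    sse: float
    ci95: dict = field(default_factory=dict)  # coefficient -> (lo, hi)
    n_points: int = 0

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(t, dtype=float) ** self.exponent + self.offset

    def derivative(self, t: np.ndarray) -> np.ndarray:
        return self.scale * self.exponent * np.asarray(t, dtype=float) ** (self.exponent - 1)


@dataclass(frozen=True)
class DensityDependence:
    """Spearman rho against PT% with a permutation-null significance call."""

    rho: float
    p_null: float
    null_quantiles: dict
    significant: bool
    n_perm: int
    degenerate: bool = False


@dataclass(frozen=True)
class Interval:
    """A sub-interval of (0, 1], possibly empty."""

    lower: float = 0.0
    upper: float = 1.0
    lower_open: bool = True
    upper_open: bool = False
    empty: bool = False

    @property
    def full(self) -> bool:
        return (not self.empty) and self.lower <= 0.0 and self.upper >= 1.0

    def contains(self, t: float) -> bool:
        if self.empty:
            return False
        lo_ok = t > self.lower if self.lower_open else t >= self.lower
        hi_ok = t < self.upper if self.upper_open else t <= self.upper
        return lo_ok and hi_ok


_METRIC_FUNCS = {
    "degree": lambda g, **kw: degree(g)[1],
    "clustering": lambda g, **kw: clustering(g)[1],
    "path_length": lambda g, **kw: char_path_length(g),
    "modularity": lambda g, *, seed=0, **kw: modularity(g, seed=seed)[0],
    "sigma": lambda g, *, seed=0, n_surrogates=50, **kw: small_worldness(
        g, seed=seed, n_surrogates=n_surrogates),
}


def metric_curve(graphs: list[ThresholdedGraph], metric: str, **kwargs) -> MetricCurve:
    """Evaluate one metric at every level of a threshold sweep.

    Levels where the metric raises (e.g. path length on a fully
    disconnected very-sparse graph) are dropped with a warning.
    """
    if not graphs:
        raise InvalidArgumentError("empty threshold sweep")
    if metric not in _METRIC_FUNCS:
        raise InvalidArgumentError(f"unknown metric {metric!r}; options: {sorted(_METRIC_FUNCS)}")
    func = _METRIC_FUNCS[metric]
    levels, values = [], []
    for g in graphs:
        try:
            values.append(float(func(g, **kwargs)))
            levels.append(g.pt_percent)
        except DegenerateInputError as exc:
            warnings.warn(f"dropping PT={g.pt_percent}%: {exc}")
    if not values:
        raise DegenerateInputError("metric failed at every threshold level")
    return MetricCurve(pt_levels=np.asarray(levels, dtype=float),
                       values=np.asarray(values), metric=metric,
                       mode=graphs[0].mode)


def _pool(curves) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curves, MetricCurve):
        curves = [curves]
    levels = np.concatenate([c.pt_levels for c in curves])
    values = np.concatenate([c.values for c in curves])
    return levels, values


def density_dependence(curves, n_perm: int = 5000, seed: int = 0) -> DensityDependence:
    """Spearman correlation of pooled metric values against PT%, with a
    permutation null (values shuffled against levels)."""
    levels, values = _pool(curves)
    if len(values) < 3:
        raise InvalidArgumentError("need at least 3 points")
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    if np.ptp(values) == 0:
        return DensityDependence(rho=0.0, p_null=1.0, null_quantiles={},
                                 significant=False, n_perm=n_perm, degenerate=True)
    rho = float(stats.spearmanr(levels, values).statistic)
    rl = stats.rankdata(levels)
    rv = stats.rankdata(values)
    rl = (rl - rl.mean()) / rl.std()
    rv = (rv - rv.mean()) / rv.std()
    rng = rng_for(seed, "density-null")
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = rl @ rng.permutation(rv) / len(rl)
    q_lo, q_hi = np.quantile(null, [0.025, 0.975])
    p = (1 + np.sum(np.abs(null) >= abs(rho))) / (n_perm + 1)
    return DensityDependence(
        rho=rho, p_null=float(p),
        null_quantiles={"q2.5": float(q_lo), "q97.5": float(q_hi)},
        significant=bool(rho < q_lo or rho > q_hi), n_perm=n_perm,
    )


_EXPONENT_STARTS = (0.05, 0.25, 0.5, 1.0, 2.0)


def fit_power_law(curve: MetricCurve) -> PowerLawFit:
    """Nonlinear least squares for value = scale * t^exponent + offset.

    Multi-start over an exponent grid guards against local minima; 95% CIs
    come from the linearised covariance at the optimum.
    """
    t = np.asarray(curve.pt_levels, dtype=float) / 100.0
    y = np.asarray(curve.values, dtype=float)
    if len(t) < 4:
        raise InvalidArgumentError("need at least 4 points to fit 3 coefficients")
    if np.any(t <= 0) or np.any(t > 1):
        raise InvalidArgumentError("t = PT%/100 must lie in (0, 1]")

    def model(tt, a, b, c):
        return a * tt**b + c

    best = None
    for b0 in _EXPONENT_STARTS:
        # linear least squares for (scale, offset) given the exponent start
        X = np.column_stack([t**b0, np.ones_like(t)])
        (a0, c0), *_ = np.linalg.lstsq(X, y, rcond=None)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    model, t, y, p0=[a0, b0, c0], maxfev=20000)
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        sse = float(np.sum((model(t, *popt) - y) ** 2))
        if np.all(np.isfinite(popt)) and (best is None or sse < best[2]):
            best = (popt, pcov, sse)
    if best is None:
        raise FitFailureError(
            f"power-law fit failed from all starts {_EXPONENT_STARTS} on "
            f"{len(t)} points (y range {y.min():.3g}..{y.max():.3g})")
    popt, pcov, sse = best
    dof = max(len(t) - 3, 1)
    tval = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    names = ("scale", "exponent", "offset")
    ci = {n: (float(p - tval * s), float(p + tval * s)) for n, p, s in zip(names, popt, se)}
    return PowerLawFit(scale=float(popt[0]), exponent=float(popt[1]),
                       offset=float(popt[2]), sse=sse, ci95=ci, n_points=len(t))


def derivative_ratio_condition(fit_binary: PowerLawFit, fit_weighted: PowerLawFit) -> Interval:
    """Closed-form t-interval on (0, 1] where the weighted fit's derivative
    is smaller than the binary fit's.

    With binary value = f t^g + h and weighted value = m t^n + q, the
    derivative ratio is (m n / (f g)) t^(n-g); the condition ratio < 1
    switches at t* = (f g / (m n))^(1/(n-g)).
    """
    f, g = fit_binary.scale, fit_binary.exponent
    m, n = fit_weighted.scale, fit_weighted.exponent
    if g == 0 or n == 0:
        raise InvalidArgumentError("exponents must be nonzero")
    if f <= 0 or m <= 0:
        raise InvalidArgumentError("scale coefficients must be positive")
    if np.sign(g) != np.sign(n):
        raise InvalidArgumentError("sign-flipped exponents: derivatives have opposite signs")
    const = (m * n) / (f * g)  # ratio at t=1; positive by the checks above
    if n == g:
        if const < 1:
            return Interval(lower=0.0, upper=1.0)
        return Interval(empty=True)
    t_star = (f * g / (m * n)) ** (1.0 / (n - g))
    if n < g:
        # ratio decreasing in t: condition holds for t > t_star
        if t_star >= 1.0:
            return Interval(empty=True)
        return Interval(lower=max(t_star, 0.0), upper=1.0)
    # ratio increasing in t: condition holds for t < t_star
    if t_star <= 0.0:
        return Interval(empty=True)
    if t_star > 1.0:
        return Interval(lower=0.0, upper=1.0)
    return Interval(lower=0.0, upper=t_star, upper_open=True)
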