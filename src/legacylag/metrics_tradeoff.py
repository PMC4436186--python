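"""Concentration-reduction metrics, thresholds and cost/time tradeoffs.

CR_t = 1 - C_ac(t)/C_bc is the fractional concentration reduction achieved
t years after conversion; CR_inf is its infinite-time limit, the maximum
benefit the conversion can ever deliver.  For an exponential TTD the limits
are closed forms:

    random:  CR_inf = p                     (the 1:1 rule, independent of mu, k)
    frontal: CR_inf = 1 - (1-p)^(1 + mu k)
    distal:  CR_inf = p^(1 + mu k)

For a general TTD, CR_inf = 1 - W(unconverted)/W(all) with
W(A) = integral_A f(tau) e^{-k tau} dtau: parcels with long travel times are
discounted by en-route denitrification, which is why converting them
(distal) buys the least and converting short-travel-time parcels (frontal)
the most.

Under a frontal pattern evaluated at a deadline t_d, conversion beyond
p* = F(t_d) buys nothing: the extra parcels' water has not arrived yet.
:func:`benefit_threshold` returns that p*, and :func:`pareto_front` maps the
(time-to-target, fraction-converted) tradeoff with p as the cost proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import TargetNotReachedError, UnreachableTargetError
from .outlet_response import (
    OutletModel,
    ScenarioSpec,
    outlet_ratio,
    _quad,
    _upper_cut,
)
from .travel_time import ExponentialTTD, TravelTimeDistribution

__all__ = [
    "ContourGrid",
    "ParetoPoint",
    "cr_t",
    "cr_inf",
    "time_to_cr",
    "benefit_threshold",
    "contour_grid",
    "pareto_front",
    "write_contour",
    "write_pareto",
]


def cr_t(t, model: OutletModel, engine: str = "auto"):
    """Fractional concentration reduction CR_t = 1 - C_ac(t)/C_bc, in [0, 1]."""
    ratio = outlet_ratio(t, model, engine=engine)
    return np.clip(1.0 - np.asarray(ratio), 0.0, 1.0) if np.ndim(ratio) else float(
        min(max(1.0 - ratio, 0.0), 1.0)
    )


def cr_inf(model: OutletModel) -> float:
    """Maximum achievable concentration reduction (t -> infinity limit).

    Requires a decaying source (converted parcels eventually leach nothing);
    a step source with a nonzero post-change concentration has no meaningful
    maximum-benefit limit and is rejected.
    """
    if not model.source.decays:
        raise ValueError("cr_inf requires a decaying source (Cs -> 0)")
    p = model.scenario.p
    pattern = model.scenario.pattern
    if pattern == "random":
        return p
    ttd, k = model.ttd, model.k
    if isinstance(ttd, ExponentialTTD):
        expo = 1.0 + ttd.mu * k
        if pattern == "frontal":
            return 1.0 - (1.0 - p) ** expo
        return p**expo
    # general TTD: unconverted decayed mass over total decayed mass
    upper = _upper_cut(ttd, k)
    b = ttd.quantile(p) if pattern == "frontal" else ttd.quantile(1.0 - p)
    b = min(b, upper)
    total = _quad(lambda tau: ttd.pdf(tau) * np.exp(-k * tau), 0.0, upper, points=(b,))
    if pattern == "frontal":
        uncon = _quad(lambda tau: ttd.pdf(tau) * np.exp(-k * tau), b, upper)
    else:
        uncon = _quad(lambda tau: ttd.pdf(tau) * np.exp(-k * tau), 0.0, b)
    return 1.0 - uncon / total


def time_to_cr(target: float, model: OutletModel, *, horizon: float = 1.0e4,
               engine: str = "auto") -> float:
    """First time (years) at which CR_t reaches ``target``.

    Raises :class:`UnreachableTargetError` (naming the model's CR_inf) when
    the target exceeds the maximum achievable reduction, and
    :class:`TargetNotReachedError` when the crossing lies beyond ``horizon``.
    For a distal pattern the result is at least the onset lag F^-1(1-p).
    """
    if not 0 < target < 1:
        raise ValueError("target must be strictly between 0 and 1")
    crmax = cr_inf(model)
    if target >= crmax:
        raise UnreachableTargetError(
            f"target CR {target:.4g} is unreachable: CR_inf = {crmax:.4g}"
        )

    def g(t):
        return cr_t(float(t), model, engine=engine) - target

    lo, hi = 0.0, 1.0
    while g(hi) < 0:
        lo, hi = hi, hi * 2.0
        if hi > horizon:
            raise TargetNotReachedError(
                f"CR {target:.4g} not reached within {horizon:g} years"
            )
    if g(lo) >= 0:  # crossed within the first bracket
        lo = 0.0
    return float(brentq(g, lo, hi, xtol=1.0e-8))


def benefit_threshold(t_d: float, ttd: TravelTimeDistribution) -> float:
    """Conversion fraction p* = F(t_d) beyond which frontal conversion adds
    no benefit at deadline ``t_d``.

    Land converted beyond p* has travel times exceeding t_d, so its water
    has not reached the outlet at the evaluation time; CR_t(t_d) is flat in
    p for p >= p*.
    """
    if t_d <= 0:
        raise ValueError("t_d must be > 0")
    return float(ttd.cdf(t_d))


@dataclass(frozen=True)
class ContourGrid:
    """CR values gridded over conversion fraction and mean travel time."""

    p_values: np.ndarray
    mu_values: np.ndarray
    cr: np.ndarray  # shape (len(p_values), len(mu_values))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "p_values", np.asarray(self.p_values, float))
        object.__setattr__(self, "mu_values", np.asarray(self.mu_values, float))
        object.__setattr__(self, "cr", np.asarray(self.cr, float))
        if self.cr.shape != (self.p_values.size, self.mu_values.size):
            raise ValueError("cr must have shape (len(p_values), len(mu_values))")

    def to_long_frame(self) -> pd.DataFrame:
        pp, mm = np.meshgrid(self.p_values, self.mu_values, indexing="ij")
        return pd.DataFrame(
            {"p": pp.ravel(), "mu_years": mm.ravel(), "cr": self.cr.ravel()}
        )


def contour_grid(p_grid, mu_grid, at, pattern: str, k: float, source) -> ContourGrid:
    """CR_t (``at`` = years) or CR_inf (``at`` = "inf") over a (p, mu) grid.

    Each column uses an exponential TTD with the column's mean travel time;
    the source and denitrification rate are held fixed.
    """
    p_grid = np.atleast_1d(np.asarray(p_grid, float))
    mu_grid = np.atleast_1d(np.asarray(mu_grid, float))
    if p_grid.size == 0 or mu_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if np.any(mu_grid <= 0):
        raise ValueError("mu values must be > 0")
    is_inf = isinstance(at, str)
    if is_inf and at != "inf":
        raise ValueError("at must be a time in years or the string 'inf'")
    cr = np.empty((p_grid.size, mu_grid.size))
    for j, mu in enumerate(mu_grid):
        ttd = ExponentialTTD(mu=float(mu))
        for i, p in enumerate(p_grid):
            model = OutletModel(source, ttd, k, ScenarioSpec(pattern, float(p)))
            cr[i, j] = cr_inf(model) if is_inf else cr_t(float(at), model)
    return ContourGrid(
        p_values=p_grid,
        mu_values=mu_grid,
        cr=cr,
        metadata={"pattern": pattern, "k": k, "at": "inf" if is_inf else float(at)},
    )


@dataclass(frozen=True)
class ParetoPoint:
    """A non-dominated (time-to-target, fraction-converted) pair."""

    time_to_target: float
    p: float


def pareto_front(
    cr_target: float,
    mu: float,
    pattern: str,
    k: float,
    source,
    p_grid,
    *,
    horizon: float = 1.0e4,
) -> list[ParetoPoint]:
    """Non-dominated (time, p) pairs achieving ``cr_target``.

    For every feasible conversion fraction in ``p_grid`` the time to reach
    the target reduction is computed; pairs are filtered to the Pareto front
    under minimization of both time and p (ties in time keep the smaller p,
    since p proxies cost).
    """
    p_grid = np.atleast_1d(np.asarray(p_grid, float))
    ttd = ExponentialTTD(mu=mu)
    candidates: list[ParetoPoint] = []
    best_crinf = 0.0
    for p in sorted(p_grid):
        model = OutletModel(source, ttd, k, ScenarioSpec(pattern, float(p)))
        best_crinf = max(best_crinf, cr_inf(model))
        try:
            t = time_to_cr(cr_target, model, horizon=horizon)
        except (UnreachableTargetError, TargetNotReachedError):
            continue
        candidates.append(ParetoPoint(time_to_target=t, p=float(p)))
    if not candidates:
        raise UnreachableTargetError(
            f"CR {cr_target:.4g} infeasible for all p in grid; "
            f"max achievable CR_inf = {best_crinf:.4g}"
        )
    front: list[ParetoPoint] = []
    best_time = np.inf
    for pt in candidates:  # ascending p: keep only strict time improvements
        if pt.time_to_target < best_time:
            front.append(pt)
            best_time = pt.time_to_target
    return front


def write_contour(grid: ContourGrid, path) -> None:
    """Long-format (p, mu_years, cr) tab-delimited export."""
    grid.to_long_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_pareto(front: list[ParetoPoint], path) -> None:
    """(time_years, p) tab-delimited export."""
    pd.DataFrame(
        {"time_years": [pt.time_to_target for pt in front], "p": [pt.p for pt in front]}
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")
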