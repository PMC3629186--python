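"""Competitive-ratio analysis of the casting-surge strategies.

Setting: a searcher starts at the origin; the target (odour source) sits at
unknown position at distance d.  Wind is fixed (downwind = -y).  The
searcher senses nothing except when its casting path crosses the target's
plume centerline — the half-line extending downwind from the target — at
which point it surges straight along the centerline to the target.  The
competitive ratio r is the worst case over target placements of (casting
path length + surge length) / d.

Two strategy families are analysed:

* spiral-surge: logarithmic spiral casting ``r = a e^{b theta}`` in the
  ``a -> 0`` limit (no direction information; target anywhere on the circle).
  The worst case over targets is attained on two discontinuity families: the
  target exactly on the spiral (detection just misses the target itself and
  defers to the next crossing), and the centerline vertically tangent to a
  spiral turn.  Minimizing the worst case over the growth rate b yields
  r = 22.513 at b ~ 0.1137.

* zigzag-surge: crosswind linear search with leg lengths multiplied by m
  every reversal (classical cow-path doubling for m = 2), under the promise
  that the target is not downwind.  The casting component alone has
  worst-case ratio 1 + 2 m^2/(m-1) (= 9 at m = 2) in the infinitesimal
  initial-leg limit; adding the orthogonal surge gives
  r = max_phi (9 cos(phi) + sin(phi)) = sqrt(82) ~ 9.0554.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize_scalar

__all__ = [
    "SpiralSurgeStrategy",
    "ZigzagSurgeStrategy",
    "RatioResult",
    "cowpath_ratio",
    "doubling_search_path",
    "doubling_search_worst_ratio",
    "zigzag_surge_ratio",
    "spiral_surge_ratio",
]


@dataclass(frozen=True)
class SpiralSurgeStrategy:
    growth_rate: float | None = None   # None = optimize over b

    def __post_init__(self) -> None:
        if self.growth_rate is not None and self.growth_rate <= 0:
            raise ValueError("growth rate must be positive")


@dataclass(frozen=True)
class ZigzagSurgeStrategy:
    factor: float = 2.0
    initial_leg: float = 1e-4

    def __post_init__(self) -> None:
        if self.factor <= 1:
            raise ValueError("doubling factor must exceed 1")


@dataclass(frozen=True)
class RatioResult:
    r: float
    argmax: str
    converged: bool
    params: dict = field(default_factory=dict)
    trace: tuple = ()


# --------------------------------------------------------------------------
# doubling (cow-path) linear search


def cowpath_ratio(factor: float = 2.0) -> float:
    """Closed-form worst-case ratio of geometric linear search (no surge)."""
    m = factor
    return 1.0 + 2.0 * m * m / (m - 1.0)


def doubling_search_path(x: float, initial_leg: float, factor: float = 2.0,
                         first_right: bool = True) -> float:
    """Path length travelled until a point at distance ``x`` on the right
    half-line is first reached (legs alternate sides, growing by ``factor``)."""
    if x <= 0:
        raise ValueError("x must be positive")
    path = 0.0
    leg = initial_leg
    right = first_right
    while True:
        if right and leg >= x:
            return path + x
        path += 2.0 * leg
        leg *= factor
        right = not right
        if leg > 1e18 * x:  # unreachable (should not happen)
            raise RuntimeError("search did not terminate")


def doubling_search_worst_ratio(initial_leg: float, factor: float = 2.0,
                                max_doublings: int = 40) -> float:
    """Empirical sup of path/x over targets just beyond every reach point."""
    worst = 1.0
    eps = 1e-9
    for k in range(max_doublings):
        x = initial_leg * factor ** k * (1.0 + eps)
        for first_right in (True, False):
            p = doubling_search_path(x, initial_leg, factor, first_right)
            worst = max(worst, p / x)
    return worst


def zigzag_surge_ratio(
    strategy: ZigzagSurgeStrategy = ZigzagSurgeStrategy(),
    n_angles: int = 4001,
    tol: float = 5e-4,
) -> RatioResult:
    """Worst-case ratio of zigzag casting plus upwind surge.

    The target (distance d, not downwind) projects onto the crosswind search
    line at offset |d cos(phi)|; the casting cost up to that point is the
    cow-path cost, the surge cost is the orthogonal distance d sin(phi).
    The infinitesimal initial-leg limit is taken by extrapolation over a
    decreasing sequence of initial legs (equivalently, ever deeper reach
    points) with a convergence check.
    """
    m = strategy.factor
    trace = []
    prev = None
    conv = False
    worst_mult = None
    for depth in (10, 20, 40):
        wm = doubling_search_worst_ratio(strategy.initial_leg, m, depth)
        trace.append(wm)
        if prev is not None and abs(wm - prev) < tol:
            conv = True
        prev = wm
        worst_mult = wm
    phis = np.linspace(0.0, math.pi / 2.0, n_angles)
    vals = worst_mult * np.cos(phis) + np.sin(phis)
    i = int(np.argmax(vals))
    r = float(vals[i])
    if not conv:
        return RatioResult(r=r, argmax="non-converged", converged=False,
                           params={"factor": m}, trace=tuple(trace))
    return RatioResult(
        r=r,
        argmax=f"target at phi = {math.degrees(phis[i]):.2f} deg off the search line, "
               f"just beyond a reversal point",
        converged=True,
        params={"factor": m, "casting_multiplier": worst_mult},
        trace=tuple(trace),
    )


# --------------------------------------------------------------------------
# spiral-surge


@njit(cache=True)
def _first_crossing(b, tx, ty, th_start, scan_step):
    """First crossing of the spiral r=exp(b*th) with the half-line
    {x = tx, y <= ty}, scanning from th_start.  Returns (theta, y) or nans."""
    th_max = th_start + 8.0 * math.pi
    n = int((th_max - th_start) / scan_step) + 2
    dth = (th_max - th_start) / (n - 1)
    f_prev = math.exp(b * th_start) * math.cos(th_start) - tx
    t_prev = th_start
    for i in range(1, n):
        t = th_start + i * dth
        f = math.exp(b * t) * math.cos(t) - tx
        if f_prev * f <= 0.0 and f != f_prev:
            lo = t_prev
            hi = t
            f_lo = f_prev
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                fm = math.exp(b * mid) * math.cos(mid) - tx
                if f_lo * fm <= 0.0:
                    hi = mid
                else:
                    lo = mid
                    f_lo = fm
            ts = 0.5 * (lo + hi)
            ys = math.exp(b * ts) * math.sin(ts)
            if ys <= ty:
                return ts, ys
        f_prev = f
        t_prev = t
    return np.nan, np.nan


@njit(cache=True)
def _ratio_on_spiral(b, psi, scan_step):
    """Worst-case family A: target exactly on the spiral at angle psi."""
    d = math.exp(b * psi)
    tx = d * math.cos(psi)
    ty = d * math.sin(psi)
    if abs(tx) < 1e-12:
        return np.nan
    ts, ys = _first_crossing(b, tx, ty - 1e-9 * d, psi + 1e-7, scan_step)
    if np.isnan(ts):
        return np.nan
    arc = math.sqrt(1.0 + b * b) / b * math.exp(b * ts)
    return (arc + (ty - ys)) / d

@njit(cache=True)
def _ratio_tangency(b, k, ty, scan_step):
    """Worst-case family B: centerline tangent to the spiral turn at
    theta = atan(b) + k*pi; target at (x_tangent, ty)."""
    tt = math.atan(b) + k * math.pi
    xt = math.exp(b * tt) * math.cos(tt)
    yt = math.exp(b * tt) * math.sin(tt)
    if ty < yt:
        return np.nan
    ts, ys = _first_crossing(b, xt, ty, tt + 0.05, scan_step)
    if np.isnan(ts):
        return np.nan
    arc = math.sqrt(1.0 + b * b) / b * math.exp(b * ts)
    d = math.hypot(xt, ty)
    return (arc + (ty - ys)) / d


@njit(cache=True)
def _sup_ratio(b, n_psi, scan_step):
    """Sup over both worst-case families for a given growth rate."""
    best = -1.0
    best_psi = 0.0
    for i in range(n_psi):
        psi = 2.0 * math.pi * i / n_psi
        v = _ratio_on_spiral(b, psi, scan_step)
        if not np.isnan(v) and v > best:
            best = v
            best_psi = psi
    # local refinement around the best on-spiral angle
    lo = best_psi - 2.0 * math.pi / n_psi
    hi = best_psi + 2.0 * math.pi / n_psi
    for i in range(60):
        psi = lo + (hi - lo) * i / 59.0
        v = _ratio_on_spiral(b, psi, scan_step)
        if not np.isnan(v) and v > best:
            best = v
    which = 0
    for k in range(2):
        tt = math.atan(b) + k * math.pi
        xt = abs(math.exp(b * tt) * math.cos(tt))
        yt = math.exp(b * tt) * math.sin(tt)
        # sweep ty upward from the touch point on a log scale
        best_ty = -1.0
        bloc = -1.0
        for i in range(260):
            ty = yt + xt * 10.0 ** (-4.0 + 6.5 * i / 259.0)
            v = _ratio_tangency(b, k, ty, scan_step)
            if not np.isnan(v) and v > bloc:
                bloc = v
                best_ty = ty
        lo_ty = best_ty / 1.3
        hi_ty = best_ty * 1.3
        for i in range(200):
            ty = lo_ty + (hi_ty - lo_ty) * i / 199.0
            v = _ratio_tangency(b, k, ty, scan_step)
            if not np.isnan(v) and v > bloc:
                bloc = v
        if bloc > best:
            best = bloc
            which = 1
    return best, which


def spiral_surge_ratio(
    strategy: SpiralSurgeStrategy = SpiralSurgeStrategy(),
    n_psi: int = 720,
    scan_step: float = 0.002,
    tol: float = 5e-4,
) -> RatioResult:
    """Worst-case ratio of logarithmic-spiral casting plus surge.

    For a fixed growth rate the sup over target placements is evaluated on
    the two discontinuity families (see module docstring); if no growth rate
    is given the sup is minimized over b (Brent).  Convergence is declared
    when refining the discretization changes r by less than ``tol``;
    otherwise the result is flagged non-converged.
    """

    def sup(b: float, npsi: int, step: float) -> float:
        return _sup_ratio(b, npsi, step)[0]

    if strategy.growth_rate is not None:
        b_star = strategy.growth_rate
    else:
        res = minimize_scalar(
            lambda b: sup(b, n_psi, scan_step),
            bracket=(0.10, 0.115, 0.13),
            method="brent",
            options={"xtol": 1e-4},
        )
        b_star = float(res.x)
    r_coarse = sup(b_star, n_psi, scan_step)
    r_fine = sup(b_star, 2 * n_psi, scan_step / 2.0)
    converged = abs(r_fine - r_coarse) < tol
    _, which = _sup_ratio(b_star, 2 * n_psi, scan_step / 2.0)
    argmax = (
        "centerline tangent to a spiral turn" if which == 1 else "target on the spiral"
    )
    return RatioResult(
        r=float(r_fine),
        argmax=argmax if converged else "non-converged",
        converged=converged,
        params={"growth_rate": b_star},
        trace=(r_coarse, r_fine),
    )
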