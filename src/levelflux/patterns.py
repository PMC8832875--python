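"""Emergent-pattern analysis of trajectories.

Free-energy-consuming systems leave characteristic signatures: the
cumulative growth curve of a species is sigmoid, with

* an *onset* where growth is (nearly) exponential, ln N_j linear in t;
* a *body* where the diagram keeps its form and N_j tracks a power of the
  elemental population, ln N_j = j ln N_1 + const, with the free-energy
  factor alpha_j = exp(sum of path affinities / kT) approximately constant;
* a *flattening* where the approach to balance decays exponentially.

Near balance the abundance factors phi_j = N_j exp(G_j/kT) satisfy
ln phi_j = c_j ln phi_1 (+ quantum offsets), i.e. ln phi is linear in the
composition — the signature behind skewed, lognormal-like abundance
distributions.

Regime boundaries are located on the logarithm of the central-difference
growth rate d ln N_j/dt: both a pure exponential and an exponential
saturation make that series exactly linear in time, so phase edges appear
as predictive-residual breaks.  Fits inside each window are plain
least-squares in log coordinates, reported with their coefficient of
determination.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .diagram import SystemSpec
from .dynamics import Trajectory
from .statmech import chemical_potentials, factor_phi, system_entropy

__all__ = [
    "RegimeFit",
    "RegimeSegmentation",
    "FactorDistributionFit",
    "AlphaReport",
    "EntropyPotentialCurve",
    "InsufficientDataError",
    "UndefinedSlopeError",
    "PathUndefinedError",
    "segment_regimes",
    "power_law_slope",
    "fit_factor_distribution",
    "alpha_factor",
    "entropy_vs_potential",
]


class InsufficientDataError(ValueError):
    """Too few usable points for the requested fit."""


class UndefinedSlopeError(ValueError):
    """Degenerate regressor (no variation) in a slope fit."""


class PathUndefinedError(ValueError):
    """No transformation path from the elemental species to the target."""


@dataclass
class RegimeFit:
    """One fitted window: [t_start, t_end], slope/rate, goodness (R^2)."""

    t_start: float
    t_end: float
    i_start: int
    i_end: int  # inclusive
    rate: float
    goodness: float

    @property
    def window(self) -> tuple[float, float]:
        return (self.t_start, self.t_end)

    @property
    def n_points(self) -> int:
        return self.i_end - self.i_start + 1


@dataclass
class RegimeSegmentation:
    """Three-phase segmentation of a cumulative growth curve."""

    onset: RegimeFit | None
    body: RegimeFit | None
    flattening: RegimeFit | None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def d(f):
            if f is None:
                return None
            return {
                "window": [f.t_start, f.t_end],
                "rate": f.rate,
                "goodness": f.goodness,
                "n_points": f.n_points,
            }

        return {
            "onset": d(self.onset),
            "body": d(self.body),
            "flattening": d(self.flattening),
            "flags": list(self.flags),
        }


@dataclass
class FactorDistributionFit:
    """Regression of ln phi_j on composition c_j over populated species."""

    species_ids: list[str]
    compositions: np.ndarray
    log_phi: np.ndarray
    slope: float
    intercept: float
    goodness: float
    residual_spread: float
    lognormal: bool
    threshold: float

    def to_dict(self) -> dict:
        return {
            "species": list(self.species_ids),
            "slope": self.slope,
            "intercept": self.intercept,
            "goodness": self.goodness,
            "residual_spread": self.residual_spread,
            "lognormal": bool(self.lognormal),
            "threshold": self.threshold,
        }


@dataclass
class AlphaReport:
    """Free-energy factor alpha_j over a window, with its relative drift."""

    species: str
    window: tuple[float, float]
    times: np.ndarray
    alpha: np.ndarray
    mean: float
    drift: float
    path: list[int]

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "window": [float(self.window[0]), float(self.window[1])],
            "mean": self.mean,
            "drift": self.drift,
            "path_transformations": list(self.path),
        }


@dataclass
class EntropyPotentialCurve:
    """(mean potential, entropy) pairs with a log-log slope."""

    mu_scale: np.ndarray
    entropy: np.ndarray
    slope: float | None
    goodness: float | None
    n_excluded: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "goodness": self.goodness,
            "n_points": int(len(self.mu_scale)),
            "n_excluded": int(self.n_excluded),
            "flags": list(self.flags),
        }


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = a x + b; returns (a, b, R^2)."""
    if np.ptp(x) == 0:
        raise UndefinedSlopeError("regressor has no variation in the window")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if np.ptp(y) > 0 else 1.0
    return float(res.slope), float(res.intercept), r2


class _RunningFit:
    """Incremental simple linear regression over a sliding index window."""

    def __init__(self, x: np.ndarray, y: np.ndarray):
        self.x, self.y = x, y
        self.n = 0
        self.sx = self.sy = self.sxx = self.sxy = self.syy = 0.0

    def add(self, i: int) -> None:
        xi, yi = float(self.x[i]), float(self.y[i])
        self.n += 1
        self.sx += xi
        self.sy += yi
        self.sxx += xi * xi
        self.sxy += xi * yi
        self.syy += yi * yi

    def remove(self, i: int) -> None:
        xi, yi = float(self.x[i]), float(self.y[i])
        self.n -= 1
        self.sx -= xi
        self.sy -= yi
        self.sxx -= xi * xi
        self.sxy -= xi * yi
        self.syy -= yi * yi

    def line(self) -> tuple[float, float]:
        vx = self.sxx - self.sx * self.sx / self.n
        cxy = self.sxy - self.sx * self.sy / self.n
        if vx <= 0:
            raise UndefinedSlopeError("regressor has no variation in the window")
        a = cxy / vx
        b = (self.sy - a * self.sx) / self.n
        return a, b

    def r2(self) -> float:
        vx = self.sxx - self.sx * self.sx / self.n
        vy = self.syy - self.sy * self.sy / self.n
        cxy = self.sxy - self.sx * self.sy / self.n
        if vy <= 0:
            return 1.0
        if vx <= 0:
            return 0.0
        r2 = (cxy * cxy) / (vx * vy)
        return float(min(max(r2, 0.0), 1.0))


def _grow_linear_window(
    x: np.ndarray,
    y: np.ndarray,
    start: int,
    direction: int,
    min_points: int = 5,
    resid_frac: float = 0.05,
    resid_abs: float = 1e-9,
    ok: np.ndarray | None = None,
) -> tuple[int, int]:
    """Grow a window from ``start`` while y stays linear in x.

    The window extends point by point in ``direction`` (+1 forward, -1
    backward), never past a sample with ``ok`` False.  A candidate is
    rejected when its predictive residual against the current window's fit
    exceeds max(resid_frac * spread(y_window), resid_abs).  On exactly
    piecewise data this stops at the first point of the next phase.
    Returns inclusive (lo, hi).
    """
    n = len(x)
    lo = hi = start
    fit = _RunningFit(x, y)
    fit.add(start)
    ymin = ymax = float(y[start])
    for _ in range(min_points - 1):
        nxt = hi + 1 if direction > 0 else lo - 1
        if nxt < 0 or nxt >= n or (ok is not None and not ok[nxt]):
            break
        fit.add(nxt)
        ymin, ymax = min(ymin, float(y[nxt])), max(ymax, float(y[nxt]))
        if direction > 0:
            hi = nxt
        else:
            lo = nxt
    while True:
        nxt = hi + 1 if direction > 0 else lo - 1
        if nxt < 0 or nxt >= n or (ok is not None and not ok[nxt]):
            break
        try:
            a, b = fit.line()
        except UndefinedSlopeError:
            break
        tol = max(resid_frac * (ymax - ymin), resid_abs)
        if abs(float(y[nxt]) - (a * float(x[nxt]) + b)) > tol:
            break
        fit.add(nxt)
        ymin, ymax = min(ymin, float(y[nxt])), max(ymax, float(y[nxt]))
        if direction > 0:
            hi = nxt
        else:
            lo = nxt
    return lo, hi


def _trim_to_goodness(
    x: np.ndarray, y: np.ndarray, lo: int, hi: int, threshold: float, min_points: int
) -> tuple[int, int, float, float]:
    """Greedily drop end points of [lo, hi] until R^2 >= threshold.

    At each step the end (left or right) whose removal improves R^2 more is
    dropped; stops at ``min_points``.  Returns (lo, hi, slope, r2).
    """
    fit = _RunningFit(x, y)
    for i in range(lo, hi + 1):
        fit.add(i)
    while hi - lo + 1 > min_points and fit.r2() < threshold:
        fit.remove(lo)
        r2_drop_left = fit.r2()
        fit.add(lo)
        fit.remove(hi)
        r2_drop_right = fit.r2()
        if r2_drop_left > r2_drop_right:
            fit.add(hi)
            fit.remove(lo)
            lo += 1
        else:
            hi -= 1
    a, _b = fit.line()
    return lo, hi, a, fit.r2()


def segment_regimes(
    trajectory: Trajectory,
    spec: SystemSpec,
    j: int | str,
    *,
    elemental: int | str | None = None,
    goodness_threshold: float = 0.98,
    min_points: int = 5,
    resid_frac: float = 0.05,
    g_floor_rel: float = 1e-6,
) -> RegimeSegmentation:
    """Segment the growth curve of species j into onset / body / flattening.

    Boundary detection runs on ln g, g the central-difference dN_j/dt,
    which is exactly linear in t for both a pure exponential (onset) and an
    exponential saturation (flattening).  The onset fit reported is
    ln N_j ~ t (rate = empirical exponential rate); the body fit is
    ln N_j ~ ln N_1 (rate = power-law exponent); the flattening rate is the
    exponential approach rate, -d ln g/dt.

    Samples where the growth rate falls below ``g_floor_rel`` times its peak
    (the converged tail, or a pre-growth plateau) are outside the analysis
    stretch.  A series whose active stretch is substantially non-monotone
    (> 20% negative growth samples, e.g. under periodic driving) is flagged
    segmentation-undefined.
    """
    j = spec.species_index(j) if isinstance(j, str) else j
    if elemental is None:
        e_idx = _default_elemental(spec)
    else:
        e_idx = spec.species_index(elemental) if isinstance(elemental, str) else elemental

    t_all = np.asarray(trajectory.times, float)
    Nj_all = np.asarray(trajectory.states[:, j], float)
    N1_all = np.asarray(trajectory.states[:, e_idx], float)
    flags: list[str] = []
    if len(t_all) < 2 * min_points + 2:
        return RegimeSegmentation(None, None, None, flags=["insufficient-data"])

    # central-difference growth rate on interior points; index i of g
    # corresponds to trajectory index i + 1
    g = (Nj_all[2:] - Nj_all[:-2]) / (t_all[2:] - t_all[:-2])
    absmax = float(np.max(np.abs(g))) if g.size else 0.0
    if absmax == 0.0:
        return RegimeSegmentation(None, None, None, flags=["segmentation-undefined: constant series"])
    active = np.abs(g) > g_floor_rel * absmax
    if not active.any():
        return RegimeSegmentation(None, None, None, flags=["segmentation-undefined: constant series"])
    # contiguous active run containing the growth peak: pre-growth plateaus
    # and the converged tail (plus its noise spikes) fall outside it
    peak = int(np.argmax(np.abs(g)))
    a0 = peak
    while a0 > 0 and active[a0 - 1]:
        a0 -= 1
    a1 = peak
    while a1 < len(g) - 1 and active[a1 + 1]:
        a1 += 1
    g_in = g[a0 : a1 + 1]
    if np.mean(g_in <= 0) > 0.2:
        return RegimeSegmentation(
            None, None, None, flags=["segmentation-undefined: non-monotone series"]
        )
    ok = g_in > 0
    if not ok.all():
        flags.append("isolated non-positive growth samples clipped")
        g_in = np.maximum(g_in, 0.5 * g_floor_rel * absmax)
    lg = np.log(g_in)
    base = a0 + 1  # trajectory index of lg[0]
    tg = t_all[base : base + len(lg)]
    m = len(lg)
    if m < 2 * min_points:
        return RegimeSegmentation(None, None, None, flags=flags + ["insufficient-data"])

    # windows grow only through strictly positive growth samples; the suffix
    # starts at the last clean sample so clipped noise cannot anchor it
    first_ok = int(np.argmax(ok))
    last_ok = int(len(ok) - 1 - np.argmax(ok[::-1]))
    on_lo, on_hi = _grow_linear_window(tg, lg, first_ok, +1, min_points, resid_frac, ok=ok)
    fl_lo, fl_hi = _grow_linear_window(tg, lg, last_ok, -1, min_points, resid_frac, ok=ok)

    lnN = np.log(np.maximum(Nj_all, 1e-300))
    o0, o1 = base + on_lo, base + on_hi
    o0r, o1r, rate_on, r2_on = _trim_to_goodness(
        t_all, lnN, o0, o1, goodness_threshold, min_points
    )
    onset = RegimeFit(
        t_start=float(t_all[o0r]),
        t_end=float(t_all[o1r]),
        i_start=o0r,
        i_end=o1r,
        rate=rate_on,
        goodness=r2_on,
    )

    if fl_lo <= on_hi:  # windows collide: never left onset
        flags.append("partial: trajectory never leaves onset")
        return RegimeSegmentation(onset, None, None, flags=flags)

    a_fl, _b, r2_fl = _linfit(tg[fl_lo : fl_hi + 1], lg[fl_lo : fl_hi + 1])
    flattening = RegimeFit(
        t_start=float(t_all[base + fl_lo]),
        t_end=float(t_all[base + fl_hi]),
        i_start=base + fl_lo,
        i_end=base + fl_hi,
        rate=float(-a_fl),
        goodness=r2_fl,
    )

    b0, b1 = base + on_hi + 1, base + fl_lo - 1
    body = None
    if b1 - b0 + 1 >= min_points:
        x = np.log(np.maximum(N1_all[b0 : b1 + 1], 1e-300))
        y = lnN[b0 : b1 + 1]
        try:
            slope, _b2, r2_b = _linfit(x, y)
            body = RegimeFit(
                t_start=float(t_all[b0]),
                t_end=float(t_all[b1]),
                i_start=b0,
                i_end=b1,
                rate=slope,
                goodness=r2_b,
            )
        except UndefinedSlopeError:
            flags.append("body window has constant elemental population")
    else:
        flags.append("body window empty")
    return RegimeSegmentation(onset, body, flattening, flags=flags)


def power_law_slope(
    trajectory: Trajectory,
    spec: SystemSpec,
    j: int | str,
    window: tuple[float, float],
    elemental: int | str | None = None,
) -> float:
    """Least-squares slope of ln N_j against ln N_1 over a time window.

    In the body regime the diagram keeps its form and the slope approaches
    the composition c_j of the species.
    """
    j = spec.species_index(j) if isinstance(j, str) else j
    e_idx = (
        _default_elemental(spec)
        if elemental is None
        else (spec.species_index(elemental) if isinstance(elemental, str) else elemental)
    )
    t = np.asarray(trajectory.times, float)
    mask = (t >= window[0]) & (t <= window[1])
    Nj = trajectory.states[mask, j]
    N1 = trajectory.states[mask, e_idx]
    if mask.sum() < 2:
        raise InsufficientDataError("window contains fewer than 2 samples")
    if np.any(Nj <= 0) or np.any(N1 <= 0):
        raise InsufficientDataError("populations must stay positive in the window")
    slope, _b, _r2 = _linfit(np.log(N1), np.log(Nj))
    return slope


def fit_factor_distribution(
    state,
    spec: SystemSpec,
    threshold: float = 0.95,
) -> FactorDistributionFit:
    """Regress ln phi_j on composition c_j over species with N_j > 0.

    A positive lognormality verdict means the abundance factors follow the
    geometric cascade ln phi_j ~ linear in c_j at goodness >= threshold.
    """
    phi = factor_phi(state, spec)
    mask = phi > 0
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 populated species for the factor fit, have {int(mask.sum())}"
        )
    c = spec.compositions()[mask]
    lphi = np.log(phi[mask])
    slope, intercept, r2 = _linfit(c, lphi)
    resid = lphi - (slope * c + intercept)
    return FactorDistributionFit(
        species_ids=[s.id for s, m in zip(spec.species, mask) if m],
        compositions=c,
        log_phi=lphi,
        slope=slope,
        intercept=intercept,
        goodness=r2,
        residual_spread=float(np.std(resid)),
        lognormal=bool(r2 >= threshold),
        threshold=threshold,
    )


def _default_elemental(spec: SystemSpec) -> int:
    """The elemental species: smallest composition, earliest in the list."""
    comps = spec.compositions()
    return int(np.argmin(comps))


def _transformation_path(spec: SystemSpec, start: int, goal: int) -> list[int]:
    """BFS path (as transformation indices) from species start to goal."""
    if start == goal:
        return []
    index = {s.id: i for i, s in enumerate(spec.species)}
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(spec.n_species)}
    for r, tr in enumerate(spec.transformations):
        for sid in tr.substrates:
            for pid in tr.products:
                adj[index[sid]].append((index[pid], r))
    prev: dict[int, tuple[int, int]] = {}
    queue = deque([start])
    seen = {start}
    while queue:
        u = queue.popleft()
        for v, r in adj[u]:
            if v not in seen:
                seen.add(v)
                prev[v] = (u, r)
                if v == goal:
                    path = []
                    node = goal
                    while node != start:
                        node, rr = prev[node]
                        path.append(rr)
                    return path[::-1]
                queue.append(v)
    raise PathUndefinedError(
        f"no transformation path from '{spec.species[start].id}' to '{spec.species[goal].id}'"
    )


def alpha_factor(
    trajectory: Trajectory,
    spec: SystemSpec,
    j: int | str,
    window: tuple[float, float],
    elemental: int | str | None = None,
) -> AlphaReport:
    """Free-energy factor alpha_j over a window.

    alpha_j(t) = exp(sum of affinities / kT) over the transformation path
    from the elemental species to j; it equals 1 exactly at balance and is
    approximately constant through the body regime.
    """
    j = spec.species_index(j) if isinstance(j, str) else j
    e_idx = (
        _default_elemental(spec)
        if elemental is None
        else (spec.species_index(elemental) if isinstance(elemental, str) else elemental)
    )
    path = _transformation_path(spec, e_idx, j)
    t = np.asarray(trajectory.times, float)
    mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 1:
        raise InsufficientDataError("window contains no samples")
    A_path = trajectory.affinity_series[mask][:, path] if path else np.zeros((mask.sum(), 0))
    alpha = np.exp(A_path.sum(axis=1) / spec.kT)
    mean = float(np.mean(alpha))
    drift = float(np.max(np.abs(alpha - mean)) / mean) if mean != 0 else np.inf
    return AlphaReport(
        species=spec.species[j].id,
        window=(float(window[0]), float(window[1])),
        times=t[mask],
        alpha=alpha,
        mean=mean,
        drift=drift,
        path=path,
    )


def entropy_vs_potential(
    trajectory: Trajectory,
    spec: SystemSpec,
    quantiles: tuple[float, float] = (0.10, 0.90),
) -> EntropyPotentialCurve:
    """Entropy against population-weighted mean potential, with log-log slope.

    Non-positive entropy or potential values are excluded (counted).  The
    slope is fit over the central quantile range of the potential axis; with
    fewer than 3 usable points it is flagged low-confidence (2 points) or
    undefined (fewer).
    """
    flags: list[str] = []
    mu_scale = []
    S_vals = []
    n_excluded = 0
    for i in range(trajectory.n_samples):
        state = trajectory.state_at(i)
        N = state.populations
        if N.sum() <= 0:
            n_excluded += 1
            continue
        mu = chemical_potentials(state, spec, floor=1e-300)
        mbar = float(np.sum(N * mu) / N.sum())
        S = (
            float(trajectory.entropy_series[i])
            if np.isfinite(trajectory.entropy_series[i])
            else system_entropy(state, spec, mode="affinity")
        )
        if mbar <= 0 or S <= 0:
            n_excluded += 1
            continue
        mu_scale.append(mbar)
        S_vals.append(S)
    mu_arr = np.array(mu_scale)
    S_arr = np.array(S_vals)
    if len(mu_arr) < 2 or np.ptp(mu_arr) == 0:
        flags.append("slope undefined: fewer than 2 distinct potential values")
        return EntropyPotentialCurve(mu_arr, S_arr, None, None, n_excluded, flags)
    lo, hi = np.quantile(mu_arr, quantiles)
    sel = (mu_arr >= lo) & (mu_arr <= hi)
    if sel.sum() < 2 or np.ptp(mu_arr[sel]) == 0:
        sel = np.ones(len(mu_arr), bool)
    if sel.sum() == 2:
        flags.append("low-confidence: slope from 2 points")
    slope, _b, r2 = _linfit(np.log(mu_arr[sel]), np.log(S_arr[sel]))
    return EntropyPotentialCurve(mu_arr, S_arr, slope, r2, n_excluded, flags)
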