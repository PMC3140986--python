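"""Self-consistent fitness landscapes: fixed points, stability, cliffs, barriers.

Two coordinate systems are solved.  In phenotype coordinates (delta, T) the
fixed-point condition lam = lambda0 - c_delta*delta - c_T*T - c_C*T/lam**2 is
the cubic lam**3 - a*lam**2 + b = 0 with a = lambda0 - c_delta*delta - c_T*T
and b = c_C*T, solved in closed form.  In genotype-environment coordinates the
phenotypes themselves depend on the growth rate, and fixed points of the
growth map G are located by dense sign-change bracketing plus Brent's method.

Where the landscape folds (a saddle-node of the growth map) the stable and
unstable fitness branches coalesce: in phenotype space this is the expression
barrier, in genotype-environment space the fitness cliff.  Beyond either, no
steady exponentially growing population exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import (
    DomainError,
    Genotype,
    ModelParams,
    growth_map,
    hill_induction,
    production_rate,
    transport_per_pump,
    transport_rate,
)

__all__ = [
    "FixedPoint",
    "SolutionSet",
    "LandscapeGrid",
    "NoCliffError",
    "solve_phenotype_fitness",
    "solve_genotype_environment",
    "classify_stability",
    "expression_barrier",
    "find_cliff",
    "landscape_grid",
    "strain_trajectory",
    "stable_lambda_fast",
]

#: fraction of lambda0 below which the growth rate is treated as extinction
EPS_FRACTION = 1e-6
#: roots closer than this fraction of lambda0 are merged and labeled marginal
MERGE_FRACTION = 1e-6

STABLE = "stable"
UNSTABLE = "unstable"
MARGINAL = "marginal"


class NoCliffError(RuntimeError):
    """Raised when no fold exists in the requested bracket."""


@dataclass(frozen=True)
class FixedPoint:
    lam: float
    stability: str
    gprime: float


@dataclass(frozen=True)
class SolutionSet:
    """All steady-state fitness values at one point of the landscape.

    ``fixed_points`` is ordered by descending fitness.  ``regime`` is one of
    ``none`` (no steady growth attainable), ``tangent`` (stable and unstable
    branches coalesced, at the cliff/barrier), ``two-branch`` (bistable
    structure: stable upper branch, unstable lower branch) or ``single``.
    """

    fixed_points: tuple = ()
    regime: str = "none"

    @property
    def stable(self) -> FixedPoint | None:
        for fp in self.fixed_points:
            if fp.stability == STABLE:
                return fp
        return None

    @property
    def unstable(self) -> FixedPoint | None:
        for fp in self.fixed_points:
            if fp.stability == UNSTABLE:
                return fp
        return None

    @property
    def lambda_stable(self) -> float:
        fp = self.stable
        return fp.lam if fp is not None else np.nan

    @property
    def lambda_unstable(self) -> float:
        fp = self.unstable
        return fp.lam if fp is not None else np.nan


def _regime_from_points(points: Sequence[FixedPoint]) -> str:
    if not points:
        return "none"
    labels = [p.stability for p in points]
    if MARGINAL in labels and len(points) == 1:
        return "tangent"
    if len(points) == 1:
        return "single"
    return "two-branch"


# ---------------------------------------------------------------------------
# phenotype coordinates: closed-form cubic
# ---------------------------------------------------------------------------

def _cubic_two_positive_roots(a: float, b: float) -> tuple[float, float]:
    """The two positive roots of lam^3 - a*lam^2 + b = 0 for 0 < b < 4a^3/27.

    Depressed-cubic trigonometric solution followed by Newton polish, which
    keeps the branch ordering bit-stable near the tangency.
    """
    p = -a * a / 3.0
    q = b - 2.0 * a**3 / 27.0
    m = 2.0 * np.sqrt(-p / 3.0)
    arg = np.clip(3.0 * q / (p * m), -1.0, 1.0)
    phi = np.arccos(arg)
    roots = [m * np.cos((phi - 2.0 * np.pi * k) / 3.0) + a / 3.0 for k in range(3)]
    pos = sorted(r for r in roots if r > 0)
    # exactly two positive roots exist in this regime; keep the largest two
    lo, hi = pos[-2], pos[-1]

    def polish(x: float) -> float:
        for _ in range(3):
            f = x**3 - a * x * x + b
            fp = 3 * x * x - 2 * a * x
            if fp != 0:
                x -= f / fp
        return x

    return polish(lo), polish(hi)


def solve_phenotype_fitness(delta: float, T: float, params: ModelParams) -> SolutionSet:
    """Steady-state fitness values for fixed pathway phenotypes (delta, T).

    Solves lam = lambda0 - c_delta*delta - c_T*T - c_C*T/lam**2 in closed
    form.  With toxicity present (b = c_C*T > 0) there are either two
    positive fixed points (the larger stable, the smaller unstable), a double
    marginal root at the tangency b = 4a^3/27, or none — the phenotype pair
    lies beyond the expression barrier.
    """
    if delta < 0 or T < 0:
        raise DomainError("phenotypes must be non-negative")
    lam0 = params.lambda0
    a = lam0 - params.c_delta * delta - params.c_T * T
    b = params.c_C * T
    merge = MERGE_FRACTION * lam0

    if b <= 0.0:
        if a <= 0.0:
            return SolutionSet((), "none")
        # no toxicity feedback: G is constant in lam, single stable point
        fp = FixedPoint(a, STABLE, 0.0)
        return SolutionSet((fp,), "single")
    if a <= 0.0:
        return SolutionSet((), "none")

    b_crit = 4.0 * a**3 / 27.0
    # G(lam) = a - b/lam^2 so G'(lam) = 2 b / lam^3
    if abs(b - b_crit) <= merge * max(1.0, a * a):
        lam = 2.0 * a / 3.0
        return SolutionSet((FixedPoint(lam, MARGINAL, 2.0 * b / lam**3),), "tangent")
    if b > b_crit:
        return SolutionSet((), "none")
    lo, hi = _cubic_two_positive_roots(a, b)
    if hi - lo <= merge:
        lam = 0.5 * (lo + hi)
        return SolutionSet((FixedPoint(lam, MARGINAL, 2.0 * b / lam**3),), "tangent")
    pts = (
        FixedPoint(hi, STABLE, 2.0 * b / hi**3),
        FixedPoint(lo, UNSTABLE, 2.0 * b / lo**3),
    )
    return SolutionSet(pts, "two-branch")


# ---------------------------------------------------------------------------
# genotype-environment coordinates: bracketing on the growth map
# ---------------------------------------------------------------------------

def classify_stability(
    lam_star: float,
    g: Genotype,
    E: float,
    params: ModelParams,
    tol: float = 1e-4,
    fp_tol: float = 1e-6,
) -> tuple[str, float]:
    """Label a fixed point by the slope of the growth map.

    A fixed point is stable when G crosses the bisecting line from above
    (G'(lam*) < 1), unstable when from below, marginal within ``tol`` of the
    tangency.  G' is computed by central finite difference.  Raises if
    ``lam_star`` is not a fixed point to ``fp_tol``.
    """
    resid = growth_map(lam_star, g, E, params) - lam_star
    if abs(resid) > fp_tol * max(1.0, params.lambda0):
        raise ValueError(
            f"lam={lam_star!r} is not a fixed point (|G(lam)-lam| = {abs(resid):.3g})"
        )
    h = 1e-6 * max(lam_star, 1e-3)
    h = min(h, 0.5 * lam_star)
    gp = (growth_map(lam_star + h, g, E, params) - growth_map(lam_star - h, g, E, params)) / (2 * h)
    if gp < 1.0 - tol:
        return STABLE, gp
    if gp > 1.0 + tol:
        return UNSTABLE, gp
    return MARGINAL, gp


def solve_genotype_environment(
    g: Genotype,
    E: float,
    params: ModelParams,
    n_scan: int = 2001,
) -> SolutionSet:
    """Steady-state fitness values of genotype ``g`` at inducer ``E``.

    Locates all fixed points of the growth map on (eps, lambda0] by a dense
    sign-change scan of F(lam) = lam - G(lam) followed by Brent bracketing,
    merging near-coincident roots as marginal.  An empty solution set is a
    valid return: the genotype/environment lies beyond the fitness cliff.
    """
    if E < 0:
        raise DomainError("E must be >= 0")
    lam0 = params.lambda0
    eps = EPS_FRACTION * lam0
    grid = np.linspace(eps, lam0, n_scan)
    F = grid - growth_map(grid, g, E, params)

    roots: list[float] = []
    zero_tol = 1e-13 * max(1.0, lam0)
    for i in range(n_scan - 1):
        f0, f1 = F[i], F[i + 1]
        if abs(f0) <= zero_tol:
            roots.append(grid[i])
            continue
        if f0 * f1 < 0:
            r = brentq(
                lambda x: x - growth_map(x, g, E, params),
                grid[i],
                grid[i + 1],
                xtol=1e-14,
                rtol=8.9e-16,
            )
            roots.append(r)
    if abs(F[-1]) <= zero_tol:
        roots.append(grid[-1])

    # merge near-coincident roots (tangency)
    roots.sort()
    merged: list[list[float]] = []
    for r in roots:
        if merged and r - merged[-1][-1] <= MERGE_FRACTION * lam0:
            merged[-1].append(r)
        else:
            merged.append([r])

    points: list[FixedPoint] = []
    for group in merged:
        lam = float(np.mean(group))
        if len(group) > 1:
            h = 1e-6 * max(lam, 1e-3)
            gp = (growth_map(lam + h, g, E, params) - growth_map(lam - h, g, E, params)) / (2 * h)
            points.append(FixedPoint(lam, MARGINAL, gp))
        else:
            label, gp = classify_stability(lam, g, E, params)
            points.append(FixedPoint(lam, label, gp))

    points.sort(key=lambda p: -p.lam)
    n_stable = sum(p.stability == STABLE for p in points)
    if len(points) > 2 or n_stable > 1:
        warnings.warn(
            f"growth map has {len(points)} fixed points ({n_stable} stable); "
            "reporting all",
            RuntimeWarning,
            stacklevel=2,
        )
    return SolutionSet(tuple(points), _regime_from_points(points))


# ---------------------------------------------------------------------------
# fast algebraic path (theta == 0): polynomial fixed-point solve
# ---------------------------------------------------------------------------

def stable_lambda_fast(
    delta_max,
    induction,
    tau,
    params: ModelParams,
    c_delta: float | None = None,
    c_T: float | None = None,
    c_C: float | None = None,
) -> np.ndarray:
    """Stable-branch fitness for arrays of strain conditions (NaN = extinct).

    ``induction`` is chi0 + (1-chi0)*h(E) and ``tau`` the per-pump transport
    including the pump factor.  When theta == 0 the fixed-point condition is
    polynomial in lambda (quartic with eta off, cubic with eta on) and is
    solved algebraically with a Newton polish; otherwise this falls back to
    the bracketing solver.  Used in inference inner loops; agrees with
    :func:`solve_genotype_environment` (tested).
    """
    cd = params.c_delta if c_delta is None else c_delta
    ct = params.c_T if c_T is None else c_T
    cc = params.c_C if c_C is None else c_C
    lam0 = params.lambda0
    eps = EPS_FRACTION * lam0

    dm = np.atleast_1d(np.asarray(delta_max, dtype=float))
    ind = np.broadcast_to(np.asarray(induction, dtype=float), dm.shape).copy()
    tv = np.broadcast_to(np.asarray(tau, dtype=float), dm.shape).copy()
    out = np.full(dm.shape, np.nan)

    if params.eta_enabled and params.theta != 0.0:
        p = params.replace(c_delta=cd, c_T=ct, c_C=cc)
        for i in range(dm.size):
            # genotype reconstruction: induction factor folded into chi0=1
            g = Genotype(dm.flat[i] * ind.flat[i], 1.0, 1.0)
            tau_i = tv.flat[i]
            sol = _solve_fixed_tau(g, tau_i, p)
            out.flat[i] = sol
        return out

    for i in range(dm.size):
        k = dm.flat[i] * ind.flat[i]
        t = tv.flat[i]
        if params.eta_enabled:
            # delta = k * (lam/lambda1)^2 -> cubic
            kk = k / params.lambda1**2
            coeffs = [cd * kk, 1.0 + ct * kk * t, -lam0, cc * kk * t]
        else:
            # delta = k constant -> quartic
            q = k * t
            coeffs = [1.0, -(lam0 - cd * k), ct * q, 0.0, cc * q]
        coeffs = np.array(coeffs, dtype=float)
        nz = np.nonzero(coeffs)[0]
        if nz.size == 0 or nz[0] == len(coeffs) - 1:
            continue
        r = np.roots(coeffs[nz[0]:])
        real = r.real[(np.abs(r.imag) <= 1e-9) & (r.real > eps)]
        if real.size == 0:
            continue
        cand = np.sort(real)[::-1]
        lam = None
        for c in cand:
            gp = _gprime_algebraic(c, k, t, params, cd, ct, cc)
            if gp < 1.0:
                lam = c
                break
        if lam is None:
            continue
        # Newton polish on the un-multiplied fixed-point residual
        for _ in range(3):
            Fv = lam - _g_algebraic(lam, k, t, params, cd, ct, cc)
            Fp = 1.0 - _gprime_algebraic(lam, k, t, params, cd, ct, cc)
            if Fp != 0:
                lam -= Fv / Fp
        if eps < lam <= lam0 * (1 + 1e-9):
            out.flat[i] = lam
    return out


def _g_algebraic(lam, k, tau, params, cd, ct, cc):
    if params.eta_enabled:
        kk = k * (lam / params.lambda1) ** 2
    else:
        kk = k
    T = kk / lam * tau
    return params.lambda0 - cd * kk - ct * T - cc * T / lam**2


def _gprime_algebraic(lam, k, tau, params, cd, ct, cc):
    if params.eta_enabled:
        kk = k / params.lambda1**2
        return -2.0 * cd * kk * lam - ct * kk * tau + cc * kk * tau / lam**2
    q = k * tau
    return ct * q / lam**2 + 3.0 * cc * q / lam**4


def _solve_fixed_tau(g: Genotype, tau: float, params: ModelParams) -> float:
    """Bracketing stable-root solve with an explicit per-pump rate (slow path)."""
    lam0 = params.lambda0
    eps = EPS_FRACTION * lam0
    from .model import growth_expression_factor

    def G(lam):
        d = g.delta_max * growth_expression_factor(lam, params)
        T = d / lam * tau
        return lam0 - params.c_delta * d - params.c_T * T - params.c_C * T / lam**2

    grid = np.linspace(eps, lam0, 801)
    F = grid - G(grid)
    best = np.nan
    for i in range(len(grid) - 1):
        if F[i] == 0.0:
            best = grid[i]
        elif F[i] * F[i + 1] < 0:
            r = brentq(lambda x: x - G(x), grid[i], grid[i + 1], xtol=1e-14)
            h = 1e-6 * max(r, 1e-3)
            gp = (G(r + h) - G(r - h)) / (2 * h)
            if gp < 1.0:
                best = r if np.isnan(best) else max(best, r)
    if abs(F[-1]) <= 1e-13:
        best = grid[-1]
    return best


# ---------------------------------------------------------------------------
# folds: expression barrier and fitness cliff
# ---------------------------------------------------------------------------

def expression_barrier(delta_grid, params: ModelParams) -> pd.DataFrame:
    """Largest transport rate admitting steady growth, per production rate.

    At the barrier the cubic is tangent: c_C*T = 4*(lambda0 - c_delta*delta
    - c_T*T)**3 / 27, with fitness lambda = 2a/3 there.  Returns an empty
    frame when the fold is absent (c_C = 0) or the production cost alone
    already exceeds lambda0.
    """
    cols = ["delta", "T_barrier", "lambda_barrier"]
    if params.c_C <= 0:
        return pd.DataFrame(columns=cols)
    rows = []
    for d in np.atleast_1d(np.asarray(delta_grid, dtype=float)):
        a0 = params.lambda0 - params.c_delta * d
        if a0 <= 0:
            continue

        def psi(T):
            a = params.lambda0 - params.c_delta * d - params.c_T * T
            return params.c_C * T - 4.0 * a**3 / 27.0

        # psi(0) < 0; psi is increasing and positive once a <= 0
        T_hi = a0 / params.c_T if params.c_T > 0 else 1.0
        if params.c_T == 0:
            while psi(T_hi) < 0:
                T_hi *= 2.0
        Tb = brentq(psi, 0.0, T_hi, xtol=1e-14, rtol=8.9e-16)
        a = params.lambda0 - params.c_delta * d - params.c_T * Tb
        rows.append((d, Tb, 2.0 * a / 3.0))
    return pd.DataFrame(rows, columns=cols)


def _has_solution(g: Genotype, E: float, params: ModelParams, axis: str, value: float) -> bool:
    if axis == "E":
        sol = solve_genotype_environment(g, value, params)
    elif axis == "delta_max":
        g2 = Genotype(value, g.chi0, g.pump_factor)
        sol = solve_genotype_environment(g2, E, params)
    else:
        raise ValueError(f"unknown cliff axis {axis!r}")
    return sol.regime != "none"


def find_cliff(
    g: Genotype,
    params: ModelParams,
    axis: str,
    bracket: tuple[float, float],
    E: float = 0.0,
    rtol: float = 1e-8,
) -> float:
    """Locate the saddle-node fold along ``axis`` ("E" or "delta_max").

    Bisection on existence of a steady-growth solution: the bracket's low end
    must admit one and the high end must not, otherwise :class:`NoCliffError`
    is raised ("no cliff in range").  Returns the critical axis value to
    relative tolerance ``rtol``.
    """
    lo, hi = bracket
    if not _has_solution(g, E, params, axis, lo):
        raise NoCliffError("no solution at bracket low end")
    if _has_solution(g, E, params, axis, hi):
        raise NoCliffError("no cliff in range: solution exists at both bracket ends")
    while (hi - lo) > rtol * max(abs(hi), abs(lo), 1e-12):
        mid = 0.5 * (lo + hi)
        if _has_solution(g, E, params, axis, mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# grids and trajectories
# ---------------------------------------------------------------------------

@dataclass
class LandscapeGrid:
    """Solution sets over a 2-D landscape slice plus fold polylines."""

    mode: str
    axis1_name: str
    axis2_name: str
    axis1: np.ndarray
    axis2: np.ndarray
    solutions: list  # list of lists of SolutionSet, indexed [i1][i2]
    cliff: pd.DataFrame = field(default_factory=pd.DataFrame)
    barrier: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, x1 in enumerate(self.axis1):
            for j, x2 in enumerate(self.axis2):
                s = self.solutions[i][j]
                rows.append(
                    {
                        self.axis1_name: x1,
                        self.axis2_name: x2,
                        "lambda_stable": s.lambda_stable,
                        "lambda_unstable": s.lambda_unstable,
                        "regime": s.regime,
                    }
                )
        return pd.DataFrame(rows)


def landscape_grid(
    mode: str,
    axis1: Iterable[float],
    axis2: Iterable[float],
    params: ModelParams,
    genotype: Genotype | None = None,
    E: float | None = None,
) -> LandscapeGrid:
    """Tabulate SolutionSets over a 2-D slice of the landscape.

    ``mode`` selects the coordinate pair:

    - ``"phenotype"``: axis1 = delta, axis2 = T; barrier polyline attached.
    - ``"genotype-env"``: axis1 = delta_max, axis2 = E (mM); ``genotype``
      supplies chi0 and pump_factor; cliff polyline attached (per-axis1 fold
      along E, refined by bisection).
    - ``"genotype-chi0"``: axis1 = delta_max, axis2 = chi0 at fixed ``E``.
    """
    a1 = np.asarray(list(axis1), dtype=float)
    a2 = np.asarray(list(axis2), dtype=float)
    sols: list[list[SolutionSet]] = []
    if mode == "phenotype":
        names = ("delta", "T")
        for d in a1:
            sols.append([solve_phenotype_fitness(d, T, params) for T in a2])
        barrier = expression_barrier(a1, params)
        return LandscapeGrid(mode, *names, a1, a2, sols, barrier=barrier)
    if mode == "genotype-env":
        if genotype is None:
            raise ValueError("genotype-env mode requires a template genotype")
        names = ("delta_max", "E_mM")
        for dm in a1:
            g = Genotype(dm, genotype.chi0, genotype.pump_factor)
            sols.append([solve_genotype_environment(g, e, params) for e in a2])
        cliff_rows = []
        for i, dm in enumerate(a1):
            regimes = [s.regime for s in sols[i]]
            for j in range(len(a2) - 1):
                if regimes[j] != "none" and regimes[j + 1] == "none":
                    g = Genotype(dm, genotype.chi0, genotype.pump_factor)
                    try:
                        e_c = find_cliff(g, params, "E", (a2[j], a2[j + 1]))
                        cliff_rows.append((dm, e_c))
                    except NoCliffError:  # pragma: no cover - regimes guarantee flip
                        pass
                    break
        cliff = pd.DataFrame(cliff_rows, columns=["delta_max", "E_cliff"])
        return LandscapeGrid(mode, *names, a1, a2, sols, cliff=cliff)
    if mode == "genotype-chi0":
        if E is None:
            raise ValueError("genotype-chi0 mode requires E")
        names = ("delta_max", "chi0")
        for dm in a1:
            pf = genotype.pump_factor if genotype is not None else 1.0
            sols.append(
                [solve_genotype_environment(Genotype(dm, c, pf), E, params) for c in a2]
            )
        return LandscapeGrid(mode, *names, a1, a2, sols)
    raise ValueError(f"unknown landscape mode {mode!r}")


def strain_trajectory(
    g: Genotype, params: ModelParams, E_grid: Iterable[float]
) -> pd.DataFrame:
    """Stable-branch phenotypes and fitness of one strain along an inducer ramp.

    Returns a frame with columns E_mM, delta, T, lambda, extinct; entries past
    the strain's cliff carry NaN phenotypes and extinct=True.
    """
    Es = np.asarray(list(E_grid), dtype=float)
    if np.any(np.diff(Es) < 0):
        raise ValueError("E_grid must be sorted ascending")
    rows = []
    for e in Es:
        sol = solve_genotype_environment(g, e, params)
        fp = sol.stable
        if fp is None:
            rows.append((e, np.nan, np.nan, np.nan, True))
        else:
            d = production_rate(g, e, fp.lam, params)
            T = transport_rate(g, e, fp.lam, params)
            rows.append((e, d, T, fp.lam, False))
    return pd.DataFrame(rows, columns=["E_mM", "delta", "T", "lambda", "extinct"])
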