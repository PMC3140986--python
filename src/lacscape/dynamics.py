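"""Relaxation dynamics of the growth rate under the expression-cost feedback.

The population growth rate relaxes toward the growth map G: a discrete damped
iteration lam_{t+1} = lam_t + f*(G(lam_t) - lam_t) (f = dt as a fraction of
the relaxation time) and the matching continuous-time description
d(lam)/dt = (G(lam) - lam)/tau_relax.  Both share the landscape module's fixed
points and stability structure exactly: populations starting above the
unstable branch converge to the stable fitness, populations below it dilute
their proteins too slowly, decline further and go extinct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import Genotype, ModelParams, growth_map
from .landscape import EPS_FRACTION

__all__ = ["Trajectory", "iterate_discrete", "integrate_continuous", "basin_classify"]

CONVERGED = "converged_stable"
EXTINCT = "extinct"
MAX_STEPS = "max_steps"


@dataclass
class Trajectory:
    times: np.ndarray  # in units of the relaxation time (discrete) or hours (ODE)
    lam: np.ndarray
    terminal: str

    @property
    def final(self) -> float:
        return float(self.lam[-1])


def iterate_discrete(
    lam_init: float,
    g: Genotype,
    E: float,
    params: ModelParams,
    dt_fraction: float = 0.1,
    max_steps: int = 200_000,
    conv_tol: float = 1e-10,
) -> Trajectory:
    """Damped fixed-point iteration of the growth map.

    dt_fraction is the time step in units of the relaxation time and must lie
    in (0, 1]; at 1 the update is the bare map lam -> G(lam).  Terminates as
    ``extinct`` once lam falls to the extinction threshold (costs diverge as
    lam -> 0 and no steady growth exists below it), as ``converged_stable``
    when the update residual |G(lam)-lam| drops below ``conv_tol``.
    """
    if not 0.0 < dt_fraction <= 1.0:
        raise ValueError("dt_fraction must lie in (0, 1]")
    if lam_init <= 0:
        raise ValueError("lam_init must be positive")
    eps = EPS_FRACTION * params.lambda0
    lam = float(lam_init)
    lams = [lam]
    terminal = MAX_STEPS
    for _ in range(max_steps):
        if lam <= eps:
            terminal = EXTINCT
            break
        resid = growth_map(lam, g, E, params) - lam
        lam_next = lam + dt_fraction * resid
        lams.append(max(lam_next, 0.0))
        if lam_next <= eps:
            lam = lam_next
            terminal = EXTINCT
            break
        if abs(resid) < conv_tol:
            lam = lam_next
            terminal = CONVERGED
            break
        lam = lam_next
    lams_arr = np.asarray(lams)
    times = np.arange(len(lams_arr)) * dt_fraction
    return Trajectory(times, lams_arr, terminal)


def integrate_continuous(
    lam_init: float,
    g: Genotype,
    E: float,
    params: ModelParams,
    t_end: float = 500.0,
    tau_relax: float = 1.0,
    conv_tol: float = 1e-8,
) -> Trajectory:
    """Continuous relaxation d(lam)/dt = (G(lam) - lam)/tau_relax.

    tau_relax defaults to one reference generation time.  Integration is
    adaptive (RK45, atol 1e-12); an extinction event terminates the solution
    when lam reaches the extinction threshold.
    """
    if lam_init <= 0 or tau_relax <= 0:
        raise ValueError("lam_init and tau_relax must be positive")
    eps = EPS_FRACTION * params.lambda0

    def rhs(t, y):
        lam = max(y[0], eps / 2.0)
        return [(growth_map(lam, g, E, params) - lam) / tau_relax]

    def hit_floor(t, y):
        return y[0] - eps

    hit_floor.terminal = True
    hit_floor.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [float(lam_init)],
        events=hit_floor,
        rtol=1e-10,
        atol=1e-12,
        max_step=t_end / 50.0,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    lam = sol.y[0]
    times = sol.t
    if sol.status == 1:  # extinction event
        return Trajectory(times, lam, EXTINCT)
    resid = growth_map(lam[-1], g, E, params) - lam[-1]
    terminal = CONVERGED if abs(resid) < conv_tol else MAX_STEPS
    return Trajectory(times, lam, terminal)


def basin_classify(
    g: Genotype,
    E: float,
    params: ModelParams,
    lam_grid,
    dt_fraction: float = 0.1,
    max_steps: int = 200_000,
) -> dict[float, str]:
    """Terminal state of the discrete dynamics for each initial growth rate.

    In the two-branch regime the basin boundary coincides with the unstable
    fixed point: starts above it converge to the stable branch, starts below
    go extinct.
    """
    out = {}
    for lam0 in np.atleast_1d(np.asarray(lam_grid, dtype=float)):
        traj = iterate_discrete(lam0, g, E, params, dt_fraction, max_steps)
        out[float(lam0)] = traj.terminal
    return out
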