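"""Core types and elementary phenotype/cost functions of the lac-pathway model.

The model maps a regulatory genotype (maximal production rate ``delta_max``,
repression ratio ``chi0``, permease activity ``pump_factor``) and an inducer
environment (external IPTG concentration ``E``, in mM) to the two pathway
phenotypes — the lac protein production rate ``delta`` and the total inducer
transport rate ``T`` — and from those to a Malthusian fitness via a combined
expression cost

    cost(delta, T, lambda) = c_delta * delta + c_T * T + c_C * T / lambda**2

measured in units of the reference (lac-deleted) strain's growth rate.  The
three terms are, respectively, the cost of protein production, a direct cost
of transport activity, and a toxicity cost proportional to the steady-state
concentration of co-transported protons (transport flux divided by cell
volume and dilution rate, with volume proportional to growth rate).

Because the production and transport rates themselves depend on the growth
rate (protein dilution, growth-dependent gene expression), fitness is defined
self-consistently as a fixed point of the growth map

    G(lambda) = lambda0 - cost(delta(lambda), T(lambda), lambda),

which downstream modules solve, classify and invert.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict

import numpy as np

__all__ = [
    "DomainError",
    "ModelParams",
    "Genotype",
    "Environment",
    "PathwayPhenotypes",
    "hill_induction",
    "transport_per_pump",
    "growth_expression_factor",
    "production_rate",
    "transport_rate",
    "fitness_cost",
    "growth_map",
]


class DomainError(ValueError):
    """An argument lies outside the model's physical domain."""


@dataclass(frozen=True)
class ModelParams:
    """Global constants of the fitness and phenotype maps.

    Parameters
    ----------
    lambda0 : float
        Fitness of the reference strain (zero lac expression), in reference
        units; 1 by the normalization used throughout.
    c_delta, c_T, c_C : float
        Cost amplitudes per unit production rate, per unit transport rate,
        and per unit steady-state toxic-molecule concentration.
    K_h : float
        Inducer half-saturation of the induction Hill function, mM.
    n_h : float
        Hill coefficient of induction (>= 1).
    K_T : float
        Inducer half-saturation of per-pump transport, mM.
    E_norm : float
        Inducer concentration at which per-pump transport is normalized
        to 1, mM.
    lambda1 : float
        Fitness corresponding to 1 doubling/hour, in reference units; the
        growth-expression factor is normalized to 1 at this growth rate.
    theta : float
        Slope of the linear decrease of constitutive protein concentration
        with growth rate (0 disables that part of the coupling).
    eta_enabled : bool
        If False the growth-expression factor is identically 1.

    Notes
    -----
    The induction and transport constants are package defaults chosen to be
    biologically plausible for IPTG induction of the lac operon; they are
    configuration parameters, not measured values.  The cell-volume
    proportionality constant and the LacY:LacZ stoichiometry are absorbed
    into ``c_T`` and ``c_C``.
    """

    lambda0: float = 1.0
    c_delta: float = 0.06
    c_T: float = 0.01
    c_C: float = 0.04
    K_h: float = 0.1
    n_h: float = 2.0
    K_T: float = 0.3
    E_norm: float = 1.0
    lambda1: float = 1.0
    theta: float = 0.0
    eta_enabled: bool = True

    def __post_init__(self) -> None:
        if self.lambda0 <= 0:
            raise DomainError("lambda0 must be positive")
        for name in ("c_delta", "c_T", "c_C"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        for name in ("K_h", "K_T", "E_norm", "lambda1"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.n_h < 1:
            raise DomainError("n_h must be >= 1")

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        d = asdict(self)
        d.update(kwargs)
        return ModelParams.from_mapping(d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ModelParams":
        """Build from a flat mapping; unknown keys are rejected."""
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise DomainError(
                f"unknown ModelParams keys: {sorted(unknown)}; known keys: {sorted(known)}"
            )
        return cls(**mapping)


@dataclass(frozen=True)
class Genotype:
    """Per-strain summary of the lac regulatory region.

    ``delta_max`` is the maximal protein production rate at a growth rate of
    1 doubling/hour (normalized units); ``chi0`` the ratio of repressed to
    unrepressed production rates (inverse of the repression level);
    ``pump_factor`` multiplies per-pump transport (1 = intact lacY,
    0 = lacY deletion).
    """

    delta_max: float
    chi0: float
    pump_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_max < 0:
            raise DomainError("delta_max must be >= 0")
        if not 0.0 <= self.chi0 <= 1.0:
            raise DomainError("chi0 must lie in [0, 1]")
        if not 0.0 <= self.pump_factor <= 1.0:
            raise DomainError("pump_factor must lie in [0, 1]")


@dataclass(frozen=True)
class Environment:
    """Inducer environment: external IPTG concentration in mM."""

    E: float

    def __post_init__(self) -> None:
        if self.E < 0:
            raise DomainError("inducer concentration E must be >= 0")


@dataclass(frozen=True)
class PathwayPhenotypes:
    """The two pathway phenotypes: production rate delta and transport rate T."""

    delta: float
    T: float

    def __post_init__(self) -> None:
        if self.delta < 0 or self.T < 0:
            raise DomainError("phenotypes must be non-negative")


def _check_E(E):
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise DomainError("inducer concentration E must be >= 0")
    return E


def _check_lam(lam):
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise DomainError("growth rate lambda must be positive")
    return lam


def _maybe_scalar(x, *inputs):
    if all(np.ndim(i) == 0 for i in inputs):
        return float(x)
    return x


def hill_induction(E, params: ModelParams):
    """Fraction of unrepressed expression at inducer concentration ``E``.

    h(E) = E^n / (E^n + K_h^n): 0 with no inducer, 1/2 at the
    half-saturation constant, saturating at 1.
    """
    Ea = _check_E(E)
    with np.errstate(divide="ignore"):
        # compute in log space for numerical robustness at extreme E
        x = np.where(Ea > 0, (np.maximum(Ea, 1e-300) / params.K_h) ** params.n_h, 0.0)
    h = x / (1.0 + x)
    return _maybe_scalar(h, E)


def transport_per_pump(E, pump_factor, params: ModelParams):
    """Normalized transport rate per permease molecule.

    Michaelis saturation in the external inducer, scaled so that an intact
    pump transports at rate 1 at ``E_norm``:
    tau(E) = pump_factor * [E/(E+K_T)] / [E_norm/(E_norm+K_T)].
    """
    Ea = _check_E(E)
    norm = params.E_norm / (params.E_norm + params.K_T)
    tau = pump_factor * (Ea / (Ea + params.K_T)) / norm
    return _maybe_scalar(tau, E)


def growth_expression_factor(lam, params: ModelParams):
    """Growth-rate dependence eta of the protein production rate.

    Combines the dilution of production into concentration (factor lambda),
    a cell volume proportional to growth rate (another factor lambda) and a
    linearly decreasing constitutive concentration with slope ``theta``:

        eta(lam) = (lam/lambda1)**2 * max(0, 1 - theta*(lam/lambda1 - 1)),

    normalized so eta(lambda1) = 1.  Identically 1 when ``eta_enabled`` is
    False.
    """
    lama = _check_lam(lam)
    if not params.eta_enabled:
        return _maybe_scalar(np.ones_like(lama), lam)
    x = lama / params.lambda1
    eta = x * x * np.maximum(0.0, 1.0 - params.theta * (x - 1.0))
    return _maybe_scalar(eta, lam)


def production_rate(g: Genotype, E, lam, params: ModelParams):
    """Protein production rate delta of genotype ``g`` at inducer ``E`` and
    growth rate ``lam``:

        delta = delta_max * eta(lam) * (chi0 + (1 - chi0) * h(E)).

    At E=0 this is the repressed rate delta_max*eta*chi0; fully induced it
    saturates at delta_max*eta.  A repressor deletion (chi0 = 1) makes delta
    independent of the inducer.
    """
    h = hill_induction(E, params)
    eta = growth_expression_factor(lam, params)
    d = g.delta_max * eta * (g.chi0 + (1.0 - g.chi0) * h)
    return _maybe_scalar(d, E, lam)


def transport_rate(g: Genotype, E, lam, params: ModelParams):
    """Total transport rate T = (delta/lam) * tau(E).

    delta/lam is the permease copy number (production balanced by dilution
    through cell division); tau the per-pump rate.  Zero without inducer or
    without a functional pump.
    """
    lama = _check_lam(lam)
    d = production_rate(g, E, lama, params)
    tau = transport_per_pump(E, g.pump_factor, params)
    T = d / lama * tau
    return _maybe_scalar(T, E, lam)


def fitness_cost(ph: PathwayPhenotypes, lam, params: ModelParams):
    """Combined fitness cost of expressing and running the pathway.

    cost = c_delta*delta + c_T*T + c_C*T/lam**2.  The last term is the
    steady-state concentration of the toxic co-transported species: influx T
    divided by dilution (lam) and by cell volume (proportional to lam).
    """
    lama = _check_lam(lam)
    c = params.c_delta * ph.delta + params.c_T * ph.T + params.c_C * ph.T / lama**2
    return _maybe_scalar(c, lam)


def growth_map(lam, g: Genotype, E, params: ModelParams):
    """The growth-feedback map G(lam) = lambda0 - cost(delta(lam), T(lam), lam).

    Fixed points of G are the model's steady-state fitness values; G <= lambda0
    always since costs are non-negative.
    """
    lama = _check_lam(lam)
    d = production_rate(g, E, lama, params)
    tau = transport_per_pump(E, g.pump_factor, params)
    T = d / lama * tau
    cost = params.c_delta * d + params.c_T * T + params.c_C * T / lama**2
    return _maybe_scalar(params.lambda0 - cost, lam)
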