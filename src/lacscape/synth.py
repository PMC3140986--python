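"""Synthetic strain panels, measurements and competition assays.

Emulates the study design the model was built for: a panel of lac operator
mutants spanning a range of maximal expression (delta_max) and repressibility
(chi0), a repressor-deletion constitutive strain, a permease-deletion control
and the lac-deleted reference, each measured at 0 and 1 mM IPTG (optionally a
dose-response grid) with 12 fitness replicates and 3 concentration replicates
per condition.  True values come from the model's stable fixed point; noise
is Gaussian.  A CFU-level competition-assay simulator provides the Malthusian
fitness estimator lambda = ln(Xf/Xi)/ln(Yf/Yi) used throughout.

Concentration convention: the reported LacZ concentration is delta/lambda**2
(production over dilution and a volume proportional to growth rate), i.e. in
units where a fully induced strain with delta_max = 1 growing at 1
doubling/hour would sit at 1.  This is the fully-induced-wild-type
normalization up to constants absorbed in the cost coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import warnings

import numpy as np
import pandas as pd

from .model import Genotype, ModelParams, production_rate
from .landscape import solve_genotype_environment

__all__ = [
    "StrainSpec",
    "PanelConfig",
    "AssayResult",
    "generate_strain_panel",
    "true_state",
    "simulate_measurements",
    "simulate_competition",
    "fitness_from_counts",
]


@dataclass(frozen=True)
class StrainSpec:
    strain_id: str
    genotype: Genotype
    role: str  # operator_mutant | constitutive | pumpless | reference

    def __post_init__(self) -> None:
        if self.role == "reference" and self.genotype.delta_max != 0:
            raise ValueError("reference strain must have delta_max = 0")
        if self.role == "constitutive" and self.genotype.chi0 != 1.0:
            raise ValueError("constitutive strain must have chi0 = 1")
        if self.role == "pumpless" and self.genotype.pump_factor != 0.0:
            raise ValueError("pumpless strain must have pump_factor = 0")


@dataclass
class PanelConfig:
    """Design of a synthetic strain panel and its measurement campaign.

    Defaults mirror the study conditions: 12 operator mutants (the first is
    the wild type), a constitutive repressor deletion, a constitutive
    permease deletion and the reference, assayed at 0 and 1 mM IPTG with 12
    fitness and 3 concentration replicates.  Noise magnitudes are stylized to
    produce standard errors of the size seen in competition/Miller assays
    (fitness SE ~0.007 on 12 replicates, concentration SE a few percent).
    """

    n_operator: int = 12
    delta_max_range: tuple[float, float] = (0.2, 3.0)
    chi0_range: tuple[float, float] = (1e-3, 0.5)
    chi0_wt: float = 1e-3
    delta_max_wt: float = 1.0
    wt_chi0_fraction: float = 0.5  # fraction of mutants sharing the wild-type chi0
    E_conditions: tuple[float, ...] = (0.0, 1.0)
    dose_response_E: tuple[float, ...] = ()
    dose_response_strains: tuple[str, ...] = ()
    n_fitness_reps: int = 12
    n_conc_reps: int = 3
    fitness_sd: float = 0.025
    conc_sd_abs: float = 0.002
    conc_sd_rel: float = 0.05
    keep_extinct: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_operator < 1:
            raise ValueError("need at least one operator mutant")
        if self.n_fitness_reps < 1 or self.n_conc_reps < 1:
            raise ValueError("replicate counts must be >= 1")
        if min(self.fitness_sd, self.conc_sd_abs, self.conc_sd_rel) < 0:
            raise ValueError("noise SDs must be >= 0")
        for lo, hi in (self.delta_max_range, self.chi0_range):
            if not (0 < lo <= hi):
                raise ValueError("ranges must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class AssayResult:
    """Competition-assay counts (integers when Poisson-sampled; exact
    expected counts, possibly fractional, in deterministic mode) and the
    derived fitness."""

    x_init: float
    x_final: float
    y_init: float
    y_final: float
    fitness: float


def generate_strain_panel(config: PanelConfig, rng: np.random.Generator | None = None):
    """Deterministic (seeded) strain panel: operator mutants plus controls.

    Operator mutants draw delta_max log-uniformly over the configured range;
    a configurable fraction keeps the wild-type chi0 (mutations that change
    expression but not repressibility), the rest draw chi0 log-uniformly.
    The first operator mutant is pinned to the wild type itself.
    """
    rng = rng or np.random.default_rng(config.seed)
    strains: list[StrainSpec] = []
    lo, hi = config.delta_max_range
    clo, chi_hi = config.chi0_range
    for i in range(config.n_operator):
        if i == 0:
            g = Genotype(config.delta_max_wt, config.chi0_wt, 1.0)
            strains.append(StrainSpec("WT", g, "operator_mutant"))
            continue
        dm = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if rng.uniform() < config.wt_chi0_fraction:
            c0 = config.chi0_wt
        else:
            c0 = float(np.exp(rng.uniform(np.log(clo), np.log(chi_hi))))
        strains.append(StrainSpec(f"O{i:02d}", Genotype(dm, c0, 1.0), "operator_mutant"))
    strains.append(
        StrainSpec("dlacI", Genotype(config.delta_max_wt, 1.0, 1.0), "constitutive")
    )
    strains.append(
        StrainSpec("dlacY", Genotype(config.delta_max_wt, 1.0, 0.0), "pumpless")
    )
    strains.append(StrainSpec("ref", Genotype(0.0, 0.0, 1.0), "reference"))
    return strains


def true_state(g: Genotype, E: float, params: ModelParams):
    """Stable-branch truth (lambda, delta, concentration) or None if extinct."""
    sol = solve_genotype_environment(g, E, params)
    fp = sol.stable
    if fp is None:
        return None
    d = production_rate(g, E, fp.lam, params)
    return fp.lam, d, d / fp.lam**2


def simulate_measurements(
    panel, params: ModelParams, config: PanelConfig, rng: np.random.Generator | None = None
):
    """Noisy replicate measurements for every strain x condition.

    Returns ``(dataset, manifest)``: the Dataset in the canonical delimited
    layout and a manifest dict recording true genotypes, true phenotypes per
    condition and all configuration.  Conditions where a strain has no stable
    fixed point are excluded with a warning (``keep_extinct`` retains them as
    fitness-NaN censored rows).
    """
    from .io import Dataset  # local import to avoid a cycle

    rng = rng or np.random.default_rng(config.seed)
    records = []
    manifest_strains = []
    for spec in panel:
        conditions = list(config.E_conditions)
        if spec.strain_id in config.dose_response_strains:
            conditions += [e for e in config.dose_response_E if e not in conditions]
        truths = {}
        for E in sorted(conditions):
            st = true_state(spec.genotype, E, params)
            if st is None:
                warnings.warn(
                    f"strain {spec.strain_id} extinct at E={E} mM; "
                    + ("kept as censored rows" if config.keep_extinct else "excluded"),
                    RuntimeWarning,
                    stacklevel=2,
                )
                truths[E] = {"lambda": None, "delta": None, "concentration": None}
                if not config.keep_extinct:
                    continue
                lam_true, c_true = np.nan, np.nan
            else:
                lam_true, _, c_true = st
                truths[E] = {
                    "lambda": lam_true,
                    "delta": st[1],
                    "concentration": c_true,
                }
            n = max(config.n_fitness_reps, config.n_conc_reps)
            fit_noise = rng.normal(0.0, config.fitness_sd, size=config.n_fitness_reps)
            conc_sd = config.conc_sd_abs + config.conc_sd_rel * (
                c_true if np.isfinite(c_true) else 0.0
            )
            conc_noise = rng.normal(0.0, conc_sd, size=config.n_conc_reps)
            for r in range(1, n + 1):
                fit = lam_true + fit_noise[r - 1] if r <= config.n_fitness_reps else np.nan
                conc = c_true + conc_noise[r - 1] if r <= config.n_conc_reps else np.nan
                records.append(
                    {
                        "strain_id": spec.strain_id,
                        "E_mM": E,
                        "replicate_id": r,
                        "fitness": fit,
                        "concentration": conc,
                    }
                )
        manifest_strains.append(
            {
                "strain_id": spec.strain_id,
                "role": spec.role,
                "delta_max": spec.genotype.delta_max,
                "chi0": spec.genotype.chi0,
                "pump_factor": spec.genotype.pump_factor,
                "truths": {str(k): v for k, v in truths.items()},
            }
        )
    dataset = Dataset(pd.DataFrame.from_records(records))
    manifest = {
        "params": params.to_dict(),
        "panel_config": asdict(config),
        "strains": manifest_strains,
    }
    return dataset, manifest


def fitness_from_counts(xi: float, xf: float, yi: float, yf: float) -> float:
    """Malthusian fitness from competition CFU counts.

    lambda = ln(Xf/Xi) / ln(Yf/Yi): mutant doublings per reference doubling.
    The associated fitness cost is lambda0 - lambda.
    """
    for name, v in (("xi", xi), ("xf", xf), ("yi", yi), ("yf", yf)):
        if v <= 0:
            raise ValueError(f"count {name} must be positive")
    denom = np.log(yf / yi)
    if denom == 0:
        raise ValueError("reference strain shows no net growth; fitness undefined")
    return float(np.log(xf / xi) / denom)


def simulate_competition(
    lam_mut: float,
    lam_ref: float = 1.0,
    N0: int = 50_000,
    doublings_ref: float = 13.0,
    stochastic: bool = True,
    rng: np.random.Generator | None = None,
) -> AssayResult:
    """Head-to-head competition assay against the reference strain.

    Both strains start at ``N0`` CFU; over the assay the reference doubles
    ``doublings_ref`` times (~5e4 -> ~4e8, saturation of a 24 h culture) and
    the mutant 2**(D*lam/lam_ref)-fold.  In stochastic mode initial and final
    counts are Poisson-sampled around their expectations, modeling plating
    noise; the derived fitness then fluctuates with SD ~ 1/sqrt(N0).
    """
    if N0 < 1:
        raise ValueError("N0 must be >= 1")
    if doublings_ref <= 0:
        raise ValueError("doublings_ref must be positive")
    mu_xf = N0 * 2.0 ** (doublings_ref * lam_mut / lam_ref)
    mu_yf = N0 * 2.0**doublings_ref
    if stochastic:
        rng = rng or np.random.default_rng()
        xi = int(rng.poisson(N0))
        yi = int(rng.poisson(N0))
        xf = int(rng.poisson(mu_xf))
        yf = int(rng.poisson(mu_yf))
    else:
        xi = yi = float(N0)
        xf, yf = mu_xf, mu_yf
    if yf <= 0 or yi <= 0:
        raise RuntimeError("assay failure: reference strain count vanished")
    if xf <= 0 or xi <= 0:
        raise RuntimeError("assay failure: mutant count vanished")
    lam = fitness_from_counts(xi, xf, yi, yf)
    return AssayResult(xi, xf, yi, yf, lam)
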