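"""Phenotype estimation, error propagation and maximum-likelihood cost fitting.

Per-strain genotype summaries are estimated from concentration/fitness pairs:
with the steady-state relation C = delta/(lam*V) and V proportional to lam,
the quantity d = C*lam**2/eta(lam) equals delta_max*(chi0 + (1-chi0)*h(E)).
Measured at E = 0 (full repression, h = 0) and at a saturating inducer
concentration this inverts to

    delta_max = d0 + (d1 - d0)/h(E_sat),        chi0 = d0/delta_max,

which reduces to the usual approximation delta_max = d1 when h(E_sat) -> 1
("repressor cannot bind").  Both estimators are independent of the cost model.

The cost coefficients (c_delta, c_T, c_C) are then fit by maximizing a
Gaussian log-likelihood of the observed mean fitness values given the model's
stable-branch predictions, with per-point variance combining the fitness
standard error and (optionally) the delta-method variance contributed by the
phenotype estimates.  A coarse grid search is refined by Nelder-Mead, and a
score grid over (c_T, c_C) at the ML c_delta supports model comparison of
nested constrained fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .model import (
    DomainError,
    Genotype,
    ModelParams,
    growth_expression_factor,
    hill_induction,
    transport_per_pump,
)
from .landscape import solve_genotype_environment, stable_lambda_fast

__all__ = [
    "StrainMeasurement",
    "StrainPhenotypeEstimate",
    "PredictionRow",
    "FitConfig",
    "FitResult",
    "pool_variances",
    "estimate_strain_phenotypes",
    "propagate_errors",
    "repression_level",
    "predict_fitness",
    "build_prediction_table",
    "log_likelihood",
    "fit_cost_coefficients",
    "compare_models",
]


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return np.nan, np.nan
    if v.size == 1:
        return float(v[0]), 0.0
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


@dataclass
class StrainMeasurement:
    """Replicate observations of one strain in one inducer condition.

    Standard errors default to sample SD / sqrt(n) over the replicates; the
    ``*_se_value`` fields let callers substitute pooled/moderated estimates
    (see :func:`pool_variances`), which are far more stable at small
    replicate counts.
    """

    strain_id: str
    E: float
    fitness: np.ndarray
    concentration: np.ndarray
    fitness_se_value: float | None = None
    conc_se_value: float | None = None

    @property
    def fitness_mean(self) -> float:
        return _mean_se(self.fitness)[0]

    @property
    def fitness_se(self) -> float:
        if self.fitness_se_value is not None:
            return self.fitness_se_value
        return _mean_se(self.fitness)[1]

    @property
    def conc_mean(self) -> float:
        return _mean_se(self.concentration)[0]

    @property
    def conc_se(self) -> float:
        if self.conc_se_value is not None:
            return self.conc_se_value
        return _mean_se(self.concentration)[1]


def pool_variances(meas: dict) -> dict:
    """Replace per-condition standard errors by pooled/moderated ones.

    Per-condition SEs estimated from 3-12 replicates are themselves noisy
    (chi-square with few degrees of freedom), which mis-calibrates any
    downstream Gaussian score.  Fitness noise is treated as homoscedastic
    and pooled across all strain x condition groups; concentration noise is
    modeled as SD = a + b*|mean| with (a, b) fit across groups, matching the
    absolute-floor-plus-relative error structure of enzymatic assays.
    """
    groups = list(meas.values())

    num = den = 0.0
    for m in groups:
        v = m.fitness[~np.isnan(m.fitness)]
        if v.size >= 2:
            num += (v.size - 1) * v.var(ddof=1)
            den += v.size - 1
    pooled_fit_sd = np.sqrt(num / den) if den > 0 else 0.0

    means, sds = [], []
    for m in groups:
        v = m.concentration[~np.isnan(m.concentration)]
        if v.size >= 2:
            means.append(abs(v.mean()))
            sds.append(v.std(ddof=1))
    a = b = 0.0
    if sds:
        A = np.column_stack([np.ones(len(means)), np.asarray(means)])
        coef, *_ = np.linalg.lstsq(A, np.asarray(sds), rcond=None)
        a, b = coef
        if b < 0:
            b, a = 0.0, float(np.mean(sds))
        if a < 0:
            a = 0.0
            m_arr = np.asarray(means)
            b = float(m_arr @ np.asarray(sds) / (m_arr @ m_arr)) if m_arr.any() else 0.0

    out = {}
    for key, m in meas.items():
        n_fit = max(int(np.sum(~np.isnan(m.fitness))), 1)
        n_conc = max(int(np.sum(~np.isnan(m.concentration))), 1)
        conc_sd = a + b * abs(m.conc_mean) if np.isfinite(m.conc_mean) else a
        out[key] = StrainMeasurement(
            m.strain_id,
            m.E,
            m.fitness,
            m.concentration,
            fitness_se_value=pooled_fit_sd / np.sqrt(n_fit),
            conc_se_value=conc_sd / np.sqrt(n_conc),
        )
    return out


@dataclass(frozen=True)
class StrainPhenotypeEstimate:
    delta_max: float
    delta_max_se: float
    chi0: float
    chi0_se: float


def propagate_errors(
    f: Callable[[np.ndarray], np.ndarray], x, se, rel_step: float = 1e-6
):
    """First-order (delta-method) error propagation through ``f``.

    Assumes independent errors on the inputs: var(f_k) = sum_i
    (df_k/dx_i * se_i)**2 with the Jacobian from central finite differences.
    Returns (value, se) with shapes matching f's output.
    """
    x = np.asarray(x, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se < 0):
        raise ValueError("input standard errors must be >= 0")
    y0 = np.atleast_1d(np.asarray(f(x), dtype=float))
    var = np.zeros_like(y0)
    for i in range(x.size):
        h = rel_step * max(abs(x[i]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        grad = (np.atleast_1d(f(xp)) - np.atleast_1d(f(xm))) / (2 * h)
        var += (grad * se[i]) ** 2
    out_se = np.sqrt(var)
    if np.ndim(f(x)) == 0:
        return float(y0[0]), float(out_se[0])
    return y0, out_se


def _phenotype_point(
    c0: float, l0: float, c1: float, l1: float, params: ModelParams, h_sat: float
) -> tuple[float, float]:
    d0 = c0 * l0**2 / growth_expression_factor(l0, params)
    d1 = c1 * l1**2 / growth_expression_factor(l1, params)
    delta_max = d0 + (d1 - d0) / h_sat
    if delta_max <= 0:
        raise DomainError("estimated delta_max is non-positive")
    return delta_max, d0 / delta_max


def estimate_strain_phenotypes(
    m0: StrainMeasurement,
    m1: StrainMeasurement,
    params: ModelParams,
    assume_full_induction: bool = False,
) -> StrainPhenotypeEstimate:
    """Estimate (delta_max, chi0) from measurements at E=0 and saturating E.

    ``m0`` must be the uninduced condition (E = 0) and ``m1`` a saturating
    one.  With ``assume_full_induction`` the induced production rate is taken
    to be delta_max exactly (h = 1); by default the known value of the
    induction function at m1.E is inverted, which makes the estimator exact
    on data generated by the model itself.  Standard errors come from
    first-order propagation assuming independent errors on concentration and
    fitness.
    """
    if m0.E != 0:
        raise ValueError("m0 must be measured at E = 0")
    if m1.E <= 0:
        raise ValueError("m1 must be measured at a positive inducer concentration")
    c1, l1 = m1.conc_mean, m1.fitness_mean
    c0, l0 = m0.conc_mean, m0.fitness_mean
    if not (l1 > 0 and l0 > 0):
        raise DomainError("measured fitness must be positive")
    if c1 <= 0:
        raise DomainError("induced concentration must be positive to estimate chi0")
    h_sat = 1.0 if assume_full_induction else float(hill_induction(m1.E, params))

    def f(x):
        dm, chi = _phenotype_point(x[0], x[1], x[2], x[3], params, h_sat)
        return np.array([dm, chi])

    x = np.array([c0, l0, c1, l1])
    se = np.array([m0.conc_se, m0.fitness_se, m1.conc_se, m1.fitness_se])
    val, out_se = propagate_errors(f, x, se)
    return StrainPhenotypeEstimate(val[0], out_se[0], val[1], out_se[1])


def repression_level(chi0: float) -> float:
    """Repression level R = 1/chi0 (ratio of unrepressed to repressed rates)."""
    if chi0 <= 0:
        raise DomainError("chi0 must be positive to define a repression level")
    return 1.0 / chi0


def predict_fitness(
    est: StrainPhenotypeEstimate | Genotype,
    E: float,
    params: ModelParams,
    pump_factor: float = 1.0,
) -> tuple[float, bool]:
    """Stable-branch fitness prediction; (nan, True) when extinct.

    Estimates are clipped into the genotype domain (delta_max >= 0,
    chi0 in [0, 1]) before solving, since noisy estimators can leave it.
    """
    if isinstance(est, Genotype):
        g = est
    else:
        g = Genotype(
            max(est.delta_max, 0.0), float(np.clip(est.chi0, 0.0, 1.0)), pump_factor
        )
    sol = solve_genotype_environment(g, E, params)
    fp = sol.stable
    if fp is None:
        return np.nan, True
    return fp.lam, False


@dataclass
class PredictionRow:
    """One strain x condition entry of the likelihood: data plus phenotype estimate.

    ``jac`` is the estimator Jacobian d(delta_max, chi0)/d(C0, lam0, C1, lam1)
    and ``var_inputs`` the variances of those four measurements; together with
    the model's sensitivity to (delta_max, chi0) they propagate measurement
    error into the prediction.  ``y_input_index`` marks which estimator input
    is the very fitness value this row observes (1 for the E=0 condition, 3
    for the saturating one, None otherwise), so that the residual's
    self-dependence on that measurement is accounted for.
    """

    strain_id: str
    E: float
    estimate: StrainPhenotypeEstimate
    pump_factor: float
    fitness_obs: float
    fitness_se: float
    jac: np.ndarray | None = None
    var_inputs: np.ndarray | None = None
    y_input_index: int | None = None


def build_prediction_table(
    dataset,
    params: ModelParams,
    pump_factors: Mapping[str, float] | None = None,
    saturating_E: float = 1.0,
    exclude: Sequence[str] = (),
    assume_full_induction: bool = False,
    variance_pooling: bool = True,
) -> tuple[list[PredictionRow], dict[str, StrainPhenotypeEstimate]]:
    """Estimate phenotypes per strain and lay out the likelihood table.

    ``dataset`` is any object with a ``measurements()`` method returning
    {(strain_id, E): StrainMeasurement}.  Strains lacking either the E=0 or
    the saturating condition, or with estimation failures (e.g. zero induced
    concentration), are skipped.  ``variance_pooling`` (default) replaces
    the unstable per-condition SEs by pooled estimates; see
    :func:`pool_variances`.
    """
    pump_factors = dict(pump_factors or {})
    meas = dataset.measurements()
    if variance_pooling:
        meas = pool_variances(meas)
    strains = sorted({k[0] for k in meas} - set(exclude))
    estimates: dict[str, StrainPhenotypeEstimate] = {}
    rows: list[PredictionRow] = []
    for s in strains:
        m0 = meas.get((s, 0.0))
        m1 = meas.get((s, saturating_E))
        if m0 is None or m1 is None:
            continue
        try:
            est = estimate_strain_phenotypes(m0, m1, params, assume_full_induction)
        except DomainError:
            continue
        estimates[s] = est

        h_sat = 1.0 if assume_full_induction else float(hill_induction(m1.E, params))
        x = np.array([m0.conc_mean, m0.fitness_mean, m1.conc_mean, m1.fitness_mean])
        var_u = np.array(
            [m0.conc_se, m0.fitness_se, m1.conc_se, m1.fitness_se], dtype=float
        ) ** 2
        jac = np.empty((2, 4))
        for i in range(4):
            h = 1e-6 * max(abs(x[i]), 1.0)
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fp = _phenotype_point(*xp, params, h_sat)
            fm = _phenotype_point(*xm, params, h_sat)
            jac[:, i] = (np.asarray(fp) - np.asarray(fm)) / (2 * h)

        pf = pump_factors.get(s, 1.0)
        for (sid, E), m in meas.items():
            if sid != s:
                continue
            y_idx = 1 if E == 0.0 else (3 if E == m1.E else None)
            rows.append(
                PredictionRow(
                    s, E, est, pf, m.fitness_mean, m.fitness_se, jac, var_u, y_idx
                )
            )
    rows.sort(key=lambda r: (r.strain_id, r.E))
    return rows, estimates


def _row_arrays(rows: Sequence[PredictionRow], params: ModelParams):
    dm = np.array([max(r.estimate.delta_max, 0.0) for r in rows])
    chi = np.clip(np.array([r.estimate.chi0 for r in rows]), 0.0, 1.0)
    h = np.array([hill_induction(r.E, params) for r in rows])
    tau = np.array(
        [transport_per_pump(r.E, r.pump_factor, params) for r in rows]
    )
    y = np.array([r.fitness_obs for r in rows])
    se = np.array([r.fitness_se for r in rows])
    sdm = np.array([r.estimate.delta_max_se for r in rows])
    schi = np.array([r.estimate.chi0_se for r in rows])
    return dm, chi, h, tau, y, se, sdm, schi


def log_likelihood(
    params: ModelParams,
    rows: Sequence[PredictionRow],
    min_sigma: float = 1e-6,
    extinct_penalty: float = 1e3,
    include_phenotype_uncertainty: bool = True,
) -> float:
    """Gaussian log-likelihood of observed mean fitness given the model.

    Per point the residual variance comes from first-order propagation of the
    independent measurement errors through the whole residual
    y - lambda_hat(estimates(C0, lam0, C1, lam1)): the Jacobian chains the
    estimator sensitivities stored on each row with the model's sensitivity
    to (delta_max, chi0), and the term for the fitness measurement that this
    row itself observes carries the factor (1 - d lambda_hat / d lam_obs),
    since that measurement moves both sides of the residual.  With
    ``include_phenotype_uncertainty`` off, only the fitness SE is used.  A
    strain predicted extinct while observed growing incurs a finite penalty
    of ``extinct_penalty`` so that optimization remains well-behaved near the
    cliff.
    """
    if not rows:
        raise ValueError("empty prediction table")
    dm, chi, h, tau, y, se, sdm, schi = _row_arrays(rows, params)
    if np.any(se < 0):
        raise ValueError("fitness standard errors must be >= 0")
    ind = chi + (1.0 - chi) * h
    lam = stable_lambda_fast(dm, ind, tau, params)
    ok = np.isfinite(lam)
    resid = y - lam
    score = -extinct_penalty * float(np.count_nonzero(~ok))

    if not include_phenotype_uncertainty:
        sigma2 = np.maximum(se**2, min_sigma**2)
        score += -0.5 * np.sum(
            np.log(2 * np.pi * sigma2[ok]) + resid[ok] ** 2 / sigma2[ok]
        )
        return float(score)

    step_d = 1e-4 * np.maximum(dm, 0.1)
    ddm = (stable_lambda_fast(dm + step_d, ind, tau, params) - lam) / step_d
    step_c = 1e-4
    chi_p = np.clip(chi + step_c, 0.0, 1.0)
    ind_p = chi_p + (1.0 - chi_p) * h
    dchi = (stable_lambda_fast(dm, ind_p, tau, params) - lam) / np.maximum(
        chi_p - chi, 1e-12
    )
    ddm = np.where(np.isfinite(ddm), ddm, 0.0)
    dchi = np.where(np.isfinite(dchi), dchi, 0.0)

    groups: dict[str, list[int]] = {}
    for i, r in enumerate(rows):
        groups.setdefault(r.strain_id, []).append(i)

    log2pi = np.log(2 * np.pi)
    for idx_all in groups.values():
        idx = [i for i in idx_all if ok[i]]
        if not idx:
            continue
        r0 = rows[idx[0]]
        if r0.jac is None or r0.var_inputs is None:
            # no estimator provenance: fall back to the diagonal delta method
            for i in idx:
                v = max(
                    se[i] ** 2 + (ddm[i] * sdm[i]) ** 2 + (dchi[i] * schi[i]) ** 2,
                    min_sigma**2,
                )
                score += -0.5 * (np.log(2 * np.pi * v) + resid[i] ** 2 / v)
            continue
        # residual Jacobian wrt the strain's independent measurement errors:
        # the 4 estimator inputs (C0, lam0, C1, lam1) plus one extra noise
        # term per row whose observation is not itself an estimator input
        k = len(idx)
        extra = [i for i in idx if rows[i].y_input_index is None]
        Jr = np.zeros((k, 4 + len(extra)))
        var_u = np.concatenate([r0.var_inputs, se[extra] ** 2])
        for p, i in enumerate(idx):
            dlam_du = ddm[i] * rows[i].jac[0] + dchi[i] * rows[i].jac[1]
            Jr[p, :4] = -dlam_du
            if rows[i].y_input_index is not None:
                Jr[p, rows[i].y_input_index] += 1.0
            else:
                Jr[p, 4 + extra.index(i)] = 1.0
        cov = (Jr * var_u) @ Jr.T + min_sigma**2 * np.eye(k)
        r_vec = resid[idx]
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:  # pragma: no cover - PD by construction + jitter
            raise np.linalg.LinAlgError("residual covariance not positive definite")
        score += -0.5 * (k * log2pi + logdet + float(r_vec @ np.linalg.solve(cov, r_vec)))
    return float(score)


@dataclass
class FitConfig:
    """Search configuration for the cost-coefficient fit (deterministic)."""

    c_delta_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 0.15, 7)
    )
    c_T_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 0.08, 5))
    c_C_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 0.12, 7))
    refine: bool = True
    nm_maxfev: int = 600
    nm_xatol: float = 1e-8
    nm_fatol: float = 1e-12
    score_grid_n: int = 25
    min_sigma: float = 1e-6
    extinct_penalty: float = 1e3
    include_phenotype_uncertainty: bool = True


@dataclass
class FitResult:
    c_delta: float
    c_T: float
    c_C: float
    score: float
    grid_c_T: np.ndarray
    grid_c_C: np.ndarray
    grid_scores: np.ndarray  # shape (len(grid_c_T), len(grid_c_C))

    @property
    def coefficients(self) -> dict[str, float]:
        return {"c_delta": self.c_delta, "c_T": self.c_T, "c_C": self.c_C}

    def to_dict(self) -> dict:
        return {**self.coefficients, "score": self.score}


def _score_fn(rows, params, config) -> Callable[[float, float, float], float]:
    def score(cd, ct, cc):
        p = params.replace(c_delta=cd, c_T=ct, c_C=cc)
        return log_likelihood(
            p,
            rows,
            min_sigma=config.min_sigma,
            extinct_penalty=config.extinct_penalty,
            include_phenotype_uncertainty=config.include_phenotype_uncertainty,
        )

    return score


def _check_identifiable(rows: Sequence[PredictionRow]) -> None:
    conditions = {r.E for r in rows}
    if len(conditions) < 2:
        raise ValueError(
            "coefficients unidentifiable: dataset must span at least two inducer "
            "conditions including E = 0 and a saturating one"
        )


def _refine(score, x0: np.ndarray, fixed: Mapping[int, float], config: FitConfig) -> np.ndarray:
    free = [i for i in range(3) if i not in fixed]

    def obj(v):
        x = np.empty(3)
        for j, i in enumerate(free):
            x[i] = max(v[j], 0.0)
        for i, val in fixed.items():
            x[i] = val
        return -score(x[0], x[1], x[2])

    res = minimize(
        obj,
        x0[free],
        method="Nelder-Mead",
        options={
            "maxfev": config.nm_maxfev,
            "xatol": config.nm_xatol,
            "fatol": config.nm_fatol,
        },
    )
    out = x0.copy()
    for j, i in enumerate(free):
        out[i] = max(res.x[j], 0.0)
    for i, val in fixed.items():
        out[i] = val
    return out


def fit_cost_coefficients(
    rows: Sequence[PredictionRow],
    params: ModelParams,
    config: FitConfig | None = None,
    fixed: Mapping[str, float] | None = None,
) -> FitResult:
    """Maximum-likelihood cost coefficients by grid search plus local polish.

    The search is a coarse grid over (c_delta, c_T, c_C) >= 0 followed by
    Nelder-Mead refinement from the best grid point; entirely deterministic
    given the data and configuration.  ``fixed`` pins coefficients for
    constrained (nested) fits.  The returned score grid spans (c_T, c_C) at
    the ML c_delta.
    """
    config = config or FitConfig()
    _check_identifiable(rows)
    score = _score_fn(rows, params, config)
    names = ("c_delta", "c_T", "c_C")
    fixed_idx = {}
    for k, v in (fixed or {}).items():
        if k not in names:
            raise ValueError(f"unknown coefficient {k!r}")
        fixed_idx[names.index(k)] = float(v)

    grids = [
        np.asarray(config.c_delta_grid, dtype=float),
        np.asarray(config.c_T_grid, dtype=float),
        np.asarray(config.c_C_grid, dtype=float),
    ]
    for i, v in fixed_idx.items():
        grids[i] = np.array([v])

    best, best_x = -np.inf, None
    for cd in grids[0]:
        for ct in grids[1]:
            for cc in grids[2]:
                s = score(cd, ct, cc)
                if s > best:
                    best, best_x = s, np.array([cd, ct, cc])

    x = best_x
    if config.refine:
        x = _refine(score, x, fixed_idx, config)
    final = score(*x)
    if final < best:  # refinement should never make things worse
        x, final = best_x, best

    if config.score_grid_n > 1 and not fixed_idx:
        gT = np.linspace(config.c_T_grid.min(), config.c_T_grid.max(), config.score_grid_n)
        gC = np.linspace(config.c_C_grid.min(), config.c_C_grid.max(), config.score_grid_n)
        grid_scores = np.empty((gT.size, gC.size))
        for i, ct in enumerate(gT):
            for j, cc in enumerate(gC):
                grid_scores[i, j] = score(x[0], ct, cc)
    else:  # constrained fits and grid-free configurations skip the surface
        gT = gC = np.empty(0)
        grid_scores = np.empty((0, 0))

    return FitResult(x[0], x[1], x[2], final, gT, gC, grid_scores)


def compare_models(
    rows: Sequence[PredictionRow],
    params: ModelParams,
    constraints: Sequence[Mapping[str, float]],
    config: FitConfig | None = None,
    full: FitResult | None = None,
) -> list[dict]:
    """Score deltas between the full ML fit and nested constrained fits.

    Each constraint is a mapping of pinned coefficients (an empty mapping
    reproduces the full model, delta = 0).  For nested constraints
    delta = score(full) - score(constrained) >= 0.
    """
    config = config or FitConfig()
    if full is None:
        full = fit_cost_coefficients(rows, params, config)
    out = []
    for cons in constraints:
        if cons:
            res = fit_cost_coefficients(rows, params, config, fixed=cons)
        else:
            res = full
        out.append(
            {
                "constraint": dict(cons),
                "score": res.score,
                "delta": full.score - res.score,
                "coefficients": res.coefficients,
            }
        )
    return out
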