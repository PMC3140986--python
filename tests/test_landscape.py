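"""Fixed-point solvers, stability labels, barrier and cliff location."""

import numpy as np
import pytest

from lacscape import (
    Genotype,
    ModelParams,
    NoCliffError,
    classify_stability,
    expression_barrier,
    find_cliff,
    hill_induction,
    landscape_grid,
    solve_genotype_environment,
    solve_phenotype_fitness,
    strain_trajectory,
    transport_per_pump,
)
from lacscape.landscape import stable_lambda_fast
from lacscape.model import growth_map


def dense_scan_roots(g, E, p, n=100_000):
    """Independent root oracle: dense scan of lam - G(lam) plus bisection."""
    lam0 = p.lambda0
    grid = np.linspace(1e-6 * lam0, lam0, n)
    F = grid - growth_map(grid, g, E, p)
    roots = []
    for i in np.nonzero(np.sign(F[:-1]) * np.sign(F[1:]) < 0)[0]:
        lo, hi = grid[i], grid[i + 1]
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if (mid - growth_map(mid, g, E, p)) * (lo - growth_map(lo, g, E, p)) <= 0:
                hi = mid
            else:
                lo = mid
        roots.append(0.5 * (lo + hi))
    if abs(F[-1]) < 1e-13:
        roots.append(grid[-1])
    return sorted(roots)


class TestPhenotypeFitness:
    def test_no_toxicity_linear_limit(self):
        p = ModelParams(c_delta=0.06, c_T=0.02, c_C=0.0)
        sol = solve_phenotype_fitness(1.0, 0.0, p)
        assert sol.regime == "single"
        assert sol.lambda_stable == pytest.approx(1.0 - 0.06)

    def test_tangency_closed_form(self):
        # a = 1, b = c_C * T = 4/27  ->  double root at 2/3
        p = ModelParams(c_delta=0.0, c_T=0.0, c_C=4.0 / 27.0)
        sol = solve_phenotype_fitness(0.0, 1.0, p)
        assert sol.regime == "tangent"
        assert sol.fixed_points[0].lam == pytest.approx(2.0 / 3.0, abs=1e-10)
        assert sol.fixed_points[0].stability == "marginal"

    def test_two_branch_against_scan_oracle(self):
        p = ModelParams(c_delta=0.0, c_T=0.0, c_C=0.1)
        sol = solve_phenotype_fitness(0.0, 1.0, p)
        assert sol.regime == "two-branch"
        # oracle: roots of lam^3 - lam^2 + 0.1 on (0, 1]
        grid = np.linspace(1e-9, 1.0, 1_000_000)
        f = grid**3 - grid**2 + 0.1
        idx = np.nonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)[0]
        assert len(idx) == 2
        oracle = []
        for i in idx:
            lo, hi = grid[i], grid[i + 1]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if (mid**3 - mid**2 + 0.1) * (lo**3 - lo**2 + 0.1) <= 0:
                    hi = mid
                else:
                    lo = mid
            oracle.append(0.5 * (lo + hi))
        got = sorted(fp.lam for fp in sol.fixed_points)
        assert got == pytest.approx(sorted(oracle), abs=1e-8)
        assert sol.stable.lam > sol.unstable.lam

    def test_regime_none_when_cost_exceeds_reference(self):
        p = ModelParams(c_delta=1.0, c_T=0.0, c_C=0.1)
        assert solve_phenotype_fitness(2.0, 1.0, p).regime == "none"

    def test_cubic_root_count_vs_discriminant(self, rng):
        """For a, b > 0 the positive-root count follows b vs 4a^3/27 exactly."""
        for _ in range(200):
            cC = rng.uniform(0.01, 0.5)
            T = rng.uniform(0.01, 5.0)
            cd = rng.uniform(0.0, 0.3)
            d = rng.uniform(0.0, 2.0)
            p = ModelParams(c_delta=cd, c_T=0.0, c_C=cC)
            a = 1.0 - cd * d
            b = cC * T
            if a <= 0 or abs(b - 4 * a**3 / 27) < 1e-6:
                continue
            sol = solve_phenotype_fitness(d, T, p)
            expected = 2 if b < 4 * a**3 / 27 else 0
            assert len(sol.fixed_points) == expected


class TestGenotypeEnvironment:
    def test_no_expression_no_cost(self, params):
        sol = solve_genotype_environment(Genotype(1.0, 0.0, 1.0), 0.0, params)
        assert sol.regime == "single"
        assert sol.lambda_stable == pytest.approx(params.lambda0, abs=1e-9)

    def test_quadratic_roots(self, quadratic_setup):
        p, g, E = quadratic_setup
        sol = solve_genotype_environment(g, E, p)
        assert sol.regime == "two-branch"
        assert sol.stable.lam == pytest.approx(0.7, abs=1e-10)
        assert sol.unstable.lam == pytest.approx(0.3, abs=1e-10)

    def test_linear_limit_closed_form(self, rng):
        p = ModelParams(eta_enabled=False, c_delta=0.08, c_T=0.0, c_C=0.0)
        for _ in range(50):
            g = Genotype(rng.uniform(0, 3), rng.uniform(0, 1), 1.0)
            E = rng.uniform(0, 2)
            expected = 1.0 - 0.08 * g.delta_max * (
                g.chi0 + (1 - g.chi0) * hill_induction(E, p)
            )
            sol = solve_genotype_environment(g, E, p)
            if expected > 1e-6:
                assert sol.lambda_stable == pytest.approx(expected, abs=1e-10)

    def test_solver_matches_scan_oracle(self, rng):
        """Bracketing solver vs dense-scan oracle on random draws."""
        for _ in range(30):
            p = ModelParams(
                c_delta=rng.uniform(0, 0.15),
                c_T=rng.uniform(0, 0.1),
                c_C=rng.uniform(0, 0.15),
                eta_enabled=bool(rng.integers(2)),
                theta=float(rng.uniform(0, 0.5)),
            )
            g = Genotype(rng.uniform(0, 3), rng.uniform(0, 1), 1.0)
            E = float(rng.uniform(0, 3))
            sol = solve_genotype_environment(g, E, p)
            oracle = dense_scan_roots(g, E, p)
            got = sorted(fp.lam for fp in sol.fixed_points if fp.stability != "marginal")
            assert len(got) == len(oracle)
            assert got == pytest.approx(oracle, abs=1e-8)

    def test_fast_path_agrees_with_bracketing(self, rng):
        for eta in (True, False):
            p = ModelParams(c_delta=0.06, c_T=0.01, c_C=0.04, eta_enabled=eta)
            dm = rng.uniform(0.05, 3.0, size=40)
            chi = rng.uniform(0, 1, size=40)
            E = rng.uniform(0, 2, size=40)
            ind = chi + (1 - chi) * np.array([hill_induction(e, p) for e in E])
            tau = np.array([transport_per_pump(e, 1.0, p) for e in E])
            fast = stable_lambda_fast(dm, ind, tau, p)
            for i in range(40):
                sol = solve_genotype_environment(Genotype(dm[i], chi[i], 1.0), E[i], p)
                slow = sol.lambda_stable
                if np.isnan(fast[i]):
                    assert sol.stable is None
                else:
                    assert fast[i] == pytest.approx(slow, abs=1e-9)

    def test_stable_branch_monotone_in_costs_and_inputs(self, rng):
        base = ModelParams(c_delta=0.05, c_T=0.02, c_C=0.03)
        g = Genotype(1.0, 0.1, 1.0)
        lam0 = solve_genotype_environment(g, 0.5, base).lambda_stable
        # non-increasing in each cost amplitude, delta_max and E
        for name in ("c_delta", "c_T", "c_C"):
            p2 = base.replace(**{name: getattr(base, name) * 1.5})
            assert solve_genotype_environment(g, 0.5, p2).lambda_stable <= lam0 + 1e-12
        g2 = Genotype(1.5, 0.1, 1.0)
        assert solve_genotype_environment(g2, 0.5, base).lambda_stable <= lam0 + 1e-12
        assert solve_genotype_environment(g, 1.0, base).lambda_stable <= lam0 + 1e-12


class TestStability:
    def test_hand_derivatives_on_quadratic_map(self, quadratic_setup):
        p, g, E = quadratic_setup
        label, gp = classify_stability(0.7, g, E, p)
        assert label == "stable"
        assert gp == pytest.approx(0.21 / 0.49, rel=1e-5)
        label, gp = classify_stability(0.3, g, E, p)
        assert label == "unstable"
        assert gp == pytest.approx(0.21 / 0.09, rel=1e-5)

    def test_non_fixed_point_rejected(self, quadratic_setup):
        p, g, E = quadratic_setup
        with pytest.raises(ValueError, match="not a fixed point"):
            classify_stability(0.5, g, E, p)


class TestExpressionBarrier:
    def test_closed_form_at_zero_production(self):
        p = ModelParams(c_delta=0.0, c_T=0.0, c_C=0.05)
        bar = expression_barrier([0.0], p)
        assert bar["T_barrier"].iloc[0] == pytest.approx(4.0 / (27 * 0.05), rel=1e-10)
        assert bar["lambda_barrier"].iloc[0] == pytest.approx(2.0 / 3.0, rel=1e-10)

    def test_tangency_consistency_and_straddle(self):
        p = ModelParams(c_delta=0.06, c_T=0.01, c_C=0.04)
        bar = expression_barrier(np.array([0.0, 0.5, 1.5]), p)
        for _, row in bar.iterrows():
            d, Tb = row["delta"], row["T_barrier"]
            a = p.lambda0 - p.c_delta * d - p.c_T * Tb
            assert p.c_C * Tb == pytest.approx(4 * a**3 / 27, abs=1e-10)
            assert solve_phenotype_fitness(d, Tb, p).regime == "tangent"
            assert solve_phenotype_fitness(d, Tb * (1 + 1e-5), p).regime == "none"
            assert solve_phenotype_fitness(d, Tb * (1 - 1e-5), p).regime == "two-branch"

    def test_absent_without_toxicity(self):
        p = ModelParams(c_delta=0.06, c_T=0.05, c_C=0.0)
        assert expression_barrier([0.0, 1.0], p).empty


class TestFindCliff:
    def test_quadratic_family_discriminant(self):
        # eta off, c_delta = c_C = 0: fold at c_T * delta_max * tau(E) = 1/4
        p = ModelParams(eta_enabled=False, c_delta=0.0, c_T=0.25, c_C=0.0)
        g = Genotype(1.0, 1.0, 1.0)
        e_c = find_cliff(g, p, "E", (0.05, 50.0))
        assert transport_per_pump(e_c, 1.0, p) * 0.25 == pytest.approx(0.25, rel=1e-7)
        assert e_c == pytest.approx(p.E_norm, rel=1e-6)
        d_c = find_cliff(g, p, "delta_max", (0.1, 10.0), E=p.E_norm)
        assert d_c == pytest.approx(1.0, rel=1e-7)

    def test_no_cliff_in_production_only_model(self):
        p = ModelParams(eta_enabled=False, c_delta=0.05, c_T=0.0, c_C=0.0)
        g = Genotype(1.0, 1.0, 1.0)
        with pytest.raises(NoCliffError, match="no cliff"):
            find_cliff(g, p, "E", (0.05, 50.0))

    def test_bisection_matches_fine_existence_scan(self):
        p = ModelParams(c_delta=0.06, c_T=0.01, c_C=0.04)  # eta on
        g = Genotype(6.0, 1.0, 1.0)
        e_c = find_cliff(g, p, "E", (0.01, 20.0), rtol=1e-8)
        scan = np.linspace(0.9 * e_c, 1.1 * e_c, 2001)
        exists = [
            solve_genotype_environment(g, e, p).regime != "none" for e in scan
        ]
        flip = np.nonzero(np.diff(np.asarray(exists).astype(int)))[0]
        assert len(flip) == 1
        assert scan[flip[0]] <= e_c <= scan[flip[0] + 1]

    def test_marginal_slope_at_fold(self):
        """At the fold the growth map is tangent to the bisecting line."""
        p = ModelParams(c_delta=0.06, c_T=0.01, c_C=0.04)
        g = Genotype(6.0, 1.0, 1.0)
        e_c = find_cliff(g, p, "E", (0.01, 20.0), rtol=1e-10)
        sol = solve_genotype_environment(g, e_c * (1 - 1e-7), p)
        gp = min(abs(fp.gprime - 1.0) for fp in sol.fixed_points)
        assert gp < 1e-3


class TestGridAndTrajectory:
    def test_grid_consistent_with_pointwise_solver(self, params):
        g = Genotype(1.0, 1e-3, 1.0)
        grid = landscape_grid(
            "genotype-env", [0.5, 1.5], [0.0, 0.5, 1.0], params, genotype=g
        )
        for i, dm in enumerate(grid.axis1):
            sol = solve_genotype_environment(Genotype(dm, 1e-3, 1.0), 0.0, params)
            got = grid.solutions[i][0]
            assert got.lambda_stable == pytest.approx(sol.lambda_stable, abs=1e-12)
        df = grid.to_frame()
        assert set(df.columns) == {
            "delta_max", "E_mM", "lambda_stable", "lambda_unstable", "regime"
        }

    def test_cliff_polyline_matches_find_cliff(self):
        p = ModelParams(c_delta=0.06, c_T=0.01, c_C=0.04)
        g = Genotype(1.0, 1.0, 1.0)
        E_axis = np.linspace(0.0, 20.0, 21)
        grid = landscape_grid("genotype-env", [5.0, 6.0], E_axis, p, genotype=g)
        assert len(grid.cliff) >= 1
        for _, row in grid.cliff.iterrows():
            gi = Genotype(row["delta_max"], 1.0, 1.0)
            e_ref = find_cliff(gi, p, "E", (0.01, 20.0))
            assert abs(row["E_cliff"] - e_ref) < (E_axis[1] - E_axis[0])

    def test_fitness_differences_grow_with_inducer(self, params):
        """Genotype-by-environment: inducer amplifies fitness differences."""
        g_lo, g_hi = Genotype(0.5, 1e-3, 1.0), Genotype(1.5, 1e-3, 1.0)
        Es = [0.0, 0.05, 0.1, 0.3, 1.0]
        diffs = []
        for e in Es:
            lo = solve_genotype_environment(g_lo, e, params).lambda_stable
            hi = solve_genotype_environment(g_hi, e, params).lambda_stable
            diffs.append(lo - hi)
        assert np.all(np.diff(diffs) >= -1e-12)

    def test_pumpless_constitutive_trajectory_is_flat(self, params):
        g = Genotype(1.0, 1.0, 0.0)
        traj = strain_trajectory(g, params, [0.0, 0.1, 1.0, 5.0])
        assert np.all(traj["T"] == 0.0)
        assert traj["lambda"].std() == pytest.approx(0.0, abs=1e-12)

    def test_trajectory_endpoint_matches_solver(self, params):
        g = Genotype(1.2, 0.01, 1.0)
        traj = strain_trajectory(g, params, [0.0, 0.5])
        sol = solve_genotype_environment(g, 0.0, params)
        assert traj["lambda"].iloc[0] == pytest.approx(sol.lambda_stable, abs=1e-12)

    def test_fitness_nonincreasing_in_inducer(self, rng):
        p = ModelParams(eta_enabled=False, c_delta=0.05, c_T=0.02, c_C=0.03)
        for _ in range(10):
            g = Genotype(rng.uniform(0.1, 2.0), rng.uniform(0, 0.5), 1.0)
            traj = strain_trajectory(g, p, np.linspace(0, 2, 15))
            lam = traj["lambda"].to_numpy()
            lam = lam[~np.isnan(lam)]
            assert np.all(np.diff(lam) <= 1e-12)
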