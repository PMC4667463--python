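"""EM-REML: MME solutions, likelihood, convergence, oracle agreement."""

import numpy as np
import pytest
import scipy.linalg
from scipy.optimize import minimize

from poolblend.design import (
    Individual,
    Measurement,
    PoolDesign,
    PoolSpec,
    VarianceComponents,
    assemble_covariance,
    build_model_matrices,
)
from poolblend.designs import mouse_design, small_pooled_design
from poolblend.reml import FitConfig, em_reml_fit, reml_loglik, solve_mme
from poolblend._batch import fit_transcripts, reduce_design
from poolblend.simulate import SimulationConfig, scenario, simulate_experiment

from conftest import gaussian_transcripts


def gls_solution(mats, y, vc):
    V = assemble_covariance(mats, vc)
    Vi = np.linalg.inv(V)
    X = mats.X
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return beta


class TestMME:
    def test_solutions_match_gls(self, mouse_mats):
        rng = np.random.default_rng(1)
        y = 10 + rng.standard_normal(mouse_mats.n)
        vc = VarianceComponents(biological=0.11, residual=0.02, blending=0.3)
        sol = solve_mme(mouse_mats, y, vc)
        assert np.allclose(sol.beta, gls_solution(mouse_mats, y, vc),
                           atol=1e-10)
        # BLUP identity: u1 = sigma1^2 G1 Z1' V^-1 (y - X beta)
        V = assemble_covariance(mouse_mats, vc)
        resid = y - mouse_mats.X @ sol.beta
        u1 = vc.biological * mouse_mats.G1 @ mouse_mats.Z1.T @ \
            np.linalg.solve(V, resid)
        assert np.allclose(sol.u1, u1, atol=1e-8)

    def test_infinite_shrinkage_limit(self, small_mats):
        # sigma1^2 -> 0 shrinks the biological predictions to zero and the
        # fixed effects to ordinary least squares
        rng = np.random.default_rng(2)
        y = rng.standard_normal(small_mats.n)
        vc = VarianceComponents(biological=1e-12, residual=1.0, blending=1e-12)
        sol = solve_mme(small_mats, y, vc)
        assert np.abs(sol.u1).max() < 1e-9
        ols, *_ = np.linalg.lstsq(small_mats.X, y, rcond=None)
        assert np.allclose(sol.beta, ols, atol=1e-8)

    def test_normal_equation_residual(self, mouse_mats):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(mouse_mats.n)
        vc = VarianceComponents(biological=0.2, residual=0.05, blending=0.1)
        sol = solve_mme(mouse_mats, y, vc)
        # rebuild the coefficient system and check the relative residual
        X, Z1, Z2 = mouse_mats.X, mouse_mats.Z1, mouse_mats.Z2
        W = np.hstack([X, Z1, Z2])
        C = W.T @ W
        p, q1 = X.shape[1], Z1.shape[1]
        C[p:p + q1, p:p + q1] += (vc.residual / vc.biological) * \
            np.linalg.inv(mouse_mats.G1)
        C[p + q1:, p + q1:] += (vc.residual / vc.blending) * \
            np.linalg.inv(mouse_mats.G2)
        sol_vec = np.concatenate([sol.beta, sol.u1, sol.u2])
        rhs = W.T @ y
        rel = np.linalg.norm(C @ sol_vec - rhs) / np.linalg.norm(rhs)
        assert rel < 1e-10


def one_way_design(n_groups=4, reps=2):
    inds = tuple(Individual(id=f"g{k}", treatment="only")
                 for k in range(n_groups))
    pools = tuple(PoolSpec(id=f"s{k}", members=(f"g{k}",))
                  for k in range(n_groups))
    meas = tuple(Measurement(array=f"a{k}.{r}", sample=f"s{k}")
                 for k in range(n_groups) for r in range(reps))
    return PoolDesign(platform="one-color", individuals=inds, pools=pools,
                      measurements=meas, treatment_levels=("only",))


class TestEMReml:
    def test_balanced_one_way_matches_anova_closed_form(self):
        # 4 subjects x 2 technical replicates: REML of the one-way random
        # effects model has the textbook ANOVA solution when MSB > MSW
        mats = build_model_matrices(one_way_design(4, 2))
        rng = np.random.default_rng(8)
        y = np.repeat(rng.normal(0, 2.0, 4), 2) + rng.normal(0, 0.3, 8)
        fit = em_reml_fit(mats, y, FitConfig(), include_blending=False)
        groups = y.reshape(4, 2)
        msw = groups.var(axis=1, ddof=1).mean()
        msb = 2 * groups.mean(axis=1).var(ddof=1)
        assert np.isclose(fit.vc.residual, msw, rtol=1e-6)
        assert np.isclose(fit.vc.biological, (msb - msw) / 2, rtol=1e-6)

    def test_monotone_loglik_in_plain_em(self, small_mats):
        rng = np.random.default_rng(4)
        cfg = FitConfig(track_loglik=True, accelerate=False, max_iter=400)
        for i in range(5):
            y = rng.normal(10, 0.7, small_mats.n)
            fit = em_reml_fit(small_mats, y, cfg)
            diffs = np.diff(fit.loglik_trace)
            assert diffs.min() > -1e-8

    def test_ascent_from_initialization(self, small_mats):
        rng = np.random.default_rng(5)
        y = rng.normal(10, 0.7, small_mats.n)
        cfg = FitConfig(init=(0.2, 0.2, 0.4))
        fit = em_reml_fit(small_mats, y, cfg)
        ll0 = reml_loglik(small_mats, y,
                          VarianceComponents(0.2, 0.4, 0.2))
        assert fit.loglik >= ll0 - 1e-8

    def test_nonconvergence_is_flagged_not_raised(self, small_mats):
        rng = np.random.default_rng(6)
        y = rng.normal(10, 0.7, small_mats.n)
        fit = em_reml_fit(small_mats, y, FitConfig(max_iter=2))
        assert fit.converged is False
        assert fit.iterations <= 3

    def test_constant_input_raises(self, small_mats):
        with pytest.raises(ValueError, match="constant"):
            em_reml_fit(small_mats, np.full(small_mats.n, 3.0), FitConfig())

    def test_m1_equals_m2_with_blending_clamped_at_zero(self, small_mats):
        rng = np.random.default_rng(7)
        y = rng.normal(10, 0.7, small_mats.n)
        f1 = em_reml_fit(small_mats, y, FitConfig(), include_blending=False)
        # likelihood of the m1 estimate is identical whether the blending
        # term is absent or present with sigma2^2 = 0
        vc0 = VarianceComponents(f1.vc.biological, f1.vc.residual, 0.0)
        assert np.isclose(
            reml_loglik(small_mats, y, vc0, include_blending=True),
            f1.loglik, atol=1e-9)


def brute_force_reml(mats, y, include_blending):
    """Grid search plus Nelder-Mead refinement of the restricted likelihood.

    Independent of the EM path: only evaluates the dense likelihood.
    """
    vy = np.var(y, ddof=1)
    grid = vy * np.array([1e-6, 0.05, 0.15, 0.3, 0.6, 1.0, 1.6])
    best, best_ll = None, -np.inf
    for s1 in grid:
        for se in grid[1:]:
            for s2 in (grid if include_blending else [None]):
                vc = VarianceComponents(s1, se, s2)
                try:
                    ll = reml_loglik(mats, y, vc, include_blending)
                except ValueError:
                    continue
                if ll > best_ll:
                    best, best_ll = vc, ll

    def neg(theta):
        theta = np.maximum(theta, 0.0)
        vc = (VarianceComponents(theta[0], theta[2], theta[1])
              if include_blending else
              VarianceComponents(theta[0], theta[1]))
        try:
            return -reml_loglik(mats, y, vc, include_blending)
        except ValueError:
            return np.inf

    x0 = ([best.biological, best.blending, best.residual]
          if include_blending else [best.biological, best.residual])
    starts = [np.asarray(x0, dtype=float)]
    # multi-start: perturbed and boundary-lifted variants guard against a
    # simplex collapsing on a boundary
    starts.append(np.maximum(np.asarray(x0) * 0.3 + 0.02 * vy, 0.0))
    starts.append(np.maximum(np.asarray(x0) * 3.0 + 0.01 * vy, 0.0))
    best_theta, best_fun = None, np.inf
    for s in starts:
        res = minimize(neg, s, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 4000})
        if res.fun < best_fun:
            best_theta, best_fun = np.maximum(res.x, 0.0), res.fun
    theta = best_theta
    if include_blending:
        return VarianceComponents(theta[0], theta[2], theta[1]), -best_fun
    return VarianceComponents(theta[0], theta[1]), -best_fun


@pytest.mark.parametrize("include_blending", [True, False])
def test_em_matches_brute_force_maximizer(small_mats, include_blending):
    """On 25 random small instances per model the EM solution agrees with an
    independent maximizer of the restricted likelihood (boundary cases
    included)."""
    rng = np.random.default_rng(9)
    n = small_mats.n
    scale = np.var
    for i in range(25):
        kind = i % 3
        if kind == 0:      # pure noise: boundary-prone
            y = rng.normal(10, 0.5, n)
        elif kind == 1:    # strong biological structure
            y = gaussian_transcripts(small_mats, 0.4, 0.0, 0.05, 1,
                                     seed=100 + i)[0]
        else:              # blending present
            y = gaussian_transcripts(small_mats, 0.2, 0.6, 0.05, 1,
                                     seed=200 + i)[0]
        fit = em_reml_fit(small_mats, y, FitConfig(), include_blending)
        oracle, oracle_ll = brute_force_reml(small_mats, y, include_blending)
        assert fit.loglik >= oracle_ll - 1e-6, f"instance {i}: EM below oracle"
        flat = abs(fit.loglik - oracle_ll) < 1e-5  # same optimum value
        tol = 1e-3 * np.var(y, ddof=1) + 1e-3 * abs(oracle.biological)
        assert flat or abs(fit.vc.biological - oracle.biological) < tol
        if include_blending:
            tol2 = 1e-3 * np.var(y, ddof=1) + 1e-3 * abs(oracle.blending)
            assert flat or abs(fit.vc.blending - oracle.blending) < tol2


class TestBatchEquivalence:
    @pytest.mark.parametrize("include_blending", [True, False])
    def test_batched_fit_equals_reference(self, small_mats, include_blending):
        rng = np.random.default_rng(10)
        Y = np.vstack([
            rng.normal(10, 0.5, (4, small_mats.n)),
            gaussian_transcripts(small_mats, 0.2, 0.5, 0.05, 4, seed=33),
        ])
        cfg = FitConfig()
        batch = fit_transcripts(small_mats, Y, cfg, include_blending)
        for i in range(Y.shape[0]):
            single = em_reml_fit(small_mats, Y[i], cfg, include_blending)
            assert np.isclose(single.vc.biological, batch.sigma1[i],
                              rtol=1e-3, atol=1e-8)
            assert np.isclose(single.vc.residual, batch.sigma_e[i],
                              rtol=1e-3, atol=1e-8)
            if include_blending:
                assert np.isclose(single.vc.blending, batch.sigma2[i],
                                  rtol=1e-3, atol=1e-8)
            assert np.isclose(single.loglik, batch.loglik[i],
                              rtol=0, atol=1e-6)

    def test_batch_order_independence(self, small_mats):
        Y = gaussian_transcripts(small_mats, 0.2, 0.4, 0.1, 6, seed=44)
        full = fit_transcripts(small_mats, Y, FitConfig())
        perm = np.array([3, 0, 5, 1, 4, 2])
        permuted = fit_transcripts(small_mats, Y[perm], FitConfig())
        # identical up to last-ulp drift of batched BLAS kernels
        assert np.allclose(permuted.sigma2, full.sigma2[perm], atol=1e-8)
        assert np.allclose(permuted.loglik, full.loglik[perm], atol=1e-8)
        repeat = fit_transcripts(small_mats, Y, FitConfig())
        assert np.array_equal(repeat.sigma2, full.sigma2)  # same call: bitwise

    def test_constant_rows_flagged(self, small_mats):
        Y = gaussian_transcripts(small_mats, 0.2, 0.4, 0.1, 2, seed=45)
        Y[0] = 5.0
        batch = fit_transcripts(small_mats, Y, FitConfig())
        assert not batch.ok[0] and batch.ok[1]
        assert np.isnan(batch.sigma1[0])


class TestRestrictedLikelihood:
    def test_translation_invariance(self, mouse_mats):
        rng = np.random.default_rng(11)
        y = rng.normal(10, 0.5, mouse_mats.n)
        vc = VarianceComponents(0.1, 0.02, 0.3)
        assert np.isclose(reml_loglik(mouse_mats, y, vc),
                          reml_loglik(mouse_mats, y + 7.5, vc), atol=1e-8)

    def test_batch_loglik_matches_dense_evaluation(self, mouse_mats):
        Y = gaussian_transcripts(mouse_mats, 0.11, 0.3, 0.02, 3, seed=46)
        for blend in (True, False):
            batch = fit_transcripts(mouse_mats, Y, FitConfig(), blend)
            for i in range(3):
                vc = VarianceComponents(
                    max(batch.sigma1[i], 1e-12), batch.sigma_e[i],
                    max(batch.sigma2[i], 1e-12) if blend else None)
                dense = reml_loglik(mouse_mats, Y[i], vc, blend)
                assert np.isclose(batch.loglik[i], dense, atol=1e-5)

    def test_nested_models_loglik_ordering(self, mouse_mats):
        Y = gaussian_transcripts(mouse_mats, 0.11, 0.3, 0.02, 40, seed=47)
        f1 = fit_transcripts(mouse_mats, Y, FitConfig(), include_blending=False)
        f2 = fit_transcripts(mouse_mats, Y, FitConfig(), include_blending=True)
        assert np.all(f2.loglik >= f1.loglik - 1e-6)

    def test_non_pd_covariance_raises(self, mouse_mats):
        y = np.zeros(mouse_mats.n)
        with pytest.raises(ValueError):
            reml_loglik(mouse_mats, y, VarianceComponents(0.0, 0.0, 0.0))


def test_variance_component_recovery_from_pooled_simulation(mouse_mats,
                                                            mouse_red):
    """m2 estimates over 2000 mechanistically simulated transcripts recover
    exp(sigma_b^2)-1, (exp(sigma_b^2)-1)*sigma_z^2 and sigma_t^2: means
    within 15%, medians within 20% (the sigma2 sampling distribution is
    right-skewed with boundary mass, so its median sits a little low)."""
    cfg = SimulationConfig(m=2000, seed=0, blending_fraction=1.0,
                           keep_decomposition=False)
    expr, design, _ = simulate_experiment(cfg)
    fit = fit_transcripts(mouse_mats, expr.to_numpy(), FitConfig(),
                          include_blending=True, red=mouse_red)
    s1_true = np.exp(cfg.sigma_b2) - 1
    truths = [s1_true, s1_true * cfg.sigma_z2, cfg.sigma_t2]
    for est, truth in zip((fit.sigma1, fit.sigma2, fit.sigma_e), truths):
        assert np.isclose(np.nanmean(est), truth, rtol=0.15)
        assert np.isclose(np.nanmedian(est), truth, rtol=0.20)
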