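"""Mixed-model machinery against dense-inverse, EM-REML and SNP-BLUP oracles."""

import numpy as np
import pandas as pd
import pytest

from jointgp import gblup
from jointgp.gblup import ModelSpec, VarianceComponents, ai_reml, build_mme, solve_mme
from jointgp.grm import GRM, build_grm

from conftest import make_genotype_set


def structured_grm(rng, n, rank=None, ids=None) -> GRM:
    rank = rank or max(2, n // 2)
    f = rng.standard_normal((n, rank)) / np.sqrt(rank)
    mat = f @ f.T + 0.05 * np.eye(n)
    return GRM(ids or [f"x{i}" for i in range(n)], mat, np.array([]), 0.05)


def records_for(ids, y, trait="t", weight=1.0):
    return pd.DataFrame(
        {"animal_id": ids, "trait": trait, "value": y,
         "weight": np.broadcast_to(weight, (len(ids),))}
    )


def simulate_single(rng, grm, sigma_g=1.0, sigma_e=1.0, mu=0.0, weights=None):
    n = len(grm.animal_ids)
    L = np.linalg.cholesky(grm.mat + 1e-10 * np.eye(n))
    g = np.sqrt(sigma_g) * (L @ rng.standard_normal(n))
    w = np.ones(n) if weights is None else weights
    y = mu + g + rng.standard_normal(n) * np.sqrt(sigma_e * w)
    return y, g, w


class TestModelSpec:
    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            ModelSpec(["t"], records_for(["a"], [1.0], weight=0.0), ["a"])

    def test_two_trait_exclusivity_enforced(self):
        rec = pd.DataFrame(
            {"animal_id": ["a", "a"], "trait": ["t1", "t2"], "value": [1.0, 2.0], "weight": 1.0}
        )
        with pytest.raises(ValueError, match="population-exclusive"):
            ModelSpec(["t1", "t2"], rec, ["a"])

    def test_stray_animal_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ModelSpec(["t"], records_for(["ghost"], [1.0]), ["a"])


class TestMME:
    def test_gls_oracle_small_system(self, rng):
        """MME solution equals explicit generalized least squares."""
        grm = structured_grm(rng, 6)
        y, _, _ = simulate_single(rng, grm, mu=1.5)
        w = rng.uniform(0.5, 2.0, 6)
        spec = ModelSpec(["t"], records_for(grm.animal_ids, y, weight=w), grm.animal_ids)
        vc = VarianceComponents(sigma_g=[0.8], sigma_e=[1.2])
        fit = solve_mme(build_mme(spec, grm, vc))
        V = 0.8 * grm.mat + 1.2 * np.diag(w)
        Vi = np.linalg.inv(V)
        X = np.ones((6, 1))
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = 0.8 * grm.mat @ Vi @ (y - X @ beta)
        assert fit.mu["t"] == pytest.approx(beta[0])
        np.testing.assert_allclose(fit.for_trait("t").to_numpy(), u, atol=1e-8)

    def test_zero_genetic_variance_shrinks_to_zero(self, rng):
        grm = structured_grm(rng, 5)
        y, _, _ = simulate_single(rng, grm)
        spec = ModelSpec(["t"], records_for(grm.animal_ids, y), grm.animal_ids)
        vc = VarianceComponents(sigma_g=[1e-10], sigma_e=[1.0])
        fit = solve_mme(build_mme(spec, grm, vc))
        np.testing.assert_allclose(fit.for_trait("t").to_numpy(), 0.0, atol=1e-6)

    def test_duplicated_record_equals_half_weight(self, rng):
        """Two copies of a record at weight d match one record at d/2."""
        grm = structured_grm(rng, 4)
        y, _, _ = simulate_single(rng, grm)
        ids = grm.animal_ids
        rec_dup = pd.DataFrame(
            {"animal_id": ids + [ids[0]], "trait": "t", "value": np.append(y, y[0]),
             "weight": 1.0}
        )
        rec_half = records_for(ids, y, weight=np.array([0.5, 1, 1, 1]))
        vc = VarianceComponents(sigma_g=[1.0], sigma_e=[1.0])
        fit_dup = solve_mme(build_mme(ModelSpec(["t"], rec_dup, ids), grm, vc))
        fit_half = solve_mme(build_mme(ModelSpec(["t"], rec_half, ids), grm, vc))
        np.testing.assert_allclose(
            fit_dup.for_trait("t").to_numpy(), fit_half.for_trait("t").to_numpy(), atol=1e-9
        )

    def test_recordless_animals_are_g_projections(self, rng):
        """GEBV of test animals equal G_test,ref (G_ref,ref)^-1 g_ref."""
        grm = structured_grm(rng, 10)
        y, _, _ = simulate_single(rng, grm)
        ref = grm.animal_ids[:7]
        spec = ModelSpec(["t"], records_for(ref, y[:7]), grm.animal_ids)
        vc = VarianceComponents(sigma_g=[1.0], sigma_e=[1.0])
        fit = solve_mme(build_mme(spec, grm, vc))
        g = fit.for_trait("t")
        G = grm.mat
        proj = G[7:, :7] @ np.linalg.solve(G[:7, :7], g.loc[ref].to_numpy())
        np.testing.assert_allclose(g.iloc[7:].to_numpy(), proj, atol=1e-7)

    def test_gebv_variance_shrunken(self, rng):
        grm = structured_grm(rng, 60)
        y, _, _ = simulate_single(rng, grm)
        spec = ModelSpec(["t"], records_for(grm.animal_ids, y), grm.animal_ids)
        vc = ai_reml(spec, grm, tol=1e-6)
        fit = solve_mme(build_mme(spec, grm, vc))
        assert fit.for_trait("t").var() <= vc.sigma_g[0] * np.diag(grm.mat).mean() + 1e-9


def em_reml_single(y, G, weights, tol=1e-12, max_iter=50_000):
    """Independent EM-REML oracle via Henderson's trace formulas.

    sigma_g' = (u' G^-1 u + tr(G^-1 C_uu)) / q
    sigma_e' = (e' D^-1 e + tr(W C^-1 W' D^-1)) / n
    with C the MME coefficient matrix at the current estimates.
    """
    n = y.size
    X = np.ones((n, 1))
    Z = np.eye(n)
    D = np.diag(weights)
    Dinv = np.linalg.inv(D)
    Ginv = np.linalg.inv(G)
    sg, se = np.var(y) / 2, np.var(y) / 2
    for _ in range(max_iter):
        Rinv = Dinv / se
        C = np.block(
            [[X.T @ Rinv @ X, X.T @ Rinv @ Z],
             [Z.T @ Rinv @ X, Z.T @ Rinv @ Z + Ginv / sg]]
        )
        rhs = np.concatenate([X.T @ Rinv @ y, Z.T @ Rinv @ y])
        Cinv = np.linalg.inv(C)
        sol = Cinv @ rhs
        b, u = sol[:1], sol[1:]
        e = y - X @ b - Z @ u
        Cuu = Cinv[1:, 1:]
        sg_new = (u @ Ginv @ u + np.trace(Ginv @ Cuu)) / n
        W = np.hstack([X, Z])
        se_new = (e @ Dinv @ e + np.trace(W @ Cinv @ W.T @ Dinv)) / n
        if abs(sg_new - sg) < tol * sg and abs(se_new - se) < tol * se:
            sg, se = sg_new, se_new
            break
        sg, se = sg_new, se_new
    return sg, se


class TestAiReml:
    def test_matches_em_reml_fixed_point(self, rng):
        """AI-REML and an independent EM-REML land on the same optimum on
        a tiny weighted instance."""
        r = np.random.default_rng(42)
        grm = structured_grm(r, 8, rank=3)
        w = r.uniform(0.5, 2.0, 8)
        # strong genetic signal keeps the optimum away from the boundary,
        # where EM's convergence is only asymptotic
        y, _, _ = simulate_single(r, grm, sigma_g=4.0, sigma_e=0.5, weights=w)
        spec = ModelSpec(["t"], records_for(grm.animal_ids, y, weight=w), grm.animal_ids)
        vc = ai_reml(spec, grm, tol=1e-12)
        sg_em, se_em = em_reml_single(y, grm.mat, w)
        assert vc.sigma_g[0] > 0.1  # interior optimum
        assert vc.sigma_g[0] == pytest.approx(sg_em, abs=1e-6)
        assert vc.sigma_e[0] == pytest.approx(se_em, abs=1e-6)

    def test_parameter_recovery_within_three_se(self, rng):
        """True (sigma_g, sigma_e) = (1, 1) recovered at n = 500."""
        for seed in (0, 1):
            r = np.random.default_rng(seed)
            grm = structured_grm(r, 500, rank=150)
            y, _, _ = simulate_single(r, grm)
            spec = ModelSpec(["t"], records_for(grm.animal_ids, y), grm.animal_ids)
            vc = ai_reml(spec, grm, tol=1e-8)
            assert vc.converged
            assert abs(vc.sigma_g[0] - 1.0) < 3 * vc.se[0]
            assert abs(vc.sigma_e[0] - 1.0) < 3 * vc.se[1]

    def test_loglik_not_below_start(self, rng):
        grm = structured_grm(rng, 40)
        y, _, _ = simulate_single(rng, grm)
        spec = ModelSpec(["t"], records_for(grm.animal_ids, y), grm.animal_ids)
        from jointgp.gblup import _reml_loglik, _v_components

        comps, x, yv, _ = _v_components(spec, grm)
        start = VarianceComponents(sigma_g=[np.var(y) / 2], sigma_e=[np.var(y) / 2])
        ll_start = _reml_loglik(start.theta(), comps, x, yv)
        vc = ai_reml(spec, grm)
        assert vc.loglik >= ll_start - 1e-8

    def test_degenerate_phenotypes_floored_and_flagged(self, rng):
        grm = structured_grm(rng, 6)
        spec = ModelSpec(["t"], records_for(grm.animal_ids, np.zeros(6)), grm.animal_ids)
        with pytest.warns(UserWarning, match="zero variance"):
            vc = ai_reml(spec, grm)
        assert not vc.converged
        assert vc.sigma_g[0] <= 1e-6


class TestTwoTrait:
    def simulate_two_pop(self, rng, na=120, nb=120, rg=0.8, sg=(1.0, 1.5), se=(0.8, 1.2)):
        n = na + nb
        grm = structured_grm(rng, n, rank=80)
        G0 = np.array(
            [[sg[0], rg * np.sqrt(sg[0] * sg[1])], [rg * np.sqrt(sg[0] * sg[1]), sg[1]]]
        )
        L = np.linalg.cholesky(np.kron(G0, grm.mat) + 1e-10 * np.eye(2 * n))
        gg = L @ rng.standard_normal(2 * n)
        y1 = gg[:n][:na] + rng.standard_normal(na) * np.sqrt(se[0])
        y2 = gg[n:][na:] + rng.standard_normal(nb) * np.sqrt(se[1])
        rec = pd.DataFrame(
            {
                "animal_id": grm.animal_ids[:na] + grm.animal_ids[na:],
                "trait": ["t1"] * na + ["t2"] * nb,
                "value": np.concatenate([y1, y2]),
                "weight": 1.0,
            }
        )
        return grm, ModelSpec(["t1", "t2"], rec, grm.animal_ids)

    def test_zero_covariance_decouples_from_single_trait(self, rng):
        grm, spec = self.simulate_two_pop(rng, na=40, nb=40)
        vc0 = ai_reml(spec, grm, fix_rg=0.0, tol=1e-8)
        assert vc0.r_g == 0.0
        fit_j = solve_mme(build_mme(spec, grm, vc0))
        rec1 = spec.records[spec.records["trait"] == "t1"]
        spec1 = ModelSpec(["t1"], rec1, spec.animal_ids)
        vc1 = VarianceComponents(sigma_g=[vc0.sigma_g[0]], sigma_e=[vc0.sigma_e[0]])
        fit_1 = solve_mme(build_mme(spec1, grm, vc1))
        np.testing.assert_allclose(
            fit_j.for_trait("t1").to_numpy(), fit_1.for_trait("t1").to_numpy(), atol=1e-8
        )

    def test_genetic_correlation_recovered(self, rng):
        """rG = 0.8 recovered within 0.15 on average over 10 seeds."""
        ests = []
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            grm, spec = self.simulate_two_pop(r)
            vc = ai_reml(spec, grm, tol=1e-6)
            ests.append(vc.r_g)
        assert abs(np.mean(ests) - 0.8) < 0.15

    def test_duplicated_population_limit(self, rng):
        """Population B as an exact copy of A with identical records under
        rG = 1 reproduces the single-trait predictions."""
        na = 50
        grm_a = structured_grm(rng, na)
        y, _, _ = simulate_single(rng, grm_a)
        ids_b = [f"copy_{i}" for i in range(na)]
        big = np.tile(grm_a.mat, (2, 2)) + 1e-4 * np.eye(2 * na)
        grm_u = GRM(grm_a.animal_ids + ids_b, big, np.array([]), 1e-4)
        rec = pd.DataFrame(
            {
                "animal_id": grm_a.animal_ids + ids_b,
                "trait": ["t1"] * na + ["t2"] * na,
                "value": np.concatenate([y, y]),
                "weight": 1.0,
            }
        )
        spec = ModelSpec(["t1", "t2"], rec, grm_u.animal_ids)
        vc, fit_j = gblup.two_trait_gblup(spec, grm_u, tol=1e-6)
        spec1 = ModelSpec(["t1"], records_for(grm_a.animal_ids, y, trait="t1"), grm_a.animal_ids)
        vc1, fit_1 = gblup.single_trait_gblup(spec1, grm_a, tol=1e-6)
        ga = fit_j.for_trait("t1").loc[grm_a.animal_ids].to_numpy()
        g1 = fit_1.for_trait("t1").to_numpy()
        assert np.corrcoef(ga, g1)[0, 1] > 0.99

    def test_too_few_records_per_trait_rejected(self, rng):
        grm = structured_grm(rng, 4)
        rec = pd.DataFrame(
            {"animal_id": grm.animal_ids, "trait": ["t1", "t1", "t1", "t2"],
             "value": [1.0, 2.0, 0.5, 1.0], "weight": 1.0}
        )
        spec = ModelSpec(["t1", "t2"], rec, grm.animal_ids)
        with pytest.raises(ValueError, match="fewer than 2"):
            gblup.two_trait_gblup(spec, grm)


class TestSnpBlupEquivalence:
    def test_gblup_equals_snp_blup(self, rng):
        """GEBV from GBLUP equal centered-marker ridge predictions when the
        variance ratio is matched through sum 2 p (1 - p)."""
        n, m = 20, 50
        p = rng.uniform(0.2, 0.8, m)
        dos = rng.binomial(2, p, size=(n, m)).astype(float)
        gs = make_genotype_set(dos)
        # centering with the *generating* p keeps G full rank (sample-p
        # centering puts the ones-vector in the null space)
        grm = build_grm(gs, p=p, ridge=0.0)
        s = np.sum(2 * grm.p * (1 - grm.p))
        y = rng.standard_normal(n) + dos @ rng.standard_normal(m) * 0.1
        sigma_g, sigma_e = 1.3, 0.9
        spec = ModelSpec(["t"], records_for(gs.animal_ids, y), gs.animal_ids)
        fit = solve_mme(
            build_mme(spec, grm, VarianceComponents(sigma_g=[sigma_g], sigma_e=[sigma_e]))
        )
        # SNP-BLUP: y = 1 mu + M a + e, a ~ N(0, I sigma_g / s)
        M = dos - 2 * grm.p
        lam = sigma_e / (sigma_g / s)
        X = np.ones((n, 1))
        C = np.block(
            [[X.T @ X, X.T @ M], [M.T @ X, M.T @ M + lam * np.eye(m)]]
        )
        sol = np.linalg.solve(C, np.concatenate([X.T @ y, M.T @ y]))
        gebv_snp = M @ sol[1:]
        np.testing.assert_allclose(fit.for_trait("t").to_numpy(), gebv_snp, atol=1e-8)
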