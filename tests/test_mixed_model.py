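"""AI-REML estimation, BLUP solutions and derived model statistics."""

import numpy as np
import pytest

from gfblup.kinship import build_grm
from gfblup.mixed_model import (
    ModelSpec,
    RandomTerm,
    VarianceEstimates,
    adjusted_phenotypes,
    fit_reml,
    hat_trace,
    heritability,
    make_gblup_spec,
    make_gfblup_spec,
    solve_blup,
)
from gfblup.simulate import SimScenario, select_causal, simulate_phenotypes


def manual_varest(components):
    names = list(components)
    return VarianceEstimates(
        components=dict(components),
        se={n: 0.0 for n in names},
        loglik=0.0,
        trace=[],
        converged=True,
        n_iterations=0,
        lower_bound=1e-12,
    )


class TestRemlOracles:
    def test_balanced_one_way_equals_anova(self, rng):
        """REML on a balanced one-way layout reproduces the closed-form
        ANOVA estimators sigma_e^2 = MSW, sigma_g^2 = (MSB - MSW)/r."""
        g, r = 10, 5
        effects = rng.normal(0, 2.0, size=g)
        y = np.repeat(effects, r) + rng.normal(0, 1.0, size=g * r)
        Z = np.kron(np.eye(g), np.ones((r, 1)))
        spec = ModelSpec(
            y=y, X=np.ones((g * r, 1)),
            random_terms=[RandomTerm("group", np.eye(g), Z=Z)],
        )
        v = fit_reml(spec)
        means = y.reshape(g, r).mean(axis=1)
        msw = ((y.reshape(g, r) - means[:, None]) ** 2).sum() / (g * (r - 1))
        msb = r * ((means - means.mean()) ** 2).sum() / (g - 1)
        assert v.residual == pytest.approx(msw, rel=1e-4)
        assert v.components["group"] == pytest.approx((msb - msw) / r, rel=1e-4)

    def test_parameter_recovery_unbiased(self, medium_ctx):
        """Mean REML h2 over replicates lies within 2 Monte-Carlo SEs of
        the simulated truth (heritability estimation is unbiased)."""
        h2_true, reps = 0.36, 15
        G = medium_ctx.G
        rng = np.random.default_rng(77)
        L = np.linalg.cholesky(G + 1e-8 * np.eye(G.shape[0]))
        ests = []
        for _ in range(reps):
            gval = np.sqrt(36.0) * (L @ rng.standard_normal(G.shape[0]))
            y = gval + np.sqrt(64.0) * rng.standard_normal(G.shape[0])
            v = fit_reml(make_gblup_spec(y, G, eig=medium_ctx.eig))
            ests.append(heritability(v)["h2"])
        ests = np.asarray(ests)
        mc_se = ests.std(ddof=1) / np.sqrt(reps)
        assert abs(ests.mean() - h2_true) < 2 * mc_se + 1e-6

    def test_constant_response_at_lower_bound(self):
        y = np.full(30, 3.14)
        spec = make_gblup_spec(y, np.eye(30))
        v = fit_reml(spec)
        assert v.components["genomic"] <= 1e-10
        assert v.residual <= 1e-10

    def test_loglik_nondecreasing(self, panel_ctx, rng):
        y = rng.standard_normal(panel_ctx.G.shape[0])
        v = fit_reml(make_gblup_spec(y, panel_ctx.G, eig=panel_ctx.eig))
        diffs = np.diff(v.trace)
        assert (diffs > -1e-6).all()

    def test_spectral_and_dense_paths_agree(self, rng):
        n = 60
        W = rng.standard_normal((n, 100))
        G = W @ W.T / 100
        y = rng.standard_normal(n)
        v_fast = fit_reml(make_gblup_spec(y, G))
        spec_dense = ModelSpec(
            y=y, X=np.ones((n, 1)),
            random_terms=[RandomTerm("genomic", G, Z=np.eye(n))],
        )
        v_dense = fit_reml(spec_dense)
        assert v_fast.components["genomic"] == pytest.approx(
            v_dense.components["genomic"], rel=1e-4
        )
        assert v_fast.loglik == pytest.approx(v_dense.loglik, abs=1e-5)

    def test_gfblup_same_matrix_recovers_gblup_total(self, panel_ctx, rng):
        """With G_f = G_r only the sum sigma_f^2 + sigma_r^2 is
        identifiable and must match the GBLUP sigma_g^2."""
        G = panel_ctx.G
        rng2 = np.random.default_rng(3)
        y = rng2.multivariate_normal(np.zeros(G.shape[0]), 5 * G + 5 * np.eye(G.shape[0]))
        vg = fit_reml(make_gblup_spec(y, G, eig=panel_ctx.eig))
        vgf = fit_reml(make_gfblup_spec(y, G, G))
        total = vgf.components["feature"] + vgf.components["rest"]
        assert total == pytest.approx(vg.components["genomic"], rel=1e-2)
        assert vgf.residual == pytest.approx(vg.residual, rel=1e-2)


class TestBlup:
    def test_mme_identity(self, panel_ctx, rng):
        y = rng.standard_normal(panel_ctx.G.shape[0])
        spec = make_gblup_spec(y, panel_ctx.G, eig=panel_ctx.eig)
        v = fit_reml(spec)
        sol = solve_blup(spec, v)
        recon = spec.X @ sol.fixed + sol.random["genomic"] + sol.residuals
        np.testing.assert_allclose(recon, y, atol=1e-8)

    def test_closed_form_gblup(self, rng):
        """g_hat matches sigma_g^2 G (sigma_g^2 G + sigma_e^2 I)^-1 (y - mu_hat)
        with mu_hat the GLS intercept."""
        n = 6
        W = rng.standard_normal((n, 12))
        G = W @ W.T / 12
        y = rng.standard_normal(n) * 2 + 1.0
        v = manual_varest({"genomic": 2.0, "residual": 1.0})
        spec = make_gblup_spec(y, G)
        sol = solve_blup(spec, v)
        V = 2.0 * G + 1.0 * np.eye(n)
        Vi = np.linalg.inv(V)
        ones = np.ones(n)
        mu = float((ones @ Vi @ y) / (ones @ Vi @ ones))
        g_direct = 2.0 * G @ Vi @ (y - mu)
        np.testing.assert_allclose(sol.random["genomic"], g_direct, atol=1e-10)
        assert sol.fixed[0] == pytest.approx(mu)

    def test_shrinkage_limit(self, rng):
        n = 40
        G = np.eye(n)
        y = rng.standard_normal(n)
        v = manual_varest({"genomic": 1e-12, "residual": 1.0})
        sol = solve_blup(make_gblup_spec(y, G), v)
        assert np.abs(sol.random["genomic"]).max() < 1e-9

    def test_var_pred_is_g_sigma_minus_pev_and_psd(self, panel_ctx, rng):
        y = rng.standard_normal(panel_ctx.G.shape[0])
        spec = make_gblup_spec(y, panel_ctx.G, eig=panel_ctx.eig)
        v = fit_reml(spec)
        sol = solve_blup(spec, v)
        expect = v.components["genomic"] * panel_ctx.G - sol.pev["genomic"]
        np.testing.assert_allclose(sol.var_pred["genomic"], expect, atol=1e-8)
        eigs = np.linalg.eigvalsh(sol.var_pred["genomic"])
        assert eigs.min() > -1e-8


class TestRatios:
    @pytest.mark.parametrize(
        "components, model, expected",
        [
            ({"feature": 10.0, "rest": 10.0, "residual": 80.0}, "gfblup",
             {"h2": 0.2, "h2_f": 0.5, "h2_r": 0.5}),
            ({"genomic": 36.0, "residual": 64.0}, "gblup", {"h2": 0.36}),
        ],
    )
    def test_ratio_arithmetic(self, components, model, expected):
        out = heritability(manual_varest(components), model=model)
        for key, val in expected.items():
            assert out[key] == pytest.approx(val)

    def test_partition_sums_to_one(self):
        out = heritability(
            manual_varest({"feature": 3.0, "rest": 9.0, "residual": 20.0}),
            model="gfblup",
        )
        assert out["h2_f"] + out["h2_r"] == pytest.approx(1.0)

    def test_zero_variance_error(self):
        with pytest.raises(ZeroDivisionError):
            heritability(manual_varest({"genomic": 0.0, "residual": 0.0}))


class TestHatTrace:
    def test_brute_force_smoother(self, rng):
        """tr(H) equals pushing each basis vector through the fitted
        predictor and summing the i-th outputs."""
        n = 8
        W = rng.standard_normal((n, 20))
        G = W @ W.T / 20
        y = rng.standard_normal(n)
        v = manual_varest({"genomic": 1.5, "residual": 0.7})
        spec = make_gblup_spec(y, G)
        tr_h, df_e = hat_trace(spec, v)
        tr_brute = 0.0
        for i in range(n):
            e_i = np.zeros(n)
            e_i[i] = 1.0
            spec_i = make_gblup_spec(e_i, G)
            sol_i = solve_blup(spec_i, v, compute_pev=False)
            yhat_i = e_i - sol_i.residuals
            tr_brute += yhat_i[i]
        assert tr_h == pytest.approx(tr_brute, abs=1e-8)
        assert df_e == pytest.approx(n - tr_h)

    def test_projection_limits(self, rng):
        n = 30
        G = np.eye(n)
        y = rng.standard_normal(n)
        spec = make_gblup_spec(y, G)
        near_zero = manual_varest({"genomic": 1e-12, "residual": 1.0})
        tr_h, df_e = hat_trace(spec, near_zero)
        assert tr_h == pytest.approx(1.0, abs=1e-6)  # intercept projection
        interp = manual_varest({"genomic": 1.0, "residual": 1e-12})
        tr_h2, _ = hat_trace(spec, interp)
        assert tr_h2 == pytest.approx(n, abs=1e-6)


class TestAdjustedPhenotypes:
    def _animal_model(self, rng):
        n, n_pens = 80, 8
        pen_of = np.repeat(np.arange(n_pens), n // n_pens)
        Zp = np.eye(n_pens)[pen_of]
        a_true = rng.normal(0, 2.0, n)
        pen_true = rng.normal(0, 3.0, n_pens)
        e_true = rng.normal(0, 1.0, n)
        y = 5.0 + Zp @ pen_true + a_true + e_true
        spec = ModelSpec(
            y=y, X=np.ones((n, 1)),
            random_terms=[
                RandomTerm("pen", np.eye(n_pens), Z=Zp),
                RandomTerm("animal", np.eye(n)),
            ],
        )
        return spec, a_true, e_true

    def test_recovery_beats_raw_phenotype(self, rng):
        spec, a_true, e_true = self._animal_model(rng)
        v = fit_reml(spec)
        adj = adjusted_phenotypes(spec, v)
        target = a_true + e_true
        assert len(adj) == spec.n
        assert np.corrcoef(adj, target)[0, 1] > np.corrcoef(spec.y, target)[0, 1]

    def test_missing_animal_term_rejected(self, rng):
        y = rng.standard_normal(20)
        spec = make_gblup_spec(y, np.eye(20))
        with pytest.raises(ValueError, match="animal"):
            adjusted_phenotypes(spec, fit_reml(spec))


class TestGfblupRecovery:
    def test_joint_h2_recovery(self, panel_ctx):
        """GFBLUP on data simulated with known (h2, h2_f) and the true C1
        as feature recovers both ratios within Monte-Carlo error."""
        ctx = panel_ctx
        h2, h2f, reps = 0.4, 0.5, 10
        rng = np.random.default_rng(9)
        est_h2, est_h2f = [], []
        from gfblup.kinship import build_grm

        for _ in range(reps):
            C1, C2 = select_causal(ctx.n_markers, model="random", n_c1=40,
                                   n_c2=160, seed=rng.integers(2**31))
            sc = SimScenario(h2=h2, h2_f=h2f, n_obs=ctx.G.shape[0],
                             n_markers=ctx.n_markers)
            ds = simulate_phenotypes(ctx.genotypes, C1, C2, sc, rng=rng, w=ctx.w)
            Gf = build_grm(ctx.w, subset=C1.indices)
            Gr = build_grm(ctx.w, subset=C1.complement(ctx.n_markers).indices)
            v = fit_reml(make_gfblup_spec(ds.y, Gf, Gr))
            ratios = heritability(v, model="gfblup")
            est_h2.append(ratios["h2"])
            est_h2f.append(ratios["h2_f"])
        for est, truth in ((est_h2, h2), (est_h2f, h2f)):
            est = np.asarray(est)
            se = est.std(ddof=1) / np.sqrt(reps)
            assert abs(est.mean() - truth) < max(2 * se, 0.05)
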