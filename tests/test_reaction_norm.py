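"""Mixed-model correctness: quadrature, fitting, LRTs, contrasts, boundary test."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from conftest import scored_frame, simulate_scored
from wallbrown import synthetic
from wallbrown.reaction_norm import (
    GlmmFit,
    ModelSpec,
    build_design,
    detect_separation,
    fit_glmm,
    fit_logistic_irls,
    glmm_loglik,
    lrt_type2,
    test_random_effect as random_effect_lrt,
    tukey_pairwise,
)


def bernoulli_loglik(eta, y):
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


class TestModelSpec:
    def test_interaction_requires_mains(self):
        with pytest.raises(ValueError):
            ModelSpec(frozenset({"daylength:population", "population"}))

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(frozenset({"moon_phase"}))


class TestMarginalLoglik:
    def test_sigma_zero_equals_bernoulli(self, eastern_scored, additive_spec):
        X, y, fidx, nf, _, _ = build_design(eastern_scored, additive_spec)
        rng = np.random.default_rng(0)
        for _ in range(5):
            beta = rng.normal(0, 1, X.shape[1])
            ll = glmm_loglik(beta, 0.0, X, y, fidx, nf)
            assert ll == pytest.approx(bernoulli_loglik(X @ beta, y), abs=1e-10)

    def test_quadrature_matches_brute_force_single_family(self):
        # one family, one observation, sigma 1: 1e5-point midpoint oracle
        one = scored_frame([("A", "F1", 15.0, "cold", 1)])
        spec = ModelSpec(frozenset({"daylength", "population"}))
        X, y, fidx, nf, _, _ = build_design(one, spec)
        for beta in ([3.0, -0.25], [0.5, 0.1], [-2.0, 0.3]):
            ll = glmm_loglik(np.array(beta), 1.0, X, y, fidx, nf, n_quad=15)
            u = np.linspace(-12, 12, 100_001)
            eta = (X @ beta)[0] + u
            like = np.where(y[0] == 1, expit(eta), 1 - expit(eta))
            integrand = like * stats.norm.pdf(u)
            oracle = np.log(np.trapezoid(integrand, u))
            assert ll == pytest.approx(oracle, abs=1e-6)

    def test_doubling_data_doubles_loglik_at_sigma_zero(self, eastern_scored, additive_spec):
        doubled = pd.concat([eastern_scored, eastern_scored], ignore_index=True)
        beta = np.zeros(build_design(eastern_scored, additive_spec)[0].shape[1]) + 0.1
        X1, y1, f1, n1, _, _ = build_design(eastern_scored, additive_spec)
        X2, y2, f2, n2, _, _ = build_design(doubled, additive_spec)
        assert glmm_loglik(beta, 0.0, X2, y2, f2, n2) == pytest.approx(
            2 * glmm_loglik(beta, 0.0, X1, y1, f1, n1), rel=1e-12
        )

    def test_nonfinite_beta_errors(self, eastern_scored, additive_spec):
        X, y, fidx, nf, _, _ = build_design(eastern_scored, additive_spec)
        with pytest.raises(ValueError):
            glmm_loglik(np.array([np.inf] + [0.0] * (X.shape[1] - 1)), 0.5, X, y, fidx, nf)


class TestFitGlmm:
    def test_parameter_recovery_large_n(self):
        # n = 4000, true slope -2, no family variance
        truth = synthetic.ExperimentTruth(
            populations=(("A", 56.0, 16.0),), slope_per_hour=-2.0, family_sd=0.0,
            families_per_population=20, offspring_per_family_per_treatment=40,
            daylengths=(14.5, 15.5, 16.0, 16.5, 17.5), mortality_rate=0.0,
        )
        scored = simulate_scored(truth, seed=1)
        fit = fit_glmm(scored, ModelSpec(frozenset({"daylength", "population"})))
        slope = fit.coef("daylength")
        se = np.sqrt(fit.vcov[fit.coef_names.index("daylength"),
                              fit.coef_names.index("daylength")])
        assert fit.converged
        assert abs(slope - (-2.0)) < 0.15
        assert abs(slope - (-2.0)) < 3 * se
        assert fit.sigma_f <= 0.2

    def test_matches_grid_search_mle(self):
        # independent oracle: exhaustive (b0, b1) search on a 0.01 lattice
        truth = synthetic.ExperimentTruth(
            populations=(("A", 56.0, 16.0),), slope_per_hour=-2.0, family_sd=0.0,
            families_per_population=10, offspring_per_family_per_treatment=6,
            daylengths=(14.5, 15.5, 16.0, 16.5, 17.5), mortality_rate=0.0,
        )
        scored = simulate_scored(truth, seed=4)
        fit = fit_glmm(scored, ModelSpec(frozenset({"daylength", "population"}),
                                         random_intercept=False))
        agg = scored.groupby("daylength_h")["diapause"].agg(["sum", "size"])
        d = agg.index.to_numpy()
        k, n = agg["sum"].to_numpy(float), agg["size"].to_numpy(float)
        b0 = np.arange(20.0, 45.0, 0.01)
        b1 = np.arange(-3.5, -0.5, 0.01)
        eta = b0[:, None, None] + b1[None, :, None] * d[None, None, :]
        ll = np.sum(k * eta - n * np.logaddexp(0.0, eta), axis=2)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        # the continuous MLE must dominate every lattice point, agree with the
        # lattice argmax to its resolution on the slope, and imply the same
        # half-response daylength (the ridge direction the lattice resolves best)
        assert fit.loglik >= ll[i, j] - 1e-9
        assert fit.coef("daylength") == pytest.approx(b1[j], abs=0.01)
        assert fit.beta[0] / -fit.coef("daylength") == pytest.approx(
            b0[i] / -b1[j], abs=0.02
        )

    def test_separation_flagged(self):
        rows = [("A", "F1", d, "cold", int(d <= 15.5))
                for d in (14.5, 15.0, 15.5, 16.0, 16.5) for _ in range(4)]
        scored = scored_frame(rows)
        fit = fit_glmm(scored, ModelSpec(frozenset({"daylength", "population"}),
                                         random_intercept=False))
        assert fit.separation_flag

    def test_single_daylength_rejected(self):
        scored = scored_frame([("A", "F1", 15.0, "cold", 1), ("A", "F1", 15.0, "cold", 0)])
        with pytest.raises(ValueError, match="daylength"):
            fit_glmm(scored, ModelSpec(frozenset({"daylength", "population"})))

    def test_fixed_effects_match_irls(self, eastern_scored, additive_spec):
        spec0 = ModelSpec(additive_spec.fixed_terms, random_intercept=False)
        fit = fit_glmm(eastern_scored, spec0)
        X, y, *_ = build_design(eastern_scored, spec0)
        beta, ll, _, conv = fit_logistic_irls(X, y)
        assert conv
        np.testing.assert_allclose(fit.beta, beta, atol=1e-6)
        # also against statsmodels GLM as an independent route
        import statsmodels.api as sm
        sm_fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta, sm_fit.params, atol=1e-5)

    def test_centering_invariance(self, western_scored):
        spec = ModelSpec(frozenset({"daylength", "population"}), random_intercept=False)
        fit = fit_glmm(western_scored, spec)
        shifted = western_scored.assign(daylength_h=western_scored["daylength_h"] - 16.0)
        fit_c = fit_glmm(shifted, spec)
        assert fit_c.coef("daylength") == pytest.approx(fit.coef("daylength"), abs=1e-5)
        for p in fit.populations:
            expected = fit.intercept_of(p) + fit.coef("daylength") * 16.0
            assert fit_c.intercept_of(p) == pytest.approx(expected, abs=1e-4)

    def test_nested_models_never_lose_loglik(self, eastern_scored):
        chains = [
            frozenset({"daylength"}),
            frozenset({"daylength", "population"}),
            frozenset({"daylength", "population", "temperature"}),
            frozenset({"daylength", "population", "temperature", "daylength:population"}),
        ]
        lls = [
            fit_glmm(eastern_scored, ModelSpec(t, random_intercept=False)).loglik
            for t in chains
        ]
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))

    def test_matches_lme4_glmer(self):
        """Independent oracle: R lme4 with 15-point adaptive quadrature."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; lme4 cross-check cannot run")
        truth = synthetic.ExperimentTruth(
            populations=(("A", 56.0, 15.9), ("B", 59.0, 16.5)), family_sd=0.8,
            families_per_population=8, offspring_per_family_per_treatment=3,
            mortality_rate=0.0,
        )
        scored = simulate_scored(truth, seed=11)
        fit = fit_glmm(scored, ModelSpec(frozenset({"daylength", "population"})))
        import tempfile, os, textwrap
        with tempfile.TemporaryDirectory() as td:
            data = os.path.join(td, "d.csv")
            scored.to_csv(data, index=False)
            script = os.path.join(td, "m.R")
            with open(script, "w") as fh:
                fh.write(textwrap.dedent(f"""
                    suppressMessages(library(lme4))
                    d <- read.csv("{data}")
                    m <- glmer(diapause ~ 0 + population + daylength_h + (1 | family_id),
                               data = d, family = binomial, nAGQ = 15)
                    cat(sprintf("%.10f ", fixef(m)))
                    cat(sprintf("%.10f %.10f", sqrt(unlist(VarCorr(m))[1]),
                        as.numeric(logLik(m))))
                """))
            out = subprocess.run(["Rscript", script], capture_output=True, text=True,
                                 check=True).stdout.split()
        r_beta = np.array(out[:3], float)
        r_sigma, r_ll = float(out[3]), float(out[4])
        np.testing.assert_allclose(fit.beta, r_beta, atol=2e-4)
        assert fit.sigma_f == pytest.approx(r_sigma, abs=2e-4)
        assert fit.loglik == pytest.approx(r_ll, abs=1e-6)


class TestLrtType2:
    def test_chi2_equals_refit_difference(self, eastern_scored):
        spec = ModelSpec(
            frozenset({"daylength", "population", "temperature"}), random_intercept=False
        )
        tests = {t.term: t for t in lrt_type2(eastern_scored, spec)}
        # oracle: direct refits for the population main effect
        full = fit_glmm(eastern_scored, spec)
        red = fit_glmm(eastern_scored, spec.drop("population"))
        assert tests["population"].chi2 == pytest.approx(
            2 * (full.loglik - red.loglik), abs=1e-8
        )
        assert tests["population"].df == 3  # 4 populations

    def test_df_matches_population_count(self, western_scored):
        spec = ModelSpec(frozenset({"daylength", "population"}), random_intercept=False)
        tests = {t.term: t for t in lrt_type2(western_scored, spec)}
        assert tests["population"].df == 4  # 5 populations
        assert tests["daylength"].df == 1

    def test_null_term_gives_zero_chi2(self):
        # warm treatment is an exact copy of the cold data, so the MLE of the
        # temperature offset is 0 and removing the term costs no likelihood
        base = [(pop, f"{pop}_F1", d, "cold", o) for pop in ("A", "B")
                for d in (14.0, 16.0, 18.0) for o in (0, 1, 1, 0, 1)]
        warm = [(p, f, d, "warm", o) for p, f, d, _, o in base]
        scored = scored_frame(base + warm)
        spec = ModelSpec(frozenset({"daylength", "population", "temperature"}),
                         random_intercept=False)
        tests = {t.term: t for t in lrt_type2(scored, spec)}
        assert tests["temperature"].chi2 == pytest.approx(0.0, abs=1e-6)
        assert tests["temperature"].p == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_term_refused(self):
        # with a single population the population indicator IS the intercept;
        # removing it changes nothing, which is not a nested comparison
        scored = scored_frame(
            [("A", "F1", d, "cold", o) for d in (14.0, 16.0, 18.0) for o in (0, 1)]
        )
        spec = ModelSpec(frozenset({"daylength", "population"}), random_intercept=False)
        with pytest.raises(ValueError, match="non-nested"):
            lrt_type2(scored, spec)

    def test_interaction_tested_against_full(self, eastern_scored):
        spec = ModelSpec(
            frozenset({"daylength", "population", "daylength:population"}),
            random_intercept=False,
        )
        tests = {t.term: t for t in lrt_type2(eastern_scored, spec)}
        full = fit_glmm(eastern_scored, spec)
        red = fit_glmm(eastern_scored, spec.drop("daylength:population"))
        assert tests["daylength:population"].chi2 == pytest.approx(
            2 * (full.loglik - red.loglik), abs=1e-8
        )
        assert tests["daylength:population"].df == 3


def synthetic_fit(beta, vcov, pops):
    names = [f"pop[{p}]" for p in pops] + ["daylength"]
    return GlmmFit(
        spec=ModelSpec(frozenset({"daylength", "population"})),
        populations=list(pops), coef_names=names, beta=np.asarray(beta, float),
        vcov=np.asarray(vcov, float), sigma_f=0.0, loglik=0.0, n_obs=10,
        n_families=2, converged=True, grad_norm=0.0,
        separation={p: False for p in pops},
    )


class TestTukeyPairwise:
    def test_two_groups_adjustment_is_identity(self):
        V = np.diag([0.04, 0.04, 0.01])
        fit = synthetic_fit([1.0, 1.5, -2.0], V, ["A", "B"])
        (c,) = tukey_pairwise(fit, mc_draws=200_000, seed=1)
        assert c.p_adjusted == pytest.approx(c.p_raw, abs=0.002)

    def test_equal_estimates_give_p_near_one(self):
        V = np.diag([0.04, 0.04, 0.04, 0.01])
        fit = synthetic_fit([1.0, 1.0, 1.0, -2.0], V, ["A", "B", "C"])
        for c in tukey_pairwise(fit, seed=2):
            assert c.p_adjusted > 0.99

    def test_matches_mvn_integration(self):
        # brute-force oracle: trivariate normal box probability for the
        # contrast correlation implied by 3 equal-variance coefficients
        V = np.diag([0.01, 0.01, 0.01, 1e-8])
        fit = synthetic_fit([0.00, 0.28, 0.05, -2.0], V, ["A", "B", "C"])
        contrasts = tukey_pairwise(fit, mc_draws=400_000, seed=4)
        C = np.array([[1, -1, 0], [1, 0, -1], [0, 1, -1]], float)
        Vc = C @ V[:3, :3] @ C.T
        corr = Vc / np.sqrt(np.outer(np.diag(Vc), np.diag(Vc)))
        mvn = stats.multivariate_normal(
            mean=np.zeros(3), cov=corr, allow_singular=True, seed=7,
        )
        for c in contrasts:
            z = abs(c.z)
            p_in = mvn.cdf(np.full(3, z), lower_limit=np.full(3, -z))
            assert c.p_adjusted == pytest.approx(1 - p_in, abs=0.005)

    def test_requires_additive_model(self, eastern_scored):
        spec = ModelSpec(
            frozenset({"daylength", "population", "daylength:population"}),
            random_intercept=False,
        )
        fit = fit_glmm(eastern_scored, spec)
        with pytest.raises(ValueError):
            tukey_pairwise(fit)


class TestRandomEffectBoundary:
    def test_zero_variance_gives_half(self, eastern_scored, additive_spec):
        var, p = random_effect_lrt(eastern_scored, additive_spec)
        assert var == 0.0
        assert p == 0.5

    def test_halving_rule(self):
        # LR = 2.706 is the chi2(1) 10% point, so the halved p is 0.05
        assert 0.5 * stats.chi2.sf(2.706, 1) == pytest.approx(0.05, abs=1e-3)
        # and the package's p equals half the chi2 tail of its own LR statistic
        truth = synthetic.ExperimentTruth(
            populations=(("A", 56.0, 16.0),), family_sd=1.0,
            families_per_population=30, offspring_per_family_per_treatment=4,
            daylengths=(15.0, 16.0, 17.0), mortality_rate=0.0,
        )
        scored = simulate_scored(truth, seed=5)
        spec = ModelSpec(frozenset({"daylength", "population"}))
        var, p = random_effect_lrt(scored, spec)
        free = fit_glmm(scored, spec)
        null = fit_glmm(scored, ModelSpec(spec.fixed_terms, random_intercept=False))
        lr = 2 * (free.loglik - null.loglik)
        assert var > 0
        assert p == pytest.approx(0.5 * stats.chi2.sf(lr, 1), rel=1e-6)

    def test_power_under_family_variance(self):
        # 30 families x 20 offspring, family_sd = 1: detected in most runs
        truth = synthetic.ExperimentTruth(
            populations=(("A", 56.0, 16.0),), family_sd=1.0,
            families_per_population=30, offspring_per_family_per_treatment=4,
            daylengths=(14.5, 15.5, 16.0, 16.5, 17.5), mortality_rate=0.0,
        )
        spec = ModelSpec(frozenset({"daylength", "population"}))
        hits = 0
        n_runs = 40
        for s in range(n_runs):
            scored = simulate_scored(truth, seed=100 + s)
            _, p = random_effect_lrt(scored, spec)
            hits += p < 0.05
        assert hits >= int(0.8 * n_runs)

    def test_requires_random_intercept_in_spec(self, eastern_scored):
        with pytest.raises(ValueError):
            random_effect_lrt(
                eastern_scored,
                ModelSpec(frozenset({"daylength", "population"}), random_intercept=False),
            )


def test_detect_separation_cases():
    sep = scored_frame([("A", "F1", d, "cold", int(d <= 15.5)) for d in (14.5, 15.5, 16.5)])
    assert detect_separation(sep)["A"]
    overlap = scored_frame(
        [("A", "F1", 15.0, "cold", 1), ("A", "F1", 15.0, "cold", 0),
         ("A", "F1", 16.0, "cold", 1), ("A", "F1", 16.0, "cold", 0)]
    )
    assert not detect_separation(overlap)["A"]
    one_class = scored_frame([("A", "F1", 15.0, "cold", 1), ("A", "F1", 16.0, "cold", 1)])
    assert detect_separation(one_class)["A"]
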