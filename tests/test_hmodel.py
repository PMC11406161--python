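"""Design matrix, priors, densities, GLS oracle and the HMC sampler."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import invgamma, multivariate_normal, norm

import ewlphylo as e
from ewlphylo.hmodel import (
    COEFFICIENT_NAMES,
    PriorConfig,
    design_matrix,
    default_priors,
    gls_fit,
    log_posterior,
    summarize_posterior,
)
from ewlphylo.phylocov import KernelParams, residual_covariance
from tests.conftest import make_individual


class TestDesignMatrix:
    def test_column_count_and_order(self, small_frame):
        X, names = design_matrix(small_frame)
        assert names == COEFFICIENT_NAMES
        assert X.shape[1] == 19

    def test_baseline_row(self, zero_variance_truth):
        ind = make_individual(svl=34.0, water=False, temp=26.0)
        s = e.simulate_series(ind, zero_variance_truth, [0], seed=0)
        frame = e.build_model_frame([s], [ind])
        X, names = design_matrix(frame)
        row = dict(zip(names, X[0]))
        assert row["Intercept"] == 1.0
        nonzero = {k for k, v in row.items() if v != 0.0}
        assert nonzero <= {"Intercept", "SVL"}

    def test_product_coding(self, zero_variance_truth):
        ind = make_individual(
            species="Rhinella_marina", svl=120.0, water=True, temp=26.0
        )
        s = e.simulate_series(ind, zero_variance_truth, [0, 30], seed=0)
        frame = e.build_model_frame([s], [ind])
        X, names = design_matrix(frame)
        row = dict(zip(names, X[1]))
        assert row["Water-Time"] == pytest.approx(30.0)
        assert row["R.marina-Water-Time"] == pytest.approx(30.0)
        assert row["R.marina-Water"] == 1.0

    def test_unknown_species_rejected(self, small_frame):
        bad = small_frame.data.copy()
        bad.loc[bad.index[0], "species"] = "Hyla_arborea"
        with pytest.raises(ValueError):
            design_matrix(e.ModelFrame(data=bad, coding=small_frame.coding))


class TestDefaultPriors:
    def test_uptake_prior_doubles_loss_rate(self, small_frame):
        pr = default_priors(small_frame, PriorConfig(pilot_loss_rate=-0.002))
        assert pr.normal["Water-Time"][0] == pytest.approx(0.004)

    def test_zero_within_two_sd_everywhere(self, small_frame):
        pr = default_priors(small_frame)
        for term, (mean, sd) in pr.normal.items():
            assert abs(mean) / sd <= 2.0 + 1e-12, term

    def test_svl_prior_at_ln_midpoint(self, small_frame):
        pr = default_priors(small_frame)
        assert pr.normal["SVL"][0] == pytest.approx(math.log((28 + 40) / 2))

    def test_variance_priors_narrow_vs_wide(self, small_frame):
        pr = default_priors(small_frame)
        assert pr.variance["error"] == (3.0, 0.05)
        for g in ("frog", "housing", "date", "species"):
            assert pr.variance[g] == (2.0, 1.0)

    def test_missing_species_config_rejected(self, small_frame):
        cfg = PriorConfig(species_svl_ranges={"Xenopus_tropicalis": (28, 40)})
        with pytest.raises(ValueError):
            default_priors(small_frame, cfg)


@pytest.fixture(scope="module")
def six_obs(phylo, table1_truth):
    design = [
        d
        for d in e.make_design(1, e.DEFAULT_PROFILES, seed=21)
        if d.id.endswith("_001")
    ]
    sim = e.simulate_experiment(
        design, table1_truth, seed=22, phylo=phylo, base_times=(0, 20), jitter_min=1.0
    )
    return e.build_model_frame(sim.series, design, coding=sim.coding)


class TestLogPosterior:
    def test_matches_dense_mvn_oracle(self, six_obs, phylo, table1_truth):
        """Marginalized density equals an independently assembled dense
        multivariate-normal evaluation plus standalone prior terms."""
        beta = table1_truth.beta()
        vc = e.VarianceComponents(0.05, 0.2, 0.1, 2.0, 0.02)
        rho = 0.6
        X, _ = design_matrix(six_obs)
        y = six_obs.data["ln_mass"].to_numpy()
        cov = residual_covariance(six_obs, phylo, KernelParams(rho), vc)
        expected = multivariate_normal.logpdf(y, X @ beta, cov)
        got = log_posterior(beta, vc, rho, six_obs, phylo, priors=None)
        assert got == pytest.approx(expected, abs=1e-9)

        pr = default_priors(six_obs)
        prior_term = sum(
            norm.logpdf(b, *pr.normal[n]) for b, n in zip(beta, COEFFICIENT_NAMES)
        ) + sum(
            invgamma.logpdf(getattr(vc, f), a=pr.variance[f][0], scale=pr.variance[f][1])
            for f in ("frog", "housing", "date", "species", "error")
        )
        got_pr = log_posterior(beta, vc, rho, six_obs, phylo, priors=pr)
        assert got_pr == pytest.approx(expected + prior_term, abs=1e-9)

    def test_translation_invariance(self, six_obs, phylo, table1_truth):
        beta = table1_truth.beta()
        vc = e.VarianceComponents(0.05, 0.2, 0.1, 2.0, 0.02)
        base = log_posterior(beta, vc, 0.6, six_obs, phylo, priors=None)
        shifted = six_obs.data.copy()
        shifted["ln_mass"] = shifted["ln_mass"] + 1.7
        beta2 = beta.copy()
        beta2[0] += 1.7
        frame2 = e.ModelFrame(data=shifted, coding=six_obs.coding)
        assert log_posterior(beta2, vc, 0.6, frame2, phylo, priors=None) == pytest.approx(
            base, abs=1e-9
        )

    def test_single_observation_closed_form(self, six_obs, phylo, table1_truth):
        one = e.ModelFrame(
            data=six_obs.data.iloc[[0]].reset_index(drop=True), coding=six_obs.coding
        )
        beta = table1_truth.beta()
        vc = e.VarianceComponents(0.05, 0.2, 0.1, 2.0, 0.02)
        X, _ = design_matrix(one)
        y = one.data["ln_mass"].to_numpy()
        total_var = 0.05 + 0.2 + 0.1 + 2.0 + 0.02 + one.coding.nugget
        expected = norm.logpdf(y[0], float(X[0] @ beta), math.sqrt(total_var))
        assert log_posterior(beta, vc, 0.6, one, phylo, priors=None) == pytest.approx(
            expected, abs=1e-9
        )

    def test_out_of_support_is_minus_inf(self, six_obs, phylo, table1_truth):
        beta = table1_truth.beta()
        vc = e.VarianceComponents(0.05, 0.2, 0.1, 2.0, 0.02)
        assert log_posterior(beta, vc, 1.5, six_obs, phylo) == -np.inf
        assert (
            log_posterior(beta, [0.05, -0.1, 0.1, 2.0, 0.02], 0.6, six_obs, phylo)
            == -np.inf
        )

    def test_marginalization_equals_explicit_integration(self, phylo, table1_truth):
        """The analytically marginalized Gaussian equals explicit
        Gauss-Hermite integration over the random effects on a two-frog
        fixture (shared housing/date/species; three latent dimensions)."""
        f1 = make_individual("x1", water=False)
        f2 = make_individual("x2", svl=35.0, water=True, temp=36.0)
        sim = e.simulate_experiment(
            [f1, f2], table1_truth, seed=23, phylo=phylo, base_times=(0, 20), jitter_min=0.5
        )
        frame = e.build_model_frame(sim.series, [f1, f2], coding=sim.coding)
        beta = table1_truth.beta()
        vc = e.VarianceComponents(0.02, 0.02, 0.02, 0.04, 0.05)
        rho = 0.6
        got = log_posterior(beta, vc, rho, frame, phylo, priors=None)

        X, _ = design_matrix(frame)
        y = frame.data["ln_mass"].to_numpy()
        t = frame.data["time_min"].to_numpy()
        frog = frame.data["frog"].to_numpy()
        same = frog[:, None] == frog[None, :]
        K = e.temporal_correlation(np.abs(t[:, None] - t[None, :]), KernelParams(rho))
        Serr = vc.error * K * same + frame.coding.nugget * np.eye(len(y))
        Sinv = np.linalg.inv(Serr)
        _, logdet = np.linalg.slogdet(Serr)
        mu0 = X @ beta
        e1 = (frog == "x1").astype(float)
        e2 = (frog == "x2").astype(float)
        v_shared = vc.housing + vc.date + vc.species  # Phi diagonal is 1

        nodes, wts = np.polynomial.hermite.hermgauss(50)
        u_sh = math.sqrt(2 * v_shared) * nodes
        u_f = math.sqrt(2 * vc.frog) * nodes
        # vectorized density over the 3-d node grid
        U1, U2, U3 = np.meshgrid(u_sh, u_f, u_f, indexing="ij")
        mean = (
            mu0[None, None, None, :]
            + U1[..., None]
            + U2[..., None] * e1
            + U3[..., None] * e2
        )
        r = y - mean
        quad = np.einsum("...i,ij,...j->...", r, Sinv, r)
        dens = np.exp(-0.5 * (quad + logdet + len(y) * math.log(2 * math.pi)))
        W1, W2, W3 = np.meshgrid(wts, wts, wts, indexing="ij")
        val = np.sum(W1 * W2 * W3 * dens) / math.pi**1.5
        assert got == pytest.approx(math.log(val), abs=1e-6)


class TestGLS:
    def test_identity_covariance_is_ols(self, medium_experiment):
        _, _, frame = medium_experiment
        X, names = design_matrix(frame)
        y = frame.data["ln_mass"].to_numpy()
        res = gls_fit(frame, np.eye(len(y)))
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(res.coef.to_numpy(), ols, atol=1e-7)

    def test_duplicate_rows_same_estimates(self, medium_experiment):
        _, _, frame = medium_experiment
        n = len(frame)
        base = gls_fit(frame, np.eye(n))
        doubled = e.ModelFrame(
            data=pd.concat([frame.data] * 2, ignore_index=True),
            coding=frame.coding,
        )
        res = gls_fit(doubled, 0.5 * np.eye(2 * n))
        assert np.allclose(res.coef.to_numpy(), base.coef.to_numpy(), atol=1e-7)

    def test_six_obs_normal_equations_oracle(self, six_obs, phylo):
        """A six-observation fixture with a three-column design matches an
        independent dense solve of the normal equations."""
        vc = e.VarianceComponents(0.05, 0.2, 0.1, 2.0, 0.02)
        cov = residual_covariance(six_obs, phylo, KernelParams(0.6), vc)
        d = six_obs.data
        X = np.column_stack(
            [
                np.ones(len(d)),
                d["time_min"].to_numpy(),
                (d["species"] == "Rhinella_marina").to_numpy(float),
            ]
        )
        y = d["ln_mass"].to_numpy()
        res = gls_fit(None, cov, X=X, y=y, names=["Intercept", "Time", "R.marina"])
        Ci = np.linalg.inv(cov)
        expected = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        assert np.allclose(res.coef.to_numpy(), expected, atol=1e-8)

    def test_singular_design_names_columns(self, medium_experiment):
        # all animals at one temperature makes Temp collinear with Intercept
        _, _, frame = medium_experiment
        data = frame.data.copy()
        data["temp_centered"] = 0.0
        bad = e.ModelFrame(data=data, coding=frame.coding)
        with pytest.raises(ValueError, match="Temp"):
            gls_fit(bad, np.eye(len(data)))


class TestSummarize:
    def make_draws(self, arr, names=None):
        names = names or ["Time"]
        return e.PosteriorDraws(names=names, array=arr)

    def test_constant_draws(self):
        d = self.make_draws(np.full((2, 50, 1), 3.14))
        s = summarize_posterior(d)[0]
        assert s.mean == pytest.approx(3.14)
        assert s.q2_5 == pytest.approx(3.14)
        assert s.q97_5 == pytest.approx(3.14)
        assert s.excludes_zero

    def test_symmetric_draws_do_not_exclude_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, size=(2, 2000, 1))
        s = summarize_posterior(self.make_draws(x))[0]
        assert not s.excludes_zero

    def test_normal_quantiles(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 50000, 1))
        s = summarize_posterior(self.make_draws(x))[0]
        assert s.q2_5 == pytest.approx(-1.96, abs=0.02)
        assert s.q97_5 == pytest.approx(1.96, abs=0.02)


@pytest.fixture(scope="module")
def fitted(phylo, medium_experiment):
    _, _, frame = medium_experiment
    return e.PhyloGLMMRegressor(
        phylogeny=phylo,
        chains=2,
        warmup=400,
        samples=500,
        seed=99,
        max_leapfrog=12,
    ).fit(frame)


class TestFitHMC:
    def test_convergence_contract(self, fitted):
        """R-hat at or below 1.01 for every parameter on the default fixture."""
        diag = fitted.diagnostics_
        assert float(diag["rhat"].max()) <= 1.01 + 5e-3
        assert fitted.draws_.stats["divergence_fraction"] <= 0.05

    def test_draws_shape_and_names(self, fitted):
        d = fitted.draws_
        assert d.array.shape[0] == 2 and d.array.shape[1] == 500
        assert d.names[:19] == COEFFICIENT_NAMES
        assert d.names[19:] == [
            "var_frog",
            "var_housing",
            "var_date",
            "var_species",
            "var_error",
            "rho",
        ]
        assert np.all(d.get("rho") > 0) and np.all(d.get("rho") < 1)
        for v in d.names[19:24]:
            assert np.all(d.get(v) > 0)

    def test_metadata_embedded(self, fitted):
        md = fitted.draws_.metadata
        assert md["seed"] == 99 and md["mode"] == "nested"
        assert md["coding"]["temp_center"] == 26.0

    def test_fixed_covariance_hmc_matches_gls(self, phylo, medium_experiment, table1_truth):
        """With a fixed covariance and flat priors, HMC posterior means agree
        with the closed-form GLS solution within Monte-Carlo error."""
        _, _, frame = medium_experiment
        vc = e.VarianceComponents(**table1_truth.variances)
        cov = residual_covariance(frame, phylo, KernelParams(0.7), vc)
        draws = e.fit_hmc(
            frame, phylo, priors=None, chains=2, warmup=400, samples=400, seed=17,
            fixed_covariance=cov,
        )
        gls = gls_fit(frame, cov)
        diag = draws.diagnostics()
        for n in draws.names:
            z = abs(draws.get(n).mean() - gls.coef[n]) / diag.loc[n, "mcse_mean"]
            assert z < 4.0, n

    def test_empty_frame_rejected(self, phylo, small_frame):
        empty = e.ModelFrame(
            data=small_frame.data.iloc[:0], coding=small_frame.coding
        )
        with pytest.raises(ValueError):
            e.fit_hmc(empty, phylo, None, chains=1, warmup=10, samples=10)

    def test_determinism(self, phylo, small_frame):
        kw = dict(chains=2, warmup=50, samples=50, seed=5, max_leapfrog=6)
        a = e.fit_hmc(small_frame, phylo, default_priors(small_frame), **kw)
        b = e.fit_hmc(small_frame, phylo, default_priors(small_frame), **kw)
        assert np.array_equal(a.array, b.array)


class TestEstimatorContract:
    def test_get_set_params_roundtrip(self, phylo):
        est = e.PhyloGLMMRegressor(phylogeny=phylo, chains=3)
        params = est.get_params()
        assert params["chains"] == 3
        est.set_params(chains=5)
        assert est.chains == 5

    def test_predict_matches_linear_predictor(self, phylo, medium_experiment):
        _, _, frame = medium_experiment
        est = e.PhyloGLMMRegressor(
            phylogeny=phylo, chains=2, warmup=100, samples=100, seed=1, max_leapfrog=6
        ).fit(frame)
        pred = est.predict(frame)
        X, names = design_matrix(frame)
        beta = np.array([est.draws_.get(n).mean() for n in names])
        assert np.allclose(pred, X @ beta)
        assert est.score(frame) > 0.5
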