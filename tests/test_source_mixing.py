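import numpy as np
import pandas as pd
import pytest

import isotroph as it
from isotroph.data_io import AAMatrix
from isotroph.errors import ConfigurationError, DomainError, ValidationError
from isotroph.fingerprinting import mean_center
from isotroph.source_mixing import (
    MCMCSettings,
    MixingModelSpec,
    MixingPosterior,
    build_spec,
    effective_sample_size,
    fit_mixing_model,
    gelman_rubin,
    ilr,
    ilr_inv,
    least_squares_simplex,
    summarize_posterior,
)


def _toy_spec(mu, y, cells=1, sigma=None, alpha=(1.0, 1.0, 1.0), **kw):
    """Hand-built 3-source spec over J tracers for controlled sampler tests."""
    mu = np.asarray(mu, dtype=float)
    y = np.asarray(y, dtype=float)
    K, J = mu.shape
    sigma = np.full((K, J), 0.5) if sigma is None else np.asarray(sigma, float)
    return MixingModelSpec(
        sources=["plant", "bacteria", "fungi"][:K],
        tracers=tuple("t%d" % j for j in range(J)),
        mu=mu,
        sigma=sigma,
        cells=[("sp", f"cell{c}") for c in range(cells)],
        y=y,
        cell_index=np.zeros(len(y), dtype=int),
        prior_alpha=np.asarray(alpha, float),
        error_model=kw.pop("error_model", "source_plus_residual"),
        **kw,
    )


class TestILR:
    def test_round_trip(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet([2.0, 1.0, 3.0], size=50)
        assert np.allclose(ilr_inv(ilr(p), 3), p, atol=1e-12)

    def test_inverse_lands_on_simplex(self):
        rng = np.random.default_rng(1)
        z = rng.normal(0, 5, (100, 2))
        p = ilr_inv(z, 3)
        assert (p > 0).all()
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_scikit_bio(self):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        rng = np.random.default_rng(2)
        p = rng.dirichlet([1.0, 1.0, 1.0], size=20)
        ours = ilr(p)
        theirs = skbio_comp.ilr(p)
        # both are isometries; bases may differ by an orthogonal map, so
        # compare pairwise distances, which any ILR basis preserves
        def dists(X):
            return np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
        assert np.allclose(dists(ours), dists(theirs), atol=1e-10)


class TestGelmanRubin:
    def test_same_distribution_chains_near_one(self):
        rng = np.random.default_rng(3)
        r = gelman_rubin(rng.standard_normal((4, 5000)))
        assert r.rhat < 1.01

    def test_shifted_chains_detected(self):
        rng = np.random.default_rng(4)
        chains = np.vstack([rng.normal(0, 1, 2000), rng.normal(3, 1, 2000)])
        assert gelman_rubin(chains).rhat > 1.05

    def test_constant_chains_degenerate(self):
        r = gelman_rubin(np.full((3, 100), 2.5))
        assert r.rhat == 1.0
        assert r.degenerate

    def test_within_chain_drift_detected(self):
        # split halves catch a trend even when full chains share a mean
        trend = np.linspace(-3, 3, 4000)
        rng = np.random.default_rng(5)
        chains = np.vstack([trend + rng.normal(0, 0.5, 4000),
                            trend + rng.normal(0, 0.5, 4000)])
        assert gelman_rubin(chains).rhat > 1.05

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(6)
        chains = rng.standard_normal((3, 1000)) + rng.normal(0, 0.2, (3, 1))
        ours = gelman_rubin(chains).rhat
        theirs = float(az.rhat(chains, method="split"))
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_too_few_chains_rejected(self):
        with pytest.raises(DomainError):
            gelman_rubin(np.zeros((1, 100)))


class TestEffectiveSampleSize:
    def test_iid_chains_near_total(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((4, 2000))
        ess = effective_sample_size(X)
        assert 0.7 * 8000 <= ess <= 1.3 * 8000

    def test_autocorrelated_chains_shrink(self):
        rng = np.random.default_rng(8)
        n, rho = 4000, 0.9
        chains = []
        for _ in range(3):
            x = np.empty(n)
            x[0] = rng.standard_normal()
            for t in range(1, n):
                x[t] = rho * x[t - 1] + np.sqrt(1 - rho ** 2) * rng.standard_normal()
            chains.append(x)
        ess = effective_sample_size(np.vstack(chains))
        # AR(1) tau = (1+rho)/(1-rho) = 19
        assert ess < 0.2 * 3 * n


class TestBuildSpec:
    def test_full_factorial_design_yields_twenty_cells(self, small_library):
        cfg = it.SyntheticConfig(seed=21, n_species=5, n_reps=2)
        bundle = it.simulate_study(cfg)
        centered = AAMatrix(mean_center(bundle.consumers_d13c.values),
                            bundle.consumers_d13c.meta.copy(), "C13")
        spec = build_spec(bundle.library, centered)
        assert spec.n_cells == 20  # 5 species x 4 litters

    def test_library_row_order_irrelevant(self, small_library, study_bundle):
        centered = AAMatrix(mean_center(study_bundle.consumers_d13c.values),
                            study_bundle.consumers_d13c.meta.copy(), "C13")
        s1 = build_spec(study_bundle.library, centered)
        shuffled = study_bundle.library
        perm = np.random.default_rng(9).permutation(len(shuffled.values))
        from isotroph.fingerprinting import SourceLibrary
        lib2 = SourceLibrary(shuffled.values.iloc[perm], shuffled.labels.iloc[perm])
        s2 = build_spec(lib2, centered)
        # class order follows first appearance, so compare per source
        for src in s1.sources:
            i, j = s1.sources.index(src), s2.sources.index(src)
            assert np.allclose(s1.mu[i], s2.mu[j], atol=1e-12)
            assert np.allclose(s1.sigma[i], s2.sigma[j], atol=1e-12)

    def test_single_specimen_class_impossible(self):
        from isotroph.fingerprinting import SourceLibrary
        values = pd.DataFrame(np.zeros((3, 5)),
                              columns=["Ile", "Leu", "Phe", "Thr", "Val"],
                              index=["a0", "b0", "c0"])
        with pytest.raises(ValidationError):
            SourceLibrary(values, pd.Series(["a", "b", "c"], index=values.index))

    def test_missing_tracer_rejected(self, study_bundle):
        centered = AAMatrix(mean_center(study_bundle.consumers_d13c.values),
                            study_bundle.consumers_d13c.meta.copy(), "C13")
        with pytest.raises(ValidationError, match="Met"):
            build_spec(study_bundle.library, centered, tracers=("Leu", "Met"))


class TestFitMixingModel:
    def test_consumers_at_plant_mean_recovered(self):
        rng = np.random.default_rng(10)
        mu = np.array([[-4.0, 2.0], [4.0, 2.0], [0.0, -5.0]])
        y = mu[0] + 0.1 * rng.standard_normal((20, 2))
        spec = _toy_spec(mu, y, sigma=np.full((3, 2), 0.1))
        post = fit_mixing_model(spec, MCMCSettings.fast(seed=1))
        s = summarize_posterior(post).set_index("source")
        assert s.loc["plant", "mean"] > 0.95

    def test_symmetric_sources_split_evenly(self):
        rng = np.random.default_rng(11)
        mu = np.array([[-3.0, 0.0], [3.0, 0.0], [0.0, 30.0]])
        y = 0.3 * rng.standard_normal((40, 2))   # centered between sources 1 and 2
        spec = _toy_spec(mu, y, sigma=np.full((3, 2), 0.3))
        post = fit_mixing_model(spec, MCMCSettings.fast(seed=2))
        s = summarize_posterior(post).set_index("source")
        assert s.loc["plant", "mean"] == pytest.approx(0.5, abs=0.05)
        assert s.loc["bacteria", "mean"] == pytest.approx(0.5, abs=0.05)
        assert s.loc["fungi", "mean"] < 0.02

    def test_unidentifiable_sources_return_prior(self):
        rng = np.random.default_rng(12)
        mu = np.zeros((3, 2))
        y = 0.5 * rng.standard_normal((10, 2))
        spec = _toy_spec(mu, y, sigma=np.full((3, 2), 0.5))
        with pytest.warns(UserWarning, match="unidentifiable"):
            post = fit_mixing_model(spec, MCMCSettings.fast(seed=3))
        s = summarize_posterior(post)
        # flat likelihood in p: posterior = Dirichlet(1,1,1) prior, mean 1/3
        assert np.allclose(s["mean"], 1.0 / 3.0, atol=0.03)

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(13)
        mu = np.array([[-3.0, 0.0], [3.0, 0.0], [0.0, 5.0]])
        y = 0.5 * rng.standard_normal((10, 2))
        settings = MCMCSettings(n_iter=3000, n_burnin=1500, thin=5, seed=7)
        p1 = fit_mixing_model(_toy_spec(mu, y), settings)
        p2 = fit_mixing_model(_toy_spec(mu, y), settings)
        assert np.array_equal(p1.p_draws, p2.p_draws)
        assert np.array_equal(p1.sigma_res_draws, p2.sigma_res_draws)

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(14)
        mu = np.array([[-4.0, 1.0], [3.0, 2.0], [0.0, -5.0]])
        y = mu[0] * 0.6 + mu[1] * 0.3 + mu[2] * 0.1 + 0.3 * rng.standard_normal((25, 2))
        post_a = fit_mixing_model(_toy_spec(mu, y), MCMCSettings.fast(seed=4))
        perm = [2, 0, 1]
        spec_b = _toy_spec(mu[perm], y)
        spec_b.sources = [post_a.spec.sources[i] for i in perm]
        post_b = fit_mixing_model(spec_b, MCMCSettings.fast(seed=5))
        sa = summarize_posterior(post_a).set_index("source")["mean"]
        sb = summarize_posterior(post_b).set_index("source")["mean"]
        for src in ("plant", "bacteria", "fungi"):
            assert sa[src] == pytest.approx(sb[src], abs=0.03)

    def test_single_chain_rejected(self):
        with pytest.raises(ConfigurationError):
            MCMCSettings(n_chains=1)

    def test_every_draw_on_simplex(self):
        rng = np.random.default_rng(15)
        mu = np.array([[-3.0, 0.0], [3.0, 0.0], [0.0, 5.0]])
        y = 0.5 * rng.standard_normal((10, 2))
        post = fit_mixing_model(_toy_spec(mu, y),
                                MCMCSettings(n_iter=3000, n_burnin=1500, thin=5, seed=8))
        flat = post.p_draws.reshape(-1, 3)
        assert (flat >= 0).all()
        assert np.allclose(flat.sum(axis=1), 1.0, atol=1e-12)


class TestZeroNoiseLimit:
    def test_posterior_concentrates_at_least_squares_solution(self):
        """With all SDs shrunk 100x the posterior pinpoints the LS simplex fit."""
        rng = np.random.default_rng(16)
        mu = np.array([[-4.0, 2.0, 1.0], [4.0, 2.0, -1.0], [0.0, -5.0, 0.5]])
        p_true = np.array([0.45, 0.35, 0.20])
        y = p_true @ mu + 0.4 * rng.standard_normal((15, 3))
        tiny = 0.4 / 100.0
        spec = _toy_spec(mu, y, sigma=np.full((3, 3), 0.005),
                         fixed_residual_sd=np.full(3, tiny))
        post = fit_mixing_model(spec, MCMCSettings.fast(seed=6))
        ls = least_squares_simplex(spec, 0, resolution=0.01)
        pm = summarize_posterior(post).set_index("source")["mean"]
        assert np.allclose(pm.to_numpy(), ls, atol=0.02)


class TestSummaries:
    def _dummy_posterior(self, draws):
        spec = _toy_spec(np.zeros((3, 2)), np.zeros((2, 2)))
        return MixingPosterior(
            spec=spec, settings=MCMCSettings(n_iter=200, n_burnin=100, seed=0),
            p_draws=draws, sigma_res_draws=np.ones((draws.shape[0], draws.shape[1], 2)),
            acceptance={}, diagnostics=pd.DataFrame(), converged=True,
        )

    def test_degenerate_posterior_collapses(self):
        # binary-exact proportions so the constant draws summarize exactly
        draws = np.tile(np.array([0.25, 0.5, 0.25]), (2, 50, 1, 1))
        s = summarize_posterior(self._dummy_posterior(draws))
        assert (s["sd"] == 0).all()
        assert (s["cri_low"] == s["cri_high"]).all()
        assert s["mean"].tolist() == pytest.approx([0.25, 0.5, 0.25])

    def test_means_sum_to_one_and_match_draws(self):
        rng = np.random.default_rng(17)
        raw = rng.dirichlet([2, 3, 4], size=(3, 40, 1))
        s = summarize_posterior(self._dummy_posterior(raw))
        assert s.groupby(["species", "litter_treatment"])["mean"].sum().iloc[0] == (
            pytest.approx(1.0, abs=1e-12))
        assert s["mean"].to_numpy() == pytest.approx(
            raw.reshape(-1, 3).mean(axis=0), abs=1e-12)

    def test_narrow_interval_nested_in_wide(self):
        rng = np.random.default_rng(18)
        raw = rng.dirichlet([2, 3, 4], size=(3, 200, 1))
        post = self._dummy_posterior(raw)
        s95 = summarize_posterior(post, level=0.95)
        s50 = summarize_posterior(post, level=0.50)
        assert (s50["cri_low"] >= s95["cri_low"] - 1e-12).all()
        assert (s50["cri_high"] <= s95["cri_high"] + 1e-12).all()
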