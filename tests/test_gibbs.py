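import numpy as np
import pytest
from scipy import optimize, special

import mvbtrial as mvb


def _simulate(beta_true, n, seed, covariate="normal"):
    """Multinomial-logit data at known coefficients, model (1, T, z, zT)."""
    rng = np.random.default_rng(seed)
    T = np.repeat([0.0, 1.0], n // 2)
    z = (rng.standard_normal(n) if covariate == "normal"
         else rng.binomial(1, 0.5, n).astype(float))
    X = np.column_stack([np.ones(n), T, z, T * z])
    psi = np.column_stack([X @ beta_true.T, np.zeros(n)])
    phi = np.exp(psi - special.logsumexp(psi, axis=1, keepdims=True))
    u = rng.random(n)
    c = (u[:, None] > phi.cumsum(axis=1)).sum(axis=1)
    return X, np.minimum(c, beta_true.shape[0]).astype(np.int64)


BETA = np.array([[0.3, 0.4, 0.2, -0.3],
                 [-0.2, 0.1, -0.1, 0.2],
                 [0.1, -0.3, 0.3, 0.1]])


@pytest.fixture(scope="module")
def big_fit():
    X, c = _simulate(BETA, 4000, seed=11)
    sample = mvb.fit_mlr(X, c, mvb.config_matrix(2),
                         settings=mvb.GibbsSettings(iterations=800, burnin=200,
                                                    chains=2, seed=5))
    return X, c, sample


class TestRecovery:
    def test_posterior_mean_near_truth(self, big_fit):
        _, _, sample = big_fit
        post = sample.stacked()
        err = np.abs(post.mean(axis=0) - BETA)
        assert (err < 3.5 * post.std(axis=0)).all()

    def test_agreement_with_maximum_likelihood(self, big_fit):
        """Diffuse prior + large n: posterior mean matches a numerically
        maximized multinomial-logit likelihood (independent oracle)."""
        X, c, sample = big_fit

        def negll(flat):
            beta = flat.reshape(3, 4)
            psi = np.column_stack([X @ beta.T, np.zeros(len(X))])
            return -(psi[np.arange(len(X)), c] - special.logsumexp(psi, axis=1)).sum()

        res = optimize.minimize(negll, np.zeros(12), method="BFGS")
        assert res.success or np.linalg.norm(res.jac) < 1e-3
        mle = res.x.reshape(3, 4)
        post_mean = sample.stacked().mean(axis=0)
        post_sd = sample.stacked().std(axis=0)
        # MC error of the mean plus O(1/n) prior/curvature effects
        assert np.abs(post_mean - mle).max() < np.maximum(0.35 * post_sd, 0.02).max()

    def test_posterior_contraction(self):
        settings = mvb.GibbsSettings(iterations=400, burnin=150, chains=1, seed=2)
        sds = []
        for n in (500, 5000):
            X, c = _simulate(BETA, n, seed=13)
            s = mvb.fit_mlr(X, c, mvb.config_matrix(2), settings=settings)
            sds.append(s.stacked().std(axis=0))
        assert (sds[1] < sds[0]).all()


class TestUnivariateSpecialCase:
    def test_matches_mlr_with_K1(self):
        X, c = _simulate(BETA, 400, seed=3)
        y = (c != 3).astype(int)  # arbitrary binary recoding
        settings = mvb.GibbsSettings(iterations=300, burnin=100, chains=1, seed=8)
        a = mvb.fit_ulr(X, y, settings=settings)
        c_bin = np.where(y == 1, 0, 1)
        b = mvb.fit_mlr(X, c_bin, mvb.config_matrix(1), settings=settings)
        assert (a.draws == b.draws).all()

    def test_matches_statsmodels_logit(self):
        """Cross-implementation oracle: posterior mean vs the frequentist
        MLE from statsmodels on the same data (diffuse prior, large n)."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(21)
        n = 3000
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        p = special.expit(0.4 + 0.8 * x)
        y = rng.binomial(1, p)
        fit = sm.Logit(y, X).fit(disp=0)
        sample = mvb.fit_ulr(X, y, settings=mvb.GibbsSettings(
            iterations=1000, burnin=200, chains=1, seed=4))
        post_mean = sample.stacked().mean(axis=0)[0]
        assert np.abs(post_mean - fit.params).max() < 3 * np.abs(fit.bse).max() / 10 + 0.02

    def test_separable_data_stays_finite(self):
        X = np.column_stack([np.ones(4), np.array([-2.0, -1.0, 1.0, 2.0])])
        y = np.array([0, 0, 1, 1])  # perfectly separable
        s = mvb.fit_ulr(X, y, settings=mvb.GibbsSettings(
            iterations=500, burnin=100, chains=1, seed=1))
        assert np.isfinite(s.draws).all()

    def test_intercept_only_concentrates_at_rate(self):
        rng = np.random.default_rng(6)
        y = rng.binomial(1, 0.3, 2000)
        X = np.ones((2000, 1))
        s = mvb.fit_ulr(X, y, settings=mvb.GibbsSettings(
            iterations=800, burnin=200, chains=1, seed=7))
        p_draws = special.expit(s.stacked()[:, 0, 0])
        assert p_draws.mean() == pytest.approx(y.mean(), abs=0.03)


class TestPriorBehaviour:
    def test_prior_pullback_with_minimal_data(self):
        # 6 subjects, informative prior at zero: posterior hugs the prior
        X, c = _simulate(BETA, 6, seed=9)
        s = mvb.fit_mlr(X, c, mvb.config_matrix(2),
                        prior=mvb.PriorSpec(mean=0.0, variance=0.05),
                        settings=mvb.GibbsSettings(iterations=400, burnin=100,
                                                   chains=1, seed=3))
        assert np.abs(s.stacked().mean(axis=0)).max() < 0.5

    def test_invalid_prior_covariance(self):
        with pytest.raises(ValueError):
            mvb.PriorSpec(variance=np.array([[1.0, 2.0], [2.0, 1.0]])
                          ).precision_array(1, 2)


class TestDeterminismAndOrder:
    def test_same_seed_bit_identical(self):
        X, c = _simulate(BETA, 300, seed=1)
        settings = mvb.GibbsSettings(iterations=200, burnin=50, chains=2, seed=42)
        a = mvb.fit_mlr(X, c, mvb.config_matrix(2), settings=settings)
        b = mvb.fit_mlr(X, c, mvb.config_matrix(2), settings=settings)
        assert (a.draws == b.draws).all()

    def test_outcome_permutation_permutes_blocks(self):
        """Swapping the two outcome columns relabels categories 2 and 3
        (patterns 10 and 01); posterior summaries must agree within MC
        error after the corresponding block swap."""
        dgm = mvb.preset("ES3", covariate="binary", rho=0.2, n_per_arm=600, seed=44)
        data, _ = mvb.generate(dgm)
        H = mvb.config_matrix(2)
        settings = mvb.GibbsSettings(iterations=600, burnin=200, chains=1, seed=10)
        spec = dgm.model_spec()
        design = mvb.build_design(data, spec)
        c12 = mvb.encode_responses(data[["y1", "y2"]].to_numpy(), H)
        c21 = mvb.encode_responses(data[["y2", "y1"]].to_numpy(), H)
        m12 = mvb.fit_mlr(design, c12, H, settings=settings).stacked().mean(axis=0)
        m21 = mvb.fit_mlr(design, c21, H, settings=settings).stacked().mean(axis=0)
        np.testing.assert_allclose(m12[[0, 1, 2]], m21[[0, 2, 1]], atol=0.12)


class TestGelmanRubin:
    def _sample_from(self, draws):
        return mvb.PosteriorSample(draws=draws, H=mvb.config_matrix(1),
                                   spec=None, prior=mvb.PriorSpec(),
                                   settings=mvb.GibbsSettings(iterations=draws.shape[1],
                                                              chains=draws.shape[0]))

    def test_identical_chains_give_unity(self):
        rng = np.random.default_rng(0)
        one = rng.standard_normal((1, 500, 1, 2))
        d = mvb.gelman_rubin(self._sample_from(np.repeat(one, 2, axis=0)))
        # zero between-chain variance: estimate is sqrt((n-1)/n), just below 1
        assert d["mpsrf"] == pytest.approx(1.0, abs=2e-3)
        assert np.allclose(d["psrf"], 1.0, atol=2e-3)

    def test_shifted_chains_diverge(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((500, 1, 2))
        d = mvb.gelman_rubin(self._sample_from(np.stack([a, a + 5.0])))
        assert d["mpsrf"] > 2.0 and d["psrf"].min() > 2.0

    def test_well_mixed_fit_converges(self, es3_binary_fit):
        d = mvb.gelman_rubin(es3_binary_fit["sample"])
        assert d["mpsrf"] <= 1.10

    def test_single_chain_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            mvb.gelman_rubin(self._sample_from(rng.standard_normal((1, 100, 1, 2))))

    def test_psrf_matches_arviz(self):
        """Classic split-free PSRF against arviz's rank-normalized rhat —
        they agree to ~1% on stationary chains."""
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        draws = rng.standard_normal((2, 800, 1, 3))
        draws[1] += 0.15  # mild disagreement
        d = mvb.gelman_rubin(self._sample_from(draws))
        ref = az.rhat(az.convert_to_dataset(draws.reshape(2, 800, 3)))
        ref_vals = np.asarray(ref.to_array()).ravel()
        np.testing.assert_allclose(d["psrf"].ravel(), ref_vals, atol=0.02)
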