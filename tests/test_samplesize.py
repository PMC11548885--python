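import numpy as np
import pytest
from scipy import stats

import mvbtrial as mvb


def _req(rule, **kw):
    base = dict(theta1=[0.6, 0.55], theta0=[0.5, 0.5], corr=0.0,
                alpha=0.05, power=0.80)
    base.update(kw)
    return mvb.PowerRequest(rule=rule, **base)


class TestCompensatoryClosedForm:
    def test_reference_case_303(self):
        # theta_w 0.6 vs 0.5, alpha 0.05 right-sided, power 0.80
        res = mvb.required_n_compensatory(
            _req("compensatory", theta1=[0.6, 0.6], theta0=[0.5, 0.5],
                 weights=[0.5, 0.5]))
        assert res.n_per_arm == 303

    def test_independent_evaluation(self):
        """Closed form against a from-scratch evaluation with quantiles
        taken straight from scipy."""
        t1w, t0w = 0.6, 0.5
        za, zb = stats.norm.ppf(0.95), stats.norm.ppf(0.80)
        n = np.ceil((t1w * 0.4 + t0w * 0.5) * ((za + zb) / 0.1) ** 2)
        res = mvb.required_n_compensatory(
            _req("compensatory", theta1=[0.6, 0.6], theta0=[0.5, 0.5],
                 weights=[0.5, 0.5]))
        assert res.n_per_arm == int(n)

    def test_inverse_square_in_effect(self):
        n_small = mvb.required_n_compensatory(
            _req("compensatory", theta1=[0.55, 0.55], weights=[0.5, 0.5],
                 theta0=[0.5, 0.5])).n_per_arm
        n_big = mvb.required_n_compensatory(
            _req("compensatory", theta1=[0.6, 0.6], weights=[0.5, 0.5],
                 theta0=[0.5, 0.5])).n_per_arm
        assert n_small / n_big == pytest.approx(4.0, rel=0.05)

    def test_degenerate_weight_reduces_to_univariate(self):
        multi = mvb.required_n_compensatory(
            _req("compensatory", weights=[1.0, 0.0]))
        uni = mvb.required_n_compensatory(
            mvb.PowerRequest(rule="compensatory", theta1=[0.6], theta0=[0.5],
                             weights=[1.0]))
        assert multi.n_per_arm == uni.n_per_arm

    def test_permutation_invariance(self):
        a = mvb.required_n_compensatory(
            _req("compensatory", theta1=[0.6, 0.7], theta0=[0.5, 0.55],
                 weights=[0.3, 0.7]))
        b = mvb.required_n_compensatory(
            _req("compensatory", theta1=[0.7, 0.6], theta0=[0.55, 0.5],
                 weights=[0.7, 0.3]))
        assert a.n_per_arm == b.n_per_arm

    def test_null_effect_rejected(self):
        with pytest.raises(ValueError):
            mvb.required_n_compensatory(
                _req("compensatory", theta1=[0.5, 0.5], weights=[0.5, 0.5]))


class TestAnalyticPower:
    def test_k1_collapse_to_univariate_formula(self):
        """With one endpoint, Any and All coincide and equal the standard
        two-proportion normal-approximation power."""
        req = mvb.PowerRequest(rule="any", theta1=[0.6], theta0=[0.5])
        n = 250
        se = np.sqrt(0.6 * 0.4 + 0.5 * 0.5) / np.sqrt(n)
        closed = stats.norm.cdf(0.1 / se - stats.norm.ppf(0.95))
        assert mvb.analytic_power("any", n, req) == pytest.approx(closed, abs=1e-9)
        assert mvb.analytic_power("all", n, req) == pytest.approx(closed, abs=1e-9)

    def test_monotone_in_n(self):
        req = _req("any")
        powers = [mvb.analytic_power("any", n, req) for n in (50, 100, 200, 400, 800)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_correlation_directions(self):
        """All rule gains from positive outcome correlation; Any and
        Compensatory gain from negative correlation."""
        n_all = {r: mvb.required_n_iterative("all", _req("all", corr=r)).n_per_arm
                 for r in (-0.4, 0.0, 0.4)}
        n_any = {r: mvb.required_n_iterative("any", _req("any", corr=r)).n_per_arm
                 for r in (-0.4, 0.0, 0.4)}
        assert n_all[0.4] <= n_all[0.0] <= n_all[-0.4]
        assert n_any[-0.4] < n_any[0.0] < n_any[0.4]

    def test_invalid_correlation_matrix(self):
        with pytest.raises(ValueError):
            _req("any", corr=np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestIterativeSearch:
    def test_minimal_integer(self):
        req = _req("any", corr=0.2)
        res = mvb.required_n_iterative("any", req)
        assert mvb.analytic_power("any", res.n_per_arm, req) >= 0.80
        assert mvb.analytic_power("any", res.n_per_arm - 1, req) < 0.80

    def test_equivalent_to_stepwise(self):
        """Bracketing + binary search returns the same n as literally
        stepping n upward by one."""
        req = _req("all", corr=-0.2, theta1=[0.65, 0.6], theta0=[0.5, 0.5])
        res = mvb.required_n_iterative("all", req)
        n = 2
        while mvb.analytic_power("all", n, req) < req.power:
            n += 1
        assert res.n_per_arm == n

    def test_doubling_effect_reduces_n(self):
        small = mvb.required_n_iterative("any", _req("any"))
        big = mvb.required_n_iterative(
            "any", _req("any", theta1=[0.7, 0.6], theta0=[0.5, 0.5]))
        assert big.n_per_arm < small.n_per_arm

    def test_all_harder_than_worst_endpoint(self):
        """Under the All rule, a second endpoint can only increase n
        relative to its hardest single endpoint."""
        joint = mvb.required_n_iterative("all", _req("all", corr=0.0))
        worst = mvb.required_n_iterative(
            "all", mvb.PowerRequest(rule="all", theta1=[0.55], theta0=[0.5]))
        assert joint.n_per_arm >= worst.n_per_arm

    def test_null_effect_error(self):
        with pytest.raises(ValueError):
            mvb.required_n_iterative("any", mvb.PowerRequest(
                rule="any", theta1=[0.5, 0.5], theta0=[0.5, 0.5]))


class TestMonteCarloVerification:
    @pytest.mark.parametrize("rule", ["any", "all"])
    def test_simulated_power_matches_analytic(self, rule):
        """Full-pipeline Monte-Carlo power at the computed n stays within
        [target-0.04, target+0.06] (Dirichlet estimator, 2000 reps)."""
        theta1, theta0, rho = np.array([0.62, 0.58]), np.array([0.5, 0.5]), 0.2
        req = mvb.PowerRequest(rule=rule, theta1=theta1, theta0=theta0, corr=rho)
        n = mvb.required_n(req).n_per_arm
        # homogeneous cells: same margins at both anchors
        theta_cells = np.empty((2, 2, 2))
        theta_cells[0, :] = theta0
        theta_cells[1, :] = theta1
        cells = mvb.CellSpec(theta=theta_cells, rho=rho)
        dgm = mvb.DGMSpec(cells=cells, covariate="binary", n_per_arm=n)
        rule_spec = mvb.DecisionRuleSpec(rule=rule, K=2)
        scn = mvb.Scenario(dgm=dgm, method="mb", rules=(rule_spec,))
        tab = mvb.run_scenario(scn, reps=2000, master_seed=99)
        assert 0.76 <= tab.prop_superior.iloc[0] <= 0.86

    def test_compensatory_n_is_conservative(self):
        """The weighted-margin closed form treats w.y as Bernoulli, whose
        variance bounds the true weighted-sum variance from above, so the
        returned n over-powers (exact only at perfect positive
        correlation)."""
        theta1, theta0 = np.array([0.6, 0.55]), np.array([0.5, 0.5])
        w = [0.75, 0.25]
        req = mvb.PowerRequest(rule="compensatory", theta1=theta1,
                               theta0=theta0, corr=0.2, weights=w)
        n = mvb.required_n(req).n_per_arm
        theta_cells = np.empty((2, 2, 2))
        theta_cells[0, :] = theta0
        theta_cells[1, :] = theta1
        dgm = mvb.DGMSpec(cells=mvb.CellSpec(theta=theta_cells, rho=0.2),
                          covariate="binary", n_per_arm=n)
        rule_spec = mvb.DecisionRuleSpec(rule="compensatory", weights=w)
        tab = mvb.run_scenario(mvb.Scenario(dgm=dgm, method="mb",
                                            rules=(rule_spec,)),
                               reps=1500, master_seed=98)
        assert tab.prop_superior.iloc[0] >= 0.78
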