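"""A priori per-arm sample sizes for the Any, All and Compensatory rules.

The Any/All rules use the large-sample multivariate-normal approximation
of the endpoint-wise test statistics: with per-arm size n, effect
delta_k = theta_1k - theta_0k and pooled binomial standard error
SE_k = sqrt(theta_1k(1-theta_1k) + theta_0k(1-theta_0k)) / sqrt(n),

* All rule:  power = Psi_K(c_1..c_K),   c_k = -z(1-alpha) + delta_k / SE_k,
* Any rule:  power = 1 - Psi_K(c_1..c_K), c_k = z(1-alpha/K) - delta_k / SE_k,

where Psi_K is the zero-mean multivariate-normal CDF with correlation
matrix Sigma (the correlation between endpoint-wise statistics, taken
equal to the user-supplied outcome correlation). For the Any rule the
rectangle Psi_K(c) is the probability that *no* endpoint rejects, i.e.
the type II error, hence the complement. The smallest integer n meeting
the target power is found by geometric bracketing plus binary search —
equivalent to stepping n upward by 1, just faster.

The Compensatory rule reduces to a single weighted proportion per arm
(theta_Tw = sum w_k theta_Tk), so n has the standard two-proportion
closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

_N_MAX = 10_000_000


@dataclass
class PowerRequest:
    """Inputs for a power / sample-size computation."""

    rule: str
    theta1: np.ndarray
    theta0: np.ndarray
    corr: np.ndarray | float = 0.0
    weights: np.ndarray | None = None
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self):
        self.theta1 = np.atleast_1d(np.asarray(self.theta1, dtype=float))
        self.theta0 = np.atleast_1d(np.asarray(self.theta0, dtype=float))
        K = len(self.theta1)
        if len(self.theta0) != K:
            raise ValueError("theta1 and theta0 must have equal length")
        for th in (self.theta1, self.theta0):
            if ((th <= 0) | (th >= 1)).any():
                raise ValueError("success probabilities must lie in (0, 1)")
        corr = np.asarray(self.corr, dtype=float)
        if corr.ndim == 0:
            sig = np.full((K, K), float(corr))
            np.fill_diagonal(sig, 1.0)
            corr = sig
        if corr.shape != (K, K) or not np.allclose(corr, corr.T):
            raise ValueError("correlation matrix must be symmetric K x K")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        self.corr = corr
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if not 0 < self.power < 1:
            raise ValueError("target power must be in (0, 1)")

    @property
    def K(self) -> int:
        return len(self.theta1)


@dataclass
class SampleSizeResult:
    n_per_arm: int
    achieved_power: float
    rule: str
    trace: list = field(default_factory=list)


def _mvn_rectangle(upper: np.ndarray, corr: np.ndarray) -> float:
    """P(Z <= upper) for Z ~ N(0, corr); deterministic for K <= 3."""
    K = len(upper)
    if K == 1:
        return float(stats.norm.cdf(upper[0]))
    val = stats.multivariate_normal.cdf(
        upper, mean=np.zeros(K), cov=corr, allow_singular=True,
        abseps=1e-8, releps=0.0, rng=np.random.default_rng(12345))
    return float(np.clip(val, 0.0, 1.0))


def analytic_power(rule: str, n: int, req: PowerRequest) -> float:
    """Large-sample analytic power at per-arm size n for the Any/All rules
    (and, via the weighted collapse, the Compensatory rule)."""
    if rule == "compensatory":
        return _compensatory_power(n, req)
    delta = req.theta1 - req.theta0
    se = np.sqrt(req.theta1 * (1 - req.theta1) + req.theta0 * (1 - req.theta0)) / np.sqrt(n)
    if rule == "any":
        z = stats.norm.ppf(1 - req.alpha / req.K)
        c = z - delta / se
        return 1.0 - _mvn_rectangle(c, req.corr)
    if rule == "all":
        z = stats.norm.ppf(1 - req.alpha)
        c = -z + delta / se
        return _mvn_rectangle(c, req.corr)
    raise ValueError(f"unknown rule: {rule}")


def _weighted_margins(req: PowerRequest) -> tuple[float, float]:
    if req.weights is None:
        raise ValueError("Compensatory sample size requires weights")
    from .transform import check_weights
    w = check_weights(req.weights, req.K)
    return float(w @ req.theta1), float(w @ req.theta0)


def _compensatory_power(n: int, req: PowerRequest) -> float:
    t1w, t0w = _weighted_margins(req)
    var = t1w * (1 - t1w) + t0w * (1 - t0w)
    za = stats.norm.ppf(1 - req.alpha)
    return float(stats.norm.cdf((t1w - t0w) * np.sqrt(n / var) - za))


def required_n_compensatory(req: PowerRequest) -> SampleSizeResult:
    """Closed-form two-proportion sample size on the weighted margins:
    n = ceil([t1w(1-t1w) + t0w(1-t0w)] * [(z_{1-a} + z_{1-b}) / (t1w - t0w)]^2).
    """
    t1w, t0w = _weighted_margins(req)
    if t1w == t0w:
        raise ValueError("weighted margins are equal: no finite sample size")
    za = stats.norm.ppf(1 - req.alpha)
    zb = stats.norm.ppf(req.power)
    n = (t1w * (1 - t1w) + t0w * (1 - t0w)) * ((za + zb) / (t1w - t0w)) ** 2
    n = max(2, int(np.ceil(n)))
    return SampleSizeResult(n_per_arm=n, achieved_power=_compensatory_power(n, req),
                            rule="compensatory")


def required_n_iterative(rule: str, req: PowerRequest) -> SampleSizeResult:
    """Smallest per-arm n with analytic power >= target, for Any/All.

    Geometric doubling brackets the solution, then binary search pins the
    minimal integer (power is increasing in n for a favorable effect).
    """
    if rule not in ("any", "all"):
        raise ValueError("iterative procedure applies to the Any/All rules")
    delta = req.theta1 - req.theta0
    if rule == "all" and not (delta > 0).all():
        raise ValueError("All rule needs a favorable effect on every endpoint")
    if not (delta > 0).any():
        raise ValueError("no favorable endpoint: power target unattainable")
    trace = []
    lo, hi = 2, 2
    while analytic_power(rule, hi, req) < req.power:
        trace.append((hi, analytic_power(rule, hi, req)))
        lo, hi = hi, hi * 2
        if hi > _N_MAX:
            raise ValueError(f"no solution below n={_N_MAX}: effect too small")
    while lo < hi:
        mid = (lo + hi) // 2
        p = analytic_power(rule, mid, req)
        trace.append((mid, p))
        if p >= req.power:
            hi = mid
        else:
            lo = mid + 1
    return SampleSizeResult(n_per_arm=hi, achieved_power=analytic_power(rule, hi, req),
                            rule=rule, trace=trace)


def required_n(req: PowerRequest) -> SampleSizeResult:
    """Dispatch on the rule in the request."""
    if req.rule == "compensatory":
        return required_n_compensatory(req)
    return required_n_iterative(req.rule, req)
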