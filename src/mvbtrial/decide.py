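"""Superiority / inferiority decision rules on posterior treatment differences.

Three rejection-region families over the K-variate difference delta:

* Any  — superior if at least one delta_k > 0 (inferior if at least one < 0);
  the two regions overlap, so a two-sided test can in principle trigger both.
* All  — superior if every delta_k > 0; mutually exclusive with inferiority.
* Compensatory — superior if the weighted sum delta(w) = sum w_k delta_k > 0,
  letting benefit on one endpoint offset harm on another.

A conclusion is reached when the operative posterior probability strictly
exceeds the threshold p_cut = 1 - alpha (All/Compensatory) or its
multiplicity-corrected version 1 - alpha/K (Any); two-sided tests halve
alpha. For the Compensatory rule the operative probability is the
Monte-Carlo probability of the rejection region itself. For the Any and
All rules it is endpoint-wise: superiority requires max_k P(delta_k > 0)
(Any) or min_k P(delta_k > 0) (All) to clear the threshold — the exact
Bayesian analog of the Bonferroni and intersection-union tests whose
multivariate-normal power formulas drive the a priori sample sizes, and
the calibration under which the corrected thresholds deliver the target
type-I rate. (The joint probability of the union region S_S^Any is *not*
alpha-calibrated: under a two-endpoint null it rejects at ~0.12, not
0.05.) Region boundaries use strict inequalities: a draw with some
delta_k exactly zero belongs to no rejection region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .transform import check_weights, weighted_delta

Rule = Literal["any", "all", "compensatory"]
Side = Literal["right", "left", "two_sided"]

_RULES = ("any", "all", "compensatory")
_SIDES = ("right", "left", "two_sided")


def make_threshold(rule: Rule, side: Side, alpha: float, K: int) -> float:
    """Decision threshold p_cut for a target type-I error rate alpha.

    The Any rule tests K endpoint-wise differences, so alpha is Bonferroni-
    corrected to alpha/K; two-sided tests use alpha/2 throughout.
    """
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    if rule not in _RULES or side not in _SIDES:
        raise ValueError(f"unknown rule/side: {rule}/{side}")
    a = alpha / 2 if side == "two_sided" else alpha
    if rule == "any":
        a /= K
    return 1.0 - a


@dataclass
class DecisionRuleSpec:
    rule: Rule
    side: Side = "right"
    alpha: float = 0.05
    weights: np.ndarray | None = None
    K: int | None = None

    def __post_init__(self):
        if self.rule == "compensatory":
            if self.weights is None:
                raise ValueError("Compensatory rule requires weights")
            self.weights = np.asarray(self.weights, dtype=float)
            check_weights(self.weights, len(self.weights))
            if self.K is None:
                self.K = len(self.weights)
        if self.K is None:
            raise ValueError("K (number of outcomes) must be set for the Any/All rules")

    @property
    def p_cut(self) -> float:
        return make_threshold(self.rule, self.side, self.alpha, self.K)


def region_membership(delta: np.ndarray, rule: Rule,
                      w=None) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw membership flags (in S_S, in S_I) for (...,K) delta draws."""
    delta = np.asarray(delta, dtype=float)
    if rule == "any":
        return delta.max(axis=-1) > 0, delta.min(axis=-1) < 0
    if rule == "all":
        return delta.min(axis=-1) > 0, delta.max(axis=-1) < 0
    if rule == "compensatory":
        if w is None:
            raise ValueError("Compensatory rule requires weights")
        dw = weighted_delta(delta, w)
        return dw > 0, dw < 0
    raise ValueError(f"unknown rule: {rule}")


def posterior_region_prob(delta_draws: np.ndarray, spec: DecisionRuleSpec
                          ) -> tuple[float, float]:
    """Monte-Carlo posterior probabilities (P(S_S), P(S_I))."""
    delta_draws = np.asarray(delta_draws, dtype=float)
    if delta_draws.shape[0] < 1:
        raise ValueError("need at least one posterior draw")
    sup, inf = region_membership(delta_draws, spec.rule, spec.weights)
    return float(sup.mean()), float(inf.mean())


def operative_prob(delta_draws: np.ndarray, spec: DecisionRuleSpec
                   ) -> tuple[float, float]:
    """The posterior probabilities actually compared against p_cut.

    Compensatory: the region probabilities themselves. Any/All:
    endpoint-wise probabilities p_k = P(delta_k > 0 | y) combined as
    max_k p_k (Any) / min_k p_k (All) for superiority, and analogously
    with P(delta_k < 0) for inferiority.
    """
    delta_draws = np.asarray(delta_draws, dtype=float)
    if delta_draws.shape[0] < 1:
        raise ValueError("need at least one posterior draw")
    if spec.rule == "compensatory":
        return posterior_region_prob(delta_draws, spec)
    p_pos = (delta_draws > 0).mean(axis=0)
    p_neg = (delta_draws < 0).mean(axis=0)
    if spec.rule == "any":
        return float(p_pos.max()), float(p_neg.max())
    return float(p_pos.min()), float(p_neg.min())


@dataclass
class DecisionResult:
    rule: Rule
    side: Side
    alpha: float
    p_cut: float
    prob_superior: float
    prob_inferior: float
    conclusion: Literal["superior", "inferior", "inconclusive"]
    n_draws: int
    double_trigger: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("rule", "side", "alpha", "p_cut", "prob_superior",
                 "prob_inferior", "conclusion", "n_draws", "double_trigger")}


def decide(delta_draws: np.ndarray, spec: DecisionRuleSpec) -> DecisionResult:
    """Full decision: region probabilities compared against p_cut.

    Sidedness: a right-sided test can only conclude superiority, a
    left-sided test only inferiority (used e.g. when outcomes are coded as
    failures and a *smaller* difference is the favorable one); two-sided
    tests evaluate both directions against the halved-alpha threshold.
    """
    p_sup, p_inf = operative_prob(delta_draws, spec)
    p_cut = spec.p_cut
    win_sup = p_sup > p_cut and spec.side in ("right", "two_sided")
    win_inf = p_inf > p_cut and spec.side in ("left", "two_sided")
    if win_sup and win_inf:
        # only possible for the Any rule's overlapping regions; report both
        conclusion = "superior"
        double = True
    else:
        conclusion = ("superior" if win_sup else
                      "inferior" if win_inf else "inconclusive")
        double = False
    return DecisionResult(rule=spec.rule, side=spec.side, alpha=spec.alpha,
                          p_cut=p_cut, prob_superior=p_sup, prob_inferior=p_inf,
                          conclusion=conclusion,
                          n_draws=int(np.asarray(delta_draws).shape[0]),
                          double_trigger=double)
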