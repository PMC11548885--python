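"""Population and subpopulation treatment effects from a posterior sample.

Two ways to define the population of interest:

* ``fixed`` — a single covariate profile (e.g. z = -1): plug the profile
  into each posterior coefficient draw for both counterfactual arms.
* ``marginal`` — a covariate-interval selector (e.g. mean-1SD <= z <= mean,
  or "all" for the trial population): for every posterior draw, evaluate
  the joint probabilities at each selected subject's covariates under both
  counterfactual arms and average within arm (empirical marginalization).

Subjects from *both* randomized arms enter the marginalization for both
counterfactual profiles; the posterior sample itself is always fit on the
full dataset — only covariate rows are subset, which is the regression
approach's advantage over stratified analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ModelSpec, counterfactual_rows, profile_row
from .gibbs import PosteriorSample
from .transform import inverse_mlogit, phi_to_theta, weighted_delta


class EmptySubpopulationError(ValueError):
    """No subject satisfies the subpopulation selector."""


@dataclass
class PopulationSpec:
    """Fixed-value or interval-marginalized (sub)population.

    ``fixed_values`` maps covariate name -> value (mode="fixed").
    ``selector`` maps covariate name -> (lo, hi) closed interval, or the
    string "all" for the whole trial population (mode="marginal").
    """

    mode: str
    fixed_values: dict[str, float] | None = None
    selector: dict[str, tuple[float, float]] | str | None = None
    label: str = ""

    def __post_init__(self):
        if self.mode not in ("fixed", "marginal"):
            raise ValueError("mode must be 'fixed' or 'marginal'")
        if self.mode == "fixed" and not self.fixed_values:
            raise ValueError("mode='fixed' requires fixed_values")
        if self.mode == "marginal" and self.selector is None:
            raise ValueError("mode='marginal' requires a selector")
        if isinstance(self.selector, dict):
            for name, (lo, hi) in self.selector.items():
                if not lo < hi:
                    raise ValueError(f"interval for {name!r} must have lo < hi")

    def select(self, data: pd.DataFrame) -> np.ndarray:
        """Boolean mask of subjects in the subpopulation."""
        if self.selector == "all" or self.selector is None:
            return np.ones(len(data), dtype=bool)
        mask = np.ones(len(data), dtype=bool)
        for name, (lo, hi) in self.selector.items():
            v = data[name].to_numpy(dtype=float)
            mask &= (v >= lo) & (v <= hi)
        return mask


def trial_population() -> PopulationSpec:
    """The whole-trial (average treatment effect) population."""
    return PopulationSpec(mode="marginal", selector="all", label="ATE")


@dataclass
class EffectDraws:
    """Posterior draws of the transformation chain for one (sub)population.

    ``phi1``/``phi0`` are (L, Q) joint-probability draws per counterfactual
    arm (absent for estimators without a joint model, e.g. univariate
    logistic fits, which supply ``theta`` draws directly).
    """

    theta1: np.ndarray
    theta0: np.ndarray
    phi1: np.ndarray | None = None
    phi0: np.ndarray | None = None
    H: np.ndarray | None = None
    n_marginalized: int | None = None
    label: str = ""

    @property
    def delta(self) -> np.ndarray:
        return self.theta1 - self.theta0

    def delta_weighted(self, w) -> np.ndarray:
        return weighted_delta(self.delta, w)

    @property
    def n_draws(self) -> int:
        return self.theta1.shape[0]

    def summary(self, w=None) -> dict:
        from .transform import summarize
        out = {
            "theta1": summarize(self.theta1),
            "theta0": summarize(self.theta0),
            "delta": summarize(self.delta),
        }
        if w is not None:
            out["delta_weighted"] = summarize(self.delta_weighted(w))
        return out


def _effect_from_phi(phi1, phi0, H, n_marg=None, label="") -> EffectDraws:
    return EffectDraws(theta1=phi_to_theta(phi1, H), theta0=phi_to_theta(phi0, H),
                       phi1=phi1, phi0=phi0, H=H, n_marginalized=n_marg,
                       label=label)


def effect_fixed(sample: PosteriorSample, pop: PopulationSpec,
                 observed: pd.DataFrame | None = None) -> EffectDraws:
    """Treatment-effect draws at fixed covariate values.

    If ``observed`` data are supplied, fixed values outside the observed
    covariate range trigger an extrapolation warning.
    """
    if pop.mode != "fixed":
        raise ValueError("effect_fixed requires a mode='fixed' population")
    spec = sample.spec
    if spec is None:
        raise ValueError("posterior sample lacks column-role metadata")
    if observed is not None:
        for name, val in pop.fixed_values.items():
            col = observed[name].to_numpy(dtype=float)
            if val < col.min() or val > col.max():
                warnings.warn(
                    f"fixed value {name}={val} lies outside the observed "
                    f"range [{col.min():.3g}, {col.max():.3g}]; "
                    "effect is an extrapolation", stacklevel=2)
    beta = sample.stacked()
    out = {}
    for arm in (0, 1):
        x = profile_row(spec, pop.fixed_values, arm)
        psi = beta @ x  # (L, Q-1)
        out[arm] = inverse_mlogit(psi)
    return _effect_from_phi(out[1], out[0], sample.H, label=pop.label)


def effect_marginal(sample: PosteriorSample, data: pd.DataFrame,
                    pop: PopulationSpec) -> EffectDraws:
    """Empirically marginalized treatment-effect draws over a covariate subset.

    For each posterior draw: evaluate phi at every selected subject's
    covariates under both counterfactual arms and average within arm.
    """
    if pop.mode != "marginal":
        raise ValueError("effect_marginal requires a mode='marginal' population")
    spec = sample.spec
    if spec is None:
        raise ValueError("posterior sample lacks column-role metadata")
    mask = pop.select(data)
    n_sel = int(mask.sum())
    if n_sel == 0:
        raise EmptySubpopulationError(
            f"no subject satisfies the selector {pop.selector!r}")
    sub = data.loc[mask]
    beta = sample.stacked()  # (L, Q-1, P+1)
    out = {}
    for arm in (0, 1):
        rows = counterfactual_rows(spec, sub, arm)  # (S, P+1)
        psi = np.einsum("lqp,sp->lsq", beta, rows)
        phi = inverse_mlogit(psi)  # (L, S, Q)
        out[arm] = phi.mean(axis=1)
    return _effect_from_phi(out[1], out[0], sample.H, n_marg=n_sel,
                            label=pop.label)


def effect_for(sample: PosteriorSample, data: pd.DataFrame,
               pop: PopulationSpec) -> EffectDraws:
    """Dispatch on the population mode."""
    if pop.mode == "fixed":
        return effect_fixed(sample, pop, observed=data)
    return effect_marginal(sample, data, pop)
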