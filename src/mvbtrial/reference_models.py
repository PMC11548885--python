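"""Reference estimators for the simulation comparison.

* Stratified multivariate Bernoulli-Dirichlet analysis ("mB"): per arm,
  category counts plus a near-Haldane Dirichlet prior (alpha0 = 0.01)
  give the joint-probability posterior directly. Subpopulation effects
  are estimated by stratification — only subjects inside the
  subpopulation contribute response data.
* Per-outcome univariate logistic regression ("uLR"): one Bayesian binary
  logistic fit per outcome; the per-outcome posterior delta_k draws are
  paired by draw index to form joint K-variate draws, which encodes the
  (correlation-ignoring) independence assumption the comparison is
  designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ModelSpec, build_design, config_matrix, encode_responses
from .gibbs import GibbsSettings, PosteriorSample, PriorSpec, fit_ulr
from .populations import (EffectDraws, EmptySubpopulationError, PopulationSpec,
                          effect_for, trial_population)
from .transform import phi_to_theta


@dataclass
class DirichletPosterior:
    """Per-arm Dirichlet concentration vectors alpha0 + category counts."""

    alpha1: np.ndarray
    alpha0_arm: np.ndarray
    prior_alpha0: float

    def mean(self, arm: int) -> np.ndarray:
        a = self.alpha1 if arm == 1 else self.alpha0_arm
        return a / a.sum()


def fit_mb(data: pd.DataFrame, outcomes, treatment: str = "T",
           pop: PopulationSpec | None = None, alpha0: float = 0.01,
           n_draws: int = 4000, seed: int | None = None,
           rng: np.random.Generator | None = None) -> EffectDraws:
    """Stratified multivariate Bernoulli-Dirichlet effect draws.

    ATE uses all rows; subpopulation effects subset rows first (fixed
    covariate values select exact matches, intervals select the range),
    mirroring a stratified analysis that discards out-of-stratum data.
    """
    pop = pop or trial_population()
    rng = rng if rng is not None else np.random.default_rng(seed)
    K = len(outcomes)
    H = config_matrix(K)
    Q = H.shape[0]
    if pop.mode == "fixed":
        mask = np.ones(len(data), dtype=bool)
        for name, val in pop.fixed_values.items():
            mask &= data[name].to_numpy(dtype=float) == val
    else:
        mask = pop.select(data)
    sub = data.loc[mask]
    t = sub[treatment].to_numpy(dtype=float)
    if (t == 1).sum() == 0 or (t == 0).sum() == 0:
        raise EmptySubpopulationError(
            f"stratum {pop.label or pop.selector!r} has an empty arm")
    c = encode_responses(sub[list(outcomes)].to_numpy(), H)
    post = DirichletPosterior(
        alpha1=alpha0 + np.bincount(c[t == 1], minlength=Q).astype(float),
        alpha0_arm=alpha0 + np.bincount(c[t == 0], minlength=Q).astype(float),
        prior_alpha0=alpha0)
    phi1 = rng.dirichlet(post.alpha1, size=n_draws)
    phi0 = rng.dirichlet(post.alpha0_arm, size=n_draws)
    return EffectDraws(theta1=phi_to_theta(phi1, H), theta0=phi_to_theta(phi0, H),
                       phi1=phi1, phi0=phi0, H=H,
                       n_marginalized=int(mask.sum()), label=pop.label)


def fit_ulr_suite(data: pd.DataFrame, spec: ModelSpec,
                  prior: PriorSpec | None = None,
                  settings: GibbsSettings | None = None
                  ) -> tuple[dict[str, PosteriorSample], "UlrEffects"]:
    """One univariate logistic fit per outcome; draws paired by index.

    Returns the per-outcome posterior samples plus a factory for
    population effects that stacks the per-outcome theta draws into
    K-variate draws.
    """
    settings = settings or GibbsSettings()
    design = build_design(data, spec)
    base_seed = np.random.SeedSequence(settings.seed)
    fits = {}
    for k, name in enumerate(spec.outcomes):
        sub_settings = GibbsSettings(
            iterations=settings.iterations, burnin=settings.burnin,
            chains=settings.chains, thin=settings.thin,
            seed=int(base_seed.generate_state(len(spec.outcomes),
                                              dtype=np.uint32)[k]),
            overdispersed_init=settings.overdispersed_init)
        sample = fit_ulr(design, data[name].to_numpy(), prior=prior,
                         settings=sub_settings)
        # carry the model spec so population profiles can be built
        sample.spec = ModelSpec(outcomes=(name,), treatment=spec.treatment,
                                covariates=spec.covariates,
                                interactions=spec.interactions)
        fits[name] = sample
    return fits, UlrEffects(fits, spec)


@dataclass
class UlrEffects:
    """Assemble per-outcome univariate posteriors into joint effect draws."""

    fits: dict[str, PosteriorSample]
    spec: ModelSpec

    def effect(self, data: pd.DataFrame, pop: PopulationSpec) -> EffectDraws:
        t1, t0 = [], []
        for name in self.spec.outcomes:
            eff = effect_for(self.fits[name], data, pop)
            t1.append(eff.theta1[:, 0])  # success prob of the K=1 model
            t0.append(eff.theta0[:, 0])
        return EffectDraws(theta1=np.column_stack(t1),
                           theta0=np.column_stack(t0),
                           H=config_matrix(self.spec.K), label=pop.label)
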