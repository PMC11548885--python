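"""Simulation orchestration: repetition studies and single-trial analysis.

``run_scenario`` executes the generate -> fit -> transform -> decide
pipeline for one data-generating mechanism and one estimation method over
many seeded repetitions and tabulates operating characteristics:
superiority-conclusion proportions (type I error under null effects,
power under favorable ones), bias of the posterior-mean differences
against the generator's ground truth, and convergence diagnostics.

Per-repetition seeds are spawned deterministically from the master seed
via ``numpy.random.SeedSequence(master_seed).spawn`` — the same master
seed reproduces the whole grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decide import DecisionRuleSpec, decide
from .design import build_design, config_matrix, encode_responses
from .gibbs import GibbsSettings, PriorSpec, fit_mlr, gelman_rubin
from .populations import PopulationSpec, effect_for, trial_population
from .reference_models import fit_mb, fit_ulr_suite
from .synthdata import DGMSpec, generate, true_effects

log = logging.getLogger("mvbtrial")

METHODS = ("mlr", "mb", "ulr")


def truth_for(dgm: DGMSpec, pop: PopulationSpec) -> dict:
    """Ground-truth effect for a population under a DGM."""
    if pop.mode == "fixed":
        z = float(pop.fixed_values["z"])
        eff = true_effects(dgm)
        for key in ("anchor_low", "anchor_high"):
            if np.isclose(eff[key]["z"], z):
                return eff[key]
        raise ValueError(f"no closed-form truth at z={z}; use an anchor value")
    if pop.selector == "all":
        return true_effects(dgm)["ate"]
    (lo, hi), = [tuple(v) for v in pop.selector.values()]
    return true_effects(dgm, interval=(lo, hi))["interval"]


@dataclass
class Scenario:
    """One cell of the simulation grid."""

    dgm: DGMSpec
    method: str = "mlr"
    rules: tuple[DecisionRuleSpec, ...] = ()
    populations: tuple[PopulationSpec, ...] = ()
    label: str = ""

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not self.populations:
            self.populations = (trial_population(),)


def _fit_effects(scn: Scenario, data, mcmc: GibbsSettings, mb_draws: int,
                 seed: int, collect_mpsrf: bool):
    """Fit one dataset with the scenario's method; return effects per
    population plus an optional convergence statistic."""
    mpsrf = np.nan
    if scn.method == "mb":
        rng = np.random.default_rng(seed)
        effs = [fit_mb(data, scn.dgm.model_spec().outcomes, treatment="T",
                       pop=pop, n_draws=mb_draws, rng=rng)
                for pop in scn.populations]
        return effs, mpsrf
    spec = scn.dgm.model_spec()
    settings = GibbsSettings(iterations=mcmc.iterations, burnin=mcmc.burnin,
                             chains=mcmc.chains, thin=mcmc.thin, seed=seed)
    if scn.method == "mlr":
        design = build_design(data, spec)
        H = config_matrix(spec.K)
        c = encode_responses(data[list(spec.outcomes)].to_numpy(), H)
        sample = fit_mlr(design, c, H, settings=settings)
        if collect_mpsrf and settings.chains >= 2:
            mpsrf = gelman_rubin(sample)["mpsrf"]
        effs = [effect_for(sample, data, pop) for pop in scn.populations]
        return effs, mpsrf
    # ulr
    _, ulr = fit_ulr_suite(data, spec, settings=settings)
    effs = [ulr.effect(data, pop) for pop in scn.populations]
    return effs, mpsrf


def run_scenario(scn: Scenario, reps: int = 500, master_seed: int = 0,
                 mcmc: GibbsSettings | None = None, mb_draws: int = 4000,
                 collect_mpsrf: bool = False,
                 max_error_frac: float = 0.01) -> pd.DataFrame:
    """Operating characteristics of one scenario over seeded repetitions.

    Returns one row per (population, rule) with the superiority proportion
    and its binomial Monte-Carlo standard error, plus per-endpoint and
    weighted-difference bias and the mean multivariate PSRF when requested.
    Individual repetition failures are logged and counted; the scenario
    aborts only if more than ``max_error_frac`` of repetitions fail.
    """
    mcmc = mcmc or GibbsSettings(iterations=2000, burnin=500, chains=2)
    ss = np.random.SeedSequence(master_seed)
    truths = [np.asarray(truth_for(scn.dgm, pop)["delta"]) for pop in scn.populations]
    n_pop, n_rule = len(scn.populations), len(scn.rules)
    sup = np.zeros((n_pop, n_rule))
    delta_sum = [np.zeros(scn.dgm.K) for _ in range(n_pop)]
    dw_sum = np.zeros((n_pop, n_rule))
    mpsrfs = []
    n_ok, n_err = 0, 0
    for rep, child in enumerate(ss.spawn(reps)):
        seeds = child.generate_state(2, dtype=np.uint32)
        try:
            data, _ = generate(scn.dgm, seed=int(seeds[0]))
            effs, mpsrf = _fit_effects(scn, data, mcmc, mb_draws,
                                       int(seeds[1]), collect_mpsrf)
        except Exception:
            n_err += 1
            log.exception("repetition %d failed", rep)
            if n_err > max(1, int(max_error_frac * reps)):
                raise RuntimeError(
                    f"more than {max_error_frac:.0%} of repetitions failed")
            continue
        n_ok += 1
        if np.isfinite(mpsrf):
            mpsrfs.append(mpsrf)
        for p, eff in enumerate(effs):
            delta = eff.delta
            delta_sum[p] += delta.mean(axis=0)
            for r, rule in enumerate(scn.rules):
                res = decide(delta, rule)
                if res.conclusion == "superior":
                    sup[p, r] += 1
                if rule.rule == "compensatory":
                    dw_sum[p, r] += eff.delta_weighted(rule.weights).mean()
    rows = []
    for p, pop in enumerate(scn.populations):
        mean_delta = delta_sum[p] / max(n_ok, 1)
        bias = mean_delta - truths[p]
        for r, rule in enumerate(scn.rules):
            prop = sup[p, r] / max(n_ok, 1)
            row = {
                "scenario": scn.label, "method": scn.method,
                "population": pop.label or pop.mode,
                "rule": rule.rule, "side": rule.side, "p_cut": rule.p_cut,
                "reps": n_ok, "errors": n_err,
                "prop_superior": prop,
                "mc_se": np.sqrt(prop * (1 - prop) / max(n_ok, 1)),
                "mean_mpsrf": float(np.mean(mpsrfs)) if mpsrfs else np.nan,
                "max_mpsrf": float(np.max(mpsrfs)) if mpsrfs else np.nan,
            }
            for k in range(scn.dgm.K):
                row[f"bias_delta{k + 1}"] = bias[k]
            if rule.rule == "compensatory":
                w = np.asarray(rule.weights)
                row["bias_delta_w"] = dw_sum[p, r] / max(n_ok, 1) - float(truths[p] @ w)
            rows.append(row)
    return pd.DataFrame(rows)


def run_grid(scenarios, reps: int = 500, master_seed: int = 0,
             **kwargs) -> pd.DataFrame:
    """Run several scenarios; each gets an independent spawned master seed."""
    ss = np.random.SeedSequence(master_seed)
    out = []
    for scn, child in zip(scenarios, ss.spawn(len(scenarios))):
        out.append(run_scenario(scn, reps=reps,
                                master_seed=int(child.generate_state(1)[0]),
                                **kwargs))
    return pd.concat(out, ignore_index=True)


def analyze_once(data: pd.DataFrame, spec, rules, populations,
                 prior: PriorSpec | None = None,
                 settings: GibbsSettings | None = None,
                 psrf_warn: float = 1.10) -> dict:
    """End-to-end single-trial analysis report.

    Fits the multivariate model, checks convergence, and evaluates every
    requested (population, rule) combination; returns a JSON-serializable
    report including posterior summaries and decisions.
    """
    settings = settings or GibbsSettings()
    design = build_design(data, spec)
    H = config_matrix(spec.K)
    c = encode_responses(data[list(spec.outcomes)].to_numpy(), H)
    sample = fit_mlr(design, c, H, prior=prior, settings=settings)
    report = {
        "n_subjects": int(len(data)),
        "K": spec.K,
        "settings": {"iterations": settings.iterations,
                     "burnin": settings.burnin, "chains": settings.chains,
                     "seed": settings.seed},
        "populations": [],
    }
    if settings.chains >= 2:
        diag = gelman_rubin(sample)
        report["mpsrf"] = diag["mpsrf"]
        report["max_psrf"] = float(np.max(diag["psrf"]))
        if diag["mpsrf"] > psrf_warn:
            report["convergence_warning"] = (
                f"multivariate PSRF {diag['mpsrf']:.3f} exceeds {psrf_warn}")
            log.warning(report["convergence_warning"])
    for pop in populations:
        eff = effect_for(sample, data, pop)
        entry = {
            "label": pop.label or pop.mode,
            "mode": pop.mode,
            "n_marginalized": eff.n_marginalized,
            "delta_mean": eff.delta.mean(axis=0).tolist(),
            "decisions": [],
        }
        for rule in rules:
            res = decide(eff.delta, rule)
            entry["decisions"].append(res.to_dict())
            if rule.rule == "compensatory":
                entry["delta_weighted_mean"] = float(
                    eff.delta_weighted(rule.weights).mean())
        report["populations"].append(entry)
    return report, sample
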