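"""Posterior sampling for multinomial logistic regression via Polya-Gamma
augmentation, plus Gelman-Rubin convergence diagnostics.

The model: subject i falls in joint-response category q with probability
phi_iq = exp(psi_iq) / (sum_r exp(psi_ir) + 1), psi_iq = x_i' beta_q, and
the reference category Q has beta_Q = 0. Introducing one Polya-Gamma
latent variable per subject and non-reference category makes each beta_q
conditionally multivariate normal, so the sampler is a systematic-sweep
Gibbs scheme with exact PG(1, z) draws (see :mod:`mvbtrial._pg`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from . import _pg
from .design import DesignMatrix, ModelSpec, config_matrix


@dataclass
class PriorSpec:
    """Independent multivariate normal prior per non-reference category.

    ``variance`` may be a scalar (diagonal prior, the default 10 is the
    usual weakly-informative choice on the log-odds scale), a length-(P+1)
    diagonal, or a full (P+1) x (P+1) covariance.
    """

    mean: float | np.ndarray = 0.0
    variance: float | np.ndarray = 10.0

    def mean_matrix(self, Qm1: int, p1: int) -> np.ndarray:
        b0 = np.broadcast_to(np.asarray(self.mean, dtype=float), (Qm1, p1))
        return np.ascontiguousarray(b0)

    def precision_array(self, Qm1: int, p1: int) -> np.ndarray:
        v = np.asarray(self.variance, dtype=float)
        if v.ndim == 0:
            cov = np.eye(p1) * float(v)
        elif v.ndim == 1:
            cov = np.diag(v)
        else:
            cov = v
        if cov.shape != (p1, p1):
            raise ValueError(f"prior covariance must be ({p1}, {p1})")
        # symmetric positive definite check via Cholesky
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise ValueError("prior covariance must be positive definite") from err
        prec = np.linalg.inv(cov)
        return np.ascontiguousarray(np.broadcast_to(prec, (Qm1, p1, p1)))


@dataclass
class GibbsSettings:
    """MCMC run lengths. Defaults mirror a full production run; simulation
    studies scale them down."""

    iterations: int = 10_000
    burnin: int = 1_000
    chains: int = 2
    thin: int = 1
    seed: int | None = None
    overdispersed_init: bool = False

    def __post_init__(self):
        if self.iterations < 1 or self.chains < 1 or self.thin < 1 or self.burnin < 0:
            raise ValueError("invalid Gibbs settings")


@dataclass
class PosteriorSample:
    """Retained coefficient draws: shape (chains, L, Q-1, P+1).

    Reference-category coefficients are identically zero and never stored.
    """

    draws: np.ndarray
    H: np.ndarray
    spec: ModelSpec | None
    prior: PriorSpec
    settings: GibbsSettings
    column_labels: tuple[str, ...] = ()

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        """Retained draws per chain."""
        return self.draws.shape[1]

    def stacked(self) -> np.ndarray:
        """All chains concatenated: (chains*L, Q-1, P+1)."""
        c, l, qm1, p1 = self.draws.shape
        return self.draws.reshape(c * l, qm1, p1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: chain, iteration, category, coefficient, value."""
        c, l, qm1, p1 = self.draws.shape
        labels = self.column_labels or tuple(f"b{j}" for j in range(p1))
        idx = pd.MultiIndex.from_product(
            [range(c), range(l), range(1, qm1 + 1), labels],
            names=["chain", "iteration", "category", "coefficient"])
        return pd.DataFrame({"value": self.draws.ravel()}, index=idx).reset_index()


def sample_pg(z, size: int | None = None, seed: int = 0) -> np.ndarray:
    """Exact, seeded draws from the Polya-Gamma PG(1, z) distribution.

    ``z`` may be a scalar (with ``size`` repetitions) or a vector of tilts.
    """
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("non-finite PG tilt")
    if z.ndim == 0:
        z = np.full(size or 1, float(z))
    return _pg.pg_draws(np.ascontiguousarray(z), np.uint32(seed))


def _chain_seeds(settings: GibbsSettings, n: int) -> list[int]:
    ss = np.random.SeedSequence(settings.seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32)]


def fit_mlr(design: DesignMatrix | np.ndarray, c: np.ndarray, H: np.ndarray,
            prior: PriorSpec | None = None,
            settings: GibbsSettings | None = None) -> PosteriorSample:
    """Fit the multivariate (multinomial) logistic model by PG Gibbs sampling.

    Parameters
    ----------
    design : DesignMatrix or ndarray
        n x (P+1) design including the intercept column.
    c : ndarray
        0-based category indices (length n), as from ``encode_responses``.
    H : ndarray
        Configuration matrix fixing Q and the reference category.
    """
    prior = prior or PriorSpec()
    settings = settings or GibbsSettings()
    spec = design.spec if isinstance(design, DesignMatrix) else None
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design, dtype=float)
    c = np.asarray(c, dtype=np.int64)
    n, p1 = X.shape
    Q = H.shape[0]
    Qm1 = Q - 1
    if n < p1 + 1:
        raise ValueError(f"need at least P+2={p1 + 1} subjects, got {n}")
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    if c.min() < 0 or c.max() >= Q:
        raise ValueError("category index out of range for H")

    b0 = prior.mean_matrix(Qm1, p1)
    B0inv = prior.precision_array(Qm1, p1)
    B0inv_b0 = np.einsum("qab,qb->qa", B0inv, b0)
    niter = settings.burnin + settings.iterations * settings.thin
    seeds = _chain_seeds(settings, 2 * settings.chains)
    keep = []
    for ch in range(settings.chains):
        if settings.overdispersed_init:
            rng = np.random.default_rng(seeds[settings.chains + ch])
            cov = np.linalg.inv(B0inv[0])
            beta0 = rng.multivariate_normal(np.zeros(p1), cov, size=Qm1)
        else:
            beta0 = np.zeros((Qm1, p1))
        raw = _pg.gibbs_chain(
            np.ascontiguousarray(X), c, Qm1, B0inv, B0inv_b0,
            niter, np.uint32(seeds[ch]), np.ascontiguousarray(beta0))
        keep.append(raw[settings.burnin::settings.thin])
    draws = np.stack(keep)
    if not np.isfinite(draws).all():
        raise FloatingPointError("divergent coefficient draws (non-finite)")
    labels = spec.column_labels if spec is not None else ()
    return PosteriorSample(draws=draws, H=H.copy(), spec=spec, prior=prior,
                           settings=settings, column_labels=labels)


def fit_ulr(design: DesignMatrix | np.ndarray, y_k: np.ndarray,
            prior: PriorSpec | None = None,
            settings: GibbsSettings | None = None) -> PosteriorSample:
    """Univariate Bayesian logistic regression on one binary outcome.

    The binary model is the K=1 special case of the multivariate one:
    H = [[1], [0]] with "failure" as the reference category.
    """
    y_k = np.asarray(y_k)
    if not np.isin(y_k, (0, 1)).all():
        raise ValueError("outcome vector must be binary (0/1)")
    H = config_matrix(1)
    c = np.where(y_k == 1, 0, 1).astype(np.int64)  # category 0 = success
    return fit_mlr(design, c, H, prior=prior, settings=settings)


def _split_params(sample: PosteriorSample) -> np.ndarray:
    c, l, qm1, p1 = sample.draws.shape
    return sample.draws.reshape(c, l, qm1 * p1)


def gelman_rubin(sample: PosteriorSample) -> dict:
    """Gelman-Rubin convergence diagnostics across chains.

    Returns per-parameter potential scale reduction factors and the
    Brooks-Gelman multivariate PSRF, both on the customary sqrt scale
    (values near 1 indicate convergence; > 1.10 is the usual warning).
    """
    if sample.n_chains < 2:
        raise ValueError("Gelman-Rubin diagnostics require at least 2 chains")
    x = _split_params(sample)  # (m, n, p)
    m, n, p = x.shape
    chain_means = x.mean(axis=1)
    chain_vars = x.var(axis=1, ddof=1)
    W = chain_vars.mean(axis=0)
    Bn = chain_means.var(axis=0, ddof=1)  # = B/n
    with np.errstate(divide="ignore", invalid="ignore"):
        psrf = np.sqrt((n - 1) / n + (m + 1) / m * Bn / W)
    psrf = np.where(W > 0, psrf, 1.0)

    Wm = np.mean([np.cov(chain, rowvar=False) for chain in x], axis=0)
    Bnm = np.cov(chain_means, rowvar=False)
    # ridge for numerically singular pooled covariance
    Wm += np.eye(p) * 1e-12 * max(1.0, np.trace(Wm) / p)
    lam = scipy.linalg.eigh(Bnm, Wm, eigvals_only=True).max()
    mpsrf = float(np.sqrt((n - 1) / n + (p + 1) / p * lam))
    return {"psrf": psrf.reshape(sample.draws.shape[2:]), "mpsrf": mpsrf}
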