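"""Coefficient-to-probability transformation chain.

Multinomial-logit coefficients have no direct clinical reading; every
retained posterior draw is therefore pushed through three stations:

1. linear predictors psi -> joint response probabilities phi (inverse
   multinomial-logit link, reference category fixed at zero),
2. phi -> marginal success probabilities theta (sums over the selection
   sets U_k, which preserves the outcome correlation encoded in phi),
3. per-arm theta -> treatment differences delta = theta_1 - theta_0,
   optionally collapsed to a weighted scalar sum(w_k * delta_k).

Transforms are applied draw-by-draw — the posterior of a transform, never
the transform of a posterior summary.
"""

from __future__ import annotations

import numpy as np

from .design import success_rows

_SIMPLEX_TOL = 1e-12


def linear_predictor(beta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """psi_q = beta_q . x for each non-reference category.

    ``beta`` has shape (..., Q-1, P+1) (leading axes are posterior draws),
    ``x`` is a profile vector of length P+1 including the intercept.
    """
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(x, dtype=float)
    if beta.shape[-1] != x.shape[-1]:
        raise ValueError(f"profile length {x.shape[-1]} does not match "
                         f"coefficient length {beta.shape[-1]}")
    return beta @ x


def inverse_mlogit(psi: np.ndarray) -> np.ndarray:
    """Map linear predictors (..., Q-1) to the joint-probability simplex (..., Q).

    phi_q = exp(psi_q) / (sum_r exp(psi_r) + 1), with the implicit
    psi_Q = 0 of the reference category; stabilized by max-subtraction.
    """
    psi = np.asarray(psi, dtype=float)
    if not np.isfinite(psi).all():
        raise ValueError("non-finite linear predictor")
    full = np.concatenate([psi, np.zeros(psi.shape[:-1] + (1,))], axis=-1)
    full -= full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)


def phi_to_theta(phi: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Marginal success probabilities: theta_k = sum of phi over U_k rows."""
    phi = np.asarray(phi, dtype=float)
    Q, K = H.shape
    if phi.shape[-1] != Q:
        raise ValueError(f"phi length {phi.shape[-1]} does not match Q={Q}")
    dev = np.abs(phi.sum(axis=-1) - 1.0)
    if (dev > 1e-9).any() or (phi < -_SIMPLEX_TOL).any():
        raise ValueError("phi is off the probability simplex")
    # H[:, k] is exactly the U_k membership indicator, so this is phi @ H
    return phi @ H.astype(float)


def theta_to_delta(theta1: np.ndarray, theta0: np.ndarray) -> np.ndarray:
    """Treatment difference delta_k = theta_1k - theta_0k, elementwise."""
    theta1 = np.asarray(theta1, dtype=float)
    theta0 = np.asarray(theta0, dtype=float)
    if theta1.shape[-1] != theta0.shape[-1]:
        raise ValueError("arms have different numbers of outcomes")
    return theta1 - theta0


def check_weights(w, K: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (K,):
        raise ValueError(f"weights must have length {K}")
    if (w < 0).any() or (w > 1).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must lie in [0, 1] and sum to 1")
    return w


def weighted_delta(delta: np.ndarray, w) -> np.ndarray:
    """Scalar compensatory difference sum_k w_k delta_k per draw."""
    delta = np.asarray(delta, dtype=float)
    w = check_weights(w, delta.shape[-1])
    return delta @ w


def summarize(draws: np.ndarray, level: float = 0.95) -> dict:
    """Posterior mean and central quantile interval along the draw axis."""
    draws = np.asarray(draws, dtype=float)
    lo = (1.0 - level) / 2.0
    return {
        "mean": draws.mean(axis=0),
        "lower": np.quantile(draws, lo, axis=0),
        "upper": np.quantile(draws, 1.0 - lo, axis=0),
        "level": level,
    }
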