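"""Synthetic two-arm trial generator with known ground-truth effects.

A data-generating mechanism (DGM) is specified the way trial simulation
studies state their conditions: per treatment arm and per anchor value of
a single covariate, the K marginal success probabilities theta and a
common pairwise outcome correlation rho. The generator

1. converts each (theta, rho) cell to a joint-probability vector phi over
   the 2^K outcome configurations (bivariate-Bernoulli phi-coefficient
   identity; for K=3 the triple-success cell is set to the midpoint of its
   feasibility interval given the pairwise cells),
2. inverts the multinomial-logit model psi_q = b0q + bTq*T + b1q*z + b2q*z*T
   through the four (T, anchor) cells to obtain exact coefficients beta
   (anchors are z in {0, 1} for a Bernoulli(0.5) covariate and z in
   {-1, +1} for a standard-normal covariate),
3. samples covariates, computes each subject's phi from the true beta, and
   draws the joint response from the corresponding multinomial.

The accompanying manifest records the true beta and the true conditional
and average effects; average effects under the continuous covariate are
integrated over the standard-normal law by Gauss-Hermite quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ModelSpec, config_matrix, decode_categories
from .transform import inverse_mlogit, phi_to_theta


class FeasibilityError(ValueError):
    """The requested (theta, rho) margins admit no valid joint distribution."""


def _pair_cell(t1: float, t2: float, rho: float) -> float:
    """P(Y_j=1, Y_k=1) for Bernoulli margins t1, t2 with correlation rho."""
    return t1 * t2 + rho * np.sqrt(t1 * (1 - t1) * t2 * (1 - t2))


def phi_from_margins(theta, rho) -> np.ndarray:
    """Joint configuration probabilities phi from margins theta and pairwise
    correlation(s) rho, ordered as the rows of ``config_matrix(K)``.

    ``rho`` is a scalar (exchangeable) or a K x K correlation matrix.
    Supported K: 1 (rho ignored), 2 (exact), 3 (pairwise cells exact,
    triple-success cell at the midpoint of its feasibility interval).
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    K = len(theta)
    if ((theta <= 0) | (theta >= 1)).any():
        raise ValueError("margins must lie strictly in (0, 1)")
    rho_m = np.asarray(rho, dtype=float)
    if rho_m.ndim == 0:
        rho_m = np.full((K, K), float(rho_m))
        np.fill_diagonal(rho_m, 1.0)
    H = config_matrix(K)

    if K == 1:
        return np.array([theta[0], 1 - theta[0]])

    if K == 2:
        p11 = _pair_cell(theta[0], theta[1], rho_m[0, 1])
        phi = np.array([p11, theta[0] - p11, theta[1] - p11,
                        1 - theta[0] - theta[1] + p11])
        _check_simplex(phi, theta, rho_m)
        return phi

    if K == 3:
        p = {(j, k): _pair_cell(theta[j], theta[k], rho_m[j, k])
             for j in range(3) for k in range(j + 1, 3)}
        # inclusion-exclusion bounds on the triple-success probability
        lo = max(0.0,
                 p[(0, 1)] + p[(0, 2)] - theta[0],
                 p[(0, 1)] + p[(1, 2)] - theta[1],
                 p[(0, 2)] + p[(1, 2)] - theta[2])
        hi = min(p.values())
        # the all-zero cell must also be non-negative:
        # phi_000 = 1 - sum(theta) + sum(pairs) - p111 >= 0
        hi = min(hi, 1 - theta.sum() + sum(p.values()))
        if lo > hi + 1e-12:
            raise FeasibilityError(
                f"no triple-success probability in [{lo:.4f}, {hi:.4f}] "
                f"for margins {theta} and correlations {rho}")
        p111 = 0.5 * (lo + hi)
        phi = np.empty(8)
        for q, row in enumerate(H):
            j = tuple(row)
            if j == (1, 1, 1):
                v = p111
            elif j == (1, 1, 0):
                v = p[(0, 1)] - p111
            elif j == (1, 0, 1):
                v = p[(0, 2)] - p111
            elif j == (0, 1, 1):
                v = p[(1, 2)] - p111
            elif j == (1, 0, 0):
                v = theta[0] - p[(0, 1)] - p[(0, 2)] + p111
            elif j == (0, 1, 0):
                v = theta[1] - p[(0, 1)] - p[(1, 2)] + p111
            elif j == (0, 0, 1):
                v = theta[2] - p[(0, 2)] - p[(1, 2)] + p111
            else:
                v = 1 - theta.sum() + sum(p.values()) - p111
            phi[q] = v
        _check_simplex(phi, theta, rho_m)
        return phi

    raise ValueError(f"phi_from_margins supports K in {{1, 2, 3}}, got K={K}")


def _check_simplex(phi, theta, rho):
    if (phi < -1e-12).any():
        q = int(np.argmin(phi))
        raise FeasibilityError(
            f"margins {np.round(theta, 3)} with correlation(s) "
            f"{np.round(rho, 3)} imply a negative configuration "
            f"probability (cell {q}: {phi[q]:.4f})")


@dataclass
class CellSpec:
    """Conditional margins per arm and anchor covariate value.

    ``theta`` has shape (2 arms, 2 anchors, K): theta[T, a] are the success
    probabilities of arm T at anchor a (a=0 is the low anchor). ``rho`` is
    a scalar applied to every cell, or shape (2, 2) per (arm, anchor).
    """

    theta: np.ndarray
    rho: float | np.ndarray = 0.0

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 3 or self.theta.shape[:2] != (2, 2):
            raise ValueError("theta must have shape (2 arms, 2 anchors, K)")

    @property
    def K(self) -> int:
        return self.theta.shape[2]

    def rho_for(self, arm: int, anchor: int):
        r = np.asarray(self.rho, dtype=float)
        return float(r) if r.ndim == 0 else float(r[arm, anchor])

    def phi_cells(self) -> np.ndarray:
        """(2, 2, Q) joint probabilities at the four (arm, anchor) cells."""
        Q = 2 ** self.K
        out = np.empty((2, 2, Q))
        for t in (0, 1):
            for a in (0, 1):
                out[t, a] = phi_from_margins(self.theta[t, a], self.rho_for(t, a))
        return out


@dataclass
class DGMSpec:
    """A full synthetic-trial recipe."""

    cells: CellSpec
    covariate: str = "binary"  # "binary" (Bernoulli 0.5) or "normal"
    n_per_arm: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if self.covariate not in ("binary", "normal"):
            raise ValueError("covariate must be 'binary' or 'normal'")

    @property
    def anchors(self) -> tuple[float, float]:
        return (0.0, 1.0) if self.covariate == "binary" else (-1.0, 1.0)

    @property
    def K(self) -> int:
        return self.cells.K

    def model_spec(self) -> ModelSpec:
        names = tuple(f"y{k + 1}" for k in range(self.K))
        return ModelSpec(outcomes=names, treatment="T", covariates=("z",),
                         interactions=(("T", "z"),))


def beta_from_cells(cells: CellSpec, anchors: tuple[float, float]) -> np.ndarray:
    """Exact multinomial-logit coefficients reproducing the four cells.

    Solves, per non-reference category q, the 4 x 4 linear system
    psi_q(T, a) = log(phi_q(T, a) / phi_Q(T, a)) over the (T, anchor)
    grid for the model columns (1, T, z, z*T). Round-trip exact.
    """
    a0, a1 = anchors
    if a0 == a1:
        raise ValueError("anchor values must differ")
    phi = cells.phi_cells()
    if (phi[..., -1] <= 0).any():
        raise FeasibilityError("a cell has zero mass in the reference "
                               "(all-failure) category; log-odds undefined")
    Q = phi.shape[-1]
    M = np.array([[1.0, t, a, a * t] for t in (0.0, 1.0) for a in (a0, a1)])
    logodds = np.log(phi[..., :-1] / phi[..., -1:])  # (2, 2, Q-1)
    rhs = np.array([logodds[int(t), ai] for t in (0, 1) for ai in (0, 1)])
    return np.linalg.solve(M, rhs).T  # (Q-1, 4)


def _phi_at(beta: np.ndarray, T: float, z: float) -> np.ndarray:
    x = np.array([1.0, T, z, z * T])
    return inverse_mlogit(beta @ x)


def _gauss_hermite_nodes(n=128):
    # probabilists' Hermite: integrates against the standard normal density
    nodes, weights = np.polynomial.hermite_e.hermegauss(n)
    return nodes, weights / weights.sum()


def true_effects(spec: DGMSpec, interval: tuple[float, float] | None = None) -> dict:
    """Ground-truth theta and delta for the DGM.

    Returns conditional effects at both anchors and the average effect over
    the covariate law; when ``interval`` is given, also the marginal effect
    over covariate values in that interval (continuous covariate:
    quadrature against the truncated standard normal).
    """
    H = config_matrix(spec.K)
    beta = beta_from_cells(spec.cells, spec.anchors)
    a0, a1 = spec.anchors

    def theta_at(T, z):
        return phi_to_theta(_phi_at(beta, T, z), H)

    out = {"beta": beta}
    for name, z in (("anchor_low", a0), ("anchor_high", a1)):
        t1, t0 = theta_at(1, z), theta_at(0, z)
        out[name] = {"z": z, "theta1": t1, "theta0": t0, "delta": t1 - t0}

    if spec.covariate == "binary":
        # exact 0.5/0.5 mixture of the conditional phi vectors
        phi = spec.cells.phi_cells()
        t1 = phi_to_theta(phi[1].mean(axis=0), H)
        t0 = phi_to_theta(phi[0].mean(axis=0), H)
    else:
        nodes, wts = _gauss_hermite_nodes()
        phi1 = np.stack([_phi_at(beta, 1.0, z) for z in nodes])
        phi0 = np.stack([_phi_at(beta, 0.0, z) for z in nodes])
        t1 = phi_to_theta(wts @ phi1, H)
        t0 = phi_to_theta(wts @ phi0, H)
    out["ate"] = {"theta1": t1, "theta0": t0, "delta": t1 - t0}

    if interval is not None:
        lo, hi = interval
        if spec.covariate == "binary":
            vals = [v for v in (0.0, 1.0) if lo <= v <= hi]
            phi = spec.cells.phi_cells()
            idx = [int(v) for v in vals]
            t1 = phi_to_theta(phi[1, idx].mean(axis=0), H)
            t0 = phi_to_theta(phi[0, idx].mean(axis=0), H)
        else:
            from scipy import stats as _st
            nodes, wts = np.polynomial.legendre.leggauss(96)
            z = 0.5 * (hi + lo) + 0.5 * (hi - lo) * nodes
            w = wts * _st.norm.pdf(z)
            w /= w.sum()
            phi1 = np.stack([_phi_at(beta, 1.0, zi) for zi in z])
            phi0 = np.stack([_phi_at(beta, 0.0, zi) for zi in z])
            t1 = phi_to_theta(w @ phi1, H)
            t0 = phi_to_theta(w @ phi0, H)
        out["interval"] = {"bounds": (lo, hi), "theta1": t1, "theta0": t0,
                           "delta": t1 - t0}
    return out


def generate(spec: DGMSpec, seed: int | None = None
             ) -> tuple[pd.DataFrame, dict]:
    """Sample one trial dataset and its ground-truth manifest.

    Returns a data frame with columns (z, T, y1..yK) — n_per_arm rows per
    arm — and a manifest holding the true coefficients and effects.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    H = config_matrix(spec.K)
    Q = H.shape[0]
    beta = beta_from_cells(spec.cells, spec.anchors)
    n = spec.n_per_arm
    T = np.repeat([0.0, 1.0], n)
    if spec.covariate == "binary":
        z = rng.binomial(1, 0.5, size=2 * n).astype(float)
    else:
        z = rng.standard_normal(2 * n)
    X = np.column_stack([np.ones(2 * n), T, z, z * T])
    phi = inverse_mlogit(X @ beta.T)  # (2n, Q)
    u = rng.random(2 * n)
    c = (u[:, None] > phi.cumsum(axis=1)).sum(axis=1)
    Y = decode_categories(np.minimum(c, Q - 1), H)
    mspec = spec.model_spec()
    data = pd.DataFrame({"z": z, "T": T.astype(int)})
    for k, name in enumerate(mspec.outcomes):
        data[name] = Y[:, k]
    manifest = true_effects(spec)
    manifest["n_per_arm"] = n
    manifest["covariate"] = spec.covariate
    return data, manifest


# --- Qualitative effect-size presets -------------------------------------
#
# ES1: homogeneous null (all conditional and average differences zero).
# ES2: heterogeneous with zero average effect (conditional effects at the
#      two anchors cancel under the covariate law).
# ES3: positive average effect; the conditional effect at the *low* anchor
#      exceeds the average.
# ES4: positive average effect; the conditional effect at the low anchor
#      is smaller than the average (stratified analysis under-powered).
#
# Control-arm margins sit at 0.5 where differences are easiest to read;
# the numbers below are package defaults, adjustable per study.

_PRESET_DELTAS = {
    "ES1": (np.zeros(2), np.zeros(2)),
    "ES2": (np.array([-0.20, -0.10]), np.array([0.20, 0.10])),
    "ES3": (np.array([0.30, 0.15]), np.array([0.10, 0.05])),
    "ES4": (np.array([0.10, 0.05]), np.array([0.30, 0.15])),
}


def preset(name: str, covariate: str = "binary", rho: float = 0.0,
           n_per_arm: int = 1000, seed: int | None = None) -> DGMSpec:
    """Named effect-size preset (ES1-ES4) as a ready DGMSpec, K=2."""
    if name not in _PRESET_DELTAS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESET_DELTAS)}")
    d_lo, d_hi = _PRESET_DELTAS[name]
    base = np.array([0.5, 0.5])
    theta = np.empty((2, 2, 2))
    theta[0, 0] = theta[0, 1] = base
    theta[1, 0] = base + d_lo
    theta[1, 1] = base + d_hi
    cells = CellSpec(theta=theta, rho=rho)
    return DGMSpec(cells=cells, covariate=covariate, n_per_arm=n_per_arm, seed=seed)
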