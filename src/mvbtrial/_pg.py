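"""Numba kernels: exact Polya-Gamma PG(1, z) sampling and the Gibbs sweep.

The PG(1, z) sampler follows Devroye's alternating-series rejection scheme
for the tilted Jacobi J*(1, z/2) distribution, with PG(1, z) = J*(1, z/2)/4.
It is exact (no truncated-sum approximation): proposals come from a mixture
of a truncated exponential (right of the crossover point 0.64) and a
truncated inverse-Gaussian (left of it), and acceptance is decided by the
partial sums of the alternating series for the Jacobi density.

Randomness uses numba's per-thread np.random state; callers seed it through
the kernels' explicit ``seed`` arguments, which keeps chains reproducible
and independent of the global numpy state.
"""

import math

import numpy as np
from numba import njit

_TRUNC = 0.64  # series crossover point t of the Jacobi density
_PSI_CLIP = 30.0  # linear predictors are clipped here before exp()


@njit(cache=True)
def _ncdf(x):
    return 0.5 * math.erfc(-x * 0.7071067811865475)


@njit(cache=True)
def _log_ncdf(x):
    if x > -8.0:
        return math.log(0.5 * math.erfc(-x * 0.7071067811865475))
    # asymptotic expansion of the lower tail
    x2 = x * x
    return (-0.5 * x2 - 0.9189385332046727 - math.log(-x)
            + math.log1p(-1.0 / x2 + 3.0 / (x2 * x2)))


@njit(cache=True)
def _a_coef(n, x):
    """n-th coefficient of the alternating series for the Jacobi density."""
    npt = n + 0.5
    if x > _TRUNC:
        return math.pi * npt * math.exp(-npt * npt * math.pi * math.pi * x / 2.0)
    return math.pi * npt * math.pow(2.0 / (math.pi * x), 1.5) * math.exp(-2.0 * npt * npt / x)


@njit(cache=True)
def _mass_texpon(zz):
    """P(proposal falls in the exponential branch) for tilt zz = |z|/2."""
    t = _TRUNC
    fz = math.pi * math.pi / 8.0 + zz * zz / 2.0
    b = math.sqrt(1.0 / t) * (t * zz - 1.0)
    a = -math.sqrt(1.0 / t) * (t * zz + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - zz + _log_ncdf(b)
    xa = x0 + zz + _log_ncdf(a)
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(zz):
    """Inverse-Gaussian IG(mu=1/zz, lambda=1) truncated to (0, _TRUNC]."""
    t = _TRUNC
    if zz < 1.0 / t:
        # mean beyond the truncation point: sample the zz=0 law on (0, t]
        # via 1/chi^2 and accept with the exponential tilt.
        while True:
            while True:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if np.random.random() <= math.exp(-0.5 * zz * zz * x):
                return x
    else:
        mu = 1.0 / zz
        while True:
            nu = np.random.standard_normal()
            y = nu * nu
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(4.0 * mu * y + (mu * y) ** 2)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= t:
                return x


@njit(cache=True)
def _pg1(z):
    """One exact draw from PG(1, z)."""
    zz = 0.5 * abs(z)
    fz = math.pi * math.pi / 8.0 + zz * zz / 2.0
    p_exp = _mass_texpon(zz)
    while True:
        if np.random.random() < p_exp:
            x = _TRUNC + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(zz)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return 0.25 * x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break  # reject; draw a new proposal


@njit(cache=True)
def pg_draws(z, seed):
    """Vector of independent PG(1, z_i) draws (seeded)."""
    np.random.seed(seed)
    out = np.empty(z.shape[0])
    for i in range(z.shape[0]):
        out[i] = _pg1(z[i])
    return out


@njit(cache=True)
def gibbs_chain(X, cidx, Qm1, B0inv, B0inv_b0, niter, seed, beta_init):
    """One MCMC chain of the PG-augmented multinomial-logit Gibbs sampler.

    Per sweep and per non-reference category q: compute the log-sum offset
    C_iq of the competing categories, draw omega_iq ~ PG(1, psi_iq - C_iq),
    and update beta_q from the conjugate multivariate normal with precision
    X' Omega X + B0inv and linear term X'(kappa + omega * C) + B0inv b0,
    where kappa_iq = I(c_i = q) - 1/2.

    Returns draws of shape (niter, Qm1, P1); burn-in is sliced off by the
    caller.
    """
    np.random.seed(seed)
    n, p1 = X.shape
    beta = beta_init.copy()
    out = np.empty((niter, Qm1, p1))
    psi = np.empty((n, Qm1))
    for q in range(Qm1):
        for i in range(n):
            s = 0.0
            for a in range(p1):
                s += X[i, a] * beta[q, a]
            psi[i, q] = s
    amat = np.empty((p1, p1))
    bvec = np.empty(p1)
    for it in range(niter):
        for q in range(Qm1):
            for a in range(p1):
                bvec[a] = B0inv_b0[q, a]
                for b in range(p1):
                    amat[a, b] = B0inv[q, a, b]
            for i in range(n):
                s = 1.0  # reference category contributes exp(0)
                for r in range(Qm1):
                    if r != q:
                        v = psi[i, r]
                        if v > _PSI_CLIP:
                            v = _PSI_CLIP
                        s += math.exp(v)
                c_off = math.log(s)
                eta = psi[i, q] - c_off
                if eta > _PSI_CLIP:
                    eta = _PSI_CLIP
                elif eta < -_PSI_CLIP:
                    eta = -_PSI_CLIP
                om = _pg1(eta)
                kap = (0.5 if cidx[i] == q else -0.5) + om * c_off
                for a in range(p1):
                    xa = X[i, a]
                    bvec[a] += xa * kap
                    for b in range(a, p1):
                        amat[a, b] += om * xa * X[i, b]
            for a in range(p1):
                for b in range(a):
                    amat[a, b] = amat[b, a]
            chol = np.linalg.cholesky(amat)
            mean = np.linalg.solve(amat, bvec)
            # beta_q = mean + L^{-T} z
            zvec = np.empty(p1)
            for a in range(p1):
                zvec[a] = np.random.standard_normal()
            for a in range(p1 - 1, -1, -1):
                s = zvec[a]
                for b in range(a + 1, p1):
                    s -= chol[b, a] * zvec[b]
                zvec[a] = s / chol[a, a]
            for a in range(p1):
                beta[q, a] = mean[a] + zvec[a]
            for i in range(n):
                s = 0.0
                for a in range(p1):
                    s += X[i, a] * beta[q, a]
                psi[i, q] = s
        out[it] = beta
    return out
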