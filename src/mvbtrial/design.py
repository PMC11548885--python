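"""Outcome configurations and design matrices for multivariate binary trials.

A trial records K binary outcomes per subject, so each subject's response
is one of Q = 2^K joint configurations. The configuration matrix ``H``
enumerates them in strictly descending binary order: the first row is
all-successes, the last row (all-failures) is the reference category whose
multinomial-logit coefficients are fixed at zero for identifiability.

Design matrices carry column-role metadata (intercept / treatment /
covariate / interaction) so that counterfactual treatment arms can be
reconstructed downstream when evaluating population effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_K = 10


def config_matrix(K: int) -> np.ndarray:
    """The Q x K matrix H of joint response configurations.

    Rows are all distinct binary K-tuples sorted in strictly descending
    binary order: row 0 is all ones, row Q-1 (the reference category)
    is all zeros.
    """
    if not isinstance(K, (int, np.integer)) or not 1 <= K <= MAX_K:
        raise ValueError(f"K must be an integer in [1, {MAX_K}], got {K!r}")
    Q = 2 ** K
    ints = np.arange(Q - 1, -1, -1, dtype=np.int64)
    bits = np.arange(K - 1, -1, -1, dtype=np.int64)
    return ((ints[:, None] >> bits) & 1).astype(np.int8)


def success_rows(H: np.ndarray, k: int) -> np.ndarray:
    """Row indices of H whose k-th element is 1 (the selection set U_k).

    These are the 2^(K-1) configurations in which outcome ``k`` (0-based)
    is a success; summing the joint probabilities over them yields the
    marginal success probability theta_k.
    """
    K = H.shape[1]
    if not 0 <= k < K:
        raise IndexError(f"outcome index k={k} out of range for K={K}")
    return np.flatnonzero(H[:, k] == 1)


def encode_responses(Y: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Map an n x K binary outcome matrix to 0-based category indices.

    Subject i gets category q iff its outcome row equals ``H[q]``. With
    the descending binary ordering this is a closed-form bit trick rather
    than a row lookup.
    """
    Y = np.asarray(Y)
    if Y.ndim == 1:
        Y = Y[None, :]
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("outcome matrix must be binary (0/1)")
    K = H.shape[1]
    if Y.shape[1] != K:
        raise ValueError(f"Y has {Y.shape[1]} columns, H expects {K}")
    weights = 2 ** np.arange(K - 1, -1, -1, dtype=np.int64)
    vals = Y.astype(np.int64) @ weights
    return (2 ** K - 1 - vals).astype(np.int64)


def decode_categories(c: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_responses`: category indices back to rows of H."""
    c = np.asarray(c, dtype=np.int64)
    Q = H.shape[0]
    if c.min() < 0 or c.max() >= Q:
        raise ValueError("category index out of range")
    return H[c].copy()


@dataclass(frozen=True)
class ModelSpec:
    """Names of the columns entering the model, in their roles.

    ``outcomes`` is ordered and defines k = 1..K. ``interactions`` are
    pairs of predictor names (typically the treatment with a covariate)
    whose elementwise product is appended to the design matrix.
    """

    outcomes: tuple[str, ...]
    treatment: str
    covariates: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "interactions",
                           tuple(tuple(pair) for pair in self.interactions))
        for a, b in self.interactions:
            known = {self.treatment, *self.covariates}
            if a not in known or b not in known:
                raise ValueError(f"interaction ({a}, {b}) references unknown column")

    @property
    def K(self) -> int:
        return len(self.outcomes)

    @property
    def n_predictors(self) -> int:
        """P: predictors beyond the intercept."""
        return 1 + len(self.covariates) + len(self.interactions)

    @property
    def column_labels(self) -> tuple[str, ...]:
        labels = ["(intercept)", self.treatment, *self.covariates]
        labels += [f"{a}:{b}" for a, b in self.interactions]
        return tuple(labels)


@dataclass
class DesignMatrix:
    """n x (P+1) design matrix with column-role metadata."""

    X: np.ndarray
    spec: ModelSpec

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def column_labels(self) -> tuple[str, ...]:
        return self.spec.column_labels


def build_design(data: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Assemble the design matrix (intercept, treatment, covariates, interactions).

    The treatment column must be strictly binary; interaction columns are
    elementwise products of their (already included) parent columns.
    """
    cols = [spec.treatment, *spec.covariates]
    for name in cols + list(spec.outcomes):
        if name not in data.columns:
            raise ValueError(f"column {name!r} missing from data")
    t = data[spec.treatment].to_numpy(dtype=float)
    if not np.isin(t, (0.0, 1.0)).all():
        raise ValueError(f"treatment column {spec.treatment!r} must be binary (0/1)")
    parts = [np.ones(len(data)), t]
    parts += [data[c].to_numpy(dtype=float) for c in spec.covariates]
    by_name = dict(zip(cols, parts[1:]))
    for a, b in spec.interactions:
        parts.append(by_name[a] * by_name[b])
    X = np.column_stack(parts)
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    return DesignMatrix(X=X, spec=spec)


def profile_row(spec: ModelSpec, covariate_values: dict[str, float],
                treatment: int) -> np.ndarray:
    """A single counterfactual design row at fixed covariate values.

    Used when evaluating population effects: the treatment column is set
    to the requested arm and interaction columns are recomputed.
    """
    unknown = set(covariate_values) - set(spec.covariates)
    if unknown:
        raise ValueError(f"unknown covariate(s): {sorted(unknown)}")
    missing = set(spec.covariates) - set(covariate_values)
    if missing:
        raise ValueError(f"fixed-value profile missing covariate(s): {sorted(missing)}")
    vals = {spec.treatment: float(treatment)}
    vals.update({c: float(covariate_values[c]) for c in spec.covariates})
    row = [1.0, vals[spec.treatment]]
    row += [vals[c] for c in spec.covariates]
    row += [vals[a] * vals[b] for a, b in spec.interactions]
    return np.array(row)


def counterfactual_rows(spec: ModelSpec, data: pd.DataFrame,
                        treatment: int) -> np.ndarray:
    """Design rows for observed subjects with the treatment forced to one arm.

    Interaction columns are recomputed from the forced treatment value.
    """
    t = np.full(len(data), float(treatment))
    cols = {spec.treatment: t}
    for c in spec.covariates:
        cols[c] = data[c].to_numpy(dtype=float)
    parts = [np.ones(len(data)), t]
    parts += [cols[c] for c in spec.covariates]
    for a, b in spec.interactions:
        parts.append(cols[a] * cols[b])
    return np.column_stack(parts)
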