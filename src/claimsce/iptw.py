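"""Propensity scores, inverse-probability-of-treatment weights and balance.

The treatment-assignment model is a maximum-likelihood logistic regression
fit by iteratively reweighted least squares (gradient-norm tolerance 1e-8,
at most 100 iterations).  Weights follow the standard IPTW form — 1/PS for
the treated cohort, 1/(1-PS) for the comparator — and are normalized by
the grand mean over *both* cohorts, so normalized weights sum exactly to
the total patient count.

Balance is assessed with standardized differences against the conventional
10% threshold: for binary covariates 100·(p1−p2)/sqrt(p̄(1−p̄)) with
p̄=(p1+p2)/2, and for continuous covariates 100·|m1−m2| divided by the
square root of the average of the two squared standard deviations.
Weighted summaries use the frequency-weight convention (denominator Σw).
"""

from __future__ import annotations

import dataclasses
import warnings as _warnings

import numpy as np
import pandas as pd

PS_CLIP = 1e-6
BALANCE_THRESHOLD = 10.0  # percent


class EstimationError(RuntimeError):
    """A model fit failed (non-convergence or degenerate inputs)."""


class DesignError(ValueError):
    """The design matrix is rank deficient or mis-specified."""


def prune_collinear(df: pd.DataFrame, tol: float = 1e-8) -> pd.DataFrame:
    """Drop constant or linearly dependent columns given an implicit intercept.

    Uses pivoted QR on the centered, column-scaled matrix; keeps a maximal
    linearly independent subset of columns.
    """
    from scipy.linalg import qr

    X = df.to_numpy(float)
    Xc = X - X.mean(axis=0)  # centering absorbs the intercept
    scale = np.linalg.norm(Xc, axis=0)
    scale[scale == 0] = 1.0
    _, r, piv = qr(Xc / scale, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > tol * diag[0])) if diag.size and diag[0] > 0 else 0
    keep_idx = set(piv[:rank])
    cols = [c for i, c in enumerate(df.columns) if i in keep_idx]
    return df[cols]


@dataclasses.dataclass
class PropensityFit:
    coef: np.ndarray
    ps: np.ndarray
    columns: list[str]
    n_iter: int
    grad_norm: float
    converged: bool


def fit_propensity(
    X: np.ndarray,
    treated: np.ndarray,
    columns: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    add_intercept: bool = True,
) -> PropensityFit:
    """Maximum-likelihood logistic regression of treatment on covariates.

    ``X`` is the covariate matrix (no intercept column unless
    ``add_intercept=False``).  Raises :class:`DesignError` on rank
    deficiency, :class:`EstimationError` on non-convergence.  Fitted
    probabilities are clipped to [1e-6, 1-1e-6].
    """
    y = np.asarray(treated, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        columns = ["intercept"] + list(columns or [f"x{i}" for i in range(X.shape[1] - 1)])
    else:
        columns = list(columns or [f"x{i}" for i in range(X.shape[1])])
    if y.min() == y.max():
        raise EstimationError("treatment is constant; need at least one patient per arm")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns involved in collinearity via QR pivoting
        _, r = np.linalg.qr(X)
        bad = [columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise DesignError(f"rank-deficient design; collinear columns: {bad or columns}")

    beta = np.zeros(X.shape[1])
    grad_norm = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        g = X.T @ (y - p)
        grad_norm = float(np.linalg.norm(g))
        if grad_norm < tol:
            break
        w = np.clip(p * (1 - p), 1e-10, None)
        XtWX = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(XtWX, g)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"singular information matrix at iteration {it}") from exc
        # step-halving safeguard against divergence on separable-ish data
        ll0 = _loglik(y, eta)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            if _loglik(y, X @ cand) >= ll0 - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
    else:
        it = max_iter
    converged = grad_norm < max(tol, 1e-6 * len(y))
    if not converged:
        raise EstimationError(
            f"logistic fit did not converge in {max_iter} iterations (|grad|={grad_norm:.3g})"
        )
    ps = np.clip(1.0 / (1.0 + np.exp(-(X @ beta))), PS_CLIP, 1 - PS_CLIP)
    return PropensityFit(coef=beta, ps=ps, columns=columns, n_iter=it, grad_norm=grad_norm, converged=True)


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclasses.dataclass
class IPTWeights:
    raw: np.ndarray
    normalized: np.ndarray
    normalization: float


def compute_weights(ps: np.ndarray, treated: np.ndarray) -> IPTWeights:
    """IPT weights 1/PS (treated) and 1/(1-PS) (comparator), mean-normalized.

    Normalization divides every raw weight by the grand mean over both
    cohorts, so the normalized weights sum to the total number of patients.
    """
    ps = np.asarray(ps, float)
    treated = np.asarray(treated, bool)
    if np.any((ps <= PS_CLIP) | (ps >= 1 - PS_CLIP)):
        _warnings.warn("propensity scores at clip boundary: extreme weights", stacklevel=2)
    raw = np.where(treated, 1.0 / ps, 1.0 / (1.0 - ps))
    norm = float(raw.mean())
    return IPTWeights(raw=raw, normalized=raw / norm, normalization=norm)


# ---------------------------------------------------------------------------
# Standardized differences


def std_diff_binary(p1: float, p2: float) -> float:
    """Standardized difference (percent) between two proportions."""
    pbar = 0.5 * (p1 + p2)
    denom = pbar * (1 - pbar)
    if denom <= 0:
        _warnings.warn("degenerate pooled proportion; standardized difference set to 0", stacklevel=2)
        return 0.0
    return 100.0 * (p1 - p2) / np.sqrt(denom)


def std_diff_continuous(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Standardized difference (percent) between two means.

    The pooled SD is the square root of the average of the squared SDs.
    """
    pooled = np.sqrt(0.5 * (sd1**2 + sd2**2))
    if pooled == 0:
        if mean1 == mean2:
            return 0.0
        raise EstimationError("zero pooled SD with unequal means: standardized difference undefined")
    return 100.0 * abs(mean1 - mean2) / pooled


# ---------------------------------------------------------------------------
# Balance table


def _is_binary(x: np.ndarray) -> bool:
    u = np.unique(x[~np.isnan(x)])
    return len(u) <= 2 and np.all(np.isin(u, (0.0, 1.0)))


def balance_table(
    covariates: pd.DataFrame,
    treated: np.ndarray,
    weights: np.ndarray | None = None,
    threshold: float = BALANCE_THRESHOLD,
) -> pd.DataFrame:
    """Per-covariate weighted summaries and standardized differences.

    ``covariates`` must be numeric (multi-level categoricals already
    expanded to indicator columns, one balance row per level).  ``weights``
    of None means unweighted (unit weights).
    """
    treated = np.asarray(treated, bool)
    w = np.ones(len(covariates)) if weights is None else np.asarray(weights, float)
    if w[treated].sum() <= 0 or w[~treated].sum() <= 0:
        raise EstimationError("empty arm after weighting")
    rows = []
    for col in covariates.columns:
        x = covariates[col].to_numpy(float)
        x1, w1 = x[treated], w[treated]
        x2, w2 = x[~treated], w[~treated]
        m1 = float((w1 * x1).sum() / w1.sum())
        m2 = float((w2 * x2).sum() / w2.sum())
        if _is_binary(x):
            sd = std_diff_binary(m1, m2)
            s1 = s2 = np.nan
        else:
            v1 = float((w1 * (x1 - m1) ** 2).sum() / w1.sum())
            v2 = float((w2 * (x2 - m2) ** 2).sum() / w2.sum())
            s1, s2 = np.sqrt(v1), np.sqrt(v2)
            sd = std_diff_continuous(m1, s1, m2, s2)
        rows.append((col, m1, s1, m2, s2, abs(sd), abs(sd) <= threshold))
    return pd.DataFrame(
        rows,
        columns=["covariate", "treated_mean", "treated_sd", "comparator_mean", "comparator_sd", "std_diff_pct", "balanced"],
    )
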