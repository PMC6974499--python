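"""Independent reference implementations used as test oracles.

These deliberately avoid the package's code paths: logistic models are
fit with statsmodels directly (with a scipy fallback under perfect
separation, following the same documented penalty convention), and the
searches are written as plain loops.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize

PENALTY = 1e-4
_EPS = 1e-12


def _clipped_llf(params, X1, y):
    p = np.clip(1.0 / (1.0 + np.exp(-(X1 @ params))), _EPS, 1 - _EPS)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def logistic_aic(X: np.ndarray, y: np.ndarray) -> float:
    """AIC (2k - 2 logL) of a logistic fit; slopes L2-penalized when the
    maximum-likelihood estimate does not exist (perfect separation)."""
    n = len(y)
    if X.shape[1] == 0:
        pbar = y.mean()
        llf = n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
        return 2 * 1 - 2 * llf
    X1 = np.column_stack([np.ones(n), X])
    params = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X1).fit(disp=0, method="newton", maxiter=200)
        if np.all(np.isfinite(res.params)) and np.abs(res.params).max() <= 1e3 \
                and res.mle_retvals.get("converged", True):
            params = np.asarray(res.params)
    except Exception:
        params = None
    if params is None:

        def objective(b):
            return -_clipped_llf(b, X1, y) + PENALTY * float(b[1:] @ b[1:])

        params = minimize(objective, np.zeros(X1.shape[1]), method="BFGS").x
    return 2 * X1.shape[1] - 2 * _clipped_llf(params, X1, y)


def exhaustive_best_subset(X: np.ndarray, y: np.ndarray) -> tuple[set, float]:
    """Enumerate every candidate subset; return the AIC-minimal one."""
    best, best_aic = set(), np.inf
    for k in range(X.shape[1] + 1):
        for subset in itertools.combinations(range(X.shape[1]), k):
            aic = logistic_aic(X[:, list(subset)], y)
            if aic < best_aic:
                best, best_aic = set(subset), aic
    return best, best_aic


def forward_stepwise(X: np.ndarray, y: np.ndarray) -> tuple[set, float]:
    """Plain-loop forward selection minimizing AIC, stopping at the
    first step where no addition improves."""
    current: list[int] = []
    current_aic = logistic_aic(X[:, []], y)
    remaining = list(range(X.shape[1]))
    while remaining:
        aics = {j: logistic_aic(X[:, sorted(current + [j])], y) for j in remaining}
        j_best = min(aics, key=aics.get)
        if aics[j_best] < current_aic:
            current.append(j_best)
            current_aic = aics[j_best]
            remaining.remove(j_best)
        else:
            break
    return set(current), current_aic
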