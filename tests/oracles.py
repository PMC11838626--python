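"""Independent reference implementations used only to check the package.

Everything here is written directly from textbook formulas (double
loops, brute-force pair enumeration) or delegates to an unrelated
library, and stays independent of the code paths it verifies.
"""

from __future__ import annotations

import numpy as np


def loglik_naive(y, status, X, beta) -> float:
    """Breslow partial log-likelihood by direct double-loop evaluation."""
    y = np.asarray(y, float)
    status = np.asarray(status)
    eta = np.asarray(X, float) @ np.asarray(beta, float)
    ll = 0.0
    for t in np.unique(y[status == 1]):
        group = (y == t) & (status == 1)
        risk = y >= t
        ll += eta[group].sum() - group.sum() * np.log(np.exp(eta[risk]).sum())
    return ll


def gradient_naive(y, status, X, beta) -> np.ndarray:
    """Gradient of the MEAN partial log-likelihood, direct double loop."""
    y = np.asarray(y, float)
    status = np.asarray(status)
    X = np.asarray(X, float)
    eta = X @ np.asarray(beta, float)
    w = np.exp(eta)
    g = np.zeros(X.shape[1])
    for t in np.unique(y[status == 1]):
        group = (y == t) & (status == 1)
        risk = y >= t
        wr = w[risk]
        g += X[group].sum(axis=0) - group.sum() * (wr @ X[risk]) / wr.sum()
    return g / len(y)


def cindex_brute(scores, y, status) -> float:
    """Harrell's C by O(n^2) enumeration of comparable pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(y, float)
    status = np.asarray(status)
    n = len(y)
    conc = ties = total = 0
    for i in range(n):
        if status[i] != 1:
            continue
        for j in range(n):
            if y[j] > y[i]:
                total += 1
                if s[i] > s[j]:
                    conc += 1
                elif s[i] == s[j]:
                    ties += 1
    if total == 0:
        raise ValueError("no comparable pairs")
    return (conc + 0.5 * ties) / total


def km_product_limit(y, status):
    """Textbook product-limit estimator: (event times, S(t) after each)."""
    y = np.asarray(y, float)
    status = np.asarray(status)
    times = np.unique(y[status == 1])
    surv = []
    s = 1.0
    for t in times:
        n_at_risk = int((y >= t).sum())
        d = int(((y == t) & (status == 1)).sum())
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return times, np.array(surv)


def sksurv_cox_coefs(y, status, X, tol=1e-12) -> np.ndarray:
    """Unpenalized Cox coefficients from scikit-survival (Breslow ties)."""
    from sksurv.linear_model import CoxPHSurvivalAnalysis

    ys = np.array(
        list(zip(np.asarray(status).astype(bool), np.asarray(y, float))),
        dtype=[("event", bool), ("time", float)],
    )
    return CoxPHSurvivalAnalysis(ties="breslow", tol=tol).fit(np.asarray(X, float), ys).coef_
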