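"""Contingency-table tests and a penalized-logistic fallback.

Two-sided Fisher exact p-values follow the standard convention: the sum of
probabilities of all tables (with the observed margins) whose point
probability does not exceed the observed table's.  For 2 x c tables with
c > 2 this is the exact conditional (Freeman-Halton) test computed by full
enumeration, which is fast at the table sizes arising here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = ["ContingencyTable2x2", "fisher_exact_2xc", "firth_logit"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table [[a, b], [c, d]] with odds ratio and two-sided Fisher p."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def odds_ratio_defined(self) -> bool:
        return self.b * self.c > 0

    @property
    def odds_ratio(self) -> float:
        """Sample odds ratio a*d/(b*c); inf/nan flagged via odds_ratio_defined."""
        if not self.odds_ratio_defined:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)

    @property
    def fisher_p(self) -> float:
        return float(stats.fisher_exact(self.table, alternative="two-sided")[1])


def _log_table_prob(row1: tuple[int, ...], colsums: np.ndarray, n1: int, n: int) -> float:
    """Log probability of a 2 x c table under the multivariate hypergeometric."""
    row1 = np.asarray(row1)
    row2 = colsums - row1
    lp = (
        gammaln(n1 + 1)
        + gammaln(n - n1 + 1)
        - gammaln(n + 1)
        + np.sum(gammaln(colsums + 1))
        - np.sum(gammaln(row1 + 1))
        - np.sum(gammaln(row2 + 1))
    )
    return float(lp)


def fisher_exact_2xc(table) -> float:
    """Exact conditional two-sided p-value for a 2 x c contingency table.

    Enumerates every table with the observed margins; p is the total
    probability of tables no more probable than the observed one.  Agrees
    with the 2x2 Fisher exact test when c == 2.
    """
    table = np.asarray(table, dtype=int)
    if table.shape[0] != 2 or table.ndim != 2:
        raise ValueError("expected a 2 x c table")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    colsums = table.sum(axis=0)
    n1 = int(table[0].sum())
    n = int(table.sum())
    if n == 0:
        return 1.0
    lp_obs = _log_table_prob(tuple(table[0]), colsums, n1, n)
    c = table.shape[1]
    total = 0.0
    # enumerate feasible first rows column by column
    ranges = [range(0, int(colsums[j]) + 1) for j in range(c - 1)]
    for prefix in itertools.product(*ranges):
        s = sum(prefix)
        last = n1 - s
        if last < 0 or last > colsums[c - 1]:
            continue
        lp = _log_table_prob(prefix + (last,), colsums, n1, n)
        # relative tolerance as in R's fisher.test (p <= p_obs * (1 + 1e-7))
        if lp <= lp_obs + 1e-7:
            total += np.exp(lp)
    return float(min(total, 1.0))


def firth_logit(
    X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Firth-penalized logistic regression (Jeffreys prior).

    Returns (coefficients, standard errors).  Used as a fallback when the
    ordinary ML fit separates; the penalty keeps estimates finite.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        # hat-matrix diagonal for the Firth adjustment
        h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        norm = np.max(np.abs(step))
        if norm > 5.0:  # dampen large Newton steps to keep iterations stable
            step *= 5.0 / norm
        beta = beta + step
        if norm < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.diag(cov))
    return beta, se
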