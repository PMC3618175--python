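"""The two statistical procedures used by the analysis, implemented from
first principles.

* An exact two-sample Mann-Whitney U test: the full null distribution of U
  is built by the standard counting recurrence (a Gaussian-binomial
  polynomial, evaluated in exact integer arithmetic), so the reported exact
  p-value involves no normal approximation.  Two-sided p is obtained by
  doubling the smaller tail, capped at 1 — the convention most software
  labels "exact".

* A quasibinomial GLM (logit link) fitted by iteratively reweighted least
  squares, with the group effect tested by an F-test on the scaled deviance
  reduction.  The dispersion is the Pearson chi-square of the full model
  divided by its residual degrees of freedom, which is what distinguishes
  the quasibinomial from the plain binomial fit when individual birds are
  overdispersed relative to binomial sampling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MannWhitneyResult",
    "QuasibinomialFResult",
    "mann_whitney_exact",
    "mann_whitney_null_counts",
    "quasibinomial_glm_f",
]


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float          # min(U_x, U_y) convention
    U_x: float        # statistic counting (x > y) pairs
    U_y: float
    p_value: float
    exact: bool       # False when ties forced the midrank/normal fallback
    n_x: int
    n_y: int


@dataclass(frozen=True)
class QuasibinomialFResult:
    F: float
    df1: int
    df2: int
    p_value: float
    dispersion: float
    deviance_full: float
    deviance_null: float
    coef: np.ndarray
    fitted: np.ndarray


def mann_whitney_null_counts(m: int, n: int) -> list[int]:
    """Exact null counts of the Mann-Whitney U statistic for group sizes
    (m, n): ``counts[u]`` is the number of the C(m+n, m) rank arrangements
    with U = u.  Computed by the Gaussian-binomial product formula in exact
    integer arithmetic; sums to C(m+n, m)."""
    if m < 1 or n < 1:
        raise ValueError("both group sizes must be >= 1")
    maxu = m * n
    # coefficients of prod_{i=1..n} (1 - q^(m+i)) / (1 - q^i)
    poly = [0] * (maxu + 1)
    poly[0] = 1
    for i in range(1, n + 1):
        nxt = [0] * (maxu + 1)
        for j, c in enumerate(poly):          # multiply by (1 - q^(m+i))
            if c:
                nxt[j] += c
                if j + m + i <= maxu:
                    nxt[j + m + i] -= c
        for j in range(i, maxu + 1):          # divide by (1 - q^i)
            nxt[j] += nxt[j - i]
        poly = nxt
    return poly


def mann_whitney_exact(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> MannWhitneyResult:
    """Exact Mann-Whitney U test.

    U_x counts pairs where an x-observation exceeds a y-observation; the
    reported ``U`` is min(U_x, U_y).  With tie-free data the p-value comes
    from the exact null distribution; with ties, U uses midranks and the
    p-value falls back to the tie-corrected normal approximation (flagged
    by ``exact=False``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    m, n = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks under ties
    r_x = ranks[:m].sum()
    u_x = r_x - m * (m + 1) / 2.0
    u_y = m * n - u_x
    u_min = min(u_x, u_y)
    has_ties = np.unique(pooled).size < pooled.size

    if not has_ties:
        counts = mann_whitney_null_counts(m, n)
        total = sum(counts)
        k = int(round(u_min))
        lower = sum(counts[: k + 1])
        if alternative == "two-sided":
            # doubling the smaller tail; distribution is symmetric about mn/2
            p = min(1.0, 2.0 * lower / total)
        elif alternative == "less":
            p = sum(counts[: int(round(u_x)) + 1]) / total
        elif alternative == "greater":
            p = sum(counts[int(round(u_x)):]) / total
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return MannWhitneyResult(u_min, u_x, u_y, float(p), True, m, n)

    # tie fallback: normal approximation with tie correction
    warnings.warn(
        "ties present: exact null unavailable, using tie-corrected normal "
        "approximation",
        stacklevel=2,
    )
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    N = m + n
    mu = m * n / 2.0
    sigma = math.sqrt(m * n / 12.0 * (N + 1 - tie_term / (N * (N - 1))))
    if sigma == 0:
        return MannWhitneyResult(u_min, u_x, u_y, 1.0, False, m, n)
    z = (u_x - mu) / sigma
    if alternative == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif alternative == "less":
        p = sps.norm.cdf(z)
    elif alternative == "greater":
        p = sps.norm.sf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return MannWhitneyResult(u_min, u_x, u_y, float(min(p, 1.0)), False, m, n)


def _binomial_deviance(s: np.ndarray, t: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(s > 0, s * np.log(s / (t * mu)), 0.0)
        term2 = np.where(t - s > 0, (t - s) * np.log((t - s) / (t - t * mu)), 0.0)
    return float(2.0 * (term1 + term2).sum())


def _irls_logit(
    X: np.ndarray,
    s: np.ndarray,
    t: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Binomial-logit IRLS on grouped counts; returns (beta, mu, deviance)."""
    eps = 1e-10
    p_obs = s / t
    mu = np.clip((s + 0.5) / (t + 1.0), eps, 1 - eps)
    dev = _binomial_deviance(s, t, mu)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        w = t * mu * (1 - mu)
        z = np.log(mu / (1 - mu)) + (p_obs - mu) / (mu * (1 - mu))
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError as exc:  # singular design
            raise RuntimeError("IRLS failed: singular weighted design") from exc
        eta = X @ beta
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), eps, 1 - eps)
        new_dev = _binomial_deviance(s, t, mu)
        if abs(new_dev - dev) < tol * (abs(dev) + 0.1):
            dev = new_dev
            break
        dev = new_dev
    else:
        raise RuntimeError("IRLS did not converge within max_iter")
    if (mu <= 2 * eps).any() or (mu >= 1 - 2 * eps).any():
        warnings.warn(
            "fitted probabilities on the boundary (complete separation)",
            stacklevel=3,
        )
    return beta, mu, dev


def quasibinomial_glm_f(
    data: pd.DataFrame | Sequence[tuple[int, int, str]],
    successes: str = "successes",
    total: str = "total",
    group: str = "group",
) -> QuasibinomialFResult:
    """Quasibinomial GLM F-test of a group effect on grouped proportions.

    ``data`` holds one row per individual with success/total counts and a
    categorical group.  Fits the group-effect model and the intercept-only
    model by IRLS; F = (deviance reduction / df1) / dispersion, with
    dispersion = Pearson chi²/df of the full model, referred to
    F(df1, df2 = residual df of the full model).
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(data, columns=[successes, total, group])
    s = data[successes].to_numpy(dtype=float)
    t = data[total].to_numpy(dtype=float)
    g = data[group].astype("category")
    if (s < 0).any() or (s > t).any():
        raise ValueError("need 0 <= successes <= total")
    levels = list(g.cat.categories)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if len(data) < len(levels) + 1:
        raise ValueError("need more individuals than groups")

    dummies = pd.get_dummies(g, drop_first=True).to_numpy(dtype=float)
    X_full = np.column_stack([np.ones(len(data)), dummies])
    X_null = np.ones((len(data), 1))

    beta, mu, dev_full = _irls_logit(X_full, s, t)
    _, _, dev_null = _irls_logit(X_null, s, t)

    df1 = X_full.shape[1] - 1
    df2 = len(data) - X_full.shape[1]
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")
    pearson = float((((s - t * mu) ** 2) / (t * mu * (1 - mu))).sum())
    dispersion = pearson / df2
    F = ((dev_null - dev_full) / df1) / dispersion
    p = float(sps.f.sf(F, df1, df2))
    return QuasibinomialFResult(
        float(F), df1, df2, p, dispersion, dev_full, dev_null, beta, mu
    )
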