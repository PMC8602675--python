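"""Log-log regression, elasticities and nonparametric tests.

The central model is an ordinary-least-squares fit on natural-log scales,

    ln(YLL rate) = b0 + b1 ln(aPM2.5) + b2 ln(HAP) + eps,

whose slopes are elasticity-type coefficients: a (1+p)-fold increase in a
predictor multiplies the outcome by (1+p)^b, i.e. changes it by
100((1+p)^b - 1) percent.

The rank-based tests (Spearman correlation, Kruskal-Wallis by ranks, Dunn's
post-hoc pairwise comparisons with Bonferroni correction) are implemented
explicitly with mid-ranks and the standard tie corrections; scipy supplies
only rank assignment and distribution tails. Exact permutation versions of
the Kruskal-Wallis and Dunn p-values are provided for small samples
(total n <= 10) and serve as independent oracles in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ArgumentError, DomainError

__all__ = [
    "RegressionFit",
    "TestResult",
    "fit_loglog",
    "elasticity",
    "spearman",
    "kruskal_wallis",
    "dunn_posthoc",
    "kruskal_wallis_exact",
    "dunn_exact",
]


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of a natural-log-linear model.

    ``coef`` maps predictor name -> slope on the ln-ln scale; the intercept
    is stored separately. ``se`` and ``p_values`` are keyed identically, with
    the intercept under ``"intercept"``.
    """

    intercept: float
    coef: dict[str, float]
    se: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    f_stat: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n: int
    residuals: np.ndarray = field(repr=False)
    design: np.ndarray = field(repr=False)

    def model_string(self, outcome: str = "YLL", ndigits: int = 3) -> str:
        terms = " + ".join(
            f"{round(b, ndigits):g} × log({name})" for name, b in self.coef.items()
        )
        return f"log({outcome}) = {round(self.intercept, ndigits):g} + {terms}"


@dataclass(frozen=True)
class TestResult:
    """Outcome of a correlation or rank test."""

    method: str
    statistic: float
    p_value: float
    df: int | None = None
    group_sizes: tuple[int, ...] | None = None
    n: int | None = None
    adjusted_p: float | None = None
    pair: tuple[str, str] | None = None


def fit_loglog(outcome, predictors: Mapping[str, Sequence[float]]) -> RegressionFit:
    """OLS on natural-log-transformed outcome and predictors.

    All values must be strictly positive; zeros or negatives raise rather
    than being offset, because an additive offset silently changes the
    elasticity interpretation — filter such rows explicitly instead.
    """
    y = np.asarray(outcome, dtype=float)
    names = list(predictors)
    X_raw = np.column_stack([np.asarray(predictors[k], dtype=float) for k in names])
    if X_raw.shape[0] != y.shape[0]:
        raise ArgumentError("outcome and predictors must have equal length")
    n, k = X_raw.shape
    if n <= k + 1:
        raise ArgumentError(f"need more than {k + 1} observations, got {n}")
    if np.any(y <= 0) or np.any(X_raw <= 0):
        raise DomainError(
            "all outcome and predictor values must be positive for the log-log model; "
            "filter non-positive rows explicitly instead of offsetting"
        )
    ly = np.log(y)
    X = np.column_stack([np.ones(n), np.log(X_raw)])
    beta, _, rank, _ = np.linalg.lstsq(X, ly, rcond=None)
    if rank < k + 1:
        raise DomainError("design matrix is rank deficient (collinear predictors)")
    fitted = X @ beta
    resid = ly - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((ly - ly.mean()) ** 2))
    df_resid = n - (k + 1)
    sigma2 = rss / df_resid
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    if rss <= np.finfo(float).eps * max(tss, 1.0):  # essentially noiseless fit
        f_stat, f_p = math.inf, 0.0
        t_p = np.zeros(k + 1)
    else:
        f_stat = ((tss - rss) / k) / sigma2
        f_p = float(stats.f.sf(f_stat, k, df_resid))
        t = beta / se
        t_p = 2.0 * stats.t.sf(np.abs(t), df_resid)
    labels = ["intercept"] + names
    return RegressionFit(
        intercept=float(beta[0]),
        coef={name: float(b) for name, b in zip(names, beta[1:])},
        se={lab: float(s) for lab, s in zip(labels, se)},
        p_values={lab: float(p) for lab, p in zip(labels, t_p)},
        r_squared=float(r2),
        f_stat=float(f_stat),
        f_pvalue=f_p,
        df_model=k,
        df_resid=df_resid,
        n=n,
        residuals=resid,
        design=X,
    )


def elasticity(coef: float, pct_increase: float) -> float:
    """Percent change of the outcome when a predictor grows by a fraction
    ``pct_increase`` (0.10 = +10%), under a log-log slope ``coef``:
    100 ((1 + p)^coef - 1)."""
    if pct_increase <= -1:
        raise ArgumentError("pct_increase must exceed -1 (predictor stays positive)")
    return 100.0 * ((1.0 + pct_increase) ** coef - 1.0)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with mid-ranks on ties; p-value from the
    t approximation with n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ArgumentError("x and y must be equal-length 1-d arrays with n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise DomainError("correlation undefined for a constant vector")
    r = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return TestResult(method="spearman", statistic=r, p_value=p, df=n - 2, n=n)


def _rank_groups(groups):
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = stats.rankdata(pooled)
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    return pooled, ranks, split, sizes


def _tie_term(pooled: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def _kw_h(groups) -> tuple[float, int, int]:
    pooled, _, split, sizes = _rank_groups(groups)
    n = pooled.size
    h = 12.0 / (n * (n + 1)) * sum(
        len(g) * (g.mean() - (n + 1) / 2.0) ** 2 for g in split
    )
    tie = _tie_term(pooled)
    denom = 1.0 - tie / (n**3 - n)
    h = 0.0 if denom == 0 else h / denom
    return h, len(groups), n


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test by ranks with tie correction; p-value from the
    chi-square distribution with k - 1 degrees of freedom."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ArgumentError("need at least 2 non-empty groups")
    h, k, n = _kw_h(groups)
    if n < 5:
        raise ArgumentError("total sample size must be at least 5")
    p = float(stats.chi2.sf(h, k - 1))
    return TestResult(
        method="kruskal-wallis",
        statistic=h,
        p_value=p,
        df=k - 1,
        group_sizes=tuple(len(g) for g in groups),
        n=n,
    )


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    correction: str = "bonferroni",
) -> list[TestResult]:
    """Dunn's pairwise mean-rank comparisons after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T the tie term sum(t^3 - t); two-sided normal p, Bonferroni-adjusted
    by the number of pairwise comparisons actually made, k(k-1)/2.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ArgumentError("need at least 2 non-empty groups")
    if correction != "bonferroni":
        raise ArgumentError(f"unsupported correction {correction!r}")
    pooled, _, split, sizes = _rank_groups(groups)
    n = pooled.size
    if n < 5:
        raise ArgumentError("total sample size must be at least 5")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    tie = _tie_term(pooled)
    var_base = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        denom = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else (split[i].mean() - split[j].mean()) / denom
        p = float(2.0 * stats.norm.sf(abs(z)))
        out.append(
            TestResult(
                method="dunn",
                statistic=z,
                p_value=p,
                adjusted_p=min(1.0, m * p),
                group_sizes=(sizes[i], sizes[j]),
                n=n,
                pair=(labels[i], labels[j]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Exact permutation versions (small n): independent oracles for the
# chi-square / normal approximations above.
# ---------------------------------------------------------------------------

_EXACT_N_LIMIT = 10


def _iter_assignments(n: int, sizes: Sequence[int]):
    """Yield index tuples assigning n pooled observations to groups of the
    given sizes (each distinct partition once)."""
    idx = frozenset(range(n))

    def rec(remaining, sizes_left):
        if not sizes_left:
            yield ()
            return
        first_size, rest = sizes_left[0], sizes_left[1:]
        for combo in itertools.combinations(sorted(remaining), first_size):
            for tail in rec(remaining - set(combo), rest):
                yield (combo,) + tail

    yield from rec(idx, list(sizes))


def kruskal_wallis_exact(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis with an exact permutation p-value (total n <= 10).

    Enumerates every assignment of the pooled observations to groups of the
    observed sizes and reports the fraction with H at least as large as
    observed.
    """
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = pooled.size
    if n > _EXACT_N_LIMIT:
        raise ArgumentError(f"exact enumeration limited to n <= {_EXACT_N_LIMIT}")
    h_obs, k, _ = _kw_h(groups)
    count = total = 0
    for assign in _iter_assignments(n, sizes):
        perm_groups = [pooled[list(ix)] for ix in assign]
        h, _, _ = _kw_h(perm_groups)
        count += h >= h_obs - 1e-12
        total += 1
    return TestResult(
        method="kruskal-wallis-exact",
        statistic=h_obs,
        p_value=count / total,
        df=k - 1,
        group_sizes=tuple(sizes),
        n=n,
    )


def dunn_exact(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> list[TestResult]:
    """Dunn comparisons with exact permutation p-values (total n <= 10).

    The pairwise statistic is the same tie-corrected z as
    :func:`dunn_posthoc`; its two-sided p-value is the permutation fraction
    with |z| at least as large, Bonferroni-adjusted identically.
    """
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = pooled.size
    if n > _EXACT_N_LIMIT:
        raise ArgumentError(f"exact enumeration limited to n <= {_EXACT_N_LIMIT}")
    observed = dunn_posthoc(groups, labels=labels)
    m = len(observed)
    counts = np.zeros(m, dtype=int)
    total = 0
    for assign in _iter_assignments(n, sizes):
        perm_groups = [pooled[list(ix)] for ix in assign]
        perm = dunn_posthoc(perm_groups)
        for q, res in enumerate(perm):
            counts[q] += abs(res.statistic) >= abs(observed[q].statistic) - 1e-12
        total += 1
    out = []
    for q, res in enumerate(observed):
        p = counts[q] / total
        out.append(
            TestResult(
                method="dunn-exact",
                statistic=res.statistic,
                p_value=p,
                adjusted_p=min(1.0, m * p),
                group_sizes=res.group_sizes,
                n=n,
                pair=res.pair,
            )
        )
    return out
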