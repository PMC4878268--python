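"""Inferential statistics: feature-feature correlation and field homogeneity.

Two tests back the analysis, both reported as -log10 P:

* :func:`spearman_test` — Spearman rank correlation between two per-cell
  feature vectors.  For n > 10 the usual two-sided t approximation
  t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom is used; for
  n <= 10 the exact permutation null distribution of rho is enumerated.
* :func:`field_proportion_test` — homogeneity of a binary per-cell flag
  (e.g. "responder") across imaging fields.  Pearson's chi-squared test on
  the fields x {flag, not-flag} contingency table is the default, with a
  likelihood-ratio (G) test and, for two fields, Fisher's exact test as
  options.

P-values are floored at the smallest positive double so -log10 P stays
finite; results carry a flag when the floor was hit.  No multiple-testing
correction is applied by default (a Bonferroni helper is provided).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

_P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class TestResult:
    """A single hypothesis-test outcome."""

    statistic: float
    p_value: float
    neg_log10_p: float
    n: int
    method: str
    p_floored: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p-value must lie in (0, 1], got {self.p_value}")


def _result(statistic: float, p: float, n: int, method: str) -> TestResult:
    floored = p < _P_FLOOR
    p = max(float(p), _P_FLOOR)
    return TestResult(
        statistic=float(statistic),
        p_value=p,
        neg_log10_p=float(-math.log10(p)),
        n=int(n),
        method=method,
        p_floored=floored,
    )


def _spearman_rho(rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    rx = rank_x - rank_x.mean()
    ry = rank_y - rank_y.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def _exact_spearman_p(rank_x: np.ndarray, rank_y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all pairings of the rank vectors."""
    n = len(rank_x)
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    rx = rank_x - rank_x.mean()
    denom_x = rx @ rx
    for perm in itertools.permutations(range(n)):
        ry = rank_y[list(perm)]
        ryc = ry - ry.mean()
        rho = rx @ ryc / np.sqrt(denom_x * (ryc @ ryc))
        total += 1
        if abs(rho) >= target:
            count += 1
    return count / total


def spearman_test(x: np.ndarray, y: np.ndarray, exact_max_n: int = 10) -> TestResult:
    """Two-sided Spearman rank-correlation test.

    Ties receive average ranks.  With n <= ``exact_max_n`` the full
    permutation distribution of rho is enumerated (exact test); beyond that
    the classical t approximation on n-2 degrees of freedom is used — the
    sample sizes of a whole imaging run (hundreds of cells) are firmly in
    approximation territory.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector; rank correlation undefined")
    n = len(x)
    rank_x = sps.rankdata(x)
    rank_y = sps.rankdata(y)
    rho = _spearman_rho(rank_x, rank_y)
    if n <= exact_max_n:
        p = _exact_spearman_p(rank_x, rank_y, rho)
        return _result(rho, p, n, "spearman-exact")
    if abs(rho) >= 1.0:
        return _result(rho, 0.0, n, "spearman-t")
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return _result(rho, min(p, 1.0), n, "spearman-t")


def field_proportion_test(
    responder_flags: np.ndarray,
    field_ids: list[str] | np.ndarray,
    method: str = "chi2",
) -> TestResult:
    """Test homogeneity of a binary flag's proportion across imaging fields.

    Builds the fields x {True, False} contingency table and tests the null
    that the flagged proportion is the same in every field.  ``method`` is
    ``"chi2"`` (Pearson chi-squared, no continuity correction — the
    default), ``"lrt"`` (likelihood-ratio / G test) or ``"fisher"``
    (Fisher's exact, two fields only).  Fields with zero cells are dropped
    with a warning; fewer than two remaining fields is an error.
    """
    flags = np.asarray(responder_flags).astype(bool)
    fields = pd.Series(field_ids).astype(str)
    if len(flags) != len(fields):
        raise ValueError("one flag per cell required")
    counts = pd.crosstab(fields, pd.Series(flags, name="flag")).reindex(
        columns=[True, False], fill_value=0
    )
    empty = counts.index[counts.sum(axis=1) == 0].tolist()
    if empty:
        warnings.warn(f"dropping empty field(s): {empty}")
        counts = counts.drop(index=empty)
    if len(counts) < 2:
        raise ValueError("need at least 2 non-empty fields")
    table = counts.to_numpy()
    n = int(table.sum())
    if method == "chi2" or method == "lrt":
        if (table.sum(axis=0) == 0).any():
            # flag identical for every cell: no evidence against homogeneity
            return _result(0.0, 1.0, n, f"{method}-homogeneity")
        lam = "pearson" if method == "chi2" else "log-likelihood"
        res = sps.chi2_contingency(table, correction=False, lambda_=lam)
        return _result(res.statistic, res.pvalue, n, f"{method}-homogeneity")
    if method == "fisher":
        if table.shape[0] != 2:
            raise ValueError("fisher exact test supports exactly 2 fields")
        stat, p = sps.fisher_exact(table)
        return _result(stat, p, n, "fisher-exact")
    raise ValueError(f"unknown method {method!r}; expected chi2, lrt or fisher")


def bonferroni(results: list[TestResult]) -> list[TestResult]:
    """Bonferroni-adjusted copies of a batch of test results (optional)."""
    m = len(results)
    return [
        _result(r.statistic, min(1.0, r.p_value * m), r.n, r.method + "+bonferroni")
        for r in results
    ]


def results_frame(named: dict[str, TestResult]) -> pd.DataFrame:
    """CSV-ready table of named test results."""
    return pd.DataFrame(
        [
            {
                "test": r.method,
                "variables": name,
                "n": r.n,
                "statistic": r.statistic,
                "p": r.p_value,
                "neg_log10_p": r.neg_log10_p,
            }
            for name, r in named.items()
        ]
    )


__all__ = [
    "TestResult",
    "spearman_test",
    "field_proportion_test",
    "bonferroni",
    "results_frame",
]
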