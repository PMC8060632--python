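"""Coincidence test for several linear regressions.

Given k groups of (x, y) points, the question is whether one common
straight line fits as well as k separate lines — i.e. whether allometric
relations fitted per cultivar or per N treatment may be pooled.  The
four-step procedure:

1. fit the single pooled OLS line and record its error sum of squares
   (``rss_pooled``, df = n − 2);
2. fit each group's own OLS line and sum their error sums of squares
   (``rss_within``, df = n − 2k);
3. difference the two decompositions: ``ss_diff = rss_pooled −
   rss_within`` on ``df_diff = 2(k − 1)`` degrees of freedom;
4. form F = (ss_diff / df_diff) / (rss_within / df_within) and compare
   with the upper-alpha F quantile.

This is the textbook extra-sum-of-squares F test of the 2-parameter
pooled model against the 2k-parameter separate-lines model.  For
allometric data the comparison is run in log-log space, on the linearized
models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "RegressionComparison",
    "compare_regressions",
    "compare_from_dataframe",
    "f_critical",
]


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper-``alpha`` quantile of the F(df1, df2) distribution.

    Computed through the inverse regularized incomplete beta function;
    deterministic.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if df1 < 1 or df2 < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    return float(scipy.stats.f.ppf(1.0 - alpha, df1, df2))


def _line_rss(x: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of the OLS line y ~ 1 + x."""
    X = np.column_stack([np.ones_like(x), x])
    _, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2:
        # degenerate x within a group: residuals of the best-fitting line
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ beta) ** 2))
    return float(rss[0]) if rss.size else 0.0


@dataclass(frozen=True)
class RegressionComparison:
    """Residual decomposition and F decision of the coincidence test.

    ``poolable`` is True when F does not exceed the critical value at
    ``alpha``, i.e. a single line is statistically adequate.  When the
    individual lines fit perfectly (``rss_within = 0``) while the pooled
    line does not, F is reported as ``inf`` and the groups are declared
    not poolable.
    """

    k: int
    n_total: int
    rss_pooled: float
    df_pooled: int
    rss_within: float
    df_within: int
    ss_diff: float
    df_diff: int
    ms_diff: float
    ms_within: float
    f: float
    f_crit: float
    alpha: float
    p_value: float
    poolable: bool

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        return d

    def summary(self) -> str:
        rows = [
            ("single line", self.rss_pooled, self.df_pooled, ""),
            ("individual lines", self.rss_within, self.df_within,
             f"{self.ms_within:.5g}"),
            ("difference", self.ss_diff, self.df_diff,
             f"{self.ms_diff:.5g}"),
        ]
        out = [
            f"Comparison of {self.k} regression lines "
            f"(n = {self.n_total}, alpha = {self.alpha})",
            f"{'source':<18}{'SS':>12}{'df':>6}{'MS':>12}",
        ]
        for name, ss, df, ms in rows:
            out.append(f"{name:<18}{ss:>12.5g}{df:>6}{ms:>12}")
        out.append(
            f"F = {self.f:.4g}   F_crit({self.df_diff}, {self.df_within}) "
            f"= {self.f_crit:.4g}   p = {self.p_value:.4g}"
        )
        out.append(
            "decision: lines may be pooled" if self.poolable
            else "decision: lines differ; do not pool"
        )
        return "\n".join(out)


def compare_regressions(
    groups: Sequence[tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
) -> RegressionComparison:
    """Run the coincidence F test on k >= 2 groups of (x, y) points.

    Each group needs at least 3 points and all coordinates must be
    finite.  For allometric comparisons pass log-transformed data.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    k = len(groups)
    if k < 2:
        raise ValueError(f"need at least 2 groups, got {k}")
    xs, ys = [], []
    for i, (x, y) in enumerate(groups):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError(f"group {i}: x and y lengths differ")
        if x.size < 3:
            raise ValueError(
                f"group {i} has only {x.size} points; at least 3 are "
                "required to fit its line"
            )
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError(f"group {i} contains non-finite values")
        xs.append(x)
        ys.append(y)

    n_total = sum(x.size for x in xs)
    df_pooled = n_total - 2
    df_within = n_total - 2 * k
    if df_within <= 0:
        raise ValueError(
            f"not enough observations: n - 2k = {df_within} <= 0"
        )

    rss_pooled = _line_rss(np.concatenate(xs), np.concatenate(ys))
    rss_within = sum(_line_rss(x, y) for x, y in zip(xs, ys))
    ss_diff = max(rss_pooled - rss_within, 0.0)
    df_diff = df_pooled - df_within  # = 2(k - 1)

    ms_diff = ss_diff / df_diff
    ms_within = rss_within / df_within
    # numeric-zero guard: residuals below this fraction of the total y
    # variation are fit-is-exact round-off, not real scatter
    y_all = np.concatenate(ys)
    eps = 1e-12 * max(float(np.sum((y_all - y_all.mean()) ** 2)), 1e-300)
    if rss_within > eps:
        f = ms_diff / ms_within
        p = float(scipy.stats.f.sf(f, df_diff, df_within))
    elif ss_diff > eps:
        f, p = float("inf"), 0.0  # perfect separate lines, imperfect pooled
    else:
        f, p = 0.0, 1.0  # all groups on one exact line
    fc = f_critical(alpha, df_diff, df_within)
    return RegressionComparison(
        k=k, n_total=n_total,
        rss_pooled=rss_pooled, df_pooled=df_pooled,
        rss_within=rss_within, df_within=df_within,
        ss_diff=ss_diff, df_diff=df_diff,
        ms_diff=ms_diff, ms_within=ms_within,
        f=f, f_crit=fc, alpha=alpha, p_value=p,
        poolable=bool(f <= fc),
    )


def compare_from_dataframe(
    data: pd.DataFrame,
    y: str,
    x: str = "cc",
    group: str = "cultivar",
    alpha: float = 0.05,
    log: bool = True,
) -> RegressionComparison:
    """Coincidence test over the levels of a grouping column.

    With ``log=True`` (default) both variables are log-transformed first,
    matching the linearized allometric comparison; all values must then
    be strictly positive.
    """
    groups = []
    for _, sub in data.groupby(group, sort=True, observed=True):
        gx = sub[x].to_numpy(dtype=float)
        gy = sub[y].to_numpy(dtype=float)
        if log:
            if (gx <= 0).any() or (gy <= 0).any():
                raise ValueError(
                    f"log comparison requires positive {x!r} and {y!r}"
                )
            gx, gy = np.log(gx), np.log(gy)
        groups.append((gx, gy))
    return compare_regressions(groups, alpha=alpha)
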