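"""Allometric power-law regression Y = a * X**b.

The allometric function links canopy cover to growth indices: ``a`` is the
index value at full cover (X = 1, in the units of Y) and ``b`` the
dimensionless scaling exponent.  The default fitting space is log-linear:
ordinary least squares of ln Y on ln X, because multiplicative scatter on
a power law becomes additive Gaussian noise after the log transform and
because the regression-coincidence machinery operates on linearized
models.  A nonlinear mode (least squares on the original scale,
initialized from the log-linear estimates) is available for reporting
parity with original-scale tables.

Usage follows the Model/Results convention::

    res = AllometricModel(y, x).fit()
    res.a, res.b, res.ci95_a, res.r2
    res.predict([0.2, 0.5])
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

__all__ = ["AllometricModel", "AllometricResults", "fit_allometric"]


def _validate_positive(name: str, values: np.ndarray) -> None:
    bad = np.flatnonzero(~(values > 0) | ~np.isfinite(values))
    if bad.size:
        shown = ", ".join(map(str, bad[:10]))
        more = "" if bad.size <= 10 else f" (+{bad.size - 10} more)"
        raise ValueError(
            f"{name} must be strictly positive and finite; offending "
            f"rows: {shown}{more}"
        )


class AllometricModel:
    """Power-law model of ``y`` on ``x``, both strictly positive.

    Parameters
    ----------
    y, x : array-like
        Observations, same length >= 3, all > 0.
    space : {"log-linear", "nonlinear"}
        Fitting space (see module docstring).
    """

    def __init__(self, y, x, space: str = "log-linear"):
        if space not in ("log-linear", "nonlinear"):
            raise ValueError(f"unknown fitting space {space!r}")
        y = np.asarray(y, dtype=float).ravel()
        x = np.asarray(x, dtype=float).ravel()
        if y.size != x.size:
            raise ValueError(
                f"x and y must have the same length ({x.size} != {y.size})"
            )
        if y.size < 3:
            raise ValueError(f"need at least 3 observations, got {y.size}")
        _validate_positive("x", x)
        _validate_positive("y", y)
        if np.ptp(x) == 0:
            raise np.linalg.LinAlgError(
                "x is constant: the design matrix is rank deficient"
            )
        self.y = y
        self.x = x
        self.space = space

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, y: str, x: str = "cc",
        space: str = "log-linear",
    ) -> "AllometricModel":
        """Build the model from named columns of a records table."""
        return cls(data[y].to_numpy(), data[x].to_numpy(), space=space)

    def fit(self) -> "AllometricResults":
        """Estimate (a, b) with standard errors, 95% CIs and R^2."""
        log_res = sm.OLS(
            np.log(self.y), sm.add_constant(np.log(self.x))
        ).fit()
        log_a, b = log_res.params
        if self.space == "log-linear":
            ci = log_res.conf_int(alpha=0.05)
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = float(log_res.rsquared)
            if not np.isfinite(r2):  # constant ln y: R^2 undefined
                r2 = 1.0 if log_res.ssr <= 1e-24 else 0.0
            return AllometricResults(
                model=self,
                a=float(np.exp(log_a)),
                b=float(b),
                se_log_a=float(log_res.bse[0]),
                se_b=float(log_res.bse[1]),
                ci95_a=(float(np.exp(ci[0, 0])), float(np.exp(ci[0, 1]))),
                ci95_b=(float(ci[1, 0]), float(ci[1, 1])),
                r2=r2,
                n=int(self.y.size),
                space="log-linear",
            )
        # nonlinear: original-scale least squares seeded by the log fit
        popt, pcov = scipy.optimize.curve_fit(
            lambda x, a, b: a * x ** b,
            self.x, self.y, p0=[np.exp(log_a), b], maxfev=10000,
        )
        a_hat, b_hat = popt
        se_a, se_b = np.sqrt(np.diag(pcov))
        tq = scipy.stats.t.ppf(0.975, self.y.size - 2)
        resid = self.y - a_hat * self.x ** b_hat
        sst = float(np.sum((self.y - self.y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 1.0
        return AllometricResults(
            model=self,
            a=float(a_hat),
            b=float(b_hat),
            se_log_a=float(se_a / a_hat),  # delta-method SE of ln a
            se_b=float(se_b),
            ci95_a=(float(a_hat - tq * se_a), float(a_hat + tq * se_a)),
            ci95_b=(float(b_hat - tq * se_b), float(b_hat + tq * se_b)),
            r2=max(0.0, min(1.0, r2)),
            n=int(self.y.size),
            space="nonlinear",
        )


@dataclass(frozen=True)
class AllometricResults:
    """Fitted power law with uncertainties.

    ``se_log_a`` is the standard error of ln a (the intercept of the
    linearized model); the CI for ``a`` is asymmetric because it is
    back-transformed from the log scale in log-linear mode.  ``r2`` is
    reported in the fitting space recorded in ``space``.
    """

    model: AllometricModel
    a: float
    b: float
    se_log_a: float
    se_b: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    r2: float
    n: int
    space: str

    def predict(self, x) -> np.ndarray:
        """Evaluate a * x**b; x must be strictly positive."""
        x = np.asarray(x, dtype=float)
        _validate_positive("x", np.atleast_1d(x))
        return self.a * x ** self.b

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b,
            "se_log_a": self.se_log_a, "se_b": self.se_b,
            "ci95_a": list(self.ci95_a), "ci95_b": list(self.ci95_b),
            "r2": self.r2, "n": self.n, "space": self.space,
        }

    def summary(self) -> str:
        lines = [
            "Allometric fit  Y = a * X^b",
            f"  space : {self.space}   n = {self.n}   R^2 = {self.r2:.3f}",
            f"  a = {self.a:.4g}  95% CI [{self.ci95_a[0]:.4g}, "
            f"{self.ci95_a[1]:.4g}]  (SE of ln a: {self.se_log_a:.3g})",
            f"  b = {self.b:.4g}  95% CI [{self.ci95_b[0]:.4g}, "
            f"{self.ci95_b[1]:.4g}]  (SE: {self.se_b:.3g})",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, scatter: bool = True):
        """Scatter the data and overlay the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if scatter:
            ax.plot(self.model.x, self.model.y, "o", alpha=0.5, ms=4)
        grid = np.linspace(self.model.x.min(), self.model.x.max(), 200)
        ax.plot(grid, self.predict(grid), "-",
                label=f"y = {self.a:.3g} x^{self.b:.3g}")
        ax.set_xlabel("X")
        ax.set_ylabel("Y")
        ax.legend()
        return ax


def fit_allometric(x, y, space: str = "log-linear") -> AllometricResults:
    """Convenience wrapper: ``AllometricModel(y, x, space).fit()``."""
    return AllometricModel(y, x, space=space).fit()
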