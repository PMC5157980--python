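"""Prediction accuracy as a function of training sample size.

The expected squared accuracy of a genomic predictor follows
r^2 = h^2 / (1 + M_e / (n h^2)) for training size n and effective number
of independent loci M_e, which is linear on the (1/n, 1/r^2) scale:
1/r^2 = 1/h^2 + (M_e / h^4) / n.  Regressing observed 1/r^2 on 1/n
therefore yields an intercept whose inverse square root is the maximum
accuracy achievable from the fitted marker panel, and lets measured
accuracies be projected to larger cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AccuracyCurveFit:
    """OLS fit of 1/r^2 on 1/n with delta-method maximum accuracy."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    cov: np.ndarray                    # 2x2 covariance of (intercept, slope)
    max_accuracy: float | None         # 1/sqrt(intercept), None if invalid
    se_max_accuracy: float | None
    points: pd.DataFrame               # n, r, inv_n, inv_r2

    @property
    def valid(self) -> bool:
        return self.max_accuracy is not None


def fit_inverse_r2(points) -> AccuracyCurveFit:
    """Unweighted OLS of 1/r^2 against 1/n over (n, r) observations.

    ``points``: iterable of (n, r) pairs or a DataFrame with columns n, r;
    one point per (size, trial).  Requires every r > 0 and at least three
    distinct n.  A nonpositive intercept yields a flagged fit with the
    maximum accuracy undefined.
    """
    if isinstance(points, pd.DataFrame):
        n = points["n"].to_numpy(dtype=float)
        r = points["r"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        n, r = arr[:, 0], arr[:, 1]
    if (r <= 0).any():
        raise ValueError("all accuracies must be positive")
    if (n <= 0).any():
        raise ValueError("all sample sizes must be positive")
    if len(np.unique(n)) < 3:
        raise ValueError("need at least 3 distinct training sizes")

    x = 1.0 / n
    yv = 1.0 / r ** 2
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ coef
    dof = max(len(x) - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    b0, b1 = float(coef[0]), float(coef[1])

    if b0 > 0:
        rmax = 1.0 / np.sqrt(b0)
        se_rmax = 0.5 * b0 ** -1.5 * np.sqrt(cov[0, 0])
    else:
        warnings.warn("nonpositive intercept; maximum accuracy undefined")
        rmax = se_rmax = None
    return AccuracyCurveFit(
        intercept=b0, slope=b1,
        se_intercept=float(np.sqrt(cov[0, 0])),
        se_slope=float(np.sqrt(cov[1, 1])),
        cov=cov, max_accuracy=rmax, se_max_accuracy=se_rmax,
        points=pd.DataFrame({"n": n, "r": r, "inv_n": x, "inv_r2": yv}))


def project_accuracy(fit: AccuracyCurveFit, n_target: float
                     ) -> tuple[float, float]:
    """Projected accuracy (and delta-method SE) at a target training size."""
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    if fit.intercept <= 0:
        raise ValueError("fit has nonpositive intercept; cannot project")
    x = 1.0 / n_target
    denom = fit.intercept + fit.slope * x
    if denom <= 0:
        raise ValueError("projected 1/r^2 is nonpositive at this size")
    r = 1.0 / np.sqrt(denom)
    grad = -0.5 * denom ** -1.5 * np.array([1.0, x])
    se = float(np.sqrt(max(0.0, grad @ fit.cov @ grad)))
    return float(r), se


def fraction_of_maximum(r: float, h2: float, *, ci_slack: float = 0.0) -> float:
    """Accuracy as a percent of the ceiling sqrt(h2) set by the heritability.

    Returns 100 * r / sqrt(h2); reports round this to the nearest integer
    percent.  An accuracy exceeding its theoretical ceiling by more than
    ``ci_slack`` draws a warning rather than an error (sampling noise can
    push r slightly past sqrt(h2)).
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    ceiling = np.sqrt(h2)
    if r > ceiling + ci_slack:
        warnings.warn("accuracy exceeds its theoretical ceiling sqrt(h2)")
    return float(100.0 * r / ceiling)


def daetwyler_r2(h2: float, n: float, me: float) -> float:
    """Expected squared accuracy for training size n and M_e effective loci."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    if n <= 0 or me <= 0:
        raise ValueError("n and Me must be positive")
    return float(h2 / (1.0 + me / (n * h2)))
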