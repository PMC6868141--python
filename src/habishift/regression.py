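"""Regional driver-effect regressions on the logit scale.

Relates a region-level loss proportion to a driver covariate by ordinary
least squares of logit(y) on x: for the land-use driver x is itself a
logit-transformed proportion of converted land; for the climate driver x is
a raw temperature difference (change in the maximum temperature of the
warmest month).  Proportions are clamped into (0, 1) by a symmetric epsilon
before the logit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import logit

LOGIT_EPS = 1e-6


@dataclass
class LogitRegressionResult:
    slope: float
    intercept: float
    adj_r2: float
    n: int
    prediction_interval: np.ndarray  # (n, 2) 95% PI at the observed x, logit scale
    fitted: np.ndarray  # fitted logit(y)


def logit_regression(
    x: np.ndarray, y: np.ndarray, logit_x: bool = False, eps: float = LOGIT_EPS
) -> LogitRegressionResult:
    """OLS of logit(y) on x (x logit-transformed when ``logit_x``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y must be proportions in [0, 1]")
    yy = logit(np.clip(y, eps, 1 - eps))
    xx = logit(np.clip(x, eps, 1 - eps)) if logit_x else x
    if np.ptp(xx) < 1e-12:
        raise ValueError("constant x")
    X = sm.add_constant(xx)
    fit = sm.OLS(yy, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=0.05)
    pi = np.column_stack([pred["obs_ci_lower"], pred["obs_ci_upper"]])
    return LogitRegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        adj_r2=float(fit.rsquared_adj),
        n=len(x),
        prediction_interval=pi,
        fitted=np.asarray(fit.fittedvalues),
    )
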