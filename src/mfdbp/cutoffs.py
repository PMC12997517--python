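"""Logistic translation of MFD into probability-of-young-age cut-offs.

A single-predictor logistic regression models the probability that a biopsy
precedes the breakpoint age, P(ABx < psi | MFD), over the analysis subset.
Inverting the fitted model at chosen probabilities (80%, 50%, 20%) yields
MFD thresholds that partition patients into zones of high, intermediate and
low probability of being on the steep, pre-breakpoint limb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize

from .cohort import Cohort

logger = logging.getLogger("mfdbp")

__all__ = ["LogisticFit", "fit_age_logistic", "invert_probability", "zone_counts"]


@dataclass
class LogisticFit:
    intercept: float
    slope: float  # per fibres/mm^2; positive: higher MFD -> younger
    n: int
    breakpoint_age: float
    separation_flag: bool = False

    def predict_probability(self, mfd) -> np.ndarray:
        z = self.intercept + self.slope * np.asarray(mfd, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


def fit_age_logistic(cohort: Cohort, breakpoint_age: float) -> LogisticFit:
    """Maximum-likelihood logistic fit of indicator(ABx < breakpoint) on MFD.

    Perfect separation is flagged and the fit falls back to a weakly
    ridge-penalised likelihood so finite coefficients are still returned.
    """
    outcome = (cohort.ages < breakpoint_age).astype(float)
    mfd = cohort.mfd
    if outcome.sum() in (0, len(outcome)):
        raise ValueError("both outcome classes must be non-empty")
    X = sm.add_constant(mfd)
    separation = False
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.Logit(outcome, X).fit(disp=0, maxiter=200)
        params = res.params
        if not res.mle_retvals.get("converged", True) or np.abs(params[1]) > 1.0:
            raise sm.tools.sm_exceptions.PerfectSeparationError("suspect separation")
    except (
        sm.tools.sm_exceptions.PerfectSeparationError,
        sm.tools.sm_exceptions.PerfectSeparationWarning,
        np.linalg.LinAlgError,
    ):
        separation = True
        logger.warning("perfect separation detected; using ridge-penalised logistic fit")
        params = _ridge_logistic(mfd, outcome)
    return LogisticFit(
        intercept=float(params[0]),
        slope=float(params[1]),
        n=len(outcome),
        breakpoint_age=float(breakpoint_age),
        separation_flag=separation,
    )


def _ridge_logistic(mfd: np.ndarray, outcome: np.ndarray, lam: float = 1e-4) -> np.ndarray:
    scale = mfd.std()

    def nll(theta):
        z = theta[0] + theta[1] * mfd / scale
        return np.sum(np.logaddexp(0.0, z) - outcome * z) + lam * (theta @ theta)

    res = optimize.minimize(nll, x0=np.zeros(2), method="BFGS")
    return np.array([res.x[0], res.x[1] / scale])


def invert_probability(fit: LogisticFit, p: float) -> float:
    """MFD value at which the predicted probability equals ``p``.

    threshold = (logit(p) - intercept) / slope; at p = 0.5 this reduces to
    -intercept/slope.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if fit.slope == 0.0:
        raise ZeroDivisionError("zero slope: probability does not depend on MFD")
    return float((np.log(p / (1.0 - p)) - fit.intercept) / fit.slope)


def zone_counts(cohort: Cohort, high: float, low: float) -> dict[str, int]:
    """Patients per MFD zone: above ``high``, in [low, high], below ``low``.

    Values exactly on a threshold fall in the middle (inclusive-bounds)
    zone.  The three counts always sum to the cohort size.
    """
    if high <= low:
        raise ValueError(f"high threshold ({high}) must exceed low ({low})")
    mfd = cohort.mfd
    return {
        "above_high": int((mfd > high).sum()),
        "between": int(((mfd >= low) & (mfd <= high)).sum()),
        "below_low": int((mfd < low).sum()),
    }
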