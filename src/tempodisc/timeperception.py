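"""Anticipatory time perception: per-subject power-law fits.

Subjects mark on a 150-mm slider how long a prospective calendar horizon
feels.  The reading T (mm) as a function of calendar time t (months) is
modelled as a psychophysical power law

    T = alpha * t ** beta,

where ``alpha`` captures the overall level of time contraction and
``beta`` diminishing sensitivity to longer horizons (beta < 1 means the
felt difference between 48 and 60 months is smaller than between 3 and
15 months).  Both parameters are constrained to [0, 5].

Fitting is robust nonlinear least squares: a Huber loss whose scale is
re-estimated from the MAD of the current residuals and iterated to
convergence, started from the log-log OLS line.  Two exclusion stages
mirror standard practice for this paradigm: fits pinned to a parameter
bound are discarded, then boxplot (Tukey 1.5*IQR) outliers on alpha or
beta among the remaining fits.

Note on units: T is fitted in slider millimetres against t in months;
the slider has no calibrated month scale, so alpha absorbs the mm/month
conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .robust import mad_scale

__all__ = [
    "PARAM_BOUNDS",
    "TimePerceptionFit",
    "TimePerceptionModel",
    "powerlaw",
    "fit_time_perception",
    "fit_time_cohort",
    "flag_outlier_fits",
]

PARAM_BOUNDS = (0.0, 5.0)
_BOUND_TOL = 1e-6
_HUBER_TUNING = 1.345


def powerlaw(t, alpha, beta):
    """Subjective time ``alpha * t**beta``; t must be positive."""
    t = np.asarray(t, float)
    if np.any(t <= 0):
        raise ValueError("calendar time t must be positive")
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    return alpha * t ** beta


@dataclass
class TimePerceptionFit:
    """Per-subject power-law estimates with exclusion flags."""

    subject_id: object
    alpha: float
    beta: float
    residual_scale: float
    bound_hit: bool
    boxplot_outlier: bool = False

    @property
    def excluded(self) -> bool:
        return self.bound_hit or self.boxplot_outlier

    def summary(self) -> str:
        return (
            "Time-perception power-law fit\n"
            "-----------------------------\n"
            f"subject:        {self.subject_id}\n"
            f"alpha:          {self.alpha:.4f}\n"
            f"beta:           {self.beta:.4f}\n"
            f"residual scale: {self.residual_scale:.4f}\n"
            f"bound hit:      {self.bound_hit}\n"
            f"boxplot outlier:{self.boxplot_outlier}\n"
            f"excluded:       {self.excluded}"
        )


class TimePerceptionModel:
    """Robust power-law model for one subject's slider probes."""

    def __init__(self, horizon_months, slider_mm, subject_id=None):
        t = np.asarray(horizon_months, float)
        T = np.asarray(slider_mm, float)
        if t.shape != T.shape or t.ndim != 1:
            raise ValueError("horizons and readings must be matching 1-d arrays")
        if np.any(t <= 0):
            raise ValueError("horizons must be positive")
        if len(np.unique(t)) < 3:
            raise ValueError("need probes at >= 3 distinct horizons")
        self.t, self.T = t, T
        self.subject_id = subject_id

    def _start(self) -> np.ndarray:
        pos = self.T > 0
        lo, hi = PARAM_BOUNDS
        if pos.sum() >= 3:
            b, loga = np.polyfit(np.log(self.t[pos]), np.log(self.T[pos]), 1)
            alpha0 = float(np.clip(np.exp(loga), lo + 1e-3, hi - 1e-3))
            beta0 = float(np.clip(b, lo + 1e-3, hi - 1e-3))
        else:
            alpha0, beta0 = 1.0, 1.0
        return np.array([alpha0, beta0])

    def fit(self, max_outer: int = 50, tol: float = 1e-8) -> TimePerceptionFit:
        """Huber robust least squares with outer-iterated MAD scale."""
        theta = self._start()
        lo, hi = PARAM_BOUNDS

        def resid(p):
            return self.T - p[0] * self.t ** p[1]

        scale = mad_scale(resid(theta), center=0.0)
        for _ in range(max_outer):
            if scale <= tol:
                # (near-)exact data: plain least squares closes the fit
                res = least_squares(resid, theta, bounds=(lo, hi), xtol=1e-14,
                                    ftol=1e-14, gtol=1e-14)
                theta = res.x
                break
            res = least_squares(resid, theta, bounds=(lo, hi), loss="huber",
                                f_scale=_HUBER_TUNING * scale, xtol=1e-12,
                                ftol=1e-12, gtol=1e-12)
            new_scale = mad_scale(resid(res.x), center=0.0)
            done = (np.max(np.abs(res.x - theta)) < tol
                    and abs(new_scale - scale) < tol * (1.0 + scale))
            theta, scale = res.x, new_scale
            if done:
                break

        alpha, beta = float(theta[0]), float(theta[1])
        bound_hit = bool(
            min(alpha - lo, hi - alpha, beta - lo, hi - beta) <= _BOUND_TOL)
        return TimePerceptionFit(
            subject_id=self.subject_id, alpha=alpha, beta=beta,
            residual_scale=float(scale), bound_hit=bound_hit)


def fit_time_perception(probes, subject_id=None) -> TimePerceptionFit:
    """Fit one subject; ``probes`` is a DataFrame with
    ``horizon_months`` and ``slider_mm`` columns, or two arrays."""
    if isinstance(probes, pd.DataFrame):
        model = TimePerceptionModel(
            probes["horizon_months"], probes["slider_mm"],
            subject_id=subject_id)
    else:
        t, T = probes
        model = TimePerceptionModel(t, T, subject_id=subject_id)
    return model.fit()


def fit_time_cohort(probes: pd.DataFrame, flag_outliers: bool = True
                    ) -> pd.DataFrame:
    """Fit every subject in a long-format probe table.

    Returns one row per subject with alpha, beta, residual_scale and the
    bound-hit / boxplot-outlier / excluded flags (boxplot flags computed
    across the cohort unless ``flag_outliers`` is False).
    """
    fits = [
        fit_time_perception(grp, subject_id=sid)
        for sid, grp in probes.groupby("subject_id", sort=True)
    ]
    if flag_outliers:
        fits = flag_outlier_fits(fits)
    return pd.DataFrame(
        [{**f.__dict__, "excluded": f.excluded} for f in fits])


def _tukey_outlier_mask(v: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)


def flag_outlier_fits(fits: list[TimePerceptionFit]) -> list[TimePerceptionFit]:
    """Tukey boxplot rule per parameter among the non-bound-hit fits.

    Fences at Q1 - 1.5*IQR and Q3 + 1.5*IQR, applied separately to alpha
    and beta; bound-hit fits are excluded already and do not enter the
    quartiles.  With fewer than 5 usable fits no flag is set (warning).
    """
    clean = [f for f in fits if not f.bound_hit]
    if len(clean) < 5:
        warnings.warn(
            "fewer than 5 non-bound-hit fits: boxplot outliers not flagged",
            stacklevel=2)
        for f in fits:
            f.boxplot_outlier = False
        return fits
    alphas = np.array([f.alpha for f in clean])
    betas = np.array([f.beta for f in clean])
    mask = _tukey_outlier_mask(alphas) | _tukey_outlier_mask(betas)
    for f, flagged in zip(clean, mask):
        f.boxplot_outlier = bool(flagged)
    return fits
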