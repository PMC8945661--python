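"""Hyperbolic delay discounting and per-subject maximum-likelihood estimation.

Model
-----
The present-day subjective value of a delayed reward of magnitude ``A``
(RMB) at delay ``D`` (days) is hyperbolic,

    SV = A / (1 + k * D),

with discount rate ``k`` (day^-1).  A binary intertemporal choice between
an immediate smaller-sooner amount ``SS`` and the delayed option is
modelled with a logistic (softmax / Luce) choice rule,

    P(choose SS) = 1 / (1 + exp(-sigma * (SS - SV))),

where ``sigma`` (RMB^-1) measures how strongly choices track the value
difference.  ``(k, sigma)`` are estimated per subject by maximum
likelihood over that subject's choices, the search running in
``(log k, log sigma)`` space so positivity is automatic.

Subjects whose likelihood carries no usable information are screened out:
optimizer failure, estimates pinned to the search boundary, degenerate
all-SS / all-LL response patterns, and flat likelihoods (the fitted model
improves on coin-flipping by less than a chi-square(2) 95% likelihood-ratio
margin).  Retained fits report ``log_k = ln(k_hat)``, the scale on which
all downstream statistics operate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit

__all__ = [
    "ChoiceItem",
    "DiscountFit",
    "ExclusionReport",
    "HyperbolicDiscounting",
    "default_items",
    "subjective_value",
    "choice_probability",
    "negative_log_likelihood",
    "fit_subject",
    "fit_cohort",
]

# Search box for (log k, log sigma).  k in [e^-9, 1] day^-1 covers
# indifference across delays of 4-939 days; sigma in [1e-6, 10] RMB^-1
# spans coin-flipping to step-function choice at the item magnitudes.
LOGK_BOUNDS = (-9.0, 0.0)
LOGSIGMA_BOUNDS = (np.log(1e-6), np.log(10.0))

_BOUNDARY_TOL = 1e-3
# 95% quantile of chi-square(2): a fit whose likelihood-ratio statistic
# against the chance model falls below this is treated as flat.
_FLAT_LR_THRESHOLD = 5.991464547107979


@dataclass(frozen=True)
class ChoiceItem:
    """One intertemporal decision: SS now versus LL after a delay."""

    item_id: int
    ss_amount: float
    ll_amount: float
    delay_days: float

    def __post_init__(self) -> None:
        if not 0 < self.ss_amount < self.ll_amount:
            raise ValueError(
                f"item {self.item_id}: need 0 < ss_amount < ll_amount, "
                f"got {self.ss_amount}, {self.ll_amount}"
            )
        if self.delay_days <= 0:
            raise ValueError(f"item {self.item_id}: delay_days must be positive")


def default_items() -> pd.DataFrame:
    """The packaged 7-item choice set.

    The instrument used only ranges (SS 840-3990 RMB, LL 2311-8190 RMB,
    delays 4-939 days); the packaged items place amounts and delays
    log-uniformly inside those ranges with the endpoints included.  They
    are a synthetic stand-in for the original items, which are not
    public, and can be overridden by any items table with the same
    columns.
    """
    with resources.files("tempodisc.data").joinpath("default_items.csv").open() as fh:
        return pd.read_csv(fh)


def _as_item_arrays(items) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(items, pd.DataFrame):
        ids = items["item_id"].to_numpy()
        ss = items["ss_amount"].to_numpy(float)
        ll = items["ll_amount"].to_numpy(float)
        dd = items["delay_days"].to_numpy(float)
    else:
        items = list(items)
        ids = np.array([it.item_id for it in items])
        ss = np.array([it.ss_amount for it in items], float)
        ll = np.array([it.ll_amount for it in items], float)
        dd = np.array([it.delay_days for it in items], float)
    if len(ids) == 0:
        raise ValueError("empty item list")
    if np.any(ss <= 0) or np.any(ll <= ss) or np.any(dd <= 0):
        raise ValueError("invalid items: need 0 < ss < ll and delay > 0")
    return ids, ss, ll, dd


def subjective_value(ll_amount, k, delay_days):
    """Discounted present value ``A / (1 + k D)``; array-friendly."""
    ll_amount = np.asarray(ll_amount, float)
    k = np.asarray(k, float)
    delay_days = np.asarray(delay_days, float)
    if np.any(ll_amount < 0) or np.any(k < 0) or np.any(delay_days < 0):
        raise ValueError("ll_amount, k and delay_days must be non-negative")
    return ll_amount / (1.0 + k * delay_days)


def choice_probability(ss_amount, sv, sigma):
    """P(choose SS) under the logistic choice rule; overflow-safe."""
    sigma = np.asarray(sigma, float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    return expit(sigma * (np.asarray(ss_amount, float) - np.asarray(sv, float)))


def negative_log_likelihood(k, sigma, chose_ss, items) -> float:
    """Negative log-likelihood of a subject's choices at ``(k, sigma)``."""
    _, ss, ll, dd = _as_item_arrays(items)
    chose_ss = np.asarray(chose_ss, float)
    if chose_ss.shape != ss.shape:
        raise ValueError("one response per item required")
    x = sigma * (ss - ll / (1.0 + k * dd))
    return float(-(np.sum(chose_ss * log_expit(x) + (1.0 - chose_ss) * log_expit(-x))))


def _nll_and_grad(theta, chose_ss, ss, ll, dd):
    """NLL and its gradient in (log k, log sigma)."""
    logk, logsig = theta
    k = np.exp(logk)
    sigma = np.exp(logsig)
    sv = ll / (1.0 + k * dd)
    delta = ss - sv
    x = sigma * delta
    nll = -np.sum(chose_ss * log_expit(x) + (1.0 - chose_ss) * log_expit(-x))
    p = expit(x)
    resid = p - chose_ss  # d nll / d x
    # dSV/dk = -A D / (1 + kD)^2, so d x/d k = sigma * A D / (1+kD)^2
    dx_dk = sigma * ll * dd / (1.0 + k * dd) ** 2
    g_logk = k * np.sum(resid * dx_dk)
    g_logsig = np.sum(resid * x)
    return float(nll), np.array([g_logk, g_logsig])


def _grid_logpmf(ss, ll, dd, logk_grid, logsig_grid):
    """log P(SS) and log P(LL) per item on the (log k, log sigma) grid.

    Returns arrays of shape (G, n_items) with G = len(logk)*len(logsig).
    """
    k = np.exp(logk_grid)[:, None, None]
    sigma = np.exp(logsig_grid)[None, :, None]
    x = sigma * (ss[None, None, :] - ll[None, None, :] / (1.0 + k * dd[None, None, :]))
    lp_ss = log_expit(x)
    lp_ll = log_expit(-x)
    g = len(logk_grid) * len(logsig_grid)
    return lp_ss.reshape(g, -1), lp_ll.reshape(g, -1)


@dataclass
class DiscountFit:
    """Per-subject discounting estimates (the Results object)."""

    subject_id: object
    k: float
    sigma: float
    log_k: float
    nll: float
    converged: bool
    n_choices: int
    exclusion_reason: str | None = None

    def summary(self) -> str:
        lines = [
            "Hyperbolic discounting fit",
            "--------------------------",
            f"subject:        {self.subject_id}",
            f"n choices:      {self.n_choices}",
            f"k (day^-1):     {self.k:.6g}",
            f"log k:          {self.log_k:.4f}",
            f"sigma (RMB^-1): {self.sigma:.6g}",
            f"NLL:            {self.nll:.4f}",
            f"converged:      {self.converged}",
        ]
        if self.exclusion_reason:
            lines.append(f"excluded:       {self.exclusion_reason}")
        return "\n".join(lines)


class HyperbolicDiscounting:
    """Maximum-likelihood model for one subject's intertemporal choices.

    Parameters
    ----------
    chose_ss : sequence of 0/1
        One indicator per item, 1 when the immediate option was taken.
    items : DataFrame or sequence of ChoiceItem
        The decision set (``item_id, ss_amount, ll_amount, delay_days``).
    subject_id : hashable, optional
        Carried through to the results.
    """

    def __init__(self, chose_ss, items, subject_id=None):
        self.item_ids, self.ss, self.ll, self.dd = _as_item_arrays(items)
        self.chose_ss = np.asarray(chose_ss, float)
        if self.chose_ss.size == 0:
            raise ValueError("at least one response is required")
        if self.chose_ss.shape != self.ss.shape:
            raise ValueError("number of responses must match number of items")
        if not np.isin(self.chose_ss, (0.0, 1.0)).all():
            raise ValueError("chose_ss must be binary")
        self.subject_id = subject_id

    @classmethod
    def from_responses(cls, responses: pd.DataFrame, items: pd.DataFrame,
                       subject_id=None) -> "HyperbolicDiscounting":
        """Build from long-format rows (``item_id, chose_ss``)."""
        ids = set(items["item_id"])
        unknown = set(responses["item_id"]) - ids
        if unknown:
            raise KeyError(f"responses reference unknown item ids: {sorted(unknown)}")
        merged = responses.merge(items, on="item_id", validate="many_to_one")
        return cls(merged["chose_ss"].to_numpy(), merged[
            ["item_id", "ss_amount", "ll_amount", "delay_days"]], subject_id=subject_id)

    def nloglike(self, k: float, sigma: float) -> float:
        x = sigma * (self.ss - self.ll / (1.0 + k * self.dd))
        return float(-(np.sum(self.chose_ss * log_expit(x)
                              + (1.0 - self.chose_ss) * log_expit(-x))))

    def _chance_nll(self) -> float:
        return self.chose_ss.size * np.log(2.0)

    def _polish(self, starts: np.ndarray) -> tuple[np.ndarray, float, bool]:
        best_theta, best_nll, ok = None, np.inf, False
        bounds = [LOGK_BOUNDS, LOGSIGMA_BOUNDS]
        for theta0 in starts:
            res = minimize(_nll_and_grad, theta0, jac=True,
                           args=(self.chose_ss, self.ss, self.ll, self.dd),
                           method="L-BFGS-B", bounds=bounds)
            if res.fun < best_nll:
                best_theta, best_nll, ok = res.x, float(res.fun), bool(res.success)
        return best_theta, best_nll, ok

    def _screen(self, theta, nll, opt_ok) -> str | None:
        if not opt_ok:
            return "optimizer_failure"
        if self.chose_ss.min() == self.chose_ss.max():
            return "degenerate_pattern"
        lo_k, hi_k = LOGK_BOUNDS
        lo_s, _ = LOGSIGMA_BOUNDS
        # k on a search bound, or sigma collapsed to zero, means the
        # discount rate is not identified.  sigma at its *upper* bound is
        # a perfectly consistent responder: k is pinned between two item
        # indifference points and the subject is kept.
        if (theta[0] - lo_k < _BOUNDARY_TOL or hi_k - theta[0] < _BOUNDARY_TOL
                or theta[1] - lo_s < _BOUNDARY_TOL):
            return "boundary_estimate"
        if 2.0 * (self._chance_nll() - nll) < _FLAT_LR_THRESHOLD:
            return "flat_likelihood"
        return None

    def fit(self, n_starts: int = 9, starts: np.ndarray | None = None) -> DiscountFit:
        """Multi-start bounded MLE over (log k, log sigma).

        The default start grid is 3x3 over the search box; additional
        starts round-robin the box.  Any failure mode (optimizer,
        boundary, degenerate or flat likelihood) clears ``converged``
        and records a reason.
        """
        if starts is None:
            side = max(3, int(np.ceil(np.sqrt(n_starts))))
            ks = np.linspace(*LOGK_BOUNDS, side + 2)[1:-1]
            sgs = np.linspace(*LOGSIGMA_BOUNDS, side + 2)[1:-1]
            starts = np.array([(a, b) for a in ks for b in sgs])[:max(n_starts, 9)]
        theta, nll, opt_ok = self._polish(np.atleast_2d(starts))
        reason = self._screen(theta, nll, opt_ok)
        k_hat = float(np.exp(theta[0]))
        return DiscountFit(
            subject_id=self.subject_id,
            k=k_hat,
            sigma=float(np.exp(theta[1])),
            log_k=float(theta[0]),
            nll=nll,
            converged=reason is None,
            n_choices=int(self.chose_ss.size),
            exclusion_reason=reason,
        )


def fit_subject(responses, items, subject_id=None, n_starts: int = 9) -> DiscountFit:
    """Functional wrapper: fit one subject from long-format responses."""
    if isinstance(responses, pd.DataFrame):
        model = HyperbolicDiscounting.from_responses(responses, _items_frame(items),
                                                     subject_id=subject_id)
    else:
        model = HyperbolicDiscounting(responses, items, subject_id=subject_id)
    return model.fit(n_starts=n_starts)


def _items_frame(items) -> pd.DataFrame:
    if isinstance(items, pd.DataFrame):
        return items
    ids, ss, ll, dd = _as_item_arrays(items)
    return pd.DataFrame({"item_id": ids, "ss_amount": ss,
                         "ll_amount": ll, "delay_days": dd})


@dataclass
class ExclusionReport:
    """Counts of subjects dropped from log-k analyses, by reason."""

    n_subjects: int
    n_excluded: int
    by_reason: dict = field(default_factory=dict)

    def render(self) -> str:
        lines = [
            "Discounting exclusion report",
            f"subjects fitted:  {self.n_subjects}",
            f"subjects excluded: {self.n_excluded}",
        ]
        for reason, n in sorted(self.by_reason.items()):
            lines.append(f"  {reason}: {n}")
        return "\n".join(lines)


# Coarse shared grid used to seed cohort fits (every node is a candidate
# start, then the best few are polished by L-BFGS-B).
_COHORT_GRID_SHAPE = (121, 91)


def fit_cohort(choices: pd.DataFrame, items: pd.DataFrame | None = None,
               n_polish: int = 3) -> tuple[pd.DataFrame, ExclusionReport]:
    """Fit every subject in a long-format choice table.

    All subjects answer the same item set, so the likelihood of every
    subject on a dense (log k, log sigma) grid is a single matrix
    product; the best grid nodes then seed a quasi-Newton polish per
    subject.  Returns a fits table (excluded subjects keep their row but
    carry ``converged=False`` and a reason; they are dropped from any
    downstream ``log_k`` analysis) and an exclusion report.

    Raises on duplicate (subject, item) rows.
    """
    if items is None:
        items = default_items()
    items = _items_frame(items)
    if choices.duplicated(subset=["subject_id", "item_id"]).any():
        dup = choices[choices.duplicated(subset=["subject_id", "item_id"])]
        raise ValueError(
            f"duplicate (subject, item) rows, e.g. {dup.iloc[0].to_dict()}")
    unknown = set(choices["item_id"]) - set(items["item_id"])
    if unknown:
        raise KeyError(f"choices reference unknown item ids: {sorted(unknown)}")

    wide = choices.pivot(index="subject_id", columns="item_id", values="chose_ss")
    item_order = items["item_id"].to_numpy()
    wide = wide.reindex(columns=item_order)
    complete = wide.notna().all(axis=1)
    _, ss, ll, dd = _as_item_arrays(items)

    logk_grid = np.linspace(*LOGK_BOUNDS, _COHORT_GRID_SHAPE[0])
    logsig_grid = np.linspace(*LOGSIGMA_BOUNDS, _COHORT_GRID_SHAPE[1])
    lp_ss, lp_ll = _grid_logpmf(ss, ll, dd, logk_grid, logsig_grid)

    fits: list[DiscountFit] = []
    c_all = wide.to_numpy(float)
    # NLL over the whole grid for all complete subjects at once
    cmat = c_all[complete.to_numpy()]
    nll_grid = -(cmat @ lp_ss.T + (1.0 - cmat) @ lp_ll.T)  # (n_subj, G)
    grid_thetas = np.array([(a, b) for a in logk_grid for b in logsig_grid])

    row = 0
    for sid, is_complete in zip(wide.index, complete.to_numpy()):
        if not is_complete:
            mask = ~np.isnan(c_all[wide.index.get_loc(sid)])
            model = HyperbolicDiscounting(
                c_all[wide.index.get_loc(sid)][mask],
                items.iloc[np.flatnonzero(mask)], subject_id=sid)
            fits.append(model.fit())
            continue
        order = np.argsort(nll_grid[row])[:n_polish]
        model = HyperbolicDiscounting(cmat[row], items, subject_id=sid)
        fits.append(model.fit(starts=grid_thetas[order]))
        row += 1

    table = pd.DataFrame([f.__dict__ for f in fits])
    excluded = table[~table["converged"]]
    report = ExclusionReport(
        n_subjects=len(table),
        n_excluded=len(excluded),
        by_reason=excluded["exclusion_reason"].value_counts().to_dict(),
    )
    return table, report
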