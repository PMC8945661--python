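"""Seeded synthetic cohorts for the lifespan delay-discounting pipeline.

The original cohort (242 Chinese adults in three age groups) is not
publicly deposited, so every downstream stage is exercised against
synthetic cohorts whose *statistical structure* matches what the
analysis assumes:

* three age groups with the published marginal moments (ages, childhood
  SES, Mini-K life-history score, subjective health, sex counts);
* a positive SES-LHS rank association, injected through a Gaussian
  copula whose correlation is chosen by the sin(pi*tau/2) map so a
  target Kendall tau holds in expectation;
* log discount rates that are linear in LHS and U-shaped in age
  (negative slope within the young group, positive within the older
  group, flat in the middle), plus an age-bias coupling confined to the
  older group and a young-male offset;
* binary choices generated from the same hyperbolic/softmax model the
  estimator fits, and slider probes from the same power law, with a
  small fraction of random responders (flat choice likelihood) and
  careless probe responders (uniform slider readings) standing in for
  the participants the original analysis had to exclude.

Everything is driven by one integer seed; identical config + seed gives
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .discounting import default_items, subjective_value

__all__ = [
    "CohortConfig",
    "DEFAULT_HORIZONS",
    "generate_cohort",
    "generate_choice_responses",
    "generate_time_probes",
    "generate_dataset",
    "true_logk",
    "write_dataset",
]

GROUP_LABELS = ("young", "middle", "older")

# Ten horizons spanning the instrument's 3-60 month range.
DEFAULT_HORIZONS = (3.0, 6.0, 9.0, 12.0, 18.0, 24.0, 30.0, 36.0, 48.0, 60.0)

SLIDER_MAX = 150.0


def _kendall_to_pearson(tau: float) -> float:
    return float(np.sin(np.pi * tau / 2.0))


@dataclass(frozen=True)
class CohortConfig:
    """Stated world for the generator.

    Group-wise defaults are the published sample's moments; the
    structural couplings (``beta_lhs``, ``u_shape``, ``bias_slope_older``,
    ``sex_logk_offset_young``) default to the scale of the published
    regression coefficients so the qualitative sign pattern is
    reproduced at realistic noise.  ``CohortConfig.null()`` zeroes every
    structural effect for type-I-error studies.
    """

    group_sizes: tuple[int, ...] = (84, 54, 104)
    group_labels: tuple[str, ...] = GROUP_LABELS
    # chronological age moments and truncation ranges per group
    age_means: tuple[float, ...] = (24.0, 39.7, 58.8)
    age_sds: tuple[float, ...] = (3.79, 2.71, 3.53)
    age_ranges: tuple[tuple[float, float], ...] = (
        (18.0, 34.0), (34.0, 48.0), (48.0, 70.0))
    # males per group (remainder female)
    sex_counts_m: tuple[int, ...] = (31, 26, 61)
    # trait moments per group
    ses_mean_sd: tuple[tuple[float, float], ...] = (
        (3.73, 1.49), (3.17, 1.40), (3.59, 1.59))
    lhs_mean_sd: tuple[tuple[float, float], ...] = (
        (5.18, 0.80), (4.73, 0.83), (5.40, 0.72))
    ftp_mean_sd: tuple[tuple[float, float], ...] = (
        (4.6, 1.0), (4.4, 1.0), (4.5, 1.0))
    phys_health_mean_sd: tuple[tuple[float, float], ...] = (
        (3.92, 0.88), (3.59, 1.00), (3.86, 0.81))
    psych_health_mean_sd: tuple[tuple[float, float], ...] = (
        (3.88, 0.96), (3.67, 1.03), (4.25, 0.80))
    # rank-association targets (Gaussian copula, sin(pi*tau/2) map)
    ses_lhs_tau_target: float = 0.22
    ftp_lhs_tau_target: float = 0.35
    # log discount-rate structure
    baseline_logk: float = -4.5
    beta_lhs: float = -0.57
    u_shape: tuple[float, float] = (-0.11, 0.15)  # (slope_young, slope_old)
    bias_slope_older: float = 0.12  # age-bias -> log k, older group only
    sex_logk_offset_young: float = 0.45  # young males discount steeper
    logk_sd: float = 0.8
    # choice sensitivity (log-uniform range, RMB^-1)
    sigma_choice_range: tuple[float, float] = (0.005, 0.05)
    # time-perception truth: beta drawn directly; alpha anchored so the
    # reading at the longest horizon sits at a fraction of the slider
    # (subjects calibrate "very long" to the scale end), which keeps
    # alpha*t^beta inside the instrument and couples alpha to beta.
    beta_mean_sd: tuple[float, float] = (0.8, 0.15)
    beta_clip: tuple[float, float] = (0.45, 1.15)
    slider_anchor_frac: tuple[float, float] = (0.6, 0.15)
    anchor_frac_clip: tuple[float, float] = (0.25, 0.9)
    alpha_clip: tuple[float, float] = (0.3, 4.5)
    probe_noise_sd: float = 7.0  # mm
    # subjective-age construction: physical_age = age + base + c*(hbar - h) + e
    bias_base: tuple[float, float, float] = (0.2, -2.1, -5.5)
    psych_bias_base: tuple[float, float, float] = (1.4, -3.6, -11.1)
    health_bias_slope: float = 2.0  # years felt older per health point lost
    phys_age_noise_sd: float = 3.0
    psych_age_noise_sd: float = 5.0
    # contamination
    random_responder_rate: float = 7.0 / 242.0
    probe_outlier_rate: float = 0.20
    likert_discretize: bool = False
    seed: int = 1

    def __post_init__(self):
        k = len(self.group_sizes)
        if any(g <= 0 for g in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if len(self.group_labels) != k:
            raise ValueError("one label per group required")
        for name in ("age_means", "age_sds", "age_ranges", "sex_counts_m",
                     "ses_mean_sd", "lhs_mean_sd", "ftp_mean_sd",
                     "phys_health_mean_sd", "psych_health_mean_sd"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have one entry per group")
        if any(sd <= 0 for sd in self.age_sds):
            raise ValueError("age SDs must be positive")
        for name in ("ses_mean_sd", "lhs_mean_sd", "ftp_mean_sd",
                     "phys_health_mean_sd", "psych_health_mean_sd"):
            if any(sd <= 0 for _, sd in getattr(self, name)):
                raise ValueError(f"{name}: SDs must be positive")
        for rate in (self.random_responder_rate, self.probe_outlier_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("contamination rates must be in [0, 1)")
        sy, so = self.u_shape
        if not (sy <= 0.0 <= so):
            raise ValueError("u_shape requires slope_young <= 0 <= slope_old")
        if not -1.0 < self.ses_lhs_tau_target < 1.0:
            raise ValueError("tau target must be in (-1, 1)")

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """All structural effects on log k zeroed (type-I studies)."""
        base = dict(beta_lhs=0.0, u_shape=(0.0, 0.0), bias_slope_older=0.0,
                    sex_logk_offset_young=0.0, random_responder_rate=0.0,
                    probe_outlier_rate=0.0)
        base.update(overrides)
        return cls(**base)

    def replace(self, **overrides) -> "CohortConfig":
        return replace(self, **overrides)


def true_logk(lhs, chronological_age, group_label, config: CohortConfig):
    """Structural (noise-free) log discount rate.

    Linear in the life-history score around the pooled LHS mean, plus a
    piecewise-linear age effect: ``slope_young`` about the young group's
    mean age, ``slope_old`` about the older group's, zero in between --
    the U shape seen across the lifespan.
    """
    labels = list(config.group_labels)
    if group_label not in labels:
        raise KeyError(f"unknown group label {group_label!r}")
    g = labels.index(group_label)
    lhs_grand_mean = float(np.mean([m for m, _ in config.lhs_mean_sd]))
    out = config.baseline_logk + config.beta_lhs * (
        np.asarray(lhs, float) - lhs_grand_mean)
    slope_young, slope_old = config.u_shape
    age = np.asarray(chronological_age, float)
    if g == 0:
        out = out + slope_young * (age - config.age_means[0])
    elif g == len(labels) - 1:
        out = out + slope_old * (age - config.age_means[-1])
    return out


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _clip_likert(v, lo, hi, discretize):
    v = np.clip(v, lo, hi)
    return np.round(v) if discretize else v


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort: (subject table, ground-truth parameter table).

    Deterministic given ``(config, seed)``; ``seed=None`` uses
    ``config.seed``.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    r_sl = _kendall_to_pearson(config.ses_lhs_tau_target)
    r_fl = _kendall_to_pearson(config.ftp_lhs_tau_target)
    # SES and FTP conditionally independent given LHS keeps the 3x3
    # correlation matrix positive definite for any admissible targets.
    corr = np.array([[1.0, r_sl, r_sl * r_fl],
                     [r_sl, 1.0, r_fl],
                     [r_sl * r_fl, r_fl, 1.0]])
    chol = np.linalg.cholesky(corr)

    rows = []
    truths = []
    sid = 0
    for g, label in enumerate(config.group_labels):
        n = config.group_sizes[g]
        lo, hi = config.age_ranges[g]
        age = _truncnorm(rng, config.age_means[g], config.age_sds[g],
                         lo, hi, n)
        sex = np.array(["M"] * config.sex_counts_m[g]
                       + ["F"] * (n - config.sex_counts_m[g]))
        rng.shuffle(sex)

        z = rng.standard_normal((n, 3)) @ chol.T
        ses_m, ses_s = config.ses_mean_sd[g]
        lhs_m, lhs_s = config.lhs_mean_sd[g]
        ftp_m, ftp_s = config.ftp_mean_sd[g]
        ses = _clip_likert(ses_m + ses_s * z[:, 0], 1, 7,
                           config.likert_discretize)
        lhs = _clip_likert(lhs_m + lhs_s * z[:, 1], 1, 7,
                           config.likert_discretize)
        ftp = _clip_likert(ftp_m + ftp_s * z[:, 2], 1, 7,
                           config.likert_discretize)

        ph_m, ph_s = config.phys_health_mean_sd[g]
        psy_m, psy_s = config.psych_health_mean_sd[g]
        phys_health = _clip_likert(ph_m + ph_s * rng.standard_normal(n),
                                   1, 5, config.likert_discretize)
        psych_health = _clip_likert(psy_m + psy_s * rng.standard_normal(n),
                                    1, 5, config.likert_discretize)

        # poorer physical health -> feels older (negative tau between
        # age bias and health), around a group-level base offset
        phys_age = (age + config.bias_base[g]
                    + config.health_bias_slope * (ph_m - phys_health)
                    + config.phys_age_noise_sd * rng.standard_normal(n))
        psych_age = (age + config.psych_bias_base[g]
                     + config.health_bias_slope * (psy_m - psych_health)
                     + config.psych_age_noise_sd * rng.standard_normal(n))
        phys_age = np.maximum(phys_age, 1.0)
        psych_age = np.maximum(psych_age, 1.0)
        age_bias = phys_age - age

        logk = true_logk(lhs, age, label, config)
        if g == len(config.group_labels) - 1:
            logk = logk + config.bias_slope_older * age_bias
        if g == 0:
            logk = logk + config.sex_logk_offset_young * (sex == "M")
        logk = logk + config.logk_sd * rng.standard_normal(n)

        lo_s, hi_s = config.sigma_choice_range
        sigma = np.exp(rng.uniform(np.log(lo_s), np.log(hi_s), n))
        b_m, b_s = config.beta_mean_sd
        beta = np.clip(b_m + b_s * rng.standard_normal(n), *config.beta_clip)
        f_m, f_s = config.slider_anchor_frac
        frac = np.clip(f_m + f_s * rng.standard_normal(n),
                       *config.anchor_frac_clip)
        t_max = max(DEFAULT_HORIZONS)
        alpha = np.clip(frac * SLIDER_MAX / t_max ** beta, *config.alpha_clip)

        is_random = rng.random(n) < config.random_responder_rate
        is_corrupt = rng.random(n) < config.probe_outlier_rate

        for i in range(n):
            rows.append(dict(
                subject_id=sid + i, sex=sex[i],
                chronological_age=age[i], physical_age=phys_age[i],
                psychological_age=psych_age[i],
                physical_health=phys_health[i],
                psychological_health=psych_health[i],
                childhood_ses=ses[i], lhs=lhs[i], ftp=ftp[i],
                age_bias=age_bias[i], group_label=label))
            truths.append(dict(
                subject_id=sid + i, k_true=float(np.exp(logk[i])),
                sigma_true=float(sigma[i]), alpha_true=float(alpha[i]),
                beta_true=float(beta[i]),
                is_random_responder=bool(is_random[i]),
                is_probe_corrupt=bool(is_corrupt[i])))
        sid += n

    return pd.DataFrame(rows), pd.DataFrame(truths)


def generate_choice_responses(true_params: pd.DataFrame,
                              items: pd.DataFrame | None = None,
                              seed: int | None = 0) -> pd.DataFrame:
    """Simulate binary choices from the hyperbolic/softmax model.

    Each subject answers every item once; the SS option is taken with
    the model's logistic probability, except random responders who flip
    a fair coin on every item.
    """
    if items is None:
        items = default_items()
    if len(items) == 0:
        raise ValueError("empty item list")
    rng = np.random.default_rng(seed)
    k = true_params["k_true"].to_numpy(float)[:, None]
    sigma = true_params["sigma_true"].to_numpy(float)[:, None]
    is_random = true_params["is_random_responder"].to_numpy(bool)[:, None]
    ss = items["ss_amount"].to_numpy(float)[None, :]
    ll = items["ll_amount"].to_numpy(float)[None, :]
    dd = items["delay_days"].to_numpy(float)[None, :]
    sv = subjective_value(ll, k, dd)
    from scipy.special import expit
    p_ss = expit(sigma * (ss - sv))
    p_ss = np.where(is_random, 0.5, p_ss)
    chose = (rng.random(p_ss.shape) < p_ss).astype(int)
    n_subj, n_items = chose.shape
    return pd.DataFrame({
        "subject_id": np.repeat(true_params["subject_id"].to_numpy(), n_items),
        "item_id": np.tile(items["item_id"].to_numpy(), n_subj),
        "ss_amount": np.tile(ss.ravel(), n_subj),
        "ll_amount": np.tile(ll.ravel(), n_subj),
        "delay_days": np.tile(dd.ravel(), n_subj),
        "chose_ss": chose.ravel(),
    })


def generate_time_probes(true_params: pd.DataFrame,
                         horizons_months=DEFAULT_HORIZONS,
                         seed: int | None = 0,
                         noise_sd: float = 10.0) -> pd.DataFrame:
    """Simulate slider probes T = alpha*t^beta + noise, clipped to the
    150-mm slider; careless subjects read uniformly on the slider."""
    horizons = np.asarray(horizons_months, float)
    if np.any(horizons <= 0):
        raise ValueError("horizons must be positive")
    rng = np.random.default_rng(seed)
    alpha = true_params["alpha_true"].to_numpy(float)[:, None]
    beta = true_params["beta_true"].to_numpy(float)[:, None]
    corrupt = true_params["is_probe_corrupt"].to_numpy(bool)[:, None]
    t = horizons[None, :]
    clean = alpha * t ** beta + noise_sd * rng.standard_normal(
        (len(alpha), len(horizons)))
    uniform = rng.uniform(0.0, SLIDER_MAX, size=clean.shape)
    slider = np.clip(np.where(corrupt, uniform, clean), 0.0, SLIDER_MAX)
    n_subj, n_h = slider.shape
    return pd.DataFrame({
        "subject_id": np.repeat(true_params["subject_id"].to_numpy(), n_h),
        "horizon_months": np.tile(horizons, n_subj),
        "slider_mm": slider.ravel(),
    })


def generate_dataset(config: CohortConfig | None = None,
                     items: pd.DataFrame | None = None,
                     seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Full synthetic dataset: subjects, truth, choices, time probes.

    Child streams for the three stochastic stages are spawned from one
    seed sequence, so a single integer pins the entire dataset.
    """
    config = config or CohortConfig()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    s_cohort, s_choice, s_probe = root.spawn(3)
    subjects, truth = generate_cohort(
        config, seed=np.random.default_rng(s_cohort))
    choices = generate_choice_responses(
        truth, items=items, seed=np.random.default_rng(s_choice))
    probes = generate_time_probes(
        truth, seed=np.random.default_rng(s_probe),
        noise_sd=config.probe_noise_sd)
    return {"subjects": subjects, "truth": truth,
            "choices": choices, "time_probes": probes}


def write_dataset(tables: dict[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    """Write subjects.csv, truth.csv, choices.csv, time_probes.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
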