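"""End-to-end lifespan analysis of delay discounting.

Orchestrates the full chain on a (real or synthetic) cohort:

1. per-subject discounting MLEs with convergence screening;
2. per-subject time-perception power-law fits with two-stage exclusion;
3. age-group assignment and age-bias scores;
4. per-group Kendall correlations of chronological age with FTP, log k
   and the time-perception parameters, plus the whole-sample trait
   associations;
5. two MM-regression models on the young + older subsample
   (Model 1: LHS + age + group + age*group; Model 2 adds age bias and
   age bias * group);
6. sex tests (per-group ANCOVA controlling LHS; sex*age interaction in
   the older group);
7. robust bootstrap mediations: childhood SES -> LHS -> log k on the
   whole sample, and physical health -> physical age -> log k within
   each age group.

Exclusions are analysis-specific: a subject whose discounting fit did
not converge is absent from every statistic that touches log k but still
contributes to, e.g., the age-FTP correlation; likewise for excluded
time-perception fits.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import discounting, timeperception
from .cohort import CohortConfig
from .mediation import MediationResult, robust_mediation
from .robust import RobustFitResult, ancova_f, kendall_tau, mm_regression

__all__ = [
    "DEFAULT_CUTOFFS",
    "AnalysisReport",
    "assign_age_groups",
    "compute_age_bias",
    "per_group_correlations",
    "run_model1",
    "run_model2",
    "run_sex_tests",
    "run_full_analysis",
]

# Contiguous default bins; the published sample had gaps (18-33, 36-46,
# 52-69) that reflect recruitment, not a rule.  Configure the gapped
# cutoffs to reproduce that exactly (gap ages stay unassigned).
DEFAULT_CUTOFFS = ((18.0, 34.0), (34.0, 48.0), (48.0, 70.0))
GROUP_ORDER = ("young", "middle", "older")


def assign_age_groups(subjects: pd.DataFrame,
                      cutoffs=DEFAULT_CUTOFFS,
                      labels=GROUP_ORDER) -> pd.DataFrame:
    """Label subjects by half-open age bins (the last bin is closed).

    Ages falling outside every bin stay unassigned (NaN label) with a
    warning.  Returns a copy with ``group_label`` plus the cutoffs used.
    """
    out = subjects.copy()
    age = out["chronological_age"].to_numpy(float)
    label = np.full(len(out), None, dtype=object)
    for i, ((lo, hi), name) in enumerate(zip(cutoffs, labels)):
        last = i == len(cutoffs) - 1
        mask = (age >= lo) & ((age <= hi) if last else (age < hi))
        label[mask] = name
    if (label == None).any():  # noqa: E711
        n_bad = int((label == None).sum())  # noqa: E711
        warnings.warn(f"{n_bad} subject(s) outside every age bin left "
                      "unassigned", stacklevel=2)
    out["group_label"] = label
    out.attrs["age_cutoffs"] = tuple(cutoffs)
    return out


def compute_age_bias(physical_age, chronological_age):
    """Age bias = physical age - chronological age (positive: feels older)."""
    physical_age = np.asarray(physical_age, float)
    chronological_age = np.asarray(chronological_age, float)
    return physical_age - chronological_age


def _tau_row(df, v1, v2, scope, group):
    sub = df[[v1, v2]].dropna()
    row = dict(scope=scope, group=group, var1=v1, var2=v2,
               n=len(sub), tau=np.nan, p=np.nan, note="")
    if len(sub) < 3:
        row["note"] = "skipped: n < 3"
        warnings.warn(f"{scope}/{group}: {v1} vs {v2} skipped (n < 3)",
                      stacklevel=3)
        return row
    try:
        res = kendall_tau(sub[v1].to_numpy(), sub[v2].to_numpy())
    except ValueError as exc:
        row["note"] = f"undefined: {exc}"
        return row
    row.update(tau=res.tau, p=res.p_value)
    return row


# Whole-sample trait pairs reported alongside the per-group table.
_WHOLE_SAMPLE_PAIRS = (
    ("childhood_ses", "lhs"),
    ("lhs", "log_k"),
    ("ftp", "lhs"),
    ("ftp", "log_k"),
    ("physical_health", "age_bias"),
    ("alpha", "log_k"),
    ("beta", "log_k"),
)

_PER_GROUP_VARS = ("ftp", "log_k", "alpha", "beta",
                   "physical_age_logk", "psychological_age_logk")


def per_group_correlations(cohort: pd.DataFrame) -> pd.DataFrame:
    """Kendall tau table: age vs key variables per group, plus the
    whole-sample trait pairs.

    ``cohort`` is the merged subject + fits table; rows excluded
    upstream must already carry NaN in the corresponding column.
    """
    rows = []
    for group, sub in cohort.groupby("group_label", sort=False):
        for v in ("ftp", "log_k", "alpha", "beta"):
            if v in sub.columns:
                rows.append(_tau_row(sub, "chronological_age", v, "per_group",
                                     group))
        for v in ("physical_age", "psychological_age"):
            if "log_k" in sub.columns:
                rows.append(_tau_row(sub, v, "log_k", "per_group", group))
    for v1, v2 in _WHOLE_SAMPLE_PAIRS:
        if v1 in cohort.columns and v2 in cohort.columns:
            rows.append(_tau_row(cohort, v1, v2, "whole_sample", "all"))
    return pd.DataFrame(rows)


def _model_frame(cohort: pd.DataFrame, need: tuple[str, ...]) -> pd.DataFrame:
    sub = cohort[cohort["group_label"].isin(["young", "older"])]
    return sub.dropna(subset=list(need))


MODEL1_TERMS = ["intercept", "lhs", "chronological_age", "age_group",
                "age_x_group"]
MODEL2_TERMS = MODEL1_TERMS + ["age_bias", "age_bias_x_group"]


def _design_model1(sub: pd.DataFrame) -> np.ndarray:
    group = (sub["group_label"] == "older").to_numpy(float)  # young=0, older=1
    age = sub["chronological_age"].to_numpy(float)
    return np.column_stack([
        np.ones(len(sub)), sub["lhs"].to_numpy(float), age, group,
        age * group])


def run_model1(cohort: pd.DataFrame, seed: int | None = 0) -> RobustFitResult:
    """MM-regression of log k on LHS, age, age group (young=0, older=1)
    and the age*group interaction; middle-aged subjects excluded."""
    sub = _model_frame(cohort, ("log_k", "lhs", "chronological_age"))
    if sub["group_label"].nunique() < 2:
        raise ValueError("Model 1 needs both young and older subjects")
    # bootstrap covariance: log-k estimates from a 7-item set are
    # near-discrete, where the asymptotic MM sandwich runs optimistic
    return mm_regression(_design_model1(sub), sub["log_k"].to_numpy(float),
                         terms=MODEL1_TERMS, seed=seed, cov="bootstrap")


def run_model2(cohort: pd.DataFrame, seed: int | None = 0) -> RobustFitResult:
    """Model 1 plus age bias and the age bias * group interaction."""
    sub = _model_frame(cohort, ("log_k", "lhs", "chronological_age",
                                "age_bias"))
    if sub["group_label"].nunique() < 2:
        raise ValueError("Model 2 needs both young and older subjects")
    group = (sub["group_label"] == "older").to_numpy(float)
    bias = sub["age_bias"].to_numpy(float)
    design = np.column_stack([_design_model1(sub), bias, bias * group])
    return mm_regression(design, sub["log_k"].to_numpy(float),
                         terms=MODEL2_TERMS, seed=seed, cov="bootstrap")


def run_sex_tests(cohort: pd.DataFrame) -> dict:
    """Sex effects on log k.

    Per group: classical ANCOVA F for sex controlling the life-history
    score.  In the older group additionally an OLS of log k on sex, age
    and sex*age (male=1), reporting the interaction coefficient.
    """
    from .robust import ols_regression

    out: dict = {"ancova": {}, "interaction_older": None, "warnings": []}
    for group, sub in cohort.groupby("group_label", sort=False):
        sub = sub.dropna(subset=["log_k", "lhs"])
        if sub["sex"].nunique() < 2:
            out["warnings"].append(f"group {group}: single sex, skipped")
            continue
        f, df1, df2, p = ancova_f(sub["log_k"].to_numpy(float),
                                  sub["sex"].to_numpy(),
                                  sub["lhs"].to_numpy(float))
        out["ancova"][group] = {"F": f, "df1": df1, "df2": df2, "p": p}
    older = cohort[cohort["group_label"] == "older"].dropna(
        subset=["log_k"])
    if len(older) and older["sex"].nunique() == 2:
        male = (older["sex"] == "M").to_numpy(float)
        age = older["chronological_age"].to_numpy(float)
        design = np.column_stack([np.ones(len(older)), male, age, male * age])
        fit = ols_regression(design, older["log_k"].to_numpy(float),
                             terms=["intercept", "male", "age", "male_x_age"])
        out["interaction_older"] = fit["male_x_age"]
    return out


@dataclass
class AnalysisReport:
    """Everything the pipeline computed, serializable and renderable."""

    correlations: pd.DataFrame
    model1: RobustFitResult
    model2: RobustFitResult
    sex_tests: dict
    mediation_ses: MediationResult
    mediation_health: dict[str, MediationResult | None]
    discount_exclusions: discounting.ExclusionReport
    time_exclusions: dict
    config_echo: dict
    seed: int | None
    n_subjects: int
    n_tests: int = 0

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v

        return _clean({
            "n_subjects": self.n_subjects,
            "seed": self.seed,
            "config": self.config_echo,
            "correlations": self.correlations.to_dict(orient="records"),
            "model1": dataclasses.asdict(self.model1),
            "model2": dataclasses.asdict(self.model2),
            "sex_tests": self.sex_tests,
            "mediation_ses_lhs_logk": self.mediation_ses.to_dict(),
            "mediation_health_physage_logk": {
                g: (r.to_dict() if r is not None else None)
                for g, r in self.mediation_health.items()},
            "discount_exclusions": dataclasses.asdict(
                self.discount_exclusions),
            "time_exclusions": self.time_exclusions,
            "n_tests": self.n_tests,
        })

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def render_text(self) -> str:
        parts = [
            "=" * 64,
            "Lifespan delay-discounting analysis report",
            "=" * 64,
            f"subjects: {self.n_subjects}   seed: {self.seed}   "
            f"uncorrected tests: {self.n_tests}",
            "",
            self.discount_exclusions.render(),
            "",
            "Time-perception exclusions: "
            f"{self.time_exclusions['n_excluded']} of "
            f"{self.time_exclusions['n_fitted']} "
            f"(bound hits {self.time_exclusions['n_bound_hit']}, "
            f"boxplot {self.time_exclusions['n_boxplot']})",
            "",
            "Kendall correlations",
            "-" * 64,
            self.correlations.to_string(
                index=False, float_format=lambda v: f"{v: .3f}"),
            "",
            "Model 1 (log k ~ LHS + age + group + age*group; "
            "young + older only)",
            "-" * 64,
            self.model1.summary(),
            "",
            "Model 2 (Model 1 + age bias + age bias*group)",
            "-" * 64,
            self.model2.summary(),
            "",
            "Sex tests (ANCOVA on log k controlling LHS)",
            "-" * 64,
        ]
        for group, res in self.sex_tests["ancova"].items():
            parts.append(
                f"  {group}: F({res['df1']}, {res['df2']}) = "
                f"{res['F']:.2f}, p = {res['p']:.3f}")
        inter = self.sex_tests.get("interaction_older")
        if inter is not None:
            parts.append(
                f"  older sex*age: b = {inter['coef']:.3f}, "
                f"t = {inter['t']:.2f}, p = {inter['p']:.3f}")
        parts += [
            "",
            "Mediation: childhood SES -> LHS -> log k (whole sample)",
            "-" * 64,
            self.mediation_ses.summary(),
            "",
            "Mediation: physical health -> physical age -> log k (per group)",
            "-" * 64,
        ]
        for group, res in self.mediation_health.items():
            if res is None:
                parts.append(f"  {group}: skipped")
            else:
                parts.append(
                    f"  {group}: a*b = {res.indirect:.3f}, "
                    f"{res.level:.0%} CI [{res.ci_low:.3f}, {res.ci_high:.3f}]"
                    f"{'  *' if res.significant else ''}")
        return "\n".join(parts)


def run_full_analysis(subjects: pd.DataFrame,
                      choices: pd.DataFrame,
                      probes: pd.DataFrame,
                      items: pd.DataFrame | None = None,
                      config: CohortConfig | None = None,
                      seed: int | None = 0,
                      n_boot: int = 2000,
                      cutoffs=DEFAULT_CUTOFFS,
                      out_dir=None) -> AnalysisReport:
    """Run the whole analysis chain and assemble the report.

    ``seed`` drives every stochastic stage (MM resampling, bootstrap);
    rerunning with identical inputs and seed reproduces the report
    exactly.  When ``out_dir`` is given, intermediate fit tables plus
    the JSON and text report are written there.
    """
    if items is None:
        items = discounting.default_items()
    root = np.random.SeedSequence(seed if seed is not None else 0)
    s_mm1, s_mm2, s_med0, *s_med_groups = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(6)]

    dd_fits, dd_report = discounting.fit_cohort(choices, items)
    tp_fits = timeperception.fit_time_cohort(probes)
    time_excl = {
        "n_fitted": int(len(tp_fits)),
        "n_bound_hit": int(tp_fits["bound_hit"].sum()),
        "n_boxplot": int(tp_fits["boxplot_outlier"].sum()),
        "n_excluded": int(tp_fits["excluded"].sum()),
    }

    cohort = assign_age_groups(subjects, cutoffs=cutoffs)
    cohort["age_bias"] = compute_age_bias(
        cohort["physical_age"], cohort["chronological_age"])

    dd_keep = dd_fits[dd_fits["converged"]][["subject_id", "log_k"]]
    cohort = cohort.merge(dd_keep, on="subject_id", how="left")
    tp_keep = tp_fits[~tp_fits["excluded"]][["subject_id", "alpha", "beta"]]
    cohort = cohort.merge(tp_keep, on="subject_id", how="left")

    correlations = per_group_correlations(cohort)
    model1 = run_model1(cohort, seed=s_mm1)
    model2 = run_model2(cohort, seed=s_mm2)
    sex_tests = run_sex_tests(cohort)

    whole = cohort.dropna(subset=["childhood_ses", "lhs", "log_k"])
    mediation_ses = robust_mediation(
        whole["childhood_ses"].to_numpy(float), whole["lhs"].to_numpy(float),
        whole["log_k"].to_numpy(float), n_boot=n_boot, seed=s_med0)

    mediation_health: dict[str, MediationResult | None] = {}
    for g_seed, group in zip(s_med_groups + [s_med0 + 1] * 3, GROUP_ORDER):
        sub = cohort[cohort["group_label"] == group].dropna(
            subset=["physical_health", "physical_age", "log_k"])
        if len(sub) < 10:
            mediation_health[group] = None
            continue
        mediation_health[group] = robust_mediation(
            sub["physical_health"].to_numpy(float),
            sub["physical_age"].to_numpy(float),
            sub["log_k"].to_numpy(float), n_boot=n_boot, seed=g_seed)

    n_tests = (int(correlations["tau"].notna().sum())
               + len(model1.terms) + len(model2.terms)
               + len(sex_tests["ancova"])
               + (1 if sex_tests["interaction_older"] else 0)
               + 1 + sum(r is not None for r in mediation_health.values()))

    report = AnalysisReport(
        correlations=correlations, model1=model1, model2=model2,
        sex_tests=sex_tests, mediation_ses=mediation_ses,
        mediation_health=mediation_health,
        discount_exclusions=dd_report, time_exclusions=time_excl,
        config_echo=(dataclasses.asdict(config) if config is not None else {}),
        seed=seed, n_subjects=int(len(subjects)), n_tests=n_tests)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dd_fits.to_csv(out / "discount_fits.csv", index=False)
        tp_fits.to_csv(out / "time_fits.csv", index=False)
        (out / "exclusions.txt").write_text(
            dd_report.render() + "\n\nTime-perception exclusions: "
            f"{time_excl['n_excluded']} of {time_excl['n_fitted']}\n")
        report.to_json(out / "report.json")
        (out / "report.txt").write_text(report.render_text())
    return report
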