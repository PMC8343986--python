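"""Cohort analysis pipeline: descriptive phase tables, then per-marker,
per-stratum joint models reporting relative risks per 10% marker increase.

Mirrors the standard reporting layout of longitudinal lipid cohort studies:

* a descriptives stage -- per-phase mean (SD) or count (%) of every variable
  by sex, a per-year linear trend with CI, and a male-female comparison;
* a modeling stage -- for each marker (TC, LDL-C, HDL-C) and each stratum
  (men, women, pooled) a joint longitudinal-survival fit adjusted for
  diabetes, smoking, lipid-lowering drugs, BMI and systolic blood pressure
  (plus sex in the pooled model), summarized as the relative risk of CVD
  death per 10% marker increase;
* a proportional-hazards screen (Grambsch-Therneau test on the
  covariates-only Cox model) per stratum.

Markers are analyzed one at a time (three univariate joint models), and no
multiple-testing adjustment is applied; p-values are reported as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm

from .cox import fit_cox, schoenfeld_test, PHTestResult
from .joint import JointModelSpec, fit_joint, rr_per_fraction
from .lmm import LMMSpec

logger = logging.getLogger("lipidjm")

MARKERS = ["TC", "LDL", "HDL"]
ADJUSTMENT = ["diabetes", "smoking", "lipid_drugs", "bmi", "sbp"]
STRATA = ["male", "female", "pooled"]


@dataclass
class PipelineConfig:
    markers: list[str] = field(default_factory=lambda: list(MARKERS))
    strata: list[str] = field(default_factory=lambda: list(STRATA))
    adjustment: list[str] = field(default_factory=lambda: list(ADJUSTMENT))
    longitudinal_extra: list[str] = field(default_factory=lambda: ["baseline_age"])
    fraction: float = 0.10
    min_events: int = 20
    n_intervals: int = 6
    quad_points: int = 9
    phase_years: float = 3.0
    ph_time_transform: str = "km"


@dataclass
class RRReport:
    marker: str
    stratum: str
    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    assoc: float
    assoc_se: float
    converged: bool
    adjusted_for: list[str]

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, list) else v) for k, v in self.__dict__.items()}


@dataclass
class DescriptiveReport:
    covariate_table: pd.DataFrame     # per-phase mean(SD)/count(%) by sex
    marker_table: pd.DataFrame        # per-phase marker mean(SD) by sex
    trends: pd.DataFrame              # per-year trend, CI, p; sex-comparison p
    n_phases: int


def assign_phase(times: np.ndarray, phase_years: float = 3.0) -> np.ndarray:
    """Visit phase number (1-based) from years since baseline."""
    return (np.rint(np.asarray(times, float) / phase_years) + 1).astype(int)


def _trend_continuous(df: pd.DataFrame, var: str) -> tuple[float, float, float, float]:
    """Per-year linear trend by OLS of the variable on continuous time."""
    X = sm.add_constant(df["time"].to_numpy(float))
    res = sm.OLS(df[var].to_numpy(float), X).fit()
    ci = res.conf_int()[1]
    return float(res.params[1]), float(ci[0]), float(ci[1]), float(res.pvalues[1])


def _trend_binary(df: pd.DataFrame, var: str) -> tuple[float, float, float, float]:
    """Per-year trend in a proportion via a binomial GLM (logit link); the
    slope is reported on the log-odds scale."""
    y = df[var].to_numpy(float)
    X = sm.add_constant(df["time"].to_numpy(float))
    if y.min() == y.max():   # constant: no trend estimable
        return 0.0, 0.0, 0.0, 1.0
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    ci = res.conf_int()[1]
    return float(res.params[1]), float(ci[0]), float(ci[1]), float(res.pvalues[1])


def descriptive_tables(long: pd.DataFrame, surv: pd.DataFrame,
                       config: PipelineConfig | None = None) -> DescriptiveReport:
    """Phase-by-phase descriptive summaries with per-year trends and
    male-female comparisons."""
    config = config or PipelineConfig()
    long = long.copy()
    long["phase"] = assign_phase(long["time"], config.phase_years)
    phases = sorted(long["phase"].unique())
    if len(phases) > 5:
        raise ValueError("more than 5 visit phases; check the time scale")

    # one row per subject-visit (covariates repeat across markers)
    visits = long.drop_duplicates(["subject_id", "phase"]).copy()
    binary = [c for c in ("diabetes", "smoking", "lipid_drugs") if c in visits.columns]
    continuous = [c for c in ("sbp", "bmi") if c in visits.columns]

    cov_rows, trend_rows = [], []
    for var in continuous + binary:
        is_bin = var in binary
        for sex, label in ((0, "male"), (1, "female")):
            sub = visits[visits["sex"] == sex]
            cells = {}
            for ph in phases:
                v = sub.loc[sub["phase"] == ph, var]
                if len(v) == 0:
                    logger.warning("phase %d has no rows for %s/%s; omitted", ph, var, label)
                    cells[f"phase_{ph}"] = None
                    continue
                cells[f"phase_{ph}"] = (f"{v.mean():.1f} ({v.std():.1f})" if not is_bin
                                        else f"{int(v.sum())} ({100 * v.mean():.1f})")
            est, lo, hi, p = (_trend_binary if is_bin else _trend_continuous)(sub, var)
            cov_rows.append({"variable": var, "sex": label, **cells})
            trend_rows.append({"variable": var, "sex": label, "per_year": est,
                               "ci_low": lo, "ci_high": hi, "p_trend": p})
        base = visits[visits["phase"] == phases[0]]
        m, f = base[base.sex == 0][var], base[base.sex == 1][var]
        if var in binary:
            tab = pd.crosstab(base["sex"], base[var])
            p_mf = float(sstats.chi2_contingency(tab)[1]) if tab.shape == (2, 2) else 1.0
        else:
            p_mf = float(sstats.ttest_ind(m, f, equal_var=False).pvalue)
        trend_rows[-1]["p_male_female"] = p_mf
        trend_rows[-2]["p_male_female"] = p_mf

    mk_rows = []
    for marker in [m for m in config.markers if m in set(long["marker"])]:
        sub_m = long[long["marker"] == marker]
        for sex, label in ((0, "male"), (1, "female")):
            sub = sub_m[sub_m["sex"] == sex]
            cells = {f"phase_{ph}": (f"{v.mean():.1f} ({v.std():.1f})" if len(v) else None)
                     for ph in phases for v in [sub.loc[sub["phase"] == ph, "marker_value"]]}
            est, lo, hi, p = _trend_continuous(sub, "marker_value")
            mk_rows.append({"marker": marker, "sex": label, **cells})
            trend_rows.append({"variable": marker, "sex": label, "per_year": est,
                               "ci_low": lo, "ci_high": hi, "p_trend": p})
        base = sub_m[sub_m["phase"] == phases[0]]
        p_mf = float(sstats.ttest_ind(base[base.sex == 0]["marker_value"],
                                      base[base.sex == 1]["marker_value"], equal_var=False).pvalue)
        trend_rows[-1]["p_male_female"] = p_mf
        trend_rows[-2]["p_male_female"] = p_mf

    return DescriptiveReport(
        covariate_table=pd.DataFrame(cov_rows),
        marker_table=pd.DataFrame(mk_rows),
        trends=pd.DataFrame(trend_rows),
        n_phases=len(phases),
    )


def _stratum_masks(surv: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "male":
        return surv["sex"] == 0
    if stratum == "female":
        return surv["sex"] == 1
    if stratum == "pooled":
        return pd.Series(True, index=surv.index)
    raise ValueError(f"unknown stratum {stratum!r}")


def run_paper_analysis(long: pd.DataFrame, surv: pd.DataFrame,
                       config: PipelineConfig | None = None
                       ) -> tuple[list[RRReport], DescriptiveReport, dict[str, PHTestResult]]:
    """Full analysis: descriptives, then marker x stratum joint fits.

    Subjects with no valid measurement of a marker are excluded from that
    marker's models (their count is logged). Strata with fewer events than
    ``config.min_events`` are skipped with a log entry.
    """
    config = config or PipelineConfig()
    desc = descriptive_tables(long, surv, config)

    ph_results: dict[str, PHTestResult] = {}
    reports: list[RRReport] = []
    for stratum in config.strata:
        mask = _stratum_masks(surv, stratum)
        surv_s = surv[mask]
        n_events = int(surv_s["event"].sum())
        if n_events < config.min_events:
            logger.warning("stratum %s skipped: only %d events (< %d)",
                           stratum, n_events, config.min_events)
            continue

        # proportionality screen on the covariates-only Cox model
        cov_list = config.adjustment + (["sex"] if stratum == "pooled" else [])
        cfit = fit_cox(surv_s, cov_list)
        ph_results[stratum] = schoenfeld_test(cfit, surv_s, config.ph_time_transform)

        for marker in config.markers:
            long_m = long[(long["marker"] == marker) & long["subject_id"].isin(surv_s["subject_id"])]
            have = set(long_m["subject_id"])
            dropped = int((~surv_s["subject_id"].isin(have)).sum())
            if dropped:
                logger.info("%s/%s: excluding %d subjects with no valid %s measurement",
                            marker, stratum, dropped, marker)
            surv_m = surv_s[surv_s["subject_id"].isin(have)]

            fixed = ["intercept", "time"] + config.longitudinal_extra + config.adjustment
            if stratum == "pooled":
                fixed = fixed + ["sex"]
            spec = JointModelSpec(
                lmm_spec=LMMSpec(fixed_terms=fixed, random_terms=["intercept", "time"]),
                survival_covariates=cov_list,
                n_intervals=config.n_intervals,
                quad_points=config.quad_points,
            )
            fit = fit_joint(long_m, surv_m, spec)
            rr, lo, hi, p = rr_per_fraction(fit, config.fraction)
            reports.append(RRReport(
                marker=marker, stratum=stratum, rr=rr, ci_low=lo, ci_high=hi,
                p_value=p, n=fit.n_subjects, n_events=fit.n_events,
                assoc=fit.assoc, assoc_se=fit.assoc_se, converged=fit.converged,
                adjusted_for=list(cov_list)))
    return reports, desc, ph_results


def rr_table(reports: list[RRReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports])


def render_rr_table(reports: list[RRReport], fraction: float = 0.10) -> str:
    """Plain-text rendering of the relative-risk table."""
    lines = [f"Relative risks of CVD death per {100 * fraction:.0f}% marker increase",
             f"{'stratum':<8} {'marker':<6} {'RR':>6} {'95% CI':>16} {'P':>8} {'events':>7}"]
    for stratum in dict.fromkeys(r.stratum for r in reports):
        for r in [r for r in reports if r.stratum == stratum]:
            if np.isnan(r.p_value):
                p, ci = "--", "(  --  ,  --  )"
            else:
                p = f"{r.p_value:.3f}" if r.p_value >= 0.001 else "<0.001"
                ci = f"({r.ci_low:5.2f}, {r.ci_high:5.2f})"
            lines.append(f"{r.stratum:<8} {r.marker:<6} {r.rr:6.2f} {ci:>16} {p:>8} {r.n_events:>7}")
    lines.append("No multiple-testing adjustment applied.")
    return "\n".join(lines)


def plot_mean_trajectories(long: pd.DataFrame, path: str, phase_years: float = 3.0) -> None:
    """Mean marker level by visit phase and sex (simple trajectory plot)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    long = long.copy()
    long["phase"] = assign_phase(long["time"], phase_years)
    markers = list(dict.fromkeys(long["marker"]))
    fig, axes = plt.subplots(1, len(markers), figsize=(4 * len(markers), 3.2), squeeze=False)
    for ax, marker in zip(axes[0], markers):
        sub = long[long["marker"] == marker]
        for sex, label in ((0, "men"), (1, "women")):
            m = sub[sub["sex"] == sex].groupby("phase")["marker_value"].mean()
            ax.plot(m.index, m.values, marker="o", label=label)
        ax.set_title(marker)
        ax.set_xlabel("phase")
        ax.set_ylabel("mean level (mg/dl)")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
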