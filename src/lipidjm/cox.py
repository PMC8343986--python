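"""Cox proportional-hazards baseline analysis and proportionality diagnostics.

The semiparametric Cox fit (Efron tie handling, Breslow baseline cumulative
hazard) is delegated to lifelines. The Grambsch-Therneau score test on scaled
Schoenfeld residuals -- the "P > 0.1" proportionality screen -- is implemented
here, since we need both per-covariate and global statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats as sstats


@dataclass
class CoxFit:
    covariates: list[str]
    gamma: np.ndarray
    vcov: np.ndarray
    partial_loglik: float
    baseline_cumhaz: pd.Series      # Breslow estimator, step function at event times
    n_events: int
    model: CoxPHFitter | None       # None when every covariate is constant

    def summary(self) -> dict:
        se = np.sqrt(np.diag(self.vcov))
        return {
            "gamma": {c: {"estimate": float(g), "se": float(s), "hr": float(np.exp(g))}
                      for c, g, s in zip(self.covariates, self.gamma, se)},
            "partial_loglik": float(self.partial_loglik),
            "n_events": int(self.n_events),
        }


@dataclass
class PHTestResult:
    covariates: list[str]
    statistic: np.ndarray           # per-covariate chi-square, 1 df each
    p_value: np.ndarray
    global_statistic: float
    global_df: int
    global_p_value: float
    time_transform: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"covariate": self.covariates, "chi2": self.statistic,
                           "df": 1, "p": self.p_value})
        df.loc[len(df)] = ["GLOBAL", self.global_statistic, self.global_df, self.global_p_value]
        return df


def _fit_with_fallback(df: pd.DataFrame, duration_col: str, event_col: str) -> CoxPHFitter:
    """Newton fit at tight precision; back off (and finally ridge-penalize)
    when the partial likelihood is near-flat or near-separated."""
    import warnings

    from lifelines.exceptions import ConvergenceError

    attempts = [
        (0.0, {"fit_options": {"precision": 1e-9, "max_steps": 500}}),
        (0.0, {}),
        (0.1, {}),
    ]
    last = None
    for penalizer, kwargs in attempts:
        try:
            cph = CoxPHFitter(penalizer=penalizer)
            cph.fit(df, duration_col=duration_col, event_col=event_col, **kwargs)
            if penalizer > 0:
                warnings.warn("Cox partial likelihood unstable (few events or "
                              "near-separation); ridge penalty 0.1 applied", stacklevel=3)
            return cph
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            last = exc
    raise RuntimeError(f"Cox fit failed to converge: {last}")


def _null_partial_loglik(T: np.ndarray, E: np.ndarray) -> float:
    """Efron partial log-likelihood at gamma = 0 (risk scores all one)."""
    order = np.argsort(T)
    T, E = T[order], E[order]
    ll = 0.0
    n = len(T)
    for t in np.unique(T[E == 1]):
        r = int(np.sum(T >= t))
        d = int(np.sum((T == t) & (E == 1)))
        ll -= sum(np.log(r - l) for l in range(d))
    return float(ll)


def fit_cox(surv: pd.DataFrame, covariates: list[str], duration_col: str = "event_time",
            event_col: str = "event", ties: str = "efron") -> CoxFit:
    """Partial-likelihood Cox fit on the per-subject survival table.

    Covariates with zero variance carry no contrast: their coefficient is 0
    by convention (the partial likelihood is flat in them) and they are
    excluded from the numerical fit.
    """
    if surv[event_col].sum() < 1:
        raise ValueError("need at least one event")
    X = surv[list(covariates)].to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariate values")
    active = [c for c in covariates if surv[c].nunique() > 1]
    p = len(covariates)
    gamma = np.zeros(p)
    vcov = np.zeros((p, p))

    if active:
        df = surv[[duration_col, event_col] + active].copy()
        cph = _fit_with_fallback(df, duration_col, event_col)
        g = cph.params_.to_numpy()
        if np.any(np.abs(g) > 50):
            raise RuntimeError("diverging coefficients: monotone partial likelihood "
                               "(perfect separation) suspected")
        idx = [covariates.index(c) for c in active]
        gamma[idx] = g
        vcov[np.ix_(idx, idx)] = cph.variance_matrix_.to_numpy()
        loglik = float(cph.log_likelihood_)
        cumhaz = cph.baseline_cumulative_hazard_.iloc[:, 0]
        model = cph
    else:
        T = surv[duration_col].to_numpy(float)
        E = surv[event_col].to_numpy(int)
        loglik = _null_partial_loglik(T, E)
        from lifelines import NelsonAalenFitter

        naf = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(T, E)
        cumhaz = naf.cumulative_hazard_.iloc[:, 0]
        model = None

    return CoxFit(
        covariates=list(covariates),
        gamma=gamma,
        vcov=vcov,
        partial_loglik=loglik,
        baseline_cumhaz=cumhaz,
        n_events=int(surv[event_col].sum()),
        model=model,
    )


def _transform_times(times: np.ndarray, surv: pd.DataFrame, kind: str,
                     duration_col: str, event_col: str) -> np.ndarray:
    if kind == "identity":
        return times.astype(float)
    if kind == "log":
        return np.log(times.astype(float))
    if kind == "km":
        km = KaplanMeierFitter().fit(surv[duration_col], surv[event_col])
        # left-continuous KM evaluated just before each event time
        s = km.survival_function_.iloc[:, 0]
        idx = np.searchsorted(s.index.to_numpy(), times, side="left") - 1
        surv_before = np.where(idx >= 0, s.to_numpy()[np.maximum(idx, 0)], 1.0)
        return 1.0 - surv_before
    raise ValueError(f"unknown time transform {kind!r}")


def schoenfeld_test(fit: CoxFit, surv: pd.DataFrame, time_transform: str = "km",
                    duration_col: str = "event_time", event_col: str = "event") -> PHTestResult:
    """Grambsch-Therneau test of proportional hazards.

    Regresses the scaled Schoenfeld residuals on a transform g(t) of event
    time; under proportional hazards the slope is zero. Per-covariate
    statistics use the j-th diagonal of the inverse information; the global
    statistic is the full quadratic form (df = number of covariates).
    """
    if fit.model is None:
        raise ValueError("proportionality test needs at least one non-constant covariate")
    d = int(surv[event_col].sum())
    p = len(fit.covariates)
    if d < 2:
        raise ValueError("need at least 2 events for the proportionality test")
    if d <= p:
        raise ValueError("fewer events than covariates: test undefined")

    events = surv.loc[surv[event_col] == 1].sort_values(duration_col)
    resid = fit.model.compute_residuals(
        surv[[duration_col, event_col] + fit.covariates], "schoenfeld")
    resid = resid.sort_index(level=0) if isinstance(resid.index, pd.MultiIndex) else resid
    # align residual rows (indexed by subject row label) with event times
    times = surv.loc[resid.index, duration_col].to_numpy() if set(resid.index) <= set(surv.index) \
        else events[duration_col].to_numpy()
    order = np.argsort(times, kind="stable")
    S = resid.to_numpy()[order]                     # (d, p) unscaled residuals
    g = _transform_times(np.sort(times), surv, time_transform, duration_col, event_col)
    gc = g - g.mean()

    vcov = fit.vcov                                 # = I^{-1} of the Cox fit
    u = S.T @ gc                                    # (p,)
    denom = float(gc @ gc)
    t_global = d * float(u @ vcov @ u) / denom
    iu = vcov @ u
    t_per = d * iu**2 / (np.diag(vcov) * denom)
    return PHTestResult(
        covariates=list(fit.covariates),
        statistic=t_per,
        p_value=sstats.chi2.sf(t_per, 1),
        global_statistic=t_global,
        global_df=p,
        global_p_value=float(sstats.chi2.sf(t_global, p)),
        time_transform=time_transform,
    )
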