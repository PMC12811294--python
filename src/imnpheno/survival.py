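"""Survival curves, group tests, proportional-hazards fits, and the
ANOVA-with-control-comparisons used for per-cell phenotypes.

Inputs are start-end-censor records (duration = end - start; event = 1
when death was observed). Kaplan-Meier estimation and the logrank test
go through lifelines; Cox proportional-hazards fitting goes through
statsmodels' PHReg, whose partial likelihood supports both Breslow
(default here: adequate at the tie density of a 2-day imaging schedule)
and Efron tie handling. Group comparisons of per-cell measurements use
one-way ANOVA with Dunnett many-to-one adjustment against the control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

Z975 = 1.959963984540054


@dataclass
class SurvivalCurve:
    """Product-limit survival curve for one group."""

    times: np.ndarray           # event-time grid (days)
    survival: np.ndarray        # S(t) at each grid time
    at_risk: np.ndarray
    events: np.ndarray
    group: str = ""

    def at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class HazardFit:
    """One Cox proportional-hazards fit."""

    covariates: list[str]
    log_hr: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    log_likelihood: float
    converged: bool

    def forest_table(self) -> pd.DataFrame:
        """Forest-plot-ready table: covariate, log HR, 95% CI bounds."""
        return pd.DataFrame(
            {"covariate": self.covariates, "log_hr": self.log_hr,
             "ci_low": self.ci_low, "ci_high": self.ci_high,
             "hr": np.exp(self.log_hr)}
        )


def _durations_events(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if "duration" in records.columns:
        dur = records["duration"].to_numpy(float)
    else:
        dur = (records["end"] - records["start"]).to_numpy(float)
    if np.any(dur < 0):
        raise ValueError("negative durations")
    return dur, records["event"].to_numpy(int)


def kaplan_meier(records: pd.DataFrame, group: str = "") -> SurvivalCurve:
    """Product-limit estimator over the observed event times.

    Censored records leave the risk set without producing a step. The
    curve starts at 1 and is non-increasing.
    """
    if len(records) == 0:
        raise ValueError("need >= 1 record")
    dur, ev = _durations_events(records)
    kmf = KaplanMeierFitter()
    kmf.fit(dur, ev)
    event_times = np.sort(np.unique(dur[ev == 1]))
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times])
    table = kmf.event_table
    at_risk = np.array([int(table.loc[t, "at_risk"]) for t in event_times])
    events = np.array([int(table.loc[t, "observed"]) for t in event_times])
    return SurvivalCurve(event_times, surv, at_risk, events, group=group)


def pairwise_logrank(
    groups: dict[str, pd.DataFrame],
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Logrank chi-square (1 df) for every pair of groups.

    Raw p-values are always reported; the default multiplicity
    adjustment is Bonferroni over the number of pairs (``adjust=None``
    disables it).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, df in groups.items():
        if len(df) == 0:
            raise ValueError(f"group {name!r} has zero observations")
    names = sorted(groups)
    rows = []
    n_pairs = len(names) * (len(names) - 1) // 2
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            da, ea = _durations_events(groups[a])
            db, eb = _durations_events(groups[b])
            res = logrank_test(da, db, event_observed_A=ea, event_observed_B=eb)
            p = float(res.p_value)
            p_adj = min(p * n_pairs, 1.0) if adjust == "bonferroni" else p
            rows.append(
                {"group_a": a, "group_b": b,
                 "statistic": float(res.test_statistic), "p": p, "p_adj": p_adj}
            )
    return pd.DataFrame(rows)


def cox_ph(
    records: pd.DataFrame,
    covariates: list[str],
    ties: str = "breslow",
) -> HazardFit:
    """Cox proportional-hazards fit by partial-likelihood maximization.

    ``covariates`` name numeric columns of ``records`` (dummy-code
    categorical groups upstream). Reports per-covariate log hazard
    ratio, its standard error from the inverse information, and the 95%
    CI as estimate +/- 1.96 SE on the log scale. Monotone likelihoods
    (complete separation) are reported with ``converged=False``.
    """
    dur, ev = _durations_events(records)
    if ev.sum() == 0:
        raise ValueError("need >= 1 event")
    X = records[covariates].to_numpy(float)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant covariate")
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    model = PHReg(dur, X, status=ev, ties=ties)
    converged = True
    with np.errstate(all="ignore"), warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(disp=False)
            params = np.asarray(res.params, float)
            se = np.asarray(res.bse, float)
            llf = float(res.llf)
            # monotone likelihood (complete separation) shows up as a
            # runaway estimate and/or an exploding standard error
            if (not np.all(np.isfinite(se)) or np.any(np.abs(params) > 20)
                    or np.any(se > 1e3)):
                converged = False
        except Exception:
            converged = False
            params = np.full(len(covariates), np.nan)
            se = np.full(len(covariates), np.nan)
            llf = math.nan
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    return HazardFit(
        covariates=list(covariates), log_hr=params, se=se,
        ci_low=params - Z975 * se, ci_high=params + Z975 * se,
        log_likelihood=llf, converged=converged,
    )


def cox_two_group(
    records: pd.DataFrame,
    group_col: str = "group",
    reference: str | None = None,
    ties: str = "breslow",
) -> HazardFit:
    """Cox fit with one-hot group covariates against a reference arm."""
    levels = sorted(records[group_col].unique())
    if reference is None:
        reference = levels[0]
    others = [g for g in levels if g != reference]
    df = records.copy()
    for g in others:
        df[f"vs_{reference}:{g}"] = (df[group_col] == g).astype(float)
    return cox_ph(df, [f"vs_{reference}:{g}" for g in others], ties=ties)


def anova_dunnett(
    measurements: dict[str, np.ndarray] | pd.DataFrame,
    control: str,
    value_col: str = "value",
    group_col: str = "group",
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """One-way ANOVA plus Dunnett many-to-one comparisons vs the control.

    Returns the overall F statistic and, per non-control group, the
    group mean, mean difference from control, and the Dunnett-adjusted
    p-value (multivariate-t, evaluated with a seeded generator so runs
    are reproducible).
    """
    if isinstance(measurements, pd.DataFrame):
        measurements = {
            str(g): df[value_col].to_numpy(float)
            for g, df in measurements.groupby(group_col)
        }
    if control not in measurements:
        raise ValueError(f"control group {control!r} not present")
    if len(measurements) < 2:
        raise ValueError("need >= 2 groups")
    for name, x in measurements.items():
        if len(x) < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    others = sorted(g for g in measurements if g != control)
    samples = [np.asarray(measurements[g], float) for g in others]
    ctrl = np.asarray(measurements[control], float)
    f_stat = float(stats.f_oneway(ctrl, *samples).statistic)
    res = stats.dunnett(*samples, control=ctrl, rng=np.random.default_rng(seed))
    rows = []
    for i, g in enumerate(others):
        rows.append(
            {"group": g, "mean": float(samples[i].mean()),
             "diff_vs_control": float(samples[i].mean() - ctrl.mean()),
             "p_adj": float(res.pvalue[i])}
        )
    table = pd.DataFrame(rows)
    table.insert(0, "control_mean", float(ctrl.mean()))
    return f_stat, table
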