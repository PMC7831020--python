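"""Outcome analyses: Kaplan-Meier estimation with log-rank tests over the
standard clinical stratifications, and univariate/multivariate Cox
proportional-hazards regression.

Overall survival (OS) is the time from first radiological detection of brain
metastases to death or last follow-up.  Continuous covariates (age, total
lesion volume, Ki-67) are dichotomized at the in-sample median by default —
ties at the median join the ">= median" group — or at configured cut points.
Patients with any infratentorial lesion fall in the "with infratentorial
involvement" group even when supratentorial lesions coexist.  Cox fits use
Efron's approximation for tied event times (the lifelines default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

logger = logging.getLogger(__name__)

#: Factor -> (reference level, ordered contrast levels).
DEFAULT_FACTORS: dict[str, tuple[str, tuple[str, ...]]] = {
    "age_group": ("young", ("old",)),
    "sex": ("female", ("male",)),
    "primary_group": ("lung", ("breast", "other")),
    "number_group": ("1", ("2", ">=3")),
    "tv_group": ("small", ("large",)),
    "infratentorial": ("without", ("with",)),
    "radiotherapy": ("no", ("yes",)),
}


@dataclass
class SurvivalData:
    """Per-patient survival outcome plus stratification covariates."""

    frame: pd.DataFrame
    medians: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"patient_id", "os_time", "event"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"missing survival columns: {sorted(missing)}")
        if (self.frame["os_time"] < 0).any():
            raise ValueError("os_time must be >= 0")


def km_estimate(
    times: Sequence[float], events: Sequence[bool], *, label: str = "KM"
) -> dict:
    """Product-limit survival estimate with the median survival time.

    The median is the earliest time at which S(t) <= 0.5; it is NaN (flagged
    ``median_defined=False``) when the curve never reaches 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) < 1:
        raise ValueError("need at least one subject")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter(label=label)
    kmf.fit(times, event_observed=events)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    return {
        "survival_function": kmf.survival_function_[label],
        "median": median,
        "median_defined": bool(np.isfinite(median)),
        "median_ci": (float(ci.iloc[0, 0]), float(ci.iloc[0, 1])),
        "fitter": kmf,
    }


def logrank_by_group(
    data: Mapping[str, tuple[Sequence[float], Sequence[bool]]],
    *,
    pairwise: bool = True,
) -> dict:
    """Log-rank test across >= 2 groups of (times, events).

    Returns the omnibus chi-square statistic with k-1 degrees of freedom and,
    for three or more groups, unadjusted pairwise comparisons.
    """
    groups = list(data)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, (t, _) in data.items():
        if len(t) < 1:
            raise ValueError(f"group {g!r} has no subjects")
    times = np.concatenate([np.asarray(t, float) for t, _ in data.values()])
    events = np.concatenate([np.asarray(e, bool) for _, e in data.values()])
    labels = np.concatenate(
        [np.repeat(g, len(t)) for g, (t, _) in data.items()]
    )
    res = multivariate_logrank_test(times, labels, events)
    out = {
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
        "df": len(groups) - 1,
    }
    if pairwise and len(groups) >= 3:
        rows = []
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1 :]:
                t1, e1 = data[g1]
                t2, e2 = data[g2]
                pr = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
                rows.append(
                    {
                        "group_1": g1,
                        "group_2": g2,
                        "statistic": float(pr.test_statistic),
                        "p": float(pr.p_value),
                    }
                )
        out["pairwise"] = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------


def _median_split(
    values: pd.Series, low_label: str, high_label: str, cut: float | None
) -> tuple[pd.Series, float]:
    cut_value = float(values.median()) if cut is None else float(cut)
    return (
        values.ge(cut_value).map({True: high_label, False: low_label}),
        cut_value,
    )


def build_strata(
    covariates: pd.DataFrame,
    summaries: pd.DataFrame,
    medians: Mapping[str, float] | None = None,
) -> SurvivalData:
    """Join covariates with lesion summaries and dichotomize for analysis.

    ``medians`` may pin the age / TV / Ki-67 cut points; otherwise in-sample
    medians are used (ties at the cut join the ">= median" side).  The TV
    median is computed over per-patient total volumes.  Ki-67 strata are
    omitted with a warning when the column is entirely missing.
    """
    medians = dict(medians or {})
    if "patient_id" not in covariates.columns:
        raise ValueError("covariate table lacks patient_id")
    frame = covariates.merge(
        summaries[["patient_id", "n_lesions", "number_group", "tv",
                   "infratentorial_involvement"]]
        if "number_group" in summaries.columns
        else summaries,
        on="patient_id",
        how="inner",
        suffixes=("", "_lesion"),
    )
    for col in ("os_time", "event"):
        if col not in frame.columns:
            raise ValueError(f"missing covariate column {col!r}")

    used: dict[str, float] = {}
    frame["age_group"], used["age"] = _median_split(
        frame["age"], "young", "old", medians.get("age")
    )
    frame["tv_group"], used["tv"] = _median_split(
        frame["tv"], "small", "large", medians.get("tv")
    )
    for src, name, cut_key in (
        ("ki67_primary", "ki67_primary_group", "ki67_primary"),
        ("ki67_bm", "ki67_bm_group", "ki67_bm"),
    ):
        if src in frame.columns and frame[src].notna().any():
            frame[name], used[cut_key] = _median_split(
                frame[src], "low", "high", medians.get(cut_key)
            )
        else:
            logger.warning("covariate %s entirely missing; stratum omitted", src)
    frame["primary_group"] = frame["primary_class"].map(
        lambda c: c if c in ("lung", "breast") else "other"
    )
    frame["infratentorial"] = frame["infratentorial_involvement"].map(
        lambda v: "with" if bool(v) else "without"
    )
    if "treatment" in frame.columns:
        frame["radiotherapy"] = frame["treatment"].map(
            lambda t: "yes" if ("WBRT" in str(t) or "SRS" in str(t)) else "no"
        )
    frame["event"] = frame["event"].astype(bool)
    return SurvivalData(frame=frame, medians=used)


# ---------------------------------------------------------------------------
# Cox proportional-hazards regression
# ---------------------------------------------------------------------------


def _dummy_design(
    frame: pd.DataFrame, factors: Sequence[str]
) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Reference-coded dummy design; returns (design, [(factor, level, column)])."""
    design = pd.DataFrame(index=frame.index)
    coding: list[tuple[str, str, str]] = []
    for factor in factors:
        if factor not in frame.columns:
            raise ValueError(f"unknown factor {factor!r}")
        values = frame[factor].astype(str)
        if values.nunique() < 2:
            raise ValueError(f"factor {factor!r} has no contrast (constant)")
        if factor in DEFAULT_FACTORS:
            ref, levels = DEFAULT_FACTORS[factor]
            levels = tuple(l for l in levels if l in set(values))
        else:
            ordered = sorted(values.unique())
            ref, levels = ordered[0], tuple(ordered[1:])
        for level in levels:
            col = f"{factor}[{level}]"
            design[col] = (values == level).astype(float)
            coding.append((factor, level, col))
    return design, coding


def cox_regression(
    data: SurvivalData,
    factors: Sequence[str],
    mode: str = "multivariate",
) -> pd.DataFrame:
    """Cox proportional-hazards fit over reference-coded factors.

    ``mode="univariate"`` fits each factor alone; ``"multivariate"`` fits all
    jointly.  Returns a tidy table (factor, level, n, HR, 95% CI, p, mode).
    Separation or non-convergence raises rather than passing silently.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    frame = data.frame
    factor_sets = [[f] for f in factors] if mode == "univariate" else [list(factors)]
    rows = []
    for fset in factor_sets:
        design, coding = _dummy_design(frame, fset)
        n_events = int(frame["event"].sum())
        if n_events < design.shape[1]:
            raise ValueError(
                f"only {n_events} events for {design.shape[1]} parameters"
            )
        fit_frame = design.assign(
            os_time=frame["os_time"].values, event=frame["event"].astype(int).values
        )
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(fit_frame, duration_col="os_time", event_col="event")
        except ConvergenceError as err:
            raise RuntimeError(f"Cox fit failed to converge for {fset}: {err}") from err
        summary = cph.summary
        for factor, level, col in coding:
            rows.append(
                {
                    "factor": factor,
                    "level": level,
                    "n": int((frame[factor].astype(str) == level).sum()),
                    "hr": float(summary.loc[col, "exp(coef)"]),
                    "ci_low": float(summary.loc[col, "exp(coef) lower 95%"]),
                    "ci_high": float(summary.loc[col, "exp(coef) upper 95%"]),
                    "p": float(summary.loc[col, "p"]),
                    "coef": float(summary.loc[col, "coef"]),
                    "se": float(summary.loc[col, "se(coef)"]),
                    "mode": mode,
                }
            )
    return pd.DataFrame(rows)


def km_by_stratum(data: SurvivalData, factor: str) -> dict:
    """KM estimates and log-rank test across the levels of one factor."""
    frame = data.frame
    if factor not in frame.columns:
        raise ValueError(f"unknown factor {factor!r}")
    groups = {}
    estimates = {}
    for level, sub in frame.groupby(factor, observed=True):
        groups[str(level)] = (sub["os_time"].values, sub["event"].values)
        estimates[str(level)] = km_estimate(
            sub["os_time"].values, sub["event"].values, label=str(level)
        )
    test = logrank_by_group(groups) if len(groups) >= 2 else None
    return {"estimates": estimates, "logrank": test}
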