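"""Outcome-cohort assembly and logistic models for hospitalization risk.

The outcome is all-cause hospitalization in the first half of the year
following the observation year (any admission counts once).  Patients are
excluded when they die before the end of that follow-up year, or when
their only follow-up-year admissions fall in the second half (such
patients cannot be cleanly labelled non-hospitalized).  Crude models
regress the outcome on the polypharmacy flag alone; adjusted models add
sex, age at 31 December of the observation year, and the count of
hospitalizations in the four preceding years.  Odds ratios are
exponentiated coefficients with Wald 95% confidence intervals.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .windows import CLASS_BINS

__all__ = [
    "AssociationEstimate",
    "long_stay_filter",
    "assemble_cohort",
    "fit_models",
    "crude_or_2x2",
]


@dataclass(frozen=True)
class AssociationEstimate:
    """One odds ratio with its Wald 95% confidence limits."""

    label: str
    term: str
    or_value: float
    lcl: float
    ucl: float
    adjusted: bool
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and not (self.lcl <= self.or_value <= self.ucl):
            raise ValueError("confidence limits must bracket the estimate")


def long_stay_filter(discharges: pd.DataFrame, min_days: int = 7) -> pd.DataFrame:
    """Keep only stays strictly longer than *min_days* days."""
    stay = (
        pd.to_datetime(discharges["discharge_date"])
        - pd.to_datetime(discharges["admission_date"])
    ).dt.days
    return discharges.loc[stay > min_days].reset_index(drop=True)


def assemble_cohort(
    registry: pd.DataFrame,
    discharges: pd.DataFrame,
    statuses: pd.DataFrame,
    observation_year: int = 2017,
    outcome_window: tuple[dt.date, dt.date] | None = None,
    prior_window: tuple[dt.date, dt.date] | None = None,
) -> pd.DataFrame:
    """Build analysis-ready rows: exposure, covariates, outcome, exclusions.

    Parameters
    ----------
    registry
        ``patient_id``, ``sex`` (F/M), ``birth_date``, ``death_date``
        (empty/NaT when alive).
    discharges
        ``patient_id``, ``admission_date``, ``discharge_date``; records
        with a discharge before the admission are rejected with a warning.
    statuses
        Patient-indexed summary table (poly5/poly10/class_bin/...), e.g.
        from :func:`polypharm.windows.summarize_table`; its index defines
        the cohort.
    outcome_window
        Inclusive admission-date range defining the outcome (default
        1 Jan - 30 Jun of the year after the observation year).
    prior_window
        Inclusive range for the prior-hospitalization count (default the
        four calendar years ending with the observation year).

    Returns
    -------
    DataFrame with one row per cohort patient: exposure columns from
    *statuses* plus ``sex``, ``age_years``, ``prior_hospitalizations``,
    ``outcome``, ``excluded``, ``exclusion_reason``.
    """
    follow_year = observation_year + 1
    if outcome_window is None:
        outcome_window = (dt.date(follow_year, 1, 1), dt.date(follow_year, 6, 30))
    if prior_window is None:
        prior_window = (
            dt.date(observation_year - 3, 1, 1),
            dt.date(observation_year, 12, 31),
        )

    reg = registry.set_index("patient_id")
    adm = pd.to_datetime(discharges["admission_date"])
    dis = pd.to_datetime(discharges["discharge_date"])
    bad = dis < adm
    if bad.any():
        warnings.warn(
            f"rejected {int(bad.sum())} discharge record(s) with "
            "discharge before admission",
            stacklevel=2,
        )
    hosp = pd.DataFrame(
        {"patient_id": discharges.loc[~bad, "patient_id"], "admission": adm[~bad]}
    )

    def _count_in(lo: dt.date, hi: dt.date) -> pd.Series:
        m = (hosp["admission"] >= pd.Timestamp(lo)) & (
            hosp["admission"] <= pd.Timestamp(hi)
        )
        return hosp.loc[m].groupby("patient_id").size()

    n_outcome = _count_in(*outcome_window)
    n_second_half = _count_in(
        dt.date(follow_year, 7, 1), dt.date(follow_year, 12, 31)
    )
    n_prior = _count_in(*prior_window)

    idx = statuses.index
    out = statuses.copy()
    out["sex"] = reg["sex"].reindex(idx)
    birth = pd.to_datetime(reg["birth_date"]).reindex(idx)
    ref = pd.Timestamp(dt.date(observation_year, 12, 31))
    # completed years of age at 31 Dec of the observation year
    age = ref.year - birth.dt.year
    age -= ((birth.dt.month * 100 + birth.dt.day) > (ref.month * 100 + ref.day)).astype(int)
    out["age_years"] = age.astype(int)
    out["prior_hospitalizations"] = (
        n_prior.reindex(idx).fillna(0).astype(int)
    )
    out["outcome"] = n_outcome.reindex(idx).fillna(0).astype(int) > 0

    death = pd.to_datetime(reg["death_date"].replace("", pd.NaT)).reindex(idx)
    died = death.notna() & (death <= pd.Timestamp(dt.date(follow_year, 12, 31)))
    second_only = (~out["outcome"]) & (
        n_second_half.reindex(idx).fillna(0).astype(int) > 0
    )
    out["excluded"] = died | second_only
    reason = np.where(
        died, "died_before_end_" + str(follow_year),
        np.where(second_only, "second_half_only_hospitalization", ""),
    )
    out["exclusion_reason"] = reason
    return out


def crude_or_2x2(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio from exposed-case/exposed-control/
    unexposed-case/unexposed-control counts."""
    return (a * d) / (b * c)


def _wald_estimates(
    result, terms: dict[str, str], label: str, adjusted: bool
) -> list[AssociationEstimate]:
    params = result.params
    ci = result.conf_int()
    out = []
    for col, term in terms.items():
        out.append(
            AssociationEstimate(
                label=label,
                term=term,
                or_value=float(np.exp(params[col])),
                lcl=float(np.exp(ci.loc[col, 0])),
                ucl=float(np.exp(ci.loc[col, 1])),
                adjusted=adjusted,
            )
        )
    return out


def fit_models(
    rows: pd.DataFrame, exposure: str = "poly5", label: str = ""
) -> list[AssociationEstimate]:
    """Crude and adjusted logistic regressions of the outcome on exposure.

    *exposure* is ``poly5`` (binary, >=5 vs <5 drugs) or ``class_bin``
    (indicator terms for 5..9 and >=10, reference 1-4).  Excluded rows are
    dropped before fitting.  A model that fails to converge (e.g. perfect
    separation in a small stratum) yields estimates flagged
    ``converged=False`` rather than raising.
    """
    df = rows.loc[~rows["excluded"]].copy()
    y = df["outcome"].astype(float)

    if exposure == "poly5":
        X_exp = pd.DataFrame({"poly5": df["poly5"].astype(float)})
        terms = {"poly5": ">=5 vs <5"}
    elif exposure == "class_bin":
        X_exp = pd.DataFrame(index=df.index)
        terms = {}
        for b in CLASS_BINS[1:]:
            col = f"bin_{b}"
            X_exp[col] = (df["class_bin"] == b).astype(float)
            terms[col] = b
    else:
        raise ValueError(f"unknown exposure: {exposure!r}")

    adj = pd.DataFrame(
        {
            "sex_M": (df["sex"] == "M").astype(float),
            "age_years": df["age_years"].astype(float),
            "prior_hospitalizations": df["prior_hospitalizations"].astype(float),
        },
        index=df.index,
    )

    estimates: list[AssociationEstimate] = []
    for adjusted, X in ((False, X_exp), (True, pd.concat([X_exp, adj], axis=1))):
        # constant columns (empty class bins, degenerate covariates) would
        # make the design singular; drop them and flag dropped exposure terms
        constant = [c for c in X.columns if X[c].nunique() <= 1]
        fit_terms = {c: t for c, t in terms.items() if c not in constant}
        for col in constant:
            if col in terms:
                estimates.append(
                    AssociationEstimate(
                        label=label, term=terms[col], or_value=float("nan"),
                        lcl=float("nan"), ucl=float("nan"),
                        adjusted=adjusted, converged=False,
                    )
                )
        X = sm.add_constant(X.drop(columns=constant), has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=False, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                raise RuntimeError("no convergence")
            estimates.extend(_wald_estimates(res, fit_terms, label, adjusted))
        except Exception:
            for term in fit_terms.values():
                estimates.append(
                    AssociationEstimate(
                        label=label, term=term, or_value=float("nan"),
                        lcl=float("nan"), ucl=float("nan"),
                        adjusted=adjusted, converged=False,
                    )
                )
    return estimates
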