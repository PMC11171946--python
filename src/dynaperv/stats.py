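"""Regression stages: recanalization logistic, outcome linear, passes Poisson.

All categorical fits use treatment (dummy) coding with ``C_NW`` — early
enhancement without washout, the clinically least favourable pattern — as the
reference level, so exponentiated coefficients read as "odds (or rate) of the
pattern relative to C_NW".  Fits are maximum likelihood via statsmodels;
confidence intervals and p-values are two-sided Wald on the link scale.

A closed-form 2x2 cross-product odds ratio with its Wald interval is provided
as an independent oracle: with a single categorical predictor and no
covariates, the logistic model is saturated and must reproduce it exactly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .core import CATEGORIES
from .errors import SeparationError, ZeroCellError

__all__ = [
    "TwoByTwo",
    "OddsRatioResult",
    "odds_ratio_2x2",
    "RecanalizationLogistic",
    "StandardPerviousnessLogistic",
    "OutcomeLinear",
    "PassesPoisson",
    "fit_recanalization_logistic",
    "fit_sp_logistic",
    "fit_outcome_linear",
    "fit_passes_poisson",
]

_TERM_RE = re.compile(r"\[T\.(.+?)\]$")


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 outcome table: (a, b) exposed successes/failures, (c, d) reference."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @classmethod
    def from_successes(cls, k_exposed: int, n_exposed: int, k_ref: int, n_ref: int) -> "TwoByTwo":
        return cls(a=k_exposed, b=n_exposed - k_exposed, c=k_ref, d=n_ref - k_ref)


@dataclass(frozen=True)
class OddsRatioResult:
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    se_log: float
    corrected: bool = False


def odds_ratio_2x2(
    t: TwoByTwo, alpha: float = 0.05, correction: str = "none"
) -> OddsRatioResult:
    """Cross-product odds ratio with a Wald interval on the log scale.

    OR = (a*d)/(b*c); SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d).  A zero cell
    makes the OR zero or infinite: with ``correction="none"`` this raises
    :class:`ZeroCellError` (the condition is reported, not silently returned
    as a number); ``correction="haldane"`` adds 0.5 to every cell instead.
    """
    if correction not in ("none", "haldane"):
        raise ValueError(f"unknown correction {correction!r}")
    cells = np.array([t.a, t.b, t.c, t.d], dtype=float)
    corrected = False
    if np.any(cells == 0):
        if correction == "none":
            zero = [n for n, v in zip("abcd", cells) if v == 0]
            raise ZeroCellError(
                f"zero cell(s) {zero} make the odds ratio degenerate "
                "(zero or infinite); use correction='haldane' for a finite estimate"
            )
        cells = cells + 0.5
        corrected = True
    a, b, c, d = cells
    log_or = np.log(a * d) - np.log(b * c)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = sps.norm.ppf(1 - alpha / 2)
    p = 2 * sps.norm.sf(abs(log_or) / se)
    return OddsRatioResult(
        estimate=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        p_value=float(p),
        se_log=se,
        corrected=corrected,
    )


def _term_label(name: str) -> str:
    m = _TERM_RE.search(name)
    return m.group(1) if m else name


def _tidy(fit, model: str, reference: str, exp: bool) -> pd.DataFrame:
    params = fit.params
    ci = fit.conf_int()
    rows = []
    for name in params.index:
        if name == "Intercept":
            continue
        est, lo, hi = params[name], ci.loc[name, 0], ci.loc[name, 1]
        if exp:
            est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
        rows.append({
            "term": _term_label(name),
            "estimate": float(est),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "p_value": float(fit.pvalues[name]),
            "model": model,
            "reference": reference,
            "n_obs": int(fit.nobs),
        })
    return pd.DataFrame(rows)


def _category_formula(reference: str) -> str:
    return f"C(dp_category, Treatment(reference='{reference}'))"


def _check_categories(df: pd.DataFrame, reference: str, need: int = 2) -> None:
    present = df["dp_category"].unique()
    if reference not in present:
        raise ValueError(f"reference category {reference!r} has no observations")
    if len(present) < need:
        raise ValueError(
            f"need at least {need} categories with data, found {sorted(present)}"
        )


class RecanalizationLogistic(BaseEstimator):
    """Logistic model of recanalization success on the enhancement pattern.

    Success is TICI 2c or 3.  Optionally adjusts for clot length.  With no
    covariate the model is saturated, so the per-category odds ratios equal
    the 2x2 cross-product ratios against the reference.

    Attributes (after ``fit``)
    --------------------------
    results_ : DataFrame
        Tidy table (term, estimate as OR, ci_low, ci_high, p_value, ...).
    fit_ : statsmodels results object.
    """

    def __init__(self, reference: str = "C_NW", adjust_clot_length: bool = False):
        self.reference = reference
        self.adjust_clot_length = adjust_clot_length

    def fit(self, cohort: pd.DataFrame, y=None) -> "RecanalizationLogistic":
        cols = ["dp_category", "success"] + (
            ["clot_length_mm"] if self.adjust_clot_length else []
        )
        df = cohort.dropna(subset=cols).copy()
        df["success"] = df["success"].astype(int)
        _check_categories(df, self.reference)
        tab = df.groupby("dp_category")["success"].agg(["sum", "count"])
        for cat, row in tab.iterrows():
            if row["sum"] == 0 or row["sum"] == row["count"]:
                raise SeparationError(
                    f"complete separation: category {cat} has "
                    f"{int(row['sum'])}/{int(row['count'])} successes"
                )
        formula = f"success ~ {_category_formula(self.reference)}"
        if self.adjust_clot_length:
            formula += " + clot_length_mm"
        self.fit_ = smf.logit(formula, data=df).fit(disp=0)
        self.results_ = _tidy(self.fit_, "logistic", self.reference, exp=True)
        return self


class StandardPerviousnessLogistic(BaseEstimator):
    """Logistic model of success on the continuous attenuation increases.

    Predictors are the standard perviousness (``delta_na``, per HU) and the
    NCCT-to-venous increase (``delta_nv``, per HU); exponentiated
    coefficients are per-HU odds ratios.
    """

    def __init__(self, predictors: tuple[str, ...] = ("delta_na", "delta_nv")):
        self.predictors = predictors

    def fit(self, cohort: pd.DataFrame, y=None) -> "StandardPerviousnessLogistic":
        df = cohort.dropna(subset=["success", *self.predictors]).copy()
        df["success"] = df["success"].astype(int)
        for p in self.predictors:
            if np.isclose(df[p].std(ddof=0), 0.0):
                raise ValueError(f"predictor {p!r} has zero variance")
        formula = "success ~ " + " + ".join(self.predictors)
        self.fit_ = smf.logit(formula, data=df).fit(disp=0)
        self.results_ = _tidy(self.fit_, "sp_logistic", "", exp=True)
        return self


class OutcomeLinear(BaseEstimator):
    """OLS of a clinical outcome on the pattern, adjusting for its baseline.

    Complete-case: rows with a missing outcome or baseline are dropped.
    Categories left with fewer than two observations are excluded with a
    warning; if no non-reference category survives, no contrast is estimable
    and a ``ValueError`` is raised.
    """

    _BASELINES = {"nihss_discharge": "nihss_admit", "mrs_3mo": "mrs_admit"}

    def __init__(self, outcome: str = "nihss_discharge", baseline: str | None = None,
                 reference: str = "C_NW"):
        self.outcome = outcome
        self.baseline = baseline
        self.reference = reference

    def fit(self, cohort: pd.DataFrame, y=None) -> "OutcomeLinear":
        baseline = self.baseline or self._BASELINES.get(self.outcome)
        if baseline is None:
            raise ValueError(f"no default baseline covariate for outcome {self.outcome!r}")
        df = cohort.dropna(subset=["dp_category", self.outcome, baseline]).copy()
        counts = df["dp_category"].value_counts()
        thin = [c for c in counts.index if counts[c] < 2]
        if thin:
            warnings.warn(
                f"dropping categories with <2 complete cases: {sorted(thin)}",
                UserWarning,
            )
            df = df[~df["dp_category"].isin(thin)]
        _check_categories(df, self.reference)
        formula = f"{self.outcome} ~ {baseline} + {_category_formula(self.reference)}"
        self.fit_ = smf.ols(formula, data=df).fit()
        self.results_ = _tidy(self.fit_, f"linear:{self.outcome}", self.reference, exp=False)
        self.baseline_ = baseline
        return self


class PassesPoisson(BaseEstimator):
    """Poisson model of retrieval passes on the enhancement pattern.

    Patients without an intervention (missing pass count) are excluded.
    Exponentiated coefficients are rate ratios versus the reference; with no
    covariates the model is saturated, so each rate ratio equals the ratio of
    group mean pass counts.
    """

    def __init__(self, reference: str = "C_NW"):
        self.reference = reference

    def fit(self, cohort: pd.DataFrame, y=None) -> "PassesPoisson":
        df = cohort.dropna(subset=["dp_category", "n_passes"]).copy()
        lost = set(cohort["dp_category"].unique()) - set(df["dp_category"].unique())
        if lost:
            warnings.warn(
                f"categories with no remaining intervention patients dropped: {sorted(lost)}",
                UserWarning,
            )
        _check_categories(df, self.reference)
        formula = f"n_passes ~ {_category_formula(self.reference)}"
        self.fit_ = smf.glm(formula, data=df, family=sm.families.Poisson()).fit()
        self.results_ = _tidy(self.fit_, "poisson", self.reference, exp=True)
        return self


# ---------------------------------------------------------------------------
# Thin functional wrappers over the estimator classes.

def fit_recanalization_logistic(
    cohort: pd.DataFrame, reference: str = "C_NW", adjust_clot_length: bool = False
) -> pd.DataFrame:
    """Odds ratios of success per category vs ``reference`` (tidy DataFrame)."""
    return RecanalizationLogistic(reference, adjust_clot_length).fit(cohort).results_


def fit_sp_logistic(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-HU odds ratios of success on the continuous attenuation increases."""
    return StandardPerviousnessLogistic().fit(cohort).results_


def fit_outcome_linear(
    cohort: pd.DataFrame,
    outcome: str = "nihss_discharge",
    baseline: str | None = None,
    reference: str = "C_NW",
) -> pd.DataFrame:
    """Baseline-adjusted per-category mean differences for a clinical outcome."""
    return OutcomeLinear(outcome, baseline, reference).fit(cohort).results_


def fit_passes_poisson(cohort: pd.DataFrame, reference: str = "C_NW") -> pd.DataFrame:
    """Rate ratios of retrieval passes per category vs ``reference``."""
    return PassesPoisson(reference).fit(cohort).results_


def category_odds_ratios(cohort: pd.DataFrame, reference: str = "C_NW",
                         correction: str = "none") -> pd.DataFrame:
    """Closed-form 2x2 odds ratios per category vs the reference (the oracle)."""
    tab = cohort.dropna(subset=["dp_category", "success"]).groupby("dp_category")["success"]
    agg = tab.agg(["sum", "count"])
    if reference not in agg.index:
        raise ValueError(f"reference category {reference!r} has no observations")
    k_ref, n_ref = int(agg.loc[reference, "sum"]), int(agg.loc[reference, "count"])
    rows = []
    for cat in CATEGORIES:
        if cat == reference or cat not in agg.index:
            continue
        t = TwoByTwo.from_successes(int(agg.loc[cat, "sum"]), int(agg.loc[cat, "count"]),
                                    k_ref, n_ref)
        r = odds_ratio_2x2(t, correction=correction)
        rows.append({"term": cat, "estimate": r.estimate, "ci_low": r.ci_low,
                     "ci_high": r.ci_high, "p_value": r.p_value,
                     "model": "or_2x2", "reference": reference,
                     "n_obs": t.a + t.b + t.c + t.d})
    return pd.DataFrame(rows)
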