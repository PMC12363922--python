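"""Recommendation-treatment concordance and outcome analysis.

Encounters are stratified by whether the therapy actually received first
after the high-risk timepoint agrees with the recommended therapy
(Indifferent recommendations are excluded from the strata), outcome rates
are tabulated per recommendation group, relative reduction/increase
metrics quantify the benefit of following the recommendation, and a
multivariable logistic regression estimates adjusted odds ratios for
concordance while controlling for age, gender, Charlson Comorbidity Index,
SOFA score and the early-warning risk score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "assign_concordance",
    "StratifiedRates",
    "stratified_rates",
    "relative_reduction",
    "relative_increase",
    "LogisticResult",
    "fit_outcome_model",
    "composite_mortality_hospice",
]

_LABELS = {"NIV", "HFNC", "Indifferent"}


def assign_concordance(recommendation: str, actual: str) -> str:
    """concordant / discordant / excluded (excluded iff Indifferent)."""
    if recommendation not in _LABELS or actual not in {"NIV", "HFNC"}:
        raise ValueError(f"unknown label: {recommendation!r} / {actual!r}")
    if recommendation == "Indifferent":
        return "excluded"
    return "concordant" if recommendation == actual else "discordant"


def composite_mortality_hospice(df: pd.DataFrame) -> pd.Series:
    """Composite endpoint: in-hospital mortality OR discharge to hospice."""
    return ((df["mortality"] == 1) | (df["hospice"] == 1)).astype(int)


@dataclass
class StratifiedRates:
    recommendation: str
    outcome: str
    n_total: int
    n_concordant: int
    n_discordant: int
    total_rate: float | None
    concordant_rate: float | None
    discordant_rate: float | None
    relative_reduction_if_concordant: float | None = None
    relative_increase_if_discordant: float | None = None


def _pct(events: int, denom: int) -> float | None:
    if denom == 0:
        return None
    return round(100.0 * events / denom, 2)


def relative_reduction(total_rate: float, concordant_rate: float) -> float:
    """100 * (total - concordant) / total, to 2 decimals."""
    if total_rate <= 0:
        raise ValueError("total rate must be positive")
    return round(100.0 * (total_rate - concordant_rate) / total_rate, 2)


def relative_increase(total_rate: float, discordant_rate: float) -> float:
    """100 * (discordant - total) / total, to 2 decimals."""
    if total_rate <= 0:
        raise ValueError("total rate must be positive")
    return round(100.0 * (discordant_rate - total_rate) / total_rate, 2)


def stratified_rates(
    cohort: pd.DataFrame,
    outcome: str,
    recommendation_group: str,
    recommendation_col: str = "recommendation",
    actual_col: str = "treatment",
) -> StratifiedRates:
    """Outcome rates for one recommendation group, split by concordance.

    The group total covers every encounter with that recommendation; the
    concordant/discordant strata partition it.  Rates are computed from
    unrounded counts; the relative columns derive from the unrounded rates
    and are reported to 2 decimals.
    """
    grp = cohort[cohort[recommendation_col] == recommendation_group]
    if grp.empty:
        raise ValueError(f"empty recommendation group {recommendation_group!r}")
    strata = [
        assign_concordance(r, a)
        for r, a in zip(grp[recommendation_col], grp[actual_col])
    ]
    y = grp[outcome].to_numpy()
    conc = np.array([s == "concordant" for s in strata])
    disc = np.array([s == "discordant" for s in strata])
    n, nc, nd = len(grp), int(conc.sum()), int(disc.sum())

    total_u = 100.0 * y.mean() if n else None
    conc_u = 100.0 * y[conc].mean() if nc else None
    disc_u = 100.0 * y[disc].mean() if nd else None
    rr = ri = None
    if total_u and conc_u is not None:
        rr = round(100.0 * (total_u - conc_u) / total_u, 2)
    if total_u and disc_u is not None:
        ri = round(100.0 * (disc_u - total_u) / total_u, 2)
    return StratifiedRates(
        recommendation=recommendation_group,
        outcome=outcome,
        n_total=n,
        n_concordant=nc,
        n_discordant=nd,
        total_rate=_pct(int(y.sum()), n),
        concordant_rate=_pct(int(y[conc].sum()), nc),
        discordant_rate=_pct(int(y[disc].sum()), nd),
        relative_reduction_if_concordant=rr,
        relative_increase_if_discordant=ri,
    )


@dataclass
class LogisticResult:
    odds_ratios: dict[str, float]
    p_values: dict[str, float]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    converged: bool
    n: int
    warnings: list[str] = field(default_factory=list)


DEFAULT_COVARIATES = ["niv_concordance", "hfnc_concordance", "age", "male",
                      "cci", "sofa", "ventio_score"]


def concordance_indicators(cohort: pd.DataFrame,
                           recommendation_col: str = "recommendation",
                           actual_col: str = "treatment") -> pd.DataFrame:
    """Add niv_concordance / hfnc_concordance indicator columns.

    An encounter is NIV-concordant when NIV was both recommended and
    received (similarly for HFNC); Indifferent recommendations contribute 0
    to both indicators."""
    out = cohort.copy()
    out["niv_concordance"] = (
        (out[recommendation_col] == "NIV") & (out[actual_col] == "NIV")
    ).astype(int)
    out["hfnc_concordance"] = (
        (out[recommendation_col] == "HFNC") & (out[actual_col] == "HFNC")
    ).astype(int)
    return out


def fit_outcome_model(
    cohort: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
) -> LogisticResult:
    """Maximum-likelihood logistic regression (IRLS) of the outcome on the
    concordance indicators and confounders; Wald p-values, exponentiated
    coefficients as odds ratios."""
    covariates = covariates or DEFAULT_COVARIATES
    y = cohort[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    if len(cohort) <= len(covariates) + 1:
        raise ValueError("need more rows than covariates")
    X = sm.add_constant(cohort[covariates].astype(float), has_constant="add")
    warnings_list: list[str] = []
    if y.min() == y.max():
        raise PerfectSeparationError("outcome is constant; model is degenerate")
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception as exc:  # separation, singular Hessian
        raise PerfectSeparationError(str(exc)) from exc
    if not converged:
        warnings_list.append("IRLS did not converge")
    params = fit.params
    return LogisticResult(
        odds_ratios={c: float(np.exp(params[c])) for c in covariates},
        p_values={c: float(fit.pvalues[c]) for c in covariates},
        coefficients={c: float(params[c]) for c in covariates},
        std_errors={c: float(fit.bse[c]) for c in covariates},
        converged=converged,
        n=len(cohort),
        warnings=warnings_list,
    )


class PerfectSeparationError(RuntimeError):
    """Raised when the logistic fit is degenerate (separation or constant
    outcome)."""
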