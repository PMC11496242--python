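"""Observational exposure-outcome regressions with a paternal negative control.

Ordinary least squares of an (inverse-normal-transformed) offspring outcome
on parental coffee consumption, under three covariate presets:

``unadjusted``
    offspring birth year + parental ages at birth;
``adjusted``
    + maternal smoking, alcohol, parental education and income (income
    models always include birth year, which the base preset provides);
``intrauterine``
    the adjusted set + pre-pregnancy coffee consumption, isolating the
    during-pregnancy (intrauterine) exposure window.

The paternal exposure serves as a negative control: a prenatal mechanism
cannot act through the father, so a paternal association of similar
magnitude signals familial confounding rather than causation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RegressionResult", "PRESETS", "fit_observational", "fit_ols_term"]

PRESETS: dict[str, list[str]] = {
    "unadjusted": ["birth_year", "mat_age", "pat_age"],
    "adjusted": [
        "birth_year",
        "mat_age",
        "pat_age",
        "smoking_cigs_week",
        "alcohol_times_week",
        "education_years",
        "income_nok",
    ],
    "intrauterine": [
        "birth_year",
        "mat_age",
        "pat_age",
        "smoking_cigs_week",
        "alcohol_times_week",
        "education_years",
        "income_nok",
        "coffee_pre",
    ],
}


@dataclass(frozen=True)
class RegressionResult:
    term: str
    beta: float
    se: float
    p: float
    n: int
    preset: str
    outcome: str = ""


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(np.asarray(X, dtype=float))
    if rank < X.shape[1]:
        # identify offending columns by greedy elimination
        bad = []
        keep: list[str] = []
        for c in X.columns:
            trial = keep + [c]
            if np.linalg.matrix_rank(np.asarray(X[trial], dtype=float)) < len(trial):
                bad.append(c)
            else:
                keep.append(c)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")


def fit_ols_term(
    pheno: pd.DataFrame, outcome: str, term: str, covariates: list[str]
) -> tuple[float, float, float, int]:
    """OLS of ``outcome`` on ``term`` + ``covariates`` (complete cases).

    Returns (beta, se, p, n) for the term of interest.
    """
    cols = [outcome, term, *covariates]
    data = pheno[cols].dropna()
    X = sm.add_constant(data[[term, *covariates]])
    _check_full_rank(X)
    fit = sm.OLS(data[outcome], X).fit()
    return (
        float(fit.params[term]),
        float(fit.bse[term]),
        float(fit.pvalues[term]),
        int(fit.nobs),
    )


def fit_observational(
    pheno: pd.DataFrame,
    exposure_role: str,
    outcome: str,
    preset: str = "unadjusted",
    exposure_col: str | None = None,
    extra_covariates: list[str] | None = None,
) -> RegressionResult:
    """Exposure-outcome OLS under one of the covariate presets.

    ``exposure_role`` selects the maternal during-pregnancy report
    (``coffee_wk15``) or the paternal report (``coffee_f``); an explicit
    ``exposure_col`` overrides this. ``extra_covariates`` lets callers add
    arbitrary columns (e.g. a genotyping-batch one-hot or a measured
    confounder) to any preset.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    if exposure_role not in ("maternal", "paternal"):
        raise ValueError("exposure_role must be 'maternal' or 'paternal'")
    term = exposure_col or ("coffee_wk15" if exposure_role == "maternal" else "coffee_f")
    covs = [c for c in PRESETS[preset] if c != term]
    if extra_covariates:
        covs = covs + [c for c in extra_covariates if c not in covs and c != term]
    beta, se, p, n = fit_ols_term(pheno, outcome, term, covs)
    return RegressionResult(term, beta, se, p, n, preset, outcome)
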