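"""Association testing for quantitative traits and weight-status categories.

Linear models assume an additive per-allele effect; quantitative traits can
be analysed raw or after rank-based inverse-normal transformation.  Weight
classes are contrasted case-vs-control with logistic regression (Wald
inference, matching OR (95% CI) reporting).  Also houses the explained
variance of a biallelic locus, 2f(1−f)β², the BMI-to-body-weight effect
conversion, and Bonferroni threshold arithmetic.

Covariate presets mirror the two adjustment sets used for adiposity traits:
``bmi-set`` = age, age², sex, region and two principal components;
``dxa-set`` = age, age², sex (for the DXA fat-percentage traits, which exist
only for a cohort subset — complete-case handling is per model, so the
analysis n floats per trait).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                             PerfectSeparationWarning)

from .panel_io import CohortTable

__all__ = [
    "AssocResult",
    "OrResult",
    "covariate_design",
    "inverse_normal_transform",
    "linear_assoc",
    "logistic_assoc",
    "explained_variance",
    "bmi_effect_to_weight",
    "bonferroni_threshold",
]

#: indicator coding references, recorded in result metadata
SEX_CODING = "male=1 (reference female)"
REGION_CODING = "Shanghai=1 (reference Beijing)"

COVARIATE_PRESETS = {
    "bmi-set": ("age", "age_sq", "sex_male", "region_shanghai", "pc1", "pc2"),
    "dxa-set": ("age", "age_sq", "sex_male"),
}


@dataclass(frozen=True)
class AssocResult:
    """Per-allele linear-model effect for one predictor on one trait."""

    predictor: str
    trait: str
    beta: float
    se: float
    p: float
    n: int
    covariates: tuple[str, ...]
    transformed: bool = False


@dataclass(frozen=True)
class OrResult:
    """Logistic-model odds ratio for a weight-class contrast."""

    predictor: str
    contrast: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n_cases: int
    n_controls: int
    covariates: tuple[str, ...] = ()


def covariate_design(cohort: CohortTable, preset: str) -> pd.DataFrame:
    """Build the covariate columns for a named adjustment set.

    Age² is always derived internally from the age column; sex and region are
    0/1 indicators (see SEX_CODING / REGION_CODING).
    """
    if preset not in COVARIATE_PRESETS:
        raise ValueError(f"unknown covariate preset {preset!r}")
    d = cohort.data
    full = pd.DataFrame({
        "age": d["age"].astype(float),
        "age_sq": d["age"].astype(float) ** 2,
        "sex_male": (d["sex"] == "male").astype(float),
        "region_shanghai": (d["region"] == "Shanghai").astype(float),
        "pc1": d["pc1"].astype(float),
        "pc2": d["pc2"].astype(float),
    }, index=d.index)
    return full[list(COVARIATE_PRESETS[preset])]


def inverse_normal_transform(values: Sequence[float] | np.ndarray,
                             offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform to mean 0, SD 1.

    Non-missing values map to Φ⁻¹((rank − c)/(n − 2c + 1)) with the Blom
    offset c = 3/8 by default and average ranks for ties; NaN stays NaN.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.nanstd(x) == 0:
        raise ValueError("constant vector cannot be transformed")
    ranks = stats.rankdata(x[obs], method="average")
    out = np.full_like(x, np.nan)
    out[obs] = stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    return out


def _check_design(X: pd.DataFrame) -> None:
    """Raise naming the collinear columns if the design is rank-deficient."""
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # greedy scan: a column is collinear if it adds no rank
        collinear, kept = [], np.empty((arr.shape[0], 0))
        for j, name in enumerate(X.columns):
            cand = np.column_stack([kept, arr[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                collinear.append(name)
            else:
                kept = cand
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


def _complete_cases(*arrays: np.ndarray) -> np.ndarray:
    ok = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        ok &= ~np.isnan(np.asarray(a, dtype=float)).reshape(len(a), -1).any(axis=1)
    return ok


def linear_assoc(trait: Sequence[float], predictor: Sequence[float],
                 covariates: pd.DataFrame | None = None,
                 trait_name: str = "trait", predictor_name: str = "predictor",
                 transformed: bool = False) -> AssocResult:
    """OLS of trait on predictor plus covariates, with intercept.

    Rows with any missing value in trait, predictor or covariates are
    dropped (complete-case per model).
    """
    y = np.asarray(trait, dtype=float)
    g = np.asarray(predictor, dtype=float)
    if covariates is None:
        covariates = pd.DataFrame(index=pd.RangeIndex(len(y)))
    Z = covariates.to_numpy(dtype=float).reshape(len(y), -1)
    ok = _complete_cases(y, g, Z)
    n = int(ok.sum())
    k = 2 + Z.shape[1]
    if n < k + 2:
        raise ValueError(f"only {n} complete cases for {k}+ parameters")
    X = pd.DataFrame({"const": 1.0, predictor_name: g[ok]})
    for j, c in enumerate(covariates.columns):
        X[str(c)] = Z[ok, j]
    _check_design(X)
    fit = sm.OLS(y[ok], X).fit()
    return AssocResult(
        predictor=predictor_name, trait=trait_name,
        beta=float(fit.params[predictor_name]),
        se=float(fit.bse[predictor_name]),
        p=float(fit.pvalues[predictor_name]),
        n=n, covariates=tuple(str(c) for c in covariates.columns),
        transformed=transformed,
    )


def logistic_assoc(weight_class: Sequence[str], case_class: str,
                   control_class: str, predictor: Sequence[float],
                   covariates: pd.DataFrame | None = None,
                   predictor_name: str = "predictor") -> OrResult:
    """Logistic regression of case vs control weight class on a predictor.

    Fits by Newton IRLS (tolerance 1e-8, max 50 iterations); reports the
    per-allele odds ratio with Wald 95% CI and p-value.
    """
    wc = pd.Series(list(weight_class))
    g = np.asarray(predictor, dtype=float)
    if covariates is None:
        covariates = pd.DataFrame(index=pd.RangeIndex(len(g)))
    Z = covariates.to_numpy(dtype=float).reshape(len(g), -1)
    in_contrast = wc.isin([case_class, control_class]).to_numpy()
    ok = in_contrast & _complete_cases(g, Z)
    y = (wc[ok] == case_class).to_numpy(dtype=float)
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(f"empty class in contrast {case_class} vs {control_class}")
    X = pd.DataFrame({"const": 1.0, predictor_name: g[ok]})
    for j, c in enumerate(covariates.columns):
        X[str(c)] = Z[ok, j]
    _check_design(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=50,
                                     disp=False)
    except (PerfectSeparationWarning, PerfectSeparationError,
            np.linalg.LinAlgError) as exc:
        raise RuntimeError(
            f"separation in logistic fit for {predictor_name}: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise RuntimeError("logistic fit did not converge (possible separation)")
    beta = float(fit.params[predictor_name])
    se = float(fit.bse[predictor_name])
    if abs(beta) > 30 or not np.isfinite(se):
        raise RuntimeError(f"degenerate logistic fit for {predictor_name} "
                           f"(beta={beta:.3g}, se={se:.3g}); likely separation")
    z = stats.norm.ppf(0.975)
    return OrResult(
        predictor=predictor_name,
        contrast=f"{case_class} vs {control_class}",
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p=float(fit.pvalues[predictor_name]),
        n_cases=n_cases, n_controls=n_controls,
        covariates=tuple(str(c) for c in covariates.columns),
    )


def explained_variance(f: float, beta_std: float) -> float:
    """Trait variance explained by a biallelic locus: 2f(1−f)·β².

    β is the per-allele effect on the standardized trait; the formula is
    symmetric in f ↔ 1−f, so effect-allele and minor-allele frequency give
    the same value.  Returns a fraction (multiply by 100 for percent).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"allele frequency {f} outside [0, 1]")
    f = min(f, 1.0 - f)
    return 2.0 * f * (1.0 - f) * beta_std ** 2


def bmi_effect_to_weight(beta_bmi: float, height_m: float) -> float:
    """Per-allele BMI effect (kg/m²) as grams of body weight at a given height.

    weight change = β · height² kilograms, returned in grams (display code
    rounds to the nearest gram).
    """
    if height_m <= 0:
        raise ValueError("height must be positive")
    return beta_bmi * height_m ** 2 * 1000.0


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level alpha/m for m tests."""
    if m < 1:
        raise ValueError("m must be ≥ 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m
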