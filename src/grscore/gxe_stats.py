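"""Gene–environment interaction and cross-study consistency statistics.

Covers the score-by-physical-activity interaction model (one joint linear
fit with a score×PA product term, PA ordinal 0/1/2, plus per-stratum fits),
the attenuation of the per-allele effect across activity strata, exact
binomial sign tests of directional consistency against discovery-study
effect directions, and Cochran's Q for two-study effect heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association import AssocResult, _check_design, _complete_cases

__all__ = [
    "StratumEffect",
    "InteractionResult",
    "SignTestResult",
    "HeterogeneityResult",
    "fit_interaction",
    "attenuation_pct",
    "sign_binomial_test",
    "count_consistent",
    "cochran_q",
]

PA_STRATA = ("low", "moderate", "high")


class StratumEffect(NamedTuple):
    beta: float | None
    se: float | None
    p: float | None
    n: int


@dataclass(frozen=True)
class InteractionResult:
    """Joint score×PA interaction fit plus per-stratum main effects."""

    predictor: str
    trait: str
    beta_interaction: float
    se: float
    p: float
    n: int
    stratum: dict[str, StratumEffect]
    covariates: tuple[str, ...]
    # joint-model score main effect (the per-allele effect at PA level 0)
    beta_main: float = float("nan")
    se_main: float = float("nan")
    p_main: float = float("nan")

    @property
    def attenuation(self) -> float:
        """Percent reduction of the per-allele effect from low to high PA."""
        low, high = self.stratum["low"], self.stratum["high"]
        if low.beta is None or high.beta is None:
            raise ValueError("attenuation needs both low and high strata")
        return attenuation_pct(low.beta, high.beta)


class SignTestResult(NamedTuple):
    n_total: int
    n_consistent: int
    p_one_sided: float


class ConsistencyCount(NamedTuple):
    n_consistent: int
    n_total: int
    n_zero: int


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q for one effect measured in two studies."""

    rsid: str
    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    q_statistic: float
    df: int
    p: float
    i_squared: float  # supplementary: max(0, (Q−df)/Q)


def fit_interaction(trait: Sequence[float], score: Sequence[float],
                    pa_code: Sequence[int],
                    covariates: pd.DataFrame | None = None,
                    trait_name: str = "trait",
                    predictor_name: str = "GRS",
                    stratified: bool = True) -> InteractionResult:
    """Test effect modification of a risk score by physical activity.

    One joint OLS with terms score, PA (ordinal 0/1/2) and score×PA plus the
    covariates; ``beta_interaction`` is the product-term coefficient — the
    change in the per-allele effect per PA-category step.  Stratum-specific
    effects come from separate per-stratum fits with the same covariates.
    An absent PA level is marked in the stratified output; the joint fit
    still proceeds when at least two levels are present.
    """
    y = np.asarray(trait, dtype=float)
    g = np.asarray(score, dtype=float)
    pa = np.asarray(pa_code, dtype=float)
    if not np.isin(pa[~np.isnan(pa)], (0.0, 1.0, 2.0)).all():
        raise ValueError("pa_code must be ordinal 0/1/2")
    if covariates is None:
        covariates = pd.DataFrame(index=pd.RangeIndex(len(y)))
    Z = covariates.to_numpy(dtype=float).reshape(len(y), -1)
    ok = _complete_cases(y, g, pa, Z)
    n = int(ok.sum())
    X = pd.DataFrame({
        "const": 1.0,
        predictor_name: g[ok],
        "pa": pa[ok],
        "score_x_pa": g[ok] * pa[ok],
    })
    for j, c in enumerate(covariates.columns):
        X[str(c)] = Z[ok, j]
    _check_design(X)
    fit = sm.OLS(y[ok], X).fit()

    stratum: dict[str, StratumEffect] = {}
    for code, label in enumerate(PA_STRATA):
        mask = ok & (pa == code)
        n_s = int(mask.sum())
        if not stratified or n_s < Z.shape[1] + 4:
            stratum[label] = StratumEffect(None, None, None, n_s)
            continue
        Xs = pd.DataFrame({"const": 1.0, predictor_name: g[mask]})
        for j, c in enumerate(covariates.columns):
            col = Z[mask, j]
            if np.ptp(col) == 0:
                continue  # constant within stratum, absorbed by intercept
            Xs[str(c)] = col
        fs = sm.OLS(y[mask], Xs).fit()
        stratum[label] = StratumEffect(
            beta=float(fs.params[predictor_name]),
            se=float(fs.bse[predictor_name]),
            p=float(fs.pvalues[predictor_name]),
            n=n_s,
        )
    return InteractionResult(
        predictor=predictor_name, trait=trait_name,
        beta_interaction=float(fit.params["score_x_pa"]),
        se=float(fit.bse["score_x_pa"]),
        p=float(fit.pvalues["score_x_pa"]),
        n=n, stratum=stratum,
        covariates=tuple(str(c) for c in covariates.columns),
        beta_main=float(fit.params[predictor_name]),
        se_main=float(fit.bse[predictor_name]),
        p_main=float(fit.pvalues[predictor_name]),
    )


def attenuation_pct(beta_low: float, beta_high: float) -> float:
    """Percent reduction of the per-allele effect between exposure strata.

    100·(β_low − β_high)/β_low; an effect larger in the high stratum yields a
    negative value (aggravation).
    """
    if beta_low == 0:
        raise ValueError("attenuation undefined for a zero low-stratum effect")
    return 100.0 * (beta_low - beta_high) / beta_low


def sign_binomial_test(n_consistent: int, n_total: int) -> SignTestResult:
    """Exact one-sided binomial tail for directional consistency.

    p = Σ_{k=n_consistent}^{n_total} C(n_total, k)·(1/2)^{n_total}, evaluated
    in exact integer arithmetic.
    """
    if n_total < 1:
        raise ValueError("n_total must be ≥ 1")
    if not 0 <= n_consistent <= n_total:
        raise ValueError("n_consistent outside [0, n_total]")
    tail = sum(math.comb(n_total, k) for k in range(n_consistent, n_total + 1))
    p = tail / (1 << n_total)
    return SignTestResult(n_total=n_total, n_consistent=n_consistent,
                          p_one_sided=float(p))


def count_consistent(results: Sequence[AssocResult],
                     reference_directions: Mapping[str, int]) -> ConsistencyCount:
    """Count betas whose sign matches the discovery-study direction.

    ``reference_directions`` maps predictor name to ±1 (for effect alleles
    defined as BMI-increasing the expected direction is +1).  Betas of
    exactly zero count as inconsistent and are tallied separately.
    """
    n_consistent = n_zero = 0
    for r in results:
        if r.predictor not in reference_directions:
            raise ValueError(f"no reference direction for {r.predictor}")
        ref = reference_directions[r.predictor]
        if ref not in (-1, 1):
            raise ValueError(f"reference direction for {r.predictor} must be ±1")
        if r.beta == 0:
            n_zero += 1
        elif math.copysign(1, r.beta) == ref:
            n_consistent += 1
    return ConsistencyCount(n_consistent=n_consistent, n_total=len(results),
                            n_zero=n_zero)


def cochran_q(beta_a: float, se_a: float, beta_b: float, se_b: float,
              rsid: str = "") -> HeterogeneityResult:
    """Cochran's Q test of heterogeneity between two effect estimates.

    Fixed-effect inverse-variance weights w = 1/se²; Q = Σ w·(β − β_pooled)²
    on 1 df.  I² = max(0, (Q − df)/Q) is reported as a supplementary
    descriptive (an extension of the two-study Q).
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    w = np.array([1.0 / se_a ** 2, 1.0 / se_b ** 2])
    b = np.array([beta_a, beta_b])
    pooled = float((w * b).sum() / w.sum())
    q = float((w * (b - pooled) ** 2).sum())
    df = 1
    return HeterogeneityResult(
        rsid=rsid, beta_a=beta_a, se_a=se_a, beta_b=beta_b, se_b=se_b,
        q_statistic=q, df=df, p=float(stats.chi2.sf(q, df)),
        i_squared=float(max(0.0, (q - df) / q)) if q > 0 else 0.0,
    )
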