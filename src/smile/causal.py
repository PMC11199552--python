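"""Two-stage instrumental-variable causal inference for location-level
exposures (SMILE-2) and the fixed-effects comparator (IND-FE).

Stage 1 regresses location-level pollution on the wind instruments (speed
and direction in a circular-safe encoding) and keeps the fitted values
P~.  Stage 2 regresses disease status on P~ within the mixed model

    Y = P~ beta + X pi_2 + u_g + Z_par u_par + Z_child u_child + eps

(no spatial term: P~ is itself a location-level variable).  Because P~
depends only on wind, which is exogenous to the unmeasured location-level
confounders, beta is a consistent estimate of the causal exposure effect.
Note the stage-2 standard errors do not propagate first-stage uncertainty
(the usual generated-regressor caveat of plain two-stage least squares).

IND-FE is the comparator: ordinary least squares of Y on (P~, X) restricted
to the (genetically unrelated) parents, with fixed effects only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .pedigree import Cohort
from .simulate import encode_wind
from .vc_model import ModelSpec, SmileFit, fit_smile

#: exposures screened per trait (Bonferroni accounts for all three)
EXPOSURES = ("pm25", "no2", "psum")


class CausalError(ValueError):
    pass


class WeakInstrumentError(CausalError):
    pass


@dataclass
class FirstStageResult:
    fitted: pd.Series  # predicted exposure per location
    r_squared: float
    f_statistic: float
    coefficients: pd.Series


@dataclass
class CausalEstimate:
    beta: float
    se: float
    p_value: float
    odds_ratio: float
    method: str
    n: int
    first_stage_r2: float | None = None
    first_stage_f: float | None = None
    fit: SmileFit | None = None


def first_stage_predict(
    exposure: pd.Series, instruments: pd.DataFrame
) -> FirstStageResult:
    """Regress a location-level exposure on the encoded wind instruments.

    Returns fitted values (the predicted exposure P~) together with the
    first-stage R^2 and F statistic as instrument-strength diagnostics.
    """
    common = exposure.index.intersection(instruments.index)
    if len(common) < 10:
        raise CausalError(f"need >= 10 locations, have {len(common)}")
    y = exposure.loc[common].to_numpy(dtype=float)
    E = encode_wind(instruments.loc[common])
    if (E.std() < 1e-12).all():
        raise WeakInstrumentError("instruments have zero variance")
    X = sm.add_constant(E.to_numpy())
    res = sm.OLS(y, X).fit()
    if res.rsquared < 0.01:
        warnings.warn(
            f"weak instruments: first-stage R^2 = {res.rsquared:.4f}",
            stacklevel=2)
    fitted = pd.Series(res.fittedvalues, index=common, name="p_tilde")
    return FirstStageResult(
        fitted=fitted,
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        coefficients=pd.Series(res.params[1:], index=E.columns),
    )


def beta_to_odds_ratio(beta: float, K: float) -> float:
    """Convert an observed-scale (linear probability) effect per one SD of
    exposure into an odds ratio at trait prevalence K."""
    p1 = np.clip(K + beta, 1e-12, 1 - 1e-12)
    return float((p1 / (1 - p1)) / (K / (1 - K)))


def fit_smile2(
    cohort: Cohort,
    Y: np.ndarray,
    p_tilde: pd.Series,
    X: np.ndarray | None = None,
    components: str = "GPC",
    *,
    exposure_sd: float | None = None,
    first_stage: FirstStageResult | None = None,
    n_starts: int = 1,
) -> CausalEstimate:
    """Stage-2 mixed-model estimate of the causal exposure effect.

    ``p_tilde`` is the per-location predicted exposure in exposure units;
    it is mapped to individuals through their family location, centred,
    divided by ``exposure_sd`` (the spread of the *observed* exposure, so
    beta is the effect per one SD of exposure — the two-stage estimand;
    defaults to the spread of p_tilde across locations), and entered as the
    leading fixed effect of a G+P+C mixed model.  The Wald p-value uses the
    fixed-effect covariance at the variance-component optimum; the odds
    ratio converts the linear-scale beta at the observed trait prevalence.
    """
    Y = np.asarray(Y, dtype=float)
    p_ind = p_tilde.reindex(cohort.location_ids).to_numpy(dtype=float)
    if np.isnan(p_ind).any():
        raise CausalError("some cohort locations missing from p_tilde")
    sd = exposure_sd if exposure_sd is not None else p_ind.std()
    if sd < 1e-12 or p_ind.std() < 1e-12:
        raise CausalError("predicted exposure is constant across the cohort")
    p_std = (p_ind - p_ind.mean()) / sd
    if X is None:
        X = np.ones((len(Y), 1))
    Xfull = np.column_stack([p_std, X])
    spec = ModelSpec.from_name(components) if components else ModelSpec()
    fit = fit_smile(cohort, Y, Xfull, spec, n_starts=n_starts, compute_se=False)
    beta = float(fit.fixed_effects["estimate"].iloc[0])
    se = float(fit.fixed_effects["se"].iloc[0])
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    K = float(Y.mean())
    return CausalEstimate(
        beta=beta, se=se, p_value=max(p, np.finfo(float).tiny),
        odds_ratio=beta_to_odds_ratio(beta, K), method="SMILE-2", n=len(Y),
        first_stage_r2=first_stage.r_squared if first_stage else None,
        first_stage_f=first_stage.f_statistic if first_stage else None,
        fit=fit,
    )


def ind_fe_two_stage(
    cohort: Cohort,
    Y: np.ndarray,
    p_tilde: pd.Series,
    X: np.ndarray | None = None,
    *,
    exposure_sd: float | None = None,
    first_stage: FirstStageResult | None = None,
) -> CausalEstimate:
    """Fixed-effects-only comparator on the unrelated parents.

    OLS of Y on (P~, X) restricted to fathers and mothers; one parent pair
    per family means no genetic relatedness in the analysis subset.
    """
    Y = np.asarray(Y, dtype=float)
    mask = cohort.roles != "child"
    p_ind = p_tilde.reindex(cohort.location_ids).to_numpy(dtype=float)
    if np.isnan(p_ind).any():
        raise CausalError("some cohort locations missing from p_tilde")
    sd = exposure_sd if exposure_sd is not None else p_ind.std()
    if sd < 1e-12 or p_ind.std() < 1e-12:
        raise CausalError("predicted exposure is constant across the cohort")
    p_std = (p_ind - p_ind.mean()) / sd
    if X is None:
        X = np.ones((len(Y), 1))
    Xfull = np.column_stack([p_std, X])[mask]
    res = sm.OLS(Y[mask], Xfull).fit()
    beta = float(res.params[0])
    se = float(res.bse[0])
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    K = float(Y[mask].mean())
    return CausalEstimate(
        beta=beta, se=se, p_value=max(p, np.finfo(float).tiny),
        odds_ratio=beta_to_odds_ratio(beta, K), method="IND-FE",
        n=int(mask.sum()),
        first_stage_r2=first_stage.r_squared if first_stage else None,
        first_stage_f=first_stage.f_statistic if first_stage else None,
    )


def phenome_screen(
    results: pd.DataFrame,
    *,
    n_traits: int | None = None,
    n_exposures: int = 3,
    alpha: float = 0.05,
    min_prevalence: float = 0.001,
) -> pd.DataFrame:
    """Bonferroni screen over (trait, exposure) causal tests.

    ``results`` needs columns trait, exposure, p_value, prevalence (plus any
    estimate columns, which pass through).  Traits below the prevalence
    floor are excluded before testing and recorded with the reason; the
    significance threshold is alpha / (n_traits * n_exposures).
    """
    out = results.copy()
    if n_traits is None:
        n_traits = out["trait"].nunique()
    threshold = alpha / (n_traits * n_exposures)
    excluded = out["prevalence"] < min_prevalence
    out["excluded"] = excluded
    out["exclusion_reason"] = np.where(
        excluded, f"prevalence below {min_prevalence}", "")
    out["bonferroni_threshold"] = threshold
    out["significant"] = (~excluded) & (out["p_value"] < threshold)
    return out
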