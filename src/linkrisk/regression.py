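"""Mixed-effects regression of feasibility contribution on vulnerability.

The headline model is a linear mixed model with feasibility contribution
I as response, vulnerability V as the fixed effect, and a random intercept
per network, fitted by restricted maximum likelihood.  Variance explained
is summarised with the mixed-model R-squared decomposition:

    R2_marginal    = s2_f / (s2_f + s2_a + s2_e)
    R2_conditional = (s2_f + s2_a) / (s2_f + s2_a + s2_e)

where s2_f is the variance of the fixed-effect linear predictor, s2_a the
random-intercept variance and s2_e the residual variance.  The slope is
tested with a Wald chi-square on 1 df (squared slope/SE ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MixedModelResult:
    """Fitted slope, Wald test and variance decomposition of one LMM."""

    response: str
    predictor: str
    slope: float
    slope_se: float
    intercept: float
    wald_chi2: float
    df: int
    p: float
    r2_marginal: float
    r2_conditional: float
    var_fixed: float
    var_random_intercept: float
    var_residual: float
    n_obs: int
    n_groups: int
    converged: bool
    singular: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _fit_lmm(
    data: pd.DataFrame, response: str, predictor: str, group_col: str = "network_id"
) -> MixedModelResult:
    import statsmodels.formula.api as smf

    work = data[[response, predictor, group_col]].dropna()
    n_groups = work[group_col].nunique()
    if n_groups < 2:
        raise ValueError("need >= 2 networks for a random-intercept model")
    if np.ptp(work[response].to_numpy(dtype=float)) == 0:
        # zero-variance response: flagged degenerate result, not a crash
        return MixedModelResult(
            response=response, predictor=predictor, slope=0.0, slope_se=np.nan,
            intercept=float(work[response].iloc[0]), wald_chi2=np.nan, df=1, p=np.nan,
            r2_marginal=0.0, r2_conditional=0.0, var_fixed=0.0,
            var_random_intercept=0.0, var_residual=0.0,
            n_obs=len(work), n_groups=n_groups, converged=False, singular=True,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(f"{response} ~ {predictor}", work, groups=work[group_col])
        fit = model.fit(reml=True)
        slope = float(fit.fe_params[predictor])
        se = float(fit.bse_fe[predictor])
    var_alpha = float(np.asarray(fit.cov_re)[0, 0])
    var_eps = float(fit.scale)
    fixed_pred = fit.fe_params["Intercept"] + slope * work[predictor].to_numpy(dtype=float)
    var_f = float(np.var(fixed_pred, ddof=1))
    total = var_f + var_alpha + var_eps
    wald = (slope / se) ** 2 if se > 0 else np.inf
    return MixedModelResult(
        response=response,
        predictor=predictor,
        slope=slope,
        slope_se=se,
        intercept=float(fit.fe_params["Intercept"]),
        wald_chi2=float(wald),
        df=1,
        p=float(stats.chi2.sf(wald, df=1)),
        r2_marginal=var_f / total if total > 0 else 0.0,
        r2_conditional=(var_f + var_alpha) / total if total > 0 else 0.0,
        var_fixed=var_f,
        var_random_intercept=var_alpha,
        var_residual=var_eps,
        n_obs=len(work),
        n_groups=n_groups,
        converged=bool(fit.converged),
        singular=bool(var_alpha == 0),
    )


def fit_vulnerability_model(table: pd.DataFrame) -> MixedModelResult:
    """Feasibility contribution ~ vulnerability with a network random intercept.

    Excluded links (no feasibility contribution) are dropped before fitting.
    """
    work = table.loc[~table["excluded"]].copy()
    if work.empty:
        raise ValueError("no included links: all feasibility contributions missing")
    return _fit_lmm(work, response="I_percent", predictor="V")


def diagnostic_regressions(table: pd.DataFrame) -> dict[str, MixedModelResult]:
    """Companion fits separating the vulnerability ingredients.

    Mixed fits (network random intercept) of contribution on generalisation
    and on frequency, plus log10(generalisation) on log10(frequency), whose
    marginal R2 is the share of generalisation variance explained by
    frequency.
    """
    work = table.loc[~table["excluded"]].copy()
    work["log_generalisation"] = np.log10(work["D_raw"].astype(float))
    work["log_frequency"] = np.log10(work["weight"].astype(float))
    return {
        "contribution_vs_generalisation": _fit_lmm(work, "I_percent", "D_std"),
        "contribution_vs_frequency": _fit_lmm(work, "I_percent", "f_std"),
        "generalisation_vs_frequency": _fit_lmm(work, "log_generalisation", "log_frequency"),
    }
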