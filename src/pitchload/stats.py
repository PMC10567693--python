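"""Nested linear mixed models for window-series trends.

Three nested models are fitted per outcome by maximum likelihood:

* M1 - random intercept across participants, no fixed trend;
* M2 - M1 plus window number as a fixed predictor;
* M3 - M2 plus a participant-level random slope for window number
  (unstructured 2x2 random-effects covariance).

Adjacent models are compared with chi-square likelihood-ratio tests at
alpha = 0.05; when a step is significant the smaller-AIC model of the pair
is adopted.  Because variance components sit on the boundary under the null,
a 50:50 chi-square mixture p-value is reported alongside the naive one as a
diagnostic.

Fixed-effect CIs are Wald intervals on a t reference with
``df = n_obs - n_groups - n_fixed``; random-effect SD CIs are Wald intervals
on the log-SD scale via the delta method (the method used is recorded in the
result).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

MODEL_IDS = ("M1", "M2", "M3")
_SINGULAR_TOL = 1e-8


class StatsError(ValueError):
    pass


@dataclass
class RandomEffectSD:
    sd: float
    ci: tuple[float, float]
    method: str = "wald-log"


@dataclass
class MixedModelResult:
    model_id: str
    outcome: str
    beta: float  # fixed window-number slope (nan for M1)
    beta_se: float
    ci: tuple[float, float]
    t_value: float
    p_value: float
    intercept: float
    random_intercept_sd: RandomEffectSD
    random_slope_sd: RandomEffectSD | None
    intercept_slope_corr: float
    residual_sd: float
    loglik: float
    k_params: int
    aic: float
    n_obs: int
    n_groups: int
    converged: bool
    singular: bool
    df_resid: float

    def __post_init__(self) -> None:
        if np.isfinite(self.beta) and not (
            self.ci[0] <= self.beta <= self.ci[1]
        ):
            raise StatsError("CI does not bracket the estimate")
        if not np.isclose(self.aic, 2 * self.k_params - 2 * self.loglik):
            raise StatsError("AIC identity violated")


def _n_params(model_id: str) -> int:
    # fixed effects + random-effect (co)variances + residual variance
    return {"M1": 1 + 1 + 1, "M2": 2 + 1 + 1, "M3": 2 + 3 + 1}[model_id]


def fit_lmm(
    data: pd.DataFrame,
    model_id: str,
    outcome: str = "y",
    centre_window: bool = False,
) -> MixedModelResult:
    """ML fit of one of the three nested models on a window series.

    ``data`` must have columns ``participant``, ``window_number`` and ``y``.
    Window number enters uncentred (1-based) unless ``centre_window``.
    """
    if model_id not in MODEL_IDS:
        raise StatsError(f"unknown model {model_id!r}; expected one of {MODEL_IDS}")
    for col in ("participant", "window_number", "y"):
        if col not in data.columns:
            raise StatsError(f"data missing column {col!r}")
    data = data.dropna(subset=["y"]).copy()
    groups = data["participant"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise StatsError("at least 2 participants are required for random effects")
    y = data["y"].to_numpy(dtype=float)
    w = data["window_number"].to_numpy(dtype=float)
    if centre_window:
        w = w - w.mean()
    n = y.size

    # internal rescaling of the predictor: the raw window number makes the
    # random intercept/slope variances differ by orders of magnitude and
    # stalls the optimizer; estimates are transformed back exactly below
    w_scale = max(1.0, float(np.std(w)))
    ws = w / w_scale

    if model_id == "M1":
        exog = np.ones((n, 1))
    else:
        exog = np.column_stack([np.ones(n), ws])
    if model_id == "M3":
        exog_re = np.column_stack([np.ones(n), ws])
    else:
        exog_re = np.ones((n, 1))

    model = MixedLM(y, exog, groups=groups, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=2000)
        except Exception:
            res = model.fit(reml=False, method="powell", maxiter=5000)
        if not res.converged:
            res = model.fit(reml=False, method="cg", maxiter=5000)

    k = _n_params(model_id)
    loglik = float(res.llf)
    aic = 2 * k - 2 * loglik
    n_groups = int(len(np.unique(groups)))
    n_fixed = exog.shape[1]
    df_resid = max(n - n_groups - n_fixed, 1)

    fe = np.asarray(res.fe_params, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fe_se = np.asarray(res.bse_fe, dtype=float)
    intercept = float(fe[0])
    if model_id == "M1":
        beta = beta_se = t_value = p_value = np.nan
        ci = (np.nan, np.nan)
    else:
        beta = float(fe[1]) / w_scale
        beta_se = float(fe_se[1]) / w_scale
        t_value = beta / beta_se if beta_se > 0 else np.nan
        tcrit = sps.t.ppf(0.975, df_resid)
        ci = (beta - tcrit * beta_se, beta + tcrit * beta_se)
        p_value = float(2 * sps.t.sf(abs(t_value), df_resid))

    cov_re = np.atleast_2d(np.asarray(res.cov_re, dtype=float)).copy()
    if cov_re.shape[0] == 2:  # undo the predictor rescaling
        cov_re[0, 1] /= w_scale
        cov_re[1, 0] /= w_scale
        cov_re[1, 1] /= w_scale**2
    scale = float(res.scale)
    var_int = float(cov_re[0, 0])
    singular = False

    # SEs of the random-effect covariance entries in data units
    # (delta method below converts variance SEs to SD CIs)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bse_re = np.asarray(res.bse_re, dtype=float)
    except Exception:  # pragma: no cover - backend failure fallback
        bse_re = np.full(cov_re.size, np.nan)

    def _sd_ci(var: float, var_se: float) -> RandomEffectSD:
        sd = float(np.sqrt(max(var, 0.0)))
        if sd <= _SINGULAR_TOL or not np.isfinite(var_se) or var_se <= 0:
            return RandomEffectSD(sd, (np.nan, np.nan))
        sd_se = var_se / (2 * sd)
        factor = float(np.exp(min(1.959963984540054 * sd_se / sd, 500.0)))
        return RandomEffectSD(sd, (sd / factor, sd * factor))

    # boundary detection relative to the residual variance (the optimizer
    # rarely lands exactly on zero); evaluated on the rescaled predictor so
    # intercept and slope components are comparable
    rel_tol = 1e-2
    ri_sd = _sd_ci(var_int, float(bse_re[0]) if bse_re.size else np.nan)
    if var_int <= _SINGULAR_TOL or var_int / scale < rel_tol:
        singular = True

    rs_sd: RandomEffectSD | None = None
    corr = np.nan
    if model_id == "M3":
        var_slope = float(cov_re[1, 1])
        # statsmodels orders cov params (v00, c10, v11) for a 2x2 cov_re
        se_slope = (
            float(bse_re[2]) / w_scale**2 if bse_re.size >= 3 else np.nan
        )
        rs_sd = _sd_ci(var_slope, se_slope)
        if var_slope <= _SINGULAR_TOL or var_slope * w_scale**2 / scale < rel_tol:
            singular = True
        denom = np.sqrt(max(var_int, 0.0) * max(var_slope, 0.0))
        corr = float(cov_re[0, 1] / denom) if denom > _SINGULAR_TOL else np.nan

    return MixedModelResult(
        model_id=model_id,
        outcome=outcome,
        beta=beta,
        beta_se=beta_se,
        ci=ci,
        t_value=t_value,
        p_value=p_value,
        intercept=intercept,
        random_intercept_sd=ri_sd,
        random_slope_sd=rs_sd,
        intercept_slope_corr=corr,
        residual_sd=float(np.sqrt(scale)),
        loglik=loglik,
        k_params=k,
        aic=aic,
        n_obs=int(n),
        n_groups=n_groups,
        converged=bool(res.converged),
        singular=singular,
        df_resid=float(df_resid),
    )


def fit_ladder(
    data: pd.DataFrame, outcome: str = "y", centre_window: bool = False
) -> dict[str, MixedModelResult]:
    return {
        mid: fit_lmm(data, mid, outcome=outcome, centre_window=centre_window)
        for mid in MODEL_IDS
    }


@dataclass
class LrtStep:
    smaller: str
    larger: str
    statistic: float
    df: int
    p_value: float
    p_value_mixture: float  # 50:50 chi-square mixture (boundary diagnostic)
    significant: bool


@dataclass
class ComparisonVerdict:
    steps: list[LrtStep]
    selected: str
    trace: list[str] = field(default_factory=list)


def _lrt(
    small: MixedModelResult, large: MixedModelResult, alpha: float
) -> LrtStep:
    if small.n_obs != large.n_obs:
        raise StatsError("models fitted on different numbers of observations")
    stat = max(0.0, 2.0 * (large.loglik - small.loglik))
    df = large.k_params - small.k_params
    if df <= 0:
        raise StatsError("models are not nested in the expected order")
    p = float(sps.chi2.sf(stat, df))
    # boundary mixture: 0.5 * chi2(df-1) + 0.5 * chi2(df); chi2(0) is a
    # point mass at zero
    if df == 1:
        p_mix = float(0.5 * (stat <= 0) + 0.5 * sps.chi2.sf(stat, 1))
    else:
        p_mix = float(
            0.5 * sps.chi2.sf(stat, df - 1) + 0.5 * sps.chi2.sf(stat, df)
        )
    return LrtStep(
        smaller=small.model_id,
        larger=large.model_id,
        statistic=stat,
        df=df,
        p_value=p,
        p_value_mixture=p_mix,
        significant=p < alpha,
    )


def compare_models(
    m1: MixedModelResult,
    m2: MixedModelResult,
    m3: MixedModelResult,
    alpha: float = 0.05,
) -> ComparisonVerdict:
    """Stepwise M1 -> M2 -> M3 selection by LRT then AIC.

    At each step, if the likelihood-ratio test is significant at ``alpha``
    the smaller-AIC model of the pair is adopted; otherwise the current
    model is retained.
    """
    fits = {"M1": m1, "M2": m2, "M3": m3}
    for mid, fit in fits.items():
        if fit.model_id != mid:
            raise StatsError(f"expected {mid}, got {fit.model_id}")
    if len({f.outcome for f in fits.values()}) != 1:
        raise StatsError("models fitted on different outcomes")

    steps = [_lrt(m1, m2, alpha), _lrt(m2, m3, alpha)]
    selected = "M1"
    trace = []
    for step in steps:
        current = fits[selected]
        challenger = fits[step.larger]
        if step.significant:
            pick = min((current, challenger), key=lambda f: f.aic)
            trace.append(
                f"{step.smaller} vs {step.larger}: LRT={step.statistic:.3f} "
                f"(df={step.df}, p={step.p_value:.4g}) significant; "
                f"AIC {current.model_id}={current.aic:.2f} vs "
                f"{challenger.model_id}={challenger.aic:.2f} -> {pick.model_id}"
            )
            selected = pick.model_id
        else:
            trace.append(
                f"{step.smaller} vs {step.larger}: LRT={step.statistic:.3f} "
                f"(df={step.df}, p={step.p_value:.4g}) not significant; "
                f"keep {selected}"
            )
    return ComparisonVerdict(steps=steps, selected=selected, trace=trace)


def report(
    results: dict[str, tuple[dict[str, MixedModelResult], ComparisonVerdict]],
) -> pd.DataFrame:
    """One row per outcome: fixed slope, CI, t, p, selected model, random SDs.

    ``results`` maps outcome name to (ladder fits, comparison verdict);
    the reported coefficients come from the selected model (M1 rows carry
    the M2 slope as a descriptive fallback would be misleading, so they are
    NaN).
    """
    rows = []
    for outcome, (fits, verdict) in results.items():
        sel = fits[verdict.selected]
        rs = sel.random_slope_sd
        rows.append(
            {
                "outcome": outcome,
                "selected_model": verdict.selected,
                "beta": sel.beta,
                "ci_lower": sel.ci[0],
                "ci_upper": sel.ci[1],
                "t": sel.t_value,
                "p": sel.p_value,
                "random_intercept_sd": sel.random_intercept_sd.sd,
                "ri_sd_ci_lower": sel.random_intercept_sd.ci[0],
                "ri_sd_ci_upper": sel.random_intercept_sd.ci[1],
                "random_slope_sd": rs.sd if rs else np.nan,
                "rs_sd_ci_lower": rs.ci[0] if rs else np.nan,
                "rs_sd_ci_upper": rs.ci[1] if rs else np.nan,
                "intercept_slope_corr": sel.intercept_slope_corr,
                "loglik": sel.loglik,
                "aic": sel.aic,
                "n_obs": sel.n_obs,
                "n_groups": sel.n_groups,
                "singular": sel.singular,
                "sd_ci_method": sel.random_intercept_sd.method,
            }
        )
    return pd.DataFrame(rows)


def participant_lines(
    fit: MixedModelResult, data: pd.DataFrame
) -> pd.DataFrame:
    """Per-participant fitted intercept/slope lines for spaghetti plots.

    Refits the model to obtain BLUPs; returns columns
    ``participant, intercept, slope``.
    """
    w = data["window_number"].to_numpy(dtype=float)
    w_scale = max(1.0, float(np.std(w)))
    exog = np.column_stack([np.ones(len(data)), w / w_scale])
    exog_re = exog if fit.model_id == "M3" else exog[:, :1]
    model = MixedLM(
        data["y"].to_numpy(dtype=float),
        exog,
        groups=data["participant"].to_numpy(),
        exog_re=exog_re,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False, method="lbfgs", maxiter=2000)
    fe = np.asarray(res.fe_params, dtype=float)
    rows = []
    for participant, re in res.random_effects.items():
        re = np.asarray(re, dtype=float)
        slope_dev = re[1] if re.size > 1 else 0.0
        rows.append(
            {
                "participant": participant,
                "intercept": float(fe[0] + re[0]),
                "slope": float((fe[1] if fe.size > 1 else 0.0) + slope_dev)
                / w_scale,
            }
        )
    return pd.DataFrame(rows)
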