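"""Regression stages: crossed random-intercept mixed models for individual
investment interest, and video-level OLS for funding amounts.

The mixed model is

    interest_{s,v} = beta0 + x_{s,v}' beta + u_s + w_v + eps_{s,v}

with independent random intercepts for subjects (u_s) and videos (w_v).
Continuous predictors are z-scored within the estimation sample before the
fit (binary predictors stay 0/1), so coefficients are reported on a
standardized scale. Fits intended for likelihood-ratio comparison use ML
rather than REML. Estimation is delegated to statsmodels' MixedLM via
variance components; this module owns the model specification,
standardization, AIC bookkeeping and comparison logic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


def standardize(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """z-score the named columns; binary 0/1 columns are left untouched."""
    out = df.copy()
    for c in columns:
        vals = out[c].astype(float)
        uniq = set(vals.dropna().unique())
        if uniq == {0.0, 1.0}:
            continue
        sd = vals.std(ddof=0)
        if sd == 0:
            raise ValueError(f"predictor {c!r} is constant; cannot standardize")
        out[c] = (vals - vals.mean()) / sd
    return out


@dataclass
class LMMFit:
    """Summary of a fitted crossed random-intercept mixed model."""

    fixed_names: list[str]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    subject_var: float
    video_var: float
    resid_var: float
    llf: float
    aic: float
    n_obs: int
    k_params: int
    reml: bool


class InvestmentInterestModel:
    """Mixed model for per-subject-per-video investment interest.

    Parameters
    ----------
    data : DataFrame
        Long format, one row per subject x video, with ``subject_id``,
        ``video_id``, the response column and the fixed-effect predictors.
    fixed : list of str
        Fixed-effect predictor columns (standardized before fitting).
    response : str
        Response column, default ``"interest"``.
    """

    def __init__(self, data: pd.DataFrame, fixed: list[str],
                 response: str = "interest"):
        need = {"subject_id", "video_id", response, *fixed}
        missing = need - set(data.columns)
        if missing:
            raise ValueError(f"data lacks columns: {sorted(missing)}")
        if data["subject_id"].nunique() < 2 or data["video_id"].nunique() < 2:
            raise ValueError("need at least 2 subjects and 2 videos")
        self.data = standardize(data.dropna(subset=sorted(need)).copy(), fixed)
        self.fixed = list(fixed)
        self.response = response
        x = sm.add_constant(self.data[fixed].astype(float)) if fixed else None
        if fixed and np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
            raise ValueError("fixed-effect design matrix is rank deficient")

    def fit(self, reml: bool = False) -> "InterestLMMResults":
        """Fit by ML (default, LRT-comparable) or REML."""
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        vc = {"subject": "0 + C(subject_id)", "video": "0 + C(video_id)"}
        self.data["_group"] = 1
        model = smf.mixedlm(f"{self.response} ~ {rhs}", data=self.data,
                            groups="_group", vc_formula=vc, re_formula="0")
        res = model.fit(reml=reml, method=["lbfgs", "cg"], maxiter=500)
        fe = res.fe_params
        k = len(fe) + len(res.vcomp) + 1  # fixed effects + 2 variances + residual
        aic = 2 * k - 2 * res.llf
        vcomp = pd.Series(res.vcomp, index=model.exog_vc.names)
        fit = LMMFit(
            fixed_names=list(fe.index),
            params=fe,
            bse=res.bse_fe,
            tvalues=fe / res.bse_fe,
            pvalues=pd.Series(
                2 * stats.norm.sf(np.abs(fe / res.bse_fe)), index=fe.index
            ),
            subject_var=float(vcomp.get("subject", np.nan)),
            video_var=float(vcomp.get("video", np.nan)),
            resid_var=float(res.scale),
            llf=float(res.llf),
            aic=float(aic),
            n_obs=int(res.nobs),
            k_params=k,
            reml=reml,
        )
        return InterestLMMResults(self, fit, res)


class InterestLMMResults:
    """Fitted mixed model: standardized coefficients, variances, AIC, LRT."""

    def __init__(self, model: InvestmentInterestModel, fit: LMMFit, sm_results):
        self.model = model
        self.fit = fit
        self._sm = sm_results

    # convenience passthroughs
    @property
    def params(self) -> pd.Series:
        return self.fit.params

    @property
    def bse(self) -> pd.Series:
        return self.fit.bse

    @property
    def pvalues(self) -> pd.Series:
        return self.fit.pvalues

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def llf(self) -> float:
        return self.fit.llf

    def compare_lrt(self, nested: "InterestLMMResults") -> tuple[float, int, float]:
        """Likelihood-ratio test of this (full) model against a nested one.

        Both fits must be ML on the same rows with nested fixed effects.
        Returns ``(chi2, df, p)``.
        """
        return compare_lrt(nested, self)

    def summary(self) -> str:
        f = self.fit
        lines = [
            f"Mixed model: {self.model.response} ~ "
            f"{' + '.join(self.model.fixed) or '1'} "
            f"+ (1|subject) + (1|video)   [{'REML' if f.reml else 'ML'}]",
            f"  n = {f.n_obs}, logLik = {f.llf:.2f}, AIC = {f.aic:.2f}",
            "  fixed effects (standardized):",
        ]
        for name in f.fixed_names:
            lines.append(
                f"    {name:<20s} beta = {f.params[name]: .3f} "
                f"(SE {f.bse[name]:.3f}), t = {f.tvalues[name]: .2f}, "
                f"p = {f.pvalues[name]:.3f}"
            )
        lines.append(
            f"  random intercept variances: subject = {f.subject_var:.3f}, "
            f"video = {f.video_var:.3f}, residual = {f.resid_var:.3f}"
        )
        return "\n".join(lines)


def fit_interest_lmm(data: pd.DataFrame, fixed: list[str],
                     response: str = "interest",
                     reml: bool = False) -> InterestLMMResults:
    """Functional wrapper around :class:`InvestmentInterestModel`."""
    return InvestmentInterestModel(data, fixed, response).fit(reml=reml)


def compare_lrt(nested: InterestLMMResults, full: InterestLMMResults
                ) -> tuple[float, int, float]:
    """Likelihood-ratio test between two nested ML mixed-model fits."""
    if nested.fit.reml or full.fit.reml:
        raise ValueError("LRT requires both fits to use ML, not REML")
    if nested.fit.n_obs != full.fit.n_obs:
        raise ValueError("LRT requires identical response rows")
    if not set(nested.model.fixed) <= set(full.model.fixed):
        raise ValueError("models are not nested (fixed effects differ)")
    df = full.fit.k_params - nested.fit.k_params
    chi2 = max(2.0 * (full.llf - nested.llf), 0.0)
    if df == 0:
        return chi2, 0, 1.0
    return chi2, df, float(stats.chi2.sf(chi2, df))


class FundingAmountModel:
    """Video-level OLS of funding amounts on standardized predictors.

    With n = videos this is deliberately small-n regression; it reports
    standardized coefficients with SE/t/p, AIC, and adjusted R^2. Unfunded
    videos enter with amount 0 by default (``funded_only`` drops them).
    """

    def __init__(self, video_table: pd.DataFrame, predictors: list[str],
                 response: str = "amount", funded_only: bool = False):
        df = video_table.copy()
        if funded_only:
            df = df[df["deal"] == 1]
        if len(df) < 5:
            raise ValueError(f"need at least 5 videos, got {len(df)}")
        if len(df) <= len(predictors) + 1:
            raise ValueError("too few videos for the number of predictors")
        self.data = standardize(df, predictors)
        self.predictors = list(predictors)
        self.response = response

    def fit(self) -> "FundingAmountResults":
        y = self.data[self.response].astype(float)
        x = sm.add_constant(self.data[self.predictors].astype(float))
        res = sm.OLS(y, x).fit()
        return FundingAmountResults(self, res)


class FundingAmountResults:
    """OLS results with a compact coefficient table."""

    def __init__(self, model: FundingAmountModel, sm_results):
        self.model = model
        self._sm = sm_results

    @property
    def params(self) -> pd.Series:
        return self._sm.params

    @property
    def bse(self) -> pd.Series:
        return self._sm.bse

    @property
    def pvalues(self) -> pd.Series:
        return self._sm.pvalues

    @property
    def aic(self) -> float:
        return float(self._sm.aic)

    @property
    def rsquared_adj(self) -> float:
        return float(self._sm.rsquared_adj)

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beta": self._sm.params, "se": self._sm.bse,
            "t": self._sm.tvalues, "p": self._sm.pvalues,
        })

    def summary(self) -> str:
        lines = [
            f"OLS: {self.model.response} ~ {' + '.join(self.model.predictors)} "
            f"(n = {int(self._sm.nobs)} videos)",
            f"  AIC = {self.aic:.2f}, adj. R^2 = {self.rsquared_adj:.3f}",
        ]
        for name, row in self.table.iterrows():
            lines.append(
                f"    {name:<20s} beta = {row['beta']: .3f} (SE {row['se']:.3f}), "
                f"t = {row['t']: .2f}, p = {row['p']:.3f}"
            )
        return "\n".join(lines)


def fit_amount_regression(video_table: pd.DataFrame, predictors: list[str],
                          response: str = "amount",
                          funded_only: bool = False) -> FundingAmountResults:
    """Functional wrapper around :class:`FundingAmountModel`."""
    return FundingAmountModel(video_table, predictors, response, funded_only).fit()
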