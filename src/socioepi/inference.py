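"""Linking analyses: three-step mediation and the meet-in-the-middle screen.

Mediation follows the classic three-step (Baron–Kenny) procedure on mixed
models: (1) exposure -> outcome, (2) exposure -> mediator and mediator ->
outcome, and — only if every step's percentile-bootstrap CI excludes zero —
(3) the outcome model refit with the mediator added.  Mediation is declared
when adding the mediator attenuates the exposure coefficient by more than
10%.  Attenuation is computed on the standardized-exposure scale, which makes
it invariant to rescaling the exposure.

The meet-in-the-middle screen looks for CpG sites associated with both the
downstream stress phenotype (from the EWAS) and an upstream maternal-care or
maternal-rank variable, requiring opposite signs: care that is protective
against a high-stress phenotype should relate to methylation in the opposite
direction from the stress hormone.  Care/rank associations use count GLMs
with methylated reads as the outcome and log(total reads) as an offset
(Poisson, switching to negative binomial when overdispersion is detected).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .stats import BootstrapCI, DegenerateInputError, fit_lmm, percentile_bootstrap_ci

logger = logging.getLogger(__name__)

__all__ = [
    "MediationStep",
    "MediationResult",
    "CountModelFit",
    "mediation_analysis",
    "fit_count_model",
    "detect_overdispersion",
    "is_mitm_hit",
    "mitm_screen",
]


@dataclass
class MediationStep:
    name: str
    beta: float
    ci: BootstrapCI
    passed: bool


@dataclass
class MediationResult:
    exposure: str
    step1: MediationStep
    step2a: MediationStep
    step2b: MediationStep
    step3_run: bool
    beta_adjusted: float | None = None
    attenuation_percent: float | None = None
    mediation_flag: bool = False

    def summary(self) -> dict:
        out = {
            "exposure": self.exposure,
            "step1": _step_dict(self.step1),
            "step2a": _step_dict(self.step2a),
            "step2b": _step_dict(self.step2b),
            "step3_run": self.step3_run,
        }
        if self.step3_run:
            out.update(beta_adjusted=self.beta_adjusted,
                       attenuation_percent=self.attenuation_percent,
                       mediation_flag=self.mediation_flag)
        else:
            out["stopped_after"] = ("step1" if not self.step1.passed else "step2")
        return out


def _step_dict(s: MediationStep) -> dict:
    return {"beta": s.beta, "ci": [s.ci.lower, s.ci.upper], "passed": s.passed}


def mediation_analysis(
    data: pd.DataFrame,
    exposure: str,
    mediator: str,
    outcome: str,
    id_col: str = "individual_id",
    mediator_group_col: str | None = None,
    covariates: list[str] | None = None,
    mediator_covariates: list[str] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    attenuation_threshold: float = 10.0,
) -> MediationResult:
    """Three-step mediation on the complete-case subsample.

    ``data`` is long over repeated outcome measurements; the exposure and
    mediator are constant within individual.  Step passes require the
    percentile bootstrap CI (cluster-resampled on the model's own grouping
    unit) to exclude zero.  The exposure is standardized, so the attenuation
    percentage is scale-invariant.
    """
    covariates = covariates or []
    mediator_covariates = mediator_covariates or []
    need = [exposure, mediator, outcome, id_col] + covariates + mediator_covariates
    df = data.dropna(subset=need).copy()
    if df[mediator].nunique() < 2:
        raise DegenerateInputError("mediator is constant; mediation not assessable")
    if df[exposure].nunique() < 2:
        raise DegenerateInputError("exposure is constant")
    # standardize exposure on the per-individual scale
    per_ind = df.drop_duplicates(id_col)
    mu, sd = per_ind[exposure].mean(), per_ind[exposure].std(ddof=1)
    df["_xz"] = (df[exposure] - mu) / sd
    mediator_group = mediator_group_col or id_col
    rng = np.random.default_rng(seed)

    def _one(df_, out_col, terms, group, focal):
        fit = fit_lmm(df_, out_col, terms, group)
        cis = percentile_bootstrap_ci(df_, out_col, terms, group,
                                      n_boot=n_boot, seed=rng)
        ci = cis[focal]
        return fit.coef(focal), ci

    b1, ci1 = _one(df, outcome, ["_xz"] + covariates, id_col, "_xz")
    step1 = MediationStep("exposure->outcome", b1, ci1, ci1.excludes_zero())

    med_df = df.drop_duplicates(id_col)
    b2a, ci2a = _one(med_df, mediator, ["_xz"] + mediator_covariates,
                     mediator_group, "_xz")
    step2a = MediationStep("exposure->mediator", b2a, ci2a, ci2a.excludes_zero())

    b2b, ci2b = _one(df, outcome, [mediator] + covariates, id_col, mediator)
    step2b = MediationStep("mediator->outcome", b2b, ci2b, ci2b.excludes_zero())

    if not (step1.passed and step2a.passed and step2b.passed):
        return MediationResult(exposure, step1, step2a, step2b, step3_run=False)

    fit3 = fit_lmm(df, outcome, ["_xz", mediator] + covariates, id_col)
    b_adj = fit3.coef("_xz")
    atten = 100.0 * (abs(b1) - abs(b_adj)) / abs(b1)
    return MediationResult(
        exposure, step1, step2a, step2b, step3_run=True,
        beta_adjusted=b_adj, attenuation_percent=atten,
        mediation_flag=bool(atten > attenuation_threshold),
    )


# --------------------------------------------------------------------------
# count models for the meet-in-the-middle screen


@dataclass
class CountModelFit:
    beta: float
    se: float
    p: float
    family: str  # 'poisson' or 'negative_binomial'
    converged: bool = True


def detect_overdispersion(pearson_chi2: float, df_resid: int, alpha: float = 0.05) -> bool:
    """Overdispersion flag: Pearson chi-square exceeds the upper ``alpha``
    tail of its chi-square reference (strict exceedance)."""
    if df_resid <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    return bool(pearson_chi2 > sps.chi2.ppf(1.0 - alpha, df_resid))


def fit_count_model(
    methylated: np.ndarray,
    totals: np.ndarray,
    exposure: np.ndarray,
    age: np.ndarray,
    family: str = "auto",
) -> CountModelFit:
    """Count GLM: methylated reads ~ exposure + age, offset log(total reads).

    With ``family='auto'`` a Poisson model is fit first; if its Pearson
    dispersion triggers the overdispersion test, a negative binomial model is
    fit instead.  ``family='poisson'`` pins the Poisson fit.  Returns Wald
    (beta, se, p) for the exposure slope and the family used.
    """
    y = np.asarray(methylated, dtype=float)
    n = np.asarray(totals, dtype=float)
    if np.any(n <= 0):
        raise ValueError("totals must be > 0 for the offset")
    X = np.column_stack([np.ones_like(y), np.asarray(exposure, float),
                         np.asarray(age, float)])
    offset = np.log(n)
    pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    over = (family == "auto"
            and detect_overdispersion(float(pois.pearson_chi2), int(pois.df_resid)))
    if not over:
        return CountModelFit(beta=float(pois.params[1]), se=float(pois.bse[1]),
                             p=float(pois.pvalues[1]), family="poisson")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nb = sm.NegativeBinomial(y, X, offset=offset).fit(disp=0, maxiter=200)
        return CountModelFit(beta=float(nb.params[1]), se=float(nb.bse[1]),
                             p=float(nb.pvalues[1]), family="negative_binomial",
                             converged=bool(nb.mle_retvals.get("converged", True)))
    except Exception as exc:  # non-convergence: flagged record, Poisson values
        logger.warning("negative binomial fit failed (%s); flagging record", exc)
        return CountModelFit(beta=float(pois.params[1]), se=float(pois.bse[1]),
                             p=float(pois.pvalues[1]), family="negative_binomial",
                             converged=False)


def is_mitm_hit(beta_care: float, p_care: float, beta_fgcm: float,
                p_cut: float = 0.1) -> bool:
    """Meet-in-the-middle decision: nominally significant care/rank
    association (p < p_cut) with sign opposite to the fGCM association."""
    opposite = np.sign(beta_care) != np.sign(beta_fgcm) and beta_care != 0
    return bool(p_care < p_cut and opposite)


def mitm_screen(
    dms_table: pd.DataFrame,
    counts,
    care_table: pd.DataFrame,
    care_vars: list[str] = ("prop_close_proximity", "prop_nursing",
                            "prop_grooming", "maternal_rank"),
    age_col: str = "age_at_darting_months",
    p_cut: float = 0.1,
) -> pd.DataFrame:
    """Screen stress-associated DMSs against maternal care/rank variables.

    For each DMS (rows of ``dms_table`` with ``site_id`` and the fGCM-model
    ``beta_corrected`` sign) and each care variable, fit the offset count
    model and flag hits where p < ``p_cut`` with opposite sign.  Individuals
    are the intersection of the count matrix and ``care_table`` (indexed by
    ``individual_id``) with nonmissing values.
    """
    if dms_table.empty:
        return pd.DataFrame(columns=["site_id", "care_var", "beta_care", "se_care",
                                     "p_care", "family", "beta_fgcm",
                                     "opposite_sign", "is_hit"])
    care = care_table.set_index("individual_id") if "individual_id" in care_table else care_table
    site_ids = counts.site_ids().tolist()
    rows = []
    for _, dms in dms_table.iterrows():
        try:
            si = site_ids.index(dms["site_id"])
        except ValueError:
            logger.warning("DMS %s not present in count matrix; skipped", dms["site_id"])
            continue
        for var in care_vars:
            sub = care.reindex(counts.individuals)[[var, age_col]].dropna()
            idx = [counts.individuals.index(i) for i in sub.index]
            y = counts.meth[si, idx]
            n = counts.total[si, idx]
            ok = n > 0
            fit = fit_count_model(y[ok], n[ok], sub[var].to_numpy()[ok],
                                  sub[age_col].to_numpy()[ok])
            opposite = bool(np.sign(fit.beta) != np.sign(dms["beta_corrected"])
                            and fit.beta != 0)
            rows.append({
                "site_id": dms["site_id"],
                "care_var": var,
                "beta_care": fit.beta,
                "se_care": fit.se,
                "p_care": fit.p,
                "family": fit.family,
                "beta_fgcm": float(dms["beta_corrected"]),
                "opposite_sign": opposite,
                "is_hit": is_mitm_hit(fit.beta, fit.p, float(dms["beta_corrected"]),
                                      p_cut=p_cut),
            })
    out = pd.DataFrame(rows)
    if not out.empty:
        # reporting convention: does the sign pattern match the protective-
        # care prediction?
        out["matches_prediction"] = np.where(out["p_care"] < p_cut,
                                             np.where(out["opposite_sign"], "Yes", "No"),
                                             "")
    return out
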