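"""Shared statistical machinery: standardization, random-intercept mixed
models, percentile cluster-bootstrap CIs, BLUP consolidation of repeated
hormone measurements, log-scale effect reporting, and multiplicity control.

Model specification here is deliberately plain: a model is an outcome column,
a list of fixed-effect columns, and a grouping column in a tidy DataFrame.
Categorical columns are expanded to treatment-coded dummies at design-build
time.  Inferential confidence intervals are percentile bootstrap intervals
obtained by resampling the random-intercept clusters with replacement (the
grouping unit is the dependence unit the random intercept models).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .lmm import LmmFit, cluster_bootstrap_betas, fit_random_intercept_lmm

__all__ = [
    "BootstrapCI",
    "standardize",
    "build_design",
    "fit_lmm",
    "percentile_bootstrap_ci",
    "extract_blups",
    "percent_change",
    "test_interaction",
    "bh_fdr",
]


class DegenerateInputError(ValueError):
    """Raised for inputs with no usable variation (e.g. constant vectors)."""


@dataclass
class BootstrapCI:
    term: str
    lower: float
    upper: float
    n_boot: int = 2000
    level: float = 0.95

    def excludes_zero(self) -> bool:
        return self.lower > 0.0 or self.upper < 0.0


def standardize(values) -> np.ndarray:
    """z-score a vector: mean 0, SD 1 (sample SD, denominator n-1)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("standardize expects a 1-D vector")
    if np.unique(x[~np.isnan(x)]).size < 2:
        raise DegenerateInputError("cannot standardize a constant vector")
    return (x - np.nanmean(x)) / np.nanstd(x, ddof=1)


def build_design(
    data: pd.DataFrame, fixed_terms: list[str], add_intercept: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Build a fixed-effect design matrix from tidy columns.

    Object/categorical/bool columns are expanded to treatment-coded dummies
    (first level dropped); numeric columns enter as-is.
    """
    cols: list[pd.Series | pd.DataFrame] = []
    names: list[str] = []
    if add_intercept:
        cols.append(pd.Series(np.ones(len(data)), index=data.index, name="Intercept"))
        names.append("Intercept")
    for term in fixed_terms:
        col = data[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            dummies = pd.get_dummies(col, prefix=term, drop_first=True, dtype=float)
            cols.append(dummies)
            names.extend(dummies.columns.tolist())
        else:
            cols.append(col.astype(float))
            names.append(term)
    X = pd.concat(cols, axis=1).to_numpy(dtype=float)
    return X, names


def _complete_cases(data: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    sub = data.dropna(subset=columns)
    n_drop = len(data) - len(sub)
    if n_drop:
        warnings.warn(f"complete-case analysis dropped {n_drop} rows with missing values",
                      stacklevel=3)
    return sub


def fit_lmm(
    data: pd.DataFrame,
    outcome: str,
    fixed_terms: list[str],
    group: str,
) -> LmmFit:
    """REML fit of ``outcome ~ fixed_terms`` with a random intercept for
    ``group``.  Wald SEs are attached; CIs should come from
    :func:`percentile_bootstrap_ci`.
    """
    sub = _complete_cases(data, [outcome, *fixed_terms, group])
    X, names = build_design(sub, fixed_terms)
    return fit_random_intercept_lmm(
        X, sub[outcome].to_numpy(dtype=float), sub[group].to_numpy(),
        fe_names=names, group_name=group,
    )


def percentile_bootstrap_ci(
    data: pd.DataFrame,
    outcome: str,
    fixed_terms: list[str],
    group: str,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
    max_fail_frac: float = 0.10,
) -> dict[str, BootstrapCI]:
    """Percentile bootstrap CIs for every fixed-effect term.

    Clusters (levels of ``group``, the random-intercept unit) are resampled
    with replacement and the model refit on each replicate; the interval is
    the empirical (alpha/2, 1-alpha/2) percentile range.  Failed refits are
    skipped and counted; more than ``max_fail_frac`` failures is an error.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = _complete_cases(data, [outcome, *fixed_terms, group])
    X, names = build_design(sub, fixed_terms)
    y = sub[outcome].to_numpy(dtype=float)
    g = sub[group].to_numpy()
    betas, n_fail = cluster_bootstrap_betas(X, y, g, n_boot=n_boot, rng=rng)
    if n_fail > max_fail_frac * n_boot:
        raise RuntimeError(
            f"cluster bootstrap: {n_fail}/{n_boot} refits failed "
            f"(> {max_fail_frac:.0%}); model too unstable for percentile CIs"
        )
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    out = {}
    for j, name in enumerate(names):
        lo, hi = np.percentile(betas[:, j], [lo_q, hi_q])
        out[name] = BootstrapCI(term=name, lower=float(lo), upper=float(hi),
                                n_boot=n_boot, level=level)
    return out


def extract_blups(fgcm: pd.DataFrame, id_col: str = "individual_id",
                  value_col: str = "log_fgcm") -> pd.Series:
    """Consolidate repeated log-fGCM measurements into one value per animal.

    Fits the intercept-only random-intercept model and returns the empirical
    BLUPs: each individual's shrunken deviation of mean log fGCM from the
    population mean.  In the balanced case the shrinkage factor is
    n sigma_b^2 / (n sigma_b^2 + sigma_e^2).
    """
    ids = fgcm[id_col].to_numpy()
    if len(np.unique(ids)) < 2:
        raise DegenerateInputError("BLUP extraction needs at least 2 individuals")
    y = fgcm[value_col].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    fit = fit_random_intercept_lmm(X, y, ids, fe_names=["Intercept"], group_name=id_col)
    return pd.Series(fit.blups, name="blup").rename_axis(id_col)


def percent_change(beta_log: float, as_int: bool = False) -> float:
    """Convert a natural-log-scale coefficient to a percent change,
    100*(exp(beta)-1).  With ``as_int`` the value is rounded to the nearest
    integer, the convention used for reporting."""
    if not np.isfinite(beta_log):
        raise ValueError("beta must be finite")
    pct = 100.0 * np.expm1(beta_log)
    if as_int:
        return float(int(np.floor(pct + 0.5)) if pct >= 0 else -int(np.floor(-pct + 0.5)))
    return float(pct)


def test_interaction(fit: LmmFit, term: str, alpha: float = 0.10) -> bool:
    """Flag effect modification: Wald p for ``term`` strictly below alpha."""
    if term not in fit.fe_names:
        raise KeyError(f"term {term!r} not in fitted model: {fit.fe_names}")
    return bool(fit.wald_p(term) < alpha)


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control.

    Returns (reject flags, BH-adjusted p-values).  Ties and ordering follow
    input (site) order for reproducibility.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
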