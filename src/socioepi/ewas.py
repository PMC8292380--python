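"""Site-level differential-methylation analysis (EWAS) on bisulfite counts.

Stages, in fixed order:

1. **Filtering** — drop sites below the per-sample coverage floor, then sites
   whose mean methylated fraction is outside (0.10, 0.90), then the 5% of
   survivors with the lowest interindividual variance.
2. **Per-site model** — binomial mixed model on the logit scale with a
   random effect covariance tau * K (K the pedigree-derived relatedness
   matrix), fit by penalized quasi-likelihood with a one-dimensional profile
   over tau.  When tau is estimated at the zero boundary the site falls back
   to a beta-binomial fit without kinship (flagged).
3. **Empirical-null correction** — a three-component normal mixture
   (central null plus one left and one right alternative) is fit to the z
   statistics by EM; the null component's mean and SD are the bias and
   inflation, and z-scores are rescaled z' = (z - bias)/inflation before
   two-sided normal p-values are recomputed.
4. **FDR** — Benjamini–Hochberg at 5% on the corrected p-values defines the
   differentially methylated site (DMS) calls.

Sites can then be labeled against CpG-density and genic interval tracks
(island > shore > open sea; promoter > exon > intron > intergenic) and DMS
label fractions compared against all tested sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps
from scipy.optimize import minimize, minimize_scalar

from .methylation import MethylationCounts
from .stats import DegenerateInputError, bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "FilterLog",
    "SiteFit",
    "NullModelEstimate",
    "filter_cpgs",
    "fit_site_model",
    "estimate_empirical_null",
    "apply_null_correction",
    "run_ewas",
    "annotate_sites",
]

_TAU_BOUNDARY = 1e-6


@dataclass
class FilterLog:
    n_input: int
    n_removed_coverage: int
    n_removed_mean_bounds: int
    n_removed_low_variance: int
    n_retained: int


def filter_cpgs(
    counts: MethylationCounts,
    min_coverage: int = 10,
    low_var_drop: float = 0.05,
    mean_bounds: tuple[float, float] = (0.10, 0.90),
) -> tuple[MethylationCounts, FilterLog]:
    """CpG filtering in fixed order: coverage, mean bounds, variance quantile.

    A site is kept only if every individual has >= ``min_coverage`` reads;
    then sites with mean methylated fraction outside ``mean_bounds`` are
    dropped; finally the ``low_var_drop`` fraction of survivors with the
    lowest variance of methylated fractions is dropped (ties broken by site
    order: earlier sites are dropped first).
    """
    if counts.n_sites == 0:
        raise ValueError("no CpG sites to filter")
    n0 = counts.n_sites
    cov_ok = (counts.total >= min_coverage).all(axis=1)
    step1 = counts.subset_sites(cov_ok)
    n_cov = n0 - step1.n_sites

    frac = step1.fractions()
    mean_ok = np.zeros(step1.n_sites, dtype=bool)
    if step1.n_sites:
        means = frac.mean(axis=1)
        mean_ok = (means >= mean_bounds[0]) & (means <= mean_bounds[1])
    step2 = step1.subset_sites(mean_ok)
    n_mean = step1.n_sites - step2.n_sites

    n_drop = int(np.floor(low_var_drop * step2.n_sites))
    if n_drop and step2.n_sites:
        var = step2.fractions().var(axis=1, ddof=1)
        order = np.argsort(var, kind="stable")  # stable: ties by site order
        keep = np.ones(step2.n_sites, dtype=bool)
        keep[order[:n_drop]] = False
        step3 = step2.subset_sites(keep)
    else:
        step3 = step2
    log = FilterLog(n_input=n0, n_removed_coverage=n_cov,
                    n_removed_mean_bounds=n_mean, n_removed_low_variance=n_drop,
                    n_retained=step3.n_sites)
    if step3.n_sites == 0:
        raise ValueError(f"all CpG sites removed by filtering: {log}")
    return step3, log


# --------------------------------------------------------------------------
# per-site binomial mixed model (PQL with profiled kinship variance)


@dataclass
class SiteFit:
    beta: float
    se: float
    p: float
    tau: float
    converged: bool
    family: str  # 'binomial-kinship', 'binomial', or 'betabinomial'
    tau_boundary: bool


def _t_referenced(beta: float, se_wald: float, df: int) -> tuple[float, float, float]:
    """Refer a Wald statistic to a t(df) distribution and map it back to the
    normal scale.

    With ~25 individuals the sampling distribution of beta/SE has heavier
    tails than N(0, 1); p-values use the t(df) reference and the reported SE
    is rescaled so that beta/SE equals the normal-scale equivalent z-score
    (Phi^-1 applied to the t-based p).  This keeps the downstream
    empirical-null machinery, which operates on z = beta/se, calibrated in
    the tails."""
    t = beta / se_wald
    p = float(2.0 * sps.t.sf(abs(t), df))
    if abs(t) < 1e-6 or p <= 0.0:
        return se_wald, p, t
    z = float(np.sign(t) * sps.norm.isf(p / 2.0))
    if z == 0.0:
        return se_wald, p, t
    return float(beta / z), p, z


def _logistic_irls(X: np.ndarray, y: np.ndarray, n: np.ndarray,
                   max_iter: int = 50, tol: float = 1e-10):
    """Plain binomial GLM (logit link) by IRLS; returns beta, cov, pearson X2."""
    p_ = X.shape[1]
    beta = np.zeros(p_)
    beta[0] = np.log((y.sum() + 0.5) / (n.sum() - y.sum() + 0.5))
    for _ in range(max_iter):
        eta = X @ beta
        mu = n / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu / n), 1e-10)
        z = eta + (y - mu) / w
        A = (X * w[:, None]).T @ X
        beta_new = np.linalg.solve(A, (X * w[:, None]).T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = n / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu / n), 1e-10)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    pearson = float(np.sum((y - mu) ** 2 / w))
    return beta, cov, pearson


def _betabinom_ml(X: np.ndarray, y: np.ndarray, n: np.ndarray,
                  beta0: np.ndarray):
    """Beta-binomial ML fit (logit mean link, common overdispersion rho)."""
    from statsmodels.tools.numdiff import approx_hess1

    def nll(theta):
        beta, lrho = theta[:-1], theta[-1]
        rho = 1.0 / (1.0 + np.exp(-lrho))
        rho = np.clip(rho, 1e-8, 1 - 1e-6)
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        p = np.clip(p, 1e-8, 1 - 1e-8)
        s = (1.0 - rho) / rho
        return -float(np.sum(sps.betabinom.logpmf(y, n, p * s, (1.0 - p) * s)))

    theta0 = np.concatenate([beta0, [-3.0]])
    res = minimize(nll, theta0, method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-7, "fatol": 1e-9})
    theta = res.x
    H = approx_hess1(theta, nll)
    try:
        cov = np.linalg.inv(H)
        se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se = np.nan
    return theta[:-1], se, res.success


def fit_site_model(
    methylated: np.ndarray,
    totals: np.ndarray,
    exposure: np.ndarray,
    age: np.ndarray,
    kinship: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> SiteFit:
    """Kinship-aware binomial mixed model for one CpG site.

    logit(p_i) = b0 + b1 * exposure_i + b2 * age_i + u_i,
    u ~ MVN(0, tau * K), methylated_i ~ Binomial(total_i, p_i).

    Fit by penalized quasi-likelihood: iterate the working linear mixed
    model, profiling the REML criterion over tau (scale fixed at 1) via the
    eigendecomposition of W^(1/2) K W^(1/2).  The reported (beta, SE, p) are
    Wald quantities for the exposure slope.  tau at the zero boundary
    triggers a beta-binomial fallback without kinship (flagged); with no
    overdispersion either, the plain binomial GLM estimates are returned.
    """
    y = np.asarray(methylated, dtype=float)
    n = np.asarray(totals, dtype=float)
    x = np.asarray(exposure, dtype=float)
    a = np.asarray(age, dtype=float)
    K = np.asarray(kinship, dtype=float)
    m = y.shape[0]
    if not (n.shape[0] == x.shape[0] == a.shape[0] == m and K.shape == (m, m)):
        raise ValueError("dimension mismatch among site inputs")
    if np.any(n <= 0):
        raise ValueError("totals must be positive (filter zero-coverage cells first)")
    if np.unique(x).size < 2:
        raise DegenerateInputError("exposure is constant; slope not identifiable")
    X = np.column_stack([np.ones(m), x, a - a.mean()])

    eta = np.log((y + 0.5) / (n - y + 0.5))
    tau = 0.1
    converged = False
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(n * p * (1.0 - p), 1e-10)
        z = eta + (y - n * p) / w
        sw = np.sqrt(w)
        M = sw[:, None] * K * sw[None, :]
        d, Q = np.linalg.eigh(M)
        d = np.maximum(d, 0.0)
        Xt = Q.T @ (X * sw[:, None])
        zt = Q.T @ (z * sw)

        def crit(log_tau: float) -> float:
            t = np.exp(log_tau)
            v = 1.0 + t * d
            Av = (Xt / v[:, None]).T @ Xt
            sign, logdet_A = np.linalg.slogdet(Av)
            if sign <= 0:
                return np.inf
            bet = np.linalg.solve(Av, (Xt / v[:, None]).T @ zt)
            r = zt - Xt @ bet
            return float(np.sum(np.log(v)) + logdet_A + np.sum(r * r / v))

        res = minimize_scalar(crit, bounds=(-14.0, 6.0), method="bounded",
                              options={"xatol": 1e-6})
        tau_new = float(np.exp(res.x))
        if crit(-30.0) <= res.fun:  # explicit tau -> 0 boundary check
            tau_new = 0.0
        v = 1.0 + tau_new * d
        Av = (Xt / v[:, None]).T @ Xt
        beta = np.linalg.solve(Av, (Xt / v[:, None]).T @ zt)
        r = zt - Xt @ beta
        u = tau_new * (K @ (sw * (Q @ (r / v))))
        eta_new = X @ beta + u
        delta = float(np.max(np.abs(eta_new - eta)))
        eta, tau = eta_new, tau_new
        if delta < max(tol, 1e-8 * (1 + float(np.max(np.abs(eta))))):
            converged = True
            break

    dof = m - X.shape[1]
    if tau > _TAU_BOUNDARY:
        cov = np.linalg.inv(Av)
        se, p, _ = _t_referenced(float(beta[1]), float(np.sqrt(cov[1, 1])), dof)
        return SiteFit(beta=float(beta[1]), se=se, p=p,
                       tau=tau, converged=converged, family="binomial-kinship",
                       tau_boundary=False)

    # tau at the boundary: no usable kinship variance at this site
    beta_g, cov_g, pearson = _logistic_irls(X, y, n)
    phi = pearson / dof if dof > 0 else 1.0
    if phi <= 1.0:
        se, p, _ = _t_referenced(float(beta_g[1]), float(np.sqrt(cov_g[1, 1])), dof)
        return SiteFit(beta=float(beta_g[1]), se=se, p=p, tau=0.0,
                       converged=converged, family="binomial", tau_boundary=True)
    beta_bb, se_bb, ok = _betabinom_ml(X, y, n, beta_g)
    if not ok or not np.isfinite(se_bb) or se_bb <= 0:
        # fall back to quasi-binomial SE scaling if the ML fit misbehaves
        se, p, _ = _t_referenced(float(beta_g[1]),
                                 float(np.sqrt(phi * cov_g[1, 1])), dof)
        return SiteFit(beta=float(beta_g[1]), se=se, p=p, tau=0.0,
                       converged=False, family="betabinomial", tau_boundary=True)
    se, p, _ = _t_referenced(float(beta_bb[1]), se_bb, dof - 1)
    return SiteFit(beta=float(beta_bb[1]), se=se, p=p, tau=0.0,
                   converged=converged, family="betabinomial", tau_boundary=True)


# --------------------------------------------------------------------------
# empirical-null (bias/inflation) estimation and correction


@dataclass
class NullModelEstimate:
    bias: float
    inflation: float
    null_proportion: float

    def __post_init__(self):
        if self.inflation <= 0:
            raise ValueError("inflation must be > 0")


def estimate_empirical_null(
    z_scores,
    max_iter: int = 300,
    tol: float = 1e-9,
    n_restarts: int = 10,
    seed: int = 0,
) -> NullModelEstimate:
    """Estimate test-statistic bias and inflation from an empirical null.

    Fits a three-component normal mixture by EM: a central null component
    N(bias, inflation^2) plus one left and one right alternative component
    whose means are constrained away from the null (at least 2 null SDs) and
    whose variances are at least the null variance.  The null component must
    carry the largest weight.  Initialization is at robust method-of-moments
    values with additional seeded random restarts; the best-likelihood valid
    solution wins, so the procedure is deterministic for a given seed.
    """
    z = np.asarray(z_scores, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 500:
        warnings.warn(f"only {z.size} z-scores; empirical-null estimates may be "
                      "unstable (>= 500 recommended)", stacklevel=2)
    if z.size < 10:
        raise ValueError("too few z-scores to estimate an empirical null")
    mu_r = float(np.median(z))
    sd_r = float(sps.median_abs_deviation(z, scale="normal"))
    sd_r = max(sd_r, 1e-3)

    rng = np.random.default_rng(seed)
    inits = [(mu_r, sd_r, 3.0)]
    for _ in range(n_restarts - 1):
        inits.append((mu_r + 0.2 * sd_r * rng.standard_normal(),
                      sd_r * np.exp(0.2 * rng.standard_normal()),
                      float(rng.uniform(2.0, 5.0))))

    best = None
    for mu0, s0, sep in inits:
        fit = _em_three_component(z, mu0, s0, sep, max_iter, tol)
        if fit is None:
            continue
        loglik, params = fit
        pi, mu, sd = params
        if pi[0] < max(pi[1], pi[2]):
            continue  # null must dominate
        if best is None or loglik > best[0]:
            best = (loglik, params)
    if best is None:
        raise RuntimeError("empirical-null EM failed to converge to a valid "
                           "solution from any initialization")
    _, (pi, mu, sd) = best
    return NullModelEstimate(bias=float(mu[0]), inflation=float(sd[0]),
                             null_proportion=float(pi[0]))


def _em_three_component(z, mu0, s0, sep, max_iter, tol):
    """EM for null + left/right alternatives with separation constraints."""
    n = z.size
    pi = np.array([0.90, 0.05, 0.05])
    mu = np.array([mu0, mu0 - sep * s0, mu0 + sep * s0])
    sd = np.array([s0, 2.0 * s0, 2.0 * s0])
    loglik_old = -np.inf
    log_2pi = np.log(2.0 * np.pi)
    for it in range(max_iter):
        d = (z[:, None] - mu[None, :]) / sd[None, :]
        logpdf = -0.5 * d * d - np.log(sd)[None, :] - 0.5 * log_2pi + np.log(pi)[None, :]
        mmax = logpdf.max(axis=1, keepdims=True)
        pz = np.exp(logpdf - mmax)
        denom = pz.sum(axis=1, keepdims=True)
        loglik = float(np.sum(np.log(denom)) + np.sum(mmax))
        resp = pz / denom
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-8):
            nk = np.maximum(nk, 1e-8)
        pi = nk / n
        mu = (resp * z[:, None]).sum(axis=0) / nk
        var = (resp * (z[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, 1e-6))
        # constraints: alternatives stay clear of the null and at least as wide
        mu[1] = min(mu[1], mu[0] - 2.0 * sd[0])
        mu[2] = max(mu[2], mu[0] + 2.0 * sd[0])
        sd[1] = max(sd[1], sd[0])
        sd[2] = max(sd[2], sd[0])
        if abs(loglik - loglik_old) < tol * (1.0 + abs(loglik)):
            return loglik, (pi, mu, sd)
        loglik_old = loglik
    return loglik, (pi, mu, sd)


def apply_null_correction(
    betas, ses, null_estimate: NullModelEstimate
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rescale estimates by the empirical null: z' = (beta/se - bias)/inflation,
    corrected beta = beta - bias*se, corrected se = se*inflation (so that
    beta'/se' = z'), and corrected p = two-sided normal tail of z'."""
    beta = np.asarray(betas, dtype=float)
    se = np.asarray(ses, dtype=float)
    if np.any(se <= 0) or np.any(~np.isfinite(se)):
        raise ValueError("all SEs must be positive and finite")
    zc = (beta / se - null_estimate.bias) / null_estimate.inflation
    beta_c = beta - null_estimate.bias * se
    se_c = se * null_estimate.inflation
    p_c = 2.0 * sps.norm.sf(np.abs(zc))
    return beta_c, se_c, p_c


# --------------------------------------------------------------------------
# pipeline


def run_ewas(
    counts: MethylationCounts,
    blups: pd.Series,
    age: pd.Series,
    kinship: pd.DataFrame,
    fdr: float = 0.05,
    min_coverage: int = 10,
    low_var_drop: float = 0.05,
    mean_bounds: tuple[float, float] = (0.10, 0.90),
    null_seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Full EWAS: filter, per-site kinship model, empirical-null correction,
    BH-FDR calls.  ``blups``/``age`` are indexed by individual id; ``kinship``
    rows/columns likewise.  Returns the result table and a stage-count log.
    """
    ids = counts.individuals
    x = blups.reindex(ids)
    a = age.reindex(ids)
    if x.isna().any() or a.isna().any():
        raise ValueError("blups/age missing for some individuals in counts")
    K = kinship.loc[ids, ids].to_numpy()

    filtered, flog = filter_cpgs(counts, min_coverage=min_coverage,
                                 low_var_drop=low_var_drop, mean_bounds=mean_bounds)
    xv = x.to_numpy(dtype=float)
    av = a.to_numpy(dtype=float)
    fits: list[SiteFit | None] = []
    for i in range(filtered.n_sites):
        try:
            fit = fit_site_model(filtered.meth[i], filtered.total[i], xv, av, K)
        except (DegenerateInputError, np.linalg.LinAlgError) as exc:
            logger.warning("site %d excluded: %s", i, exc)
            fit = None
        fits.append(fit)

    res = pd.DataFrame({
        "site_id": filtered.site_ids().to_numpy(),
        "chrom": filtered.sites["chrom"].to_numpy(),
        "start": filtered.sites["start"].to_numpy(),
        "beta_raw": [f.beta if f else np.nan for f in fits],
        "se_raw": [f.se if f else np.nan for f in fits],
        "p_raw": [f.p if f else np.nan for f in fits],
        "tau": [f.tau if f else np.nan for f in fits],
        "family": [f.family if f else "failed" for f in fits],
        "converged": [bool(f.converged) if f else False for f in fits],
    })
    usable = res["converged"] & np.isfinite(res["se_raw"]) & (res["se_raw"] > 0)
    z = (res.loc[usable, "beta_raw"] / res.loc[usable, "se_raw"]).to_numpy()
    null_est = estimate_empirical_null(z, seed=null_seed)
    beta_c = np.full(len(res), np.nan)
    se_c = np.full(len(res), np.nan)
    p_c = np.full(len(res), np.nan)
    bc, sc, pc = apply_null_correction(res.loc[usable, "beta_raw"].to_numpy(),
                                       res.loc[usable, "se_raw"].to_numpy(), null_est)
    beta_c[usable.to_numpy()] = bc
    se_c[usable.to_numpy()] = sc
    p_c[usable.to_numpy()] = pc
    res["beta_corrected"] = beta_c
    res["se_corrected"] = se_c
    res["p_corrected"] = p_c

    q = np.full(len(res), np.nan)
    is_dms = np.zeros(len(res), dtype=bool)
    reject, p_adj = bh_fdr(res.loc[usable, "p_corrected"].to_numpy(), q=fdr)
    q[usable.to_numpy()] = p_adj
    is_dms[usable.to_numpy()] = p_adj <= fdr
    res["q_bh"] = q
    res["is_dms"] = is_dms

    stage_log = {
        "filter": flog.__dict__,
        "n_fit": int(usable.sum()),
        "n_excluded_model": int((~usable).sum()),
        "null_bias": null_est.bias,
        "null_inflation": null_est.inflation,
        "null_proportion": null_est.null_proportion,
        "n_dms": int(is_dms.sum()),
        "fdr": fdr,
    }
    return res, stage_log


# --------------------------------------------------------------------------
# genomic-context annotation


_CPG_PRECEDENCE = ["island", "shore"]
_GENIC_PRECEDENCE = ["promoter", "exon", "intron"]


def _build_trees(track: pd.DataFrame) -> dict[str, IntervalTree]:
    if np.any(track["end"].to_numpy() <= track["start"].to_numpy()):
        raise ValueError("malformed intervals: end must be > start")
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in track.groupby("chrom"):
        tree = IntervalTree()
        for _, row in sub.iterrows():
            tree.addi(int(row["start"]), int(row["end"]), row["name"])
        trees[chrom] = tree
    return trees


def _label_sites(sites: pd.DataFrame, trees, precedence: list[str], default: str) -> list[str]:
    labels = []
    for _, row in sites.iterrows():
        tree = trees.get(row["chrom"])
        hits = {iv.data for iv in tree[int(row["start"])]} if tree else set()
        for lab in precedence:
            if lab in hits:
                labels.append(lab)
                break
        else:
            labels.append(default)
    return labels


def annotate_sites(
    sites: pd.DataFrame,
    cpg_track: pd.DataFrame | None = None,
    genic_track: pd.DataFrame | None = None,
    is_dms=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label sites by CpG-density and genic context, with enrichment summary.

    Tracks are BED-like frames (chrom, start, end, name) with 0-based
    half-open intervals; ``name`` is one of island/shore (CpG track) or
    promoter/exon/intron (genic track).  Precedence: island > shore >
    open_sea; promoter > exon > intron > intergenic.  The enrichment table
    compares label fractions among DMSs against all tested sites.
    """
    out = sites[["chrom", "start"]].copy()
    if cpg_track is not None:
        out["cpg_context"] = _label_sites(sites, _build_trees(cpg_track),
                                          _CPG_PRECEDENCE, "open_sea")
    if genic_track is not None:
        out["genic_context"] = _label_sites(sites, _build_trees(genic_track),
                                            _GENIC_PRECEDENCE, "intergenic")
    enrich_rows = []
    if is_dms is not None:
        flags = np.asarray(is_dms, dtype=bool)
        for col in [c for c in ("cpg_context", "genic_context") if c in out]:
            for lab in out[col].unique():
                in_lab = (out[col] == lab).to_numpy()
                enrich_rows.append({
                    "track": col,
                    "label": lab,
                    "frac_all_sites": float(in_lab.mean()),
                    "frac_dms": float(in_lab[flags].mean()) if flags.any() else np.nan,
                })
    return out, pd.DataFrame(enrich_rows)
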