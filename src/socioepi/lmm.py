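"""Linear mixed models with a single random intercept, fit by profiled REML.

The model is

    y = X beta + Z b + e,    b_g ~ N(0, sigma_b^2),    e ~ N(0, sigma_e^2 I),

with Z the indicator matrix of a single grouping factor (hyena ID for repeated
hormone measurements, maternal ID for global-methylation outcomes).  Writing
lambda = sigma_b^2 / sigma_e^2, the marginal covariance is
sigma_e^2 (I + lambda Z Z'), which is block diagonal, so GLS quantities reduce
to per-group sufficient statistics (n_g, sums, cross-products).  The REML
criterion is profiled down to a one-dimensional search over log(lambda).

Because the criterion depends on the data only through those per-group
statistics, a cluster bootstrap replicate (groups resampled with replacement)
is just a reweighted sum of precomputed group statistics — no data copying and
no per-replicate design rebuild.  This is what makes percentile bootstrap CIs
with thousands of cluster refits cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import minimize_scalar

__all__ = ["LmmFit", "RankDeficientError", "fit_random_intercept_lmm"]

# lambda = sigma_b^2/sigma_e^2 search range on the log scale
_LOG_LAM_LO = -12.0
_LOG_LAM_HI = 12.0
_VAR_FLOOR = 1e-12


class RankDeficientError(ValueError):
    """Raised when the fixed-effect design is not full rank."""


@dataclass
class LmmFit:
    """Result of a random-intercept LMM fit.

    ``fixed_effects`` maps each fixed-effect name to its (beta, SE) pair.
    Wald SEs are reported for convenience; inferential CIs in this package
    come from the percentile cluster bootstrap.
    """

    fe_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    group_var: float
    resid_var: float
    group_name: str
    n_obs: int
    n_groups: int
    loglik: float
    blups: dict = field(default_factory=dict, repr=False)

    @property
    def fixed_effects(self) -> dict[str, tuple[float, float]]:
        return {k: (float(b), float(s)) for k, b, s in zip(self.fe_names, self.beta, self.se)}

    def coef(self, term: str) -> float:
        return float(self.beta[self.fe_names.index(term)])

    def se_of(self, term: str) -> float:
        return float(self.se[self.fe_names.index(term)])

    def wald_p(self, term: str) -> float:
        from scipy.stats import norm

        i = self.fe_names.index(term)
        if self.se[i] <= 0:
            return 0.0 if self.beta[i] != 0 else 1.0
        z = self.beta[i] / self.se[i]
        return float(2.0 * norm.sf(abs(z)))


class _GroupStats:
    """Per-group sufficient statistics for the profiled REML criterion."""

    __slots__ = ("n", "Sy", "yty", "Sx", "XtX", "Xty", "labels", "p")

    def __init__(self, X: np.ndarray, y: np.ndarray, codes: np.ndarray, labels: np.ndarray):
        G = len(labels)
        n, p = X.shape
        self.p = p
        self.labels = labels
        self.n = np.bincount(codes, minlength=G).astype(float)
        self.Sy = np.bincount(codes, weights=y, minlength=G)
        self.yty = np.bincount(codes, weights=y * y, minlength=G)
        self.Sx = np.zeros((G, p))
        self.Xty = np.zeros((G, p))
        self.XtX = np.zeros((G, p, p))
        for j in range(p):
            self.Sx[:, j] = np.bincount(codes, weights=X[:, j], minlength=G)
            self.Xty[:, j] = np.bincount(codes, weights=X[:, j] * y, minlength=G)
            for k in range(j, p):
                v = np.bincount(codes, weights=X[:, j] * X[:, k], minlength=G)
                self.XtX[:, j, k] = v
                self.XtX[:, k, j] = v


def _criterion_and_fit(stats: _GroupStats, w: np.ndarray, lam: float):
    """Profiled REML deviance (up to a constant) and GLS quantities at lambda.

    ``w`` holds nonnegative group multiplicities (all ones for the full-data
    fit; multinomial counts for a cluster-bootstrap replicate).
    """
    active = w > 0
    n_g = stats.n[active]
    wg = w[active]
    c = lam / (1.0 + lam * n_g)  # shrinkage coefficient per group
    A = np.einsum("g,gij->ij", wg, stats.XtX[active]) - np.einsum(
        "g,gi,gj->ij", wg * c, stats.Sx[active], stats.Sx[active]
    )
    b = np.einsum("g,gi->i", wg, stats.Xty[active]) - np.einsum(
        "g,gi->i", wg * c * stats.Sy[active], stats.Sx[active]
    )
    q = float(np.dot(wg, stats.yty[active]) - np.dot(wg * c, stats.Sy[active] ** 2))
    N = float(np.dot(wg, n_g))
    p = stats.p
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return np.inf, None
    beta = np.linalg.solve(A, b)
    rss = max(q - float(beta @ b), _VAR_FLOOR)
    sigma2 = rss / (N - p)
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(L))))
    logdet_V0 = float(np.dot(wg, np.log1p(lam * n_g)))
    crit = (N - p) * np.log(sigma2) + logdet_V0 + logdet_A
    return crit, (beta, sigma2, A, N)


def _profile_lambda(stats: _GroupStats, w: np.ndarray):
    """Minimize the profiled REML criterion over log(lambda), checking the
    lambda -> 0 boundary explicitly."""

    def obj(u: float) -> float:
        return _criterion_and_fit(stats, w, np.exp(u))[0]

    res = minimize_scalar(obj, bounds=(_LOG_LAM_LO, _LOG_LAM_HI), method="bounded",
                          options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    crit0, _ = _criterion_and_fit(stats, w, 0.0)
    if crit0 <= res.fun:
        lam = 0.0
    return lam


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a dependent column set via pivoted QR
        _, _, piv = scipy.linalg.qr(X, pivoting=True)
        bad = [names[j] for j in piv[rank:]]
        raise RankDeficientError(
            f"fixed-effect design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear terms: {bad}"
        )


def fit_random_intercept_lmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    fe_names: list[str] | None = None,
    group_name: str = "group",
) -> LmmFit:
    """Fit a Gaussian LMM with one random intercept by profiled REML.

    Parameters
    ----------
    X : (n, p) fixed-effect design (include an intercept column explicitly).
    y : (n,) outcome.
    groups : (n,) grouping labels for the random intercept.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if X.ndim != 2 or X.shape[0] != y.shape[0] or groups.shape[0] != y.shape[0]:
        raise ValueError("X, y, groups must have matching first dimensions")
    if fe_names is None:
        fe_names = [f"x{j}" for j in range(X.shape[1])]
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for a random-intercept model")
    if len(labels) > len(y):
        raise ValueError("n_groups cannot exceed n_obs")
    _check_full_rank(X, fe_names)

    stats = _GroupStats(X, y, codes, labels)
    w = np.ones(len(labels))
    lam = _profile_lambda(stats, w)
    crit, fit = _criterion_and_fit(stats, w, lam)
    beta, sigma2, A, N = fit
    if lam == 0.0:
        warnings.warn(
            "random-intercept variance estimated at the zero boundary",
            RuntimeWarning,
            stacklevel=2,
        )
    group_var = lam * sigma2
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    p = X.shape[1]
    # full REML log-likelihood (statsmodels convention, without the |X'X| term)
    loglik = -0.5 * (crit + (N - p) * (1.0 + np.log(2.0 * np.pi)))

    # empirical BLUPs: b_g = (lam / (1 + lam n_g)) * sum of marginal residuals
    resid_sums = stats.Sy - stats.Sx @ beta
    shrink = lam / (1.0 + lam * stats.n)
    blup_vals = shrink * resid_sums
    blups = {lab: float(v) for lab, v in zip(labels, blup_vals)}

    return LmmFit(
        fe_names=list(fe_names),
        beta=beta,
        se=se,
        group_var=float(group_var),
        resid_var=float(sigma2),
        group_name=group_name,
        n_obs=int(N),
        n_groups=len(labels),
        loglik=float(loglik),
        blups=blups,
    )


def _crit_batch(stats: _GroupStats, W: np.ndarray, lam: np.ndarray, WX: np.ndarray,
                Wb: np.ndarray, Wq: np.ndarray, WN: np.ndarray):
    """Profiled REML criterion and GLS betas for B replicates at once.

    ``W`` (B, G) holds group multiplicities, ``lam`` (B,) the candidate
    lambda per replicate; WX/Wb/Wq/WN are the lambda-independent weighted
    sums, precomputed once per bootstrap run.
    """
    p = stats.p
    C = lam[:, None] / (1.0 + lam[:, None] * stats.n[None, :])  # (B, G)
    WC = W * C
    A = WX - np.einsum("bg,gp,gq->bpq", WC, stats.Sx, stats.Sx, optimize=True)
    b_vec = Wb - np.einsum("bg,gp->bp", WC * stats.Sy[None, :], stats.Sx)
    q = Wq - np.einsum("bg,g->b", WC, stats.Sy**2)
    sign, logdet_A = np.linalg.slogdet(A)
    bad = sign <= 0
    if np.any(bad):
        A = A.copy()
        A[bad] = np.eye(p)
    beta = np.linalg.solve(A, b_vec[..., None])[..., 0]
    rss = np.maximum(q - np.einsum("bp,bp->b", beta, b_vec), _VAR_FLOOR)
    sigma2 = rss / np.maximum(WN - p, 1.0)
    logdet_V0 = np.einsum("bg->b", W * np.log1p(lam[:, None] * stats.n[None, :]))
    crit = (WN - p) * np.log(sigma2) + logdet_V0 + logdet_A
    crit[bad] = np.inf
    return crit, beta


def cluster_bootstrap_betas(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Percentile-bootstrap machinery: resample groups with replacement and
    refit via the sufficient-statistic representation.

    The lambda profile is minimized by a vectorized three-stage grid
    refinement over log(lambda), shared across all replicates, with an
    explicit lambda -> 0 boundary check.  Returns the (n_ok, p) array of
    fixed-effect estimates from successful refits and the number of failed
    refits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    stats = _GroupStats(X, y, codes, labels)
    G = len(labels)
    W = rng.multinomial(G, np.full(G, 1.0 / G), size=n_boot).astype(float)

    WX = np.einsum("bg,gpq->bpq", W, stats.XtX)
    Wb = W @ stats.Xty
    Wq = W @ stats.yty
    WN = W @ stats.n

    def crit_at(lam_vec):
        return _crit_batch(stats, W, lam_vec, WX, Wb, Wq, WN)

    # stage 1: shared coarse grid on log(lambda)
    grid1 = np.linspace(_LOG_LAM_LO, _LOG_LAM_HI, 31)
    best_crit = np.full(n_boot, np.inf)
    best_log = np.full(n_boot, grid1[0])
    for lv in grid1:
        c, _ = crit_at(np.full(n_boot, np.exp(lv)))
        upd = c < best_crit
        best_crit[upd] = c[upd]
        best_log[upd] = lv
    # stages 2-3: per-replicate refinement around the coarse optimum
    for half, steps in ((0.9, 13), (0.9 * 2 / 12, 13)):
        offsets = np.linspace(-half, half, steps)
        center = best_log.copy()
        for off in offsets:
            lv = center + off
            c, _ = crit_at(np.exp(lv))
            upd = c < best_crit
            best_crit[upd] = c[upd]
            best_log[upd] = lv[upd]
    # boundary lambda = 0
    c0, beta0 = crit_at(np.zeros(n_boot))
    lam_best = np.exp(best_log)
    use0 = c0 <= best_crit
    lam_best[use0] = 0.0
    crit_f, beta_f = crit_at(lam_best)
    ok = np.isfinite(crit_f)
    return beta_f[ok], int(n_boot - ok.sum())
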