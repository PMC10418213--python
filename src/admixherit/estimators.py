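"""Random-effects heritability estimators and marginal GWAS.

Implements the three estimators whose behavior in admixed populations this
package studies:

* :func:`reml` -- restricted maximum likelihood for the single-GRM model
  V(y) = sigma_g^2 K + sigma_e^2 I with fixed effects.  After projecting
  the fixed effects out (restricted likelihood) and rotating into the
  eigenbasis of the projected GRM, the likelihood profiles to a
  one-dimensional problem in the variance ratio, which is solved exactly
  by scalar minimization.  Unconstrained by default so negative variance
  components are observable rather than floored.
* :func:`he_regression` -- Haseman-Elston regression: the slope of
  phenotypic cross-products y_k y_l on GRM entries psi_kl over all pairs
  k < l.  With covariates, both the phenotype and the GRM are projected
  (residual-maker on both sides), the moment-matching ancestry adjustment.
* :func:`gwas_marginal`, :func:`ld_scores`, :func:`ldsc_fit` -- per-variant
  OLS association, LD scores l_k = sum_i r_ik^2 (optionally on
  PC-residualized genotypes, the ancestry-adjusted variant), and the LD
  score regression of chi^2 on l_k whose slope estimates n Vg / m.

All variance denominators use the population convention (divide by n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .grm import GRMatrix

__all__ = [
    "VarianceEstimate",
    "SummaryStats",
    "LDSCFit",
    "reml",
    "RemlWorkspace",
    "he_regression",
    "gwas_marginal",
    "expected_marginal_effects",
    "ld_scores",
    "ldsc_fit",
]


@dataclass
class VarianceEstimate:
    """A fitted variance component and derived heritability."""

    method: str
    sigma_g2: float
    sigma_resid2: float
    h2: float
    se_sigma_g2: float = np.nan
    se_h2: float = np.nan
    adjusted: bool = False
    scaling: str = ""
    source: str = "genotype"
    converged: bool = True
    constrained: bool = False
    negative: bool = field(init=False)

    def __post_init__(self) -> None:
        self.negative = self.sigma_g2 < 0


@dataclass
class SummaryStats:
    """Per-variant marginal GWAS results."""

    table: pd.DataFrame  # columns: snp, beta, se, chi2, freq, flagged
    n: int
    n_covariates: int = 0

    @property
    def chi2(self) -> np.ndarray:
        return self.table["chi2"].to_numpy()

    @property
    def beta(self) -> np.ndarray:
        return self.table["beta"].to_numpy()


@dataclass
class LDSCFit:
    """LD score regression fit."""

    slope: float
    intercept: float
    vg_hat: float
    ld_scores: np.ndarray
    n_pcs_projected: int = 0
    weights: str = "ols"


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones((n, 1))]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    C = np.hstack(cols)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix (with intercept) is rank deficient")
    return C


class RemlWorkspace:
    """Precomputed spectral pieces of the restricted likelihood.

    Projects the fixed effects (intercept + covariates) out of the model,
    eigendecomposes the projected GRM once, and then fits any number of
    phenotypes on the same (GRM, covariates) pair with a cheap 1-D
    optimization each.
    """

    def __init__(self, K: GRMatrix | np.ndarray, covariates: np.ndarray | None = None):
        A = K.K if isinstance(K, GRMatrix) else np.asarray(K, dtype=float)
        self.scaling = K.scaling if isinstance(K, GRMatrix) else ""
        self.source = K.source if isinstance(K, GRMatrix) else "genotype"
        self.adjusted = covariates is not None
        n = A.shape[0]
        C = _design(n, covariates)
        evals_min = scipy.linalg.eigh(A, eigvals_only=True, subset_by_index=(0, 0))[0]
        if evals_min < -1e-6 * max(1.0, np.abs(A).max()):
            raise ValueError("GRM is not positive semidefinite")
        # orthonormal basis of the complement of span(C)
        B = scipy.linalg.null_space(C.T)
        self.q = B.shape[1]
        s, U = scipy.linalg.eigh(B.T @ A @ B)
        self.s = s
        self.T = B @ U  # n x q rotation into the restricted eigenbasis

    def fit(self, y: np.ndarray, constrain: bool = False) -> VarianceEstimate:
        y = np.asarray(y, dtype=float)
        s, q = self.s, self.q
        w2 = (self.T.T @ y) ** 2
        s_max = s[-1]
        lam_lo = (-1.0 / s_max) * 0.999 if (s_max > 0 and not constrain) else 0.0

        def nll(lam: float) -> float:
            d = lam * s + 1.0
            if np.any(d <= 0):
                return np.inf
            sig2 = float(np.mean(w2 / d))
            if sig2 <= 0:
                return np.inf
            return q * np.log(sig2) + float(np.sum(np.log(d)))

        grid = np.concatenate(
            [np.linspace(lam_lo, 0.0, 40, endpoint=True), np.logspace(-6, 6, 60)]
        )
        vals = np.array([nll(l) for l in grid])
        k = int(np.argmin(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, grid.size - 1)]
        if lo == hi:
            lam_hat = float(lo)
        else:
            res = scipy.optimize.minimize_scalar(
                nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
            )
            lam_hat = float(res.x) if res.fun <= vals[k] else float(grid[k])
        sigma_e2 = float(np.mean(w2 / (lam_hat * s + 1.0)))
        sigma_g2 = lam_hat * sigma_e2

        # Fisher information in (sigma_g2, sigma_e2)
        d = sigma_g2 * s + sigma_e2
        info = 0.5 * np.array(
            [
                [np.sum(s**2 / d**2), np.sum(s / d**2)],
                [np.sum(s / d**2), np.sum(1.0 / d**2)],
            ]
        )
        converged = True
        try:
            cov = np.linalg.inv(info)
            se_g = float(np.sqrt(max(cov[0, 0], 0.0)))
            tot = sigma_g2 + sigma_e2
            grad = np.array([sigma_e2, -sigma_g2]) / tot**2
            se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        except np.linalg.LinAlgError:
            se_g = se_h2 = np.nan
            converged = False
        if np.ptp(s) < 1e-10 * max(1.0, abs(s_max)):
            converged = False  # no relatedness contrast: components unidentifiable
        h2 = sigma_g2 / (sigma_g2 + sigma_e2)
        return VarianceEstimate(
            method="reml",
            sigma_g2=sigma_g2,
            sigma_resid2=sigma_e2,
            h2=h2,
            se_sigma_g2=se_g,
            se_h2=se_h2,
            adjusted=self.adjusted,
            scaling=self.scaling,
            source=self.source,
            converged=converged,
            constrained=constrain,
        )


def reml(
    y: np.ndarray,
    K: GRMatrix | np.ndarray,
    covariates: np.ndarray | None = None,
    constrain: bool = False,
) -> VarianceEstimate:
    """Single-GRM REML via null-space projection and spectral rotation.

    Estimates (sigma_g^2, sigma_e^2) in V(y) = sigma_g^2 K + sigma_e^2 I
    with fixed effects = intercept + ``covariates``.  When
    ``constrain=False`` (default) sigma_g^2 may come out negative.
    Standard errors come from the inverse Fisher information; a flat or
    degenerate likelihood is reported via ``converged=False``.  To fit
    many phenotypes on one (GRM, covariates) pair, build a
    :class:`RemlWorkspace` once and call its ``fit``.
    """
    return RemlWorkspace(K, covariates).fit(y, constrain=constrain)


def _he_slope(y_r: np.ndarray, Kmat: np.ndarray) -> float:
    n = y_r.size
    iu = np.triu_indices(n, k=1)
    psi = Kmat[iu]
    Y = np.outer(y_r, y_r)[iu]
    vp = float(np.var(psi))
    if vp == 0:
        raise ValueError("GRM off-diagonal entries are constant; slope undefined")
    return float(np.cov(Y, psi, bias=True)[0, 1] / vp)


def he_regression(
    y: np.ndarray,
    K: GRMatrix | np.ndarray,
    covariates: np.ndarray | None = None,
    n_jackknife_blocks: int = 20,
) -> VarianceEstimate:
    """Haseman-Elston regression of cross-products on GRM entries.

    Without covariates the phenotype is mean-centered and the GRM used
    as-is.  With covariates, both phenotype and GRM are projected with the
    residual maker M = I - C(C'C)^-1 C' (M y and M K M) before the
    regression -- the moment-matching ancestry adjustment.  Standard
    errors by delete-a-block jackknife over individuals.
    """
    Kmat = K.K if isinstance(K, GRMatrix) else np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least three individuals")
    if covariates is None:
        y_r = y - y.mean()
        Kuse = Kmat
    else:
        C = _design(n, covariates)
        H = C @ np.linalg.solve(C.T @ C, C.T)
        y_r = y - H @ y
        Kuse = Kmat - H @ Kmat - Kmat @ H + H @ Kmat @ H
    slope = _he_slope(y_r, Kuse)
    mdiag = float(np.mean(np.diag(Kuse)))
    sigma_resid2 = float(np.var(y_r)) - slope * mdiag
    h2 = slope / (slope + sigma_resid2) if (slope + sigma_resid2) != 0 else np.nan

    # block jackknife
    se = np.nan
    if n_jackknife_blocks and n >= 2 * n_jackknife_blocks:
        blocks = np.array_split(np.arange(n), n_jackknife_blocks)
        reps = []
        for blk in blocks:
            keep = np.setdiff1d(np.arange(n), blk, assume_unique=True)
            reps.append(_he_slope(y_r[keep], Kuse[np.ix_(keep, keep)]))
        reps = np.asarray(reps)
        g = reps.size
        se = float(np.sqrt((g - 1) / g * np.sum((reps - reps.mean()) ** 2)))
    return VarianceEstimate(
        method="he",
        sigma_g2=slope,
        sigma_resid2=sigma_resid2,
        h2=h2,
        se_sigma_g2=se,
        se_h2=np.nan,
        adjusted=covariates is not None,
        scaling=K.scaling if isinstance(K, GRMatrix) else "",
        source=K.source if isinstance(K, GRMatrix) else "genotype",
    )


def gwas_marginal(
    y: np.ndarray,
    X: np.ndarray,
    covariates: np.ndarray | None = None,
) -> SummaryStats:
    """Per-variant OLS of y on genotype dosage plus covariates.

    Covariates (and the intercept) are residualized out of both phenotype
    and genotypes; each variant's slope, standard error and chi^2 follow
    from the simple regression on the residuals with the correct degrees
    of freedom.  Monomorphic variants yield flagged NaN records.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    C = _design(n, covariates)
    c = C.shape[1]
    if n <= c + 2:
        raise ValueError("sample size too small for the covariate set")
    H = C @ np.linalg.solve(C.T @ C, C.T)
    y_r = y - H @ y
    X_r = X - H @ X
    sxx = np.einsum("ij,ij->j", X_r, X_r)
    mono = sxx <= 1e-12
    sxx_safe = np.where(mono, np.nan, sxx)
    beta = (X_r.T @ y_r) / sxx_safe
    rss = float(y_r @ y_r) - beta**2 * sxx_safe
    dof = n - c - 1
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (beta / se) ** 2
    perfect = (se == 0) | np.isinf(chi2)
    table = pd.DataFrame(
        {
            "snp": [f"snp{i}" for i in range(m)],
            "beta": beta,
            "se": se,
            "chi2": chi2,
            "freq": X.mean(axis=0) / 2.0,
            "flagged": mono | perfect,
        }
    )
    return SummaryStats(table=table, n=n, n_covariates=c - 1)


def expected_marginal_effects(beta: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Expected marginal GWAS effects E[beta_hat] = R beta.

    R is the variant-correlation matrix (symmetric, unit diagonal) over
    all variants; beta holds the true causal effects (zero for
    non-causal variants).
    """
    R = np.asarray(R, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if R.shape[0] != R.shape[1] or R.shape[1] != beta.size:
        raise ValueError("R must be square and conform with beta")
    return R @ beta


def ld_scores(
    X: np.ndarray, pcs_to_project: int = 0
) -> np.ndarray:
    """LD scores l_k = sum_i r_ik^2 over all variants (self term included).

    Loci are unlinked in this package's generative model, so admixture LD
    is global and the sum runs over every variant rather than a physical
    window.  With ``pcs_to_project`` > 0, that many genotype principal
    components are projected out of the standardized genotypes first
    (ancestry-adjusted LD scores), collapsing admixture LD.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic column in genotype matrix")
    Z = (X - X.mean(axis=0)) / sd
    if pcs_to_project > 0:
        # PCs of the standardized genotype matrix via thin SVD
        Uv, _, _ = np.linalg.svd(Z, full_matrices=False)
        Upc = Uv[:, :pcs_to_project]
        Z = Z - Upc @ (Upc.T @ Z)
        sd = Z.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("a column became constant after PC projection")
        Z = (Z - Z.mean(axis=0)) / sd
    R = (Z.T @ Z) / n
    return np.einsum("ij,ij->j", R, R)


def ldsc_fit(
    stats: SummaryStats | np.ndarray,
    ell: np.ndarray,
    m: int,
    weights: str = "ols",
    n_pcs_projected: int = 0,
) -> LDSCFit:
    """Regression of chi^2 on LD scores with a free intercept.

    slope estimates n sigma_u^2 / m, so vg_hat = slope * m / n.  weights
    is ``"ols"`` or ``"reciprocal_ell"`` (1/l_k weights).
    """
    if isinstance(stats, SummaryStats):
        chi2 = stats.chi2
        n = stats.n
    else:
        raise TypeError("ldsc_fit needs a SummaryStats object (for n)")
    ell = np.asarray(ell, dtype=float)
    ok = np.isfinite(chi2) & np.isfinite(ell)
    chi2, ell_ok = chi2[ok], ell[ok]
    if chi2.size < 3:
        raise ValueError("need at least three variants")
    if weights == "ols":
        wts = np.ones_like(ell_ok)
    elif weights == "reciprocal_ell":
        wts = 1.0 / ell_ok
    else:
        raise ValueError("weights must be 'ols' or 'reciprocal_ell'")
    A = np.column_stack([ell_ok, np.ones_like(ell_ok)])
    Aw = A * wts[:, None]
    coef = np.linalg.solve(A.T @ Aw, Aw.T @ chi2)
    slope, intercept = float(coef[0]), float(coef[1])
    return LDSCFit(
        slope=slope,
        intercept=intercept,
        vg_hat=slope * m / n,
        ld_scores=ell,
        n_pcs_projected=n_pcs_projected,
        weights=weights,
    )
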