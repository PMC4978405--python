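"""Per-gene spline regression, empirical-Bayes moderated F-test, FDR selection.

Each gene is fitted by ordinary least squares on the shared two-group spline
design.  Residual variances s_g^2 (with d_g = n - 2(m+1) degrees of freedom)
are shrunk toward a pooled prior under the hierarchical model

    s_g^2 | sigma_g^2  ~  sigma_g^2 * chi2_{d_g} / d_g
    1 / sigma_g^2      ~  chi2_{d0} / (d0 * s0^2)

whose hyperparameters (d0, s0^2) are estimated by matching the first two
moments of log s_g^2 (digamma/trigamma moment equations).  The moderated F
statistic on the differential coefficient block d = (d0..dm) is

    F_g = d_hat' C^{-1} d_hat / ((m+1) * s_tilde_g^2),

C being the unscaled covariance of the d block from the design, with null
distribution F(m+1, d0 + d_g); d0 = +inf degenerates to a chi-square test.
P-values are Benjamini-Hochberg adjusted and genes with adjusted p strictly
below the FDR threshold (default 0.05) are declared differentially expressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .containers import TimecourseExperiment
from .design import SplineDesign, build_design

logger = logging.getLogger(__name__)


@dataclass
class GeneFits:
    """OLS results for all genes on one shared design."""

    genes: list[str]
    coefficients: np.ndarray      # genes x 2(m+1), order [b0..bm, d0..dm]
    s2: np.ndarray                # residual variances, denominator d_g
    residual_df: int              # d_g = n - 2(m+1)
    cov_diff: np.ndarray          # (m+1) x (m+1) unscaled covariance of the d block
    m: int

    @property
    def diff_coefficients(self) -> np.ndarray:
        return self.coefficients[:, self.m + 1:]


@dataclass
class ModerationParams:
    """Empirical-Bayes variance hyperparameters and per-gene posterior variances."""

    prior_df: float               # d0, possibly +inf
    prior_var: float              # s0^2
    posterior_var: np.ndarray     # s_tilde_g^2


@dataclass
class DiffExprResult:
    table: pd.DataFrame
    fits: GeneFits
    moderation: ModerationParams
    design: SplineDesign
    n_dropped_missing: int = 0


def fit_ols(y: np.ndarray, x: np.ndarray, n_diff: int) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Vectorized OLS of every row of ``y`` on the design ``x``.

    Returns (coefficients, residual variances, residual df, unscaled
    covariance of the trailing ``n_diff`` coefficients).
    """
    n, p = x.shape
    if y.ndim == 1:
        y = y[None, :]
    if n <= p:
        raise ValueError(f"need more observations ({n}) than coefficients ({p})")
    xtx = x.T @ x
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("rank-deficient design matrix")
    coef = np.linalg.solve(xtx, x.T @ y.T).T
    resid = y - coef @ x.T
    dg = n - p
    s2 = np.einsum("ij,ij->i", resid, resid) / dg
    cov = np.linalg.inv(xtx)
    return coef, s2, dg, cov[p - n_diff:, p - n_diff:]


def fit_gene_models(experiment: TimecourseExperiment, design: SplineDesign) -> GeneFits:
    """Ordinary least squares per gene on the spline design.

    The experiment must be free of missing values (use
    :meth:`TimecourseExperiment.drop_incomplete_genes` first).
    """
    y = experiment.values.to_numpy(float)
    if np.isnan(y).any():
        raise ValueError(
            "expression matrix contains missing values; drop incomplete gene rows first"
        )
    if experiment.samples != design.samples:
        raise ValueError("design was built for a different sample set/order")
    coef, s2, dg, cov_diff = fit_ols(y, design.matrix, design.m + 1)
    n_exact = int((s2 == 0).sum())
    if n_exact:
        logger.warning("%d gene(s) with zero residual variance (exact fit)", n_exact)
    return GeneFits(
        genes=experiment.genes, coefficients=coef, s2=s2,
        residual_df=dg, cov_diff=cov_diff, m=design.m,
    )


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + step
        if -step / x < tol:
            break
    return float(x)


def estimate_moderation(s2: np.ndarray, residual_df: float | np.ndarray) -> ModerationParams:
    """Estimate (d0, s0^2) by moments of log s_g^2 and form posterior variances.

    Genes with s_g^2 = 0 cannot enter the log-moment equations and are
    excluded from estimation with a logged warning; they still receive a
    strictly positive posterior variance through the prior.  When the
    spread of log-variances is no larger than the sampling noise implied by
    d_g the prior df is infinite and every gene is shrunk fully to s0^2.
    """
    s2 = np.asarray(s2, float)
    dg = np.broadcast_to(np.asarray(residual_df, float), s2.shape)
    if np.any(dg < 1):
        raise ValueError("residual df must be >= 1 for every gene")
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all residual variances are zero; nothing to moderate")
    if (~ok).sum():
        logger.warning(
            "%d gene(s) with zero residual variance excluded from hyperparameter "
            "estimation (still moderated through the prior)", int((~ok).sum()),
        )
    z = np.log(s2[ok])
    e = z - digamma(dg[ok] / 2.0) + np.log(dg[ok] / 2.0)
    if e.size < 2:
        raise ValueError("need at least 2 genes with positive residual variance")
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(np.mean(polygamma(1, dg[ok] / 2.0)))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s02 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # degenerate spread: the sample variances carry no more dispersion
        # than pure sampling noise, so pool completely; the geometric mean
        # keeps the fully-degenerate case (all variances equal) fixed
        d0 = np.inf
        s02 = float(np.exp(z.mean()))
    if np.isfinite(d0):
        post = (d0 * s02 + dg * s2) / (d0 + dg)
    else:
        post = np.full_like(s2, s02)
    return ModerationParams(prior_df=float(d0), prior_var=s02, posterior_var=post)


def moderated_f(fits: GeneFits, moderation: ModerationParams) -> tuple[np.ndarray, np.ndarray]:
    """Moderated F statistic and p-value for the differential block of every gene."""
    k = fits.m + 1
    try:
        cho = cho_factor(fits.cov_diff)
    except np.linalg.LinAlgError as err:  # pragma: no cover - guarded upstream
        raise ValueError("singular covariance block for the differential coefficients") from err
    d_hat = fits.diff_coefficients
    quad = np.einsum("ij,ij->i", d_hat, cho_solve(cho, d_hat.T).T)
    f_stat = quad / (k * moderation.posterior_var)
    total_df = moderation.prior_df + fits.residual_df
    if np.isfinite(total_df):
        p = stats.f.sf(f_stat, k, total_df)
    else:
        p = stats.chi2.sf(k * f_stat, k)
    return f_stat, p


def adjust_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_differential(table: pd.DataFrame, fdr: float = 0.05) -> list[str]:
    """Genes with adjusted p strictly below ``fdr``, ordered by (adjusted p, symbol)."""
    sel = table[table["adj_p"] < fdr]
    sel = sel.sort_values(["adj_p", "gene"], kind="mergesort")
    return sel["gene"].tolist()


def differential_expression(
    experiment: TimecourseExperiment,
    df: int = 3,
    fdr: float = 0.05,
) -> DiffExprResult:
    """Full time-course differential-expression analysis for one experiment.

    Gene rows containing missing values are excluded (with a logged count)
    before fitting; the remaining genes are fitted, moderated, tested and
    BH-adjusted.  The result table carries the differential coefficients,
    the moderated F, raw and adjusted p-values and the selection flag.
    """
    clean, n_dropped = experiment.drop_incomplete_genes()
    if n_dropped:
        logger.info("excluded %d gene(s) with missing values from testing", n_dropped)
    design = build_design(clean, df=df)
    fits = fit_gene_models(clean, design)
    moderation = estimate_moderation(fits.s2, fits.residual_df)
    f_stat, p = moderated_f(fits, moderation)
    adj = adjust_bh(p)
    table = pd.DataFrame({"gene": fits.genes})
    for j in range(fits.m + 1):
        table[f"d_{j}"] = fits.diff_coefficients[:, j]
    table["F"] = f_stat
    table["p_value"] = p
    table["adj_p"] = adj
    table["selected"] = adj < fdr
    return DiffExprResult(
        table=table, fits=fits, moderation=moderation,
        design=design, n_dropped_missing=n_dropped,
    )
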