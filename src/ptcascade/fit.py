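"""Per-gene left-censored (Tobit) spline regression along pseudotime.

Each gene's expression is modeled as ``y = f(t) + eps`` where ``f`` is a
smooth function of pseudotime represented in a natural cubic spline
basis with a small fixed number of degrees of freedom, and ``eps`` is
Gaussian with observations at or below a censoring threshold ``c``
contributing a cumulative-probability term to the likelihood instead of
a density term.  Left-censoring reflects the floor that normalization
and dropout impose on low expression values: an observed value at the
floor only tells us the latent expression was at most the floor.

The log-likelihood maximized is

    sum_{y_i > c} [ log phi((y_i - mu_i)/sigma) - log sigma ]
  + sum_{y_i <= c} log Phi((c - mu_i)/sigma)

with ``mu = beta0 + B(t) beta``.  Temporal variation is tested with a
likelihood-ratio chi-square against the intercept-only censored model,
and p-values are Benjamini-Hochberg adjusted across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, PseudotimeOrdering

logger = logging.getLogger(__name__)

__all__ = [
    "SplineBasis",
    "TobitFit",
    "ScaledTrajectory",
    "build_spline_basis",
    "fit_tobit_spline",
    "test_temporal_variation",
    "adjust_bh",
    "scale_trajectory",
    "fit_all_genes",
]

#: lower bound below which the residual scale is considered collapsed
SIGMA_FLOOR = 1e-8


class SplineBasis:
    """Natural cubic spline basis with fixed degrees of freedom.

    Uses the classical truncated-power construction: with knots
    ``xi_1 < ... < xi_K`` placed at quantiles of the pseudotimes the
    basis was built on, the non-intercept columns are the linear term
    and ``N_k(x) = d_k(x) - d_{K-1}(x)`` for ``k = 1..K-2``, where
    ``d_k(x) = ((x - xi_k)_+^3 - (x - xi_K)_+^3) / (xi_K - xi_k)``.
    The curve is linear beyond the boundary knots.  ``df`` columns need
    ``K = df + 1`` knots; ``df = 1`` degenerates to a single centered
    linear column.  Deterministic given ``t`` and ``df``, evaluable at
    any new pseudotime.
    """

    def __init__(self, t: np.ndarray, df: int = 2):
        t = np.asarray(t, dtype=float)
        if df < 1:
            raise ValueError("df must be >= 1")
        n_distinct = np.unique(t).size
        if n_distinct < df + 2:
            raise ValueError(
                f"need at least {df + 2} distinct pseudotimes for df={df}, got {n_distinct}"
            )
        self.df = df
        self.t_min, self.t_max = float(t.min()), float(t.max())
        self._center = float(t.mean())
        self._scale = float(t.std()) or 1.0
        if df == 1:
            self.knots = np.array([])
        else:
            qs = np.linspace(0.0, 1.0, df + 1)
            knots = np.quantile(np.unique(t), qs)
            if np.unique(knots).size < df + 1:
                raise ValueError("degenerate spline design: coincident quantile knots")
            self.knots = knots
        self.matrix = self(t)
        if np.linalg.matrix_rank(self.matrix) < df:
            raise ValueError("degenerate spline design (rank-deficient basis)")

    def __call__(self, t_new: np.ndarray) -> np.ndarray:
        x = np.asarray(t_new, dtype=float)
        lin = (x - self._center) / self._scale
        if self.df == 1:
            return lin[:, None]
        K = self.knots
        h = (K[-1] - K[0]) or 1.0

        def d(k: float) -> np.ndarray:
            return (
                np.clip(x - k, 0.0, None) ** 3 - np.clip(x - K[-1], 0.0, None) ** 3
            ) / (K[-1] - k)

        d_last = d(K[-2])
        cols = [lin] + [(d(K[k]) - d_last) / h**2 for k in range(len(K) - 2)]
        return np.column_stack(cols)


def build_spline_basis(t: np.ndarray, df: int = 2) -> SplineBasis:
    """Construct the smooth basis used by the censored regression.

    The intercept is handled separately by the fitter; the returned
    basis has exactly ``df`` columns of full rank.
    """
    return SplineBasis(t, df)


@dataclass
class TobitFit:
    """Censored-regression fit of one gene along pseudotime."""

    gene_id: str
    basis: SplineBasis
    beta0: float
    beta: np.ndarray
    sigma: float
    censor: float
    loglik_full: float
    loglik_null: float
    pvalue: float
    converged: bool
    n_iter: int
    n_cells: int
    n_censored: int
    padj: float = field(default=np.nan)

    def predict(self, t: np.ndarray) -> np.ndarray:
        """Latent mean mu(t) = beta0 + B(t) beta at arbitrary pseudotimes."""
        return self.beta0 + self.basis(t) @ self.beta


@dataclass
class ScaledTrajectory:
    """Fitted latent mean standardized to mean 0 / sd 1 over a grid."""

    gene_id: str
    grid: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.grid.shape != self.x.shape:
            raise ValueError("grid and values must have equal length")


def _censored_negloglik_and_grad(
    theta: np.ndarray, X: np.ndarray, y: np.ndarray, c: float
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient in (beta0, beta, log sigma)."""
    beta = theta[:-1]
    log_sigma = np.clip(theta[-1], -30.0, 30.0)
    sigma = np.exp(log_sigma)
    mu = X @ beta
    cens = y <= c
    obs = ~cens

    r = (y[obs] - mu[obs]) / sigma
    ll_obs = -0.5 * r**2 - 0.5 * np.log(2 * np.pi) - log_sigma

    z = (c - mu[cens]) / sigma
    log_cdf = stats.norm.logcdf(z)
    ll = ll_obs.sum() + log_cdf.sum()

    grad = np.zeros_like(theta)
    # observed part
    grad[:-1] += X[obs].T @ (r / sigma)
    grad[-1] += np.sum(r**2 - 1.0)
    # censored part: inverse Mills ratio lambda = phi(z)/Phi(z)
    lam = np.exp(stats.norm.logpdf(z) - log_cdf)
    grad[:-1] += X[cens].T @ (-lam / sigma)
    grad[-1] += np.sum(-lam * z)
    return -ll, -grad


def _fit_censored(
    X: np.ndarray, y: np.ndarray, c: float, max_iter: int
) -> tuple[np.ndarray, float, float, bool, int]:
    """Maximize the censored-Gaussian likelihood; returns
    (beta, sigma, loglik, converged, n_iter)."""
    n, p = X.shape
    obs = y > c
    # least-squares init on uncensored points (all points if too few)
    X0, y0 = (X[obs], y[obs]) if obs.sum() > p else (X, y)
    beta_init, *_ = np.linalg.lstsq(X0, y0, rcond=None)
    resid = y0 - X0 @ beta_init
    sigma0 = float(np.sqrt(np.mean(resid**2)))
    sigma0 = max(sigma0, 1e-3)
    theta0 = np.concatenate([beta_init, [np.log(sigma0)]])

    res = optimize.minimize(
        _censored_negloglik_and_grad,
        theta0,
        args=(X, y, c),
        jac=True,
        method="BFGS",
        options={"maxiter": max_iter, "gtol": 1e-8},
    )
    beta = res.x[:-1]
    sigma = float(np.exp(np.clip(res.x[-1], -30.0, 30.0)))
    if sigma < SIGMA_FLOOR:
        raise FloatingPointError("residual scale collapsed below 1e-8")
    converged = bool(res.success) or float(np.linalg.norm(res.jac)) < 1e-4
    return beta, sigma, -float(res.fun), converged, int(res.nit)


def fit_tobit_spline(
    y: np.ndarray,
    basis: SplineBasis,
    c: float = 0.1,
    max_iter: int = 50,
    gene_id: str = "",
) -> TobitFit:
    """Fit the left-censored spline regression for one gene.

    Requires at least one uncensored observation (``y > c``); a fully
    censored gene carries no information about its latent trajectory.
    Non-convergence within ``max_iter`` iterations is recorded on the
    returned fit, not raised.
    """
    y = np.asarray(y, dtype=float)
    B = basis.matrix
    if y.shape[0] != B.shape[0]:
        raise ValueError("expression vector and basis have different lengths")
    if not np.any(y > c):
        raise ValueError(f"non-identifiable gene {gene_id!r}: all observations censored at {c}")
    X_full = np.column_stack([np.ones(len(y)), B])
    X_null = np.ones((len(y), 1))

    beta_f, sigma_f, ll_f, conv_f, it_f = _fit_censored(X_full, y, c, max_iter)
    beta_n, sigma_n, ll_n, conv_n, it_n = _fit_censored(X_null, y, c, max_iter)
    # nested models: full likelihood can never be below null
    ll_f = max(ll_f, ll_n)

    lam = max(0.0, 2.0 * (ll_f - ll_n))
    p = float(stats.chi2.sf(lam, basis.df)) if basis.df > 0 else 1.0

    return TobitFit(
        gene_id=gene_id,
        basis=basis,
        beta0=float(beta_f[0]),
        beta=np.asarray(beta_f[1:]),
        sigma=sigma_f,
        censor=c,
        loglik_full=ll_f,
        loglik_null=ll_n,
        pvalue=p,
        converged=conv_f and conv_n,
        n_iter=max(it_f, it_n),
        n_cells=len(y),
        n_censored=int(np.sum(y <= c)),
    )


def test_temporal_variation(
    y: np.ndarray, t: np.ndarray, c: float = 0.1, df: int = 2
) -> float:
    """Likelihood-ratio p-value for variation of a gene along pseudotime.

    The statistic is ``2 (loglik_full - loglik_null)`` (clipped at 0)
    referred to a chi-square with ``df`` degrees of freedom, the number
    of spline columns in the alternative.
    """
    if df == 0:
        return 1.0
    basis = build_spline_basis(np.asarray(t, dtype=float), df)
    return fit_tobit_spline(np.asarray(y, dtype=float), basis, c=c).pvalue


def adjust_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order of input preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def scale_trajectory(fit: TobitFit, grid: np.ndarray) -> ScaledTrajectory:
    """Standardize the fitted latent mean over ``grid`` to mean 0 / sd 1
    (population standard deviation over grid points)."""
    grid = np.asarray(grid, dtype=float)
    mu = fit.predict(grid)
    sd = float(np.std(mu))
    if sd < 1e-12 or not np.isfinite(sd):
        raise ValueError(f"constant fitted curve for gene {fit.gene_id!r}: cannot scale")
    return ScaledTrajectory(fit.gene_id, grid, (mu - mu.mean()) / sd)


def fit_all_genes(
    m: ExpressionMatrix,
    ordering: PseudotimeOrdering,
    alpha: float = 0.05,
    c: float = 0.1,
    df: int = 2,
    max_iter: int = 50,
    grid: np.ndarray | None = None,
) -> tuple[dict[str, TobitFit], dict[str, ScaledTrajectory]]:
    """Fit every gene of an aligned matrix, BH-adjust across genes, and
    return scaled trajectories for genes with ``padj < alpha``.

    Genes whose individual fit fails (fully censored, collapsed scale,
    constant fitted curve) are skipped with a logged warning and are
    excluded from the BH family.
    """
    t = np.asarray(ordering.pseudotime, dtype=float)
    if m.n_cells != len(ordering):
        raise ValueError("matrix must be aligned to the ordering first (align_cells)")
    if m.n_genes == 0:
        return {}, {}
    basis = build_spline_basis(t, df)
    eval_grid = t if grid is None else np.asarray(grid, dtype=float)

    fits: dict[str, TobitFit] = {}
    for gi, gene in enumerate(m.gene_ids):
        try:
            fits[gene] = fit_tobit_spline(m.values[gi], basis, c=c, max_iter=max_iter, gene_id=gene)
        except (ValueError, FloatingPointError) as exc:
            logger.warning("skipping gene %s: %s", gene, exc)
    if not fits:
        logger.warning("no gene could be fitted")
        return {}, {}

    genes = list(fits)
    padj = adjust_bh(np.array([fits[g].pvalue for g in genes]))
    for g, q in zip(genes, padj):
        fits[g].padj = float(q)

    scaled: dict[str, ScaledTrajectory] = {}
    for g in genes:
        if fits[g].padj < alpha:
            try:
                scaled[g] = scale_trajectory(fits[g], eval_grid)
            except ValueError as exc:
                logger.warning("dropping gene %s: %s", g, exc)
    if not scaled:
        logger.warning("no gene passed the significance filter (alpha=%g)", alpha)
    logger.info("fit_all_genes: %d fitted, %d significant at padj<%g", len(fits), len(scaled), alpha)
    return fits, scaled
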