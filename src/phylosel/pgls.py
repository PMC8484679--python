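"""Phylogenetic generalized least squares with ML Pagel's lambda.

The regression model is y = X b + e with e ~ N(0, sigma^2 * C_lambda),
where C is the Brownian among-species covariance of the phylogeny and
C_lambda multiplies its off-diagonal entries by lambda in [0, 1].  For a
fixed lambda the GLS estimates are

    b_hat = (X' C_lambda^-1 X)^-1 X' C_lambda^-1 y,

sigma^2 is profiled out analytically (ML value RSS_w / n, with RSS_w the
whitened residual sum of squares), and lambda is estimated by maximising
the resulting one-dimensional profile log-likelihood on [0, 1].

Standard errors, t and p values use the unbiased residual variance
RSS_w / (n - k) on n - k degrees of freedom, the standard GLS convention;
it reduces exactly to OLS when lambda = 0 or the tree is a star.  The
reported ``sigma2_ml`` is the ML profile value RSS_w / n that enters the
likelihood.

On ultrametric trees (constant diagonal of C) the lambda transform shares
C's eigenvectors, so the whole profile is computed from one eigendecomposition;
non-ultrametric trees fall back to a Cholesky factorisation per lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar

from .phylogeny import Phylogeny, lambda_transform

__all__ = [
    "PGLSFit",
    "SingularDesignError",
    "InsufficientDataError",
    "DegenerateResponseError",
    "gls_fit",
    "fit_lambda_ml",
    "pgls",
    "diagnostics",
]

_LOG2PI = np.log(2.0 * np.pi)


class SingularDesignError(ValueError):
    """Design matrix is rank deficient after casewise deletion."""


class InsufficientDataError(ValueError):
    """Too few complete rows to fit the requested model."""


class DegenerateResponseError(ValueError):
    """The response is constant (or otherwise uninformative)."""


@dataclass
class PGLSFit:
    """One fitted phylogenetic regression."""

    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    lambda_hat: float
    sigma2_ml: float
    loglik: float
    adj_r2: float
    n_used: int
    df_resid: int
    residuals: np.ndarray            # response scale, order of used rows
    fitted: np.ndarray
    whitened_residuals: np.ndarray   # C_lambda^{-1/2} residuals
    whitened_fitted: np.ndarray
    used_species: list[str] = field(default_factory=list)
    model: str = ""

    def summary(self) -> pd.DataFrame:
        """Per-term table mirroring the usual comparative-analysis layout."""
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        ).assign(
            lambda_hat=self.lambda_hat,
            adj_r2=self.adj_r2,
            n=self.n_used,
        )


class _LambdaProfile:
    """Profile machinery: whitening of (X, y) under C_lambda for any lambda."""

    def __init__(self, X: np.ndarray, y: np.ndarray, C: np.ndarray):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, float)
        self.C = np.asarray(C, float)
        self.n, self.k = self.X.shape
        d = np.diag(self.C)
        self.depth = float(d[0])
        # Ultrametric fast path: C_lambda = U diag(lam*w + (1-lam)*T) U'.
        self.ultrametric = bool(
            np.allclose(d, self.depth, rtol=1e-10, atol=1e-12 * max(self.depth, 1))
        )
        if self.ultrametric:
            w, U = np.linalg.eigh(self.C)
            self.w = w
            self.Xt = U.T @ self.X
            self.yt = U.T @ self.y

    def whiten(self, lam: float):
        """Return (X_w, y_w, logdet) with X_w = C_lambda^{-1/2} X."""
        if self.ultrametric:
            v = lam * self.w + (1.0 - lam) * self.depth
            if np.any(v <= 0):
                raise np.linalg.LinAlgError("singular lambda-covariance")
            s = 1.0 / np.sqrt(v)
            return self.Xt * s[:, None], self.yt * s, float(np.sum(np.log(v)))
        C_lam = lambda_transform(self.C, lam)
        L = np.linalg.cholesky(C_lam)
        Xw = solve_triangular(L, self.X, lower=True)
        yw = solve_triangular(L, self.y, lower=True)
        return Xw, yw, float(2.0 * np.sum(np.log(np.diag(L))))

    def solve(self, lam: float):
        """GLS solution at fixed lambda.

        Returns (params, XtX_inv, rss_w, logdet, resid_w, fitted_w).
        """
        Xw, yw, logdet = self.whiten(lam)
        XtX = Xw.T @ Xw
        if np.linalg.matrix_rank(XtX, tol=1e-10 * max(1.0, np.abs(XtX).max())) < self.k:
            raise SingularDesignError("design matrix is rank deficient")
        XtX_inv = np.linalg.inv(XtX)
        params = XtX_inv @ (Xw.T @ yw)
        fitted_w = Xw @ params
        resid_w = yw - fitted_w
        rss = float(resid_w @ resid_w)
        return params, XtX_inv, rss, logdet, resid_w, fitted_w

    def loglik(self, lam: float) -> float:
        _, _, rss, logdet, _, _ = self.solve(lam)
        sigma2 = max(rss / self.n, 1e-300)
        return -0.5 * (self.n * _LOG2PI + self.n * np.log(sigma2) + logdet + self.n)

    def loglik_reml(self, lam: float) -> float:
        """Restricted likelihood: integrates out the fixed effects."""
        Xw, yw, logdet = self.whiten(lam)
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        r = yw - Xw @ beta
        rss = float(r @ r)
        df = self.n - self.k
        sigma2 = max(rss / df, 1e-300)
        sign, logdet_xtx = np.linalg.slogdet(XtX)
        return -0.5 * (
            df * _LOG2PI + df * np.log(sigma2) + logdet + logdet_xtx + df
        )


def _finish_fit(
    prof: _LambdaProfile,
    lam: float,
    terms: list[str],
    species: list[str],
    model: str,
) -> PGLSFit:
    n, k = prof.n, prof.k
    params, XtX_inv, rss, logdet, resid_w, fitted_w = prof.solve(lam)
    df_resid = n - k
    if df_resid <= 0:
        raise InsufficientDataError("no residual degrees of freedom")
    sigma2_unb = rss / df_resid
    bse = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2_unb, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = params / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    sigma2_ml = rss / n
    loglik = -0.5 * (n * _LOG2PI + n * np.log(max(sigma2_ml, 1e-300)) + logdet + n)

    # Adjusted R^2 from whitened variables: null model is the GLS
    # intercept-only fit under the same C_lambda.
    Xw, yw, _ = prof.whiten(lam)
    has_intercept = any(np.allclose(prof.X[:, j], 1.0) for j in range(k))
    if has_intercept:
        ones_w, _, _ = _LambdaProfile(np.ones((n, 1)), prof.y, prof.C).whiten(lam)
        mu = float((ones_w[:, 0] @ yw) / (ones_w[:, 0] @ ones_w[:, 0]))
        tss = float(np.sum((yw - mu * ones_w[:, 0]) ** 2))
        n_pred = k - 1
    else:
        tss = float(yw @ yw)
        n_pred = k
    if tss <= 0:
        adj_r2 = np.nan
    else:
        r2 = 1.0 - rss / tss
        denom = n - n_pred - 1
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / denom if denom > 0 else np.nan

    fitted = prof.X @ params
    return PGLSFit(
        terms=list(terms),
        params=params,
        bse=bse,
        tvalues=np.asarray(tvals),
        pvalues=np.asarray(pvals),
        lambda_hat=float(lam),
        sigma2_ml=sigma2_ml,
        loglik=float(loglik),
        adj_r2=float(adj_r2),
        n_used=n,
        df_resid=df_resid,
        residuals=prof.y - fitted,
        fitted=fitted,
        whitened_residuals=np.asarray(resid_w),
        whitened_fitted=np.asarray(fitted_w),
        used_species=list(species),
        model=model,
    )


def _as_design(X, terms=None):
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if terms is None:
        terms = [f"x{j}" for j in range(X.shape[1])]
    return X, list(terms)


def gls_fit(
    X,
    y,
    C_lambda: np.ndarray,
    terms: list[str] | None = None,
    species: list[str] | None = None,
    model: str = "",
) -> PGLSFit:
    """GLS fit at a fixed error covariance (lambda already applied).

    ``C_lambda`` is used as the error correlation structure; the Brownian
    rate sigma^2 is profiled out.  ``lambda_hat`` on the returned fit is
    NaN since lambda was supplied implicitly through ``C_lambda``.
    """
    X, terms = _as_design(X, terms)
    y = np.asarray(y, float)
    C = np.asarray(C_lambda, float)
    if C.shape != (len(y), len(y)):
        raise ValueError("covariance shape does not match response length")
    prof = _LambdaProfile(X, y, C)
    fit = _finish_fit(prof, 1.0, terms, species or [], model)
    fit.lambda_hat = float("nan")
    return fit


def fit_lambda_ml(
    X,
    y,
    tree_or_C,
    terms: list[str] | None = None,
    species: list[str] | None = None,
    model: str = "",
    xatol: float = 1e-6,
    method: str = "ml",
) -> PGLSFit:
    """PGLS with Pagel's lambda estimated by maximum likelihood on [0, 1].

    The coefficients and sigma^2 are profiled out analytically at each
    lambda; the remaining one-dimensional profile likelihood is maximised
    by a coarse grid followed by bounded scalar search, so the reported
    optimum always dominates both endpoints.  Near-ties are broken toward
    the smaller lambda.  ``method='reml'`` maximises the restricted
    likelihood instead (exposed for comparison; ML is the default and the
    convention followed throughout the analysis).
    """
    X, terms = _as_design(X, terms)
    y = np.asarray(y, float)
    if y.size < 4:
        raise InsufficientDataError(f"need >= 4 usable species, got {y.size}")
    if np.ptp(y) == 0:
        raise DegenerateResponseError("response is constant")
    C = tree_or_C.vcv(species) if isinstance(tree_or_C, Phylogeny) else np.asarray(tree_or_C, float)
    prof = _LambdaProfile(X, y, C)
    if method not in ("ml", "reml"):
        raise ValueError(f"method must be 'ml' or 'reml', got {method!r}")
    objective = prof.loglik if method == "ml" else prof.loglik_reml

    grid = np.linspace(0.0, 1.0, 11)
    ll_grid = np.array([objective(l) for l in grid])
    i_best = int(np.argmax(ll_grid))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, len(grid) - 1)]
    candidates = [(float(l), float(ll)) for l, ll in zip(grid, ll_grid)]
    if hi > lo:
        res = minimize_scalar(
            lambda l: -objective(l),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": xatol},
        )
        candidates.append((float(np.clip(res.x, 0.0, 1.0)), float(-res.fun)))
    best_ll = max(ll for _, ll in candidates)
    # near-ties (within 1e-8 log-units) resolve to the smallest lambda
    lam_hat = min(l for l, ll in candidates if ll >= best_ll - 1e-8)
    return _finish_fit(prof, lam_hat, terms, species or [], model)


def _parse_model(model: str) -> tuple[str, list[str]]:
    if "~" not in model:
        raise ValueError(f"model must look like 'response ~ a + b', got {model!r}")
    lhs, rhs = model.split("~", 1)
    response = lhs.strip()
    predictors = [t.strip() for t in rhs.split("+") if t.strip() and t.strip() != "1"]
    if not response or not predictors:
        raise ValueError(f"model needs a response and >= 1 predictor: {model!r}")
    return response, predictors


def pgls(
    model: str,
    table: pd.DataFrame,
    tree: Phylogeny,
    lam: float | None = None,
) -> PGLSFit:
    """Fit ``response ~ predictor [+ predictor ...]`` on a species table.

    Rows with a missing value in any model variable are dropped (casewise
    deletion) before fitting; the species kept are recorded on the fit.
    ``lam=None`` estimates Pagel's lambda by ML, otherwise the given value
    is fixed.  The table index must hold species names matching tree tips.
    """
    response, predictors = _parse_model(model)
    cols = [response] + predictors
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise KeyError(f"model variables not in table: {missing_cols}")
    sub = table[cols].apply(pd.to_numeric, errors="coerce").dropna()
    if len(sub) < 4:
        raise InsufficientDataError(
            f"only {len(sub)} complete rows for model {model!r}; need >= 4"
        )
    species = list(sub.index)
    C = tree.vcv(species)
    y = sub[response].to_numpy(float)
    X = np.column_stack([np.ones(len(sub))] + [sub[p].to_numpy(float) for p in predictors])
    terms = ["Intercept"] + predictors
    if lam is None:
        return fit_lambda_ml(X, y, C, terms=terms, species=species, model=model)
    C_lam = lambda_transform(C, lam)
    prof = _LambdaProfile(X, y, C_lam)
    return _finish_fit(prof, 1.0, terms, species, model)


def diagnostics(fit: PGLSFit, plot_path: str | None = None) -> dict:
    """Residual checks on the phylogenetically whitened scale.

    Returns a Shapiro-Wilk normality statistic/p on the whitened residuals
    and a Spearman trend statistic of |whitened residual| against whitened
    fitted values (a scale-location check).  With ``plot_path`` a two-panel
    diagnostic figure (residuals vs fitted, normal QQ) is written.
    """
    r = fit.whitened_residuals
    f = fit.whitened_fitted
    if np.allclose(r, 0.0, atol=1e-12):
        out = {
            "shapiro_stat": 1.0,
            "shapiro_p": 1.0,
            "trend_rho": 0.0,
            "trend_p": 1.0,
            "exact_fit": True,
        }
    else:
        sw = stats.shapiro(r)
        if np.ptp(f) == 0:
            rho, rho_p = 0.0, 1.0
        else:
            rho, rho_p = stats.spearmanr(f, np.abs(r))
        out = {
            "shapiro_stat": float(sw.statistic),
            "shapiro_p": float(sw.pvalue),
            "trend_rho": float(rho),
            "trend_p": float(rho_p),
            "exact_fit": False,
        }
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
        axes[0].scatter(f, r, s=12)
        axes[0].axhline(0.0, lw=0.8, color="grey")
        axes[0].set_xlabel("whitened fitted")
        axes[0].set_ylabel("whitened residual")
        stats.probplot(r, dist="norm", plot=axes[1])
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        out["plot"] = plot_path
    return out
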