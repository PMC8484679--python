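"""Phylogenetic multiple imputation under a multivariate Brownian+lambda model.

Missing trait cells are treated as draws from a joint multivariate normal
over all (species, trait) cells: stacking the n-by-p trait matrix row-major,

    vec(X) ~ N(1_n (x) a,  C_lambda (x) R)

with ``a`` the per-trait root means, ``R`` the p-by-p cross-trait Brownian
rate covariance, ``C`` the tree's Brownian covariance, and a single common
Pagel's lambda rescaling C's off-diagonal.  The workflow mirrors standard
phylogenetic imputation practice:

1. :func:`fit_phylo_mvn` — ML parameters from the observed cells only
   (EM over (a, R) at fixed lambda, one-dimensional search over lambda);
2. :func:`impute_moments` — the conditional mean and variance of every
   missing cell given all observed cells (exact joint-normal conditioning);
3. :func:`draw_imputations` — m completed tables (default 10) with
   independent normal draws at those moments, observed cells untouched;
4. each completed table is analysed separately and :func:`pool_fits`
   reports the mean and SD of every fitted parameter across the m fits;
5. :func:`loo_reliability` — mask each observed cell in turn, re-impute
   it, and correlate imputed with true values per trait.

Species observed for only a subset of traits (auxiliary taxa) participate
in both fitting and conditioning, which is how extra literature species
sharpen the imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import pearsonr

from .pgls import PGLSFit
from .phylogeny import Phylogeny, lambda_transform

__all__ = [
    "PhyloMVNParams",
    "ImputationMoments",
    "ImputationSet",
    "PooledResult",
    "UnidentifiableTraitError",
    "ConditioningError",
    "IncompatibleFitsError",
    "fit_phylo_mvn",
    "impute_moments",
    "draw_imputations",
    "pool_fits",
    "loo_reliability",
]

_LOG2PI = np.log(2.0 * np.pi)


class UnidentifiableTraitError(ValueError):
    """A trait has too few observations to estimate its parameters."""


class ConditioningError(ValueError):
    """The observed-block covariance is singular."""


class IncompatibleFitsError(ValueError):
    """Fits being pooled do not share a model specification."""


@dataclass
class PhyloMVNParams:
    """ML parameters of the multivariate Brownian+lambda trait model.

    ``lam`` is normally a single common lambda (the default model, and the
    only one the fitter estimates); a per-trait vector is also accepted by
    the conditioning step, in which case off-diagonal species covariance of
    the (s, t) trait block is scaled by sqrt(lam_s * lam_t).
    """

    root_means: np.ndarray      # (p,)
    trait_cov: np.ndarray       # (p, p) Brownian rates per unit branch length
    lam: float | np.ndarray
    loglik: float
    trait_names: list[str]
    n_em_iter: int = 0


@dataclass
class ImputationMoments:
    """Conditional mean/variance of every missing cell given the observed."""

    species: list[str]          # per missing cell
    traits: list[str]
    cond_mean: np.ndarray
    cond_var: np.ndarray
    marginal_var: np.ndarray    # same cells, unconditional model variance

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "trait": self.traits,
                "cond_mean": self.cond_mean,
                "cond_var": self.cond_var,
                "marginal_var": self.marginal_var,
            }
        )


@dataclass
class ImputationSet:
    """m completed tables plus the moments and seeds that produced them."""

    tables: list[pd.DataFrame]
    moments: ImputationMoments
    seeds: list[int]
    m: int


@dataclass
class PooledResult:
    """Across-imputation mean and SD of every fitted model parameter."""

    table: pd.DataFrame
    m: int
    model: str = ""


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _prepare(table: pd.DataFrame, tree: Phylogeny):
    num = table.apply(pd.to_numeric, errors="coerce")
    X = num.to_numpy(float)
    n, p = X.shape
    obs = ~np.isnan(X)
    n_obs_per_trait = obs.sum(axis=0)
    empty = [c for c, k in zip(num.columns, n_obs_per_trait) if k == 0]
    if empty:
        raise UnidentifiableTraitError(f"traits with no observations: {empty}")
    C = tree.vcv(list(num.index))
    return num, X, obs, C


def _em_at_lambda(
    X: np.ndarray,
    obs: np.ndarray,
    C: np.ndarray,
    lam: float,
    a0: np.ndarray,
    R0: np.ndarray,
    max_iter: int,
    tol: float,
):
    """EM over (root means, trait covariance) at fixed lambda.

    Returns (a, R, observed-data loglik, n_iter).  The E-step conditions
    the missing cells on the observed ones under the current joint normal;
    the M-step is the complete-data GLS update with the usual trace
    correction from the conditional covariance.
    """
    n, p = X.shape
    C_lam = lambda_transform(C, lam)
    Cinv = np.linalg.inv(C_lam)
    w1 = Cinv.sum(axis=0)            # Cinv @ 1
    s11 = float(w1.sum())            # 1' Cinv 1
    flat_obs = obs.ravel()
    o_idx = np.flatnonzero(flat_obs)
    m_idx = np.flatnonzero(~flat_obs)
    x_flat = X.ravel().copy()
    x_o = x_flat[o_idx]
    mis_rows, mis_cols = np.divmod(m_idx, p)

    a, R = a0.copy(), R0.copy()
    ll_prev = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        Sigma = np.kron(C_lam, R)
        mu = np.tile(a, n)
        Soo = Sigma[np.ix_(o_idx, o_idx)]
        try:
            cf = cho_factor(Soo, lower=True)
        except np.linalg.LinAlgError as exc:
            raise ConditioningError(f"singular observed-block covariance: {exc}")
        r_o = x_o - mu[o_idx]
        alpha = cho_solve(cf, r_o)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        ll = -0.5 * (o_idx.size * _LOG2PI + logdet + float(r_o @ alpha))

        if m_idx.size:
            Smo = Sigma[np.ix_(m_idx, o_idx)]
            cond_mean = mu[m_idx] + Smo @ alpha
            cond_cov = Sigma[np.ix_(m_idx, m_idx)] - Smo @ cho_solve(cf, Smo.T)
            x_flat[m_idx] = cond_mean
        EX = x_flat.reshape(n, p)

        # M-step
        a = (EX.T @ w1) / s11
        D = EX - a[None, :]
        S = D.T @ Cinv @ D
        if m_idx.size:
            W = Cinv[np.ix_(mis_rows, mis_rows)] * cond_cov
            np.add.at(S, (mis_cols[:, None], mis_cols[None, :]), W)
        R_new = (S + S.T) / (2.0 * n)
        # keep strictly PD for the next Cholesky
        w, V = np.linalg.eigh(R_new)
        floor = max(w.max(), 1e-12) * 1e-10
        R = (V * np.clip(w, floor, None)) @ V.T

        if abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
            ll_prev = ll
            break
        ll_prev = ll
    return a, R, ll_prev, n_iter


def _init_params(X: np.ndarray, obs: np.ndarray, C: np.ndarray):
    n, p = X.shape
    depth = float(np.mean(np.diag(C)))
    a0 = np.array([np.nanmean(np.where(obs[:, j], X[:, j], np.nan)) for j in range(p)])
    R0 = np.zeros((p, p))
    for j in range(p):
        xj = X[obs[:, j], j]
        R0[j, j] = max(np.var(xj, ddof=1) if xj.size > 1 else 1.0, 1e-8) / depth
    return a0, R0


def fit_phylo_mvn(
    table: pd.DataFrame,
    tree: Phylogeny,
    lam: float | None = None,
    *,
    max_em_iter: int = 300,
    tol: float = 1e-8,
    lam_tol: float = 1e-3,
    min_obs_per_trait: int = 4,
) -> PhyloMVNParams:
    """ML fit of the joint Brownian+lambda model to a table with missing cells.

    The observed-data likelihood is maximised by EM over the root means and
    the trait covariance at fixed lambda, nested in a bounded scalar search
    over lambda on [0, 1] (skipped when ``lam`` is given).  Traits observed
    in fewer than ``min_obs_per_trait`` species are rejected as
    unidentifiable.
    """
    num, X, obs, C = _prepare(table, tree)
    thin = [c for c, k in zip(num.columns, obs.sum(axis=0)) if k < min_obs_per_trait]
    if thin:
        raise UnidentifiableTraitError(
            f"traits observed in < {min_obs_per_trait} species: {thin}"
        )
    a0, R0 = _init_params(X, obs, C)
    state = {"a": a0, "R": R0}

    def score(lam_val: float):
        a, R, ll, it = _em_at_lambda(
            X, obs, C, float(lam_val), state["a"], state["R"], max_em_iter, tol
        )
        state["a"], state["R"] = a, R  # warm start the next evaluation
        return a, R, ll, it

    if lam is not None:
        if not (0.0 <= lam <= 1.0):
            raise ValueError("lambda must be in [0, 1]")
        a, R, ll, it = score(lam)
        return PhyloMVNParams(a, R, float(lam), ll, list(num.columns), it)

    grid = np.linspace(0.0, 1.0, 6)
    evals: dict[float, tuple] = {}
    for l in grid:
        evals[float(l)] = score(l)
    best = max(evals, key=lambda l: evals[l][2])
    i = int(np.where(grid == best)[0][0])
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda l: -score(l)[2], bounds=(lo, hi), method="bounded",
        options={"xatol": lam_tol},
    )
    lam_cand = float(np.clip(res.x, 0.0, 1.0))
    evals[lam_cand] = score(lam_cand)
    best_ll = max(v[2] for v in evals.values())
    lam_hat = min(l for l, v in evals.items() if v[2] >= best_ll - 1e-8)
    a, R, ll, it = evals[lam_hat]
    return PhyloMVNParams(a, R, lam_hat, ll, list(num.columns), it)


# ---------------------------------------------------------------------------
# conditioning and draws
# ---------------------------------------------------------------------------

def _joint(params: PhyloMVNParams, C: np.ndarray, n: int):
    lam = params.lam
    if np.ndim(lam) == 0:
        Sigma = np.kron(lambda_transform(C, float(lam)), params.trait_cov)
    else:
        from .synthetic_data import _joint_covariance

        Sigma = _joint_covariance(C, params.trait_cov, np.asarray(lam, float))
    mu = np.tile(params.root_means, n)
    return Sigma, mu


def impute_moments(
    table: pd.DataFrame, tree: Phylogeny, params: PhyloMVNParams
) -> ImputationMoments:
    """Conditional mean and variance of every missing cell.

    Exact joint-normal conditioning of the missing block on all observed
    cells under the fitted (tree (x) trait) covariance.  Conditional
    variances never exceed the cell's marginal model variance.
    """
    num, X, obs, C = _prepare(table, tree)
    n, p = X.shape
    flat_obs = obs.ravel()
    o_idx = np.flatnonzero(flat_obs)
    m_idx = np.flatnonzero(~flat_obs)
    if m_idx.size == 0:
        raise ValueError("table has no missing cells to impute")
    Sigma, mu = _joint(params, C, n)
    Soo = Sigma[np.ix_(o_idx, o_idx)]
    try:
        cf = cho_factor(Soo, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(f"singular observed-block covariance: {exc}")
    r_o = X.ravel()[o_idx] - mu[o_idx]
    Smo = Sigma[np.ix_(m_idx, o_idx)]
    cond_mean = mu[m_idx] + Smo @ cho_solve(cf, r_o)
    cond_cov = Sigma[np.ix_(m_idx, m_idx)] - Smo @ cho_solve(cf, Smo.T)
    cond_var = np.clip(np.diag(cond_cov), 0.0, None)
    rows, cols = np.divmod(m_idx, p)
    return ImputationMoments(
        species=[num.index[i] for i in rows],
        traits=[num.columns[j] for j in cols],
        cond_mean=cond_mean,
        cond_var=cond_var,
        marginal_var=np.diag(Sigma)[m_idx].copy(),
    )


def draw_imputations(
    moments: ImputationMoments,
    table: pd.DataFrame,
    m: int = 10,
    seed: int = 0,
) -> ImputationSet:
    """m completed tables with independent normal draws at the cell moments.

    Observed cells are carried over untouched; each completed dataset uses
    its own child stream spawned deterministically from ``seed``.
    """
    if m < 2:
        raise ValueError("need m >= 2 completed datasets")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(m)]
    sd = np.sqrt(moments.cond_var)
    tables = []
    for cs in child_seeds:
        rng = np.random.default_rng(cs)
        filled = table.copy()
        draws = moments.cond_mean + sd * rng.standard_normal(sd.size)
        for sp, tr, val in zip(moments.species, moments.traits, draws):
            filled.loc[sp, tr] = val
        tables.append(filled)
    return ImputationSet(tables=tables, moments=moments, seeds=child_seeds, m=m)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

_POOLED_SCALARS = ("lambda_hat", "adj_r2", "n_used")


def pool_fits(fits: list[PGLSFit], rule: str = "moments") -> PooledResult:
    """Pool parameters across the m per-dataset fits.

    ``rule='moments'`` (default) reports the mean and sample SD (n-1) of
    every statistic — the across-imputation SD describes how much each
    reported value moves between completed datasets.  ``rule='rubin'``
    applies Rubin's rules instead: pooled estimate = mean, total variance =
    within + (1 + 1/m) between, t on Rubin's degrees of freedom.
    """
    if len(fits) < 1:
        raise IncompatibleFitsError("no fits to pool")
    terms0 = fits[0].terms
    model0 = fits[0].model
    for f in fits[1:]:
        if f.terms != terms0 or f.model != model0:
            raise IncompatibleFitsError(
                f"fits disagree on model: {f.model!r} vs {model0!r}"
            )
    if rule == "rubin":
        return _pool_rubin(fits, terms0, model0)
    if rule != "moments":
        raise ValueError(f"rule must be 'moments' or 'rubin', got {rule!r}")
    rows = []
    for j, term in enumerate(terms0):
        rec = {"term": term}
        for name, attr in (("estimate", "params"), ("se", "bse"),
                           ("t", "tvalues"), ("p", "pvalues")):
            vals = np.array([getattr(f, attr)[j] for f in fits], float)
            rec[f"{name}_mean"] = vals.mean()
            rec[f"{name}_sd"] = vals.std(ddof=1) if len(fits) > 1 else 0.0
        for scal in _POOLED_SCALARS:
            vals = np.array([getattr(f, scal) for f in fits], float)
            rec[f"{scal}_mean"] = vals.mean()
            rec[f"{scal}_sd"] = vals.std(ddof=1) if len(fits) > 1 else 0.0
        rows.append(rec)
    return PooledResult(table=pd.DataFrame(rows), m=len(fits), model=model0)


def _pool_rubin(fits: list[PGLSFit], terms: list[str], model: str) -> PooledResult:
    from scipy import stats as _st

    m = len(fits)
    rows = []
    for j, term in enumerate(terms):
        q = np.array([f.params[j] for f in fits], float)
        u = np.array([f.bse[j] ** 2 for f in fits], float)
        qbar = q.mean()
        ubar = u.mean()
        b = q.var(ddof=1) if m > 1 else 0.0
        total = ubar + (1.0 + 1.0 / m) * b
        se = np.sqrt(total)
        if b > 0:
            df = (m - 1) * (1.0 + ubar / ((1.0 + 1.0 / m) * b)) ** 2
        else:
            df = np.inf
        t = qbar / se if se > 0 else np.nan
        p = 2.0 * _st.t.sf(abs(t), df) if np.isfinite(df) else \
            2.0 * _st.norm.sf(abs(t))
        rows.append({"term": term, "estimate": qbar, "se": se, "t": t,
                     "p": p, "df": df, "between_var": b, "within_var": ubar})
    return PooledResult(table=pd.DataFrame(rows), m=m, model=model)


# ---------------------------------------------------------------------------
# leave-one-out reliability
# ---------------------------------------------------------------------------

def loo_reliability(
    table: pd.DataFrame,
    tree: Phylogeny,
    params: PhyloMVNParams,
    *,
    refit: bool = False,
    min_obs: int = 5,
) -> dict[str, float]:
    """Per-trait correlation between held-out observed values and imputations.

    Each observed cell is masked in turn, its conditional mean given every
    other observed cell is recomputed, and the Pearson correlation between
    original and imputed values is reported per trait.  By default the
    model parameters fitted once on all data are re-used for every deletion
    (conditioning only); ``refit=True`` refits the model per deletion — the
    exact but n-times costlier reading of the check.
    """
    num, X, obs, C = _prepare(table, tree)
    n, p = X.shape
    flat_obs = obs.ravel()
    o_idx = np.flatnonzero(flat_obs)
    x_o = X.ravel()[o_idx]
    rows, cols = np.divmod(o_idx, p)

    if refit:
        preds = np.empty(o_idx.size)
        for k in range(o_idx.size):
            holed = num.copy()
            holed.iloc[rows[k], cols[k]] = np.nan
            pk = fit_phylo_mvn(holed, tree, lam=params.lam)
            mom = impute_moments(holed, tree, pk)
            sel = [
                t for t, (sp, tr) in enumerate(zip(mom.species, mom.traits))
                if sp == num.index[rows[k]] and tr == num.columns[cols[k]]
            ]
            preds[k] = mom.cond_mean[sel[0]]
    else:
        Sigma, mu = _joint(params, C, n)
        Soo = Sigma[np.ix_(o_idx, o_idx)]
        try:
            cf = cho_factor(Soo, lower=True)
        except np.linalg.LinAlgError as exc:
            raise ConditioningError(f"singular observed-block covariance: {exc}")
        Lam = cho_solve(cf, np.eye(o_idx.size))   # precision of observed block
        r = x_o - mu[o_idx]
        g = Lam @ r
        # conditional mean of cell k given all other observed cells
        preds = x_o - g / np.diag(Lam)

    out: dict[str, float] = {}
    for j, trait in enumerate(num.columns):
        sel = cols == j
        if sel.sum() < min_obs:
            continue
        truth = x_o[sel]
        if np.ptp(truth) == 0:
            raise ValueError(f"trait {trait!r} is constant: correlation undefined")
        out[trait] = float(pearsonr(truth, preds[sel])[0])
    return out
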