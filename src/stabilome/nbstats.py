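"""Negative-binomial count statistics.

Building blocks for all differential tests in the package: median-of-ratios
size factors, per-gene dispersion estimation with a gamma-regression
mean-dispersion trend, NB GLM fitting with a log link and fixed dispersion
(IRLS with a direct-optimisation fallback), likelihood-ratio tests and
Benjamini-Hochberg adjustment.

The NB parameterisation throughout is variance = mu + k * mu^2, i.e. ``k``
is the dispersion (alpha) and 1/k the NB size parameter.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import chi2

from .counts_io import Arm, CountMatrix, ExpressionMatrix, ExpressionUnit, SampleSheet

__all__ = [
    "DISPERSION_FLOOR",
    "DISPERSION_CEILING",
    "GlmFit",
    "DispersionModel",
    "size_factors",
    "normalized_counts",
    "nb_loglik",
    "fit_nb_glm",
    "fit_nb_glm_batch",
    "estimate_raw_dispersions",
    "fit_dispersion_trend",
    "estimate_dispersion",
    "lrt",
    "bh_adjust",
    "two_group_test",
]

DISPERSION_FLOOR = 1e-8
DISPERSION_CEILING = 10.0

_MU_FLOOR = 1e-10
_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors(counts: CountMatrix | pd.DataFrame,
                 allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean across all libraries,
    restricted to genes with positive counts in every sample.  If no such
    gene exists, an error advises the ``allow_pseudo_reference`` fallback,
    which computes geometric means over the positive entries of genes
    expressed in at least half of the samples.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] == 0:
        raise ValueError("no samples")
    vals = df.to_numpy(dtype=float)
    all_pos = np.all(vals > 0, axis=1)
    if all_pos.any():
        logc = np.log(vals[all_pos])
        ref = logc.mean(axis=1)
        logf = np.median(logc - ref[:, None], axis=0)
    elif allow_pseudo_reference:
        pos_frac = (vals > 0).mean(axis=1)
        use = pos_frac >= 0.5
        if not use.any():
            raise ValueError("no gene expressed in at least half the samples")
        sub = vals[use]
        with np.errstate(divide="ignore"):
            logc = np.where(sub > 0, np.log(sub), np.nan)
        ref = np.nanmean(logc, axis=1)
        ratios = logc - ref[:, None]
        logf = np.nanmedian(ratios, axis=0)
    else:
        raise ValueError(
            "no gene has positive counts in all samples; re-run with "
            "allow_pseudo_reference=True to use a pseudo-reference built "
            "from genes expressed in at least half of the libraries"
        )
    logf = logf - logf.mean()
    return pd.Series(np.exp(logf), index=df.columns, name="size_factor")


def normalized_counts(counts: CountMatrix, sf: pd.Series) -> ExpressionMatrix:
    """Counts divided by their library size factor."""
    df = counts.counts.div(sf.loc[counts.sample_ids], axis=1)
    return ExpressionMatrix(df, ExpressionUnit.NORM_COUNTS)


# ---------------------------------------------------------------------------
# NB log-likelihood and GLM fitting
# ---------------------------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray | float) -> np.ndarray:
    """Elementwise NB log-likelihood with variance mu + alpha*mu^2."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _MU_FLOOR)
    alpha = np.maximum(np.asarray(alpha, dtype=float), DISPERSION_FLOOR)
    r = 1.0 / alpha
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))


@dataclass
class GlmFit:
    """Result of a fixed-dispersion NB GLM fit with log link."""

    coef: np.ndarray
    mu: np.ndarray
    loglik: float
    n_params: int
    converged: bool
    design_names: tuple[str, ...] | None = None


def fit_nb_glm_batch(Y: np.ndarray, X: np.ndarray, alpha: np.ndarray,
                     offset: np.ndarray, max_iter: int = 100,
                     tol: float = 1e-8) -> dict:
    """Fit one NB GLM per row of ``Y`` against a shared design matrix.

    Parameters
    ----------
    Y : (G, n) counts, one gene per row.
    X : (n, p) design matrix, full column rank.
    alpha : (G,) per-gene dispersions (> 0).
    offset : (n,) or (G, n) log offsets (log size factors).

    Returns a dict with ``coef`` (G, p), ``mu`` (G, n), ``loglik`` (G,),
    ``converged`` (G,) boolean and ``n_params``.

    IRLS with step-halving; convergence when the log-likelihood change
    falls below ``tol * (1 + |loglik|)``.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    G, n = Y.shape
    p = X.shape[1]
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (G,)).copy()
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    off = np.broadcast_to(np.asarray(offset, dtype=float), (G, n))

    mu = np.maximum(Y, 0.5)
    eta = np.log(mu)
    beta = np.zeros((G, p))
    # starting values are not in model space; accept the first IRLS step
    ll = np.full(G, -np.inf)
    converged = np.zeros(G, dtype=bool)
    eye = np.eye(p) * 1e-10

    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - off) + (Y - mu) / np.maximum(mu, _MU_FLOOR)
        A = np.einsum("ni,gn,nj->gij", X, w, X) + eye
        b = np.einsum("ni,gn->gi", X, w * z)
        try:
            beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.stack([np.linalg.lstsq(A[g], b[g], rcond=None)[0]
                                 for g in range(G)])
        # step-halving for genes whose likelihood would decrease
        step = np.ones(G)
        for _half in range(12):
            trial = beta + step[:, None] * (beta_new - beta)
            eta_t = np.clip(off + trial @ X.T, -_ETA_CLIP, _ETA_CLIP)
            mu_t = np.exp(eta_t)
            ll_t = nb_loglik(Y, mu_t, alpha[:, None]).sum(axis=1)
            worse = active & (ll_t < ll - 1e-10)
            if not worse.any():
                break
            step[worse] *= 0.5
        improve = active & (ll_t >= ll - 1e-10)
        beta[improve] = trial[improve]
        eta[improve] = eta_t[improve]
        mu[improve] = mu_t[improve]
        delta = np.abs(ll_t - ll)
        ll[improve] = ll_t[improve]
        converged |= active & (delta < tol * (1.0 + np.abs(ll)))

    degenerate = Y.sum(axis=1) == 0
    converged = converged & ~degenerate
    return {"coef": beta, "mu": mu, "loglik": ll,
            "converged": converged, "n_params": p}


def _fit_numeric(y: np.ndarray, X: np.ndarray, alpha: float,
                 offset: np.ndarray, beta0: np.ndarray) -> tuple[np.ndarray, float]:
    """Direct Nelder-Mead maximization, used as an IRLS fallback."""
    def neg(beta):
        eta = np.clip(offset + X @ beta, -_ETA_CLIP, _ETA_CLIP)
        return -nb_loglik(y, np.exp(eta), alpha).sum()

    res = optimize.minimize(neg, beta0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-10,
                                     "fatol": 1e-12})
    return res.x, -res.fun


def fit_nb_glm(y: np.ndarray, X: np.ndarray, alpha: float,
               offset: np.ndarray | None = None,
               design_names: Sequence[str] | None = None,
               max_iter: int = 100, tol: float = 1e-8) -> GlmFit:
    """Fit a single NB GLM (log link, fixed dispersion).

    Falls back to direct numeric maximization if IRLS does not converge.
    All-zero responses yield a flagged degenerate fit.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("responses must be non-negative integers")
    if float(alpha) <= 0:
        raise ValueError("dispersion must be positive")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if offset is None:
        offset = np.zeros(len(y))
    offset = np.asarray(offset, dtype=float)

    res = fit_nb_glm_batch(y[None, :], X, np.array([alpha]), offset,
                           max_iter=max_iter, tol=tol)
    coef, mu = res["coef"][0], res["mu"][0]
    ll = float(res["loglik"][0])
    converged = bool(res["converged"][0])
    if not converged and y.sum() > 0:
        coef_n, ll_n = _fit_numeric(y, X, float(alpha), offset, coef)
        if ll_n >= ll - 1e-9:
            coef, ll = coef_n, ll_n
            mu = np.exp(np.clip(offset + X @ coef, -_ETA_CLIP, _ETA_CLIP))
            converged = True
    return GlmFit(coef=coef, mu=np.maximum(mu, _MU_FLOOR), loglik=ll,
                  n_params=X.shape[1], converged=converged,
                  design_names=tuple(design_names) if design_names else None)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def _group_profile_loglik(Yg: list[np.ndarray], sfg: list[np.ndarray],
                          log_alpha: np.ndarray, cr_adjust: bool) -> np.ndarray:
    """Profile log-likelihood at given per-gene log dispersions.

    Group means are profiled out by Newton iteration on the per-group
    scaled mean; optionally Cox-Reid adjusted (-0.5 log det X'WX, which is
    diagonal for a group-indicator design).
    """
    a = np.exp(log_alpha)
    ll = np.zeros(a.shape[0])
    for y, s in zip(Yg, sfg):
        # y: (G, r) counts of one group; s: (r,) size factors
        q = np.maximum(y.sum(axis=1) / s.sum(), 1e-8)
        logq = np.log(q)
        for _ in range(8):
            mu = np.exp(logq)[:, None] * s
            denom = 1.0 + a[:, None] * mu
            f = ((y - mu) / denom).sum(axis=1)
            fp = -(mu * (1.0 + a[:, None] * y) / denom**2).sum(axis=1)
            step = np.clip(f / np.where(np.abs(fp) > 1e-12, fp, -1e-12), -5, 5)
            logq = logq - step
        mu = np.exp(logq)[:, None] * s
        ll += nb_loglik(y, mu, a[:, None]).sum(axis=1)
        if cr_adjust:
            w = mu / (1.0 + a[:, None] * mu)
            ll -= 0.5 * np.log(np.maximum(w.sum(axis=1), 1e-300))
    return ll


def estimate_raw_dispersions(counts_df: pd.DataFrame,
                             groups: Sequence[Sequence[str]],
                             sf: pd.Series,
                             cr_adjust: bool = True,
                             n_iter: int = 45) -> pd.Series:
    """Per-gene ML dispersion under a saturated group-mean NB model.

    ``groups`` is a list of sample-id lists, one per design cell; means are
    profiled out per cell.  The likelihood is maximized over log dispersion
    in [floor, ceiling] by golden-section search, vectorized over genes.
    Cox-Reid adjustment (on by default) removes most of the downward bias
    from estimating one mean per cell.
    """
    Yg = [counts_df[list(g)].to_numpy(dtype=float) for g in groups]
    sfg = [sf.loc[list(g)].to_numpy(dtype=float) for g in groups]
    G = counts_df.shape[0]

    lo = np.full(G, np.log(DISPERSION_FLOOR))
    hi = np.full(G, np.log(DISPERSION_CEILING))
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1 = _group_profile_loglik(Yg, sfg, x1, cr_adjust)
    f2 = _group_profile_loglik(Yg, sfg, x2, cr_adjust)
    for _ in range(n_iter):
        take1 = f1 >= f2  # keep the half containing the larger value
        hi = np.where(take1, x2, hi)
        lo = np.where(take1, lo, x1)
        x1 = hi - invphi * (hi - lo)
        x2 = lo + invphi * (hi - lo)
        f1 = _group_profile_loglik(Yg, sfg, x1, cr_adjust)
        f2 = _group_profile_loglik(Yg, sfg, x2, cr_adjust)
    raw = np.exp(0.5 * (lo + hi))
    return pd.Series(raw, index=counts_df.index, name="raw_dispersion")


@dataclass
class DispersionModel:
    """Raw per-gene dispersions plus the fitted mean-dispersion trend.

    The trend is a gamma regression E[k] = a0 + a1 / mean; the final
    dispersion used in GLM fits is the floored trend prediction.
    """

    raw: pd.Series
    fitted: pd.Series
    trend_coef: tuple[float, float]
    base_mean: pd.Series
    floor: float = DISPERSION_FLOOR

    def predict(self, mean: np.ndarray | float) -> np.ndarray:
        a0, a1 = self.trend_coef
        pred = a0 + a1 / np.maximum(np.asarray(mean, dtype=float), 1e-8)
        return np.clip(pred, self.floor, DISPERSION_CEILING)


def fit_dispersion_trend(raw: pd.Series, base_mean: pd.Series,
                         trim_fold: float = 1e4,
                         max_trim_iter: int = 10) -> tuple[float, float]:
    """Gamma regression of raw dispersions on 1/mean with outlier trimming.

    Fits E[k] = a0 + a1/mean by a Gamma GLM (identity link); points more
    than ``trim_fold``-fold away from the current trend are dropped and the
    fit repeated, up to ``max_trim_iter`` rounds.
    """
    import statsmodels.api as sm

    mask = (raw.to_numpy() > 10 * DISPERSION_FLOOR) & (base_mean.to_numpy() > 0)
    if mask.sum() < 10:
        # too few informative genes for a regression: constant trend
        warnings.warn(
            f"only {int(mask.sum())} usable raw dispersions; falling back "
            "to a constant dispersion trend"
        )
        fallback = float(np.median(raw.to_numpy()[mask])) if mask.any() \
            else DISPERSION_FLOOR
        return max(fallback, DISPERSION_FLOOR), 0.0
    k = raw.to_numpy()[mask]
    m = base_mean.to_numpy()[mask]
    use = np.ones(k.shape[0], dtype=bool)
    coef = np.array([np.median(k), 0.0])
    log_tf = np.log(trim_fold)
    for _ in range(max_trim_iter):
        X = np.column_stack([np.ones(use.sum()), 1.0 / m[use]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = sm.GLM(k[use], X,
                               family=sm.families.Gamma(sm.families.links.Identity()))
                fit = model.fit(start_params=np.maximum(coef, [1e-6, 0.0]),
                                maxiter=200)
                coef = fit.params
            except Exception as exc:  # pragma: no cover - diagnostics path
                raise RuntimeError(
                    f"gamma regression for the dispersion trend failed: {exc}"
                ) from exc
        pred = np.maximum(coef[0] + coef[1] / m, DISPERSION_FLOOR)
        keep = np.abs(np.log(k) - np.log(pred)) < log_tf
        if keep.sum() < 10 or np.array_equal(keep, use):
            break
        use = keep
    a0 = float(max(coef[0], 0.0))
    a1 = float(max(coef[1], 0.0))
    if a0 <= DISPERSION_FLOOR and a1 <= 0.0:
        a0 = float(np.median(k))
    return a0, a1


def estimate_dispersion(counts: CountMatrix | pd.DataFrame,
                        sheet: SampleSheet, sf: pd.Series,
                        cr_adjust: bool = True) -> DispersionModel:
    """Raw dispersions per gene plus gamma-regression trend.

    Design cells are the (arm, time) groups of the sheet; at least one cell
    must contain >= 2 replicates or dispersion is unidentifiable.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    cells = sheet.table.groupby(["arm", "time_h"])["sample_id"].agg(list)
    groups = [g for g in cells if len(g) >= 2 and set(g) <= set(df.columns)]
    if not groups:
        raise ValueError(
            "dispersion is unidentifiable: no (arm, time) cell has >= 2 "
            "replicates among the supplied samples"
        )
    used = [s for g in groups for s in g]
    raw = estimate_raw_dispersions(df, groups, sf, cr_adjust=cr_adjust)
    base_mean = df[used].div(sf.loc[used], axis=1).mean(axis=1)
    a0, a1 = fit_dispersion_trend(raw, base_mean)
    fitted = pd.Series(
        np.clip(a0 + a1 / np.maximum(base_mean.to_numpy(), 1e-8),
                DISPERSION_FLOOR, DISPERSION_CEILING),
        index=df.index, name="dispersion")
    return DispersionModel(raw=raw, fitted=fitted, trend_coef=(a0, a1),
                           base_mean=base_mean)


# ---------------------------------------------------------------------------
# testing
# ---------------------------------------------------------------------------

def lrt(loglik_null: float, loglik_alt: float, df: int = 1,
        tol: float = 1e-6) -> tuple[float, float]:
    """Likelihood-ratio statistic and chi^2 upper-tail p-value.

    Statistics that are negative within ``tol`` are clipped to 0; larger
    negatives indicate a failed alternative fit and raise.
    """
    stat = 2.0 * (loglik_alt - loglik_null)
    if stat < -tol:
        raise ValueError(
            f"alternative log-likelihood below null by {-stat / 2:.3g}; "
            "refit before testing"
        )
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, df))


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def two_group_test(counts_df: pd.DataFrame, samples_ref: Sequence[str],
                   samples_alt: Sequence[str], sf: pd.Series,
                   dispersion: pd.Series | None = None,
                   pseudocount: float = 0.5) -> pd.DataFrame:
    """NB GLM two-group LRT (df = 1) for every gene of ``counts_df``.

    Returns a frame with ``log2fc`` (alt vs ref, pseudocount-stabilized
    normalized means), ``stat``, ``pvalue``, ``padj`` and ``converged``.
    If no ``dispersion`` is given, one is estimated from the two groups.
    """
    ref = list(samples_ref)
    alt = list(samples_alt)
    if len(ref) < 2 or len(alt) < 2:
        raise ValueError("each group needs >= 2 replicates")
    sub = counts_df[ref + alt]
    sfv = sf.loc[ref + alt]
    if dispersion is None:
        raw = estimate_raw_dispersions(sub, [ref, alt], sfv)
        base_mean = sub.div(sfv, axis=1).mean(axis=1)
        a0, a1 = fit_dispersion_trend(raw, base_mean)
        dispersion = pd.Series(
            np.clip(a0 + a1 / np.maximum(base_mean.to_numpy(), 1e-8),
                    DISPERSION_FLOOR, DISPERSION_CEILING), index=sub.index)

    n = len(ref) + len(alt)
    X_alt = np.column_stack([np.ones(n),
                             np.r_[np.zeros(len(ref)), np.ones(len(alt))]])
    X_null = X_alt[:, :1]
    Y = sub.to_numpy(dtype=float)
    offs = np.log(sfv.to_numpy(dtype=float))
    alpha = dispersion.loc[sub.index].to_numpy(dtype=float)

    fit0 = fit_nb_glm_batch(Y, X_null, alpha, offs)
    fit1 = fit_nb_glm_batch(Y, X_alt, alpha, offs)
    stat = np.maximum(2.0 * (fit1["loglik"] - fit0["loglik"]), 0.0)
    pval = chi2.sf(stat, 1)
    norm = sub.div(sfv, axis=1)
    log2fc = np.log2((norm[alt].mean(axis=1) + pseudocount)
                     / (norm[ref].mean(axis=1) + pseudocount))
    out = pd.DataFrame({
        "log2fc": log2fc,
        "stat": stat,
        "pvalue": pval,
        "padj": bh_adjust(pval),
        "converged": fit0["converged"] & fit1["converged"],
    }, index=sub.index)
    out.index.name = "gene_id"
    return out
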