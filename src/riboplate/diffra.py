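"""Differential ribosome association via a negative-binomial interaction LRT.

For one drug condition versus vehicle control, the ribo and total libraries
of the selected wells are stacked into a single sample-by-gene count matrix
and each gene is fit with a log-link NB GLM:

    full:    ~ condition + type + condition:type
    reduced: ~ condition + type

with log size factors as offsets and NB variance ``mu + alpha * mu**2``.
The interaction coefficient is the change, between conditions, in the log
ratio of ribo to total counts — i.e. differential ribosome association
(lfcRA, reported on the log2 scale). Significance comes from a likelihood
ratio test against chi-square with 1 df, adjusted per contrast by
Benjamini-Hochberg.

Dispersion is estimated per gene by Cox-Reid-adjusted profile likelihood on
fitted means, a robust ``a0 + a1/mean`` trend is fit across genes, and the
final dispersion is a weighted geometric mean of the gene estimate and the
trend (moderation weight 0.5 by default), floored at ``ALPHA_FLOOR``.

All fitting is implemented here directly (batched IRLS / Newton scoring
across genes); no external GLM library is involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .plateio import GeneAnno, PairedCounts, PlateMeta
from .ranorm import size_factors

logger = logging.getLogger(__name__)

ALPHA_FLOOR = 1e-8
IRLS_TOL = 1e-8
IRLS_MAXIT = 100
RIDGE = 1e-6


class DesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# likelihood and batched IRLS
# ---------------------------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha) -> np.ndarray:
    """NB log-likelihood summed over the last axis; alpha=0 is the Poisson limit.

    ``alpha`` may be scalar or broadcastable against ``y`` / ``mu``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    alpha = np.asarray(alpha, dtype=float)
    alpha_b = np.broadcast_to(alpha, np.broadcast_shapes(alpha.shape, y.shape))
    pois = y * np.log(mu) - mu - gammaln(y + 1)
    out = np.where(alpha_b < 1e-12, pois, 0.0)
    nbmask = alpha_b >= 1e-12
    if np.any(nbmask):
        a = np.where(nbmask, alpha_b, 1.0)
        r = 1.0 / a
        nb = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
        out = np.where(nbmask, nb, out)
    return out.sum(axis=-1)


def _batch_irls(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    ridge: float = 0.0,
    tol: float = IRLS_TOL,
    maxit: int = IRLS_MAXIT,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fisher-scoring NB GLM fits for all genes at once.

    Y: (G, n) counts; X: (n, p) shared design; offset: (n,); alpha: (G,).
    Returns (beta (G, p) natural-log scale, loglik (G,), converged (G,)).
    Convergence: max |score component| < tol. A small ridge penalty
    stabilizes separated fits (all-zero design cells).
    """
    Y = np.asarray(Y, dtype=float)
    G, n = Y.shape
    p = X.shape[1]
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (G,)).copy()

    # init from least squares on shifted-log response
    z0 = np.log(Y + 0.5) - offset[None, :]
    beta = z0 @ np.linalg.pinv(X).T

    eye = np.eye(p) * max(ridge, 1e-12)
    active = np.ones(G, dtype=bool)
    converged = np.zeros(G, dtype=bool)

    def _mu(b):
        eta = np.clip(b @ X.T + offset[None, :], -50, 50)
        return np.exp(eta)

    def _ll(b, idx):
        mu = _mu(b)
        ll = nb_loglik(Y[idx], mu, alpha[idx][:, None])
        if ridge > 0:
            ll = ll - 0.5 * ridge * np.sum(b**2, axis=1)
        return ll

    for _ in range(maxit):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        b = beta[idx]
        a = alpha[idx][:, None]
        mu = _mu(b)
        denom = 1.0 + a * mu
        score = ((Y[idx] - mu) / denom) @ X
        if ridge > 0:
            score = score - ridge * b
        done = np.max(np.abs(score), axis=1) < tol
        converged[idx[done]] = True
        active[idx[done]] = False
        work = ~done
        if not np.any(work):
            continue
        sub = idx[work]
        b = b[work]
        W = (mu / denom)[work]
        info = np.einsum("gn,ni,nj->gij", W, X, X) + eye[None, :, :]
        try:
            delta = np.linalg.solve(info, score[work][:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            delta = np.einsum(
                "gij,gj->gi", np.linalg.pinv(info), score[work]
            )
        ll_old = _ll(b, sub)
        step = delta
        b_new = b + step
        for _half in range(6):
            ll_new = _ll(b_new, sub)
            worse = ll_new < ll_old - 1e-10
            if not np.any(worse):
                break
            step = np.where(worse[:, None], step * 0.5, step)
            b_new = b + step
        beta[sub] = b_new

    mu = _mu(beta)
    ll = nb_loglik(Y, mu, alpha[:, None])
    return beta, ll, converged


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    alpha: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Fit one NB GLM (log link, fixed dispersion); returns (beta, loglik).

    Coefficients are on the natural-log scale. If the plain fit does not
    converge (e.g. a design cell is all zero), a ridge-penalized fit is
    used as a fallback and a warning is logged.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    if alpha < 0:
        raise DesignError("alpha must be nonnegative")
    off = np.zeros(X.shape[0]) if offset is None else np.asarray(offset, dtype=float)
    beta, ll, conv = _batch_irls(y, X, off, np.array([alpha]))
    if not conv[0]:
        logger.warning("NB GLM did not converge; retrying with ridge penalty")
        beta, ll, conv = _batch_irls(y, X, off, np.array([alpha]), ridge=RIDGE)
    return beta[0], float(ll[0])


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionFit:
    """Per-gene raw dispersions, the fitted trend, and moderated values."""

    alpha_mle: np.ndarray
    alpha_trend: np.ndarray
    alpha_moderated: np.ndarray
    trend_coefficients: tuple[float, float]  # (a0, a1) in alpha(m) = a0 + a1/m
    mean_norm: np.ndarray


def _alpha_grid_mle(
    Y: np.ndarray, mu: np.ndarray, X: np.ndarray, cr_adjust: bool = True
) -> np.ndarray:
    """Per-gene profile-ML dispersion on a log grid with Cox-Reid adjustment.

    ``mu`` holds fitted means (G, n). The CR term subtracts
    0.5 * logdet(X' W X) with W = mu / (1 + alpha mu), reducing the downward
    bias of plug-in ML dispersion estimates at small sample sizes.
    """
    grid = np.concatenate([[ALPHA_FLOOR], np.geomspace(1e-6, 30.0, 80)])
    G = Y.shape[0]
    ll = np.empty((G, grid.size))
    for k, a in enumerate(grid):
        ll[:, k] = nb_loglik(Y, mu, a)
        if cr_adjust:
            W = mu / (1.0 + a * mu)
            info = np.einsum("gn,ni,nj->gij", W, X, X)
            sign, logdet = np.linalg.slogdet(info)
            bad = sign <= 0
            logdet = np.where(bad, 0.0, logdet)
            ll[:, k] -= 0.5 * logdet
    best = np.argmax(ll, axis=1)
    alpha_hat = grid[best]
    # quadratic refinement in log-alpha where the max is interior
    interior = (best > 0) & (best < grid.size - 1)
    if np.any(interior):
        i = best[interior]
        g = np.flatnonzero(interior)
        x0, x1, x2 = np.log(grid[i - 1]), np.log(grid[i]), np.log(grid[i + 1])
        y0, y1, y2 = ll[g, i - 1], ll[g, i], ll[g, i + 1]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a_quad = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        b_quad = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
        with np.errstate(divide="ignore", invalid="ignore"):
            x_star = -b_quad / (2 * a_quad)
        ok = (a_quad < 0) & (x_star > x0) & (x_star < x2) & np.isfinite(x_star)
        refined = np.where(ok, np.exp(x_star), alpha_hat[interior])
        alpha_hat = alpha_hat.copy()
        alpha_hat[interior] = refined
    return np.maximum(alpha_hat, ALPHA_FLOOR)


def _fit_trend(alpha_hat: np.ndarray, mean_norm: np.ndarray) -> tuple[float, float]:
    """Robust fit of alpha(m) = a0 + a1/m across genes (Huber loss)."""
    import statsmodels.api as sm

    ok = np.isfinite(alpha_hat) & np.isfinite(mean_norm) & (mean_norm > 0)
    a = alpha_hat[ok]
    m = mean_norm[ok]
    if a.size < 10 or np.all(a <= ALPHA_FLOOR * 10):
        return float(max(np.median(a) if a.size else ALPHA_FLOOR, ALPHA_FLOOR)), 0.0
    Xd = np.column_stack([np.ones_like(m), 1.0 / m])
    try:
        fit = sm.RLM(a, Xd, M=sm.robust.norms.HuberT()).fit(maxiter=50)
        a0, a1 = float(fit.params[0]), float(fit.params[1])
    except Exception:  # pragma: no cover - degenerate design
        a0, a1 = float(np.median(a)), 0.0
    return max(a0, 0.0), max(a1, 0.0)


def estimate_dispersions(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    shrink_weight: float = 0.5,
) -> DispersionFit:
    """Estimate per-gene NB dispersions for a stacked count matrix.

    Fitted means come from a preliminary Poisson fit of the full design;
    per-gene dispersions are CR-adjusted profile-ML on a grid; the trend
    ``a0 + a1/m`` is fit by Huber regression over genes; moderated values
    are the weighted geometric mean of gene estimate and trend
    (``shrink_weight`` toward the trend), floored at ``ALPHA_FLOOR``.
    """
    Y = np.asarray(Y, dtype=float)
    beta, _, _ = _batch_irls(Y, X, offset, np.zeros(Y.shape[0]), ridge=RIDGE)
    mu = np.exp(np.clip(beta @ X.T + offset[None, :], -50, 50))
    alpha_mle = _alpha_grid_mle(Y, mu, X)
    mean_norm = (Y / np.exp(offset)[None, :]).mean(axis=1)
    a0, a1 = _fit_trend(alpha_mle, mean_norm)
    trend = np.maximum(a0 + a1 / np.maximum(mean_norm, 1e-12), ALPHA_FLOOR)
    log_mod = (1 - shrink_weight) * np.log(np.maximum(alpha_mle, ALPHA_FLOOR)) + (
        shrink_weight
    ) * np.log(trend)
    moderated = np.maximum(np.exp(log_mod), ALPHA_FLOOR)
    return DispersionFit(
        alpha_mle=alpha_mle,
        alpha_trend=trend,
        alpha_moderated=moderated,
        trend_coefficients=(a0, a1),
        mean_norm=mean_norm,
    )


# ---------------------------------------------------------------------------
# LRT
# ---------------------------------------------------------------------------

def lrt_interaction(
    y: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    offset: np.ndarray | None = None,
    alpha: float = 0.0,
) -> tuple[float, float]:
    """Likelihood ratio test of the last (interaction) column of the design.

    stat = 2 (loglik_full - loglik_reduced) clipped at 0; p from
    chi-square with df = rank(X_full) - rank(X_reduced) = 1.
    """
    _, ll_full = fit_nb_glm(y, X_full, offset, alpha)
    _, ll_red = fit_nb_glm(y, X_reduced, offset, alpha)
    df = np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_reduced)
    stat = max(2.0 * (ll_full - ll_red), 0.0)
    return stat, float(chi2.sf(stat, df))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through.

    NaN entries are excluded from the number of tests m and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    ps = p[ok]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = vals
    out[ok] = res
    return out


# ---------------------------------------------------------------------------
# the per-condition contrast
# ---------------------------------------------------------------------------

def _stack_design(
    pc: PairedCounts, meta: PlateMeta, condition: str, control: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    wells_ctrl = [w for w in pc.wells if meta.condition_of(w) == control]
    wells_drug = [w for w in pc.wells if meta.condition_of(w) == condition]
    if len(wells_ctrl) < 2 or len(wells_drug) < 2:
        raise DesignError(
            f"need >= 2 wells per arm; control={len(wells_ctrl)}, "
            f"{condition}={len(wells_drug)}"
        )
    wells_sub = wells_ctrl + wells_drug
    pos = {w: i for i, w in enumerate(pc.wells)}
    idx = [pos[w] for w in wells_sub]
    # samples: all ribo libraries first, then all total libraries
    Y = np.hstack([pc.ribo[:, idx], pc.total[:, idx]])
    n_w = len(wells_sub)
    cond = np.tile([0] * len(wells_ctrl) + [1] * len(wells_drug), 2).astype(float)
    lib_ribo = np.concatenate([np.ones(n_w), np.zeros(n_w)])
    X_full = np.column_stack(
        [np.ones(2 * n_w), cond, lib_ribo, cond * lib_ribo]
    )
    return Y, X_full, lib_ribo, wells_sub


def differential_ra(
    pc: PairedCounts,
    meta: PlateMeta,
    condition: str,
    control: str = "DMSO",
    anno: GeneAnno | None = None,
    shrink_weight: float = 0.5,
    min_mean_count: float = 0.0,
) -> pd.DataFrame:
    """Per-gene differential RA for one drug condition versus control.

    Returns a tidy table indexed by gene with columns ``baseMean, lfcRA,
    stat, pvalue, fdr, condition, status``. lfcRA is the interaction
    coefficient on the log2 scale (positive = RA increased under drug).
    Genes that are all zero, excluded by annotation (spike-ins,
    blacklisted), or fail to converge carry NA results and do not enter the
    BH denominator. ``min_mean_count`` optionally filters low-count genes
    before testing (off by default).
    """
    Y, X_full, _, _ = _stack_design(pc, meta, condition, control)
    X_red = X_full[:, :3]

    mask = None
    if anno is not None:
        mask = anno.analysis_mask(pc.genes)
    sf = size_factors(Y, mask)
    offset = np.log(sf)

    n_genes = pc.n_genes
    status = np.full(n_genes, "ok", dtype=object)
    tested = np.ones(n_genes, dtype=bool)
    if anno is not None:
        excluded = ~mask
        status[excluded] = "excluded"
        tested &= ~excluded
    allzero = Y.sum(axis=1) == 0
    status[allzero & tested] = "all_zero"
    tested &= ~allzero
    base_mean = (Y / sf[None, :]).mean(axis=1)
    if min_mean_count > 0:
        low = base_mean < min_mean_count
        status[low & tested] = "low_count"
        tested &= ~low

    lfc = np.full(n_genes, np.nan)
    stat = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)

    ti = np.flatnonzero(tested)
    if ti.size:
        Yt = Y[ti]
        disp = estimate_dispersions(Yt, X_full, offset, shrink_weight=shrink_weight)
        alpha = disp.alpha_moderated

        beta_f, ll_f, conv_f = _batch_irls(Yt, X_full, offset, alpha)
        beta_r, ll_r, conv_r = _batch_irls(Yt, X_red, offset, alpha)
        bad = ~(conv_f & conv_r)
        if np.any(bad):
            # ridge fallback for separated / hard fits
            bi = np.flatnonzero(bad)
            bf, lf, cf = _batch_irls(Yt[bi], X_full, offset, alpha[bi], ridge=RIDGE)
            br, lr, cr_ = _batch_irls(Yt[bi], X_red, offset, alpha[bi], ridge=RIDGE)
            beta_f[bi], ll_f[bi] = bf, lf
            beta_r[bi], ll_r[bi] = br, lr
            still_bad = bi[~(cf & cr_)]
            status[ti[still_bad]] = "no_convergence"
            ridge_ok = bi[(cf & cr_)]
            status[ti[ridge_ok]] = "ridge"
            if still_bad.size:
                logger.warning(
                    "%d genes failed to converge for %s vs %s",
                    still_bad.size,
                    condition,
                    control,
                )
        good = np.array([s in ("ok", "ridge") for s in status[ti]])
        g = ti[good]
        rel = np.flatnonzero(good)
        lfc[g] = beta_f[rel, 3] / np.log(2.0)
        s = np.maximum(2.0 * (ll_f[rel] - ll_r[rel]), 0.0)
        stat[g] = s
        pval[g] = chi2.sf(s, 1)

    fdr = bh_adjust(pval)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "lfcRA": lfc,
            "stat": stat,
            "pvalue": pval,
            "fdr": fdr,
            "condition": condition,
            "status": status,
        },
        index=pd.Index(pc.genes, name="gene"),
    )
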