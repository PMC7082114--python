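"""Negative-binomial generalized log-linear models with fixed dispersion.

The NB2 model used throughout the pipeline has variance ``mu + phi * mu**2``
with a common dispersion ``phi`` shared by all genes (default 0.2, as in the
screen analysis). Fitting is iteratively reweighted least squares with a log
link, batched across genes sharing one design matrix, with step halving so the
deviance is non-increasing over iterations. Responses may be non-integer
(median-summarized counts): the likelihood is evaluated with continuous
gamma-function terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2, norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NbGlmFit",
    "nb_deviance",
    "nb_glm_fit_many",
    "nb_glm_fit",
    "lrt_pvalues",
    "nb_exact_test",
    "bh_adjust",
    "stouffer_combine",
]

LN2 = float(np.log(2.0))


def nb_deviance(y: np.ndarray, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Rowwise NB2 deviance, valid for continuous non-negative responses.

    Unit deviance ``2*[y*log(y/mu) - (y + 1/phi)*log((1+phi*y)/(1+phi*mu))]``
    with the ``y*log(y/mu)`` term taken as 0 at ``y = 0``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    term2 = (y + 1.0 / dispersion) * np.log1p(dispersion * (y - mu) / (1.0 + dispersion * mu))
    dev = 2.0 * (term1 - term2)
    return dev.sum(axis=-1)


@dataclass
class NbGlmFit:
    """Result of a batched NB GLM fit.

    ``coefficients`` is (n_genes, n_covariates) on the natural-log scale;
    ``deviance`` per gene; ``deviance_trace`` holds the per-iteration deviance
    (n_iter x n_genes) and is non-increasing by construction.
    """

    coefficients: np.ndarray
    deviance: np.ndarray
    fitted: np.ndarray
    converged: np.ndarray
    dispersion: float
    design: np.ndarray
    offsets: np.ndarray
    deviance_trace: np.ndarray


def nb_glm_fit_many(
    y: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray,
    dispersion: float = 0.2,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> NbGlmFit:
    """Fit one NB GLM per row of ``y`` (shape genes x samples) sharing ``design``.

    ``offsets`` are log effective library sizes, one per sample (or one row per
    gene). All-zero genes are fitted on 0.5-augmented responses so the
    intercept stays finite. Convergence: relative deviance change below
    ``tol`` (or ``max_iter`` reached); step halving enforces a monotone
    deviance trajectory.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if y.shape[1] != n:
        raise ValueError("response and design disagree on sample count")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is not full rank")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    offsets = np.asarray(offsets, dtype=float)
    if offsets.ndim == 1:
        offsets = np.broadcast_to(offsets, y.shape)
    g = y.shape[0]

    all_zero = (y == 0).all(axis=1)
    y = np.where(all_zero[:, None], y + 0.5, y)

    # init: OLS of log working response
    z0 = np.log(np.maximum(y, 0.5)) - offsets
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (g, p)

    def mu_of(b: np.ndarray) -> np.ndarray:
        eta = np.clip(b @ X.T + offsets, -700, 700)
        return np.exp(eta)

    mu = np.maximum(mu_of(beta), 1e-10)
    dev = nb_deviance(y, mu, dispersion)
    trace = [dev.copy()]
    converged = np.zeros(g, dtype=bool)

    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        eta = np.log(mu)
        w = mu / (1.0 + dispersion * mu)
        z = (eta - offsets) + (y - mu) / mu
        a = np.einsum("ni,gn,nj->gij", X, w, X)
        b = np.einsum("ni,gn,gn->gi", X, w, z)
        try:
            beta_new = np.linalg.solve(a, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(
                a.reshape(-1, p), b.reshape(-1, 1), rcond=None
            )[0].reshape(g, p)
        step = beta_new - beta
        t = np.ones(g)
        cand = beta + t[:, None] * step
        mu_c = np.maximum(mu_of(cand), 1e-10)
        dev_c = nb_deviance(y, mu_c, dispersion)
        for _half in range(30):  # step halving keeps the deviance monotone
            worse = active & (dev_c > dev + 1e-12)
            if not worse.any():
                break
            t = np.where(worse, t * 0.5, t)
            cand = beta + t[:, None] * step
            mu_c = np.maximum(mu_of(cand), 1e-10)
            dev_c = nb_deviance(y, mu_c, dispersion)
        improved = active & (dev_c <= dev + 1e-12)
        beta = np.where(improved[:, None], cand, beta)
        new_dev = np.where(improved, dev_c, dev)
        rel = np.abs(dev - new_dev) / np.maximum(np.abs(new_dev), 1.0)
        converged = converged | (active & (rel < tol))
        dev = new_dev
        mu = np.where(improved[:, None], mu_c, mu)
        trace.append(dev.copy())

    return NbGlmFit(
        coefficients=beta,
        deviance=dev,
        fitted=mu,
        converged=converged,
        dispersion=dispersion,
        design=X,
        offsets=offsets[0] if np.ptp(offsets, axis=0).max() == 0 else offsets,
        deviance_trace=np.asarray(trace),
    )


def nb_glm_fit(
    y: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray,
    dispersion: float = 0.2,
    **kw,
) -> NbGlmFit:
    """Single-gene convenience wrapper around :func:`nb_glm_fit_many`."""
    return nb_glm_fit_many(np.atleast_2d(y), design, offsets, dispersion, **kw)


def lrt_pvalues(full: NbGlmFit, null: NbGlmFit, df: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood-ratio test of nested NB GLMs (same dispersion).

    Returns ``(statistic, p)`` per gene; a statistic below -1e-6 marks a fit
    failure and yields ``p = NaN``. Small negative rounding noise is clipped
    to zero.
    """
    if full.dispersion != null.dispersion:
        raise ValueError("nested fits must share the dispersion")
    stat = null.deviance - full.deviance
    bad = stat < -1e-6
    stat = np.clip(stat, 0.0, None)
    p = chi2.sf(stat, df)
    p = np.where(bad, np.nan, p)
    stat = np.where(bad, np.nan, stat)
    return stat, p


def _nb_logpmf(k: np.ndarray, mean: float, dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    return (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1.0)
        + r * np.log(r / (r + mean))
        + k * np.log(mean / (r + mean))
    )


def nb_exact_test(
    y1: float,
    y2: float,
    lib1: float,
    lib2: float,
    dispersion: float = 0.2,
) -> float:
    """Two-sided exact NB test for an unreplicated pair, conditional on the total.

    Under the null the two counts share one underlying abundance split
    according to library size; conditioning on ``t = y1 + y2``, every split
    ``(k, t - k)`` has probability proportional to ``NB(k; mu1) * NB(t-k;
    mu2)`` with ``mu_i = t * lib_i / (lib1 + lib2)``. The p-value sums the
    probabilities of all splits at most as probable as the observed one
    (probability-mass method), normalized over the conditional distribution.
    """
    t = int(round(y1 + y2))
    if t == 0:
        return 1.0
    frac = lib1 / (lib1 + lib2)
    mu1, mu2 = t * frac, t * (1.0 - frac)
    k = np.arange(t + 1)
    logp = _nb_logpmf(k, mu1, dispersion) + _nb_logpmf(t - k, mu2, dispersion)
    logp -= logp.max()
    pr = np.exp(logp)
    obs = pr[int(round(y1))]
    return float(pr[pr <= obs * (1.0 + 1e-10)].sum() / pr.sum())


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjustment, capped at 1.

    NaN entries are excluded from the ranking and propagated as NaN.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    if (arr[ok] < 0).any() or (arr[ok] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index)
    return out


def stouffer_combine(p: np.ndarray, logfc: np.ndarray) -> np.ndarray:
    """Directional Stouffer combination of per-line two-sided p-values.

    Each p is converted to a signed z (sign of the line's logFC); the mean z
    times sqrt(k) is referred back to a two-sided normal p.
    """
    p = np.asarray(p, dtype=float)
    z = norm.isf(np.clip(p, 1e-300, 1.0) / 2.0) * np.sign(np.asarray(logfc))
    zbar = z.sum(axis=-1) / np.sqrt(p.shape[-1])
    return 2.0 * norm.sf(np.abs(zbar))
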