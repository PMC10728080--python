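"""Parametric empirical-Bayes batch adjustment (ComBat-style, no covariates).

Per gene the data are standardized against the grand location/scale, batch
location (gamma) and scale (delta^2) are estimated, shrunk toward their
across-gene priors by the standard method-of-moments empirical-Bayes scheme,
removed, and the grand location/scale restored.  With a reference batch, that
batch defines the standardization and is returned unchanged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    n = sdat.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(
    expr: ExpressionMatrix,
    batch: pd.Series,
    reference_batch: str | None = None,
) -> ExpressionMatrix:
    """Remove additive/multiplicative batch effects from ``expr``.

    ``batch`` maps sample ids to batch labels; every batch needs >= 2 samples.
    A single batch is returned unchanged.  Genes with zero pooled variance are
    passed through unadjusted (logged).  With ``reference_batch`` the other
    batches are mapped onto it and the reference samples are left untouched.
    """
    batch = batch.reindex(expr.sample_ids)
    if batch.isna().any():
        missing = batch.index[batch.isna()].tolist()
        raise ValueError(f"samples without batch label: {missing[:5]}")
    levels = list(pd.unique(batch))
    if len(levels) == 1:
        logger.info("single batch; returning expression unchanged")
        return ExpressionMatrix(expr.data.copy())
    counts = batch.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"batches with fewer than 2 samples: {small}")
    if reference_batch is not None and reference_batch not in levels:
        raise ValueError(f"reference batch {reference_batch!r} not among batch labels")

    X = expr.data.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    masks = {b: (batch == b).to_numpy() for b in levels}
    n_b = {b: int(masks[b].sum()) for b in levels}

    batch_means = {b: X[:, masks[b]].mean(axis=1) for b in levels}
    if reference_batch is not None:
        stand_mean = batch_means[reference_batch]
        ref = masks[reference_batch]
        var_pooled = ((X[:, ref] - stand_mean[:, None]) ** 2).mean(axis=1)
    else:
        stand_mean = sum((n_b[b] / n_samples) * batch_means[b] for b in levels)
        fitted = np.zeros_like(X)
        for b in levels:
            fitted[:, masks[b]] = batch_means[b][:, None]
        var_pooled = ((X - fitted) ** 2).sum(axis=1) / n_samples

    ok = var_pooled > 0
    if not ok.all():
        logger.warning("%d genes with zero pooled variance passed through unadjusted",
                       int((~ok).sum()))
    out = X.copy()
    Xg = X[ok]
    sd = np.sqrt(var_pooled[ok])
    Z = (Xg - stand_mean[ok][:, None]) / sd[:, None]

    adjusted = Z.copy()
    adjust_batches = [b for b in levels if b != reference_batch]
    for b in adjust_batches:
        zb = Z[:, masks[b]]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        d_hat = np.maximum(d_hat, 1e-12)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        a, b_pr = _aprior(d_hat), _bprior(d_hat)
        g_star, d_star = _it_sol(zb, g_hat, d_hat, g_bar, t2, a, b_pr)
        adjusted[:, masks[b]] = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]
    if reference_batch is not None:
        adjusted[:, masks[reference_batch]] = Z[:, masks[reference_batch]]

    out[ok] = adjusted * sd[:, None] + stand_mean[ok][:, None]
    return ExpressionMatrix(pd.DataFrame(out, index=expr.gene_ids, columns=expr.sample_ids))
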