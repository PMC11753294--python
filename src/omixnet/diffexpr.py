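"""Negative-binomial differential expression with likelihood-ratio testing.

The model is the standard NB GLM with log link, per-sample size factors as
offsets and a fixed per-gene dispersion alpha (Var = mu + alpha mu^2).  The
full model has an intercept and a case/control coefficient; the reduced
model only the intercept; twice the log-likelihood difference is referred
to chi-square with 1 df.  Genes with raw p < 0.05 are called differentially
expressed and signed by the fold-change direction; BH-adjusted p-values are
reported alongside.

Dispersion is estimated by a per-gene method of moments pooled within
condition — a deliberate simplification of shrinkage-based estimators,
adequate because downstream stages consume directions and ranks rather
than exact tail probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix

logger = logging.getLogger(__name__)

_ALPHA_FLOOR = 1e-8
_MAX_ITER = 100
_TOL = 1e-8


@dataclass
class QCResult:
    matrix: CountMatrix
    removed: list[tuple[str, float]] = field(default_factory=list)


def sample_qc(counts: CountMatrix, min_correlation: float = 0.8) -> QCResult:
    """Iteratively drop the least-correlated sample until all pass.

    Correlation is Pearson on log2(count + 1); a sample is removed while its
    mean correlation with the remaining samples is below ``min_correlation``.
    """
    if counts.counts.shape[1] < 3:
        raise ValueError("sample QC needs at least 3 samples")
    log = np.log2(counts.counts.to_numpy(dtype=float) + 1.0)
    samples = list(counts.samples)
    keep = list(range(len(samples)))
    removed: list[tuple[str, float]] = []
    while len(keep) > 1:
        sub = log[:, keep]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        np.fill_diagonal(corr, np.nan)
        mean_corr = np.nanmean(corr, axis=0)
        worst = int(np.nanargmin(mean_corr))
        if mean_corr[worst] >= min_correlation:
            break
        removed.append((samples[keep[worst]], float(mean_corr[worst])))
        keep.pop(worst)
    if len(keep) <= 1:
        raise ValueError("sample QC removed (almost) all samples; dataset unusable")
    retained = [samples[i] for i in keep]
    for name, r in removed:
        logger.info("sample_qc: removed %s (mean r = %.3f)", name, r)
    return QCResult(counts.subset_samples(retained), removed)


def balance_groups(counts: CountMatrix, seed: int) -> CountMatrix:
    """Subsample the larger case/control group to the size of the smaller."""
    cond = counts.meta["condition"]
    groups = {label: list(cond.index[cond == label]) for label in ("case", "control")}
    if not groups["case"] or not groups["control"]:
        raise ValueError("both case and control samples are required")
    n = min(len(groups["case"]), len(groups["control"]))
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for label in ("case", "control"):
        members = groups[label]
        if len(members) > n:
            members = sorted(rng.choice(members, size=n, replace=False))
            logger.info("balance_groups: subsampled %s to %d samples", label, n)
        keep.extend(members)
    keep = [s for s in counts.samples if s in set(keep)]  # preserve column order
    return counts.subset_samples(keep)


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, rescaled to geometric mean 1.

    Uses only genes with strictly positive counts in every sample as the
    reference, like the median-of-ratios method of DESeq-style tools.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    values = mat.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene is positive in all samples; median-of-ratios undefined "
            "(consider a pseudo-reference fallback)"
        )
    ref = values[positive]
    log_geo_mean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geo_mean[:, None]
    s = np.exp(np.median(ratios, axis=0))
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=mat.columns, name="size_factor")


def estimate_dispersion(counts: CountMatrix, sf: pd.Series) -> pd.Series:
    """Per-gene method-of-moments dispersion on normalized counts.

    alpha_hat = max(0, (s^2 - mean) / mean^2) within each condition, then
    averaged across conditions; floored at 1e-8.
    """
    norm = counts.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    alphas = []
    for label in ("case", "control"):
        mask = counts.condition_mask(label)
        if mask.sum() < 2:
            raise ValueError("dispersion estimation needs >= 2 samples per condition")
        sub = norm[:, mask]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / mu**2
        alphas.append(np.where(np.isfinite(a), a, 0.0))
    alpha = np.maximum(np.mean(alphas, axis=0), _ALPHA_FLOOR)
    return pd.Series(alpha, index=counts.genes, name="dispersion")


def _nb_loglik_mu_part(y: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Per-gene sum of the mu-dependent NB log-likelihood terms.

    The lgamma terms depend only on y and the fixed dispersion and cancel in
    likelihood ratios, so they are omitted.
    """
    return np.sum(y * np.log(mu) - (y + r) * np.log1p(mu / r), axis=1)


def _irls_fit(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    r: np.ndarray,
    beta0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for an NB GLM with shared design across genes.

    y: (G, n); X: (n, p); offset: (n,); r: (G,) = 1/alpha; beta0: (G, p).
    Returns (beta, loglik, converged).
    """
    G, n = y.shape
    p = X.shape[1]
    beta = beta0.copy()
    ll_old = np.full(G, -np.inf)
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    for _ in range(_MAX_ITER):
        eta = beta @ X.T + offset[None, :]
        eta = np.clip(eta, -50.0, 50.0)
        mu = np.exp(eta)
        # Fisher weights for NB with log link
        w = mu / (1.0 + mu / r[:, None])
        z = eta - offset[None, :] + (y - mu) / mu
        XtWX = np.einsum("gn,np,nq->gpq", w, X, X)
        XtWz = np.einsum("gn,np,gn->gp", w, X, z)
        XtWX += np.eye(p)[None, :, :] * 1e-10
        beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        step = np.max(np.abs(beta_new - beta), axis=1)
        beta = np.where(active[:, None], beta_new, beta)
        eta = np.clip(beta @ X.T + offset[None, :], -50.0, 50.0)
        ll = _nb_loglik_mu_part(y, np.exp(eta), r[:, None])
        delta = np.abs(ll - ll_old) / (np.abs(ll) + 1.0)
        # require both the likelihood and the coefficients to be stable
        newly = active & (delta < _TOL) & (step < 1e-8)
        converged |= newly
        active &= ~newly
        ll_old = ll
        if not active.any():
            break
    return beta, ll_old, converged


def nb_lrt(
    counts: CountMatrix,
    sf: pd.Series,
    alpha: pd.Series,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Likelihood-ratio test of the case/control effect per gene.

    Returns a DataFrame indexed by gene with columns log2fc, lr, pvalue,
    padj, deg (bool), direction, base_mean, converged.  All-zero genes are
    skipped.
    """
    is_case = counts.condition_mask("case").astype(float)
    if is_case.all() or not is_case.any():
        raise ValueError("both conditions required for the LRT")
    y_all = counts.counts.to_numpy(dtype=float)
    nonzero = y_all.sum(axis=1) > 0
    if (~nonzero).any():
        logger.info("nb_lrt: skipping %d all-zero genes", int((~nonzero).sum()))
    y = y_all[nonzero]
    genes = counts.genes[nonzero]
    r = 1.0 / np.maximum(alpha.loc[genes].to_numpy(), _ALPHA_FLOOR)
    s = sf.loc[counts.samples].to_numpy(dtype=float)
    offset = np.log(s)
    norm = y / s[None, :]
    base_mean = norm.mean(axis=1)

    eps = 0.5
    mu_case = (norm[:, is_case == 1].mean(axis=1) + eps)
    mu_ctrl = (norm[:, is_case == 0].mean(axis=1) + eps)

    X_full = np.column_stack([np.ones_like(is_case), is_case])
    beta0_full = np.column_stack([np.log(mu_ctrl), np.log(mu_case) - np.log(mu_ctrl)])
    beta_f, ll_f, conv_f = _irls_fit(y, X_full, offset, r, beta0_full)

    X_red = np.ones((len(is_case), 1))
    beta0_red = np.log(norm.mean(axis=1) + eps)[:, None]
    beta_r, ll_r, conv_r = _irls_fit(y, X_red, offset, r, beta0_red)

    lr = np.maximum(2.0 * (ll_f - ll_r), 0.0)
    pval = stats.chi2.sf(lr, df=1)
    converged = conv_f & conv_r
    pval = np.where(converged, pval, 1.0)
    padj = multipletests(pval, method="fdr_bh")[1]
    log2fc = beta_f[:, 1] / np.log(2.0)
    direction = np.sign(log2fc).astype(int)
    deg = (pval < p_threshold) & (direction != 0)

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "lr": lr,
            "pvalue": pval,
            "padj": padj,
            "deg": deg,
            "direction": direction,
            "base_mean": base_mean,
            "converged": converged,
        },
        index=pd.Index(genes, name="gene"),
    )


def run_de(
    counts: CountMatrix,
    seed: int,
    min_correlation: float = 0.8,
    p_threshold: float = 0.05,
) -> tuple[pd.DataFrame, QCResult]:
    """QC -> balance -> size factors -> dispersion -> LRT on one dataset."""
    qc = sample_qc(counts, min_correlation=min_correlation)
    balanced = balance_groups(qc.matrix, seed)
    sf = size_factors(balanced)
    alpha = estimate_dispersion(balanced, sf)
    result = nb_lrt(balanced, sf, alpha, p_threshold=p_threshold)
    return result, qc


def de_signature(result: pd.DataFrame) -> dict[str, int]:
    """gene -> direction for genes called differentially expressed."""
    called = result[result["deg"]]
    return dict(zip(called.index, called["direction"].astype(int)))
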