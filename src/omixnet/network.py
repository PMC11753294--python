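"""Signed weighted co-expression networks (WGCNA-style).

Pipeline: low-count filter per original dataset -> variance-stabilizing
transform (log2 of normalized counts + 1) -> empirical-Bayes batch
adjustment with the condition protected -> Pearson correlation -> signed
adjacency ((1 + r)/2)^beta at a soft threshold chosen for approximate
scale-free topology (fit R^2 ~ 0.8) -> topological overlap matrix ->
average-linkage clustering of 1 - TOM -> module detection with a static
tree cut, eigengene-based merging at height 0.25 and a minimum module size
of 30 -> module eigengenes (first principal component) and module-trait
correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import CountMatrix

logger = logging.getLogger(__name__)


def low_count_filter(
    datasets: list[CountMatrix], min_count: int = 15, frac: float = 0.5
) -> pd.Index:
    """Retain genes not lowly expressed in any of their original datasets.

    A gene is removed if in ANY dataset its count is below ``min_count`` in
    more than ``frac`` of that dataset's samples.
    """
    genes = datasets[0].genes
    keep = np.ones(len(genes), dtype=bool)
    for ds in datasets:
        low = (ds.counts.to_numpy() < min_count)
        keep &= low.mean(axis=1) <= frac
    return genes[keep]


def vst(counts: CountMatrix, sf: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1) — a variance-stabilizing transform."""
    s = sf.loc[counts.samples].to_numpy(dtype=float)
    return pd.DataFrame(
        np.log2(counts.counts.to_numpy(dtype=float) / s[None, :] + 1.0),
        index=counts.genes,
        columns=counts.samples,
    )


def batch_adjust(
    expr: pd.DataFrame, batch: pd.Series, condition: pd.Series
) -> pd.DataFrame:
    """Empirical-Bayes batch correction (ComBat) with condition protected.

    Operates on the transformed scale; a single batch returns the input
    unchanged.  Delegates to scanpy's ComBat implementation.
    """
    batch = batch.loc[expr.columns]
    condition = condition.loc[expr.columns]
    if batch.nunique() < 2:
        return expr
    crosstab = pd.crosstab(batch, condition)
    if (crosstab > 0).sum().sum() == batch.nunique():
        raise ValueError("condition is fully confounded with batch; design singular")
    import anndata as ad
    import scanpy as sc

    # condition enters as a numeric indicator: a categorical covariate would
    # be dummy-expanded without a reference level and leave the design singular
    cond_codes = condition.astype("category").cat.codes.astype(float)
    adata = ad.AnnData(
        X=expr.to_numpy(dtype=float).T,
        obs=pd.DataFrame({"batch": batch.astype(str).to_numpy(),
                          "condition": cond_codes.to_numpy()},
                         index=expr.columns.astype(str)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected = sc.pp.combat(adata, key="batch", covariates=["condition"], inplace=False)
    return pd.DataFrame(np.asarray(corrected).T, index=expr.index, columns=expr.columns)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of a connectivity vector.

    Bins k into ``n_bins`` equal-width bins and regresses log10(frequency)
    on log10(mean k); returns (R^2 * -sign(slope), slope).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r**2 * -np.sign(slope)), float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: list[int] | None = None,
    target_r2: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Smallest power with signed scale-free fit >= target_r2.

    Falls back (with a warning) to the power maximizing the fit when no
    power reaches the target.  Returns (beta, per-power fit table).
    """
    if expr.shape[0] < 30:
        raise ValueError("soft-threshold selection needs >= 30 genes")
    if np.any(expr.std(axis=1) == 0):
        raise ValueError("constant gene expression; correlations undefined")
    powers = powers or list(range(1, 21))
    r = np.corrcoef(expr.to_numpy(dtype=float))
    base = (1.0 + r) / 2.0
    np.fill_diagonal(base, 0.0)
    rows = []
    for beta in powers:
        k = (base**beta).sum(axis=1)
        fit, slope = scale_free_fit(k)
        rows.append((beta, fit, slope, float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "fit", "slope", "mean_k"])
    good = table[table["fit"] >= target_r2]
    if len(good):
        beta = int(good.iloc[0]["power"])
    else:
        beta = int(table.loc[table["fit"].idxmax(), "power"])
        logger.warning(
            "no power reached scale-free fit %.2f; using beta=%d (fit=%.3f)",
            target_r2, beta, table["fit"].max(),
        )
    return beta, table


@dataclass
class Network:
    genes: pd.Index
    corr: np.ndarray
    beta: int
    adjacency: np.ndarray
    tom: np.ndarray
    diss_tom: np.ndarray
    labels: pd.Series | None = None
    linkage_matrix: np.ndarray | None = None


def build_network(expr: pd.DataFrame, beta: int) -> Network:
    """Signed adjacency and topological overlap from Pearson correlations.

    a_ij = ((1 + r_ij)/2)^beta with unit diagonal;
    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj over u != i, j and k_i the node connectivity.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    sd = expr.std(axis=1)
    if (sd == 0).any():
        bad = list(expr.index[sd == 0])[:5]
        raise ValueError(f"constant expression for genes {bad}; correlation undefined")
    r = np.corrcoef(expr.to_numpy(dtype=float))
    a = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1.0
    l = a @ a - 2.0 * a  # subtracts the u=i and u=j terms (diagonal = 1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / denom  # diagonal is overwritten below
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return Network(expr.index, r, beta, a, tom, 1.0 - tom)


def _standardize(mat: np.ndarray) -> np.ndarray:
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (mat - mu) / sd


def _first_pc(sub: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit-norm first right-singular vector and variance explained."""
    z = _standardize(sub)
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    ev = vt[0]
    var_expl = float(s[0] ** 2 / (s**2).sum()) if s.sum() > 0 else 0.0
    return ev, var_expl


@dataclass
class ModuleEigengenes:
    eigengenes: pd.DataFrame  # samples x modules
    kme: pd.DataFrame  # genes x modules
    var_explained: dict[int, float] = field(default_factory=dict)


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> ModuleEigengenes:
    """First-PC eigengene per module, sign-fixed so mean member kME > 0.

    kME (module membership) is computed for every gene against every module
    eigengene.
    """
    labels = labels.loc[expr.index]
    modules = sorted(set(labels) - {0})
    values = expr.to_numpy(dtype=float)
    z = _standardize(values)
    me = {}
    var_expl = {}
    for m in modules:
        rows = np.flatnonzero((labels == m).to_numpy())
        if len(rows) == 1:
            ev = z[rows[0]] / np.linalg.norm(z[rows[0]])
            var_expl[m] = 1.0
        else:
            ev, var_expl[m] = _first_pc(values[rows])
        # sign convention: members correlate positively on average
        if _corr_with_vector(values[rows], ev).mean() < 0:
            ev = -ev
        me[m] = ev / np.linalg.norm(ev)
    me_df = pd.DataFrame(me, index=expr.columns)
    kme = pd.DataFrame(
        {m: _corr_with_vector(values, me_df[m].to_numpy()) for m in modules},
        index=expr.index,
    )
    return ModuleEigengenes(me_df, kme, var_expl)


def _corr_with_vector(mat: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of `mat` (g x n) with `vec` (n,)."""
    mz = mat - mat.mean(axis=1, keepdims=True)
    vz = vec - vec.mean()
    denom = np.sqrt((mz**2).sum(axis=1) * (vz**2).sum())
    denom[denom == 0] = np.inf
    return (mz @ vz) / denom


def detect_modules(
    network: Network,
    expr: pd.DataFrame,
    min_module_size: int = 30,
    merge_height: float = 0.25,
    min_coherence: float = 0.3,
) -> pd.Series:
    """Module detection on the 1 - TOM dendrogram with eigengene merging.

    The average-linkage tree is decomposed top-down: a branch is split
    while its two sub-branches' eigengenes correlate below
    ``1 - merge_height``; a branch whose sub-branches cohere, with
    >= ``min_module_size`` members and an eigengene explaining
    >= ``min_coherence`` of member variance, becomes a module; everything
    else is label 0.  (A single static cut height proved unable to separate
    dense background merges from module branches, so the split criterion is
    applied per branch.)  Finally, modules whose eigengene dissimilarity
    (1 - cor) falls below ``merge_height`` are merged iteratively.  Labels
    are canonical: 1, 2, ... by decreasing size, ties by smallest member
    gene id.
    """
    genes = network.genes
    if len(genes) < min_module_size:
        logger.warning("fewer than %d genes; no modules detected", min_module_size)
        return pd.Series(0, index=genes, name="module")
    order = np.argsort(genes.to_numpy())  # deterministic gene order
    diss = network.diss_tom[np.ix_(order, order)]
    Z = linkage(squareform(diss, checks=False), method="average")
    network.linkage_matrix = Z
    sorted_genes = genes.to_numpy()[order]
    values = expr.loc[genes].to_numpy(dtype=float)
    gene_row = {g: i for i, g in enumerate(genes)}

    n = len(sorted_genes)
    children = Z[:, :2].astype(int)
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    for node in range(len(children)):
        left, right = children[node]
        leaves[n + node] = leaves[left] + leaves[right]

    def branch_ev(node: int) -> np.ndarray:
        rows = [gene_row[sorted_genes[i]] for i in leaves[node]]
        if len(rows) == 1:
            z = _standardize(values[rows])[0]
            return z / max(np.linalg.norm(z), 1e-12)
        ev = _first_pc(values[rows])[0]
        # orient so members point positive: signed (not absolute) eigengene
        # correlation is what distinguishes branches in a signed network
        if _corr_with_vector(values[rows], ev).mean() < 0:
            ev = -ev
        return ev

    labels = pd.Series(0, index=genes, name="module")
    next_label = 1
    stack = [n + len(children) - 1]  # root
    while stack:
        node = stack.pop()
        members = leaves[node]
        if len(members) < min_module_size:
            continue
        left, right = children[node - n]
        ev_l, ev_r = branch_ev(left), branch_ev(right)
        child_cor = float(np.corrcoef(ev_l, ev_r)[0, 1])
        rows = [gene_row[sorted_genes[i]] for i in members]
        _, var_expl = _first_pc(values[rows])
        if child_cor >= 1.0 - merge_height and var_expl >= min_coherence:
            labels.iloc[rows] = next_label
            next_label += 1
        else:
            stack.extend((int(left), int(right)))
    if labels.max() == 0:
        return labels

    # eigengene-based merging
    while True:
        me = module_eigengenes(expr.loc[genes], labels)
        mods = list(me.eigengenes.columns)
        if len(mods) < 2:
            break
        me_corr = np.corrcoef(me.eigengenes.to_numpy().T)
        diss_me = 1.0 - me_corr
        np.fill_diagonal(diss_me, np.inf)
        i, j = np.unravel_index(np.argmin(diss_me), diss_me.shape)
        if diss_me[i, j] >= merge_height:
            break
        a, b = mods[i], mods[j]
        labels[labels == b] = a
        logger.info("merged modules %s and %s (eigengene diss %.3f)", b, a, diss_me[i, j])

    return _canonical_labels(labels)


def _canonical_labels(labels: pd.Series) -> pd.Series:
    groups = [
        (int((labels == m).sum()), labels.index[labels == m].min(), m)
        for m in sorted(set(labels) - {0})
    ]
    groups.sort(key=lambda t: (-t[0], t[1]))
    mapping = {old: new + 1 for new, (_, _, old) in enumerate(groups)}
    out = labels.map(lambda m: mapping.get(m, 0))
    out.name = "module"
    return out


def module_trait_correlation(
    me: ModuleEigengenes, trait: pd.Series, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with a binary per-sample trait."""
    trait = trait.loc[me.eigengenes.index].astype(float)
    if trait.nunique() < 2:
        raise ValueError("trait is constant")
    n = len(trait)
    rows = []
    for m in me.eigengenes.columns:
        r = float(np.corrcoef(me.eigengenes[m], trait)[0, 1])
        t = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        rows.append((m, r, p, p < p_threshold))
    return pd.DataFrame(rows, columns=["module", "r", "pvalue", "significant"]).set_index("module")
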