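"""Over-representation, gene set enrichment, and term clustering.

ORA is the hypergeometric upper tail of the query/term overlap within a
stated universe.  GSEA is the weighted Kolmogorov-Smirnov running-sum
statistic (weight 1) on a ranking by mean log2 fold change across the two
conditions, with significance from seeded gene-label permutations — the
ranking is a derived statistic, so phenotype permutation does not apply.
Enriched terms are grouped by average-linkage clustering on one minus the
Jaccard similarity of their annotated gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GeneSetCollection = dict[str, tuple[str, list[str]]]  # id -> (name, genes)


def ora(
    query: set[str],
    universe: set[str],
    sets: GeneSetCollection,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the query list."""
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for term_id, (name, genes) in sets.items():
        members = set(genes) & universe
        M = len(members)
        if M == 0:
            continue
        k = len(query & members)
        # P(X >= k) for X ~ Hypergeom(N, M, n)
        p = float(stats.hypergeom.sf(k - 1, N, M, n))
        rows.append((term_id, name, k, M, p))
    out = pd.DataFrame(rows, columns=["term_id", "name", "k", "set_size", "pvalue"])
    if len(out):
        out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
        out["significant"] = out["padj"] < padj_threshold
        out = out.sort_values(["pvalue", "term_id"], kind="mergesort").reset_index(drop=True)
    return out


def _es_curve(ranked_abs: np.ndarray, hit_mask: np.ndarray) -> np.ndarray:
    """Running-sum curve for one hit mask over a descending ranking."""
    N = len(ranked_abs)
    M = int(hit_mask.sum())
    steps = np.where(hit_mask, ranked_abs / ranked_abs[hit_mask].sum(), -1.0 / (N - M))
    return np.cumsum(steps)


def _es_value(curve: np.ndarray) -> float:
    idx = int(np.argmax(np.abs(curve)))
    return float(curve[idx])


@dataclass
class GseaRecord:
    term_id: str
    name: str
    es: float
    pvalue: float
    leading_edge: list[str]
    set_size: int


def gsea(
    ranking: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Weighted-KS gene set enrichment on a precomputed gene ranking.

    ``ranking``: gene -> score (e.g. mean log2FC across conditions), no NaN.
    ES p-values come from ``n_perm`` seeded gene-label permutations:
    p = (1 + #{|ES*| >= |ES|}) / (1 + n_perm).
    """
    if ranking.isna().any():
        raise ValueError("ranking contains NaN")
    order = ranking.sort_values(ascending=False, kind="mergesort")
    genes = order.index.to_numpy()
    ranked_abs = np.abs(order.to_numpy(dtype=float))
    gene_pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)
    rng = np.random.default_rng(seed)

    records: list[GseaRecord] = []
    for term_id, (name, members) in sets.items():
        pos = sorted(gene_pos[g] for g in members if g in gene_pos)
        M = len(pos)
        if M == 0:
            logger.warning("gsea: term %s has no genes in the ranking; skipped", term_id)
            continue
        if M == N:
            logger.warning("gsea: term %s covers the whole ranking; skipped", term_id)
            continue
        hit = np.zeros(N, dtype=bool)
        hit[pos] = True
        curve = _es_curve(ranked_abs, hit)
        es = _es_value(curve)
        ext = int(np.argmax(np.abs(curve)))
        if es >= 0:
            leading = [genes[i] for i in pos if i <= ext]
        else:
            leading = [genes[i] for i in pos if i >= ext]

        # vectorized permutation null over random hit sets of the same size
        perm_hits = np.zeros((n_perm, N), dtype=bool)
        draws = np.argsort(rng.random((n_perm, N)), axis=1)[:, :M]
        np.put_along_axis(perm_hits, draws, True, axis=1)
        denom = (ranked_abs[None, :] * perm_hits).sum(axis=1)
        steps = np.where(perm_hits, ranked_abs[None, :] / denom[:, None], -1.0 / (N - M))
        curves = np.cumsum(steps, axis=1)
        null_es = np.take_along_axis(
            curves, np.argmax(np.abs(curves), axis=1)[:, None], axis=1
        )[:, 0]
        p = float((1 + np.sum(np.abs(null_es) >= abs(es))) / (1 + n_perm))
        records.append(GseaRecord(term_id, name, es, p, leading, M))

    out = pd.DataFrame(
        [(r.term_id, r.name, r.es, r.set_size, r.pvalue, ",".join(r.leading_edge))
         for r in records],
        columns=["term_id", "name", "es", "set_size", "pvalue", "leading_edge"],
    )
    if len(out):
        out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
        out["significant"] = out["padj"] < padj_threshold
        out = out.sort_values(["pvalue", "term_id"], kind="mergesort").reset_index(drop=True)
    return out


def term_similarity_clusters(
    results: pd.DataFrame, sets: GeneSetCollection, k: int = 5
) -> pd.Series:
    """Average-linkage clustering of enriched terms on 1 - Jaccard similarity."""
    terms = list(results["term_id"])
    if k > len(terms):
        raise ValueError("k exceeds the number of terms")
    members = [frozenset(sets[t][1]) for t in terms]
    n = len(terms)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(members[i] | members[j])
            jac = len(members[i] & members[j]) / union if union else 0.0
            dist[i, j] = dist[j, i] = 1.0 - jac
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=pd.Index(terms, name="term_id"), name="cluster")
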