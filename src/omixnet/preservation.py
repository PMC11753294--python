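"""Permutation-based module preservation and hub gene identification.

Seven preservation statistics (netRep-style) quantify whether a discovery
module's density and connectivity structure recur in a test network:

- avg.weight   mean off-diagonal test adjacency among members
- coherence    proportion of member variance explained by the test eigengene
               (mean squared test kME of members)
- avg.cor      mean absolute test correlation over member pairs
- avg.contrib  mean absolute test kME of members
- cor.cor      correlation of discovery vs test member correlations
- cor.degree   correlation of discovery vs test within-module degrees
- cor.contrib  correlation of discovery vs test kME vectors

Null distributions come from seeded draws of random same-size gene sets
from the shared universe, recomputing the test-side quantities against the
discovery module's structure; p = (1 + #{null >= obs}) / (1 + n_perm), BH
across module x statistic pairs.  A module is preserved when all seven
adjusted p-values fall below 0.05 (the strictest rule; configurable).

Hubs in a module satisfy both criteria — intramodular connectivity kIM in
the top decile of the module and module membership kME > 0.8 — and are
ranked by kIM to pick the top five.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .network import ModuleEigengenes, Network, _corr_with_vector, _first_pc

logger = logging.getLogger(__name__)

STATISTICS = (
    "avg.contrib", "avg.cor", "avg.weight", "coherence",
    "cor.contrib", "cor.cor", "cor.degree",
)


def _module_stats(
    disc_corr: np.ndarray,
    disc_adj: np.ndarray,
    disc_kme: np.ndarray,
    test_corr: np.ndarray,
    test_adj: np.ndarray,
    test_expr: np.ndarray,
) -> dict[str, float]:
    """Seven statistics for one module given member-submatrix views.

    Discovery-side inputs are fixed module structure; test-side inputs are
    the (possibly permuted) gene set in the test network.
    """
    m = disc_corr.shape[0]
    off = ~np.eye(m, dtype=bool)
    iu = np.triu_indices(m, k=1)

    test_ev, _ = _first_pc(test_expr)
    test_kme = _corr_with_vector(test_expr, test_ev)
    if test_kme.mean() < 0:  # eigengene sign convention: members point positive
        test_kme = -test_kme

    disc_degree = disc_adj.sum(axis=1) - 1.0
    test_degree = test_adj.sum(axis=1) - 1.0

    def _cor(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    return {
        "avg.weight": float(test_adj[off].mean()),
        "coherence": float(np.mean(test_kme**2)),
        "avg.cor": float(np.abs(test_corr[iu]).mean()),
        "avg.contrib": float(np.abs(test_kme).mean()),
        "cor.cor": _cor(disc_corr[iu], test_corr[iu]),
        "cor.degree": _cor(disc_degree, test_degree),
        "cor.contrib": _cor(disc_kme, test_kme),
    }


def preservation_stats(
    discovery_expr: pd.DataFrame,
    discovery_net: Network,
    test_expr: pd.DataFrame,
    test_net: Network,
    module_genes: list[str],
) -> dict[str, float]:
    """Observed preservation statistics of one discovery module."""
    if len(module_genes) < 3:
        raise ValueError("module needs at least 3 genes")
    d_idx = discovery_net.genes.get_indexer(module_genes)
    t_idx = test_net.genes.get_indexer(module_genes)
    if (d_idx < 0).any() or (t_idx < 0).any():
        raise ValueError("module genes absent from one of the networks")

    d_sub = np.ix_(d_idx, d_idx)
    t_sub = np.ix_(t_idx, t_idx)
    d_expr = discovery_expr.loc[module_genes].to_numpy(dtype=float)
    d_ev, _ = _first_pc(d_expr)
    d_kme = _corr_with_vector(d_expr, d_ev)
    if d_kme.mean() < 0:
        d_kme = -d_kme
    return _module_stats(
        discovery_net.corr[d_sub],
        discovery_net.adjacency[d_sub],
        d_kme,
        test_net.corr[t_sub],
        test_net.adjacency[t_sub],
        test_expr.loc[module_genes].to_numpy(dtype=float),
    )


def preservation_permutation(
    discovery_expr: pd.DataFrame,
    discovery_net: Network,
    test_expr: pd.DataFrame,
    test_net: Network,
    modules: dict[int, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    exclude_module_genes: bool = False,
) -> pd.DataFrame:
    """Permutation p-values for all modules x statistics, BH-corrected.

    Returns a long DataFrame (module, statistic, observed, pvalue, padj)
    plus a ``preserved`` column repeated per module (all seven adjusted
    p < alpha).
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives uselessly coarse p-values")
    shared = test_net.genes.intersection(discovery_net.genes)
    largest = max(len(g) for g in modules.values())
    if len(shared) <= largest:
        raise ValueError("test universe must exceed the largest module")
    rng = np.random.default_rng(seed)

    test_gene_pos = {g: i for i, g in enumerate(test_net.genes)}
    shared_arr = shared.to_numpy()
    test_values = test_expr.loc[test_net.genes].to_numpy(dtype=float)

    rows = []
    for mod_id, genes in sorted(modules.items()):
        obs = preservation_stats(discovery_expr, discovery_net, test_expr, test_net, genes)
        m = len(genes)
        d_idx = discovery_net.genes.get_indexer(genes)
        d_sub = np.ix_(d_idx, d_idx)
        disc_corr = discovery_net.corr[d_sub]
        disc_adj = discovery_net.adjacency[d_sub]
        d_expr = discovery_expr.loc[genes].to_numpy(dtype=float)
        d_ev, _ = _first_pc(d_expr)
        disc_kme = _corr_with_vector(d_expr, d_ev)
        if disc_kme.mean() < 0:
            disc_kme = -disc_kme
        pool = shared_arr
        if exclude_module_genes:
            pool = np.array([g for g in shared_arr if g not in set(genes)])
        null = {s: np.empty(n_perm) for s in STATISTICS}
        for b in range(n_perm):
            draw = rng.choice(pool, size=m, replace=False)
            t_idx = np.array([test_gene_pos[g] for g in draw])
            t_sub = np.ix_(t_idx, t_idx)
            stats_b = _module_stats(
                disc_corr, disc_adj, disc_kme,
                test_net.corr[t_sub], test_net.adjacency[t_sub],
                test_values[t_idx],
            )
            for s in STATISTICS:
                null[s][b] = stats_b[s]
        for s in STATISTICS:
            p = (1 + np.sum(null[s] >= obs[s])) / (1 + n_perm)
            rows.append((mod_id, s, obs[s], float(p)))

    out = pd.DataFrame(rows, columns=["module", "statistic", "observed", "pvalue"])
    out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    preserved = out.groupby("module")["padj"].apply(lambda p: bool((p < alpha).all()))
    out["preserved"] = out["module"].map(preserved)
    return out


def hub_genes(
    network: Network,
    labels: pd.Series,
    me: ModuleEigengenes,
    degree_quantile: float = 0.9,
    kme_min: float = 0.8,
    top_n: int = 5,
) -> pd.DataFrame:
    """Hubs per module: kIM in the top decile AND kME above threshold.

    Returns rows (module, gene, kim, kme, hub, rank) with rank set on hubs
    ordered by kIM descending (ties by kME descending, then gene id); the
    top ``top_n`` ranks form each module's headline hub list.
    """
    labels = labels.loc[network.genes]
    frames = []
    for mod in sorted(set(labels) - {0}):
        members = network.genes[labels == mod]
        idx = network.genes.get_indexer(members)
        sub_adj = network.adjacency[np.ix_(idx, idx)]
        kim = sub_adj.sum(axis=1) - 1.0
        kme = me.kme.loc[members, mod].to_numpy()
        threshold = np.quantile(kim, degree_quantile)
        hub = (kim >= threshold) & (kme > kme_min)
        df = pd.DataFrame(
            {"module": mod, "gene": members, "kim": kim, "kme": kme, "hub": hub}
        )
        df = df.sort_values(["kim", "kme", "gene"], ascending=[False, False, True],
                            kind="mergesort").reset_index(drop=True)
        ranks = np.full(len(df), 0)
        ranks[df["hub"].to_numpy()] = np.arange(1, int(df["hub"].sum()) + 1)
        df["rank"] = ranks
        if not df["hub"].any():
            logger.warning("module %s has no gene meeting both hub criteria", mod)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["module", "gene", "kim", "kme", "hub", "rank"])
    return pd.concat(frames, ignore_index=True)


def top_hubs(report: pd.DataFrame, top_n: int = 5) -> pd.DataFrame:
    return report[(report["hub"]) & (report["rank"] > 0) & (report["rank"] <= top_n)]
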