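"""H3K27ac differentially enriched regions and gene annotation.

Two DER modes mirror common practice: a count-based mode (NB LRT on a
consensus-peak count matrix, BH-FDR < 0.05) for datasets with usable signal
in both groups, and a presence/absence mode (peaks with zero overlap in the
other condition) for low-quality data.  DERs are annotated to genes through
promoter windows (TSS +/- 3 kb, strand-aware) or, for intergenic peaks,
through score-filtered enhancer-gene associations; genic non-promoter peaks
are discarded.  A gained acetylation peak is signed +1 (activating mark),
a lost peak -1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import CountMatrix, EnhancerDB, PeakSet

logger = logging.getLogger(__name__)


def _trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in df.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), i) for i, (s, e) in zip(sub.index, zip(sub["start"], sub["end"]))
        )
    return trees


def _overlaps_any(df: pd.DataFrame, trees: dict[str, IntervalTree]) -> np.ndarray:
    out = np.zeros(len(df), dtype=bool)
    for pos, (_, row) in enumerate(df.iterrows()):
        tree = trees.get(row["chrom"])
        if tree is not None and tree.overlap(int(row["start"]), int(row["end"])):
            out[pos] = True
    return out


def consensus_peaks(replicates: list[PeakSet], min_replicates: int = 2) -> PeakSet:
    """Merge replicate peaks; keep merged intervals seen in >= min_replicates.

    Overlap is >= 1 shared base; a merged interval is the union (span) of the
    chained overlapping peaks, and its support is the number of distinct
    replicates contributing to the chain.
    """
    if not replicates:
        raise ValueError("at least one replicate required")
    if min_replicates > len(replicates):
        raise ValueError("min_replicates exceeds the number of replicates")
    frames = []
    for ri, rep in enumerate(replicates):
        sub = rep.df[["chrom", "start", "end"]].copy()
        sub["rep"] = ri
        frames.append(sub)
    pooled = pd.concat(frames).sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    for chrom, sub in pooled.groupby("chrom"):
        cur_start = cur_end = None
        reps: set[int] = set()
        for s, e, r in zip(sub["start"], sub["end"], sub["rep"]):
            if cur_start is None:
                cur_start, cur_end, reps = s, e, {r}
            elif s < cur_end:  # half-open overlap chain
                cur_end = max(cur_end, e)
                reps.add(r)
            else:
                if len(reps) >= min_replicates:
                    rows.append((chrom, cur_start, cur_end))
                cur_start, cur_end, reps = s, e, {r}
        if cur_start is not None and len(reps) >= min_replicates:
            rows.append((chrom, cur_start, cur_end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"consensus_{i}" for i in range(len(df))]
    return PeakSet(df, label="consensus")


def differential_regions_counts(
    peak_counts: CountMatrix, fdr: float = 0.05
) -> pd.DataFrame:
    """Count-mode DERs: NB LRT on the peak-count matrix at BH FDR < fdr.

    Index = peak names; columns include log2fc, pvalue, padj, der (bool),
    direction.
    """
    from .diffexpr import estimate_dispersion, nb_lrt, size_factors

    sf = size_factors(peak_counts)
    alpha = estimate_dispersion(peak_counts, sf)
    res = nb_lrt(peak_counts, sf, alpha)
    res["der"] = (res["padj"] < fdr) & (res["direction"] != 0)
    return res


def differential_regions_presence(case: PeakSet, control: PeakSet) -> pd.DataFrame:
    """Presence/absence DERs: peaks with zero >=1 bp overlap in the other set.

    Returns rows (chrom, start, end, direction) with direction +1 for
    case-only (gain) and -1 for control-only (loss).
    """
    case_trees = _trees(case.df)
    ctrl_trees = _trees(control.df)
    gains = case.df[~_overlaps_any(case.df, ctrl_trees)].copy()
    gains["direction"] = 1
    losses = control.df[~_overlaps_any(control.df, case_trees)].copy()
    losses["direction"] = -1
    out = pd.concat([gains, losses], ignore_index=True)
    return out[["chrom", "start", "end", "direction"]]


def filter_enhancer_associations(db: EnhancerDB) -> EnhancerDB:
    """Keep high-confidence enhancer-gene associations.

    Enhancers with enhancer_score >= Q1 (25th percentile, linear
    interpolation) of all enhancer scores; associations with
    association_score >= Q1 of all association scores; enhancers left with
    more than five associated genes are dropped entirely.
    """
    if not len(db.enhancers):
        raise ValueError("empty enhancer database")
    q1_enh = float(np.quantile(db.enhancers["enhancer_score"], 0.25))
    q1_assoc = float(np.quantile(db.associations["association_score"], 0.25))
    enh = db.enhancers[db.enhancers["enhancer_score"] >= q1_enh]
    assoc = db.associations[
        db.associations["enhancer_id"].isin(enh.index)
        & (db.associations["association_score"] >= q1_assoc)
    ]
    n_genes = assoc.groupby("enhancer_id")["gene"].nunique()
    keep = set(n_genes.index[n_genes <= 5])
    enh = enh.loc[enh.index.isin(keep)]
    assoc = assoc[assoc["enhancer_id"].isin(keep)].reset_index(drop=True)
    if not len(enh):
        logger.warning("no enhancer survived the association filter")
    return EnhancerDB(enh, assoc)


def annotate_peaks(
    ders: pd.DataFrame,
    annotation: pd.DataFrame,
    db: EnhancerDB,
    promoter_halfwidth: int = 3000,
) -> pd.DataFrame:
    """Assign signed DERs to genes via promoter windows or enhancers.

    Classification per peak: promoter if it overlaps any strand-aware
    [TSS - hw, TSS + hw) window (ties -> nearest TSS, then smallest gene
    id); else, if free of gene-body overlap, intergenic -> all genes of
    overlapping filtered enhancers; otherwise genic non-promoter ->
    discarded.  Returns rows (gene, direction, element, peak_id) sorted for
    determinism.
    """
    ann = annotation
    windows = pd.DataFrame(
        {
            "chrom": ann["chrom"],
            "start": np.maximum(0, ann["tss"] - promoter_halfwidth),
            "end": ann["tss"] + promoter_halfwidth,
        },
        index=ann.index,
    )
    win_trees = _trees(windows)
    body_trees = _trees(ann[["chrom", "start", "end"]])
    enh_trees = _trees(db.enhancers[["chrom", "start", "end"]])
    assoc_by_enh = db.associations.groupby("enhancer_id")["gene"].apply(sorted).to_dict()
    known_chroms = set(ann["chrom"])

    rows = []
    for pid, row in ders.iterrows():
        chrom, start, end = row["chrom"], int(row["start"]), int(row["end"])
        direction = int(row["direction"])
        if chrom not in known_chroms:
            logger.warning("peak %s on unknown chromosome %s skipped", pid, chrom)
            continue
        hits = win_trees.get(chrom, IntervalTree()).overlap(start, end)
        if hits:
            centre = (start + end) / 2.0
            best = min(
                (abs(ann.loc[iv.data, "tss"] - centre), iv.data) for iv in hits
            )[1]
            rows.append((best, direction, "promoter", pid))
            continue
        if body_trees.get(chrom, IntervalTree()).overlap(start, end):
            continue  # genic, non-promoter
        for iv in enh_trees.get(chrom, IntervalTree()).overlap(start, end):
            for gene in assoc_by_enh.get(iv.data, []):
                rows.append((gene, direction, "enhancer", pid))
    out = pd.DataFrame(rows, columns=["gene", "direction", "element", "peak_id"])
    out = out.drop_duplicates(["gene", "peak_id"])
    return out.sort_values(["gene", "peak_id"], kind="mergesort").reset_index(drop=True)


def gader_signature(gaders: pd.DataFrame) -> dict[str, int]:
    """gene -> direction from an annotated DER table; ambiguous genes dropped.

    A gene supported by both gained and lost regions carries no usable sign
    for the concordance logic, so it is omitted here (the merge step treats
    cross-evidence conflicts; within-table conflicts are resolved the same
    way, by exclusion).
    """
    per_gene = gaders.groupby("gene")["direction"].agg(set)
    return {g: next(iter(d)) for g, d in per_gene.items() if len(d) == 1}


def annotate_der_counts(
    der_table: pd.DataFrame, consensus: PeakSet
) -> pd.DataFrame:
    """Attach coordinates to count-mode DER calls (index = consensus names)."""
    coords = consensus.df.set_index("name")
    called = der_table[der_table["der"]]
    out = coords.loc[called.index, ["chrom", "start", "end"]].copy()
    out["direction"] = called["direction"].to_numpy()
    return out.reset_index(drop=True)
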