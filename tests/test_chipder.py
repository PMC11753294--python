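"""Differential H3K27ac regions: consensus, two DER modes, gene annotation."""

import numpy as np
import pandas as pd
import pytest

from omixnet.chipder import (
    annotate_peaks,
    consensus_peaks,
    differential_regions_counts,
    differential_regions_presence,
    filter_enhancer_associations,
    gader_signature,
)
from omixnet.containers import EnhancerDB, PeakSet
from .conftest import make_count_matrix


def _peaks(rows, label=""):
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), label=label)


# --- consensus ---------------------------------------------------------------


def test_identical_replicates_kept_verbatim():
    rows = [("chr1", 100, 200), ("chr1", 500, 700), ("chr2", 10, 50)]
    cons = consensus_peaks([_peaks(rows), _peaks(rows)], min_replicates=2)
    assert [tuple(r) for r in cons.df[["chrom", "start", "end"]].to_numpy()] == sorted(rows)


def test_single_replicate_peak_excluded_at_two_replicate_support():
    a = _peaks([("chr1", 100, 200), ("chr1", 500, 700)])
    b = _peaks([("chr1", 120, 210)])
    cons = consensus_peaks([a, b], min_replicates=2)
    assert len(cons) == 1
    assert (cons.df["start"][0], cons.df["end"][0]) == (100, 210)


def test_min_replicates_exceeding_inputs_rejected():
    with pytest.raises(ValueError, match="min_replicates"):
        consensus_peaks([_peaks([("chr1", 0, 10)])], min_replicates=2)


def test_consensus_equals_pairwise_overlap_merge_oracle():
    """Oracle: union-find over the O(n^2) interval overlap graph."""
    rng = np.random.default_rng(4)
    reps = []
    for _ in range(3):
        starts = np.sort(rng.integers(0, 5000, size=25))
        reps.append(_peaks([("chr1", int(s), int(s + rng.integers(20, 300))) for s in starts]))

    pooled = []
    for ri, rep in enumerate(reps):
        for _, r in rep.df.iterrows():
            pooled.append((r["start"], r["end"], ri))
    parent = list(range(len(pooled)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pooled)):
        for j in range(i + 1, len(pooled)):
            if pooled[i][0] < pooled[j][1] and pooled[j][0] < pooled[i][1]:
                parent[find(i)] = find(j)
    clusters = {}
    for i, (s, e, ri) in enumerate(pooled):
        clusters.setdefault(find(i), []).append((s, e, ri))
    expected = sorted(
        (min(s for s, _, _ in c), max(e for _, e, _ in c))
        for c in clusters.values()
        if len({ri for _, _, ri in c}) >= 2
    )
    cons = consensus_peaks(reps, min_replicates=2)
    got = sorted(zip(cons.df["start"], cons.df["end"]))
    assert got == expected


# --- presence/absence DERs ---------------------------------------------------


def test_identical_sets_produce_no_ders():
    rows = [("chr1", 100, 200), ("chr1", 500, 700)]
    assert len(differential_regions_presence(_peaks(rows), _peaks(rows))) == 0


def test_disjoint_sets_every_peak_is_a_der():
    case = _peaks([("chr1", 0, 100), ("chr1", 1000, 1100)])
    ctrl = _peaks([("chr1", 5000, 5100)])
    ders = differential_regions_presence(case, ctrl)
    assert (ders["direction"] == 1).sum() == 2
    assert (ders["direction"] == -1).sum() == 1


def test_jittered_shared_peaks_leave_only_planted_uniques():
    rng = np.random.default_rng(5)
    shared = [("chr1", int(s), int(s) + 400) for s in np.arange(1000, 21000, 2000)]
    case_rows = [(c, s + int(rng.integers(-50, 51)), e + int(rng.integers(-50, 51)))
                 for c, s, e in shared]
    ctrl_rows = [(c, s + int(rng.integers(-50, 51)), e + int(rng.integers(-50, 51)))
                 for c, s, e in shared]
    case_rows.append(("chr1", 50000, 50400))  # planted gain
    ctrl_rows.append(("chr1", 60000, 60400))  # planted loss
    ders = differential_regions_presence(_peaks(case_rows), _peaks(ctrl_rows))
    assert len(ders) == 2
    gain = ders[ders["direction"] == 1].iloc[0]
    loss = ders[ders["direction"] == -1].iloc[0]
    assert (gain["start"], loss["start"]) == (50000, 60000)


def test_swapping_conditions_swaps_gain_and_loss_labels():
    rng = np.random.default_rng(6)
    case = _peaks([("chr1", int(s), int(s + 300)) for s in rng.integers(0, 9000, 12)])
    ctrl = _peaks([("chr1", int(s), int(s + 300)) for s in rng.integers(0, 9000, 12)])
    fwd = differential_regions_presence(case, ctrl)
    rev = differential_regions_presence(ctrl, case)
    fwd_key = sorted(zip(fwd["start"], fwd["direction"]))
    rev_key = sorted(zip(rev["start"], -rev["direction"]))
    assert fwd_key == rev_key


# --- count-mode DERs ---------------------------------------------------------


def test_equal_peak_counts_give_no_ders():
    col = np.arange(50, 80)
    cm = make_count_matrix(np.tile(col[:, None], (1, 8)), ["case"] * 4 + ["control"] * 4)
    res = differential_regions_counts(cm)
    assert not res["der"].any()


def test_planted_fourfold_gains_recovered(nb_sampler):
    rng = np.random.default_rng(7)
    n_peaks, n = 200, 4
    mu0 = np.exp(rng.uniform(4, 7, size=n_peaks))
    mu = np.tile(mu0[:, None], (1, 2 * n))
    mu[:40, :n] *= 4.0
    counts = nb_sampler(rng, mu, 0.05)
    cm = make_count_matrix(counts, ["case"] * n + ["control"] * n)
    res = differential_regions_counts(cm, fdr=0.05)
    gains = res.iloc[:40]
    assert ((gains["der"]) & (gains["direction"] == 1)).mean() >= 0.8
    # unshrunk small-n dispersion estimates are mildly anti-conservative
    assert res.iloc[40:]["der"].mean() <= 0.1


def test_der_calls_invariant_to_peak_row_order(nb_sampler):
    rng = np.random.default_rng(8)
    mu = np.tile(np.exp(rng.uniform(4, 6, size=60))[:, None], (1, 8))
    mu[:10, :4] *= 4
    counts = nb_sampler(rng, mu, 0.05)
    cm = make_count_matrix(counts, ["case"] * 4 + ["control"] * 4)
    res1 = differential_regions_counts(cm)
    perm = rng.permutation(60)
    cm2 = make_count_matrix(counts[perm], ["case"] * 4 + ["control"] * 4,
                            genes=[f"g{i}" for i in perm])
    res2 = differential_regions_counts(cm2)
    called1 = set(res1.index[res1["der"]])
    called2 = set(res2.index[res2["der"]])
    assert called1 == called2


# --- enhancer filtering ------------------------------------------------------


def _db(enh_rows, assoc_rows):
    enh = pd.DataFrame(enh_rows, columns=["enhancer_id", "chrom", "start", "end",
                                          "enhancer_score"]).set_index("enhancer_id")
    assoc = pd.DataFrame(assoc_rows, columns=["enhancer_id", "gene", "association_score"])
    return EnhancerDB(enh, assoc)


def test_equal_scores_keep_small_enhancers():
    db = _db([("E1", "chr1", 0, 100, 1.0), ("E2", "chr1", 500, 600, 1.0)],
             [("E1", "gA", 5.0), ("E1", "gB", 5.0), ("E2", "gC", 5.0)])
    out = filter_enhancer_associations(db)
    assert set(out.enhancers.index) == {"E1", "E2"}
    assert len(out.associations) == 3


def test_enhancer_with_six_surviving_genes_dropped():
    assoc = [("E1", f"g{i}", 10.0) for i in range(6)] + [("E2", "gX", 10.0)]
    db = _db([("E1", "chr1", 0, 100, 1.0), ("E2", "chr1", 500, 600, 1.0)], assoc)
    out = filter_enhancer_associations(db)
    assert set(out.enhancers.index) == {"E2"}


def test_filter_matches_explicit_quantile_oracle():
    rng = np.random.default_rng(9)
    enh_rows = [(f"E{i}", "chr1", i * 1000, i * 1000 + 100, float(rng.uniform(0, 3)))
                for i in range(40)]
    assoc_rows = [(f"E{rng.integers(0, 40)}", f"g{rng.integers(0, 60)}",
                   float(rng.uniform(0, 30))) for _ in range(200)]
    assoc_rows = list({(e, g): (e, g, s) for e, g, s in assoc_rows}.values())
    db = _db(enh_rows, assoc_rows)
    out = filter_enhancer_associations(db)

    q1e = np.quantile([r[4] for r in enh_rows], 0.25)
    q1a = np.quantile([r[2] for r in assoc_rows], 0.25)
    surv = {}
    for e, g, s in assoc_rows:
        if s >= q1a and db.enhancers.loc[e, "enhancer_score"] >= q1e:
            surv.setdefault(e, set()).add(g)
    expected_enh = {e for e, genes in surv.items() if len(genes) <= 5}
    assert set(out.enhancers.index) == expected_enh
    expected_assoc = {(e, g) for e in expected_enh for g in surv[e]}
    assert set(zip(out.associations["enhancer_id"], out.associations["gene"])) == expected_assoc


# --- annotation --------------------------------------------------------------


@pytest.fixture
def toy_genome():
    """Hand-placed genome: two genes, one enhancer, known promoter windows.

    gA: chr1:[10000,15000) '+', TSS 10000, window [7000,13000)
    gB: chr1:[40000,46000) '-', TSS 46000, window [43000,49000)
    E1: chr1:[25000,25500) -> gA, gB
    """
    ann = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [10000, 40000], "end": [15000, 46000],
         "strand": ["+", "-"], "tss": [10000, 46000]},
        index=pd.Index(["gA", "gB"], name="gene"),
    )
    db = _db([("E1", "chr1", 25000, 25500, 2.0)],
             [("E1", "gA", 10.0), ("E1", "gB", 9.0)])
    return ann, db


def test_hand_computed_classification_table(toy_genome):
    """Eight hand-computed cases covering promoter, intergenic, discard, tie."""
    ann, db = toy_genome
    ders = pd.DataFrame(
        [
            ("chr1", 9800, 10200, 1),    # 1 centred on gA TSS -> promoter gA
            ("chr1", 12500, 12900, 1),   # 2 inside gA body but within window -> promoter gA
            ("chr1", 13500, 14000, -1),  # 3 genic, beyond window -> discarded
            ("chr1", 25100, 25400, 1),   # 4 intergenic on E1 -> gA and gB
            ("chr1", 30000, 30500, -1),  # 5 intergenic, no enhancer -> nothing
            ("chr1", 43100, 43600, -1),  # 6 in gB window (TSS 46000 on '-') -> promoter gB
            ("chr1", 6500, 7500, 1),     # 7 upstream edge of gA window -> promoter gA
            ("chr9", 100, 200, 1),       # 8 unknown chromosome -> skipped
        ],
        columns=["chrom", "start", "end", "direction"],
    )
    out = annotate_peaks(ders, ann, db, promoter_halfwidth=3000)
    got = set(zip(out["gene"], out["peak_id"], out["element"], out["direction"]))
    expected = {
        ("gA", 0, "promoter", 1),
        ("gA", 1, "promoter", 1),
        ("gA", 3, "enhancer", 1),
        ("gB", 3, "enhancer", 1),
        ("gB", 5, "promoter", -1),
        ("gA", 6, "promoter", 1),
    }
    assert got == expected


def test_tie_breaks_to_nearest_then_lexicographic():
    ann = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [0, 5000], "end": [100, 5100],
         "strand": ["+", "+"], "tss": [0, 5000]},
        index=pd.Index(["gZ", "gA"], name="gene"),
    )
    db = _db([("E1", "chr1", 0, 10, 0.5)], [("E1", "gZ", 1.0)])
    # peak centred at 2500: exactly halfway between both TSSs -> smallest id
    ders = pd.DataFrame([("chr1", 2400, 2600, 1)],
                        columns=["chrom", "start", "end", "direction"])
    out = annotate_peaks(ders, ann, db)
    assert list(out["gene"]) == ["gA"]


def test_annotation_independent_of_peak_order(toy_genome):
    ann, db = toy_genome
    rows = [("chr1", 9800, 10200, 1), ("chr1", 25100, 25400, -1),
            ("chr1", 43100, 43600, 1)]
    fwd = annotate_peaks(pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"]),
                         ann, db)
    rev = annotate_peaks(pd.DataFrame(rows[::-1], columns=["chrom", "start", "end", "direction"]),
                         ann, db)
    assert set(zip(fwd["gene"], fwd["element"], fwd["direction"])) == \
        set(zip(rev["gene"], rev["element"], rev["direction"]))


def test_gader_signature_drops_conflicting_genes():
    gaders = pd.DataFrame(
        {"gene": ["gA", "gA", "gB"], "direction": [1, -1, 1],
         "element": ["promoter", "enhancer", "promoter"], "peak_id": [0, 1, 2]}
    )
    assert gader_signature(gaders) == {"gB": 1}
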