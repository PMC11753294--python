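"""Signed network construction, TOM, module detection, eigengenes."""

import numpy as np
import pandas as pd
import pytest

from omixnet.network import (
    batch_adjust,
    build_network,
    detect_modules,
    low_count_filter,
    module_eigengenes,
    module_trait_correlation,
    pick_soft_threshold,
    scale_free_fit,
    vst,
)
from .conftest import make_count_matrix


def _block_expr(rng, sizes, loading=0.9, n_samples=40, n_noise=0):
    """Latent-factor correlation blocks plus independent noise genes."""
    rows, labels = [], []
    for b, size in enumerate(sizes, start=1):
        factor = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(loading * factor + np.sqrt(1 - loading**2) * rng.normal(size=n_samples))
            labels.append(b)
    for _ in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        labels.append(0)
    genes = [f"g{i:04d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=genes), pd.Series(labels, index=genes)


# --- filtering + transform ---------------------------------------------------


def test_low_count_filter_rules():
    rng = np.random.default_rng(0)
    counts = rng.integers(20, 100, size=(3, 6))
    counts[0] = 0  # all-zero gene: removed
    counts[1] = 50  # comfortably expressed: retained
    cm1 = make_count_matrix(counts, ["case"] * 3 + ["control"] * 3, dataset="ds1")
    kept = low_count_filter([cm1])
    assert "g0" not in kept and "g1" in kept


def test_low_count_filter_matches_direct_counting_oracle():
    rng = np.random.default_rng(1)
    datasets = []
    for d in range(3):
        counts = rng.integers(0, 40, size=(50, 8))
        datasets.append(make_count_matrix(counts, ["case"] * 4 + ["control"] * 4,
                                          dataset=f"ds{d}"))
    kept = set(low_count_filter(datasets, min_count=15, frac=0.5))
    for gi in range(50):
        removed = any(
            (ds.counts.iloc[gi].to_numpy() < 15).mean() > 0.5 for ds in datasets
        )
        assert (f"g{gi}" in kept) == (not removed)


def test_vst_closed_forms():
    cm = make_count_matrix(np.array([[0, 3, 6]]), ["case", "control", "control"])
    sf = pd.Series([1.0, 1.0, 2.0], index=cm.samples)
    out = vst(cm, sf)
    assert out.iloc[0, 0] == 0.0
    assert out.iloc[0, 1] == pytest.approx(2.0)  # log2(3/1 + 1)
    assert out.iloc[0, 2] == pytest.approx(2.0)  # doubling count and factor


# --- batch adjustment --------------------------------------------------------


def test_single_batch_returned_unchanged():
    rng = np.random.default_rng(2)
    expr = pd.DataFrame(rng.normal(size=(20, 10)),
                        index=[f"g{i}" for i in range(20)],
                        columns=[f"s{j}" for j in range(10)])
    batch = pd.Series("b1", index=expr.columns)
    cond = pd.Series(["case"] * 5 + ["control"] * 5, index=expr.columns)
    pd.testing.assert_frame_equal(batch_adjust(expr, batch, cond), expr)


def test_planted_batch_offsets_removed_condition_preserved():
    rng = np.random.default_rng(3)
    n_genes, n_per = 150, 20
    base = rng.normal(5, 1, size=n_genes)
    offsets = rng.normal(0, 1.0, size=n_genes)  # batch 2 offset per gene
    cond_effect = np.zeros(n_genes)
    cond_effect[:30] = 1.5
    cols, batches, conds = [], [], []
    for b in range(2):
        for c, label in ((1, "case"), (0, "control")):
            for _ in range(n_per // 2):
                cols.append(base + b * offsets + c * cond_effect
                            + rng.normal(0, 0.5, size=n_genes))
                batches.append(f"b{b}")
                conds.append(label)
    expr = pd.DataFrame(np.column_stack(cols), index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(len(cols))])
    batch = pd.Series(batches, index=expr.columns)
    cond = pd.Series(conds, index=expr.columns)
    out = batch_adjust(expr, batch, cond)

    def batch_gap(df):
        m1 = df.loc[:, (batch == "b0").to_numpy()].mean(axis=1)
        m2 = df.loc[:, (batch == "b1").to_numpy()].mean(axis=1)
        return np.abs(m1 - m2).mean()

    assert batch_gap(out) < 0.2 * batch_gap(expr)

    def cond_gap(df):
        m1 = df.loc[:, (cond == "case").to_numpy()].iloc[:30].mean(axis=1)
        m2 = df.loc[:, (cond == "control").to_numpy()].iloc[:30].mean(axis=1)
        return (m1 - m2).mean()

    assert cond_gap(out) == pytest.approx(cond_gap(expr), rel=0.2)


def test_confounded_design_rejected():
    rng = np.random.default_rng(4)
    expr = pd.DataFrame(rng.normal(size=(10, 8)), columns=[f"s{j}" for j in range(8)])
    batch = pd.Series(["b0"] * 4 + ["b1"] * 4, index=expr.columns)
    cond = pd.Series(["case"] * 4 + ["control"] * 4, index=expr.columns)
    with pytest.raises(ValueError, match="confounded"):
        batch_adjust(expr, batch, cond)


# --- soft threshold ----------------------------------------------------------


def test_fit_statistic_matches_independent_binned_regression():
    from scipy import stats as sps

    rng = np.random.default_rng(5)
    k = rng.pareto(2.0, size=400) * 5 + 1
    fit, slope = scale_free_fit(k, n_bins=10)

    edges = np.linspace(k.min(), k.max(), 11)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
    xs, ys = [], []
    for b in range(10):
        mask = which == b
        if mask.sum():
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.mean()))
    sl, _, r, _, _ = sps.linregress(xs, ys)
    assert fit == pytest.approx(r**2 * -np.sign(sl), abs=1e-10)


def test_exact_scale_free_degree_sequence_reaches_target_fit():
    """A power-law degree sequence scores a signed fit >= 0.8."""
    rng = np.random.default_rng(6)
    # Zipf-like connectivities with mild multiplicative noise
    k = 200.0 * np.arange(1, 500) ** -0.7 * np.exp(rng.normal(0, 0.05, size=499))
    fit, slope = scale_free_fit(k)
    assert slope < 0
    assert fit >= 0.8


def test_constant_gene_rejected():
    expr = pd.DataFrame(np.ones((31, 10)))
    with pytest.raises(ValueError, match="constant"):
        pick_soft_threshold(expr)


# --- adjacency + TOM ---------------------------------------------------------


def test_perfectly_correlated_pair_saturates_tom():
    x = np.arange(10.0)
    expr = pd.DataFrame([x, 2 * x + 1], index=["g0", "g1"])
    net = build_network(expr, beta=6)
    assert net.adjacency[0, 1] == pytest.approx(1.0)
    assert net.tom[0, 1] == pytest.approx(1.0)
    assert net.diss_tom[0, 1] == pytest.approx(0.0)


def test_anticorrelated_pair_disconnected_in_signed_network():
    x = np.arange(10.0)
    expr = pd.DataFrame([x, -x], index=["g0", "g1"])
    net = build_network(expr, beta=6)
    assert net.adjacency[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_tom_matches_triple_loop_oracle():
    """Oracle: O(n^3) direct evaluation of the TOM formula, 12 genes."""
    rng = np.random.default_rng(7)
    expr = pd.DataFrame(rng.normal(size=(12, 30)))
    net = build_network(expr, beta=6)
    a = net.adjacency
    n = a.shape[0]
    expected = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            expected[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    np.testing.assert_allclose(net.tom, expected, atol=1e-10)


def test_tom_bounded_and_adjacency_monotone_in_beta():
    rng = np.random.default_rng(8)
    expr = pd.DataFrame(rng.normal(size=(25, 20)))
    prev = None
    for beta in (2, 4, 8):
        net = build_network(expr, beta=beta)
        assert (net.tom >= 0).all() and (net.tom <= 1).all()
        off = net.adjacency[~np.eye(25, dtype=bool)]
        if prev is not None:
            assert (off <= prev + 1e-12).all()
        prev = off


# --- module detection --------------------------------------------------------


def test_two_planted_blocks_recovered_exactly():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(9)
    expr, labels_true = _block_expr(rng, [50, 60], loading=0.9, n_noise=40)
    net = build_network(expr, beta=6)
    labels = detect_modules(net, expr)
    assert adjusted_rand_score(labels_true, labels) == 1.0


def test_pure_noise_yields_no_modules():
    rng = np.random.default_rng(10)
    expr, _ = _block_expr(rng, [], n_noise=120)
    net = build_network(expr, beta=6)
    labels = detect_modules(net, expr)
    assert labels.max() == 0


def test_modules_sharing_a_factor_are_merged():
    rng = np.random.default_rng(11)
    factor = rng.normal(size=40)
    rows = [0.9 * factor + 0.35 * rng.normal(size=40) for _ in range(80)]
    expr = pd.DataFrame(rows, index=[f"g{i:03d}" for i in range(80)])
    net = build_network(expr, beta=6)
    labels = detect_modules(net, expr, min_module_size=30)
    assert labels.max() == 1  # one module despite two nominal halves


def test_module_labels_invariant_to_gene_order():
    rng = np.random.default_rng(12)
    expr, _ = _block_expr(rng, [40, 35], loading=0.85, n_noise=30)
    net1 = build_network(expr, beta=6)
    l1 = detect_modules(net1, expr)
    perm = rng.permutation(len(expr))
    expr2 = expr.iloc[perm]
    net2 = build_network(expr2, beta=6)
    l2 = detect_modules(net2, expr2)
    pd.testing.assert_series_equal(l1.sort_index(), l2.sort_index())


# --- eigengenes + trait ------------------------------------------------------


def test_identical_member_genes_give_unit_kme():
    profile = np.sin(np.arange(20.0))
    expr = pd.DataFrame([profile + i * 0 for i in range(5)],
                        index=[f"g{i}" for i in range(5)])
    labels = pd.Series(1, index=expr.index)
    me = module_eigengenes(expr, labels)
    np.testing.assert_allclose(me.kme[1], 1.0, atol=1e-10)


def test_eigengene_beats_random_directions():
    rng = np.random.default_rng(13)
    expr, labels_true = _block_expr(rng, [30], loading=0.7, n_noise=0)
    me = module_eigengenes(expr, pd.Series(1, index=expr.index))
    z = (expr - expr.mean(axis=1).to_numpy()[:, None]).div(
        expr.std(axis=1, ddof=0), axis=0).to_numpy()
    ev = me.eigengenes[1].to_numpy()
    var_ev = ((z @ ev) ** 2).sum()
    for _ in range(100):
        d = rng.normal(size=expr.shape[1])
        d /= np.linalg.norm(d)
        assert var_ev >= ((z @ d) ** 2).sum() - 1e-9


def test_sign_convention_restores_positive_membership():
    rng = np.random.default_rng(14)
    expr, _ = _block_expr(rng, [20], loading=0.9, n_noise=0)
    me1 = module_eigengenes(expr, pd.Series(1, index=expr.index))
    me2 = module_eigengenes(-expr, pd.Series(1, index=expr.index))
    assert me1.kme[1].mean() > 0
    assert me2.kme[1].mean() > 0


def test_trait_correlation_matches_t_formula():
    from scipy import stats as sps

    rng = np.random.default_rng(15)
    expr, _ = _block_expr(rng, [25], loading=0.8, n_noise=0, n_samples=30)
    me = module_eigengenes(expr, pd.Series(1, index=expr.index))
    trait = pd.Series(rng.integers(0, 2, size=30), index=me.eigengenes.index)
    out = module_trait_correlation(me, trait)
    r_ref, p_ref = sps.pearsonr(me.eigengenes[1], trait)
    assert out.loc[1, "r"] == pytest.approx(r_ref, abs=1e-10)
    assert out.loc[1, "pvalue"] == pytest.approx(p_ref, abs=1e-10)


def test_eigengene_identical_to_trait_gives_unit_correlation():
    trait = pd.Series([1, 0] * 10, index=[f"s{i}" for i in range(20)])
    rng = np.random.default_rng(16)
    expr = pd.DataFrame([trait.to_numpy() * 1.0 + 1e-6 * rng.normal(size=20)
                         for _ in range(5)],
                        index=[f"g{i}" for i in range(5)],
                        columns=trait.index)
    me = module_eigengenes(expr, pd.Series(1, index=expr.index))
    out = module_trait_correlation(me, trait)
    assert abs(out.loc[1, "r"]) == pytest.approx(1.0, abs=1e-3)


def test_constant_trait_rejected():
    rng = np.random.default_rng(17)
    expr, _ = _block_expr(rng, [10], n_samples=12)
    me = module_eigengenes(expr, pd.Series(1, index=expr.index))
    with pytest.raises(ValueError, match="constant"):
        module_trait_correlation(me, pd.Series(1, index=me.eigengenes.index))
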