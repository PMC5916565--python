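"""Binarization, ortholog expansion, UPGMA and multiscale bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jaccard as scipy_jaccard

from hsnsig.homology import (
    average_linkage,
    binarize_cpm,
    binary_distance,
    control_random_sets,
    expand_orthologs,
    filter_neuron_matrix,
    multiscale_bootstrap,
    pairwise_binary_distance,
)


# ---------------------------------------------------------------------------
# binarization and filtering


def test_binarize_cpm_strict_threshold():
    cpm = pd.DataFrame({"s": [19.0, 19.01, 0.0, 140.0]},
                       index=["a", "b", "c", "d"])
    out = binarize_cpm(cpm, 19.0)
    assert out["s"].tolist() == [0, 1, 0, 1]


def test_binarize_rejects_negative():
    with pytest.raises(ValueError):
        binarize_cpm(pd.DataFrame({"s": [-1.0]}), 19.0)


def test_binarize_threshold_sweep_monotone():
    rng = np.random.default_rng(0)
    cpm = pd.DataFrame(rng.lognormal(np.log(20), 1.5, size=(500, 3)))
    counts = [binarize_cpm(cpm, t).to_numpy().sum()
              for t in np.linspace(9, 140, 12)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_filter_column_floor_boundary():
    genes = [f"g{i}" for i in range(40)]
    mat = pd.DataFrame(0, index=genes, columns=["c29", "c30", "c40"])
    mat.iloc[:29, 0] = 1
    mat.iloc[:30, 1] = 1
    mat.iloc[:40, 2] = 1
    out = filter_neuron_matrix(mat, 30, [])
    assert list(out.columns) == ["c30", "c40"]


def test_filter_drops_pan_genes_before_counting():
    genes = [f"g{i}" for i in range(40)]
    mat = pd.DataFrame(0, index=genes, columns=["c"])
    mat.iloc[:31, 0] = 1
    # without pan removal the column passes; removing two pan genes sinks it
    assert filter_neuron_matrix(mat, 30, []).shape[1] == 1
    with pytest.raises(ValueError):
        filter_neuron_matrix(mat, 30, ["g0", "g1"])


def test_filter_counting_oracle():
    rng = np.random.default_rng(1)
    mat = pd.DataFrame(rng.integers(0, 2, (60, 8)),
                       index=[f"g{i}" for i in range(60)],
                       columns=[f"c{i}" for i in range(8)])
    pan = [f"g{i}" for i in range(5)]
    out = filter_neuron_matrix(mat, 20, pan)
    survivors = [c for c in mat.columns
                 if sum(mat.loc[g, c] for g in mat.index if g not in pan) >= 20]
    assert list(out.columns) == survivors
    assert len(out.index) == 55


# ---------------------------------------------------------------------------
# ortholog expansion


def test_expand_duplicates_multi_ortholog_genes():
    src = pd.DataFrame({"n1": [1, 1, 0], "n2": [0, 1, 0]},
                       index=["g1", "g2", "g3"])
    out = expand_orthologs(src, {"g1": ["m1", "m2"], "g2": ["m3"], "g3": ["m4"]})
    # g1 duplicated; g3 dropped (not expressed anywhere)
    assert sorted(out.index) == ["m1", "m2", "m3"]
    assert out.loc["m1"].tolist() == out.loc["m2"].tolist() == [1, 0]


def test_expand_drops_unmapped_genes():
    src = pd.DataFrame({"n1": [1, 1]}, index=["g1", "g2"])
    out = expand_orthologs(src, {"g1": ["m1"]})
    assert list(out.index) == ["m1"]


def test_expand_row_count_oracle():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(50)]
    src = pd.DataFrame(rng.integers(0, 2, (50, 4)), index=genes)
    omap = {g: [f"m{g}_{j}" for j in range(rng.integers(0, 4))] for g in genes}
    out = expand_orthologs(src, omap)
    expected = sum(len(omap[g]) for g in genes if src.loc[g].sum() > 0)
    assert len(out) == expected


# ---------------------------------------------------------------------------
# binary distance


def test_binary_distance_examples():
    assert binary_distance([1, 0, 1, 0], [1, 0, 1, 0]) == 0.0
    assert binary_distance([1, 0, 1, 0], [0, 1, 1, 0]) == pytest.approx(2 / 3)
    assert binary_distance([1, 1, 1], [0, 0, 0]) == 1.0
    assert binary_distance([0, 0], [0, 0]) == 0.0  # defined, not NaN


def test_binary_distance_matches_scipy_jaccard():
    rng = np.random.default_rng(3)
    for _ in range(50):
        u = rng.integers(0, 2, 30).astype(bool)
        v = rng.integers(0, 2, 30).astype(bool)
        if not (u | v).any():
            continue
        assert binary_distance(u, v) == pytest.approx(scipy_jaccard(u, v))


def test_pairwise_matches_elementwise():
    rng = np.random.default_rng(4)
    x = rng.integers(0, 2, (40, 6))
    d = pairwise_binary_distance(x)
    for i, j in itertools.combinations(range(6), 2):
        assert d[i, j] == pytest.approx(binary_distance(x[:, i], x[:, j]))
        assert d[i, j] == d[j, i]


# ---------------------------------------------------------------------------
# average linkage


def test_upgma_hand_example():
    d = np.array([[0.0, 0.1, 0.4],
                  [0.1, 0.0, 0.4],
                  [0.4, 0.4, 0.0]])
    tree = average_linkage(d, ["A", "B", "C"])
    assert tree.merges[0][2] == pytest.approx(0.1)
    assert tree.merges[0][0] | tree.merges[0][1] == frozenset("AB")
    assert tree.merges[1][2] == pytest.approx(0.4)


def test_identical_columns_merge_first_at_zero():
    x = np.array([[1, 1, 0], [0, 0, 1], [1, 1, 1]])
    d = pairwise_binary_distance(x)
    tree = average_linkage(d, ["a", "b", "c"])
    assert tree.merges[0][2] == 0.0
    assert tree.merges[0][0] | tree.merges[0][1] == frozenset(["a", "b"])


def _oracle_upgma(d, labels):
    """Naive UPGMA recomputing cluster means from the original matrix."""
    clusters = [[i] for i in range(len(labels))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            mean = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            tag = tuple(sorted((min(labels[i] for i in clusters[a]),
                                min(labels[j] for j in clusters[b]))))
            key = (mean, tag)
            if best is None or key < best[0]:
                best = (key, a, b)
        (mean, _), a, b = best
        merges.append((frozenset(labels[i] for i in clusters[a]),
                       frozenset(labels[i] for i in clusters[b]), mean))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] \
            + [clusters[a] + clusters[b]]
    return merges


def test_upgma_equals_naive_oracle():
    rng = np.random.default_rng(5)
    for trial in range(40):
        n = int(rng.integers(3, 11))
        x = rng.integers(0, 2, (30, n))
        d = pairwise_binary_distance(x)
        labels = [f"L{i}" for i in range(n)]
        got = average_linkage(d, labels)
        want = _oracle_upgma(d, labels)
        for (ga, gb, gh), (wa, wb, wh) in zip(got.merges, want):
            assert {ga, gb} == {wa, wb}, trial
            assert gh == pytest.approx(wh)


def test_upgma_rejects_asymmetric():
    with pytest.raises(ValueError):
        average_linkage(np.array([[0.0, 1.0], [0.5, 0.0]]), ["a", "b"])


def test_newick_output_is_parseable():
    dendropy = pytest.importorskip("dendropy")
    rng = np.random.default_rng(6)
    x = rng.integers(0, 2, (40, 6))
    tree = average_linkage(pairwise_binary_distance(x),
                           [f"L{i}" for i in range(6)])
    t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    assert len(t.leaf_nodes()) == 6


# ---------------------------------------------------------------------------
# multiscale bootstrap


def planted_blocks(n_rows=200, p_in=0.9, p_out=0.1, seed=0):
    rng = np.random.default_rng(seed)
    cols = [f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)]
    x = np.zeros((n_rows, 10), dtype=int)
    block = rng.random(n_rows) < 0.5      # rows assigned to block A or B
    for ci, c in enumerate(cols):
        in_a = c.startswith("A")
        p = np.where(block == in_a, p_in, p_out)
        x[:, ci] = rng.random(n_rows) < p
    return pd.DataFrame(x, columns=cols)


def test_planted_blocks_get_high_au():
    mat = planted_blocks()
    tree = multiscale_bootstrap(mat, nboot=400, seed=1)
    for block in ("A", "B"):
        node = tree.node([c for c in mat.columns if c.startswith(block)])
        assert node.bp > 0.9
        assert node.au > 0.95


def test_perfect_cluster_clamps_to_one():
    mat = planted_blocks(p_in=1.0, p_out=0.0)
    tree = multiscale_bootstrap(mat, nboot=100, seed=2)
    node = tree.node([c for c in mat.columns if c.startswith("A")])
    assert node.bp == 1.0
    assert node.au == 1.0


def test_single_scale_reports_bp_but_no_au():
    mat = planted_blocks()
    tree = multiscale_bootstrap(mat, nboot=200, scales=[1.0], seed=3)
    node = tree.node([c for c in mat.columns if c.startswith("A")])
    assert node.au is None
    assert 0.0 <= node.bp <= 1.0


def test_column_permutation_equivariance():
    """Permuting columns permutes leaves; topology, heights, BP, AU and the
    row-resampling stream are unchanged."""
    mat = planted_blocks(seed=4)
    perm = list(np.random.default_rng(5).permutation(mat.columns))
    t1 = multiscale_bootstrap(mat, nboot=150, seed=6)
    t2 = multiscale_bootstrap(mat[perm], nboot=150, seed=6)
    s1 = {n.leaves: (n.bp, n.au, round(n.height, 12)) for n in t1.nodes}
    s2 = {n.leaves: (n.bp, n.au, round(n.height, 12)) for n in t2.nodes}
    assert set(s1) == set(s2)
    for k in s1:
        assert s1[k][0] == s2[k][0]
        assert s1[k][1] == pytest.approx(s2[k][1], abs=1e-9)
        assert s1[k][2] == pytest.approx(s2[k][2])


def test_au_monotone_in_block_contrast():
    """Stronger planted contrast never weakens the planted cluster's AU."""
    aus = []
    for p_in in (0.6, 0.75, 0.9):
        mat = planted_blocks(p_in=p_in, p_out=1 - p_in, seed=7)
        tree = multiscale_bootstrap(mat, nboot=300, seed=8)
        want = frozenset(c for c in mat.columns if c.startswith("A"))
        # a contrast too weak to put the block in the base tree counts as 0
        au = tree.node(want).au if tree.has_cluster(want) else 0.0
        aus.append(au)
    assert aus[0] <= aus[1] <= aus[2] + 1e-9


def test_bootstrap_needs_enough_columns():
    with pytest.raises(ValueError):
        multiscale_bootstrap(pd.DataFrame({"a": [1, 0], "b": [0, 1]}), nboot=10)


# ---------------------------------------------------------------------------
# control sets


def test_control_sets_contain_anchors_and_have_size():
    pool = [f"g{i}" for i in range(300)] + ["tph-1", "bas-1", "cat-1", "cat-4"]
    sets = control_random_sets(pool, ["tph-1", "bas-1", "cat-1", "cat-4"],
                               n_sets=20, set_size=96, seed=0)
    for s in sets:
        assert len(s) == 96
        assert {"tph-1", "bas-1", "cat-1", "cat-4"} <= set(s)
        assert len(set(s)) == 96


def test_control_sets_sample_pool_uniformly():
    pool = [f"g{i}" for i in range(100)] + ["a1", "a2", "a3", "a4"]
    sets = control_random_sets(pool, ["a1", "a2", "a3", "a4"],
                               n_sets=200, set_size=30, seed=1)
    counts = pd.Series([g for s in sets for g in s if not g.startswith("a")])
    freq = counts.value_counts()
    # every non-anchor gene drawn a similar number of times
    assert freq.max() < 2.5 * freq.min()


def test_control_sets_pool_too_small():
    with pytest.raises(ValueError):
        control_random_sets(["a1", "g1"], ["a1"], n_sets=1, set_size=10, seed=0)
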