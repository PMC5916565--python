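"""Signature-window discovery, merging and gene classification."""

import itertools

import numpy as np
import pytest

from hsnsig.motifs import MotifMatch
from hsnsig.windows import (
    SignatureWindow,
    classify_genes,
    find_gene_windows,
    find_windows,
    merge_windows,
    prevalence_by_class,
)

FAMS = ["ETS", "GATA", "HLH", "INSM", "SPALT", "POU"]


def mk(family, start, width=6, region="r1"):
    return MotifMatch(family, region, start, start + width, "+", 0.9)


# ---------------------------------------------------------------------------
# find_windows examples


def test_six_families_within_span_give_tier6_window():
    matches = [mk(f, p) for f, p in zip(FAMS, range(100, 700, 100))]
    ws = find_windows(matches, l_max=700, k_min=4)
    tier6 = [w for w in ws if w.tier == 6]
    assert len(tier6) == 1
    assert (tier6[0].start, tier6[0].end) == (100, 606)


def test_distant_sixth_family_caps_tier_at_five():
    positions = dict(zip(FAMS, [0, 100, 200, 300, 400, 850]))
    ws = find_windows([mk(f, p) for f, p in positions.items()], 700, 4)
    assert max(w.tier for w in ws) == 5
    best = max(ws, key=lambda w: w.tier)
    assert best.families == frozenset(FAMS[:5])


def test_below_k_min_yields_nothing():
    assert find_windows([mk("ETS", 0), mk("GATA", 50)], 700, 4) == []
    assert find_windows([], 700, 4) == []


def test_windows_from_two_regions_rejected():
    with pytest.raises(ValueError):
        find_windows([mk("ETS", 0, region="a"), mk("GATA", 0, region="b")])


# ---------------------------------------------------------------------------
# merge_windows


def w(start, end, fams, tier_region="r1"):
    return SignatureWindow(tier_region, "g", start, end, frozenset(fams))


def test_merge_overlapping_same_tier():
    merged = merge_windows([w(100, 500, FAMS[:4]), w(400, 800, FAMS[:4])])
    assert [(m.start, m.end) for m in merged] == [(100, 800)]


def test_merge_disjoint_unchanged():
    merged = merge_windows([w(0, 100, FAMS[:4]), w(200, 300, FAMS[:4])])
    assert [(m.start, m.end) for m in merged] == [(0, 100), (200, 300)]


def test_merge_keeps_tiers_separate():
    merged = merge_windows([w(0, 100, FAMS[:4]), w(50, 150, FAMS[:5])])
    assert len(merged) == 2


def _sweep_merge(intervals):
    """Independent sort-and-sweep union oracle."""
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def test_merge_equals_sweep_oracle():
    rng = np.random.default_rng(5)
    for _ in range(50):
        iv = [(int(s), int(s + l)) for s, l in
              zip(rng.integers(0, 1000, 20), rng.integers(10, 200, 20))]
        merged = merge_windows([w(s, e, FAMS[:4]) for s, e in iv])
        assert [(m.start, m.end) for m in merged] == _sweep_merge(iv)


# ---------------------------------------------------------------------------
# exhaustive interval oracle


def oracle_windows(matches, l_max, k_min):
    """All match-bounded intervals of span <= l_max, grouped by exact
    distinct-family count, merged per group (pure enumeration)."""
    per_tier = {}
    for a, b in itertools.product(matches, matches):
        s, e = a.start, b.end
        if e <= s or e - s > l_max:
            continue
        fams = frozenset(m.family for m in matches if m.start >= s and m.end <= e)
        if len(fams) >= k_min:
            per_tier.setdefault(len(fams), []).append((s, e, fams))
    out = []
    for k, items in per_tier.items():
        merged = []
        for s, e, fams in sorted(items):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2] |= fams
            else:
                merged.append([s, e, set(fams)])
        out.extend((s, e, k, frozenset(f)) for s, e, f in merged)
    return sorted(out, key=lambda t: (t[0], t[1], t[2]))


def random_matches(rng, n, region_len=3000):
    fams = rng.choice(FAMS, size=n)
    starts = rng.integers(0, region_len - 10, size=n)
    widths = rng.integers(6, 11, size=n)
    return [mk(f, int(s), int(wd)) for f, s, wd in zip(fams, starts, widths)]


def test_find_windows_equals_interval_oracle():
    rng = np.random.default_rng(6)
    for trial in range(60):
        matches = random_matches(rng, int(rng.integers(4, 40)))
        l_max = int(rng.choice([600, 700, 800]))
        k_min = int(rng.choice([2, 3, 4]))
        got = sorted(((w.start, w.end, w.tier, w.families)
                      for w in find_windows(matches, l_max, k_min)),
                     key=lambda t: (t[0], t[1], t[2]))
        assert got == oracle_windows(matches, l_max, k_min), trial


def test_permutation_safety():
    rng = np.random.default_rng(7)
    matches = random_matches(rng, 25)
    ref = find_windows(matches, 700, 4)
    for _ in range(5):
        rng.shuffle(matches)
        assert find_windows(matches, 700, 4) == ref


def test_lmax_monotonicity():
    """Growing L_max never removes a gene from any >=k class."""
    rng = np.random.default_rng(8)
    matches = random_matches(rng, 30)
    tiers = {}
    for l_max in (600, 700, 800):
        ws = find_windows(matches, l_max, 2)
        tiers[l_max] = max((w.tier for w in ws), default=0)
    assert tiers[600] <= tiers[700] <= tiers[800]


# ---------------------------------------------------------------------------
# classification


def test_classify_genes_max_over_regions():
    matches = [mk(f, p, region="up") for f, p in zip(FAMS, range(0, 600, 100))]
    matches += [mk(f, p, region="in") for f, p in zip(FAMS[:4], range(0, 400, 100))]
    profiles = find_gene_windows(matches, {"up": "g1", "in": "g1", "other": "g2"})
    cls = classify_genes(profiles)
    assert cls["g1"] == 6
    assert cls["g2"] is None


def test_classify_unknown_region_fails():
    with pytest.raises(KeyError):
        find_gene_windows([mk("ETS", 0, region="nowhere")], {"up": "g1"})


def test_classify_unknown_gene_fails():
    matches = [mk(f, p, region="up") for f, p in zip(FAMS, range(0, 600, 100))]
    profiles = find_gene_windows(matches, {"up": "g1"})
    with pytest.raises(ValueError):
        classify_genes(profiles, gene_universe=["g2"])


def test_classification_matches_generator_truth(models, small_genome):
    from hsnsig.motifs import scan_regions
    g = small_genome
    matches = scan_regions(models.values(), g.regions)
    profiles = find_gene_windows(matches, {r.region_id: r.gene_id for r in g.regions})
    cls = classify_genes(profiles, g.universe.index)
    planted = set(g.truth.query("planted_tier == 6")["gene_id"])
    found = {k for k, v in cls.items() if v is not None and v >= 6}
    assert planted <= found  # every planted cluster is recovered


# ---------------------------------------------------------------------------
# prevalence


def test_prevalence_independence_and_formula():
    classes = {}
    cls = {}
    # balanced table -> chi2 0, p 1
    for i in range(40):
        g = f"g{i}"
        classes[g] = "neuronal" if i < 20 else "non_neuronal"
        cls[g] = 6 if i % 2 == 0 else None
    res = prevalence_by_class(classes, cls, 6)
    assert res["chi2"] == pytest.approx(0.0)
    assert res["p_value"] == pytest.approx(1.0)


def test_prevalence_hand_computed_chi2():
    # table [[30,10],[10,30]]: chi2 = sum (O-E)^2/E = 20.0
    classes = {}
    cls = {}
    i = 0
    for klass, with_sig, without in (("neuronal", 30, 10), ("non_neuronal", 10, 30)):
        for _ in range(with_sig):
            classes[f"g{i}"] = klass; cls[f"g{i}"] = 6; i += 1
        for _ in range(without):
            classes[f"g{i}"] = klass; cls[f"g{i}"] = None; i += 1
    res = prevalence_by_class(classes, cls, 6)
    assert res["chi2"] == pytest.approx(20.0)


def test_prevalence_detects_planted_enrichment():
    rng = np.random.default_rng(9)
    classes, cls = {}, {}
    for i in range(800):
        g = f"g{i}"
        classes[g] = "neuronal" if i < 400 else "non_neuronal"
        rate = 0.3 if classes[g] == "neuronal" else 0.12
        cls[g] = 6 if rng.random() < rate else None
    res = prevalence_by_class(classes, cls, 6)
    assert res["p_value"] < 0.05
    assert res["prop"]["neuronal"] > res["prop"]["non_neuronal"]


def test_prevalence_empty_class_fails():
    with pytest.raises(ValueError):
        prevalence_by_class({"g1": "neuronal"}, {"g1": 6}, 6)
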