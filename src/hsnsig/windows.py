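"""Multi-motif signature windows: discovery, merging, gene classification.

A regulatory signature window is a stretch of a regulatory region (at most
``L_max`` bp before merging) containing at least one consensus-filtered PWM
match for each of ``k`` distinct TF families.  Windows are tiered by their
exact distinct-family count (4, 5 or 6 with the default collective); gene
level classes use "at least k" on the best window.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .motifs import MotifMatch

DEFAULT_L_MAX = 700
DEFAULT_K_MIN = 4


@dataclass(frozen=True)
class SignatureWindow:
    """A (possibly merged) interval with the families matched inside it.

    ``tier`` is the exact distinct-family count of the pre-merge interval;
    merging same-tier windows unions their family sets but keeps the group
    tier (a merged tier-4 window may incidentally cover extra families).
    """

    region_id: str
    gene_id: str
    start: int
    end: int
    families: frozenset[str]
    tier: int = -1

    def __post_init__(self) -> None:
        if self.tier < 0:
            object.__setattr__(self, "tier", len(self.families))


def find_windows(
    matches: Sequence[MotifMatch],
    l_max: int = DEFAULT_L_MAX,
    k_min: int = DEFAULT_K_MIN,
    *,
    gene_id: str = "",
) -> list[SignatureWindow]:
    """Signature windows of one region, merged per tier.

    Candidate intervals run from one match start to another match end and
    span at most ``l_max`` bp; an interval's family set is the set of
    families with a match falling entirely inside it.  For every tier
    k >= ``k_min`` the result is the union (overlapping and bookended
    intervals merged) of all candidate intervals with exactly k distinct
    families; merged windows may exceed ``l_max``.
    """
    if not matches:
        return []
    region_ids = {m.region_id for m in matches}
    if len(region_ids) != 1:
        raise ValueError("find_windows expects matches from a single region")
    region_id = region_ids.pop()

    ms = sorted(matches, key=lambda m: (m.start, m.end))
    starts = np.array([m.start for m in ms])
    ends = np.array([m.end for m in ms])
    fams = [m.family for m in ms]

    candidates: list[SignatureWindow] = []
    for left in sorted(set(int(s) for s in starts)):
        inside = (starts >= left) & (ends <= left + l_max)
        if not inside.any():
            continue
        idx = np.nonzero(inside)[0]
        # candidate right boundaries: every distinct match end; interval
        # [left, e) holds every inside-match with end <= e
        order = idx[np.argsort(ends[idx], kind="stable")]
        seen: set[str] = set()
        prev_e: int | None = None
        for j in order:
            e = int(ends[j])
            if prev_e is not None and e != prev_e and len(seen) >= k_min:
                candidates.append(SignatureWindow(region_id, gene_id, left,
                                                  prev_e, frozenset(seen)))
            seen.add(fams[j])
            prev_e = e
        if prev_e is not None and len(seen) >= k_min:
            candidates.append(SignatureWindow(region_id, gene_id, left,
                                              prev_e, frozenset(seen)))
    return merge_windows(candidates)


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of overlapping or bookended half-open intervals."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merge_windows(windows: Sequence[SignatureWindow]) -> list[SignatureWindow]:
    """Merge overlapping/bookended same-tier windows of one region.

    The merged window's family set is the union of its constituents'.
    """
    by_tier: dict[int, list[SignatureWindow]] = defaultdict(list)
    for w in windows:
        by_tier[w.tier].append(w)
    out: list[SignatureWindow] = []
    for tier, ws in by_tier.items():
        ws = sorted(ws, key=lambda w: (w.start, w.end))
        current: SignatureWindow | None = None
        for w in ws:
            if current is not None and w.start <= current.end:
                current = replace(current, end=max(current.end, w.end),
                                  families=current.families | w.families)
            else:
                if current is not None:
                    out.append(current)
                current = w
        if current is not None:
            out.append(current)
    return sorted(out, key=lambda w: (w.start, w.end, w.tier))


@dataclass
class GeneSignatureProfile:
    """Per-gene summary: all windows over the gene's regions, best tier."""

    gene_id: str
    windows: list[SignatureWindow]
    conserved: dict[int, bool] | None = None

    @property
    def max_tier(self) -> int | None:
        return max((w.tier for w in self.windows), default=None)


def find_gene_windows(
    matches: Iterable[MotifMatch],
    region_genes: Mapping[str, str],
    l_max: int = DEFAULT_L_MAX,
    k_min: int = DEFAULT_K_MIN,
) -> dict[str, GeneSignatureProfile]:
    """Window discovery over many regions, grouped into gene profiles.

    ``region_genes`` maps region_id -> gene_id; windows never span distinct
    regions of the same gene (upstream and intronic sequences are separate).
    """
    by_region: dict[str, list[MotifMatch]] = defaultdict(list)
    for m in matches:
        by_region[m.region_id].append(m)
    profiles: dict[str, GeneSignatureProfile] = {
        g: GeneSignatureProfile(g, []) for g in set(region_genes.values())
    }
    for region_id, ms in by_region.items():
        if region_id not in region_genes:
            raise KeyError(f"match references unknown region {region_id!r}")
        gene = region_genes[region_id]
        ws = find_windows(ms, l_max, k_min, gene_id=gene)
        profiles[gene].windows.extend(ws)
    return profiles


def classify_genes(
    profiles: Mapping[str, GeneSignatureProfile],
    gene_universe: Iterable[str] | None = None,
) -> dict[str, int | None]:
    """gene_id -> best window tier (None when the gene has no window)."""
    table: dict[str, int | None] = {g: p.max_tier for g, p in profiles.items()}
    if gene_universe is not None:
        universe = set(gene_universe)
        unknown = set(table) - universe
        if unknown:
            raise ValueError(f"windows reference unknown genes: {sorted(unknown)[:5]}")
        for g in universe - set(table):
            table[g] = None
    return table


def prevalence_by_class(
    gene_classes: Mapping[str, str],
    classifications: Mapping[str, int | None],
    tier: int,
    classes: tuple[str, str] = ("neuronal", "non_neuronal"),
) -> dict:
    """Pearson chi-squared (no continuity correction) on signature-by-class.

    Builds the 2x2 table of (has window of tier >= ``tier``) against the two
    gene classes and tests independence, as in a neuronal vs non-neuronal
    genome comparison.
    """
    table = np.zeros((2, 2), dtype=int)
    for ci, cls in enumerate(classes):
        genes = [g for g, c in gene_classes.items() if c == cls]
        if not genes:
            raise ValueError(f"empty gene class {cls!r}")
        has = sum(1 for g in genes
                  if classifications.get(g) is not None and classifications[g] >= tier)
        table[0, ci] = has
        table[1, ci] = len(genes) - has
    if table.sum(axis=0).min() == 0:
        raise ValueError("empty gene class")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return {
        "table": table,
        "chi2": float(chi2),
        "p_value": float(p),
        "dof": int(dof),
        "prop": {classes[i]: table[0, i] / table[:, i].sum() for i in range(2)},
    }
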