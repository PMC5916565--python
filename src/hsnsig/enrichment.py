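"""Resampling-based enrichment of the signature in a reference gene set.

The observed proportion of reference genes (e.g. the 96 genes known to be
expressed in the HSN neuron) carrying a signature window is placed in the
empirical distribution of the same proportion over many random gene sets,
each matched to the reference for total regulatory-region length
(Mann-Whitney U, p > 0.05) and restricted to genes with at least one
described ortholog.  Enrichment is called significant when the reference
sits above the 95th percentile of the matched null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_N_SETS = 10_000
DEFAULT_SET_SIZE = 96
DEFAULT_ATTEMPT_CAP = 1_000
MATCH_P_THRESHOLD = 0.05


class MatchingInfeasibleError(RuntimeError):
    """Length-matched resampling failed within the attempt cap."""


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration for small untied samples (n <= 8 per group),
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EnrichmentResult:
    """Observed signature proportion against a matched resampling null."""

    observed_prop: float
    null_props: np.ndarray
    tier: int
    set_size: int
    seed: int | None = None
    percentile: float = field(init=False)
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.null_props = np.asarray(self.null_props, dtype=float)
        below = np.sum(self.null_props < self.observed_prop - 1e-12)
        equal = np.sum(np.abs(self.null_props - self.observed_prop) <= 1e-12)
        # mid-rank convention: ties count half
        self.percentile = float(100.0 * (below + 0.5 * equal) / len(self.null_props))
        self.significant = self.percentile > 95.0

    @property
    def n_sets(self) -> int:
        return len(self.null_props)

    def to_dict(self) -> dict:
        return {
            "observed_prop": self.observed_prop,
            "percentile": self.percentile,
            "significant": bool(self.significant),
            "tier": self.tier,
            "n_sets": self.n_sets,
            "set_size": self.set_size,
            "seed": self.seed,
        }


def _lengths(universe: pd.DataFrame, genes: Sequence[str],
             two_tests: bool) -> tuple[np.ndarray, ...]:
    sub = universe.loc[list(genes)]
    if two_tests:
        return (sub["upstream_len"].to_numpy(float),
                sub["intronic_len"].to_numpy(float))
    return ((sub["upstream_len"] + sub["intronic_len"]).to_numpy(float),)


def sample_matched_sets(
    universe: pd.DataFrame,
    reference: Sequence[str],
    n_sets: int = DEFAULT_N_SETS,
    set_size: int = DEFAULT_SET_SIZE,
    seed: int | np.random.Generator | None = None,
    *,
    attempt_cap: int = DEFAULT_ATTEMPT_CAP,
    two_tests: bool = False,
) -> list[list[str]]:
    """Random gene sets matched to the reference for regulatory length.

    ``universe`` is indexed by gene_id with columns ``upstream_len``,
    ``intronic_len`` and ``has_ortholog``.  Each returned set (1) excludes
    reference genes, (2) contains only genes with at least one ortholog, and
    (3) is accepted only when a Mann-Whitney U test of its regulatory-region
    lengths against the reference's gives p > 0.05 (one test on the
    upstream+intronic total by default; ``two_tests`` requires both the
    upstream and the intronic comparison to pass).  Rejection sampling with
    ``attempt_cap`` attempts per set.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ref = list(dict.fromkeys(reference))
    missing = set(ref) - set(universe.index)
    if missing:
        raise KeyError(f"reference genes missing from universe: {sorted(missing)[:5]}")
    pool = universe.index[universe["has_ortholog"].astype(bool)
                          & ~universe.index.isin(ref)].to_numpy()
    if len(pool) < set_size:
        raise MatchingInfeasibleError(
            f"only {len(pool)} eligible genes (non-reference, with ortholog) "
            f"for sets of size {set_size}")
    ref_lengths = _lengths(universe, ref, two_tests)
    pool_lengths = [
        universe.loc[pool, "upstream_len"].to_numpy(float)
        + (0 if two_tests else universe.loc[pool, "intronic_len"].to_numpy(float)),
        universe.loc[pool, "intronic_len"].to_numpy(float),
    ]
    sets: list[list[str]] = []
    for _ in range(n_sets):
        for attempt in range(attempt_cap):
            take = rng.choice(len(pool), size=set_size, replace=False)
            ok = True
            for comp, ref_l in enumerate(ref_lengths):
                _, p = mann_whitney_u(pool_lengths[comp][take], ref_l)
                if p <= MATCH_P_THRESHOLD:
                    ok = False
                    break
            if ok:
                sets.append(list(pool[take]))
                break
        else:
            raise MatchingInfeasibleError(
                "could not draw a length-matched set within "
                f"{attempt_cap} attempts (Mann-Whitney p > {MATCH_P_THRESHOLD} "
                "criterion keeps failing; length distributions likely differ)")
    return sets


def signature_proportion(
    classifications: Mapping[str, int | None],
    genes: Sequence[str],
    tier: int,
) -> float:
    """Fraction of ``genes`` whose best window reaches ``tier``."""
    if not genes:
        raise ValueError("empty gene set")
    n = sum(1 for g in genes
            if classifications[g] is not None and classifications[g] >= tier)
    return n / len(genes)


def enrichment_test(
    classifications: Mapping[str, int | None],
    reference: Sequence[str],
    sampled_sets: Sequence[Sequence[str]],
    tier: int,
    seed: int | None = None,
) -> EnrichmentResult:
    """Empirical percentile of the reference proportion among matched nulls."""
    observed = signature_proportion(classifications, list(reference), tier)
    nulls = np.array([signature_proportion(classifications, list(s), tier)
                      for s in sampled_sets])
    return EnrichmentResult(observed, nulls, tier, len(list(reference)), seed)
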