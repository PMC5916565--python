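"""Cross-species cell-type homology clustering with multiscale bootstrap.

Binary (presence/absence) expression profiles of cell types from two
species are placed in a common gene space through an ortholog map, compared
with the asymmetric binary (Jaccard) distance, clustered by average linkage
(UPGMA), and each cluster is assigned a bootstrap probability (BP) and an
approximately unbiased p-value (AU) estimated by multiscale bootstrap:
genes are resampled at several resample-size scales r, per-scale cluster
frequencies are probit-transformed and extrapolated in r by weighted least
squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

DEFAULT_CPM_THRESHOLD = 19.0
DEFAULT_MIN_GENES = 30
DEFAULT_NBOOT = 10_000
DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


# ---------------------------------------------------------------------------
# matrix preparation


def binarize_cpm(cpm: pd.DataFrame, threshold: float = DEFAULT_CPM_THRESHOLD) -> pd.DataFrame:
    """Presence/absence call on a CPM matrix: present iff strictly above
    ``threshold`` (a value of exactly 19 CPM is absent)."""
    values = cpm.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("CPM values must be non-negative")
    return pd.DataFrame((values > threshold).astype(np.int8),
                        index=cpm.index, columns=cpm.columns)


def filter_neuron_matrix(
    matrix: pd.DataFrame,
    min_genes_per_column: int = DEFAULT_MIN_GENES,
    pan_gene_list: Iterable[str] = (),
) -> pd.DataFrame:
    """Drop pan-neuronal genes and sparsely annotated cell-type columns.

    Columns in which fewer than ``min_genes_per_column`` genes are present
    are excluded (a column with exactly the floor is kept).
    """
    pan = set(pan_gene_list)
    out = matrix.loc[[g for g in matrix.index if g not in pan]]
    keep = out.sum(axis=0) >= min_genes_per_column
    out = out.loc[:, keep]
    if out.shape[1] == 0:
        raise ValueError("all columns dropped by the per-column gene floor")
    return out


def expand_orthologs(
    source_matrix: pd.DataFrame,
    ortholog_map: Mapping[str, Sequence[str]] | pd.DataFrame,
) -> pd.DataFrame:
    """Re-index a binary matrix into the target species' gene space.

    ``ortholog_map`` maps source gene -> target ortholog ids (or a DataFrame
    with ``source_gene``/``target_gene`` columns).  Source genes with no
    target ortholog are dropped, as are genes absent in every source column;
    a gene with k orthologs contributes k rows, each a copy of its presence
    vector.  Distinct source genes mapping to the same target id are kept as
    distinct rows (logged).
    """
    if isinstance(ortholog_map, pd.DataFrame):
        ortholog_map = {g: list(grp["target_gene"])
                        for g, grp in ortholog_map.groupby("source_gene")}
    rows: list[np.ndarray] = []
    index: list[str] = []
    expressed = source_matrix.to_numpy().sum(axis=1) > 0
    for i, gene in enumerate(source_matrix.index):
        if not expressed[i]:
            continue
        for target in ortholog_map.get(gene, ()):  # no ortholog -> dropped
            rows.append(source_matrix.iloc[i].to_numpy())
            index.append(target)
    if not rows:
        return pd.DataFrame(columns=source_matrix.columns)
    out = pd.DataFrame(np.vstack(rows), index=index, columns=source_matrix.columns)
    dup = out.index[out.index.duplicated()].unique()
    if len(dup):
        logger.info("%d target ids received rows from multiple source genes", len(dup))
    return out


# ---------------------------------------------------------------------------
# distances and linkage


def binary_distance(u: Sequence[int], v: Sequence[int]) -> float:
    """Asymmetric binary (Jaccard) distance between two 0/1 vectors.

    d = #(exactly one present) / #(at least one present); two all-zero
    vectors are at distance 0 (logged when it occurs).
    """
    u = np.asarray(u, dtype=bool)
    v = np.asarray(v, dtype=bool)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    union = np.sum(u | v)
    if union == 0:
        logger.debug("binary_distance of two all-zero vectors: defined 0")
        return 0.0
    return float(np.sum(u ^ v) / union)


def pairwise_binary_distance(matrix: np.ndarray) -> np.ndarray:
    """Column-by-column binary distance matrix (rows = features)."""
    x = np.asarray(matrix, dtype=np.float64)
    inter = x.T @ x
    ones = x.sum(axis=0)
    union = ones[:, None] + ones[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class ClusterNode:
    """Internal node of the dendrogram (leaf set + merge height + support)."""

    leaves: frozenset[str]
    height: float
    bp: float | None = None
    au: float | None = None
    bp_per_scale: dict[float, float] = field(default_factory=dict)


@dataclass
class ClusterTree:
    """Rooted dendrogram over cell-type columns with per-cluster support."""

    labels: list[str]
    merges: list[tuple[frozenset[str], frozenset[str], float]]
    nodes: list[ClusterNode] = field(init=False)

    def __post_init__(self) -> None:
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")
        self.nodes = [ClusterNode(a | b, h) for a, b, h in self.merges]

    def clusters(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes, root included."""
        return [n.leaves for n in self.nodes]

    def node(self, leaves: Iterable[str]) -> ClusterNode:
        key = frozenset(leaves)
        for n in self.nodes:
            if n.leaves == key:
                return n
        raise KeyError(f"no cluster with leaves {sorted(key)}")

    def has_cluster(self, leaves: Iterable[str]) -> bool:
        key = frozenset(leaves)
        return any(n.leaves == key for n in self.nodes)

    def cophenetic_height(self, a: str, b: str) -> float:
        for n in self.nodes:
            if a in n.leaves and b in n.leaves:
                return n.height
        raise KeyError(f"{a} and {b} never merge")

    def to_newick(self, with_support: bool = True) -> str:
        """Newick string; internal-node labels carry AU|BP when present."""
        children: dict[frozenset[str], tuple[frozenset[str], frozenset[str], float]] = {}
        for a, b, h in self.merges:
            children[a | b] = (a, b, h)
        support = {n.leaves: n for n in self.nodes}
        heights = {frozenset([l]): 0.0 for l in self.labels}
        for a, b, h in self.merges:
            heights[a | b] = h

        def render(cluster: frozenset[str], parent_h: float) -> str:
            h = heights[cluster]
            branch = max(parent_h - h, 0.0)
            if len(cluster) == 1:
                (leaf,) = cluster
                return f"{leaf}:{branch:.6g}"
            a, b, _ = children[cluster]
            sub = ",".join(sorted((render(a, h), render(b, h))))
            label = ""
            node = support.get(cluster)
            if with_support and node is not None and node.au is not None:
                label = f"au{node.au:.3f}_bp{node.bp:.3f}"
            return f"({sub}){label}:{branch:.6g}"

        root = frozenset(self.labels)
        return render(root, heights[root]) + ";"


def average_linkage(
    dist: np.ndarray,
    labels: Sequence[str],
) -> ClusterTree:
    """UPGMA agglomeration with a deterministic tie-break.

    Repeatedly merges the pair of clusters with the smallest unweighted mean
    inter-cluster distance; the merge height is that mean.  Ties are broken
    by the lexicographically smallest (sorted) pair of smallest leaf labels,
    so the tree is identical across platforms.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if n != len(labels):
        raise ValueError("labels must match the distance matrix")
    clusters: dict[int, frozenset[str]] = {i: frozenset([labels[i]]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dd = {(min(i, j), max(i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[frozenset[str], frozenset[str], float]] = []
    next_id = n
    while len(clusters) > 1:
        best_key = None
        best = (np.inf, ("", ""))
        for (i, j), dij in dd.items():
            tag = tuple(sorted((min(clusters[i]), min(clusters[j]))))
            cand = (dij, tag)
            if cand < best:
                best = cand
                best_key = (i, j)
        i, j = best_key
        h = dd.pop((i, j))
        merges.append((clusters[i], clusters[j], h))
        new = next_id
        next_id += 1
        ni, nj = sizes[i], sizes[j]
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dd.pop((min(i, k), max(i, k)))
            djk = dd.pop((min(j, k), max(j, k)))
            dd[(min(new, k), max(new, k))] = (ni * dik + nj * djk) / (ni + nj)
        clusters[new] = clusters.pop(i) | clusters.pop(j)
        sizes[new] = ni + nj
        del sizes[i], sizes[j]
    return ClusterTree(list(labels), merges)


# ---------------------------------------------------------------------------
# multiscale bootstrap


def _scipy_cluster_sets(z: np.ndarray, labels: Sequence[str]) -> set[frozenset[str]]:
    """Internal-node leaf sets of a scipy linkage matrix."""
    n = len(labels)
    sets: list[frozenset[str]] = [frozenset([l]) for l in labels]
    out: set[frozenset[str]] = set()
    for a, b, _, _ in z:
        merged = sets[int(a)] | sets[int(b)]
        sets.append(merged)
        out.add(merged)
    return out


def _replicate_cluster_sets(matrix: np.ndarray, idx: np.ndarray,
                            labels: Sequence[str]) -> set[frozenset[str]]:
    sub = matrix[idx]
    d = pairwise_binary_distance(sub)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return _scipy_cluster_sets(z, labels)


def _fit_au(scales: np.ndarray, bp: np.ndarray, nboot: int) -> tuple[float, float, float]:
    """Weighted least-squares extrapolation of probit cluster frequencies.

    Fits z(r) = v*sqrt(r) + c/sqrt(r) with z = probit(1 - BP_r) and returns
    (au, v, c) with AU = 1 - Phi(v - c).  BP values are clamped away from
    {0,1} before the probit; weights follow the delta method,
    w_r = nboot * phi(z_r)^2 / (BP_r (1 - BP_r)).
    """
    eps = 1.0 / (2.0 * nboot)
    clamped = np.clip(bp, eps, 1.0 - eps)
    if np.all(bp >= 1.0 - 1e-12):
        return 1.0, np.nan, np.nan
    if np.all(bp <= 1e-12):
        return 0.0, np.nan, np.nan
    z = stats.norm.ppf(1.0 - clamped)
    x = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    w = nboot * stats.norm.pdf(z) ** 2 / (clamped * (1.0 - clamped))
    xw = x * w[:, None]
    try:
        beta = np.linalg.solve(x.T @ xw, xw.T @ z)
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate grid
        return float(np.mean(bp)), np.nan, np.nan
    v, c = beta
    return float(1.0 - stats.norm.cdf(v - c)), float(v), float(c)


def multiscale_bootstrap(
    matrix: pd.DataFrame,
    nboot: int = DEFAULT_NBOOT,
    scales: Sequence[float] = DEFAULT_SCALES,
    seed: int | np.random.Generator | None = None,
) -> ClusterTree:
    """Average-linkage tree over columns with BP and AU cluster support.

    Rows (genes) are resampled with replacement; at each scale r the
    replicate size is round(r * n_rows).  BP of a cluster is its replicate
    frequency at r = 1 (nearest scale, with a warning, if 1.0 is absent
    from the grid); AU extrapolates the per-scale frequencies through a
    probit-scale WLS fit.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 columns to cluster")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to resample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [str(c) for c in matrix.columns]
    x = matrix.to_numpy(dtype=np.float64)
    n = x.shape[0]
    # canonical column order makes replicate trees (and hence BP/AU counts)
    # invariant to the caller's column permutation
    order = np.argsort(labels, kind="stable")
    xs = np.ascontiguousarray(x[:, order])
    sorted_labels = [labels[i] for i in order]

    base = average_linkage(pairwise_binary_distance(x), labels)
    targets = [node.leaves for node in base.nodes]
    counts = np.zeros((len(scales), len(targets)), dtype=np.int64)
    tindex = {leaves: i for i, leaves in enumerate(targets)}

    for si, r in enumerate(scales):
        m = max(2, int(round(r * n)))
        for _ in range(nboot):
            idx = rng.integers(0, n, size=m)
            for cl in _replicate_cluster_sets(xs, idx, sorted_labels):
                ti = tindex.get(cl)
                if ti is not None:
                    counts[si, ti] += 1

    scales_arr = np.asarray(scales, dtype=float)
    bp_all = counts / nboot
    if np.any(np.isclose(scales_arr, 1.0)):
        r1 = int(np.argmin(np.abs(scales_arr - 1.0)))
    else:
        r1 = int(np.argmin(np.abs(scales_arr - 1.0)))
        logger.warning("no scale at r=1.0; BP reported from nearest scale r=%g",
                       scales_arr[r1])
    for ti, node in enumerate(base.nodes):
        node.bp_per_scale = {float(s): float(bp_all[si, ti])
                             for si, s in enumerate(scales_arr)}
        node.bp = float(bp_all[r1, ti])
        if len(scales_arr) < 2:
            node.au = None
        else:
            au, _, _ = _fit_au(scales_arr, bp_all[:, ti], nboot)
            node.au = au
    # the root is present in every replicate by construction
    return base


def plain_bootstrap_bp(
    matrix: pd.DataFrame,
    nboot: int = 2_000,
    seed: int | np.random.Generator | None = None,
) -> dict[frozenset[str], float]:
    """Ordinary (single-scale, r=1) bootstrap cluster frequencies.

    Kept deliberately simple; serves as an independent check of BP values
    from :func:`multiscale_bootstrap` at scale 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [str(c) for c in matrix.columns]
    x = matrix.to_numpy(dtype=np.float64)
    n = x.shape[0]
    order = np.argsort(labels, kind="stable")
    xs = np.ascontiguousarray(x[:, order])
    sorted_labels = [labels[i] for i in order]
    base = average_linkage(pairwise_binary_distance(x), labels)
    counts: dict[frozenset[str], int] = {node.leaves: 0 for node in base.nodes}
    for _ in range(nboot):
        idx = rng.integers(0, n, size=n)
        for cl in _replicate_cluster_sets(xs, idx, sorted_labels):
            if cl in counts:
                counts[cl] += 1
    return {k: v / nboot for k, v in counts.items()}


def control_random_sets(
    pool: Sequence[str],
    anchor_genes: Sequence[str],
    n_sets: int = 100,
    set_size: int = 96,
    seed: int | np.random.Generator | None = None,
) -> list[list[str]]:
    """Random gene sets anchored on the serotonin-pathway genes.

    Each set holds the anchors (tph-1, cat-1, cat-4, bas-1 in the real
    analysis) plus ``set_size - len(anchors)`` genes sampled without
    replacement from the expressed pool; downstream, each set replaces the
    reference cell type's profile and the clustering is re-run.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anchors = list(dict.fromkeys(anchor_genes))
    pool_rest = [g for g in pool if g not in set(anchors)]
    missing = set(anchors) - set(pool)
    if missing:
        raise ValueError(f"anchor genes absent from pool: {sorted(missing)}")
    k = set_size - len(anchors)
    if k < 0 or len(pool_rest) < k:
        raise ValueError("pool too small for the requested set size")
    out = []
    for _ in range(n_sets):
        take = rng.choice(len(pool_rest), size=k, replace=False)
        out.append(anchors + [pool_rest[i] for i in take])
    return out
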