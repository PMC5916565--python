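"""End-to-end orchestration of the signature and homology analyses.

``run_signature_pipeline`` chains PWM building → scanning → window
discovery → gene classification → matched-resampling enrichment →
conservation filtering → conservation-filtered enrichment, writing every
intermediate artifact so each stage can be re-run in isolation.
``run_homology_pipeline`` chains binarization → matrix filtering → ortholog
expansion → binary-distance average-linkage clustering → multiscale
bootstrap → anchored control sets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io as hio
from .conservation import OrthologTable, conservation_filter, conserved_classifications
from .enrichment import enrichment_test, sample_matched_sets
from .homology import (
    binarize_cpm,
    control_random_sets,
    expand_orthologs,
    filter_neuron_matrix,
    multiscale_bootstrap,
    pairwise_binary_distance,
    average_linkage,
)
from .motifs import MotifModel, RegulatoryRegion, scan_regions
from .simulate import ANCHOR_GENES
from .windows import classify_genes, find_gene_windows, prevalence_by_class


@dataclass
class PipelineConfig:
    """Every tunable of both pipelines, defaulting to the study settings."""

    pseudocount: float = 0.1
    min_rel_score: float = 0.70
    l_max: int = 700
    k_min: int = 4
    tier: int = 6
    n_sets: int = 10_000
    set_size: int = 96
    enrichment_seed: int = 0
    conservation_mode: str = "strict"   # or "any_per_species"
    cpm_threshold: float = 19.0
    min_genes_per_column: int = 30
    nboot: int = 10_000
    scales: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))
    clustering_seed: int = 0
    n_control_sets: int = 100

    def __post_init__(self) -> None:
        if self.l_max not in (600, 700, 800):
            raise ValueError("l_max must be one of 600, 700, 800")
        if self.conservation_mode not in ("strict", "any_per_species"):
            raise ValueError("conservation_mode must be strict|any_per_species")

    def digest(self) -> str:
        raw = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(raw.encode()).hexdigest()[:12]


def _stamp(config: PipelineConfig) -> dict:
    return {"tool_version": __version__, "config_hash": config.digest(),
            "config": asdict(config)}


def run_signature_pipeline(
    models: dict[str, MotifModel],
    regions: list[RegulatoryRegion],
    universe: pd.DataFrame,
    gene_classes: dict[str, str],
    reference: list[str],
    config: PipelineConfig,
    *,
    ortholog_table: OrthologTable | None = None,
    species_regions: dict[str, list[RegulatoryRegion]] | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run scan → windows → classify → enrich (→ conserve → enrich again).

    ``universe`` is the gene table (index gene_id; columns ``upstream_len``,
    ``intronic_len``, ``has_ortholog``).  Conservation runs only when both
    an ortholog table and per-species regions are supplied.
    """
    region_genes = {r.region_id: r.gene_id for r in regions}
    unknown = set(region_genes.values()) - set(universe.index)
    if unknown:
        raise ValueError(f"regions reference genes missing from the universe: "
                         f"{sorted(unknown)[:5]}")

    matches = scan_regions(models.values(), regions)
    profiles = find_gene_windows(matches, region_genes, config.l_max, config.k_min)
    classifications = classify_genes(profiles, universe.index)

    rng = np.random.default_rng(config.enrichment_seed)
    sets = sample_matched_sets(universe, reference, config.n_sets,
                               config.set_size, rng)
    enr = enrichment_test(classifications, reference, sets, config.tier,
                          seed=config.enrichment_seed)
    # reference genes are themselves neuronal for the genome-wide comparison
    prev_classes = {g: ("neuronal" if c == "reference" else c)
                    for g, c in gene_classes.items()}
    prevalence = prevalence_by_class(prev_classes, classifications, config.tier)

    report = {
        **_stamp(config),
        "n_regions": len(regions),
        "n_matches": len(matches),
        "n_genes": len(universe),
        "tier_proportions": {
            k: float(np.mean([t is not None and t >= k
                              for t in classifications.values()]))
            for k in range(config.k_min, config.tier + 1)
        },
        "enrichment": enr.to_dict(),
        "prevalence": {
            "chi2": prevalence["chi2"], "p_value": prevalence["p_value"],
            "prop": prevalence["prop"],
            "table": prevalence["table"].tolist(),
        },
    }

    conserved: set[str] | None = None
    if ortholog_table is not None and species_regions is not None:
        per_species = {}
        for sp, sp_regions in species_regions.items():
            sp_matches = scan_regions(models.values(), sp_regions)
            sp_genes = {r.region_id: r.gene_id for r in sp_regions}
            sp_profiles = find_gene_windows(sp_matches, sp_genes,
                                            config.l_max, config.k_min)
            per_species[sp] = classify_genes(sp_profiles)
        conserved = conservation_filter(
            classifications, ortholog_table, per_species, config.tier,
            any_ortholog_per_species=(config.conservation_mode == "any_per_species"))
        cons_cls = conserved_classifications(classifications, conserved)
        cons_enr = enrichment_test(cons_cls, reference, sets, config.tier,
                                   seed=config.enrichment_seed)
        cons_prev = prevalence_by_class(prev_classes, cons_cls, config.tier)
        report["conservation"] = {
            "n_conserved": len(conserved),
            "enrichment": cons_enr.to_dict(),
            "prevalence": {
                "chi2": cons_prev["chi2"], "p_value": cons_prev["p_value"],
                "prop": cons_prev["prop"],
                "table": cons_prev["table"].tolist(),
            },
        }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hio.write_pwms(outdir / "pwms.json", models)
        hio.write_matches_bed(outdir / "matches.bed", matches)
        all_windows = [w for p in profiles.values() for w in p.windows]
        hio.write_windows_bed(outdir / "windows.bed", all_windows)
        hio.write_classification(outdir / "classification.tsv", classifications)
        pd.DataFrame({"null_prop": enr.null_props}).to_csv(
            outdir / "null_props.tsv", sep="\t", index=False)
        if conserved is not None:
            pd.Series(sorted(conserved), name="gene_id").to_csv(
                outdir / "conserved_genes.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


@dataclass
class HomologyResult:
    """Clustered tree plus the report dictionary."""

    tree: object
    report: dict
    matrix: pd.DataFrame = field(repr=False, default=None)


def build_homology_matrix(
    worm_binary: pd.DataFrame,
    mouse_cpm: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    pan_genes: list[str],
    config: PipelineConfig,
) -> pd.DataFrame:
    """The combined binary matrix in mouse gene space.

    Worm columns are filtered (pan-neuronal genes and <30-gene columns out)
    and expanded through the ortholog map; mouse CPM columns are binarized
    at the CPM threshold; the two blocks are joined on mouse gene ids
    (duplicated target rows keep the matching mouse values).
    """
    worm = filter_neuron_matrix(worm_binary, config.min_genes_per_column, pan_genes)
    worm_in_mouse = expand_orthologs(worm, ortholog_map)
    mouse_bin = binarize_cpm(mouse_cpm, config.cpm_threshold)
    mouse_rows = mouse_bin.reindex(worm_in_mouse.index.unique()).fillna(0)
    mouse_block = mouse_rows.loc[worm_in_mouse.index].to_numpy()
    combined = pd.DataFrame(
        np.hstack([worm_in_mouse.to_numpy(), mouse_block]).astype(np.int8),
        index=worm_in_mouse.index,
        columns=[*worm_in_mouse.columns, *mouse_bin.columns],
    )
    return combined


def run_homology_pipeline(
    worm_binary: pd.DataFrame,
    mouse_cpm: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    pan_genes: list[str],
    config: PipelineConfig,
    *,
    reference_label: str = "HSN",
    run_controls: bool = False,
    outdir: str | Path | None = None,
) -> HomologyResult:
    """Cluster worm cell types with mouse samples and attach BP/AU support."""
    combined = build_homology_matrix(worm_binary, mouse_cpm, ortholog_map,
                                     pan_genes, config)
    rng = np.random.default_rng(config.clustering_seed)
    tree = multiscale_bootstrap(combined, config.nboot, config.scales, rng)

    mouse_labels = [str(c) for c in mouse_cpm.columns]
    report = {
        **_stamp(config),
        "n_rows": int(combined.shape[0]),
        "columns": [str(c) for c in combined.columns],
        "clusters": [
            {"leaves": sorted(n.leaves), "height": n.height,
             "bp": n.bp, "au": n.au}
            for n in tree.nodes
        ],
    }
    if reference_label in combined.columns:
        report["reference_nearest_mouse"] = nearest_mouse_partner(
            combined, reference_label, mouse_labels)

    if run_controls:
        pool = [g for g in worm_binary.index
                if g not in set(pan_genes) and worm_binary.loc[g].sum() > 0]
        control_hits = 0
        sets = control_random_sets(pool, list(ANCHOR_GENES),
                                   config.n_control_sets, config.set_size, rng)
        for genes in sets:
            wb = worm_binary.copy()
            wb[reference_label] = [1 if g in set(genes) else 0 for g in wb.index]
            cm = build_homology_matrix(wb, mouse_cpm, ortholog_map, pan_genes, config)
            if nearest_mouse_partner(cm, reference_label, mouse_labels):
                control_hits += 1
        report["controls"] = {
            "n_sets": len(sets),
            "nearest_mouse_rate": control_hits / len(sets),
        }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tree.nwk").write_text(tree.to_newick())
        pd.DataFrame([
            {"leaves": ",".join(sorted(n.leaves)), "height": n.height,
             "bp": n.bp, "au": n.au}
            for n in tree.nodes
        ]).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return HomologyResult(tree=tree, report=report, matrix=combined)


def nearest_mouse_partner(
    combined: pd.DataFrame,
    reference_label: str,
    mouse_labels: list[str],
) -> bool:
    """Is a mouse sample the reference column's nearest neighbour?

    Uses the binary distance on the combined matrix; returns True when the
    closest other column to ``reference_label`` is one of ``mouse_labels``.
    """
    labels = [str(c) for c in combined.columns]
    d = pairwise_binary_distance(combined.to_numpy(dtype=float))
    i = labels.index(reference_label)
    dist = d[i].copy()
    dist[i] = np.inf
    return labels[int(np.argmin(dist))] in set(mouse_labels)
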