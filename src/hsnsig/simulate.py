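"""Synthetic inputs with known ground truth for every pipeline stage.

Two generators are provided.  ``simulate_genome`` emulates the regulatory
side: per-gene upstream/intronic background DNA (order-0 model at a worm-like
GC), signature clusters planted at per-class rates, ortholog species with
controlled per-species conservation.  ``simulate_expression`` emulates the
homology side: a binary gene-by-neuron matrix for the worm, a CPM
gene-by-sample matrix for mouse raphe-like samples plus cortical controls,
an ortholog map between the two gene spaces, and one planted homologous
worm cell type whose profile overlaps the mouse expressed set at a
controlled fraction.

The built-in per-family "functional site" collections are synthetic:
deterministic expansions of the six family consensus strings (the published
functional-site alignments are not bundled), adequate to give each family a
consensus-consistent PWM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import (
    BASES,
    DEFAULT_MIN_REL_SCORE,
    DEFAULT_PSEUDOCOUNT,
    FAMILY_CONSENSUS,
    IUPAC,
    MotifModel,
    RegulatoryRegion,
    build_pwm,
    rel_score,
    reverse_complement,
)

DEFAULT_SPECIES = ("c_briggsae", "c_japonica", "c_remanei", "c_brenneri")
ANCHOR_GENES = ("tph-1", "bas-1", "cat-1", "cat-4")

_FLANK_CYCLE = "ACGT"


def builtin_site_collections(n_sites: int = 12, flank: int = 1) -> dict[str, list[str]]:
    """Synthetic aligned binding-site collections, one per TF family.

    Site i takes, at consensus position j, the (i mod k)-th base of that
    position's IUPAC class (k = class size); flanking positions cycle
    through ACGT.  Deterministic, no RNG.
    """
    out: dict[str, list[str]] = {}
    for family, consensus in FAMILY_CONSENSUS.items():
        sites = []
        for i in range(n_sites):
            core = "".join(IUPAC[sym][i % len(IUPAC[sym])] for sym in consensus)
            left = "".join(_FLANK_CYCLE[(i + j) % 4] for j in range(flank))
            right = "".join(_FLANK_CYCLE[(i + j + 1) % 4] for j in range(flank))
            sites.append(left + core + right)
        out[family] = sites
    return out


def default_models(
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_rel_score: float = DEFAULT_MIN_REL_SCORE,
) -> dict[str, MotifModel]:
    """PWMs for the six collective families, from the built-in site sets."""
    return {
        family: build_pwm(sites, pseudocount, family=family,
                          min_rel_score=min_rel_score)
        for family, sites in builtin_site_collections().items()
    }


# ---------------------------------------------------------------------------
# genome simulation


@dataclass
class GenomeSimSpec:
    """Study conditions for the regulatory-genome generator."""

    n_genes: int = 2000
    n_reference: int = 96
    neuronal_fraction: float = 1 / 3  # of the non-reference genes
    upstream_median: float = 800.0
    upstream_sigma: float = 0.5
    intronic_median: float = 300.0
    intronic_sigma: float = 0.7
    gc: float = 0.36
    #: per-class probability of carrying a planted full (tier-6) cluster
    p_signature: Mapping[str, float] = field(default_factory=lambda: {
        "reference": 0.40, "neuronal": 0.25, "non_neuronal": 0.10})
    #: per-class, per-species probability that a planted cluster is copied
    #: into that species' orthologs
    p_conserved: Mapping[str, float] = field(default_factory=lambda: {
        "reference": 0.90, "neuronal": 0.80, "non_neuronal": 0.40})
    planted_span_min: int = 300
    l_max: int = 700
    species: tuple[str, ...] = DEFAULT_SPECIES
    #: per-species ortholog multiplicity distribution P(0), P(1), P(2)
    ortholog_multiplicity: tuple[float, float, float] = (0.10, 0.80, 0.10)
    #: when False, ortholog tables and conservation truth are still drawn
    #: but no comparison-species sequence is generated (faster when the
    #: conservation stage is not being exercised)
    simulate_species_regions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in [*self.p_signature.items(), *self.p_conserved.items()]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {name!r} outside [0,1]")
        if self.planted_span_min > self.l_max:
            raise ValueError("planted span bound exceeds l_max")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must lie in (0,1)")


@dataclass
class SimulatedGenome:
    """All regulatory-pipeline inputs plus the generator's truth table."""

    spec: GenomeSimSpec
    models: dict[str, MotifModel]
    regions: list[RegulatoryRegion]                 # focal species
    region_table: pd.DataFrame                      # region_id, gene_id, kind, length
    gene_classes: pd.DataFrame                      # gene_id, class
    universe: pd.DataFrame                          # lengths + has_ortholog, by gene
    orthologs: pd.DataFrame                         # source_gene, species, ortholog_gene
    species_regions: dict[str, list[RegulatoryRegion]]
    species_region_tables: dict[str, pd.DataFrame]
    truth: pd.DataFrame                             # planted tier/coords/conservation

    def write(self, outdir: str | Path) -> None:
        from . import io as hio
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hio.write_fasta(outdir / "regions.fa",
                        [(r.region_id, r.sequence) for r in self.regions])
        self.region_table.to_csv(outdir / "regions.tsv", sep="\t", index=False)
        self.gene_classes.to_csv(outdir / "gene_classes.tsv", sep="\t", index=False)
        self.universe.to_csv(outdir / "universe.tsv", sep="\t")
        self.orthologs.to_csv(outdir / "orthologs.tsv", sep="\t", index=False)
        for sp, regions in self.species_regions.items():
            hio.write_fasta(outdir / f"regions_{sp}.fa",
                            [(r.region_id, r.sequence) for r in regions])
            self.species_region_tables[sp].to_csv(
                outdir / f"regions_{sp}.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        (outdir / "sim_spec.json").write_text(
            json.dumps({**asdict(self.spec),
                        "p_signature": dict(self.spec.p_signature),
                        "p_conserved": dict(self.spec.p_conserved)},
                       indent=2, default=str))


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")


def _sample_site(model: MotifModel, rng: np.random.Generator,
                 max_attempts: int = 200) -> str:
    """A concrete site drawn from the PWM, guaranteed to pass both filters."""
    from .motifs import matches_consensus
    for _ in range(max_attempts):
        site = "".join(BASES[rng.choice(4, p=model.matrix[j])]
                       for j in range(model.width))
        if matches_consensus(model.consensus, site) and \
                rel_score(model, site) >= model.min_rel_score:
            return site
    # deterministic fallback: consensus core over per-position argmax flanks
    best = [BASES[int(np.argmax(model.matrix[j]))] for j in range(model.width)]
    off = (model.width - len(model.consensus)) // 2
    for j, sym in enumerate(model.consensus):
        allowed = IUPAC[sym]
        probs = [model.matrix[off + j][BASES.index(b)] for b in allowed]
        best[off + j] = allowed[int(np.argmax(probs))]
    return "".join(best)


def _plant_cluster(
    sequence: str,
    models: Sequence[MotifModel],
    span: int,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Write one site per family into a random window of the sequence.

    Returns (new sequence, first site start, last site end).  Sites are
    non-overlapping, on random strands, inside a window of at most ``span``
    bp; the window position is uniform over the region.
    """
    widths = [m.width for m in models]
    total = sum(widths)
    span = min(span, len(sequence))
    if span < total:
        raise ValueError("planted span shorter than the total motif width")
    w0 = rng.integers(0, len(sequence) - span + 1)
    for _ in range(100):
        offs = np.sort(rng.choice(span - max(widths) + 1, size=len(models),
                                  replace=False))
        positions = [int(w0 + o) for o in offs]
        ok = all(positions[i] + widths[i] <= positions[i + 1]
                 for i in range(len(models) - 1))
        if ok and positions[-1] + widths[-1] <= w0 + span:
            break
    else:  # evenly spaced fallback
        gap = (span - total) // len(models)
        positions = []
        cur = int(w0)
        for w in widths:
            positions.append(cur)
            cur += w + gap
    seq = list(sequence)
    for model, pos in zip(models, positions):
        site = _sample_site(model, rng)
        if rng.random() < 0.5:
            site = reverse_complement(site)
        seq[pos:pos + model.width] = site
    first = positions[0]
    last = positions[-1] + widths[-1]
    return "".join(seq), first, last


def simulate_genome(
    spec: GenomeSimSpec,
    models: dict[str, MotifModel] | None = None,
) -> SimulatedGenome:
    """Generate the full regulatory benchmark from a :class:`GenomeSimSpec`."""
    rng = np.random.default_rng(spec.seed)
    models = models or default_models()
    model_list = [models[f] for f in sorted(models)]
    min_span_floor = sum(m.width for m in model_list)

    genes = [f"gene{i:05d}" for i in range(spec.n_genes)]
    classes = ["reference"] * spec.n_reference
    for _ in range(spec.n_genes - spec.n_reference):
        classes.append("neuronal" if rng.random() < spec.neuronal_fraction
                       else "non_neuronal")

    regions: list[RegulatoryRegion] = []
    region_rows, class_rows, universe_rows, truth_rows, orth_rows = [], [], [], [], []
    species_regions: dict[str, list[RegulatoryRegion]] = {s: [] for s in spec.species}
    species_tables: dict[str, list[dict]] = {s: [] for s in spec.species}

    for gene, cls in zip(genes, classes):
        up_len = max(min_span_floor,
                     int(rng.lognormal(np.log(spec.upstream_median), spec.upstream_sigma)))
        in_len = max(40, int(rng.lognormal(np.log(spec.intronic_median),
                                           spec.intronic_sigma)))
        seqs = {"upstream": _random_dna(rng, up_len, spec.gc),
                "intronic": _random_dna(rng, in_len, spec.gc)}

        planted = rng.random() < spec.p_signature[cls]
        plant_info = None
        if planted:
            span = int(rng.integers(max(spec.planted_span_min, min_span_floor),
                                    spec.l_max + 1))
            kind = "upstream" if up_len >= span or up_len >= in_len else "intronic"
            seqs[kind], first, last = _plant_cluster(
                seqs[kind], model_list, span, rng)
            plant_info = (kind, first, last)

        # orthologs & conservation
        per_species_orths: dict[str, list[str]] = {}
        conserved_by_species: dict[str, bool] = {}
        for sp in spec.species:
            k = int(rng.choice(3, p=spec.ortholog_multiplicity))
            orths = [f"{sp}_{gene}_o{j}" for j in range(k)]
            per_species_orths[sp] = orths
            for o in orths:
                orth_rows.append({"source_gene": gene, "species": sp,
                                  "ortholog_gene": o})
            conserve = bool(orths) and planted and \
                rng.random() < spec.p_conserved[cls]
            conserved_by_species[sp] = conserve
            if not spec.simulate_species_regions:
                continue
            for o in orths:
                o_len = max(min_span_floor,
                            int(rng.lognormal(np.log(spec.upstream_median),
                                              spec.upstream_sigma)))
                o_seq = _random_dna(rng, o_len, spec.gc)
                if conserve:
                    span = int(rng.integers(max(spec.planted_span_min, min_span_floor),
                                            spec.l_max + 1))
                    o_seq, _, _ = _plant_cluster(o_seq, model_list, span, rng)
                rid = f"{o}_up"
                species_regions[sp].append(
                    RegulatoryRegion(rid, o, "upstream", o_seq))
                species_tables[sp].append({"region_id": rid, "gene_id": o,
                                           "kind": "upstream",
                                           "length": len(o_seq)})
        has_orth = any(per_species_orths[sp] for sp in spec.species)
        truth_conserved = planted and all(
            per_species_orths[sp] and conserved_by_species[sp]
            for sp in spec.species)

        for kind, seq in seqs.items():
            rid = f"{gene}_{kind}"
            regions.append(RegulatoryRegion(rid, gene, kind, seq))
            region_rows.append({"region_id": rid, "gene_id": gene,
                                "kind": kind, "length": len(seq)})
        class_rows.append({"gene_id": gene, "class": cls})
        universe_rows.append({"gene_id": gene, "class": cls,
                              "upstream_len": up_len, "intronic_len": in_len,
                              "has_ortholog": has_orth})
        truth_rows.append({
            "gene_id": gene, "class": cls,
            "planted_tier": len(model_list) if planted else 0,
            "planted_region": f"{gene}_{plant_info[0]}" if plant_info else "",
            "planted_start": plant_info[1] if plant_info else -1,
            "planted_end": plant_info[2] if plant_info else -1,
            **{f"conserved_{sp}": conserved_by_species[sp] for sp in spec.species},
            "conserved": truth_conserved,
        })

    return SimulatedGenome(
        spec=spec,
        models=models,
        regions=regions,
        region_table=pd.DataFrame(region_rows),
        gene_classes=pd.DataFrame(class_rows),
        universe=pd.DataFrame(universe_rows).set_index("gene_id"),
        orthologs=pd.DataFrame(orth_rows,
                               columns=["source_gene", "species", "ortholog_gene"]),
        species_regions=species_regions,
        species_region_tables={sp: pd.DataFrame(rows, columns=[
            "region_id", "gene_id", "kind", "length"])
            for sp, rows in species_tables.items()},
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# expression simulation


@dataclass
class ExpressionSimSpec:
    """Study conditions for the cross-species expression generator."""

    n_genes: int = 800
    n_worm_neurons: int = 40
    neuron_gene_count_mean: float = 150.0
    neuron_gene_count_sd: float = 30.0
    n_pan_genes: int = 10
    n_raphe_samples: int = 6
    n_cortex_samples: int = 2
    mouse_expressed_fraction: float = 1 / 3
    cpm_expressed_log_mean: float = float(np.log(100.0))
    cpm_absent_log_mean: float = float(np.log(2.0))
    cpm_log_sd: float = 1.0
    planted_label: str = "HSN"
    planted_profile_size: int = 200
    overlap_fraction: float = 0.8
    #: ortholog multiplicity distribution P(0), P(1), P(2)
    ortholog_multiplicity: tuple[float, float, float] = (0.15, 0.75, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction outside [0,1]")
        if self.planted_profile_size > self.n_genes:
            raise ValueError("planted profile larger than the gene universe")

    @property
    def raphe_labels(self) -> list[str]:
        base = ["R1Dorsal", "R1Medial", "R2", "R3", "R5", "R6"]
        return [base[i] if i < len(base) else f"R{i + 1}"
                for i in range(self.n_raphe_samples)]

    @property
    def cortex_labels(self) -> list[str]:
        return [f"Cortex{i + 1}" for i in range(self.n_cortex_samples)]


@dataclass
class SimulatedExpression:
    """Worm binary matrix, mouse CPM matrix, ortholog map and truth."""

    spec: ExpressionSimSpec
    worm_binary: pd.DataFrame      # worm genes x neuron labels, 0/1
    mouse_cpm: pd.DataFrame        # mouse genes x sample labels, CPM
    ortholog_map: pd.DataFrame     # source_gene (worm), target_gene (mouse)
    pan_genes: list[str]
    anchors: tuple[str, ...]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.worm_binary.to_csv(outdir / "worm_binary.tsv", sep="\t")
        self.mouse_cpm.to_csv(outdir / "mouse_cpm.tsv", sep="\t",
                              float_format="%.4f")
        self.ortholog_map.to_csv(outdir / "ortholog_map.tsv", sep="\t", index=False)
        pd.Series(self.pan_genes, name="gene_id").to_csv(
            outdir / "pan_genes.tsv", sep="\t", index=False)
        (outdir / "expression_truth.json").write_text(
            json.dumps(self.truth, indent=2))


def simulate_expression(spec: ExpressionSimSpec) -> SimulatedExpression:
    """Generate the cross-species homology benchmark."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    worm_genes = list(ANCHOR_GENES) + [f"wg{i:05d}" for i in range(n - len(ANCHOR_GENES))]
    pan_genes = [f"pan{i:02d}" for i in range(spec.n_pan_genes)]

    # ortholog map worm -> mouse; anchors always mapped
    mult = rng.choice(3, size=n, p=spec.ortholog_multiplicity)
    mult[:len(ANCHOR_GENES)] = np.maximum(mult[:len(ANCHOR_GENES)], 1)
    orth_rows = []
    mouse_of: dict[str, list[str]] = {}
    counter = 0
    for g, k in zip(worm_genes, mult):
        targets = []
        for _ in range(int(k)):
            targets.append(f"Mg{counter:05d}")
            counter += 1
        mouse_of[g] = targets
        for t in targets:
            orth_rows.append({"source_gene": g, "target_gene": t})
    mouse_genes = [t for g in worm_genes for t in mouse_of[g]]

    # mouse expressed set (gene-level), anchors' orthologs always expressed
    expressed_mouse = set(
        t for t in mouse_genes if rng.random() < spec.mouse_expressed_fraction)
    for g in ANCHOR_GENES:
        expressed_mouse.update(mouse_of[g])
    cortex_expressed = set(
        t for t in mouse_genes if rng.random() < spec.mouse_expressed_fraction)

    def cpm_column(expressed: set[str]) -> np.ndarray:
        mu = np.where([t in expressed for t in mouse_genes],
                      spec.cpm_expressed_log_mean, spec.cpm_absent_log_mean)
        return np.exp(rng.normal(mu, spec.cpm_log_sd))

    cols = {}
    for lab in spec.raphe_labels:
        cols[lab] = cpm_column(expressed_mouse)
    for lab in spec.cortex_labels:
        cols[lab] = cpm_column(cortex_expressed)
    mouse_cpm = pd.DataFrame(cols, index=mouse_genes)

    # worm binary profiles
    worm_has_expressed_orth = [g for g in worm_genes
                               if any(t in expressed_mouse for t in mouse_of[g])]
    worm_other = [g for g in worm_genes
                  if mouse_of[g] and not any(t in expressed_mouse for t in mouse_of[g])]
    size = spec.planted_profile_size
    n_overlap = int(round(spec.overlap_fraction * size))
    if n_overlap > len(worm_has_expressed_orth) or \
            size - n_overlap > len(worm_other):
        raise ValueError("requested overlap infeasible for this gene universe")
    planted = set(ANCHOR_GENES)
    # anchors (whose mouse orthologs are always expressed) count toward the
    # overlap quota; at overlap 0 they are the only overlapping genes
    need = max(0, n_overlap - len(planted))
    pool_in = [g for g in worm_has_expressed_orth if g not in planted]
    planted.update(rng.choice(pool_in, size=need, replace=False))
    n_rest = size - len(planted)
    planted.update(rng.choice(worm_other, size=n_rest, replace=False))

    neuron_labels = [spec.planted_label] + [
        f"neuron{i:02d}" for i in range(1, spec.n_worm_neurons)]
    all_rows = worm_genes + pan_genes
    mat = np.zeros((len(all_rows), len(neuron_labels)), dtype=np.int8)
    row_of = {g: i for i, g in enumerate(all_rows)}
    for g in planted:
        mat[row_of[g], 0] = 1
    for ci in range(1, len(neuron_labels)):
        count = int(np.clip(rng.normal(spec.neuron_gene_count_mean,
                                       spec.neuron_gene_count_sd), 30, n))
        take = rng.choice(n, size=count, replace=False)
        mat[take, ci] = 1
    for g in pan_genes:  # pan-neuronal genes: present everywhere
        mat[row_of[g], :] = 1
    worm_binary = pd.DataFrame(mat, index=all_rows, columns=neuron_labels)

    return SimulatedExpression(
        spec=spec,
        worm_binary=worm_binary,
        mouse_cpm=mouse_cpm,
        ortholog_map=pd.DataFrame(orth_rows, columns=["source_gene", "target_gene"]),
        pan_genes=pan_genes,
        anchors=ANCHOR_GENES,
        truth={
            "planted_neuron": spec.planted_label,
            "overlap_fraction": spec.overlap_fraction,
            "planted_profile_size": size,
            "n_mouse_expressed": len(expressed_mouse),
            "seed": spec.seed,
        },
    )
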