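"""Phylogenetic conservation filter for signature windows.

A gene's signature is conserved when its orthologs in the comparison
species (C. briggsae, C. japonica, C. remanei, C. brenneri by default) all
carry a signature window of at least the same tier, each species scanned
with the same PWMs and window parameters.  Conservation tests window
presence, not sequence identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SPECIES = ("c_briggsae", "c_japonica", "c_remanei", "c_brenneri")


@dataclass
class OrthologTable:
    """(source_gene, species, ortholog_gene) records over a fixed species list."""

    records: pd.DataFrame
    species: tuple[str, ...] = DEFAULT_SPECIES
    _by_gene: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.records
        need = {"source_gene", "species", "ortholog_gene"}
        if not need <= set(df.columns):
            raise ValueError(f"ortholog table needs columns {sorted(need)}")
        unknown = set(df["species"]) - set(self.species)
        if unknown:
            raise ValueError(f"species not in declared list: {sorted(unknown)}")
        if df.duplicated(["source_gene", "species", "ortholog_gene"]).any():
            raise ValueError("duplicate (source, species, ortholog) triples")
        self._by_gene = {
            gene: {sp: list(grp2["ortholog_gene"])
                   for sp, grp2 in grp.groupby("species")}
            for gene, grp in df.groupby("source_gene")
        }

    @classmethod
    def from_tsv(cls, path, species: Sequence[str] = DEFAULT_SPECIES) -> "OrthologTable":
        return cls(pd.read_csv(path, sep="\t"), tuple(species))

    def orthologs(self, gene: str) -> dict[str, list[str]]:
        """species -> ortholog gene ids (may be empty)."""
        return self._by_gene.get(gene, {})

    def has_ortholog(self, gene: str) -> bool:
        return bool(self._by_gene.get(gene))


def conserved_signature(
    gene: str,
    tier: int,
    ortholog_table: OrthologTable,
    per_species_classifications: Mapping[str, Mapping[str, int | None]],
    *,
    any_ortholog_per_species: bool = False,
) -> bool:
    """Whether every comparison species supports the gene's signature.

    Strict reading (default): every ortholog of the gene, in every declared
    species, has a window of tier >= ``tier``.  With
    ``any_ortholog_per_species`` one supporting ortholog per species
    suffices.  Genes with no ortholog anywhere are non-conserved.
    """
    missing = set(per_species_classifications) - set(ortholog_table.species)
    if missing:
        raise ValueError(f"classifications for undeclared species: {sorted(missing)}")
    orths = ortholog_table.orthologs(gene)
    if not orths:
        logger.debug("no-ortholog: %s", gene)
        return False
    for sp in ortholog_table.species:
        sp_orths = orths.get(sp, [])
        if not sp_orths:
            return False
        cls = per_species_classifications.get(sp)
        if cls is None:
            raise ValueError(f"no classifications provided for species {sp!r}")
        support = [cls.get(o) is not None and cls[o] >= tier for o in sp_orths]
        ok = any(support) if any_ortholog_per_species else all(support)
        if not ok:
            return False
    return True


def conservation_filter(
    classifications: Mapping[str, int | None],
    ortholog_table: OrthologTable,
    per_species_classifications: Mapping[str, Mapping[str, int | None]],
    tier: int,
    *,
    any_ortholog_per_species: bool = False,
) -> set[str]:
    """Signature-positive genes whose signature is conserved at ``tier``."""
    positive = [g for g, t in classifications.items()
                if t is not None and t >= tier]
    return {
        g for g in positive
        if conserved_signature(g, tier, ortholog_table,
                               per_species_classifications,
                               any_ortholog_per_species=any_ortholog_per_species)
    }


def conserved_classifications(
    classifications: Mapping[str, int | None],
    conserved: Iterable[str],
) -> dict[str, int | None]:
    """Classification table where non-conserved genes lose their signature."""
    conserved = set(conserved)
    return {g: (t if g in conserved else None)
            for g, t in classifications.items()}
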