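"""Readers and writers for the pipeline's file formats.

FASTA via Biopython; BED6 and all tables as plain TSV through pandas; PWM
collections as JSON; Newick comes from :meth:`ClusterTree.to_newick`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import MotifMatch, MotifModel, RegulatoryRegion
from .windows import SignatureWindow


def read_fasta(path) -> dict[str, str]:
    """id -> sequence (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write((SeqRecord(Seq(seq), id=name, description="")
                 for name, seq in records), str(path), "fasta")


def read_regions(fasta_path, table_path) -> list[RegulatoryRegion]:
    """Regions from a FASTA plus a (region_id, gene_id, kind, length) TSV."""
    seqs = read_fasta(fasta_path)
    table = pd.read_csv(table_path, sep="\t")
    regions = []
    for row in table.itertuples():
        if row.region_id not in seqs:
            raise KeyError(f"region {row.region_id!r} missing from FASTA")
        regions.append(RegulatoryRegion(row.region_id, row.gene_id, row.kind,
                                        seqs[row.region_id]))
    return regions


def read_sites_tsv(path) -> dict[str, list[str]]:
    """Two-column (family, sequence) TSV -> family -> aligned sites."""
    df = pd.read_csv(path, sep="\t")
    return {fam: list(grp[df.columns[1]]) for fam, grp in df.groupby(df.columns[0])}


def write_pwms(path, models: dict[str, MotifModel]) -> None:
    payload = {
        fam: {
            "matrix": np.asarray(m.matrix).tolist(),
            "consensus": m.consensus,
            "min_rel_score": m.min_rel_score,
        }
        for fam, m in models.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_pwms(path) -> dict[str, MotifModel]:
    payload = json.loads(Path(path).read_text())
    return {fam: MotifModel(fam, np.array(d["matrix"]), d["consensus"],
                            d["min_rel_score"])
            for fam, d in payload.items()}


def matches_to_bed(matches: Sequence[MotifMatch]) -> pd.DataFrame:
    """BED6: chrom=region_id, name=family, score=round(1000*rel_score)."""
    return pd.DataFrame({
        "chrom": [m.region_id for m in matches],
        "start": [m.start for m in matches],
        "end": [m.end for m in matches],
        "name": [m.family for m in matches],
        "score": [int(round(1000 * m.rel_score)) for m in matches],
        "strand": [m.strand for m in matches],
    })


def write_matches_bed(path, matches: Sequence[MotifMatch]) -> None:
    matches_to_bed(matches).to_csv(path, sep="\t", header=False, index=False)


def read_matches_bed(path) -> list[MotifMatch]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return [MotifMatch(r.name, r.chrom, int(r.start), int(r.end), r.strand,
                       r.score / 1000.0)
            for r in df.itertuples(index=False)]


def write_windows_bed(path, windows: Sequence[SignatureWindow]) -> None:
    """BED with names w<tier>_<n>, echoing how windows are labelled."""
    rows = []
    counter: dict[int, int] = {}
    for w in sorted(windows, key=lambda w: (w.region_id, w.start)):
        counter[w.tier] = counter.get(w.tier, 0) + 1
        rows.append((w.region_id, w.start, w.end,
                     f"w{w.tier}_{counter[w.tier]}", w.tier,
                     ",".join(sorted(w.families))))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_classification(path, classifications: dict[str, int | None]) -> None:
    df = pd.DataFrame({
        "gene_id": list(classifications),
        "max_tier": [t if t is not None else 0 for t in classifications.values()],
    }).sort_values("gene_id")
    df.to_csv(path, sep="\t", index=False)


def read_classification(path) -> dict[str, int | None]:
    df = pd.read_csv(path, sep="\t")
    return {r.gene_id: (int(r.max_tier) if r.max_tier > 0 else None)
            for r in df.itertuples(index=False)}


def read_matrix_tsv(path) -> pd.DataFrame:
    """Gene-by-column matrix TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)
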