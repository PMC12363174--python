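"""Plain-text readers and writers for the pipeline's tabular formats.

All tables are tab-separated with a header row. Genome annotations use the
columns (genome_id, contig, start, end, strand, cog, protein_id) with
1-based inclusive coordinates; count tables are samples x strains with a
companion metadata table keyed by sample; distance matrices are square
with matching header row and index column; trees are Newick.
"""

from __future__ import annotations

import json
from collections import defaultdict

import numpy as np
import pandas as pd
from Bio import SeqIO

from .community import CountTable
from .errors import FormatError
from .screen import Gene, GenomeAnnotation

__all__ = [
    "read_annotations",
    "read_tssb_fasta",
    "write_clusters",
    "read_count_table",
    "write_count_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_scores",
    "read_config",
    "write_config",
]

_ANNOT_COLS = ["genome_id", "contig", "start", "end", "strand", "cog", "protein_id"]


def read_annotations(path) -> list[GenomeAnnotation]:
    """Read a per-gene annotation TSV into GenomeAnnotation objects."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _ANNOT_COLS if c not in frame.columns]
    if missing:
        raise FormatError(f"annotation table missing columns: {missing}")
    genomes: dict[str, list[Gene]] = defaultdict(list)
    for row in frame.itertuples(index=False):
        cog = None if pd.isna(row.cog) or row.cog == "" else str(row.cog)
        genomes[row.genome_id].append(Gene(
            contig=str(row.contig), start=int(row.start), end=int(row.end),
            strand=str(row.strand), cog=cog, protein_id=str(row.protein_id),
        ))
    return [GenomeAnnotation(gid, genes) for gid, genes in genomes.items()]


def read_tssb_fasta(path) -> dict[str, str]:
    """TssB protein sequences keyed by record id (matching protein_id)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_clusters(clusters, path) -> None:
    """Write called clusters as TSV (one row per cluster)."""
    rows = [{
        "genome_id": c.genome_id,
        "contig": c.contig,
        "start": c.start,
        "end": c.end,
        "n_genes": len(c.member_genes),
        "n_core_cogs": len(c.cogs_present),
        "cogs_present": ";".join(sorted(c.cogs_present)),
        "subtype": c.subtype,
    } for c in clusters]
    pd.DataFrame(rows, columns=[
        "genome_id", "contig", "start", "end", "n_genes", "n_core_cogs",
        "cogs_present", "subtype",
    ]).to_csv(path, sep="\t", index=False)


def read_count_table(counts_path, meta_path) -> CountTable:
    """Read a samples x strains count TSV plus its metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    missing = counts.index.difference(meta.index)
    if len(missing):
        raise FormatError(f"samples missing metadata: {list(missing)[:5]}")
    return CountTable(counts, meta.loc[counts.index])


def write_count_table(table: CountTable, counts_path, meta_path) -> None:
    table.counts.to_csv(counts_path, sep="\t")
    table.meta.to_csv(meta_path, sep="\t")


def read_distance_matrix(path) -> pd.DataFrame:
    dm = pd.read_csv(path, sep="\t", index_col=0)
    if list(dm.index) != list(dm.columns):
        raise FormatError("distance matrix header row and index column differ")
    data = dm.to_numpy(dtype=float)
    if not np.allclose(data, data.T):
        raise FormatError("distance matrix is not symmetric")
    return dm


def write_distance_matrix(dm, path) -> None:
    if hasattr(dm, "ids"):  # skbio DistanceMatrix
        dm = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    dm.to_csv(path, sep="\t")


def write_scores(scores: pd.DataFrame, path) -> None:
    """Sensitivity scores TSV: strain, S, ci_low, ci_high, status."""
    scores.to_csv(path, sep="\t")


def read_config(path) -> dict:
    with open(path) as handle:
        return json.load(handle)


def write_config(cfg, path) -> None:
    payload = {}
    for key, value in vars(cfg).items():
        if isinstance(value, np.ndarray):
            value = value.tolist()
        elif isinstance(value, tuple):
            value = list(value)
        payload[key] = value
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2)
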