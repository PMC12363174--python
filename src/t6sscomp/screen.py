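"""T6SS gene-cluster detection, subtype classification, and prevalence.

Detection follows the 10-COG rule: a type VI secretion system locus is
called from the co-localization of genes annotated with the ten T6SS core
Clusters of Orthologous Groups (COG3515, COG3516, COG3517, COG3518,
COG3519, COG3520, COG3521, COG3522, COG3455, COG3523). Within a contig,
maximal runs of core-COG genes separated by at most ``max_gap_genes``
non-core genes are collected; a run is emitted as a cluster when it carries
at least ``min_core_cogs`` distinct core COGs (default 8 of 10, tolerant of
fragmented draft assemblies while rejecting orphan genes).

Subtype classification (i1, i2, i3, i4a, i4b, i5, iii) is by best global
percent identity of the cluster's TssB sheath protein (COG3516) against a
labelled reference panel.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import FormatError

__all__ = [
    "T6SS_CORE_COGS",
    "SUBTYPES",
    "Gene",
    "GenomeAnnotation",
    "T6SSCluster",
    "ReferencePanel",
    "PrevalenceSummary",
    "detect_clusters",
    "classify_subtype",
    "classify_cluster",
    "summarize_prevalence",
]

T6SS_CORE_COGS = frozenset({
    "COG3515", "COG3516", "COG3517", "COG3518", "COG3519",
    "COG3520", "COG3521", "COG3522", "COG3455", "COG3523",
})

#: TssB COG used for subtype classification
TSSB_COG = "COG3516"

SUBTYPES = ("i1", "i2", "i3", "i4a", "i4b", "i5", "iii")

_AA = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class Gene:
    """One annotated gene: 1-based inclusive coordinates, optional COG."""

    contig: str
    start: int
    end: int
    strand: str
    cog: str | None
    protein_id: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.protein_id}: unknown strand symbol {self.strand!r}"
            )
        if self.start > self.end:
            raise FormatError(
                f"gene {self.protein_id}: start {self.start} > end {self.end}"
            )


@dataclass
class GenomeAnnotation:
    """Per-gene records of one genome, sortable by (contig, start)."""

    genome_id: str
    genes: list[Gene] = field(default_factory=list)

    def sorted_genes(self) -> list[Gene]:
        return sorted(self.genes, key=lambda g: (g.contig, g.start, g.end))


@dataclass
class T6SSCluster:
    genome_id: str
    contig: str
    member_genes: list[Gene]
    cogs_present: frozenset
    subtype: str = "unclassified"

    @property
    def start(self) -> int:
        return min(g.start for g in self.member_genes)

    @property
    def end(self) -> int:
        return max(g.end for g in self.member_genes)


def detect_clusters(annotation: GenomeAnnotation, max_gap_genes: int = 5,
                    min_core_cogs: int = 8) -> list[T6SSCluster]:
    """Call T6SS clusters in one genome by the 10-COG co-localization rule.

    Gene records are sorted internally, so the result is invariant under
    record permutation; clusters are ordered by (contig, start).
    """
    if not 1 <= min_core_cogs <= 10:
        raise ValueError("min_core_cogs must be in 1..10")
    clusters: list[T6SSCluster] = []
    genes = annotation.sorted_genes()

    run: list[Gene] = []
    gap = 0
    current_contig = None

    def flush():
        if run:
            cogs = frozenset(g.cog for g in run)
            if len(cogs) >= min_core_cogs:
                clusters.append(T6SSCluster(
                    genome_id=annotation.genome_id,
                    contig=run[0].contig,
                    member_genes=list(run),
                    cogs_present=cogs,
                ))
            run.clear()

    for gene in genes:
        if gene.contig != current_contig:
            flush()
            current_contig = gene.contig
            gap = 0
        if gene.cog in T6SS_CORE_COGS:
            if run and gap > max_gap_genes:
                flush()
            run.append(gene)
            gap = 0
        else:
            gap += 1
    flush()
    clusters.sort(key=lambda c: (c.genome_id, c.contig, c.start))
    return clusters


@dataclass
class ReferencePanel:
    """Labelled TssB reference sequences, >= 2 representatives per subtype."""

    entries: list[tuple[str, str]]  # (subtype label, amino-acid sequence)

    def __post_init__(self):
        for label, seq in self.entries:
            if label not in SUBTYPES:
                raise FormatError(f"unknown subtype label {label!r} in panel")
            if not seq or not set(seq) <= _AA:
                raise FormatError(f"panel entry {label!r}: invalid sequence")

    @classmethod
    def from_fasta(cls, path) -> "ReferencePanel":
        """Read a panel FASTA whose description lines carry ``subtype=<label>``."""
        entries = []
        for rec in SeqIO.parse(path, "fasta"):
            fields = dict(
                kv.split("=", 1) for kv in rec.description.split() if "=" in kv
            )
            if "subtype" not in fields:
                raise FormatError(f"panel record {rec.id}: missing subtype= tag")
            entries.append((fields["subtype"], str(rec.seq).upper()))
        return cls(entries)

    @classmethod
    def default(cls) -> "ReferencePanel":
        """The packaged synthetic TssB panel (stand-in reference set)."""
        ref = resources.files("t6sscomp.data") / "tssb_panel_synthetic.fasta"
        with resources.as_file(ref) as path:
            return cls.from_fasta(path)


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


def global_identity(query: str, subject: str) -> float:
    """Percent identity over the global alignment length, terminal gaps
    included (fraction in [0, 1])."""
    aln = _aligner().align(query, subject)[0]
    c = aln.counts()
    total = c.identities + c.mismatches + c.gaps
    return c.identities / total if total else 0.0


def classify_subtype(tssb_sequence: str, panel: ReferencePanel | None = None,
                     min_identity: float = 0.30) -> tuple[str, float]:
    """Label a TssB sequence by its best panel hit.

    Returns ``(label, best_identity)``; ``"unclassified"`` when the best
    identity falls below ``min_identity``, ``"ambiguous"`` when two distinct
    subtypes tie within 1e-6.
    """
    seq = tssb_sequence.upper()
    if not seq:
        raise FormatError("empty TssB sequence")
    bad = set(seq) - _AA
    if bad:
        raise FormatError(f"non-amino-acid characters in TssB sequence: {sorted(bad)}")
    if panel is None:
        panel = ReferencePanel.default()

    best_per_subtype: dict[str, float] = {}
    for label, ref in panel.entries:
        ident = global_identity(seq, ref)
        if ident > best_per_subtype.get(label, -1.0):
            best_per_subtype[label] = ident
    ranked = sorted(best_per_subtype.items(), key=lambda kv: (-kv[1], kv[0]))
    label, best = ranked[0]
    if best < min_identity:
        return "unclassified", best
    if len(ranked) > 1 and best - ranked[1][1] <= 1e-6:
        return "ambiguous", best
    return label, best


def classify_cluster(cluster: T6SSCluster, tssb_sequences: dict[str, str],
                     panel: ReferencePanel | None = None,
                     min_identity: float = 0.30) -> str:
    """Assign a cluster subtype from its TssB gene(s).

    Each COG3516 member with an available protein sequence is classified;
    the cluster label is the majority vote, ``"ambiguous"`` on ties, and
    ``"unclassified"`` when no TssB sequence is available. Mutates and
    returns ``cluster.subtype``.
    """
    if panel is None:
        panel = ReferencePanel.default()
    labels = []
    for gene in cluster.member_genes:
        if gene.cog == TSSB_COG and gene.protein_id in tssb_sequences:
            label, _ = classify_subtype(
                tssb_sequences[gene.protein_id], panel, min_identity
            )
            labels.append(label)
    if not labels:
        cluster.subtype = "unclassified"
    else:
        counts = Counter(labels).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            cluster.subtype = "ambiguous"
        else:
            cluster.subtype = counts[0][0]
    return cluster.subtype


@dataclass
class PrevalenceSummary:
    """Cluster prevalence accounting, overall and per taxonomic order."""

    n_genomes: int
    n_positive: int
    total_clusters: int
    subtype_counts: dict[str, int]
    clusters_per_genome: dict[str, int]
    per_order: pd.DataFrame

    @property
    def fraction_positive(self) -> float:
        return self.n_positive / self.n_genomes if self.n_genomes else float("nan")

    @property
    def percent_positive(self) -> float:
        """Percent of genomes with >= 1 cluster, rounded to one decimal."""
        return round(100.0 * self.fraction_positive, 1)

    @property
    def subtype_i_total(self) -> int:
        """Clusters in any of the subtype-i groups (i1..i5)."""
        return sum(v for k, v in self.subtype_counts.items() if k.startswith("i")
                   and k != "iii")

    @property
    def mean_clusters_per_positive_genome(self) -> float:
        if self.n_positive == 0:
            return float("nan")
        return self.total_clusters / self.n_positive

    @property
    def mean_clusters_per_genome(self) -> float:
        if self.n_genomes == 0:
            return float("nan")
        return self.total_clusters / self.n_genomes

    @property
    def min_clusters(self) -> int:
        return min(self.clusters_per_genome.values(), default=0)

    @property
    def max_clusters(self) -> int:
        return max(self.clusters_per_genome.values(), default=0)


def summarize_prevalence(clusters_by_genome: dict[str, list[T6SSCluster]],
                         taxonomy: dict[str, str]) -> PrevalenceSummary:
    """Prevalence accounting over a screened genome collection.

    ``clusters_by_genome`` maps every screened genome (including negatives,
    with empty lists) to its called clusters; ``taxonomy`` maps each genome
    to its taxonomic order. Reports, per order and overall, the fraction of
    T6SS-positive genomes, cluster totals, subtype counts, and
    mean/min/max clusters per genome (both genome denominators).
    """
    missing = [g for g in clusters_by_genome if g not in taxonomy]
    if missing:
        raise ValueError(f"genomes missing from taxonomy: {sorted(missing)[:5]}")

    per_genome = {g: len(cl) for g, cl in clusters_by_genome.items()}
    subtype_counts = Counter(
        c.subtype for cl in clusters_by_genome.values() for c in cl
    )

    rows = []
    for order in sorted(set(taxonomy[g] for g in clusters_by_genome)):
        genomes = [g for g in clusters_by_genome if taxonomy[g] == order]
        n_pos = sum(per_genome[g] > 0 for g in genomes)
        n_clusters = sum(per_genome[g] for g in genomes)
        rows.append({
            "order": order,
            "n_genomes": len(genomes),
            "n_positive": n_pos,
            "fraction_positive": n_pos / len(genomes),
            "total_clusters": n_clusters,
        })
    per_order = pd.DataFrame(rows).set_index("order")

    return PrevalenceSummary(
        n_genomes=len(clusters_by_genome),
        n_positive=sum(v > 0 for v in per_genome.values()),
        total_clusters=sum(per_genome.values()),
        subtype_counts=dict(subtype_counts),
        clusters_per_genome=per_genome,
        per_order=per_order,
    )
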