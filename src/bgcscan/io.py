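"""Readers, writers and the concatenated genome coordinate system.

Sequence data come in as plain FASTA, gene models as GFF3 (1-based,
inclusive), cluster intervals as GFF3 or BED, and gene-category labels as a
two-column TSV.  The :class:`GenomeLayout` maps per-contig coordinates onto a
single concatenated axis built from the large "supercontigs" of an assembly,
ordered by decreasing size — the convention used to draw a whole-genome
enrichment track for a fragmented fungal assembly.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ContigRecord",
    "GeneModel",
    "GeneAnnotation",
    "GenomeLayout",
    "ClusterInterval",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_labels",
    "write_labels",
    "read_clusters_bed",
    "read_clusters_gff3",
    "write_clusters_bed",
    "build_layout",
    "compute_gc",
]

_DNA_OK = set("ACGTN")


@dataclass(frozen=True)
class ContigRecord:
    """A single assembly contig: id, length and (optionally) its sequence."""

    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"contig {self.id!r}: length must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.id!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon structure, 1-based inclusive coordinates.

    Introns are implicit: the gaps between consecutive exons.
    """

    id: str
    contig_id: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id!r}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id!r}: strand must be + or -")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"gene {self.id!r}: exon start > end")
            if s < self.start or e > self.end:
                raise ValueError(
                    f"gene {self.id!r}: exon ({s},{e}) outside gene span "
                    f"({self.start},{self.end})"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"gene {self.id!r}: exons overlap or are unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        """Floor midpoint in 1-based contig coordinates."""
        return (self.start + self.end) // 2

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)


class GeneAnnotation:
    """A collection of gene models keyed by id, indexed by contig."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self.by_contig: dict[str, list[GeneModel]] = {}
        for g in genes:
            if g.id in self.genes:
                raise ValueError(f"duplicate gene id {g.id!r}")
            self.genes[g.id] = g
            self.by_contig.setdefault(g.contig_id, []).append(g)
        for lst in self.by_contig.values():
            lst.sort(key=lambda g: (g.start, g.end, g.id))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


@dataclass(frozen=True)
class ClusterInterval:
    """A secondary-metabolite gene-cluster interval on a contig."""

    id: str
    contig_id: str
    start: int
    end: int
    cluster_type: str = "other"
    member_gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"cluster {self.id!r}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeLayout:
    """Supercontigs longer than a threshold, concatenated in size order.

    ``entries`` holds ``(contig_id, length, global_offset)`` with offsets
    equal to the cumulative lengths of the preceding included contigs.
    Contigs at or below ``min_contig_length`` are excluded and have no
    global coordinate.
    """

    entries: tuple[tuple[str, int, int], ...]
    min_contig_length: int
    _index: Mapping[str, tuple[int, int]] = field(repr=False, hash=False, compare=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {cid: (length, off) for cid, length, off in self.entries}
        )

    @property
    def total_length(self) -> int:
        return sum(length for _, length, _ in self.entries)

    @property
    def contig_ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _, _ in self.entries)

    def includes(self, contig_id: str) -> bool:
        return contig_id in self._index

    def contig_length(self, contig_id: str) -> int:
        return self._index[contig_id][0]

    def offset(self, contig_id: str) -> int:
        return self._index[contig_id][1]

    def to_global(self, contig_id: str, pos: int) -> int:
        """Map a 1-based contig position to the 1-based concatenated axis."""
        if contig_id not in self._index:
            raise KeyError(f"contig {contig_id!r} is not included in the layout")
        length, off = self._index[contig_id]
        if not 1 <= pos <= length:
            raise ValueError(
                f"position {pos} outside contig {contig_id!r} (length {length})"
            )
        return off + pos

    def from_global(self, gpos: int) -> tuple[str, int]:
        """Inverse of :meth:`to_global`."""
        if not 1 <= gpos <= self.total_length:
            raise ValueError(f"global position {gpos} outside the axis")
        for cid, length, off in self.entries:
            if off < gpos <= off + length:
                return cid, gpos - off
        raise AssertionError("unreachable: offsets are a partition")


def read_fasta(path: str | Path, with_sequence: bool = True) -> list[ContigRecord]:
    """Read a (multi-)FASTA file into :class:`ContigRecord` objects.

    Lowercase residues are normalized to uppercase.  Raises on an empty file
    and on duplicate record ids.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        records.append(
            ContigRecord(rec.id, len(seq), seq if with_sequence else None)
        )
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[ContigRecord], path: str | Path, width: int = 80) -> None:
    seqrecs = []
    for rec in records:
        if rec.sequence is None:
            raise ValueError(f"contig {rec.id!r} has no sequence to write")
        seqrecs.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def _merge_exon_intervals(ivals: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of possibly overlapping exon intervals (across isoforms)."""
    ivals = sorted(ivals)
    merged: list[list[int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def read_gff3(
    path: str | Path, contigs: Sequence[ContigRecord] | None = None
) -> GeneAnnotation:
    """Parse gene/mRNA/exon features from a GFF3 file into gene models.

    Exons are attached to their gene through Parent relations (directly or
    via an mRNA).  A gene without exon children becomes a single-exon gene
    spanning its full extent.  Exons from multiple isoforms are unioned.
    When ``contigs`` is given, genes referencing unknown contigs raise.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    known = {c.id for c in contigs} if contigs is not None else None
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if known is not None and gene.seqid not in known:
            raise ValueError(
                f"gene {gene.id!r} references unknown contig {gene.seqid!r}"
            )
        exon_ivals: list[tuple[int, int]] = []
        for exon in db.children(gene, featuretype="exon"):
            if exon.start < gene.start or exon.end > gene.end:
                raise ValueError(
                    f"exon ({exon.start},{exon.end}) outside gene "
                    f"{gene.id!r} span ({gene.start},{gene.end})"
                )
            exon_ivals.append((exon.start, exon.end))
        if not exon_ivals:
            exons = ((gene.start, gene.end),)
        else:
            exons = _merge_exon_intervals(exon_ivals)
        genes.append(
            GeneModel(
                id=gene.id,
                contig_id=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=exons,
            )
        )
    return GeneAnnotation(genes)


def write_gff3(annotation: GeneAnnotation, path: str | Path, source: str = "bgcscan") -> None:
    """Write an annotation as gene/mRNA/exon GFF3 rows (1-based, inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig_id in sorted(annotation.by_contig):
            for g in annotation.by_contig[contig_id]:
                attrs = f"ID={g.id}"
                fh.write(
                    f"{g.contig_id}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                mrna_id = f"{g.id}.t1"
                fh.write(
                    f"{g.contig_id}\t{source}\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={mrna_id};Parent={g.id}\n"
                )
                for i, (s, e) in enumerate(g.exons, 1):
                    fh.write(
                        f"{g.contig_id}\t{source}\texon\t{s}\t{e}\t.\t{g.strand}\t.\tID={mrna_id}.exon{i};Parent={mrna_id}\n"
                    )


def read_labels(
    path: str | Path, annotation: GeneAnnotation | None = None
) -> dict[str, str]:
    """Read a two-column TSV of ``gene_id -> category`` labels.

    Lines starting with ``#`` are comments.  A gene may carry at most one
    category; conflicting duplicates raise.  With ``annotation`` given,
    label ids absent from the annotation raise, naming the first offender.
    """
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            gene_id, category = parts[0], parts[1]
            if gene_id in labels and labels[gene_id] != category:
                raise ValueError(
                    f"gene {gene_id!r} labeled with conflicting categories "
                    f"{labels[gene_id]!r} and {category!r}"
                )
            labels[gene_id] = category
    if annotation is not None:
        for gene_id in labels:
            if gene_id not in annotation:
                raise ValueError(f"label references unknown gene id {gene_id!r}")
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tcategory\n")
        for gene_id in sorted(labels):
            fh.write(f"{gene_id}\t{labels[gene_id]}\n")


def read_clusters_bed(path: str | Path) -> list[ClusterInterval]:
    """Read cluster intervals from BED (0-based half-open -> 1-based inclusive).

    Columns: chrom, start, end, [name, score, strand].  The score column,
    when non-numeric, is reused as the cluster type (a common antiSMASH
    export shortcut); otherwise the type defaults to "other".
    """
    clusters: list[ClusterInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else f"cluster{lineno}"
            ctype = "other"
            if len(parts) > 4:
                try:
                    float(parts[4])
                except ValueError:
                    ctype = parts[4]
            clusters.append(ClusterInterval(name, chrom, start0 + 1, end0, ctype))
    return clusters


def read_clusters_gff3(path: str | Path) -> list[ClusterInterval]:
    """Read cluster intervals from a GFF3 of region-level features.

    Any feature row is taken as one cluster; the type comes from a
    ``cluster_type`` or ``product`` attribute, falling back to the feature
    type column.
    """
    clusters: list[ClusterInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns")
            seqid, _src, ftype, start, end, _score, _strand, _phase, attrs = parts
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            cid = attr_map.get("ID", f"cluster{lineno}")
            ctype = attr_map.get("cluster_type", attr_map.get("product", ftype))
            members = tuple(
                m for m in attr_map.get("member_genes", "").split(",") if m
            )
            clusters.append(
                ClusterInterval(cid, seqid, int(start), int(end), ctype, members)
            )
    return clusters


def write_clusters_bed(clusters: Iterable[ClusterInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(f"{c.contig_id}\t{c.start - 1}\t{c.end}\t{c.id}\t{c.cluster_type}\t.\n")


def build_layout(
    contigs: Sequence[ContigRecord], min_contig_length: int = 100_000
) -> GenomeLayout:
    """Concatenate contigs strictly longer than the threshold, largest first.

    Equal-length contigs are ordered lexicographically by id so the axis is
    deterministic.  Raises if no contig exceeds the threshold.
    """
    included = [c for c in contigs if c.length > min_contig_length]
    if not included:
        raise ValueError(
            f"empty layout: no contig longer than {min_contig_length} bp"
        )
    included.sort(key=lambda c: (-c.length, c.id))
    entries = []
    offset = 0
    for c in included:
        entries.append((c.id, c.length, offset))
        offset += c.length
    return GenomeLayout(tuple(entries), min_contig_length)


def compute_gc(records: Sequence[ContigRecord]) -> float:
    """GC percent over all sequences: 100*(G+C)/(A+C+G+T).

    Ambiguous bases (N etc.) are excluded from the denominator; an input
    with no unambiguous bases raises.
    """
    gc = 0
    acgt = 0
    for rec in records:
        if rec.sequence is None:
            raise ValueError(f"contig {rec.id!r} has no sequence")
        s = rec.sequence.upper()
        g = s.count("G")
        c = s.count("C")
        gc += g + c
        acgt += s.count("A") + s.count("T") + g + c
    if acgt == 0:
        raise ValueError("no unambiguous bases in the input sequences")
    return 100.0 * gc / acgt
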