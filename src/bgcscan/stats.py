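"""Assembly and annotation summary statistics.

The numbers mirror the usual "general genome features" table of a fungal
genome report: assembly size, contig counts above size thresholds, N50, GC
content, gene counts, exon/intron structure and the fraction of the genome
covered by genes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

from .io import ContigRecord, GeneAnnotation, compute_gc

__all__ = ["AssemblyStats", "AnnotationStats", "n50", "assembly_stats", "annotation_stats"]


@dataclass(frozen=True)
class AssemblyStats:
    total_length: int
    n_contigs_over_200bp: int
    n_supercontigs_over_100kb: int
    longest_contig: int
    n50: int
    gc_percent: float | None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class AnnotationStats:
    n_genes: int
    n_genes_with_introns: int
    mean_exons_per_gene: float
    mean_introns_per_gene: float
    longest_gene: int
    mean_gene_length: float
    mean_exon_length: float
    mean_intron_length: float
    percent_genome_covered: float

    def to_dict(self) -> dict:
        return asdict(self)


def n50(lengths: Sequence[int]) -> int:
    """The length L such that contigs >= L sum to at least half the total."""
    if not lengths:
        raise ValueError("n50 of an empty length list")
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if 2 * acc >= total:
            return L
    raise AssertionError("unreachable")


def assembly_stats(
    contigs: Sequence[ContigRecord],
    contig_threshold: int = 200,
    supercontig_threshold: int = 100_000,
) -> AssemblyStats:
    """Summarize an assembly; size-class counts use strict "longer than"."""
    lengths = [c.length for c in contigs]
    have_seq = all(c.sequence is not None for c in contigs)
    return AssemblyStats(
        total_length=sum(lengths),
        n_contigs_over_200bp=sum(1 for L in lengths if L > contig_threshold),
        n_supercontigs_over_100kb=sum(1 for L in lengths if L > supercontig_threshold),
        longest_contig=max(lengths),
        n50=n50(lengths),
        gc_percent=compute_gc(contigs) if have_seq else None,
    )


def annotation_stats(
    annotation: GeneAnnotation,
    genome_length: int,
    contigs: Sequence[ContigRecord] | None = None,
) -> AnnotationStats:
    """Summarize gene models; coverage is the union of gene spans.

    Introns per gene equal exons minus one, so the intron mean is tied to
    the exon mean by construction.  Overlapping genes are not
    double-counted in coverage, which therefore never exceeds 100%.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    if contigs is not None:
        clen = {c.id: c.length for c in contigs}
        for g in annotation:
            if g.contig_id in clen and g.end > clen[g.contig_id]:
                raise ValueError(
                    f"gene {g.id!r} extends past the end of contig {g.contig_id!r}"
                )

    genes = list(annotation)
    if not genes:
        raise ValueError("annotation holds no genes")
    n_genes = len(genes)
    exon_lengths: list[int] = []
    intron_lengths: list[int] = []
    n_with_introns = 0
    for g in genes:
        exon_lengths.extend(e - s + 1 for s, e in g.exons)
        ivs = g.introns
        if ivs:
            n_with_introns += 1
            intron_lengths.extend(e - s + 1 for s, e in ivs)

    covered = 0
    for contig_genes in annotation.by_contig.values():
        # genes are sorted by start; sweep the union of spans
        cur_s, cur_e = None, None
        for g in contig_genes:
            if cur_e is None or g.start > cur_e + 1:
                if cur_e is not None:
                    covered += cur_e - cur_s + 1
                cur_s, cur_e = g.start, g.end
            else:
                cur_e = max(cur_e, g.end)
        if cur_e is not None:
            covered += cur_e - cur_s + 1

    return AnnotationStats(
        n_genes=n_genes,
        n_genes_with_introns=n_with_introns,
        mean_exons_per_gene=len(exon_lengths) / n_genes,
        mean_introns_per_gene=len(intron_lengths) / n_genes,
        longest_gene=max(g.length for g in genes),
        mean_gene_length=sum(g.length for g in genes) / n_genes,
        mean_exon_length=sum(exon_lengths) / len(exon_lengths),
        mean_intron_length=(
            sum(intron_lengths) / len(intron_lengths) if intron_lengths else 0.0
        ),
        percent_genome_covered=100.0 * covered / genome_length,
    )
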