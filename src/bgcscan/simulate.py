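"""Synthetic genomes, annotations, labels and diverged protein clusters.

Every analysis stage in this package can be exercised on generated data
with known ground truth: multi-contig assemblies with a target GC, gene
models with exon/intron structure at fungal-like densities, gene-category
labels planted at a uniform base rate plus high-density regions, and
protein clusters diverged from a reference at controlled substitution and
indel rates with optional adjacent-gene swaps and fusions.

Default parameter values emulate a compact fungal genome: roughly one gene
per 2.7 kb, a mean of 3 exons per gene, ~450 bp exons, ~95 bp introns and
49% GC.  All randomness flows through an explicit integer seed; identical
configurations give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import ContigRecord, GeneAnnotation, GeneModel
from .homology import ProteinRecord

__all__ = [
    "SimulationConfig",
    "PlantedRegion",
    "SyntheticTruth",
    "simulate_genome",
    "simulate_annotation",
    "plant_label_enrichment",
    "simulate_proteins",
    "diverge_cluster",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedRegion:
    """A contig interval whose genes carry labels at an elevated rate."""

    contig_id: str
    start: int  # 1-based inclusive
    end: int
    multiplier: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("planted region start > end")
        if self.multiplier < 1:
            raise ValueError("planted multiplier must be >= 1")


@dataclass
class SimulationConfig:
    """Knobs of the generator; the seed is mandatory.

    contig_lengths: explicit list of contig lengths (bp).
    gc: target GC percent of the simulated sequence.
    mean_bp_per_gene: gene density (one gene every this many bp on average).
    mean_exons_per_gene: mean of the (shifted-Poisson) exon-count draw.
    mean_exon_length / mean_intron_length: exponential means, floored at
    minimum lengths so gene models stay valid.
    """

    seed: int
    contig_lengths: tuple[int, ...] = (1_000_000,)
    gc: float = 49.0
    mean_bp_per_gene: float = 2700.0
    mean_exons_per_gene: float = 3.0
    mean_exon_length: float = 450.0
    min_exon_length: int = 30
    mean_intron_length: float = 95.0
    min_intron_length: int = 20
    base_label_rate: float = 0.05
    label_category: str = "CAZy"
    planted_regions: tuple[PlantedRegion, ...] = ()
    cap_label_rate: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.gc <= 100:
            raise ValueError("gc must be in [0, 100]")
        if not 0 <= self.base_label_rate <= 1:
            raise ValueError("base_label_rate must be in [0, 1]")
        if self.mean_exons_per_gene < 1:
            raise ValueError("mean_exons_per_gene must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation run, serializable to JSON."""

    planted_regions: list[dict] = field(default_factory=list)
    labels: dict[str, str] = field(default_factory=dict)
    ortholog_map: dict[str, list[str]] = field(default_factory=dict)
    swaps: list[list[str]] = field(default_factory=list)
    fusions: list[list[str]] = field(default_factory=list)
    substitution_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def simulate_genome(
    config: SimulationConfig, with_sequence: bool = True
) -> list[ContigRecord]:
    """I.i.d. sequence with P(G)+P(C) = gc/100, split G/C and A/T evenly.

    ``with_sequence=False`` emits length-only contigs for analyses that
    need coordinates but not residues (e.g. the window scan).
    """
    rng = np.random.default_rng(config.seed)
    g = config.gc / 200.0
    a = (100.0 - config.gc) / 200.0
    probs = np.array([a, g, g, a])  # A, C, G, T
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    contigs = []
    for i, length in enumerate(config.contig_lengths, 1):
        if with_sequence:
            draws = rng.choice(4, size=length, p=probs)
            seq = alphabet[draws].tobytes().decode("ascii")
        else:
            seq = None
        contigs.append(ContigRecord(f"contig{i:03d}", length, seq))
    return contigs


def simulate_annotation(
    contigs: Sequence[ContigRecord], config: SimulationConfig
) -> GeneAnnotation:
    """Place non-overlapping genes left-to-right with exponential gaps.

    Mean gap = mean_bp_per_gene - expected gene length, so the realized
    density approaches the target; raises when the density leaves no room
    for the genes themselves.
    """
    rng = np.random.default_rng(config.seed + 1)
    exp_introns = config.mean_exons_per_gene - 1
    exp_gene_len = (
        config.mean_exons_per_gene * max(config.mean_exon_length, config.min_exon_length)
        + exp_introns * max(config.mean_intron_length, config.min_intron_length)
    )
    mean_gap = config.mean_bp_per_gene - exp_gene_len
    if mean_gap <= 0:
        raise ValueError(
            "gene density too high: expected gene length "
            f"{exp_gene_len:.0f} bp exceeds mean_bp_per_gene"
        )
    genes: list[GeneModel] = []
    counter = 0
    for contig in contigs:
        pos = 1
        while True:
            gap = int(rng.exponential(mean_gap)) + 1
            start = pos + gap
            n_exons = 1 + rng.poisson(exp_introns)
            exon_lens = np.maximum(
                rng.exponential(config.mean_exon_length, size=n_exons).astype(int),
                config.min_exon_length,
            )
            intron_lens = np.maximum(
                rng.exponential(config.mean_intron_length, size=max(n_exons - 1, 0)).astype(int),
                config.min_intron_length,
            )
            exons = []
            cur = start
            for i, el in enumerate(exon_lens):
                exons.append((cur, cur + int(el) - 1))
                cur = cur + int(el)
                if i < len(intron_lens):
                    cur += int(intron_lens[i])
            end = exons[-1][1]
            if end > contig.length:
                break
            counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    id=f"gene{counter:05d}",
                    contig_id=contig.id,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=tuple(exons),
                )
            )
            pos = end
    return GeneAnnotation(genes)


def plant_label_enrichment(
    annotation: GeneAnnotation,
    config: SimulationConfig,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Label genes at the base rate, elevated inside planted regions.

    Membership in a planted region is decided by the gene midpoint.  The
    in-region rate is base_rate * multiplier, capped at 1 when
    ``cap_label_rate`` is set; otherwise a rate above 1 raises.
    """
    rng = np.random.default_rng(config.seed + 2)
    truth = SyntheticTruth(
        planted_regions=[asdict(p) for p in config.planted_regions]
    )
    labels: dict[str, str] = {}
    for g in sorted(annotation, key=lambda g: g.id):
        rate = config.base_label_rate
        for p in config.planted_regions:
            if g.contig_id == p.contig_id and p.start <= g.midpoint <= p.end:
                rate = config.base_label_rate * p.multiplier
                break
        if rate > 1:
            if not config.cap_label_rate:
                raise ValueError(
                    f"label rate {rate:.3f} exceeds 1 inside a planted region"
                )
            rate = 1.0
        if rng.random() < rate:
            labels[g.id] = config.label_category
    truth.labels = dict(labels)
    return labels, truth


def simulate_proteins(
    n: int, seed: int, length_range: tuple[int, int] = (150, 450), prefix: str = "ref"
) -> list[ProteinRecord]:
    """Random amino-acid sequences to serve as a reference cluster."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(1, n + 1):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(_AA20[j] for j in rng.integers(0, 20, size=L))
        out.append(ProteinRecord(f"{prefix}{i}", seq))
    return out


def diverge_cluster(
    reference: Sequence[ProteinRecord],
    seed: int,
    substitution: float = 0.1,
    indel_rate: float = 0.0,
    swaps: Sequence[tuple[int, int]] = (),
    fusions: Sequence[tuple[int, int]] = (),
    query_prefix: str = "q",
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Derive a query cluster from a reference with known operations.

    Per protein, each residue is substituted independently with the given
    probability (replacement uniform over the 19 alternatives), then
    single-residue indels are applied at ``indel_rate`` per position.
    ``swaps`` lists adjacent index pairs (i, i+1) whose order is exchanged
    in the query; ``fusions`` lists adjacent index pairs concatenated into
    one query protein.  Truth records the intended query-to-reference
    ortholog map, the applied operations and realized substitution counts.
    """
    if not reference:
        raise ValueError("reference cluster is empty")
    if not 0 <= substitution <= 1:
        raise ValueError("substitution proportion must be in [0, 1]")
    for i, j in list(swaps) + list(fusions):
        if j != i + 1:
            raise ValueError("swaps and fusions must name adjacent index pairs")
    fused_idx = {i for pair in fusions for i in pair}
    swap_idx = {i for pair in swaps for i in pair}
    if fused_idx & swap_idx:
        raise ValueError("a gene cannot be both swapped and fused")

    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    mutated: list[str] = []
    for r in reference:
        seq = list(r.sequence)
        n_sub = 0
        for pos in range(len(seq)):
            if rng.random() < substitution:
                alternatives = _AA20.replace(seq[pos], "")
                seq[pos] = alternatives[int(rng.integers(0, len(alternatives)))]
                n_sub += 1
        if indel_rate > 0:
            out = []
            for ch in seq:
                u = rng.random()
                if u < indel_rate / 2:
                    continue  # deletion
                out.append(ch)
                if indel_rate / 2 <= u < indel_rate:
                    out.append(_AA20[int(rng.integers(0, 20))])  # insertion
            seq = out if out else [seq[0]]
        mutated.append("".join(seq))
        truth.substitution_counts[r.id] = n_sub

    # assemble query order: start from reference order, apply swaps
    order: list[int] = list(range(len(reference)))
    for i, j in swaps:
        a, b = order.index(i), order.index(j)
        order[a], order[b] = order[b], order[a]
        truth.swaps.append([reference[i].id, reference[j].id])

    fusion_first = {i: j for i, j in fusions}
    skip = {j for _, j in fusions}
    query: list[ProteinRecord] = []
    qn = 0
    for idx in order:
        if idx in skip:
            continue
        qn += 1
        qid = f"{query_prefix}{qn}"
        if idx in fusion_first:
            j = fusion_first[idx]
            query.append(ProteinRecord(qid, mutated[idx] + mutated[j]))
            truth.ortholog_map[qid] = [reference[idx].id, reference[j].id]
            truth.fusions.append([reference[idx].id, reference[j].id])
        else:
            query.append(ProteinRecord(qid, mutated[idx]))
            truth.ortholog_map[qid] = [reference[idx].id]
    return query, truth
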