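"""Protein-level comparison of a predicted gene cluster with a reference
pathway cluster.

A query cluster (ordered proteins of a predicted biosynthetic gene cluster)
is matched against a reference cluster (the characterised pathway, e.g. a
pyripyropene or fumagillin/pseurotin cluster from another species).  Genes
are called orthologous when a pairwise protein alignment exceeds identity
and coverage thresholds — the operational rule "more than 30% identity and
more than 50% coverage", read strictly.  On top of the one-to-one ortholog
assignment the module counts synteny breakpoints (reference gene adjacencies
lost in the query) and flags fusion candidates: single query proteins whose
distinct segments each match two adjacent reference genes, the pattern seen
when two ancestral genes are merged into one ORF.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ProteinRecord",
    "OrthologCriteria",
    "AlignmentStats",
    "ClusterMatchReport",
    "FusionCandidate",
    "global_align",
    "is_ortholog",
    "match_clusters",
    "count_breakpoints",
    "detect_fusions",
    "read_protein_fasta",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYX")

# BLAST protein defaults: BLOSUM62, gap existence 11, extension 1.  In the
# aligner's convention the first gap position costs open+extend.
_GAP_OPEN = -12
_GAP_EXTEND = -1
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence (20 canonical residues plus X)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence.upper()) - _AA
        if bad:
            raise ValueError(
                f"protein {self.id!r}: illegal characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class OrthologCriteria:
    """Thresholds for the ortholog call; both are strict ("more than")."""

    min_identity: float = 30.0
    min_coverage: float = 50.0
    coverage_basis: str = "reference"  # reference | query | shorter

    def __post_init__(self) -> None:
        for v in (self.min_identity, self.min_coverage):
            if not 0 <= v <= 100:
                raise ValueError("thresholds must be in [0, 100]")
        if self.coverage_basis not in ("reference", "query", "shorter"):
            raise ValueError("coverage_basis must be reference|query|shorter")


@dataclass(frozen=True)
class AlignmentStats:
    """Identity/coverage of one pairwise alignment.

    identity = 100 * identical aligned pairs / alignment columns (gap
    columns included); coverage = percent of the coverage-basis sequence's
    residues aligned to a residue (not a gap).  Segment bounds are 0-based
    half-open on each input sequence.
    """

    identity: float
    coverage: float
    alignment_length: int
    score: float
    query_segment: tuple[int, int]
    reference_segment: tuple[int, int]
    query_coverage: float
    reference_coverage: float


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    if mode not in ("global", "local"):
        raise ValueError("mode must be 'global' or 'local'")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = _GAP_OPEN
    aligner.extend_gap_score = _GAP_EXTEND
    aligner.mode = mode
    return aligner


def global_align(
    query: ProteinRecord,
    reference: ProteinRecord,
    criteria: OrthologCriteria | None = None,
    mode: str = "global",
) -> AlignmentStats:
    """Align two proteins and report identity/coverage.

    ``mode="global"`` is Needleman-Wunsch with affine gaps (BLOSUM62,
    open 11 / extend 1, end gaps penalised); identity runs over all
    alignment columns including terminal gaps.  ``mode="local"`` is
    Smith-Waterman with the same scoring — the BLAST-like reading, and the
    right shape for probing a fused query protein with one reference gene
    at a time; identity then runs over the local alignment's columns.
    Coverage is mode-independent: the share of the coverage-basis
    sequence's residues aligned to a residue.
    """
    criteria = criteria or OrthologCriteria()
    aligner = _make_aligner(mode)
    aln = aligner.align(query.sequence.upper(), reference.sequence.upper())[0]
    q_len = len(query.sequence)
    r_len = len(reference.sequence)

    q_blocks, r_blocks = aln.aligned
    identical = 0
    aligned_res = 0
    for (qs, qe), (rs, re) in zip(q_blocks, r_blocks):
        identical += sum(
            1
            for qc, rc in zip(query.sequence[qs:qe], reference.sequence[rs:re])
            if qc.upper() == rc.upper()
        )
        aligned_res += qe - qs

    if len(q_blocks) == 0:
        q_seg = r_seg = (0, 0)
        span_cols = 0
    else:
        q_seg = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
        r_seg = (int(r_blocks[0][0]), int(r_blocks[-1][1]))
        # columns between the first and last aligned pair: residue pairs
        # plus internal gap columns on either sequence
        span_cols = aligned_res
        for i in range(1, len(q_blocks)):
            span_cols += int(q_blocks[i][0] - q_blocks[i - 1][1])
            span_cols += int(r_blocks[i][0] - r_blocks[i - 1][1])
        if mode == "global":
            # terminal gap columns count toward identity's denominator
            span_cols += q_seg[0] + r_seg[0]
            span_cols += (q_len - q_seg[1]) + (r_len - r_seg[1])

    q_cov = 100.0 * aligned_res / q_len
    r_cov = 100.0 * aligned_res / r_len
    if criteria.coverage_basis == "reference":
        cov = r_cov
    elif criteria.coverage_basis == "query":
        cov = q_cov
    else:
        cov = r_cov if r_len <= q_len else q_cov

    identity = 100.0 * identical / span_cols if span_cols else 0.0
    return AlignmentStats(
        identity=identity,
        coverage=cov,
        alignment_length=span_cols,
        score=float(aln.score),
        query_segment=q_seg,
        reference_segment=r_seg,
        query_coverage=q_cov,
        reference_coverage=r_cov,
    )


def is_ortholog(stats: AlignmentStats, criteria: OrthologCriteria | None = None) -> bool:
    """True iff identity and coverage strictly exceed their thresholds."""
    criteria = criteria or OrthologCriteria()
    return (
        stats.identity > criteria.min_identity
        and stats.coverage > criteria.min_coverage
    )


@dataclass(frozen=True)
class FusionCandidate:
    """A query protein covering >= 2 adjacent reference genes.

    Each covered reference meets the ortholog criteria with
    reference-based coverage, and the corresponding query segments are
    essentially disjoint (pairwise overlap below the tolerance).
    """

    query_id: str
    reference_ids: tuple[str, ...]
    stats: tuple[AlignmentStats, ...]
    query_segments: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class ClusterMatchReport:
    """Cluster-versus-cluster summary: "n orthologs / m reference genes"."""

    n_orthologs: int
    n_reference_genes: int
    avg_identity: float
    avg_coverage: float
    pairs: tuple[tuple[str, str, AlignmentStats], ...]
    synteny_breakpoints: int
    order_conserved: bool
    fusion_candidates: tuple[FusionCandidate, ...] = ()

    def summary(self) -> str:
        return (
            f"{self.n_orthologs}/{self.n_reference_genes} orthologs, "
            f"avg {self.avg_identity:.0f}% ID / {self.avg_coverage:.0f}% coverage, "
            f"{self.synteny_breakpoints} breakpoints, "
            f"{len(self.fusion_candidates)} fusion candidate(s)"
        )

    def to_dict(self) -> dict:
        return {
            "n_orthologs": self.n_orthologs,
            "n_reference_genes": self.n_reference_genes,
            "avg_identity": self.avg_identity,
            "avg_coverage": self.avg_coverage,
            "synteny_breakpoints": self.synteny_breakpoints,
            "order_conserved": self.order_conserved,
            "pairs": [
                {
                    "query": q,
                    "reference": r,
                    "identity": s.identity,
                    "coverage": s.coverage,
                }
                for q, r, s in self.pairs
            ],
            "fusions": [
                {"query": f.query_id, "references": list(f.reference_ids)}
                for f in self.fusion_candidates
            ],
        }


def _assign_pairs(
    stats: dict[tuple[int, int], AlignmentStats],
    n_query: int,
    n_ref: int,
    criteria: OrthologCriteria,
) -> list[tuple[int, int]]:
    """One-to-one assignment maximizing ortholog-pair count, then identity.

    Solved exactly as a linear assignment with a large per-qualifying-pair
    bonus, so the count is maximized first and total identity breaks ties.
    """
    BIG = 1e6
    weights = np.zeros((n_query, n_ref))
    for (qi, ri), st in stats.items():
        if is_ortholog(st, criteria):
            weights[qi, ri] = BIG + st.identity
    rows, cols = linear_sum_assignment(weights, maximize=True)
    return [
        (int(qi), int(ri))
        for qi, ri in zip(rows, cols)
        if weights[qi, ri] >= BIG
    ]


def count_breakpoints(
    pairs: Mapping[str, str],
    query_order: Sequence[str],
    reference_order: Sequence[str],
) -> int:
    """Synteny breakpoints between two gene orders under a one-to-one map.

    Both orders are restricted to mapped genes; a breakpoint is a reference
    adjacency (unordered pair of neighbours) absent from the query's
    adjacencies.  Strand-agnostic: a wholly reversed cluster has zero
    breakpoints.
    """
    ref_mapped = [r for r in reference_order if r in set(pairs.values())]
    query_as_ref = [pairs[q] for q in query_order if q in pairs]
    ref_adj = {frozenset(p) for p in zip(ref_mapped, ref_mapped[1:])}
    qry_adj = {frozenset(p) for p in zip(query_as_ref, query_as_ref[1:])}
    return len(ref_adj - qry_adj)


def detect_fusions(
    query: Sequence[ProteinRecord],
    reference: Sequence[ProteinRecord],
    criteria: OrthologCriteria | None = None,
    max_segment_overlap: float = 0.20,
) -> list[FusionCandidate]:
    """Find query proteins that appear to fuse adjacent reference genes.

    A query protein is a candidate when >= 2 reference genes, adjacent in
    the reference gene order, each align to it meeting the ortholog
    criteria with reference-based coverage, on query segments that overlap
    pairwise by less than ``max_segment_overlap`` of the shorter segment.
    Maximal runs of adjacent reference genes are reported as one candidate.
    """
    criteria = criteria or OrthologCriteria()
    ref_cov_criteria = OrthologCriteria(
        criteria.min_identity, criteria.min_coverage, "reference"
    )
    candidates: list[FusionCandidate] = []
    for q in query:
        hits: dict[int, AlignmentStats] = {}
        for ri, r in enumerate(reference):
            st = global_align(q, r, ref_cov_criteria, mode="local")
            if is_ortholog(st, ref_cov_criteria):
                hits[ri] = st

        def seg_ok(a: AlignmentStats, b: AlignmentStats) -> bool:
            (s1, e1), (s2, e2) = a.query_segment, b.query_segment
            ov = max(0, min(e1, e2) - max(s1, s2))
            shorter = min(e1 - s1, e2 - s2)
            return shorter > 0 and ov < max_segment_overlap * shorter

        # maximal runs of adjacent reference indices with compatible segments
        run: list[int] = []
        for ri in sorted(hits):
            if run and ri == run[-1] + 1 and seg_ok(hits[run[-1]], hits[ri]):
                run.append(ri)
            else:
                if len(run) >= 2:
                    candidates.append(_make_candidate(q, reference, run, hits))
                run = [ri]
        if len(run) >= 2:
            candidates.append(_make_candidate(q, reference, run, hits))
    return candidates


def _make_candidate(
    q: ProteinRecord,
    reference: Sequence[ProteinRecord],
    run: list[int],
    hits: dict[int, AlignmentStats],
) -> FusionCandidate:
    return FusionCandidate(
        query_id=q.id,
        reference_ids=tuple(reference[ri].id for ri in run),
        stats=tuple(hits[ri] for ri in run),
        query_segments=tuple(hits[ri].query_segment for ri in run),
    )


def match_clusters(
    query: Sequence[ProteinRecord],
    reference: Sequence[ProteinRecord],
    criteria: OrthologCriteria | None = None,
    mode: str = "global",
    with_fusions: bool = True,
) -> ClusterMatchReport:
    """All-vs-all cluster comparison yielding an "n/m" ortholog report.

    Orthologs are a one-to-one assignment of query to reference proteins
    (each reference gene used at most once) that maximizes the number of
    qualifying pairs; identity/coverage averages run over the assigned
    pairs only.  Synteny breakpoints are counted on the assigned map, and
    fusion candidates add their (otherwise unassigned) reference genes to
    the ortholog count once each.
    """
    if not query or not reference:
        raise ValueError("both clusters must be non-empty")
    criteria = criteria or OrthologCriteria()
    stats: dict[tuple[int, int], AlignmentStats] = {}
    for qi, q in enumerate(query):
        for ri, r in enumerate(reference):
            stats[(qi, ri)] = global_align(q, r, criteria, mode=mode)

    assigned = _assign_pairs(stats, len(query), len(reference), criteria)
    pair_list = tuple(
        (query[qi].id, reference[ri].id, stats[(qi, ri)]) for qi, ri in assigned
    )
    pair_map = {query[qi].id: reference[ri].id for qi, ri in assigned}

    fusion_candidates: tuple[FusionCandidate, ...] = ()
    orth_refs = {reference[ri].id for _, ri in assigned}
    if with_fusions:
        fusion_candidates = tuple(detect_fusions(query, reference, criteria))
        for f in fusion_candidates:
            orth_refs.update(f.reference_ids)

    if assigned:
        avg_id = float(np.mean([stats[p].identity for p in assigned]))
        avg_cov = float(np.mean([stats[p].coverage for p in assigned]))
    else:
        avg_id = avg_cov = 0.0

    bp = count_breakpoints(
        pair_map, [q.id for q in query], [r.id for r in reference]
    )
    return ClusterMatchReport(
        n_orthologs=len(orth_refs),
        n_reference_genes=len(reference),
        avg_identity=avg_id,
        avg_coverage=avg_cov,
        pairs=pair_list,
        synteny_breakpoints=bp,
        order_conserved=(bp == 0),
        fusion_candidates=fusion_candidates,
    )


def read_protein_fasta(path) -> list[ProteinRecord]:
    """Read an ordered protein FASTA; record order encodes gene order."""
    from Bio import SeqIO

    records = [
        ProteinRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no records in protein FASTA {path}")
    return records
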