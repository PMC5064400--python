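"""Sliding-window hypergeometric enrichment scan on a concatenated genome axis.

The scan asks, for each window, whether the window holds more labeled genes
(e.g. CAZymes) than expected if the K labeled genes were scattered at random
among the N genes of the assembly — an upper-tail hypergeometric test.
Significant windows are merged into maximal enriched regions, which can then
be intersected with secondary-metabolite cluster intervals.

Windows advance by a fixed step within each supercontig of the layout; by
default they do not span contig junctions, since a window crossing a
junction on the concatenated axis would test an interval that does not exist
in the genome.  Positions on the axis are reported 0-based, half-open
(BED-like); gene anchors are single points so each gene lands in a
deterministic set of windows.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import ClusterInterval, GeneAnnotation, GenomeLayout

__all__ = [
    "ScanParams",
    "WindowScanResult",
    "EnrichedRegion",
    "OverlapReport",
    "GeneAnchor",
    "hypergeom_upper_tail",
    "assign_genes",
    "scan",
    "call_regions",
    "overlap_with_clusters",
    "benjamini_hochberg",
    "windows_to_tsv",
    "regions_to_bed",
]

logger = logging.getLogger(__name__)

_ANCHORS = ("midpoint", "start", "any_overlap")


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the sliding-window scan.

    window_size and step are in bp; alpha is the per-window p-value
    threshold (no multiple-testing correction by default, matching the
    plain p < 0.01 convention for this kind of genome track; set
    ``fdr=True`` for Benjamini-Hochberg adjusted thresholds).
    """

    window_size: int = 100_000
    step: int = 10_000
    alpha: float = 0.01
    gene_anchor: str = "midpoint"
    span_contig_junctions: bool = False
    fdr: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window_size:
            raise ValueError("require 0 < step <= window_size")
        if not 0 < self.alpha < 1:
            raise ValueError("require 0 < alpha < 1")
        if self.gene_anchor not in _ANCHORS:
            raise ValueError(f"gene_anchor must be one of {_ANCHORS}")


@dataclass(frozen=True)
class GeneAnchor:
    """A gene reduced to one point (0-based) on the concatenated axis."""

    gene_id: str
    contig_id: str
    global_pos: int  # 0-based position on the concatenated axis
    labeled: bool


@dataclass(frozen=True)
class WindowScanResult:
    """One window of the scan with its hypergeometric counts.

    k of the window's n genes are labeled, out of K labeled among N genes
    genome-wide (restricted to the layout's supercontigs); p_value is
    P(X >= k) for X ~ Hypergeometric(N, K, n).
    """

    contig_id: str
    global_start: int  # 0-based, half-open
    global_end: int
    k: int
    n: int
    K: int
    N: int
    p_value: float


@dataclass(frozen=True)
class EnrichedRegion:
    """Maximal union of overlapping/abutting significant windows."""

    contig_id: str
    global_start: int  # 0-based, half-open
    global_end: int
    n_windows: int
    min_p: float
    labeled_gene_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class OverlapReport:
    """Region-by-cluster overlaps (>= 1 shared bp on the same contig)."""

    pairs: tuple[tuple[EnrichedRegion, ClusterInterval, int], ...]
    n_regions: int
    n_clusters: int
    n_regions_overlapping: int
    n_clusters_overlapping: int

    def to_dict(self) -> dict:
        return {
            "n_regions": self.n_regions,
            "n_clusters": self.n_clusters,
            "n_regions_overlapping": self.n_regions_overlapping,
            "n_clusters_overlapping": self.n_clusters_overlapping,
            "pairs": [
                {
                    "region": [r.contig_id, r.global_start, r.global_end],
                    "cluster": c.id,
                    "overlap_bp": bp,
                }
                for r, c, bp in self.pairs
            ],
        }


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), via the survival function.

    N genes in the genome, K of them labeled; a window holds n genes, k of
    them labeled.  Computed in a numerically stable way (no explicit
    factorial ratios).
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if not (k <= n <= N and k <= K <= N):
        raise ValueError(
            f"invalid hypergeometric bounds: k={k}, n={n}, K={K}, N={N}"
        )
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


def assign_genes(
    layout: GenomeLayout,
    annotation: GeneAnnotation,
    labels: Mapping[str, str],
    params: ScanParams | None = None,
) -> list[GeneAnchor]:
    """Anchor every gene on an included contig to one point on the axis.

    Genes on excluded contigs are dropped (with a log line) and count
    toward neither N nor K.  The default anchor is the floor midpoint; with
    ``gene_anchor="start"`` the 5'-most coordinate (gene start) is used.
    ``any_overlap`` membership is resolved at scan time, but anchors are
    still midpoints for reporting.
    """
    params = params or ScanParams()
    anchors: list[GeneAnchor] = []
    n_dropped = 0
    for g in annotation:
        if not layout.includes(g.contig_id):
            n_dropped += 1
            continue
        if params.gene_anchor == "start":
            pos = g.start
        else:
            pos = g.midpoint
        gpos0 = layout.to_global(g.contig_id, pos) - 1
        anchors.append(GeneAnchor(g.id, g.contig_id, gpos0, g.id in labels))
    if n_dropped:
        logger.warning(
            "%d genes on contigs excluded from the layout were dropped", n_dropped
        )
    return anchors


def _window_starts(contig_len: int, step: int) -> np.ndarray:
    """Window start offsets 0, step, 2*step, ... below the contig length."""
    return np.arange(0, contig_len, step, dtype=np.int64)


def scan(
    layout: GenomeLayout,
    annotation: GeneAnnotation,
    labels: Mapping[str, str],
    params: ScanParams | None = None,
) -> list[WindowScanResult]:
    """Run the sliding-window scan over every supercontig of the layout.

    Windows are placed every ``step`` bp; the trailing windows of a contig
    are truncated at the contig end.  Empty windows get p = 1 so that the
    window count depends only on the layout and parameters.
    """
    params = params or ScanParams()
    anchors = assign_genes(layout, annotation, labels, params)
    N = len(anchors)
    K = sum(a.labeled for a in anchors)
    if K == 0:
        raise ValueError("no labeled genes on the layout contigs")

    positions = np.array([a.global_pos for a in anchors], dtype=np.int64)
    labeled = np.array([a.labeled for a in anchors], dtype=bool)
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    labeled = labeled[order]
    lab_cum = np.concatenate(([0], np.cumsum(labeled)))

    if params.gene_anchor == "any_overlap":
        # membership by interval overlap needs per-gene spans
        spans = _gene_spans(layout, annotation, labels)

    results: list[WindowScanResult] = []
    windows: list[tuple[str, int, int]] = []
    if params.span_contig_junctions:
        total = layout.total_length
        for ws in _window_starts(total, params.step):
            we = min(ws + params.window_size, total)
            cid, _ = layout.from_global(int(ws) + 1)
            windows.append((cid, int(ws), int(we)))
    else:
        for cid, clen, off in layout.entries:
            for ws in _window_starts(clen, params.step):
                we = min(ws + params.window_size, clen)
                windows.append((cid, off + int(ws), off + int(we)))

    ks = np.empty(len(windows), dtype=np.int64)
    ns = np.empty(len(windows), dtype=np.int64)
    if params.gene_anchor == "any_overlap":
        for i, (_, gs, ge) in enumerate(windows):
            in_win = (spans[:, 0] < ge) & (spans[:, 1] > gs)
            ns[i] = int(in_win.sum())
            ks[i] = int((in_win & spans[:, 2].astype(bool)).sum())
    else:
        gs_arr = np.array([w[1] for w in windows])
        ge_arr = np.array([w[2] for w in windows])
        lo = np.searchsorted(positions, gs_arr, side="left")
        hi = np.searchsorted(positions, ge_arr, side="left")
        ns = hi - lo
        ks = lab_cum[hi] - lab_cum[lo]

    ps = hypergeom.sf(ks - 1, N, K, ns)
    for (cid, gs, ge), k, n, p in zip(windows, ks, ns, ps):
        results.append(WindowScanResult(cid, gs, ge, int(k), int(n), K, N, float(p)))
    return results


def _gene_spans(
    layout: GenomeLayout, annotation: GeneAnnotation, labels: Mapping[str, str]
) -> np.ndarray:
    rows = []
    for g in annotation:
        if not layout.includes(g.contig_id):
            continue
        gs = layout.to_global(g.contig_id, g.start) - 1
        ge = layout.to_global(g.contig_id, g.end)  # half-open
        rows.append((gs, ge, int(g.id in labels)))
    return np.array(rows, dtype=np.int64).reshape(-1, 3)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    from scipy.stats import false_discovery_control

    return false_discovery_control(np.asarray(p_values, dtype=float), method="bh")


def call_regions(
    results: Sequence[WindowScanResult],
    alpha: float,
    anchors: Sequence[GeneAnchor] | None = None,
    fdr: bool = False,
) -> list[EnrichedRegion]:
    """Merge significant windows (p < alpha, strict) into enriched regions.

    Windows on the same contig whose intervals overlap or abut are merged
    into maximal regions; regions never span contigs.  A region's p-value
    is the minimum over its member windows.  When ``anchors`` is supplied,
    the labeled genes falling inside each region are listed.
    """
    if fdr:
        q = benjamini_hochberg([r.p_value for r in results])
        sig = [r for r, qv in zip(results, q) if qv < alpha]
    else:
        sig = [r for r in results if r.p_value < alpha]
    sig.sort(key=lambda r: (r.contig_id, r.global_start, r.global_end))
    regions: list[EnrichedRegion] = []
    cur: list[WindowScanResult] = []

    def flush() -> None:
        if not cur:
            return
        start = cur[0].global_start
        end = max(w.global_end for w in cur)
        cid = cur[0].contig_id
        members: tuple[str, ...] = ()
        if anchors is not None:
            members = tuple(
                a.gene_id
                for a in sorted(anchors, key=lambda a: a.global_pos)
                if a.labeled and start <= a.global_pos < end
            )
        regions.append(
            EnrichedRegion(
                cid, start, end, len(cur), min(w.p_value for w in cur), members
            )
        )

    for w in sig:
        if cur and w.contig_id == cur[0].contig_id and w.global_start <= max(
            x.global_end for x in cur
        ):
            cur.append(w)
        else:
            flush()
            cur = [w]
    flush()
    return regions


def overlap_with_clusters(
    regions: Sequence[EnrichedRegion],
    clusters: Sequence[ClusterInterval],
    layout: GenomeLayout,
) -> OverlapReport:
    """Intersect enriched regions with cluster intervals (>= 1 shared bp).

    Clusters on contigs excluded from the layout are skipped with a
    warning.  The summary counts are deduplicated: a region overlapping
    two clusters counts once among regions, and vice versa.
    """
    pairs: list[tuple[EnrichedRegion, ClusterInterval, int]] = []
    hit_regions: set[int] = set()
    hit_clusters: set[str] = set()
    n_clusters_on_axis = 0
    for c in clusters:
        if not layout.includes(c.contig_id):
            logger.warning(
                "cluster %s on contig %s excluded from the layout; ignored",
                c.id,
                c.contig_id,
            )
            continue
        n_clusters_on_axis += 1
        cg_start = layout.to_global(c.contig_id, c.start) - 1
        cg_end = layout.to_global(c.contig_id, c.end)  # half-open
        for ridx, r in enumerate(regions):
            if r.contig_id != c.contig_id:
                continue
            ov = min(r.global_end, cg_end) - max(r.global_start, cg_start)
            if ov >= 1:
                pairs.append((r, c, int(ov)))
                hit_regions.add(ridx)
                hit_clusters.add(c.id)
    return OverlapReport(
        pairs=tuple(pairs),
        n_regions=len(regions),
        n_clusters=n_clusters_on_axis,
        n_regions_overlapping=len(hit_regions),
        n_clusters_overlapping=len(hit_clusters),
    )


def windows_to_tsv(results: Sequence[WindowScanResult], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.contig_id, r.global_start, r.global_end, r.k, r.n, r.K, r.N, r.p_value)
            for r in results
        ],
        columns=["contig", "global_start", "global_end", "k", "n", "K", "N", "p"],
    )
    df.to_csv(path, sep="\t", index=False)


def regions_to_bed(regions: Sequence[EnrichedRegion], path: str | Path) -> None:
    """BED6 of enriched regions; score = -log10(min p), capped at 300."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            score = 300.0 if r.min_p <= 0 else min(300.0, -math.log10(r.min_p))
            fh.write(
                f"{r.contig_id}\t{r.global_start}\t{r.global_end}\tregion{i}\t{score:.2f}\t.\n"
            )
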