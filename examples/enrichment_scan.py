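"""Locate gene-category enrichment along a genome and intersect it with
secondary-metabolite clusters.

Builds a synthetic 5 Mb single-contig genome with one planted 100 kb
CAZyme-dense region, runs the 100 kb / 10 kb sliding-window hypergeometric
scan, merges significant windows into regions and overlaps them with a
cluster interval placed inside the planted region.
"""

from bgcscan import ScanParams, build_layout, call_regions, overlap_with_clusters, scan
from bgcscan.enrichment import assign_genes
from bgcscan.io import ClusterInterval
from bgcscan.simulate import (
    PlantedRegion,
    SimulationConfig,
    plant_label_enrichment,
    simulate_annotation,
    simulate_genome,
)

cfg = SimulationConfig(
    seed=11,
    contig_lengths=(5_000_000,),
    mean_bp_per_gene=3000.0,
    base_label_rate=0.05,
    planted_regions=(PlantedRegion("contig001", 2_000_001, 2_100_000, 10.0),),
)
contigs = simulate_genome(cfg, with_sequence=False)
annotation = simulate_annotation(contigs, cfg)
labels, truth = plant_label_enrichment(annotation, cfg)

layout = build_layout(contigs)  # supercontigs > 100 kb, ordered by size
params = ScanParams()  # 100 kb window, 10 kb step, alpha 0.01
results = scan(layout, annotation, labels, params)
anchors = assign_genes(layout, annotation, labels, params)
regions = call_regions(results, params.alpha, anchors)

print(f"genes: {len(annotation)}, labeled: {len(labels)}")
print(f"windows tested: {len(results)}")
print(f"significant windows (p < {params.alpha}): "
      f"{sum(r.p_value < params.alpha for r in results)}")
for r in regions:
    print(
        f"enriched region {r.contig_id}:{r.global_start}-{r.global_end} "
        f"({r.n_windows} windows, min p = {r.min_p:.2e}, "
        f"{len(r.labeled_gene_ids)} labeled genes)"
    )

clusters = [ClusterInterval("PKS_cluster_1", "contig001", 2_040_000, 2_075_000, "PKS")]
report = overlap_with_clusters(regions, clusters, layout)
print(
    f"{report.n_regions_overlapping}/{report.n_regions} enriched regions "
    f"overlap {report.n_clusters_overlapping}/{report.n_clusters} clusters"
)
# The planted region sits at 2.0-2.1 Mb: the scan should report one merged
# region covering it, and that region should overlap the PKS cluster.
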