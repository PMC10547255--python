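"""Pair KRAB/ZF domain hits into KZFP gene calls and call gene clusters.

Builds a toy domain-hit table, pairs hits by proximity and strand, then
delineates clusters of >= 3 genes whose centers lie within 250 kb of
another member, named from the short arm of each chromosome.
"""

from kzfptools.census import (
    DomainHit, call_clusters, clusters_to_frame, genes_to_frame, name_clusters,
    pair_domains,
)

krab_hits = [
    DomainHit("chr19", 100_000, 100_300, "+", "KRAB"),
    DomainHit("chr19", 300_000, 300_300, "+", "KRAB"),
    DomainHit("chr19", 520_000, 520_300, "-", "KRAB"),
    DomainHit("chr19", 2_000_000, 2_000_300, "+", "KRAB"),  # isolated
]
zf_hits = [
    DomainHit("chr19", 104_000, 106_000, "+", "ZF_ARRAY"),
    DomainHit("chr19", 303_500, 305_500, "+", "ZF_ARRAY"),
    DomainHit("chr19", 514_000, 516_000, "-", "ZF_ARRAY"),
    DomainHit("chr19", 2_004_000, 2_006_000, "+", "ZF_ARRAY"),
]

genes, unpaired = pair_domains(krab_hits, zf_hits, max_gap=50_000)
print(genes_to_frame(genes)[["gene_id", "chrom", "start", "end", "strand"]])
print(f"unpaired hits: {len(unpaired)}")

clusters = name_clusters(call_clusters(genes, min_size=3, max_center_gap=250_000))
print(clusters_to_frame(clusters))
# The three neighboring genes form cluster "Chr 19.1" (consecutive center
# gaps ~200 kb <= 250 kb); the gene at 2 Mb stays isolated, so one cluster.
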