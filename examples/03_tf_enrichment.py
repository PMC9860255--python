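"""TF occupancy of ACR classes and constituent-vs-promoter odds ratios.

An ACR counts as bound when more than half its length is covered by a
TF's ChIP peaks; enrichment is the log odds ratio per TF between
constituent ACRs of SEs and promoter ACRs.
"""

from seatlas import SimulationConfig, simulate
from seatlas.atlas import build_union_acrs, classify_acrs
from seatlas.se import cluster_nonpromoter_acrs, select_super_enhancers
from seatlas.tf import (
    TFPeakSet,
    acr_classes_with_constituents,
    enrichment_scan,
    tf_counts_per_acr,
    tf_occupancy,
)

ds = simulate(SimulationConfig(seed=3, n_chromosomes=1, chromosome_length=500_000,
                               n_genes=100, n_samples=3, n_planted_ses=8,
                               n_background_acrs=100, n_insertion_loci=1))
# use the per-sample peak BEDs directly so constituents stay individual
acrs = build_union_acrs(ds.samples)
classify_acrs(acrs, ds.genes)
ses, _ = select_super_enhancers(cluster_nonpromoter_acrs(acrs), length_threshold=1500)

occupancy = tf_occupancy(acrs, [TFPeakSet(t, iv) for t, iv in sorted(ds.tf_peaks.items())])
classes = acr_classes_with_constituents(acrs, ses)
counts = tf_counts_per_acr(occupancy)
print("mean TFs bound per ACR class:")
for cls in sorted(classes.unique()):
    print(f"  {cls:12s} {counts[classes[classes == cls].index].mean():.2f}")

scan = enrichment_scan(occupancy, classes, "constituent", "promoter")
print("\ntop TFs enriched at SE constituents vs promoter ACRs (log odds ratio):")
print(scan.head(3)[["tf_id", "a", "b", "c", "d", "log_odds_ratio"]].to_string(index=False))
# The generator plants two TFs binding 80% of constituents but only 10%
# of promoter ACRs; they should top the ranking with log-OR >> 0.
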