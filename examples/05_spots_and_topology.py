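"""Spot segmentation and sample-topology diagnostics.

Detects spot modules (connected high-score map regions) in the portrait
collection, builds the spot correlation network, and scores cluster
cohesion of the samples with the silhouette on portrait correlations.
"""

import snpsom

geno, truth = snpsom.simulate_admixed(
    K=3, G=800, S=150, n_module_snps_per_component=50, seed=4
)
geno = snpsom.polarize_to_minor(geno)
scores = snpsom.compute_snp_score(geno)
model = snpsom.train_som(scores, width=15, height=15, epochs=10, seed=4)

portraits = [snpsom.sample_portrait(model, s) for s in model.sample_ids]
over, seg = snpsom.summary_maps(portraits, quantile=0.95, model=model)
print(f"segmentation map: {len(seg.spots)} spots "
      f"({', '.join(sp.label for sp in seg.spots)})")
for sp in seg.spots:
    print(f"  spot {sp.label}: {len(sp.units)} units, {len(sp.snp_ids)} SNPs, "
          f"centroid ({sp.centroid[0]:.1f}, {sp.centroid[1]:.1f})")

if len(seg.spots) >= 2:
    profiles = snpsom.spot_profiles(seg, model)
    net = snpsom.spot_correlation_network(profiles)
    for a, b, w in net.edges:
        kind = "positive" if w > 0 else "negative"
        print(f"  edge {a}-{b}: {kind} (r={w:+.2f})")

groups = snpsom.SampleGroups.from_q(truth.q)
pcm = snpsom.pairwise_correlation_map(model, groups)
rep = snpsom.silhouette(pcm)
print(f"mean silhouette: {rep.mean:.3f}")
for label, value in rep.group_means.items():
    print(f"  group {label}: {value:.3f}")
print("-> positive silhouettes: samples sit closer to their own ancestry group")
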