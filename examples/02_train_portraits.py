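"""Train a self-organizing map and render sample portraits.

Each SNP (a profile across samples) is mapped onto a 2-D grid of meta-SNPs;
a sample's portrait is the grid of its meta-SNP values.  The supporting maps
summarize the trained map: per-unit variance, distance to neighbors (D-map)
and SNP population.  PNGs are written next to this script's working dir.
"""

import numpy as np

import snpsom
from snpsom.render import render_portrait

geno, truth = snpsom.simulate_admixed(
    K=3, G=600, S=120, n_module_snps_per_component=50, seed=1
)
geno = snpsom.polarize_to_minor(geno)
scores = snpsom.compute_snp_score(geno)
model = snpsom.train_som(scores, width=12, height=12, epochs=10, seed=1)

print(f"trained {model.width}x{model.height} map -> {model.n_units} meta-SNPs")
maps = snpsom.supporting_maps(model)
print(f"population map sums to G: {int(maps['population_map'].sum())}")
print(f"mean quantization error: {snpsom.quantization_error(model, scores):.3f}")

groups = snpsom.SampleGroups.from_q(truth.q)
for label in groups.labels:
    portrait = snpsom.mean_portrait(model, groups.members(label), subject=label)
    render_portrait(portrait).save(f"mean_portrait_{label}.png")
    peak = np.argmax(portrait.values)
    print(
        f"group {label}: mean portrait peak at unit {peak} "
        f"(row {peak // model.width}, col {peak % model.width})"
    )
print("-> each ancestry group lights up its own map region of co-mutated SNPs")
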