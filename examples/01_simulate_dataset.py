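"""Generate a synthetic tumor expression dataset with planted CNA sources.

Builds a small cohort (1200 genes, 150 samples) in which two latent sources
are copy-number driven — their weights live in one contiguous genomic region
each — and five are dispersed confounder programs. Prints the planted truth
that the rest of the pipeline will try to recover.
"""

import numpy as np

from tacna import SimulationConfig, simulate_dataset, write_dataset

cfg = SimulationConfig(
    p=1200, n=150, n_chromosomes=4, k_cna=2, k_conf=5,
    region_span=(60, 90), confounder_scale=0.3, seed=7,
)
X, ann, meta, segs, truth = simulate_dataset(cfg)

print(f"expression matrix: {X.n_genes} genes x {X.n_samples} samples (standardized)")
print(f"normal samples: {int(meta.is_normal.sum())}")
for reg in truth.planted_regions:
    span = reg.last_order_index - reg.first_order_index + 1
    print(
        f"planted CNA source {reg.component_index}: chromosome {reg.chromosome}, "
        f"genes {reg.first_order_index}..{reg.last_order_index} ({span} genes)"
    )
altered = truth.altered_gene_count()
print(f"altered genes per tumor sample: median {int(np.median(altered[~truth.is_normal]))}, "
      f"max {altered.max()}")

write_dataset("scratch_example_data", X, ann, meta, segs, truth, cfg)
print("fixture files written under scratch_example_data/")
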