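# tacna

**TACNA profiling: extract the transcriptional effects of copy-number
alterations from tumor gene-expression profiles — without paired DNA data.**

Copy-number alterations (CNAs) drive tumor progression by changing the
expression of genes in the affected genomic regions, but transcriptional
adaptation means a copy change rarely translates proportionally into an
expression change — and in bulk biopsies the CNA signal is buried under
microenvironment and other non-genetic regulation. `tacna` separates these
effects directly from an expression matrix:

1. **Consensus ICA.** The standardized gene × sample matrix X is decomposed
   into statistically independent *estimated sources* (weight vectors over
   genes) and a *mixing matrix* (per-sample activities): X ≈ Sᵀ M. The
   component count *i* is the smallest number of principal components
   capturing ≥ 85% of total variance. ICA is run 25 times with random
   initialization; sources are clustered across runs at |Pearson r| > 0.9
   (at most one member per run), averaged within clusters, and kept when their
   *credibility index* (cluster size / runs) is ≥ 50%.
2. **CNA-CES detection.** A consensus source whose extreme-|weight| genes
   (robust z > 3) concentrate in contiguous genomic regions — found by a
   sliding-window binomial scan with Bonferroni control — is called a
   **CNA-CES**: a source capturing the transcriptional footprint of a CNA.
3. **TACNA profiles.** Weights outside marked regions are zeroed and the
   masked source matrix is multiplied by the mixing matrix, yielding each
   sample's CNA-driven expression. Profiles are centered with a per-gene
   Hodges–Lehmann baseline over normal samples so zero ⇔ two copies.
4. **Derived statistics.** A rank-based 0–1 *degree of transcriptional
   adaptation* per gene (0 = expression tracks copy number, 1 = fully
   buffered), a per-sample *CNA burden*, an expression-rank *immune metric*,
   and the complement ("microenvironment") reconstruction from all non-CNA
   sources.

Everything is validated against a packaged simulator that plants CNA sources
with known regions, per-gene attenuation, and per-sample copy states, along
with dispersed confounder programs and a matching SEG-format truth.

## Worked example

```python
import warnings
from tacna import (SimulationConfig, simulate_dataset, call_cnaces,
                   mask_sources, compute_tacna, center_on_normals,
                   tacna_cna_correlation)
from tacna.ica import decompose
import numpy as np

cfg = SimulationConfig(p=1200, n=150, n_chromosomes=4, k_cna=2, k_conf=5,
                       region_span=(60, 90), confounder_scale=0.3, seed=7)
X, ann, meta, segs, truth = simulate_dataset(cfg)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    S = decompose(X, n_runs=25, master_seed=11)
calls = call_cnaces(S, ann)
T = center_on_normals(compute_tacna(mask_sources(S, calls)), meta)
r = tacna_cna_correlation(T, segs, ann)
print(np.nanmedian(r[meta.sample_ids[~meta.is_normal]]))
```

This prints (see `examples/` for the full scripts):

```
consensus sources: 7 (from 25 runs)
credibility indices: [1.   1.   1.   0.84 0.84 0.84 0.84]
CES_001: chromosome 1, genes 156..242, 87 extreme genes
CES_003: chromosome 2, genes 521..588, 62 extreme genes
median Pearson r vs SEG truth over tumors: 0.859
in-region TACNA amplitude, normals vs tumors: 0.028 vs 0.214
```

Both planted CNA sources are recovered as stable consensus sources, their
regions are marked with near-exact boundaries, tumor TACNA profiles correlate
at r ≈ 0.86 with the paired copy-number truth, and normal samples carry
essentially no CNA signal. `examples/05_adaptation_and_burden.py` goes on to
recover the planted per-gene attenuation (Spearman ≈ 0.76) and the true
per-sample alteration load (Spearman ≈ 0.66).

## Command line

The same pipeline is available as a thin CLI:

```bash
tacna simulate  --config sim.yaml --out data/          # synthetic cohort + truth
tacna run-all   --data-dir data/ --out results/        # decompose → detect → TACNA → metrics
tacna decompose --expression expr.tsv --out ica/       # individual stages
tacna detect    --sources ica/consensus --annotation genes.bed --out regions/
tacna tacna     --sources ica/consensus --annotation genes.bed \
                --metadata meta.tsv --out tacna/
```

Inputs are plain TSV/GCT expression matrices, BED4 or TSV gene annotation,
SEG copy-number segments and a TSV sample sheet; every run writes a JSON
provenance record (version, config, seeds, input checksums). A flat YAML
config can override any parameter (`n_runs`, `variance_threshold`,
`r_threshold`, `credibility_min`, detection thresholds, `master_seed`, ...).

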