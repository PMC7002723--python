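"""TACNA profiles: masking consensus sources to marked regions, reconstructing
the CNA-driven expression, centering on normal tissue, and the complement
(microenvironment) reconstruction.

The TACNA profile of a sample is the product of the region-masked CNA-CES
weight matrix with the sample's mixing coefficients: the part of its
transcriptome attributable to copy-number alterations. Centering subtracts a
per-gene Hodges-Lehmann estimate over normal samples so that zero corresponds
to a two-copy state. The complement reconstruction uses every component
*except* large CNA-CESs and captures the non-CNA (e.g., microenvironment)
signal; by construction TACNA + complement over the same component split equals
the full additive reconstruction exactly.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import RegionCall, SampleMetadata, SourceSet, TacnaProfileSet
from .errors import NothingToReconstructError, TacnaError, ValidationError

logger = logging.getLogger(__name__)

_HL_MAX_EXACT = 10_000


def _align_calls(S: SourceSet, calls: list[RegionCall]) -> list[RegionCall]:
    by_id = {c.component_id: c for c in calls}
    missing = [cid for cid in S.component_ids if cid not in by_id]
    if missing:
        raise ValidationError(f"no RegionCall for component(s) {missing[:3]}")
    return [by_id[cid] for cid in S.component_ids]


def mask_sources(S: SourceSet, calls: list[RegionCall]) -> SourceSet:
    """Drop non-CNA-CES components and zero weights outside marked regions.

    Mixing rows of surviving components are kept unchanged. Idempotent.
    """
    aligned = _align_calls(S, calls)
    keep = np.asarray([c.is_cna_ces for c in aligned], dtype=bool)
    if not keep.any():
        raise NothingToReconstructError("no CNA-CES called; nothing to reconstruct")
    masked = S.sources[keep].copy()
    for row, call in enumerate(c for c, k in zip(aligned, keep) if k):
        if call.indicator is None or len(call.indicator) != S.n_genes:
            raise ValidationError(f"component {call.component_id} lacks a gene indicator")
        masked[row, ~call.indicator] = 0.0
    return SourceSet(
        sources=masked,
        mixing=S.mixing[keep],
        credibility=S.credibility[keep],
        n_runs=S.n_runs,
        gene_ids=S.gene_ids,
        sample_ids=S.sample_ids,
        component_ids=S.component_ids[keep],
    )


def compute_tacna(S_masked: SourceSet) -> TacnaProfileSet:
    """TACNA profiles: masked CES matrix times the consensus mixing matrix."""
    values = S_masked.sources.T @ S_masked.mixing
    return TacnaProfileSet(
        values=values,
        gene_ids=S_masked.gene_ids,
        sample_ids=S_masked.sample_ids,
        centered=False,
    )


def hodges_lehmann(values, rng_seed: int = 0) -> float:
    """One-sample Hodges-Lehmann location estimate: the median of all Walsh
    averages (x_i + x_j) / 2 over i <= j (pairs including i = j).

    Exact enumeration up to 10^4 values; beyond that a seeded subsample of 10^4
    values is used.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise TacnaError("Hodges-Lehmann estimate of an empty sample")
    if v.size > _HL_MAX_EXACT:
        rng = np.random.default_rng(rng_seed)
        v = rng.choice(v, size=_HL_MAX_EXACT, replace=False)
    iu = np.triu_indices(v.size)
    walsh = (v[iu[0]] + v[iu[1]]) / 2.0
    return float(np.median(walsh))


def _hl_rows(matrix: np.ndarray) -> np.ndarray:
    """Row-wise Hodges-Lehmann estimates of a p x m matrix (vectorized)."""
    p, m = matrix.shape
    iu = np.triu_indices(m)
    walsh = (matrix[:, iu[0]] + matrix[:, iu[1]]) / 2.0
    return np.median(walsh, axis=1)


def center_on_normals(T: TacnaProfileSet, meta: SampleMetadata) -> TacnaProfileSet:
    """Subtract the per-gene Hodges-Lehmann baseline of TACNA values over normal
    samples, so that zero corresponds to exactly two copies."""
    aligned = meta.aligned_to(T.sample_ids)
    normals = aligned.is_normal
    if not normals.any():
        raise TacnaError(
            "no normal samples available for centering; skip centering explicitly "
            "if the dataset has none"
        )
    m = int(normals.sum())
    sub = T.values[:, normals]
    if m > _HL_MAX_EXACT:  # pragma: no cover - desk-scale guard
        rng = np.random.default_rng(0)
        sub = sub[:, rng.choice(m, size=_HL_MAX_EXACT, replace=False)]
    baseline = _hl_rows(sub) if m > 1 else sub[:, 0].copy()
    return TacnaProfileSet(
        values=T.values - baseline[:, None],
        gene_ids=T.gene_ids,
        sample_ids=T.sample_ids,
        centered=True,
        baseline=baseline,
    )


def complement_reconstruction(
    S: SourceSet, calls: list[RegionCall], min_region_genes: int = 50
) -> np.ndarray:
    """Reconstruction using every component except CNA-CESs whose marked regions
    hold at least ``min_region_genes`` genes (p x n).

    The excluded components' reconstruction plus this complement equals
    ``reconstruct_full(S)`` exactly.
    """
    aligned = _align_calls(S, calls)
    exclude = np.asarray(
        [c.is_cna_ces and c.n_region_genes >= min_region_genes for c in aligned], dtype=bool
    )
    keep = ~exclude
    logger.info("complement reconstruction excludes %d/%d components",
                int(exclude.sum()), len(aligned))
    if not keep.any():
        return np.zeros((S.n_genes, S.n_samples))
    return S.sources[keep].T @ S.mixing[keep]
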