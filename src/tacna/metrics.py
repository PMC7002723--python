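"""Derived statistics: degree-of-adaptation metric, inferred CNA burden,
expression-based immune metric, TACNA-vs-CNA correlations, and cross-dataset
CNA-CES comparison.

The degree of transcriptional adaptation of a gene is a rank-based 0-1
transform of its |weight| within its marked region: 0 for the highest absolute
weight (expression tracks copy number proportionally) and 1 for the lowest
(fully buffered). CNA burden aggregates, per sample, the absolute mixing
coefficients of large CNA-CESs and is min-max normalized within tumor type, as
is the immune metric (mean expression rank of a cytotoxic-lymphocyte gene
panel).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AdaptationTable,
    CopyNumberSegments,
    ExpressionMatrix,
    GeneAnnotation,
    RegionCall,
    SampleMetadata,
    SourceSet,
    TacnaProfileSet,
)
from .errors import TacnaError
from .io import segments_to_gene_vector

logger = logging.getLogger(__name__)

#: CD8+ T cell / NK cell activity panel
DEFAULT_IMMUNE_PANEL: tuple[str, ...] = ("CD2", "CD3E", "CD247", "GZMK", "NKG7", "PRF1")


def adaptation_metric(region_weights: list[tuple[str, float]]) -> list[tuple[str, float]]:
    """Rank-transform |weights| within one marked region to [0, 1].

    metric = (rank of |weight| in descending order - 1) / (m - 1), ties by
    average rank: the highest absolute weight maps to 0, the lowest to 1.
    Regions with fewer than two genes are skipped (the scale is undefined).
    """
    if len(region_weights) < 2:
        warnings.warn("region with fewer than 2 genes skipped: adaptation scale undefined")
        return []
    genes = [g for g, _ in region_weights]
    w = np.abs(np.asarray([v for _, v in region_weights], dtype=np.float64))
    ranks = stats.rankdata(-w, method="average")
    metric = (ranks - 1.0) / (len(w) - 1.0)
    return list(zip(genes, metric.tolist()))


def gene_adaptation_table(calls: list[RegionCall], S: SourceSet) -> AdaptationTable:
    """Per-gene degree of adaptation: the minimum metric over all marked regions
    containing the gene, with the component contributing that minimum and the
    number of distinct CNA-CESs containing the gene."""
    if not any(c.is_cna_ces for c in calls):
        raise TacnaError("no CNA-CES available for the adaptation table")
    comp_row = {cid: j for j, cid in enumerate(S.component_ids)}
    gene_row = {g: j for j, g in enumerate(S.gene_ids)}
    best: dict[str, tuple[float, str]] = {}
    containing: dict[str, set] = {}
    for call in calls:
        if not call.is_cna_ces:
            continue
        row = comp_row[call.component_id]
        for region in call.regions:
            pairs = [
                (g, S.sources[row, gene_row[g]])
                for g in region.member_gene_ids
                if g in gene_row
            ]
            for g, m in adaptation_metric(pairs):
                containing.setdefault(g, set()).add(call.component_id)
                if g not in best or m < best[g][0]:
                    best[g] = (m, call.component_id)
    frame = pd.DataFrame(
        {
            "gene_id": list(best.keys()),
            "metric": [best[g][0] for g in best],
            "component_id": [best[g][1] for g in best],
            "n_components_containing": [len(containing[g]) for g in best],
        }
    )
    return AdaptationTable(frame)


def _minmax_by_group(raw: pd.Series, groups: pd.Series) -> pd.Series:
    out = pd.Series(np.nan, index=raw.index, dtype=float)
    for label, idx in raw.groupby(groups).groups.items():
        vals = raw.loc[idx]
        if len(vals) < 2:
            warnings.warn(
                f"tumor type {label!r} has a single sample; its normalized score is undefined"
            )
            continue
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            warnings.warn(f"tumor type {label!r} has constant raw scores")
            continue
        out.loc[idx] = (vals - lo) / (hi - lo)
    return out


def cna_burden(
    S: SourceSet,
    calls: list[RegionCall],
    meta: SampleMetadata,
    min_region_genes: int = 50,
) -> pd.Series:
    """Per-sample CNA burden in [0, 1].

    Raw burden = sum of |mixing coefficients| over CNA-CESs with at least
    ``min_region_genes`` genes in their marked regions (absolute values because
    mixing signs depend on source orientation); then min-max normalized within
    tumor type.
    """
    by_id = {c.component_id: c for c in calls}
    qualifying = [
        j
        for j, cid in enumerate(S.component_ids)
        if cid in by_id and by_id[cid].is_cna_ces and by_id[cid].n_region_genes >= min_region_genes
    ]
    if not qualifying:
        raise TacnaError(f"no CNA-CES with >= {min_region_genes} region genes")
    raw = pd.Series(
        np.abs(S.mixing[qualifying]).sum(axis=0), index=S.sample_ids, name="cna_burden"
    )
    aligned = meta.aligned_to(S.sample_ids)
    groups = pd.Series(aligned.tumor_type, index=S.sample_ids)
    return _minmax_by_group(raw, groups)


def immune_metric(
    X: ExpressionMatrix,
    panel: tuple[str, ...] = DEFAULT_IMMUNE_PANEL,
    meta: SampleMetadata | None = None,
) -> pd.Series:
    """Per-sample immune activity score in [0, 1].

    For each sample, every panel gene's expression is ranked (ascending, average
    ties) among all genes; the sample's raw score is the mean panel rank, then
    min-max normalized within tumor type (globally when no metadata is given).
    """
    present = [g for g in panel if g in set(X.gene_ids)]
    if not present:
        raise TacnaError("no immune panel gene present in the expression matrix")
    missing = [g for g in panel if g not in set(X.gene_ids)]
    if missing:
        warnings.warn(f"immune panel genes absent from the matrix: {missing}")
    ranks = stats.rankdata(X.values, axis=0, method="average")
    gene_row = {g: j for j, g in enumerate(X.gene_ids)}
    rows = [gene_row[g] for g in present]
    raw = pd.Series(ranks[rows].mean(axis=0), index=X.sample_ids, name="immune_metric")
    if meta is None:
        groups = pd.Series("all", index=raw.index)
    else:
        groups = pd.Series(meta.aligned_to(X.sample_ids).tumor_type, index=raw.index)
    return _minmax_by_group(raw, groups)


def tacna_cna_correlation(
    T: TacnaProfileSet,
    segs: CopyNumberSegments,
    ann: GeneAnnotation,
    gene_mask: np.ndarray | None = None,
    all_genes: bool = False,
) -> pd.Series:
    """Per-sample Pearson r between the TACNA column and the SEG-derived gene
    vector, over genes inside at least one marked region (default) or all
    annotated genes (``all_genes=True``).

    Samples whose SEG-derived vector has zero variance (e.g., CNA-neutral
    normals) are reported as NaN.
    """
    shared = [s for s in T.sample_ids if s in set(segs.sample_ids)]
    if not shared:
        raise TacnaError("no shared samples between TACNA profiles and segments")
    if gene_mask is None:
        # rows identically zero are genes outside every marked region
        gene_mask = np.any(T.values != 0, axis=1) | (T.baseline != 0)
    if all_genes:
        gene_mask = np.ones(len(T.gene_ids), dtype=bool)
    ann_set = set(ann.gene_ids)
    gene_mask = gene_mask & np.asarray([g in ann_set for g in T.gene_ids], dtype=bool)
    if gene_mask.sum() < 3:
        raise TacnaError("fewer than 3 usable genes for correlation")
    genes = T.gene_ids[gene_mask]
    sub_ann = ann.subset(genes)
    # sub_ann preserves the order of `genes`
    col = {s: j for j, s in enumerate(T.sample_ids)}
    out = {}
    for s in shared:
        seg_vec = segments_to_gene_vector(segs, sub_ann, s)
        t_vec = T.values[gene_mask, col[s]]
        if np.ptp(seg_vec) == 0 or np.ptp(t_vec) == 0:
            out[s] = np.nan
            continue
        out[s] = float(stats.pearsonr(t_vec, seg_vec)[0])
    series = pd.Series(out, name="tacna_cna_r")
    n_flat = int(series.isna().sum())
    if n_flat:
        logger.info("%d sample(s) had a zero-variance CNA vector (reported NaN)", n_flat)
    return series


def compare_cnaces(
    S_a: SourceSet,
    call_a: RegionCall,
    S_b: SourceSet,
    call_b: RegionCall,
    shared_genes=None,
    min_shared: int = 10,
) -> tuple[float, float]:
    """Spearman rho (and p-value) between two CNA-CESs from different datasets,
    over shared genes in the union of their marked regions, on absolute weights.

    Returns (nan, nan) with a warning when fewer than ``min_shared`` genes are
    available.
    """
    if not (call_a.is_cna_ces and call_b.is_cna_ces):
        raise TacnaError("both components must be CNA-CESs")
    if shared_genes is None:
        shared_genes = set(S_a.gene_ids) & set(S_b.gene_ids)
    union = (call_a.region_gene_ids | call_b.region_gene_ids) & set(shared_genes)
    if len(union) < min_shared:
        warnings.warn(
            f"only {len(union)} shared genes in the union of marked regions "
            f"(< {min_shared}); comparison not reported"
        )
        return float("nan"), float("nan")
    row_a = {g: j for j, g in enumerate(S_a.gene_ids)}
    row_b = {g: j for j, g in enumerate(S_b.gene_ids)}
    ka = int(np.flatnonzero(S_a.component_ids == call_a.component_id)[0])
    kb = int(np.flatnonzero(S_b.component_ids == call_b.component_id)[0])
    genes = sorted(union)
    wa = np.abs([S_a.sources[ka, row_a[g]] for g in genes])
    wb = np.abs([S_b.sources[kb, row_b[g]] for g in genes])
    rho, p = stats.spearmanr(wa, wb)
    return float(rho), float(p)
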