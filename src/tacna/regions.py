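"""Detection of contiguous genomic regions enriched for extreme-valued weights.

A consensus source is called a CNA-CES when its extreme-|weight| genes
concentrate in one or more contiguous genomic regions. Extremeness is a robust
z-score against the genome-wide weight distribution (median / 1.4826*MAD);
contiguity is assessed by sliding a fixed-size window over genome-ordered genes
within each chromosome and testing the window's extreme-gene count against a
binomial null whose success probability is the genome-wide extreme fraction,
Bonferroni-corrected over all windows tested for that source. Significant
windows that overlap or lie within ``merge_gap`` genes are merged, trimmed to
their outermost extreme genes, extended over runs of adjacent extreme genes
(regions are maximal), and dropped when they contain fewer than
``min_extreme_in_region`` extreme genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .datatypes import GeneAnnotation, Region, RegionCall, SourceSet, chromosome_sort_key
from .errors import TacnaError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DetectionParams:
    """Free parameters of the region detector.

    z_threshold: robust z-score above which a gene's |weight| is extreme.
    window_size: sliding-window width in genes.
    alpha: family-wise significance level for the window scan (Bonferroni over
        the windows tested within one source).
    min_extreme_in_region: minimum extreme genes a surviving region must hold.
    merge_gap: maximum gene gap between significant windows that still merges.
    """

    z_threshold: float = 3.0
    window_size: int = 50
    alpha: float = 0.01
    min_extreme_in_region: int = 10
    merge_gap: int = 10

    def __post_init__(self):
        if self.z_threshold <= 0 or self.window_size <= 0 or self.merge_gap < 0:
            raise ValidationError("detection parameters must be positive")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.min_extreme_in_region <= 0:
            raise ValidationError("min_extreme_in_region must be positive")


def flag_extreme(weights: np.ndarray, params: DetectionParams | None = None) -> np.ndarray:
    """Boolean mask of genes whose |weight - median| exceeds ``z_threshold``
    robust SDs (1.4826 * MAD); falls back to mean/SD when the MAD is zero, and
    flags nothing for constant weights."""
    params = params or DetectionParams()
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim != 1 or len(w) < 2:
        raise TacnaError("flag_extreme expects a 1-D vector of length >= 2")
    med = np.median(w)
    mad = np.median(np.abs(w - med))
    if mad > 0:
        z = np.abs(w - med) / (1.4826 * mad)
    else:
        sd = w.std(ddof=1)
        if sd == 0:
            return np.zeros(len(w), dtype=bool)
        z = np.abs(w - w.mean()) / sd
    return z > params.z_threshold


def _chromosome_blocks(ann: GeneAnnotation):
    """Yield (chromosome, array of positions in genome order) blocks in declared
    chromosome order. Positions index the genome-ordered arrays."""
    order = np.argsort(ann.order_index)
    chrom = ann.chromosome[order]
    labels = sorted(set(chrom), key=chromosome_sort_key)
    for lab in labels:
        yield lab, np.flatnonzero(chrom == lab)


def detect_regions(
    weights: np.ndarray,
    annotation: GeneAnnotation,
    params: DetectionParams | None = None,
    component_id: str = "CES",
) -> RegionCall:
    """Scan one source's weights for contiguous extreme-valued regions.

    ``weights`` must be aligned to ``annotation.gene_ids`` (same order); the
    returned indicator is in that same order.
    """
    params = params or DetectionParams()
    w = np.asarray(weights, dtype=np.float64)
    if len(w) != annotation.n_genes:
        raise TacnaError("weights and annotation have different lengths")
    flags_input_order = flag_extreme(w, params)
    order = np.argsort(annotation.order_index)
    flags = flags_input_order[order]  # genome order
    gene_ids_sorted = annotation.gene_ids[order]
    q = flags.mean()

    regions: list[Region] = []
    if q > 0:
        blocks = list(_chromosome_blocks(annotation))
        wsz = params.window_size
        n_windows = sum(max(len(pos) - wsz + 1, 1) for _, pos in blocks)
        alpha_adj = params.alpha / n_windows
        for lab, pos in blocks:
            f = flags[pos]
            L = len(pos)
            if L >= wsz:
                csum = np.concatenate([[0], np.cumsum(f)])
                counts = csum[wsz:] - csum[:-wsz]
                lengths = np.full(len(counts), wsz)
                starts = np.arange(len(counts))
            else:
                counts = np.asarray([int(f.sum())])
                lengths = np.asarray([L])
                starts = np.asarray([0])
            crit = stats.binom.ppf(1 - alpha_adj, lengths, q)
            sig = counts > crit
            if not sig.any():
                continue
            # merge significant windows within merge_gap, as [start, end) spans
            spans = [(int(s), int(s + l)) for s, l in zip(starts[sig], lengths[sig])]
            merged = [list(spans[0])]
            for s, e in spans[1:]:
                if s - merged[-1][1] <= params.merge_gap:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            # within each merged span, group extreme genes at gaps <= merge_gap;
            # each group is trimmed to its outermost extremes and extended over
            # runs of adjacent extremes (regions are maximal). Sparse stray
            # flags in the window flanks form small groups that fall below
            # min_extreme_in_region and are dropped.
            trimmed = []
            for s, e in merged:
                idx = np.flatnonzero(f[s:e]) + s
                if len(idx) == 0:
                    continue
                breaks = np.flatnonzero(np.diff(idx) > params.merge_gap)
                for grp in np.split(idx, breaks + 1):
                    lo, hi = int(grp[0]), int(grp[-1])
                    while lo > 0 and f[lo - 1]:
                        lo -= 1
                    while hi < L - 1 and f[hi + 1]:
                        hi += 1
                    trimmed.append([lo, hi])
            # extension can make neighbours touch; re-merge overlaps
            final = []
            for lo, hi in trimmed:
                if final and lo <= final[-1][1] + 1 and f[final[-1][1]] and f[lo]:
                    final[-1][1] = max(final[-1][1], hi)
                elif final and lo <= final[-1][1]:
                    final[-1][1] = max(final[-1][1], hi)
                else:
                    final.append([lo, hi])
            for lo, hi in final:
                n_extreme = int(f[lo : hi + 1].sum())
                if n_extreme < params.min_extreme_in_region:
                    continue
                first = int(pos[lo])
                last = int(pos[hi])
                members = tuple(gene_ids_sorted[first : last + 1])
                regions.append(Region(str(lab), first, last, members, n_extreme))

    indicator_sorted = np.zeros(annotation.n_genes, dtype=bool)
    for reg in regions:
        indicator_sorted[reg.first_order_index : reg.last_order_index + 1] = True
    indicator = np.zeros(annotation.n_genes, dtype=bool)
    indicator[order] = indicator_sorted
    return RegionCall(
        component_id=component_id,
        regions=regions,
        is_cna_ces=bool(regions),
        indicator=indicator,
    )


def call_cnaces(
    S: SourceSet,
    annotation: GeneAnnotation,
    params: DetectionParams | None = None,
) -> list[RegionCall]:
    """One RegionCall per consensus source.

    Genes absent from the annotation are excluded from detection (their
    indicator entries stay False); the returned indicators are aligned to
    ``S.gene_ids``.
    """
    params = params or DetectionParams()
    ann_genes = set(annotation.gene_ids)
    covered = np.asarray([g in ann_genes for g in S.gene_ids], dtype=bool)
    if not covered.all():
        logger.info(
            "%d/%d genes lack annotation and are excluded from region detection",
            int((~covered).sum()), len(covered),
        )
    sub_ann = annotation.subset(S.gene_ids[covered])
    # sub_ann rows follow S gene order restricted to covered genes
    calls: list[RegionCall] = []
    for k in range(S.n_components):
        call = detect_regions(
            S.sources[k][covered], sub_ann, params, component_id=str(S.component_ids[k])
        )
        indicator = np.zeros(S.n_genes, dtype=bool)
        indicator[covered] = call.indicator
        calls.append(
            RegionCall(call.component_id, call.regions, call.is_cna_ces, indicator)
        )
    n_ces = sum(c.is_cna_ces for c in calls)
    in_any = np.zeros(S.n_genes, dtype=bool)
    for c in calls:
        in_any |= c.indicator
    if S.n_components:
        logger.info(
            "called %d/%d CNA-CESs (%.0f%%); %.0f%% of genes inside >=1 marked region",
            n_ces, S.n_components, 100 * n_ces / S.n_components, 100 * in_any.mean(),
        )
    return calls


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def regions_to_bed(calls: list[RegionCall], annotation: GeneAnnotation, path: str | Path) -> None:
    """One BED line per marked region: name = component id, score = extreme-gene
    count."""
    order = np.argsort(annotation.order_index)
    start_of = annotation.start[order]
    end_of = annotation.end[order]
    chrom_of = annotation.chromosome[order]
    with open(path, "w") as fh:
        for call in calls:
            for reg in call.regions:
                fh.write(
                    f"{chrom_of[reg.first_order_index]}\t{start_of[reg.first_order_index]}"
                    f"\t{end_of[reg.last_order_index]}\t{call.component_id}\t{reg.n_extreme_genes}\n"
                )


def calls_to_table(calls: list[RegionCall]):
    """Per-component summary as a DataFrame."""
    import pandas as pd

    rows = []
    for call in calls:
        rows.append(
            {
                "component_id": call.component_id,
                "is_cna_ces": call.is_cna_ces,
                "n_regions": len(call.regions),
                "n_region_genes": call.n_region_genes,
                "n_extreme_genes": sum(r.n_extreme_genes for r in call.regions),
            }
        )
    return pd.DataFrame(rows)


def indicator_to_bedgraph(
    call: RegionCall, annotation: GeneAnnotation, path: str | Path
) -> None:
    """Extreme-valued region indicator as a bedGraph track (1 inside regions)."""
    order = np.argsort(annotation.order_index)
    ind = call.indicator[order] if call.indicator is not None else np.zeros(annotation.n_genes, bool)
    chrom_of = annotation.chromosome[order]
    start_of = annotation.start[order]
    end_of = annotation.end[order]
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{call.component_id} indicator"\n')
        for j in range(annotation.n_genes):
            fh.write(f"{chrom_of[j]}\t{start_of[j]}\t{end_of[j]}\t{int(ind[j])}\n")
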