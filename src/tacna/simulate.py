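"""Synthetic tumor expression data with planted, genomically localized CNA
sources and dispersed confounder sources, plus full ground truth.

The generative model mirrors the latent-factor view of bulk expression: the
observed gene x sample matrix is ``true_sources.T @ true_mixing + noise``,
standardized per gene. CNA sources have nonzero weights only inside one planted
contiguous genomic region, with per-gene weights proportional to ``1 - a`` where
``a`` in [0, 1] is the degree of transcriptional adaptation (1 = fully buffered).
Their mixing coefficients are discrete copy states (loss/neutral/gain/
amplification) so that expression correlates blockwise with the SEG truth.
Confounder sources are genomically dispersed: diffuse programs with Laplace
weights over all genes, plus one proliferation-like program hitting a random 10%
of genes with large weights, which stresses the specificity of region detection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .datatypes import (
    CopyNumberSegments,
    ExpressionMatrix,
    GeneAnnotation,
    SampleMetadata,
)
from .errors import TacnaError, ValidationError
from . import io as tio

import pandas as pd

COPY_STATES = (-1, 0, 1, 2)  # change in copy number relative to diploid


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    Defaults are the packaged reference conditions: 4000 genes on 8 chromosomes,
    300 samples (10% normal tissue), 6 planted CNA sources spanning 60-150 genes
    each, 6 confounders (5 diffuse + 1 proliferation-like), gene-level noise SD
    0.3 on the pre-standardization scale.
    """

    p: int = 4000
    n: int = 300
    n_chromosomes: int = 8
    k_cna: int = 6
    k_conf: int = 6
    region_span: tuple[int, int] = (60, 150)
    attenuation: tuple[float, float] = (0.0, 0.9)
    coefficient_scale: float = 1.0
    noise_sd: float = 0.3
    fraction_normal: float = 0.1
    confounder_scale: float = 0.25
    proliferation_scale: float = 1.0
    proliferation_fraction: float = 0.10
    copy_state_probs: tuple[float, float, float, float] = (0.15, 0.55, 0.20, 0.10)
    tumor_type_label: str = "simulated_tumor"
    seed: int = 7
    structure_seed: int | None = None  # reuse across seeds to replay the same planted genome

    def __post_init__(self):
        if self.p < self.n_chromosomes:
            raise ValidationError("p must be at least n_chromosomes")
        if self.k_cna + self.k_conf >= min(self.p, self.n):
            raise ValidationError("k_cna + k_conf must be < min(p, n)")
        lo, hi = self.region_span
        if not (0 < lo <= hi):
            raise ValidationError("invalid region_span")
        a_lo, a_hi = self.attenuation
        if not (0 <= a_lo <= a_hi <= 1):
            raise ValidationError("attenuation bounds must satisfy 0 <= lo <= hi <= 1")
        if not math.isclose(sum(self.copy_state_probs), 1.0, abs_tol=1e-9):
            raise ValidationError("copy_state_probs must sum to 1")
        if not (0 <= self.fraction_normal < 1):
            raise ValidationError("fraction_normal must be in [0, 1)")


@dataclass(frozen=True)
class PlantedRegion:
    component_index: int  # row in true_sources
    chromosome: str
    first_order_index: int
    last_order_index: int  # inclusive


@dataclass
class SimulationTruth:
    """Ground truth: latent sources/mixing on the raw scale, planted regions,
    per-gene attenuation, per-(source, sample) copy changes, and the per-gene
    scale factors applied by the final standardization."""

    true_sources: np.ndarray          # k x p, raw scale
    true_mixing: np.ndarray           # k x n
    planted_regions: list = field(default_factory=list)
    attenuation: np.ndarray = None    # length p; 0 outside planted regions
    in_region: np.ndarray = None      # length p bool
    copy_changes: np.ndarray = None   # k_cna x n integers in {-1,0,1,2}
    is_normal: np.ndarray = None
    gene_mean: np.ndarray = None      # per-gene mean removed by standardization
    gene_scale: np.ndarray = None     # per-gene SD divided out by standardization
    kept_genes: np.ndarray = None     # bool, genes surviving standardization

    @property
    def k_cna(self) -> int:
        return self.copy_changes.shape[0]

    def standardized_sources(self) -> np.ndarray:
        """Latent sources expressed in the standardized coordinate system
        (each gene's weight divided by that gene's pre-standardization SD),
        restricted to genes that survived standardization."""
        keep = self.kept_genes
        return self.true_sources[:, keep] / self.gene_scale[keep]

    def gene_copy_changes(self) -> np.ndarray:
        """Per-gene, per-sample integer copy change (p x n), from the planted
        regions and the per-source copy states."""
        p = self.true_sources.shape[1]
        n = self.true_mixing.shape[1]
        out = np.zeros((p, n), dtype=np.int8)
        for reg in self.planted_regions:
            rows = self._region_gene_mask(reg)
            out[rows, :] += self.copy_changes[reg.component_index][None, :]
        return out

    def altered_gene_count(self) -> np.ndarray:
        """Per-sample number of genes with a nonzero copy change."""
        return (self.gene_copy_changes() != 0).sum(axis=0)

    def _region_gene_mask(self, reg: PlantedRegion) -> np.ndarray:
        # planted regions are stored in order_index space; the simulated genome
        # is built in genome order, so order_index == row index
        mask = np.zeros(self.true_sources.shape[1], dtype=bool)
        mask[reg.first_order_index : reg.last_order_index + 1] = True
        return mask


def simulate_genome(cfg: SimulationConfig) -> GeneAnnotation:
    """Evenly spaced, non-overlapping 1-kb gene intervals, ``p`` genes split over
    ``n_chromosomes`` (remainder on the last chromosome)."""
    if cfg.p < cfg.n_chromosomes:
        raise TacnaError("p must be >= n_chromosomes")
    base = cfg.p // cfg.n_chromosomes
    counts = [base] * cfg.n_chromosomes
    counts[-1] += cfg.p - base * cfg.n_chromosomes
    ids, chroms, starts, ends = [], [], [], []
    g = 0
    for c, count in enumerate(counts, start=1):
        for j in range(count):
            ids.append(f"g{g + 1:05d}")
            chroms.append(str(c))
            starts.append(2000 * j)
            ends.append(2000 * j + 1000)
            g += 1
    return GeneAnnotation.from_intervals(ids, chroms, starts, ends)


def _place_regions(cfg: SimulationConfig, ann: GeneAnnotation, rng: np.random.Generator):
    """Assign each CNA source a contiguous block of genes, round-robin over
    chromosomes, sampling spans from ``region_span``. Raises if spans cannot be
    placed without overlap."""
    order = np.argsort(ann.order_index)
    chrom_of = ann.chromosome[order]
    chrom_labels = list(dict.fromkeys(chrom_of))
    chrom_ranges = {}
    for lab in chrom_labels:
        pos = np.flatnonzero(chrom_of == lab)
        chrom_ranges[lab] = (int(pos[0]), int(pos[-1]))
    per_chrom: dict[str, list[int]] = {lab: [] for lab in chrom_labels}
    for k in range(cfg.k_cna):
        per_chrom[chrom_labels[k % len(chrom_labels)]].append(k)
    regions = [None] * cfg.k_cna
    lo, hi = cfg.region_span
    for lab, ks in per_chrom.items():
        if not ks:
            continue
        first, last = chrom_ranges[lab]
        length = last - first + 1
        block = length // len(ks)
        for slot, k in enumerate(ks):
            span = int(rng.integers(lo, hi + 1))
            block_start = first + slot * block
            free = block - span
            if free < 1:
                raise TacnaError(
                    f"planted region of span {span} does not fit on chromosome {lab} "
                    f"(block of {block} genes); regions would overlap"
                )
            offset = int(rng.integers(0, free))
            s = block_start + offset
            regions[k] = PlantedRegion(k, lab, s, s + span - 1)
    return regions


def simulate_dataset(cfg: SimulationConfig):
    """Generate ``(ExpressionMatrix, GeneAnnotation, SampleMetadata,
    CopyNumberSegments, SimulationTruth)`` under ``cfg``.

    Deterministic: identical config (including seeds) gives bit-identical output.
    """
    ann = simulate_genome(cfg)
    struct_seed = cfg.seed if cfg.structure_seed is None else cfg.structure_seed
    rng_struct = np.random.default_rng(np.random.SeedSequence([struct_seed, 101]))
    rng_sample = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))

    p, n, k = cfg.p, cfg.n, cfg.k_cna + cfg.k_conf
    regions = _place_regions(cfg, ann, rng_struct)

    # --- sources ---------------------------------------------------------
    sources = np.zeros((k, p))
    attenuation = np.zeros(p)
    in_region = np.zeros(p, dtype=bool)
    a_lo, a_hi = cfg.attenuation
    for reg in regions:
        rows = slice(reg.first_order_index, reg.last_order_index + 1)
        m = reg.last_order_index - reg.first_order_index + 1
        a = rng_struct.uniform(a_lo, a_hi, size=m)
        attenuation[rows] = a
        in_region[rows] = True
        sources[reg.component_index, rows] = 1.0 - a
    for j in range(cfg.k_conf):
        row = cfg.k_cna + j
        if j == cfg.k_conf - 1 and cfg.proliferation_fraction > 0:
            # proliferation-like program: sparse, large, genome-dispersed
            n_hit = max(1, int(round(cfg.proliferation_fraction * p)))
            hit = rng_sample.choice(p, size=n_hit, replace=False)
            sources[row, hit] = rng_sample.normal(0.0, cfg.proliferation_scale, size=n_hit)
        else:
            sources[row] = rng_sample.laplace(0.0, cfg.confounder_scale, size=p)

    # --- mixing ----------------------------------------------------------
    n_normal = int(round(cfg.fraction_normal * n))
    is_normal = np.zeros(n, dtype=bool)
    if n_normal:
        is_normal[-n_normal:] = True
    tumor = ~is_normal
    copy_changes = np.zeros((cfg.k_cna, n), dtype=np.int64)
    copy_changes[:, tumor] = rng_sample.choice(
        COPY_STATES, size=(cfg.k_cna, int(tumor.sum())), p=cfg.copy_state_probs
    )
    mixing = np.zeros((k, n))
    mixing[: cfg.k_cna] = copy_changes * cfg.coefficient_scale
    mixing[cfg.k_cna :] = rng_sample.normal(0.0, 1.0, size=(cfg.k_conf, n))

    # --- expression ------------------------------------------------------
    raw = sources.T @ mixing
    if cfg.noise_sd > 0:
        raw = raw + rng_sample.normal(0.0, cfg.noise_sd, size=(p, n))
    sample_ids = np.asarray(
        [f"{'N' if is_normal[j] else 'T'}{j + 1:04d}" for j in range(n)], dtype=object
    )
    X_raw = ExpressionMatrix(raw, ann.gene_ids.copy(), sample_ids, standardized=False)
    gene_mean = raw.mean(axis=1)
    gene_sd = raw.std(axis=1, ddof=1)
    kept = gene_sd > 0
    X = ExpressionMatrix(
        (raw[kept] - gene_mean[kept, None]) / gene_sd[kept, None],
        ann.gene_ids[kept],
        sample_ids,
        standardized=True,
    )

    # --- metadata, SEG truth --------------------------------------------
    tumor_type = np.where(is_normal, "normal", cfg.tumor_type_label).astype(object)
    meta = SampleMetadata(sample_ids, tumor_type, is_normal)
    segs = _segments_from_truth(cfg, ann, regions, copy_changes, sample_ids)

    truth = SimulationTruth(
        true_sources=sources,
        true_mixing=mixing,
        planted_regions=regions,
        attenuation=attenuation,
        in_region=in_region,
        copy_changes=copy_changes,
        is_normal=is_normal,
        gene_mean=gene_mean,
        gene_scale=gene_sd,
        kept_genes=kept,
    )
    return X, ann, meta, segs, truth


def _segments_from_truth(cfg, ann, regions, copy_changes, sample_ids) -> CopyNumberSegments:
    """Tile each chromosome per sample: background segments at seg_mean 0 and one
    segment per planted region with seg_mean = log2((2 + c) / 2)."""
    order = np.argsort(ann.order_index)
    chrom_of = ann.chromosome[order]
    start_of = ann.start[order]
    end_of = ann.end[order]
    per_chrom: dict[str, list[PlantedRegion]] = {}
    for reg in regions:
        per_chrom.setdefault(reg.chromosome, []).append(reg)
    records = []
    chrom_labels = list(dict.fromkeys(chrom_of))
    for s_idx, sid in enumerate(sample_ids):
        for lab in chrom_labels:
            pos = np.flatnonzero(chrom_of == lab)
            chrom_lo = int(start_of[pos[0]])
            chrom_hi = int(end_of[pos[-1]])
            cuts = []
            for reg in sorted(per_chrom.get(lab, []), key=lambda r: r.first_order_index):
                c = int(copy_changes[reg.component_index, s_idx])
                r_lo = int(start_of[reg.first_order_index])
                r_hi = int(end_of[reg.last_order_index])
                cuts.append((r_lo, r_hi, math.log2((2 + c) / 2)))
            cursor = chrom_lo
            for r_lo, r_hi, val in cuts:
                if r_lo > cursor:
                    records.append((sid, lab, cursor, r_lo, 0.0))
                records.append((sid, lab, r_lo, r_hi, val))
                cursor = r_hi
            if cursor < chrom_hi:
                records.append((sid, lab, cursor, chrom_hi, 0.0))
    df = pd.DataFrame(records, columns=["sample_id", "chromosome", "start", "end", "seg_mean"])
    return CopyNumberSegments(df)


def simulate_laplacian_dataset(p: int, n: int, k: int, seed: int, scale: float = 1.0):
    """Noiseless mixtures of ``k`` Laplacian sources: the identifiable ICA test
    bed. Returns ``(ExpressionMatrix, true_sources k x p, true_mixing k x n)``.

    Gene rows are centered but deliberately *not* rescaled to unit variance: in
    a noiseless rank-k matrix every gene's variance comes from the k sources
    alone, so per-gene rescaling would divide each loading vector by its own
    norm, collapsing the loadings onto the unit sphere and destroying the
    independent-Laplace structure the test bed exists to provide.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    sources = rng.laplace(0.0, scale, size=(k, p))
    mixing = rng.normal(0.0, 1.0, size=(k, n))
    raw = sources.T @ mixing
    values = raw - raw.mean(axis=1, keepdims=True)
    gene_ids = np.asarray([f"g{j + 1:05d}" for j in range(p)], dtype=object)
    sample_ids = np.asarray([f"s{j + 1:04d}" for j in range(n)], dtype=object)
    X = ExpressionMatrix(values, gene_ids, sample_ids, standardized=False)
    return X, sources, mixing


def write_dataset(directory: str | Path, X, ann, meta, segs, truth, cfg: SimulationConfig) -> None:
    """Write the full fixture set (TSV matrix, BED annotation, SEG, metadata TSV,
    truth JSON) under one directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tio.write_expression(X, directory / "expression.tsv")
    tio.write_annotation(ann, directory / "genes.bed")
    tio.write_metadata(meta, directory / "metadata.tsv")
    tio.write_segments(segs, directory / "copy_number.seg")
    payload = {
        "config": {**asdict(cfg), "region_span": list(cfg.region_span),
                   "attenuation": list(cfg.attenuation),
                   "copy_state_probs": list(cfg.copy_state_probs)},
        "planted_regions": [
            {
                "component_index": r.component_index,
                "chromosome": r.chromosome,
                "first_order_index": r.first_order_index,
                "last_order_index": r.last_order_index,
            }
            for r in truth.planted_regions
        ],
        "attenuation": truth.attenuation.tolist(),
        "copy_changes": truth.copy_changes.tolist(),
        "is_normal": truth.is_normal.tolist(),
    }
    (directory / "truth.json").write_text(json.dumps(payload))
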