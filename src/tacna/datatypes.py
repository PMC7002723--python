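"""Domain containers for TACNA profiling.

The central objects are a gene x sample :class:`ExpressionMatrix`, a genome-ordered
:class:`GeneAnnotation`, the :class:`SourceSet` produced by consensus independent
component analysis (components x genes weights plus components x samples mixing
coefficients), per-component :class:`RegionCall` objects marking contiguous genomic
regions of extreme weights, and the derived :class:`TacnaProfileSet` /
:class:`AdaptationTable` outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_CHROMOSOME_ORDER: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X", "Y")


def normalize_chromosome(label: str) -> str:
    """Strip a leading ``chr`` prefix; ``chr1``/``Chr1``/``1`` all map to ``1``."""
    return re.sub(r"^chr", "", str(label), flags=re.IGNORECASE)


def chromosome_sort_key(label: str, order: tuple[str, ...] = DEFAULT_CHROMOSOME_ORDER):
    """Sort key placing declared chromosomes first (1..22, X, Y by default),
    anything else after them in lexicographic order."""
    name = normalize_chromosome(label)
    try:
        return (0, order.index(name), "")
    except ValueError:
        return (1, 0, name)


@dataclass
class GeneAnnotation:
    """Genomic intervals for genes, 0-based half-open, with a genome-order rank.

    ``order_index`` is a permutation of ``0..p-1`` obtained by sorting on
    (declared chromosome order, interval midpoint).
    """

    gene_ids: np.ndarray
    chromosome: np.ndarray
    start: np.ndarray
    end: np.ndarray
    order_index: np.ndarray

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.order_index = np.asarray(self.order_index, dtype=np.int64)
        p = len(self.gene_ids)
        if not (len(self.chromosome) == len(self.start) == len(self.end) == len(self.order_index) == p):
            raise ValidationError("annotation fields have mismatched lengths")
        if np.any(self.end <= self.start):
            bad = self.gene_ids[self.end <= self.start][0]
            raise ValidationError(f"gene {bad!r} has end <= start")
        if np.any(self.start < 0):
            raise ValidationError("negative start coordinate")
        if len(set(self.gene_ids)) != p:
            raise ValidationError("duplicate gene_id in annotation")
        if sorted(self.order_index) != list(range(p)):
            raise ValidationError("order_index is not a permutation of 0..p-1")

    @classmethod
    def from_intervals(
        cls,
        gene_ids,
        chromosome,
        start,
        end,
        chrom_order: tuple[str, ...] = DEFAULT_CHROMOSOME_ORDER,
    ) -> "GeneAnnotation":
        """Build an annotation, assigning ``order_index`` by chromosome order then
        interval midpoint."""
        gene_ids = np.asarray(gene_ids, dtype=object)
        chromosome = np.asarray(chromosome, dtype=object)
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        mid = (start + end) / 2.0
        keys = sorted(
            range(len(gene_ids)),
            key=lambda j: (chromosome_sort_key(chromosome[j], chrom_order), mid[j]),
        )
        order = np.empty(len(gene_ids), dtype=np.int64)
        order[np.asarray(keys, dtype=np.int64)] = np.arange(len(gene_ids))
        return cls(gene_ids, chromosome, start, end, order)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def midpoint(self) -> np.ndarray:
        return (self.start + self.end) / 2.0

    def index_of(self, gene_ids) -> np.ndarray:
        """Positions of ``gene_ids`` in this annotation (raises on missing)."""
        lookup = {g: j for j, g in enumerate(self.gene_ids)}
        try:
            return np.asarray([lookup[g] for g in gene_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(f"gene {exc.args[0]!r} not in annotation") from exc

    def subset(self, gene_ids) -> "GeneAnnotation":
        """Restrict to ``gene_ids`` (those present), keeping relative genome order.

        ``order_index`` is re-ranked to 0..m-1 but preserves the original ordering.
        """
        present = [g for g in gene_ids if g in set(self.gene_ids)]
        idx = self.index_of(present)
        order = self.order_index[idx]
        rank = np.empty(len(order), dtype=np.int64)
        rank[np.argsort(order)] = np.arange(len(order))
        return GeneAnnotation(
            self.gene_ids[idx], self.chromosome[idx], self.start[idx], self.end[idx], rank
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "chromosome": self.chromosome,
                "start": self.start,
                "end": self.end,
                "order_index": self.order_index,
            }
        )


@dataclass
class ExpressionMatrix:
    """A gene x sample matrix of (log-scale) expression values.

    After :func:`tacna.io.standardize` each gene row has mean 0 and sample
    variance 1 (denominator n-1) and ``standardized`` is True.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be 2-D (genes x samples)")
        p, n = self.values.shape
        if len(self.gene_ids) != p or len(self.sample_ids) != n:
            raise ValidationError("expression identifier lengths do not match matrix shape")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")
        if len(set(self.gene_ids)) != p:
            raise ValidationError("duplicate gene_ids in expression matrix")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleMetadata:
    """Per-sample tumor-type labels and normal/tumor flags."""

    sample_ids: np.ndarray
    tumor_type: np.ndarray
    is_normal: np.ndarray

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.tumor_type = np.asarray(self.tumor_type, dtype=object)
        self.is_normal = np.asarray(self.is_normal, dtype=bool)
        n = len(self.sample_ids)
        if len(self.tumor_type) != n or len(self.is_normal) != n:
            raise ValidationError("metadata fields have mismatched lengths")
        if n == 0:
            raise ValidationError("metadata must describe at least one sample")

    def aligned_to(self, sample_ids) -> "SampleMetadata":
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            idx = np.asarray([lookup[s] for s in sample_ids], dtype=np.int64)
        except KeyError as exc:
            raise ValidationError(f"sample {exc.args[0]!r} missing from metadata") from exc
        return SampleMetadata(self.sample_ids[idx], self.tumor_type[idx], self.is_normal[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "tumor_type": self.tumor_type, "is_normal": self.is_normal}
        )


@dataclass
class CopyNumberSegments:
    """Segmented copy-number records (SEG): sample, chromosome, 0-based half-open
    interval, and the segment mean log2 copy ratio."""

    frame: pd.DataFrame  # columns: sample_id, chromosome, start, end, seg_mean

    REQUIRED = ("sample_id", "chromosome", "start", "end", "seg_mean")

    def __post_init__(self):
        df = pd.DataFrame(self.frame)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"segment table missing columns {missing}")
        df = df.reset_index(drop=True)
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(
                f"segment with start >= end for sample {bad['sample_id']!r} on {bad['chromosome']!r}"
            )
        for (sid, chrom), grp in df.groupby(["sample_id", "chromosome"], sort=False):
            g = grp.sort_values("start")
            overlap = g["start"].values[1:] < g["end"].values[:-1]
            if overlap.any():
                j = int(np.flatnonzero(overlap)[0])
                a, b = g.iloc[j], g.iloc[j + 1]
                raise ValidationError(
                    f"overlapping segments for sample {sid!r} on {chrom!r}: "
                    f"[{a['start']},{a['end']}) and [{b['start']},{b['end']})"
                )
        self.frame = df

    @property
    def sample_ids(self) -> np.ndarray:
        return self.frame["sample_id"].unique()

    def for_sample(self, sample_id) -> pd.DataFrame:
        return self.frame[self.frame["sample_id"] == sample_id]


@dataclass
class SourceSet:
    """Consensus sources (components x genes) with their mixing matrix
    (components x samples) and per-component credibility indices."""

    sources: np.ndarray
    mixing: np.ndarray
    credibility: np.ndarray
    n_runs: int
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    component_ids: np.ndarray = None

    def __post_init__(self):
        self.sources = np.atleast_2d(np.asarray(self.sources, dtype=np.float64))
        self.mixing = np.atleast_2d(np.asarray(self.mixing, dtype=np.float64))
        self.credibility = np.asarray(self.credibility, dtype=np.float64)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        i, p = self.sources.shape
        if self.mixing.shape[0] != i:
            raise ValidationError("sources and mixing disagree on component count")
        if len(self.credibility) != i:
            raise ValidationError("credibility length does not match component count")
        if len(self.gene_ids) != p:
            raise ValidationError("gene_ids length does not match sources")
        if self.mixing.shape[1] != len(self.sample_ids):
            raise ValidationError("sample_ids length does not match mixing")
        if i > 0 and np.any((self.credibility <= 0) | (self.credibility > 1)):
            raise ValidationError("credibility indices must lie in (0, 1]")
        if self.component_ids is None:
            self.component_ids = np.asarray([f"CES_{k + 1:03d}" for k in range(i)], dtype=object)
        else:
            self.component_ids = np.asarray(self.component_ids, dtype=object)
            if len(self.component_ids) != i:
                raise ValidationError("component_ids length does not match component count")

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    @property
    def n_genes(self) -> int:
        return self.sources.shape[1]

    @property
    def n_samples(self) -> int:
        return self.mixing.shape[1]


@dataclass(frozen=True)
class Region:
    """One contiguous genomic region of extreme weights (order indices inclusive)."""

    chromosome: str
    first_order_index: int
    last_order_index: int
    member_gene_ids: tuple
    n_extreme_genes: int


@dataclass
class RegionCall:
    """Detection result for one component: marked regions, the CNA-CES flag, and
    the boolean extreme-valued region indicator aligned to the component's genes."""

    component_id: str
    regions: list = field(default_factory=list)
    is_cna_ces: bool = False
    indicator: np.ndarray = None

    def __post_init__(self):
        if self.indicator is not None:
            self.indicator = np.asarray(self.indicator, dtype=bool)
        if self.is_cna_ces != bool(self.regions):
            raise ValidationError("is_cna_ces must equal (regions non-empty)")

    @property
    def n_region_genes(self) -> int:
        """Total genes inside marked regions (union size)."""
        return sum(len(r.member_gene_ids) for r in self.regions)

    @property
    def region_gene_ids(self) -> set:
        out = set()
        for r in self.regions:
            out.update(r.member_gene_ids)
        return out


@dataclass
class TacnaProfileSet:
    """The CNA-driven part of each expression profile (genes x samples).

    Rows for genes outside every marked region are identically zero. When
    ``centered`` a per-gene Hodges-Lehmann baseline over normal samples has been
    subtracted, so zero corresponds to a neutral (two-copy) state.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    centered: bool = False
    baseline: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        p, n = self.values.shape
        if len(self.gene_ids) != p or len(self.sample_ids) != n:
            raise ValidationError("TACNA identifier lengths do not match matrix shape")
        if self.baseline is None:
            self.baseline = np.zeros(p)
        self.baseline = np.asarray(self.baseline, dtype=np.float64)
        if len(self.baseline) != p:
            raise ValidationError("baseline length does not match gene count")


@dataclass
class AdaptationTable:
    """Per-gene degree of transcriptional adaptation in [0, 1].

    0 = highest absolute weight in its marked region (expression tracks copy
    number), 1 = lowest (fully buffered). For genes in several marked regions the
    minimum metric is recorded.
    """

    frame: pd.DataFrame  # gene_id, metric, component_id, n_components_containing

    def __post_init__(self):
        df = pd.DataFrame(self.frame).reset_index(drop=True)
        required = {"gene_id", "metric", "component_id", "n_components_containing"}
        if not required.issubset(df.columns):
            raise ValidationError(f"adaptation table missing columns {required - set(df.columns)}")
        if len(df) and ((df["metric"] < 0) | (df["metric"] > 1)).any():
            raise ValidationError("adaptation metric outside [0, 1]")
        self.frame = df
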