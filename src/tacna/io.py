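"""Readers, writers and per-gene standardization.

Supported dialects: tab-separated gene x sample matrices, GCT 1.2, BED4 gene
annotation (0-based half-open), TSV annotation with named columns, and SEG
segmented copy-number files (1-based inclusive by convention, converted to the
internal 0-based half-open coordinates on read).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_CHROMOSOME_ORDER,
    CopyNumberSegments,
    ExpressionMatrix,
    GeneAnnotation,
    SampleMetadata,
    SourceSet,
    normalize_chromosome,
)
from .errors import ParseError, TacnaError, ValidationError

logger = logging.getLogger(__name__)

SEG_COLUMNS = ("Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    return "gct" if str(path).lower().endswith(".gct") else "tsv"


def _finish_expression(df: pd.DataFrame, path) -> ExpressionMatrix:
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError("expression matrix has zero genes or zero samples", str(path))
    # collapse duplicated gene rows by mean, keeping first-occurrence order
    if df.index.duplicated().any():
        order = df.index.drop_duplicates()
        df = df.groupby(level=0, sort=False).mean().loc[order]
    return ExpressionMatrix(
        values=df.to_numpy(dtype=np.float64),
        gene_ids=df.index.to_numpy(dtype=object),
        sample_ids=df.columns.to_numpy(dtype=object),
        standardized=False,
    )


def _read_matrix_body(lines: list[str], path, first_line: int, n_columns: int | None = None,
                      drop_description: bool = False) -> pd.DataFrame:
    """Parse header + data lines into a gene-indexed float DataFrame with
    per-line error reporting."""
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 2:
        raise ParseError("matrix header has fewer than two columns", str(path), first_line)
    samples = header[2:] if drop_description else header[1:]
    if n_columns is not None and len(samples) != n_columns:
        raise ParseError(
            f"header lists {len(samples)} samples but dimension line declared {n_columns}",
            str(path), first_line,
        )
    ids, rows = [], []
    for offset, line in enumerate(lines[1:], start=first_line + 1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        expected = len(samples) + (2 if drop_description else 1)
        if len(parts) != expected:
            raise ParseError(
                f"expected {expected} fields, found {len(parts)}", str(path), offset
            )
        values = parts[2:] if drop_description else parts[1:]
        try:
            rows.append([float(v) for v in values])
        except ValueError:
            raise ParseError("non-numeric expression value", str(path), offset) from None
        ids.append(parts[0])
    df = pd.DataFrame(rows, index=ids, columns=samples, dtype=np.float64)
    return df


def read_expression(path: str | Path, fmt: str | None = None) -> ExpressionMatrix:
    """Read a gene x sample expression matrix from TSV or GCT 1.2.

    Duplicate gene rows are collapsed by mean. The returned matrix is flagged as
    not standardized.
    """
    path = Path(path)
    text = path.read_text().splitlines(keepends=True)
    fmt = _infer_format(path, fmt)
    if fmt == "tsv":
        if not text:
            raise ParseError("empty file", str(path))
        df = _read_matrix_body(text, path, first_line=1)
    elif fmt == "gct":
        if len(text) < 3:
            raise ParseError("truncated GCT file", str(path), len(text))
        if text[0].strip() != "#1.2":
            raise ParseError("missing '#1.2' GCT version line", str(path), 1)
        dims = text[1].split()
        try:
            p, n = int(dims[0]), int(dims[1])
        except (IndexError, ValueError):
            raise ParseError("malformed GCT dimension line", str(path), 2) from None
        df = _read_matrix_body(text[2:], path, first_line=3, n_columns=n, drop_description=True)
        if df.shape[0] != p:
            raise ParseError(f"GCT declared {p} genes but file has {df.shape[0]}", str(path))
    else:
        raise ValueError(f"unknown expression format {fmt!r}")
    return _finish_expression(df, path)


def write_expression(X: ExpressionMatrix, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    df = X.to_frame()
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index_label="gene_id")
    elif fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{X.n_genes}\t{X.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(map(str, X.sample_ids)) + "\n")
            for g, row in zip(X.gene_ids, X.values):
                fh.write(str(g) + "\t" + str(g) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    else:
        raise ValueError(f"unknown expression format {fmt!r}")


def standardize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scores: mean 0, sample variance 1 (denominator n-1).

    Constant gene rows carry no usable signal and are dropped with a warning.
    """
    if X.standardized:
        raise TacnaError("matrix is already standardized")
    if X.n_samples < 2:
        raise TacnaError("standardization needs at least two samples")
    mean = X.values.mean(axis=1, keepdims=True)
    sd = X.values.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        dropped = X.gene_ids[~keep]
        logger.warning("dropping %d constant gene(s) during standardization: %s%s",
                       len(dropped), ", ".join(map(str, dropped[:5])),
                       "..." if len(dropped) > 5 else "")
    if not keep.any():
        raise TacnaError("all gene rows are constant; nothing to standardize")
    values = (X.values[keep] - mean[keep]) / sd[keep]
    return ExpressionMatrix(values, X.gene_ids[keep], X.sample_ids, standardized=True)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_annotation(
    path: str | Path,
    fmt: str | None = None,
    chrom_order: tuple[str, ...] = DEFAULT_CHROMOSOME_ORDER,
    one_based: bool = False,
) -> GeneAnnotation:
    """Read gene positions from BED4 (0-based half-open, no header) or a TSV with
    columns gene_id/chromosome/start/end. ``order_index`` is assigned by declared
    chromosome order then interval midpoint."""
    path = Path(path)
    if fmt is None:
        fmt = "bed" if str(path).lower().endswith(".bed") else "tsv"
    fmt = fmt.lower()
    ids, chroms, starts, ends = [], [], [], []
    lines = path.read_text().splitlines()
    if fmt == "bed":
        rows = enumerate(lines, start=1)
    elif fmt == "tsv":
        if not lines:
            raise ParseError("empty annotation file", str(path))
        header = lines[0].split("\t")
        try:
            cols = {name: header.index(name) for name in ("gene_id", "chromosome", "start", "end")}
        except ValueError:
            raise ParseError(
                "annotation TSV must have columns gene_id, chromosome, start, end",
                str(path), 1,
            ) from None
        rows = (
            (ln, "\t".join(line.split("\t")[cols[c]] for c in ("chromosome", "start", "end", "gene_id")))
            for ln, line in enumerate(lines[1:], start=2)
            if line.strip()
        )
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    for ln, line in rows:
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ParseError("annotation line has fewer than 4 fields", str(path), ln)
        chrom, s, e, gid = parts[0], parts[1], parts[2], parts[3]
        try:
            s, e = int(s), int(e)
        except ValueError:
            raise ParseError("non-integer coordinate", str(path), ln) from None
        if one_based:
            s -= 1
        if e <= s:
            raise ParseError(f"gene {gid!r} has end <= start", str(path), ln)
        if gid in set(ids):
            raise ParseError(f"duplicate gene_id {gid!r}", str(path), ln)
        ids.append(gid)
        chroms.append(chrom)
        starts.append(s)
        ends.append(e)
    if not ids:
        raise ParseError("annotation contains no genes", str(path))
    return GeneAnnotation.from_intervals(ids, chroms, starts, ends, chrom_order)


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    """Write BED4 in genome order."""
    order = np.argsort(ann.order_index)
    with open(path, "w") as fh:
        for j in order:
            fh.write(f"{ann.chromosome[j]}\t{ann.start[j]}\t{ann.end[j]}\t{ann.gene_ids[j]}\n")


# ---------------------------------------------------------------------------
# SEG copy-number segments
# ---------------------------------------------------------------------------

def read_segments(path: str | Path, one_based: bool = True,
                  strip_chr: bool | None = None) -> CopyNumberSegments:
    """Read a SEG file (tab-separated, header). ``Num_Probes`` is optional.

    SEG coordinates are 1-based inclusive by default and converted to the
    internal 0-based half-open convention. Set ``strip_chr`` to harmonize
    chromosome labels with an annotation that omits/includes the ``chr`` prefix.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty SEG file", str(path))
    header = lines[0].split("\t")
    if len(header) < 5:
        raise ParseError("SEG header has fewer than 5 columns", str(path), 1)
    has_probes = len(header) >= 6
    records = []
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        expected = 6 if has_probes else 5
        if len(parts) != expected:
            raise ParseError(f"expected {expected} fields, found {len(parts)}", str(path), ln)
        sid, chrom, s, e = parts[0], parts[1], parts[2], parts[3]
        seg_mean = parts[5] if has_probes else parts[4]
        try:
            s, e = int(s), int(e)
            seg_mean = float(seg_mean)
        except ValueError:
            raise ParseError("non-numeric SEG field", str(path), ln) from None
        if one_based:
            s -= 1
        if strip_chr is True:
            chrom = normalize_chromosome(chrom)
        elif strip_chr is False and not str(chrom).startswith("chr"):
            chrom = f"chr{chrom}"
        records.append((sid, chrom, s, e, seg_mean))
    df = pd.DataFrame(records, columns=["sample_id", "chromosome", "start", "end", "seg_mean"])
    return CopyNumberSegments(df)


def write_segments(segs: CopyNumberSegments, path: str | Path) -> None:
    """Write SEG with the conventional header, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for rec in segs.frame.itertuples(index=False):
            fh.write(
                f"{rec.sample_id}\t{rec.chromosome}\t{rec.start + 1}\t{rec.end}\t.\t{float(rec.seg_mean)!r}\n"
            )


def segments_to_gene_vector(
    segs: CopyNumberSegments,
    ann: GeneAnnotation,
    sample_id,
    fill: float = 0.0,
) -> np.ndarray:
    """Per-gene seg_mean for one sample: each gene takes the value of the segment
    containing its interval midpoint (half-open containment); genes covered by no
    segment take ``fill``. Returned in the order of ``ann.gene_ids``."""
    sub = segs.for_sample(sample_id)
    if len(sub) == 0:
        raise TacnaError(f"sample {sample_id!r} not present in segments")
    out = np.full(ann.n_genes, float(fill))
    mid = ann.midpoint
    chrom_norm = np.asarray([normalize_chromosome(c) for c in ann.chromosome], dtype=object)
    for chrom, grp in sub.groupby("chromosome", sort=False):
        mask = chrom_norm == normalize_chromosome(chrom)
        if not mask.any():
            continue
        g = grp.sort_values("start")
        starts = g["start"].to_numpy(dtype=np.float64)
        ends = g["end"].to_numpy(dtype=np.float64)
        means = g["seg_mean"].to_numpy(dtype=np.float64)
        pos = mid[mask]
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        vals = np.full(len(pos), float(fill))
        vals[ok] = means[j[ok]]
        out[mask] = vals
    return out


# ---------------------------------------------------------------------------
# metadata, source sets
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path, tumor_type_column: str = "tumor_type") -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", tumor_type_column, "is_normal"):
        if col not in df.columns:
            raise ParseError(f"metadata missing column {col!r}", str(path))
    is_normal = df["is_normal"]
    if is_normal.dtype == object:
        is_normal = is_normal.astype(str).str.lower().isin(("true", "1", "yes"))
    return SampleMetadata(
        df["sample_id"].to_numpy(dtype=object),
        df[tumor_type_column].to_numpy(dtype=object),
        is_normal.to_numpy(dtype=bool),
    )


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.to_frame().to_csv(path, sep="\t", index=False)


def save_source_set(S: SourceSet, prefix: str | Path) -> None:
    """Persist a SourceSet as three TSVs: ``<prefix>.sources.tsv`` (components x
    genes), ``<prefix>.mixing.tsv`` (components x samples) and
    ``<prefix>.credibility.tsv``."""
    prefix = str(prefix)
    pd.DataFrame(S.sources, index=S.component_ids, columns=S.gene_ids).to_csv(
        f"{prefix}.sources.tsv", sep="\t", index_label="component_id"
    )
    pd.DataFrame(S.mixing, index=S.component_ids, columns=S.sample_ids).to_csv(
        f"{prefix}.mixing.tsv", sep="\t", index_label="component_id"
    )
    pd.DataFrame(
        {"component_id": S.component_ids, "credibility": S.credibility, "n_runs": S.n_runs}
    ).to_csv(f"{prefix}.credibility.tsv", sep="\t", index=False)


def load_source_set(prefix: str | Path) -> SourceSet:
    prefix = str(prefix)
    sources = pd.read_csv(f"{prefix}.sources.tsv", sep="\t", index_col=0)
    mixing = pd.read_csv(f"{prefix}.mixing.tsv", sep="\t", index_col=0)
    cred = pd.read_csv(f"{prefix}.credibility.tsv", sep="\t")
    if list(sources.index) != list(mixing.index) or list(sources.index) != list(cred["component_id"]):
        raise ValidationError("source-set TSVs disagree on component ids")
    return SourceSet(
        sources=sources.to_numpy(),
        mixing=mixing.to_numpy(),
        credibility=cred["credibility"].to_numpy(),
        n_runs=int(cred["n_runs"].iloc[0]) if len(cred) else 0,
        gene_ids=sources.columns.to_numpy(dtype=object),
        sample_ids=mixing.columns.to_numpy(dtype=object),
        component_ids=sources.index.to_numpy(dtype=object),
    )
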