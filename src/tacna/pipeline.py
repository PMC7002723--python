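"""End-to-end orchestration: decompose -> detect -> reconstruct -> metrics.

This is the programmatic equivalent of the ``tacna run-all`` command; each stage
can also be run on its own through the per-module functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import ica, metrics, reconstruction
from .datatypes import (
    CopyNumberSegments,
    ExpressionMatrix,
    GeneAnnotation,
    SampleMetadata,
    SourceSet,
)
from .io import standardize
from .regions import DetectionParams, call_cnaces

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Every tunable of the pipeline, with the package defaults."""

    n_runs: int = 25
    variance_threshold: float = 0.85
    r_threshold: float = 0.9
    credibility_min: float = 0.5
    master_seed: int = 0
    max_iter: int = 500
    tol: float = 1e-4
    detection: DetectionParams = field(default_factory=DetectionParams)
    min_region_genes: int = 50
    skip_centering: bool = False
    immune_panel: tuple = metrics.DEFAULT_IMMUNE_PANEL


@dataclass
class PipelineResult:
    source_set: SourceSet
    calls: list
    tacna: object  # TacnaProfileSet (centered when normals were available)
    adaptation: object | None = None
    burden: pd.Series | None = None
    immune: pd.Series | None = None
    tacna_cna_r: pd.Series | None = None


def run_pipeline(
    X: ExpressionMatrix,
    annotation: GeneAnnotation,
    meta: SampleMetadata | None = None,
    segments: CopyNumberSegments | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the whole TACNA pipeline on one dataset.

    ``X`` may be raw (it is standardized first) or already standardized.
    Centering on normals and the metadata-dependent metrics are computed only
    when metadata is supplied; the TACNA-vs-CNA correlation only when segments
    are supplied.
    """
    params = params or PipelineParams()
    if not X.standardized:
        X = standardize(X)
    S = ica.decompose(
        X,
        n_runs=params.n_runs,
        variance_threshold=params.variance_threshold,
        r_threshold=params.r_threshold,
        credibility_min=params.credibility_min,
        master_seed=params.master_seed,
        max_iter=params.max_iter,
        tol=params.tol,
    )
    calls = call_cnaces(S, annotation, params.detection)
    S_masked = reconstruction.mask_sources(S, calls)
    tacna = reconstruction.compute_tacna(S_masked)

    adaptation = burden = immune = corr = None
    if any(c.is_cna_ces for c in calls):
        adaptation = metrics.gene_adaptation_table(calls, S)
    if meta is not None and not params.skip_centering:
        if meta.aligned_to(tacna.sample_ids).is_normal.any():
            tacna = reconstruction.center_on_normals(tacna, meta)
        else:
            logger.info("no normal samples; TACNA profiles left uncentered")
    if meta is not None:
        try:
            burden = metrics.cna_burden(S, calls, meta, params.min_region_genes)
        except Exception as exc:  # noqa: BLE001 - optional output
            logger.warning("CNA burden not computed: %s", exc)
        try:
            immune = metrics.immune_metric(X, params.immune_panel, meta)
        except Exception as exc:  # noqa: BLE001 - optional output
            logger.warning("immune metric not computed: %s", exc)
    if segments is not None:
        corr = metrics.tacna_cna_correlation(tacna, segments, annotation)
    return PipelineResult(S, calls, tacna, adaptation, burden, immune, corr)
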