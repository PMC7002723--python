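"""Shared fixtures: small simulated datasets and their decompositions.

Everything is generated programmatically at test time; the heavier consensus
decompositions are session-scoped so that the region/reconstruction/metric
tests share one run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from tacna import (
    SimulationConfig,
    call_cnaces,
    simulate_dataset,
)
from tacna.ica import decompose


SMALL_CFG = SimulationConfig(
    p=1200,
    n=150,
    n_chromosomes=4,
    k_cna=2,
    k_conf=5,
    region_span=(60, 90),
    confounder_scale=0.3,
    seed=7,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-truth dataset: 1200 genes, 150 samples, 2 CNA sources."""
    return simulate_dataset(SMALL_CFG)


@pytest.fixture(scope="session")
def small_run(small_sim):
    """Consensus decomposition + CNA-CES calls on the small dataset."""
    X, ann, meta, segs, truth = small_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        S = decompose(X, master_seed=11)
    calls = call_cnaces(S, ann)
    return S, calls


def best_match_abs_corr(truth_sources: np.ndarray, est_sources: np.ndarray) -> np.ndarray:
    """For each truth source, |Pearson r| with its best-matching estimate under
    one-to-one assignment (Hungarian algorithm) — the matching oracle."""
    from scipy.optimize import linear_sum_assignment

    A = truth_sources - truth_sources.mean(axis=1, keepdims=True)
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    B = est_sources - est_sources.mean(axis=1, keepdims=True)
    B /= np.linalg.norm(B, axis=1, keepdims=True)
    C = np.abs(A @ B.T)
    rows, cols = linear_sum_assignment(-C)
    return C[rows, cols]


@pytest.fixture(scope="session")
def matcher():
    return best_match_abs_corr
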