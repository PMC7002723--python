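"""Consensus independent component analysis of expression matrices.

The decomposition treats genes as observations: each estimated source is a
weight vector over genes, and the mixing matrix holds per-sample coefficients
(the "activity" of each source in each profile). The pipeline is:

1. PCA of the standardized gene x sample matrix; the component count ``i`` is
   the smallest number of top components capturing >= 85% of total variance.
2. Fixed-point ICA (log-cosh contrast) run ``R`` times (default 25) with random
   initialization on the PCA-whitened data.
3. Icasso-style clustering of the ``R x i`` estimated sources at |Pearson r| >
   0.9, at most one member per run, with sign alignment to the cluster seed.
4. Consensus sources = cluster means; the credibility index of a cluster is its
   size divided by ``R``; clusters below the credibility threshold (default 50%)
   are discarded.

PCA/whitening uses the SVD of the standardized matrix directly (gene rows are
already centered, so no further column centering is applied); this keeps the
additive identity "consensus sources x mixing = rank-i PCA approximation" exact
when the mixing matrix is refit against the data (``consensus(..., X=X)``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .datatypes import ExpressionMatrix, SourceSet
from .errors import IcaConvergenceWarning, NoConsensusError, TacnaError, ValidationError

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-10


@dataclass
class IcaRunResult:
    """One ICA run: ``sources`` (i x p, each row unit gene-variance) and
    ``mixing`` (i x n) with ``sources.T @ mixing`` equal to the rank-i PCA
    approximation of the input."""

    run_index: int
    sources: np.ndarray
    mixing: np.ndarray
    seed: int
    converged: bool = True
    n_iter: int = 0


@dataclass
class ComponentCluster:
    """A cluster of matched sources across runs.

    ``members`` are (run_index, component_index, sign) triples; the sign flips a
    member so that it correlates positively with the cluster seed.
    """

    members: list
    consensus_weights: np.ndarray
    consensus_coefficients: np.ndarray
    credibility: float


# ---------------------------------------------------------------------------
# whitening / component count
# ---------------------------------------------------------------------------

def _svd(values: np.ndarray):
    """SVD with canonical signs: each left singular vector is oriented so its
    largest-magnitude entry is positive. Removes the arbitrary sign freedom so
    that whitening (and hence every ICA run) is invariant to sample order."""
    U, s, Vt = np.linalg.svd(values, full_matrices=False)
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, s, Vt * signs[:, None]


def _check_centered(X: ExpressionMatrix) -> None:
    """The decomposition assumes centered gene rows; per-gene standardization is
    the normal preparation but is not required (a noiseless low-rank matrix, for
    instance, must not be rescaled per gene)."""
    if not X.standardized:
        if np.max(np.abs(X.values.mean(axis=1))) > 1e-6:
            raise TacnaError("matrix is neither standardized nor row-centered")
        logger.warning("matrix is not standardized; proceeding on centered rows")


def select_component_count(
    X: ExpressionMatrix, variance_threshold: float = 0.85, svd=None
) -> int:
    """Smallest i whose top principal components capture at least
    ``variance_threshold`` of the total variance of the standardized matrix
    (PCA on the covariance between samples)."""
    if not (0 < variance_threshold <= 1):
        raise TacnaError("variance_threshold must lie in (0, 1]")
    _check_centered(X)
    _, s, _ = _svd(X.values) if svd is None else svd
    ev = s**2
    total = ev.sum()
    if variance_threshold == 1.0:
        return int((s > s[0] * _RANK_TOL).sum())
    frac = np.cumsum(ev) / total
    return int(np.searchsorted(frac, variance_threshold) + 1)


# ---------------------------------------------------------------------------
# single ICA run
# ---------------------------------------------------------------------------

def _derived_seed(seed: int) -> int:
    return int((seed * 1_000_003 + 12_345) % (2**31 - 1))


def run_ica(
    X: ExpressionMatrix,
    i: int,
    seed: int,
    max_iter: int = 500,
    tol: float = 1e-4,
    svd=None,
    run_index: int = 0,
    on_fail: str = "warn",
) -> IcaRunResult:
    """One fixed-point ICA run with ``i`` components, deterministic given ``seed``.

    A run that hits the iteration cap is retried once with a derived seed; if it
    still fails the result is returned with ``converged=False`` and an
    :class:`IcaConvergenceWarning` is issued (``on_fail="raise"`` raises instead).
    """
    _check_centered(X)
    p, n = X.values.shape
    if i > min(p, n):
        raise TacnaError(f"i={i} exceeds min(p, n)={min(p, n)}")
    U, s, Vt = _svd(X.values) if svd is None else svd
    rank = int((s > s[0] * _RANK_TOL).sum())
    if i > rank:
        raise TacnaError(f"i={i} exceeds the matrix rank {rank}")

    scale = np.sqrt(p)
    Y = U[:, :i] * scale  # whitened: p x i, unit-variance columns
    M = (s[:i, None] * Vt[:i]) / scale  # Y @ M == rank-i approximation of X

    def _attempt(rs: int):
        ica = FastICA(
            whiten=False,
            fun="logcosh",
            algorithm="parallel",
            max_iter=max_iter,
            tol=tol,
            random_state=rs,
        )
        with warnings.catch_warnings():
            # non-convergence is detected from n_iter_ below (not all sklearn
            # code paths emit ConvergenceWarning with whiten=False)
            warnings.simplefilter("ignore", ConvergenceWarning)
            S = ica.fit_transform(Y)
        return S, ica.components_, ica.n_iter_ < max_iter, ica.n_iter_

    S, W, ok, n_iter = _attempt(seed)
    if not ok:
        S, W, ok, n_iter = _attempt(_derived_seed(seed))
        if not ok:
            msg = f"ICA run {run_index} (seed {seed}) did not converge after retry"
            if on_fail == "raise":
                raise TacnaError(msg)
            warnings.warn(msg, IcaConvergenceWarning)

    mixing = W @ M  # i x n; S @ mixing == rank-i approximation
    sd = S.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    sources = (S / sd).T
    mixing = mixing * sd[:, None]
    return IcaRunResult(run_index, sources, mixing, seed, ok, int(n_iter))


# ---------------------------------------------------------------------------
# clustering across runs
# ---------------------------------------------------------------------------

def _row_normalize(A: np.ndarray) -> np.ndarray:
    Z = A - A.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Z, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return Z / norm


def cluster_runs(runs: list[IcaRunResult], r_threshold: float = 0.9) -> list[ComponentCluster]:
    """Greedy icasso-style clustering of sources across runs.

    Seeds are visited in descending (run, component) order; each seed collects,
    from every other run, that run's best-correlated still-unclustered component
    when |Pearson r| exceeds ``r_threshold``. Members are sign-aligned to the
    seed before averaging, so each cluster holds at most one component per run
    and every component ends up in exactly one (possibly singleton) cluster.
    """
    if len(runs) < 2:
        raise TacnaError("clustering requires at least two ICA runs")
    i = runs[0].sources.shape[0]
    p = runs[0].sources.shape[1]
    for r in runs:
        if r.sources.shape != (i, p) or r.mixing.shape[0] != i:
            raise ValidationError("ICA runs have mismatched dimensions")
    R = len(runs)
    A = np.vstack([r.sources for r in runs])  # (R*i) x p
    Z = _row_normalize(A)
    C = Z @ Z.T
    np.clip(C, -1.0, 1.0, out=C)

    assigned = np.zeros(R * i, dtype=bool)
    clusters: list[ComponentCluster] = []
    for run_idx in range(R - 1, -1, -1):
        for comp_idx in range(i - 1, -1, -1):
            seed_flat = run_idx * i + comp_idx
            if assigned[seed_flat]:
                continue
            assigned[seed_flat] = True
            members = [(run_idx, comp_idx, 1)]
            for other in range(R):
                if other == run_idx:
                    continue
                block = slice(other * i, (other + 1) * i)
                corr = C[seed_flat, block].copy()
                corr[assigned[block]] = 0.0
                best = int(np.argmax(np.abs(corr)))
                if abs(corr[best]) > r_threshold:
                    assigned[other * i + best] = True
                    members.append((other, best, 1 if corr[best] > 0 else -1))
            w = np.zeros(p)
            m = np.zeros(runs[0].mixing.shape[1])
            for ri, ci, sign in members:
                w += sign * runs[ri].sources[ci]
                m += sign * runs[ri].mixing[ci]
            w /= len(members)
            m /= len(members)
            clusters.append(ComponentCluster(members, w, m, len(members) / R))
    return clusters


def consensus(
    clusters: list[ComponentCluster],
    n_runs: int,
    credibility_min: float = 0.5,
    X: ExpressionMatrix | None = None,
) -> SourceSet:
    """Stack clusters with credibility >= ``credibility_min`` into a SourceSet.

    Each consensus source is rescaled to unit gene-variance and oriented so its
    largest-magnitude weight is positive. When ``X`` is given the mixing matrix
    is refit by least squares against the data, which restores the exact
    additive reconstruction; otherwise the (sign-consistent) member-mean
    coefficients are used.
    """
    kept = [c for c in clusters if c.credibility >= credibility_min]
    if not kept:
        raise NoConsensusError("no consensus sources survive credibility filtering")
    kept = sorted(kept, key=lambda c: (-c.credibility, c.members[0]))
    W = np.vstack([c.consensus_weights for c in kept])
    M = np.vstack([c.consensus_coefficients for c in kept])
    sd = W.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    W = W / sd[:, None]
    M = M * sd[:, None]
    flip = np.sign(W[np.arange(len(kept)), np.argmax(np.abs(W), axis=1)])
    flip[flip == 0] = 1.0
    W = W * flip[:, None]
    M = M * flip[:, None]
    if X is not None:
        if X.n_genes != W.shape[1]:
            raise ValidationError("X gene count does not match cluster weights")
        M, *_ = np.linalg.lstsq(W.T, X.values, rcond=None)
        gene_ids, sample_ids = X.gene_ids, X.sample_ids
    else:
        gene_ids = np.asarray([f"g{j}" for j in range(W.shape[1])], dtype=object)
        sample_ids = np.asarray([f"s{j}" for j in range(M.shape[1])], dtype=object)
    return SourceSet(
        sources=W,
        mixing=M,
        credibility=np.asarray([c.credibility for c in kept]),
        n_runs=n_runs,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
    )


# ---------------------------------------------------------------------------
# reconstruction / projection
# ---------------------------------------------------------------------------

def reconstruct_full(S: SourceSet) -> np.ndarray:
    """Additive reconstruction ``sources.T @ mixing`` (p x n)."""
    return S.sources.T @ S.mixing


def project_samples(
    S: SourceSet, X_new: ExpressionMatrix, min_overlap: float = 0.5
) -> np.ndarray:
    """Least-squares mixing coefficients (i x m) of new standardized samples
    against the fixed consensus sources, on the shared gene set."""
    if not X_new.standardized:
        raise TacnaError("projection expects a standardized matrix")
    shared = [g for g in S.gene_ids if g in set(X_new.gene_ids)]
    frac = len(shared) / len(S.gene_ids)
    if frac < min_overlap:
        raise TacnaError(
            f"gene overlap {frac:.2f} below the minimum fraction {min_overlap:.2f}"
        )
    s_idx = {g: j for j, g in enumerate(S.gene_ids)}
    x_idx = {g: j for j, g in enumerate(X_new.gene_ids)}
    rows_s = np.asarray([s_idx[g] for g in shared])
    rows_x = np.asarray([x_idx[g] for g in shared])
    coeffs, *_ = np.linalg.lstsq(S.sources[:, rows_s].T, X_new.values[rows_x], rcond=None)
    return coeffs


# ---------------------------------------------------------------------------
# end-to-end decomposition
# ---------------------------------------------------------------------------

def decompose(
    X: ExpressionMatrix,
    n_runs: int = 25,
    variance_threshold: float = 0.85,
    r_threshold: float = 0.9,
    credibility_min: float = 0.5,
    master_seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    n_components: int | None = None,
    refit_mixing: bool = True,
) -> SourceSet:
    """Run the full consensus-ICA pipeline on a standardized matrix.

    The SVD is computed once and shared by component selection and all runs;
    per-run seeds are derived from ``master_seed`` via a counter-based seed
    sequence, so results are reproducible and independent of execution order.
    """
    svd = _svd(X.values)
    i = n_components if n_components is not None else select_component_count(
        X, variance_threshold, svd=svd
    )
    logger.info("consensus ICA: %d components, %d runs", i, n_runs)
    seeds = np.random.SeedSequence(master_seed).generate_state(n_runs) % (2**31 - 1)
    runs = [
        run_ica(X, i, int(seeds[r]), max_iter=max_iter, tol=tol, svd=svd, run_index=r)
        for r in range(n_runs)
    ]
    n_bad = sum(not r.converged for r in runs)
    if n_bad:
        logger.warning("%d/%d ICA runs did not converge", n_bad, n_runs)
    clusters = cluster_runs(runs, r_threshold=r_threshold)
    return consensus(
        clusters, n_runs, credibility_min=credibility_min, X=X if refit_mixing else None
    )
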