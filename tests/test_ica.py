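"""Consensus-ICA: component selection, run determinism, clustering, consensus
filtering, reconstruction identities and sample projection."""

import warnings

import numpy as np
import pytest

from tacna import (
    ExpressionMatrix,
    IcaConvergenceWarning,
    NoConsensusError,
    TacnaError,
    simulate_laplacian_dataset,
)
from tacna.ica import (
    ComponentCluster,
    IcaRunResult,
    cluster_runs,
    consensus,
    decompose,
    project_samples,
    reconstruct_full,
    run_ica,
    select_component_count,
)


def _matrix_with_eigenfractions(fractions, p=400, n=40, seed=0):
    """Build a standardized-like matrix whose squared singular values have the
    given fractions of total variance."""
    rng = np.random.default_rng(seed)
    U, _ = np.linalg.qr(rng.normal(size=(p, len(fractions))))
    V, _ = np.linalg.qr(rng.normal(size=(n, len(fractions))))
    s = np.sqrt(np.asarray(fractions))
    values = (U * s) @ V.T
    values -= values.mean(axis=1, keepdims=True)
    return ExpressionMatrix(values, [f"g{j}" for j in range(p)],
                            [f"s{j}" for j in range(n)], standardized=False)


class TestSelectComponentCount:
    def test_threshold_crossing(self):
        # centering slightly perturbs the spectrum; use well-separated fractions
        X = _matrix_with_eigenfractions([0.6, 0.2, 0.1, 0.1])
        X.standardized = True  # spectrum is what matters here
        assert select_component_count(X, 0.85) == 3

    def test_threshold_one_gives_rank(self):
        X = _matrix_with_eigenfractions([0.5, 0.3, 0.2])
        X.standardized = True
        assert select_component_count(X, 1.0) == 3

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_threshold_rejected(self, bad):
        X = _matrix_with_eigenfractions([1.0])
        X.standardized = True
        with pytest.raises(TacnaError):
            select_component_count(X, bad)

    def test_rank_two_noiseless_matrix(self):
        """Oracle: eigenvalue count above numerical zero."""
        X, _, _ = simulate_laplacian_dataset(p=300, n=50, k=2, seed=1)
        s = np.linalg.svd(X.values, compute_uv=False)
        assert int((s > s[0] * 1e-10).sum()) == 2
        assert select_component_count(X, 1.0) == 2


class TestRunIca:
    def test_recovers_laplacian_sources(self, matcher):
        X, truth_s, _ = simulate_laplacian_dataset(p=2000, n=120, k=2, seed=2)
        res = run_ica(X, 2, seed=42)
        assert res.converged
        assert (matcher(truth_s, res.sources) > 0.99).all()

    def test_deterministic_given_seed(self):
        X, _, _ = simulate_laplacian_dataset(p=500, n=60, k=3, seed=4)
        a = run_ica(X, 3, seed=7)
        b = run_ica(X, 3, seed=7)
        np.testing.assert_array_equal(a.sources, b.sources)
        np.testing.assert_array_equal(a.mixing, b.mixing)

    def test_unit_variance_sources_and_exact_reconstruction(self):
        X, _, _ = simulate_laplacian_dataset(p=500, n=60, k=3, seed=4)
        res = run_ica(X, 3, seed=7)
        np.testing.assert_allclose(res.sources.std(axis=1, ddof=1), 1.0, atol=1e-8)
        # rank-3 PCA approximation of a rank-3 matrix is the matrix itself
        np.testing.assert_allclose(res.sources.T @ res.mixing, X.values, atol=1e-8)

    def test_nonconvergence_warns_after_retry(self):
        """A run that cannot reach the tolerance within the iteration cap is
        retried once and then returned with a recorded warning."""
        rng = np.random.default_rng(11)
        raw = rng.normal(size=(3, 400)).T @ rng.normal(size=(3, 80))
        raw -= raw.mean(axis=1, keepdims=True)
        X = ExpressionMatrix(raw, [f"g{j}" for j in range(400)],
                             [f"s{j}" for j in range(80)], standardized=False)
        with pytest.warns(IcaConvergenceWarning):
            res = run_ica(X, 3, seed=0, max_iter=3, tol=1e-12)
        assert not res.converged
        with pytest.raises(TacnaError):
            run_ica(X, 3, seed=0, max_iter=3, tol=1e-12, on_fail="raise")

    def test_component_count_beyond_rank_rejected(self):
        X, _, _ = simulate_laplacian_dataset(p=300, n=50, k=2, seed=1)
        with pytest.raises(TacnaError):
            run_ica(X, 10, seed=0)


def _fake_run(run_index, sources, mixing):
    return IcaRunResult(run_index, np.asarray(sources, float),
                        np.asarray(mixing, float), seed=run_index)


class TestClusterRuns:
    def test_sign_flipped_members_cluster_together(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=(1, 50))
        m = rng.normal(size=(1, 10))
        runs = [_fake_run(0, s, m), _fake_run(1, -s, -m)]
        clusters = cluster_runs(runs)
        assert len(clusters) == 1
        (c,) = clusters
        assert len(c.members) == 2
        signs = {ri: sign for ri, _, sign in c.members}
        assert signs[0] * signs[1] == -1  # opposite orientation detected
        # consensus equals s up to overall sign
        r = np.corrcoef(c.consensus_weights, s[0])[0, 1]
        assert abs(r) > 0.9999

    def test_uncorrelated_component_is_singleton(self):
        rng = np.random.default_rng(1)
        shared = rng.normal(size=50)
        runs = []
        for ri in range(5):
            lone = rng.normal(size=50)  # fresh noise each run: max |r| well below 0.9
            runs.append(_fake_run(ri, np.vstack([shared, lone]), rng.normal(size=(2, 8))))
        clusters = cluster_runs(runs)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes[-1] == 5  # the shared component clusters across all runs
        assert all(s == 1 for s in sizes[:-1])
        singleton = [c for c in clusters if len(c.members) == 1][0]
        assert singleton.credibility == pytest.approx(1 / 5)

    def test_well_separated_sources_give_full_clusters(self, matcher):
        """Oracle: exhaustive pairwise correlation of run sources."""
        X, truth_s, _ = simulate_laplacian_dataset(p=1500, n=100, k=3, seed=6)
        runs = [run_ica(X, 3, seed=100 + r, run_index=r) for r in range(25)]
        clusters = cluster_runs(runs)
        full = [c for c in clusters if len(c.members) == 25]
        assert len(full) == 3
        assert all(c.credibility == 1.0 for c in full)
        # oracle check: within each cluster every member correlates with the
        # consensus at |r| > 0.9
        for c in full:
            for ri, ci, sign in c.members:
                r = np.corrcoef(sign * runs[ri].sources[ci], c.consensus_weights)[0, 1]
                assert r > 0.9

    def test_mismatched_dimensions_rejected(self):
        rng = np.random.default_rng(2)
        runs = [_fake_run(0, rng.normal(size=(2, 50)), rng.normal(size=(2, 8))),
                _fake_run(1, rng.normal(size=(3, 50)), rng.normal(size=(3, 8)))]
        with pytest.raises(Exception):
            cluster_runs(runs)


def _cluster_of_size(size, R, p=30, n=8, seed=0):
    rng = np.random.default_rng(seed)
    return ComponentCluster(
        members=[(r, 0, 1) for r in range(size)],
        consensus_weights=rng.normal(size=p),
        consensus_coefficients=rng.normal(size=n),
        credibility=size / R,
    )


class TestConsensus:
    def test_credibility_cut_at_half(self):
        """Cluster sizes (25, 13, 12) of 25 runs: 25/25 and 13/25 kept, 12/25
        dropped at the 50% credibility threshold."""
        clusters = [_cluster_of_size(s, 25, seed=s) for s in (25, 13, 12)]
        S = consensus(clusters, 25)
        assert S.n_components == 2
        np.testing.assert_allclose(sorted(S.credibility), [13 / 25, 1.0])

    def test_zero_threshold_keeps_everything(self):
        clusters = [_cluster_of_size(s, 25, seed=s) for s in (25, 13, 12)]
        assert consensus(clusters, 25, credibility_min=0).n_components == 3

    def test_no_survivors_is_an_error(self):
        clusters = [_cluster_of_size(5, 25)]
        with pytest.raises(NoConsensusError):
            consensus(clusters, 25, credibility_min=0.5)

    def test_canonical_orientation_and_scale(self):
        clusters = [_cluster_of_size(25, 25, seed=3)]
        S = consensus(clusters, 25)
        w = S.sources[0]
        assert w.std(ddof=1) == pytest.approx(1.0)
        assert w[np.argmax(np.abs(w))] > 0


class TestReconstructFull:
    def test_single_source_inner_product(self):
        from tacna import SourceSet

        S = SourceSet(sources=[[1.0, 2.0]], mixing=[[3.0]], credibility=[1.0],
                      n_runs=1, gene_ids=["g1", "g2"], sample_ids=["s1"])
        np.testing.assert_array_equal(reconstruct_full(S), [[3.0], [6.0]])

    def test_matches_pca_truncation_on_noiseless_data(self):
        X, _, _ = simulate_laplacian_dataset(p=800, n=80, k=3, seed=8)
        S = decompose(X, n_runs=5, variance_threshold=1.0, master_seed=2)
        rms = np.sqrt(np.mean((reconstruct_full(S) - X.values) ** 2))
        assert rms < 1e-6

    def test_empty_sample_dimension(self):
        from tacna import SourceSet

        S = SourceSet(sources=np.ones((1, 3)), mixing=np.ones((1, 0)),
                      credibility=[1.0], n_runs=1,
                      gene_ids=["a", "b", "c"], sample_ids=[])
        assert reconstruct_full(S).shape == (3, 0)


class TestProjectSamples:
    def test_recovers_training_coefficients(self):
        X, _, _ = simulate_laplacian_dataset(p=800, n=80, k=3, seed=8)
        S = decompose(X, n_runs=5, variance_threshold=1.0, master_seed=2)
        recon = reconstruct_full(S)
        X_new = ExpressionMatrix(recon - recon.mean(axis=1, keepdims=True) * 0,
                                 X.gene_ids, X.sample_ids, standardized=True)
        coeffs = project_samples(S, X_new)
        np.testing.assert_allclose(coeffs, S.mixing, atol=1e-8)

    def test_orthogonal_samples_give_zero_coefficients(self):
        X, _, _ = simulate_laplacian_dataset(p=800, n=80, k=2, seed=9)
        S = decompose(X, n_runs=5, variance_threshold=1.0, master_seed=2)
        # residual of a random vector against the source span is orthogonal
        rng = np.random.default_rng(0)
        v = rng.normal(size=(800, 1))
        coef, *_ = np.linalg.lstsq(S.sources.T, v, rcond=None)
        resid = v - S.sources.T @ coef
        X_new = ExpressionMatrix(resid, X.gene_ids, ["q"], standardized=True)
        np.testing.assert_allclose(project_samples(S, X_new), 0.0, atol=1e-8)

    def test_insufficient_gene_overlap_rejected(self):
        X, _, _ = simulate_laplacian_dataset(p=400, n=50, k=2, seed=10)
        S = decompose(X, n_runs=5, variance_threshold=1.0, master_seed=2)
        X_new = ExpressionMatrix(X.values[:100], [f"other{j}" for j in range(100)],
                                 X.sample_ids, standardized=True)
        with pytest.raises(TacnaError, match="overlap"):
            project_samples(S, X_new)


class TestDecomposeInvariances:
    def test_sample_permutation_equivalence(self, matcher):
        """Permuting sample columns leaves the source set unchanged up to
        component order (|r| > 0.99 matching)."""
        X, _, _ = simulate_laplacian_dataset(p=800, n=80, k=3, seed=12)
        S1 = decompose(X, n_runs=5, variance_threshold=1.0, master_seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.n_samples)
        Xp = ExpressionMatrix(X.values[:, perm], X.gene_ids, X.sample_ids[perm],
                              standardized=False)
        S2 = decompose(Xp, n_runs=5, variance_threshold=1.0, master_seed=3)
        assert S1.n_components == S2.n_components
        assert (matcher(S1.sources, S2.sources) > 0.99).all()

    def test_credibility_filter_is_monotone(self, small_run):
        S, _ = small_run
        assert np.all(S.credibility >= 0.5)
        assert np.all(S.credibility <= 1.0)
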