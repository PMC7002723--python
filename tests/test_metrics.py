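"""Adaptation metric, CNA burden, immune metric, correlation metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tacna import (
    CopyNumberSegments,
    DEFAULT_IMMUNE_PANEL,
    ExpressionMatrix,
    GeneAnnotation,
    Region,
    RegionCall,
    SampleMetadata,
    SimulationConfig,
    SourceSet,
    TacnaError,
    TacnaProfileSet,
    adaptation_metric,
    cna_burden,
    compare_cnaces,
    compute_tacna,
    gene_adaptation_table,
    immune_metric,
    mask_sources,
    simulate_dataset,
    tacna_cna_correlation,
)


class TestAdaptationMetric:
    def test_descending_weights(self):
        out = dict(adaptation_metric([("a", 5.0), ("b", 3.0), ("c", 1.0)]))
        assert out == {"a": 0.0, "b": 0.5, "c": 1.0}

    def test_sign_ignored(self):
        out = dict(adaptation_metric([("a", -5.0), ("b", 3.0), ("c", 1.0)]))
        assert out == {"a": 0.0, "b": 0.5, "c": 1.0}

    def test_ties_get_average_rank(self):
        # |weights| (4, 4, 1): ranks (1.5, 1.5, 3) -> metrics (0.25, 0.25, 1)
        out = dict(adaptation_metric([("a", 4.0), ("b", 4.0), ("c", 1.0)]))
        assert out == {"a": 0.25, "b": 0.25, "c": 1.0}

    def test_tiny_region_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert adaptation_metric([("a", 1.0)]) == []

    def test_spans_unit_interval(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=17)
        out = np.asarray([m for _, m in adaptation_metric(list(zip("abcdefghijklmnopq", w)))])
        assert out.min() == 0.0
        assert out.max() == 1.0


def _region_call(cid, genes, p_genes, lo, hi):
    indicator = np.zeros(len(p_genes), dtype=bool)
    indicator[lo : hi + 1] = True
    return RegionCall(cid, [Region("1", lo, hi, tuple(genes), hi - lo + 1)], True, indicator)


class TestGeneAdaptationTable:
    def test_minimum_over_containing_regions(self):
        genes = [f"g{j}" for j in range(6)]
        S = SourceSet(
            sources=np.asarray([[5.0, 3.0, 1.0, 0, 0, 0], [0, 0, 4.0, 2.0, 1.0, 0]]),
            mixing=np.zeros((2, 2)),
            credibility=[1.0, 1.0],
            n_runs=1,
            gene_ids=genes,
            sample_ids=["s0", "s1"],
            component_ids=["A", "B"],
        )
        calls = [
            _region_call("A", genes[0:3], genes, 0, 2),
            _region_call("B", genes[2:5], genes, 2, 4),
        ]
        table = gene_adaptation_table(calls, S).frame.set_index("gene_id")
        # g2: metric 1.0 in region A (lowest |w|) but 0.0 in region B -> 0.0
        assert table.loc["g2", "metric"] == 0.0
        assert table.loc["g2", "component_id"] == "B"
        assert table.loc["g2", "n_components_containing"] == 2
        assert table.loc["g0", "metric"] == 0.0
        assert table.loc["g4", "metric"] == 1.0
        assert set(table.index) == {"g0", "g1", "g2", "g3", "g4"}

    def test_recovers_planted_attenuation(self, small_sim, small_run):
        """Estimated 0-1 metric correlates with planted attenuation within
        regions (oracle: simulator truth)."""
        X, ann, meta, segs, truth = small_sim
        S, calls = small_run
        table = gene_adaptation_table(calls, S).frame.set_index("gene_id")
        order = np.argsort(ann.order_index)
        gidx = {g: j for j, g in enumerate(ann.gene_ids)}
        common = [g for g in table.index if truth.in_region[gidx[g]]]
        rho = stats.spearmanr(
            table.loc[common, "metric"], truth.attenuation[[gidx[g] for g in common]]
        )[0]
        assert rho >= 0.7


class TestCnaBurden:
    def _setup(self):
        genes = [f"g{j}" for j in range(60)]
        S = SourceSet(
            sources=np.random.default_rng(0).normal(size=(2, 60)),
            mixing=np.asarray([[0.5, 1.0, -2.0, 0.0], [-0.3, 0.5, 1.0, -0.2]]),
            credibility=[1.0, 1.0],
            n_runs=1,
            gene_ids=genes,
            sample_ids=["a", "b", "c", "d"],
            component_ids=["A", "B"],
        )
        calls = [
            _region_call("A", genes[0:55], genes, 0, 54),
            _region_call("B", genes[0:55], genes, 0, 54),
        ]
        meta = SampleMetadata(["a", "b", "c", "d"], ["t1"] * 4, [False] * 4)
        return S, calls, meta

    def test_absolute_sum_and_minmax(self):
        S, calls, meta = self._setup()
        burden = cna_burden(S, calls, meta)
        raw = np.abs(S.mixing).sum(axis=0)  # [0.8, 1.5, 3.0, 0.2]
        expect = (raw - raw.min()) / (raw.max() - raw.min())
        np.testing.assert_allclose(burden.values, expect)
        assert burden["d"] == 0.0
        assert burden["c"] == 1.0

    def test_small_regions_do_not_qualify(self):
        S, calls, meta = self._setup()
        with pytest.raises(TacnaError):
            cna_burden(S, calls, meta, min_region_genes=100)

    def test_singleton_tumor_type_is_missing(self):
        S, calls, meta = self._setup()
        meta.tumor_type[:] = ["t1", "t1", "t1", "lonely"]
        with pytest.warns(UserWarning, match="single sample"):
            burden = cna_burden(S, calls, meta)
        assert np.isnan(burden["d"])
        assert not burden[["a", "b", "c"]].isna().any()

    def test_tracks_true_alteration_load(self, small_sim, small_run):
        X, ann, meta, segs, truth = small_sim
        S, calls = small_run
        burden = cna_burden(S, calls, meta, min_region_genes=50)
        alt = truth.altered_gene_count()
        rho = stats.spearmanr(burden.values, alt)[0]
        assert rho >= 0.6


def _expression_with_panel(seed=0):
    rng = np.random.default_rng(seed)
    other = [f"g{j}" for j in range(40)]
    genes = list(DEFAULT_IMMUNE_PANEL) + other
    values = rng.normal(size=(len(genes), 5))
    return genes, values


class TestImmuneMetric:
    def test_extreme_samples_score_zero_and_one(self):
        genes, values = _expression_with_panel()
        values[:6, 0] = 100.0  # panel genes top-ranked in sample 0
        values[:6, 1] = -100.0  # bottom-ranked in sample 1
        X = ExpressionMatrix(values, genes, [f"s{j}" for j in range(5)])
        score = immune_metric(X)
        assert score["s0"] == 1.0
        assert score["s1"] == 0.0

    def test_single_gene_panel(self):
        genes, values = _expression_with_panel()
        X = ExpressionMatrix(values, genes, [f"s{j}" for j in range(5)])
        with pytest.warns(UserWarning):
            score = immune_metric(X, panel=("CD2", "NOT_A_GENE"))
        ranks = stats.rankdata(values, axis=0)[0]
        expect = (ranks - ranks.min()) / (ranks.max() - ranks.min())
        np.testing.assert_allclose(score.values, expect)

    def test_invariant_to_gene_order_and_monotone_transform(self):
        genes, values = _expression_with_panel()
        X = ExpressionMatrix(values, genes, [f"s{j}" for j in range(5)])
        base = immune_metric(X)
        perm = np.random.default_rng(1).permutation(len(genes))
        Xp = ExpressionMatrix(values[perm], [genes[j] for j in perm],
                              X.sample_ids)
        pd.testing.assert_series_equal(base, immune_metric(Xp))
        Xm = ExpressionMatrix(np.exp(values / 3), genes, X.sample_ids)
        pd.testing.assert_series_equal(base, immune_metric(Xm))

    def test_no_panel_gene_present_is_an_error(self):
        X = ExpressionMatrix(np.zeros((2, 3)) + np.arange(3), ["x", "y"], ["a", "b", "c"])
        with pytest.raises(TacnaError):
            immune_metric(X)


class TestTacnaCnaCorrelation:
    def _inputs(self):
        ann = GeneAnnotation.from_intervals(
            [f"g{j}" for j in range(10)], ["1"] * 10,
            [j * 1000 for j in range(10)], [j * 1000 + 500 for j in range(10)],
        )
        seg = CopyNumberSegments(pd.DataFrame({
            "sample_id": ["s0"] * 2,
            "chromosome": ["1", "1"],
            "start": [0, 5000],
            "end": [5000, 10000],
            "seg_mean": [1.0, -1.0],
        }))
        return ann, seg

    def test_proportional_profile_gives_r_one(self):
        ann, seg = self._inputs()
        vals = np.asarray([[1.0]] * 5 + [[-1.0]] * 5) * 0.7
        T = TacnaProfileSet(vals, ann.gene_ids, ["s0"])
        r = tacna_cna_correlation(T, seg, ann)
        assert r["s0"] == pytest.approx(1.0)

    def test_constant_seg_vector_reported_missing(self):
        ann, seg = self._inputs()
        seg.frame["seg_mean"] = 0.3
        vals = np.asarray([[1.0]] * 5 + [[-1.0]] * 5)
        T = TacnaProfileSet(vals, ann.gene_ids, ["s0"])
        assert np.isnan(tacna_cna_correlation(T, seg, ann)["s0"])

    def test_no_shared_samples_is_an_error(self):
        ann, seg = self._inputs()
        T = TacnaProfileSet(np.ones((10, 1)), ann.gene_ids, ["other"])
        with pytest.raises(TacnaError):
            tacna_cna_correlation(T, seg, ann)

    def test_simulated_tumors_correlate_with_seg_truth(self, small_sim, small_run):
        X, ann, meta, segs, truth = small_sim
        S, calls = small_run
        T = compute_tacna(mask_sources(S, calls))
        r = tacna_cna_correlation(T, segs, ann)
        tumor_ids = meta.sample_ids[~meta.is_normal]
        med = np.nanmedian(r[tumor_ids])
        assert med >= 0.7
        # normal samples have exactly-neutral profiles -> zero-variance, NaN
        normal_ids = meta.sample_ids[meta.is_normal]
        assert r[normal_ids].isna().all()


class TestCompareCnaces:
    def _pair(self, wb=None):
        genes = [f"g{j}" for j in range(30)]
        rng = np.random.default_rng(0)
        wa = rng.normal(size=30)
        if wb is None:
            wb = wa.copy()
        Sa = SourceSet(sources=wa[None], mixing=np.zeros((1, 2)), credibility=[1.0],
                       n_runs=1, gene_ids=genes, sample_ids=["a", "b"], component_ids=["A"])
        Sb = SourceSet(sources=wb[None], mixing=np.zeros((1, 2)), credibility=[1.0],
                       n_runs=1, gene_ids=genes, sample_ids=["c", "d"], component_ids=["B"])
        ca = _region_call("A", genes[:20], genes, 0, 19)
        cb = _region_call("B", genes[5:25], genes, 5, 24)
        return Sa, ca, Sb, cb

    def test_identical_weights_give_rho_one(self):
        Sa, ca, Sb, cb = self._pair()
        rho, p = compare_cnaces(Sa, ca, Sb, cb)
        assert rho == pytest.approx(1.0)

    def test_reverse_ranked_weights_give_rho_minus_one(self):
        genes_abs = np.abs(np.random.default_rng(0).normal(size=30))
        order = np.argsort(np.argsort(genes_abs))
        reversed_abs = np.sort(genes_abs)[::-1][order]
        Sa, ca, Sb, cb = self._pair(wb=reversed_abs)
        # wa |.| ranks are exactly reversed in wb
        rho, p = compare_cnaces(Sa, ca, Sb, cb)
        assert rho == pytest.approx(-1.0)

    def test_too_few_shared_genes_is_missing(self):
        Sa, ca, Sb, cb = self._pair()
        with pytest.warns(UserWarning, match="shared genes"):
            rho, p = compare_cnaces(Sa, ca, Sb, cb, shared_genes=["g0", "g1"])
        assert np.isnan(rho)

    def test_matched_planted_components_across_replicates(self):
        """Two simulations sharing the planted genome but different sampling
        seeds: matched planted components pair at clearly positive rank
        correlation, unmatched pairs near 0 (oracle: simulator component
        identity). Matched correlations sit around 0.5-0.7 rather than near 1
        because per-gene standardization rescales weights by a gene variance
        that fluctuates independently between replicates; unmatched pairs are
        strongly negative because on the union of two disjoint marked regions
        the two components' absolute weights have complementary support."""
        import warnings as _w

        from tacna.ica import decompose
        from tacna import call_cnaces

        base = dict(p=1200, n=160, n_chromosomes=2, k_cna=2, k_conf=5,
                    region_span=(100, 140), confounder_scale=0.3, structure_seed=42)
        runs = []
        for seed in (1, 2):
            cfg = SimulationConfig(seed=seed, **base)
            X, ann, meta, segs, truth = simulate_dataset(cfg)
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                S = decompose(X, master_seed=5)
            calls = call_cnaces(S, ann)
            keep = {}
            for call in calls:
                if not call.is_cna_ces:
                    continue
                k = int(np.flatnonzero(S.component_ids == call.component_id)[0])
                ts = truth.standardized_sources()[: truth.k_cna]
                match = int(np.argmax([abs(np.corrcoef(t, S.sources[k])[0, 1]) for t in ts]))
                keep[match] = (S, call)
            runs.append(keep)
        a, b = runs
        assert set(a) == set(b) == {0, 1}
        for planted in (0, 1):
            rho, _ = compare_cnaces(*a[planted], *b[planted])
            assert rho > 0.5
        rho_cross, _ = compare_cnaces(*a[0], *b[1])
        assert rho_cross < 0
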