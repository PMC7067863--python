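"""Differential stage: filters, TMM, transform, moderated fit, calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meripseq import diffmeth as dm
from meripseq.genomic_io import SampleMetadata


def meta(sample_id, role="IP", condition="CONV", seq="s1", lib_b="l1",
         proc="p1", lib=1_000_000):
    return SampleMetadata(sample_id, role, sample_id, condition, seq, lib_b,
                          proc, lib)


class TestCpmFilter:
    def test_rule_one_keeps_three_of_many(self):
        samples = [meta(f"s{i}") for i in range(6)]
        counts = pd.DataFrame(
            [[6, 6, 6, 0, 0, 0], [6, 6, 0, 0, 0, 0]],
            index=["keep", "drop"],
            columns=[s.sample_id for s in samples],
        )
        # CPM = count (libraries of 1e6)
        out = dm.filter_by_cpm(counts, samples, min_cpm=5, min_samples=3)
        assert list(out.index) == ["keep"]

    def test_rule_two_requires_support_per_procedure_and_condition(self):
        samples = [
            meta("a1", proc="p1"), meta("a2", proc="p1"),
            meta("a3", proc="p2"), meta("a4", proc="p2"),
        ]
        counts = pd.DataFrame(
            # >=5 CPM in 3 samples but only one of procedure p2
            [[9, 9, 9, 0], [9, 9, 9, 9]],
            index=["drop", "keep"],
            columns=[s.sample_id for s in samples],
        )
        out = dm.filter_by_cpm(counts, samples, min_cpm=5, min_samples=3,
                               ip_procedure_rule=True, min_per_procedure=2)
        assert list(out.index) == ["keep"]

    def test_zero_threshold_is_identity(self):
        samples = [meta(f"s{i}") for i in range(3)]
        counts = pd.DataFrame(np.arange(9).reshape(3, 3),
                              columns=[s.sample_id for s in samples])
        out = dm.filter_by_cpm(counts, samples, min_cpm=0, min_samples=0)
        assert out.equals(counts)


def tmm_oracle(counts, lib, k, ref):
    """Independent recomputation: sort-based double trim, weighted mean."""
    o, r = counts[:, k].astype(float), counts[:, ref].astype(float)
    keep0 = (o > 0) & (r > 0)
    o, r = o[keep0], r[keep0]
    m = np.log2((o / lib[k]) / (r / lib[ref]))
    a = 0.5 * np.log2((o / lib[k]) * (r / lib[ref]))
    n = m.size
    if n == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
    lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
    rm, ra = stats.rankdata(m), stats.rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    w = 1.0 / ((lib[k] - o) / (lib[k] * o) + (lib[ref] - r) / (lib[ref] * r))
    if not sel.any():
        return 1.0
    return 2.0 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel]))


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        x = np.tile(np.arange(1, 51).reshape(-1, 1), (1, 4))
        f = dm.tmm_factors(x)
        assert f == pytest.approx(np.ones(4))

    def test_proportional_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=100)
        x = np.column_stack([base, base * 3])
        f = dm.tmm_factors(x)
        assert f == pytest.approx(np.ones(2), abs=1e-8)

    def test_spiked_sample_compensated(self):
        rng = np.random.default_rng(1)
        base = rng.integers(50, 500, size=200)
        spiked = base.copy()
        spiked[:10] *= 50  # composition bias: few huge features
        x = np.column_stack([base, spiked])
        f = dm.tmm_factors(x)
        # the spiked sample's non-spiked features look depleted after
        # library-size division; its factor must shrink effective size
        assert f[1] < 1.0 < f[0]

    def test_matches_independent_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            nf = int(rng.integers(20, 50))
            ns = int(rng.integers(2, 5))
            x = rng.integers(0, 300, size=(nf, ns)).astype(float)
            x[0, :] += 1  # avoid all-zero samples
            lib = x.sum(axis=0)
            uq = np.quantile(x / lib, 0.75, axis=0)
            ref = int(np.argmin(np.abs(uq - uq.mean())))
            raw = np.array([tmm_oracle(x, lib, k, ref) for k in range(ns)])
            expected = raw / np.exp(np.mean(np.log(raw)))
            assert dm.tmm_factors(x, lib) == pytest.approx(expected, rel=1e-10)

    def test_all_zero_sample_rejected(self):
        x = np.column_stack([np.arange(10), np.zeros(10)])
        with pytest.raises(ValueError):
            dm.tmm_factors(x)


class TestVoomTransform:
    def test_zero_count_log_cpm(self):
        y, _ = dm.voom_transform(np.zeros((1, 1)), np.array([1e6]))
        assert y[0, 0] == pytest.approx(np.log2(0.5 / (1e6 + 1) * 1e6), abs=1e-12)

    def test_library_doubling_near_invariance(self):
        rng = np.random.default_rng(3)
        c = rng.integers(10, 1000, size=(30, 1)).astype(float)
        y1, _ = dm.voom_transform(c, np.array([1e6]))
        y2, _ = dm.voom_transform(2 * c, np.array([2e6]))
        # exact invariance is broken only by the +0.5/+1 offsets, whose
        # log2 effect is bounded by ~0.7/min(count)
        assert np.abs(y1 - y2).max() < 0.7 / c.min() + 1e-6

    def test_constant_variance_data_gets_flat_weights(self):
        rng = np.random.default_rng(4)
        n, s = 400, 8
        mu = 7.0  # constant log2 abundance
        counts = rng.poisson(2.0 ** mu, size=(n, s)).astype(float)
        lib = np.full(s, counts.sum(axis=0).mean())
        _, w = dm.voom_transform(counts, lib)
        cv = w.std() / w.mean()
        assert cv < 0.2

    def test_too_few_features_unit_weights(self):
        with pytest.warns(UserWarning, match="unit weights"):
            _, w = dm.voom_transform(np.ones((5, 3)), np.array([1e6] * 3))
        assert (w == 1).all()


def two_group_design(n_per_group=4):
    design = np.column_stack([
        np.ones(2 * n_per_group),
        np.repeat([0.0, 1.0], n_per_group),
    ])
    return design, ["Intercept", "condition[B]"]


class TestModeratedLm:
    def test_unit_weight_two_group_logfc_is_mean_difference(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(20, 8))
        design, names = two_group_design(4)
        tab = dm.fit_moderated_lm(y, np.ones_like(y), design, names)
        cond = tab[tab["coef"] == "condition[B]"]
        expected = y[:, 4:].mean(axis=1) - y[:, :4].mean(axis=1)
        assert cond["estimate"].to_numpy() == pytest.approx(expected)

    def test_prior_df_zero_equals_classical_t(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(50, 10))
        design, names = two_group_design(5)
        tab = dm.fit_moderated_lm(y, np.ones_like(y), design, names, prior_df=0)
        cond = tab[tab["coef"] == "condition[B]"].reset_index(drop=True)
        for g in range(y.shape[0]):
            t_ref, p_ref = stats.ttest_ind(y[g, 5:], y[g, :5], equal_var=True)
            assert abs(cond.loc[g, "t"] - t_ref) < 1e-10
            assert abs(cond.loc[g, "p"] - p_ref) < 1e-10

    def test_infinite_prior_pools_variances(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(30, 8))
        design, names = two_group_design(4)
        tab = dm.fit_moderated_lm(y, np.ones_like(y), design, names,
                                  prior_df=np.inf)
        cond = tab[tab["coef"] == "condition[B]"]
        # pooled variance: se proportional to a single constant across features
        se_ratio = cond["se"].to_numpy() / cond["se"].to_numpy()[0]
        assert se_ratio == pytest.approx(np.ones(30))

    def test_moderation_squeezes_between_feature_and_prior(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(100, 8)) * rng.uniform(0.5, 2.0, size=(100, 1))
        design, names = two_group_design(4)
        tab = dm.fit_moderated_lm(y, np.ones_like(y), design, names)
        assert 0 < tab.attrs["prior_df"] < np.inf
        assert tab.attrs["prior_var"] > 0

    def test_rank_deficient_design_names_aliased_column(self):
        y = np.random.default_rng(9).normal(size=(5, 4))
        design = np.column_stack([np.ones(4), [0, 0, 1, 1], [0, 0, 1, 1]])
        with pytest.raises(ValueError, match="dup"):
            dm.fit_moderated_lm(y, np.ones_like(y), design,
                                ["Intercept", "cond", "dup"])


class TestBhAdjust:
    def test_hand_step_up_example(self):
        adj = dm.bh_adjust(np.array([0.005, 0.01, 0.03, 0.04]))
        assert adj == pytest.approx([0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert dm.bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_equal_ps_unchanged(self):
        adj = dm.bh_adjust(np.full(5, 0.2))
        assert adj == pytest.approx(np.full(5, 0.2))

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(10)
        for _ in range(10):
            p = rng.uniform(size=int(rng.integers(1, 50)))
            ours = dm.bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_nan_propagates_and_is_excluded_from_family(self):
        adj = dm.bh_adjust(np.array([0.01, np.nan, 0.02]))
        assert np.isnan(adj[1])
        assert adj[[0, 2]] == pytest.approx(dm.bh_adjust(np.array([0.01, 0.02])))

    def test_monotone_and_at_least_p(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=40)
        adj = dm.bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestSignificanceCalls:
    def table(self, p_adj, logfc):
        return pd.DataFrame({"feature_id": ["f"], "logFC": [logfc],
                             "t": [0.0], "p": [p_adj], "p_adj": [p_adj]})

    @pytest.mark.parametrize(
        "p_adj,logfc,expected",
        [(0.04, 1.2, True), (0.04, 0.9, False), (0.05, 1.2, False),
         (0.04, 1.0, False), (0.04, -1.2, True)],
    )
    def test_strict_cutoffs(self, p_adj, logfc, expected):
        out = dm.call_significant(self.table(p_adj, logfc))
        assert bool(out["significant"][0]) is expected


class TestClassification:
    def test_categories(self):
        peaks = pd.DataFrame({"feature_id": ["p1", "p2", "p3"],
                              "significant": [True, True, False]})
        genes = pd.DataFrame({"feature_id": ["g1", "g2", "g3"],
                              "significant": [True, False, False]})
        mapping = {"p1": "g1", "p2": "g2", "p3": "g3"}
        out = dm.classify_peaks_vs_expression(peaks, genes, mapping)
        assert out["category"].tolist() == ["meth_and_expr", "meth_only",
                                            "not_significant"]

    def test_orphan_peak_excluded_with_warning(self):
        peaks = pd.DataFrame({"feature_id": ["p1"], "significant": [True]})
        genes = pd.DataFrame({"feature_id": [], "significant": []})
        with pytest.warns(UserWarning, match="without a host gene"):
            out = dm.classify_peaks_vs_expression(peaks, genes, {})
        assert out.empty


class TestBatchRemoval:
    def test_no_batch_columns_is_identity(self):
        y = np.random.default_rng(12).normal(size=(10, 6))
        out = dm.remove_batch_effects(y, np.ones((6, 1)), np.empty((6, 0)))
        assert out == pytest.approx(y)

    def test_constructed_shift_removed_condition_preserved(self):
        rng = np.random.default_rng(13)
        n, s = 30, 8
        cond = np.repeat([0.0, 1.0], s // 2)
        batch = np.tile([0.0, 1.0], s // 2)  # balanced within condition
        y = rng.normal(size=(n, s))
        y += 3.0 * batch[None, :]  # additive batch shift
        y += 1.5 * cond[None, :]
        design_cond = np.column_stack([np.ones(s), cond])
        design_batch = batch.reshape(-1, 1)
        adj = dm.remove_batch_effects(y, design_cond, design_batch)
        # with a balanced design the fitted batch coefficient absorbs the
        # whole between-batch mean difference: residual shift is numerically 0
        shift = adj[:, batch == 1].mean(axis=1) - adj[:, batch == 0].mean(axis=1)
        assert np.abs(shift).max() < 1e-8
        # condition difference unchanged
        d_adj = adj[:, cond == 1].mean(axis=1) - adj[:, cond == 0].mean(axis=1)
        d_raw = y[:, cond == 1].mean(axis=1) - y[:, cond == 0].mean(axis=1)
        assert d_adj == pytest.approx(d_raw, abs=1e-8)


class TestModelObjects:
    def test_fit_contrast_and_summary(self):
        from meripseq.synthetic import simulate_count_matrix

        counts, samples, truth = simulate_count_matrix(
            n_features=300, n_true=5, seed=3)
        model = dm.DifferentialModel(counts, samples)
        res = model.fit()
        table = res.contrast("GF")
        assert set(table.columns) >= {"feature_id", "logFC", "t", "p", "p_adj",
                                      "significant"}
        assert (table["p_adj"] >= table["p"] - 1e-15).all()
        text = res.summary("GF")
        assert "significant features" in text and "TMM factors" in text

    def test_unknown_contrast_raises(self):
        from meripseq.synthetic import simulate_count_matrix

        counts, samples, _ = simulate_count_matrix(n_features=50, n_true=0, seed=4)
        res = dm.DifferentialModel(counts, samples).fit()
        with pytest.raises(KeyError, match="no coefficient"):
            res.contrast("vanco")

    def test_batch_corrected_shape(self):
        from meripseq.synthetic import simulate_count_matrix

        counts, samples, _ = simulate_count_matrix(n_features=60, n_true=0, seed=5)
        res = dm.DifferentialModel(counts, samples).fit()
        assert res.batch_corrected().shape == counts.shape
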