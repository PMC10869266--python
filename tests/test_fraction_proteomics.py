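"""Normalization, mixed imputation, moderated testing, shift classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from runoffkit.errors import (
    DesignError,
    NormalizationError,
    ParameterError,
)
from runoffkit.fraction_proteomics import (
    CONTRAST_HRN_VS_CHX_POLY,
    CONTRAST_POLY_VS_MONO_CHX,
    AbundanceTable,
    DiffResult,
    ShiftClasses,
    apply_rejections,
    classify_fraction_shifts,
    impute_mixed,
    moderated_test,
    p_adjust,
    run_shift_pipeline,
    vsn_normalize,
)
from runoffkit.runoff_sim import simulate_proteomics


def small_table(n_proteins=120, n_replicates=2, seed=0, **kw):
    return simulate_proteomics(n_proteins=n_proteins,
                               n_replicates=n_replicates, seed=seed, **kw)


class TestVsnNormalize:
    def test_pure_scale_factor_removed(self):
        tab = small_table(n_proteins=300, seed=1)
        data = tab.data.copy()
        data.iloc[:, 0] = data.iloc[:, 1] * 8.0  # sample 0 = scaled sample 1
        tab = AbundanceTable(data=data, design=tab.design, stage="raw")
        norm = vsn_normalize(tab)
        delta = (norm.data.iloc[:, 0] - norm.data.iloc[:, 1]).abs()
        assert delta.median() < 0.05

    def test_identical_samples_identical_output(self):
        tab = small_table(n_proteins=200, seed=2)
        data = tab.data.copy()
        data.iloc[:, 3] = data.iloc[:, 2]
        tab = AbundanceTable(data=data, design=tab.design, stage="raw")
        norm = vsn_normalize(tab)
        assert (norm.data.iloc[:, 3] - norm.data.iloc[:, 2]).abs().max() < 1e-9

    def test_rank_order_preserved_within_sample(self):
        tab = small_table(n_proteins=200, seed=3)
        norm = vsn_normalize(tab)
        for col in tab.data.columns[:3]:
            raw_rank = tab.data[col].rank()
            norm_rank = norm.data[col].rank()
            pd.testing.assert_series_equal(raw_rank, norm_rank)

    def test_variance_flattening_beats_plain_log2(self):
        # additive background noise blows up log2 variance at low intensity;
        # the glog transform must flatten the SD-vs-rank trend >= 5-fold
        tab = simulate_proteomics(
            n_proteins=1500, n_replicates=3, additive_sd=2.0**17,
            within_sd=0.05, seed=4,
        )
        norm = vsn_normalize(tab)

        def sd_slope(mat):
            sd = mat.std(axis=1)
            order = np.argsort(mat.mean(axis=1).to_numpy())
            rank = np.empty_like(order, dtype=float)
            rank[order] = np.linspace(0, 1, len(order))
            return abs(np.polyfit(rank, sd.to_numpy(), 1)[0])

        log2_slope = sd_slope(np.log2(tab.data))
        glog_slope = sd_slope(norm.data)
        assert log2_slope / glog_slope >= 5.0

    def test_sparse_sample_rejected(self):
        tab = small_table(n_proteins=120, seed=5)
        data = tab.data.copy()
        data.iloc[40:, 0] = np.nan  # 40 observed < 50
        tab = AbundanceTable(data=data, design=tab.design, stage="raw")
        with pytest.raises(NormalizationError):
            vsn_normalize(tab)

    def test_wrong_stage(self):
        tab = small_table(seed=6)
        norm = vsn_normalize(tab)
        with pytest.raises(ParameterError):
            vsn_normalize(norm)

    def test_nonpositive_intensity_rejected(self):
        tab = small_table(seed=7)
        data = tab.data.copy()
        data.iloc[0, 0] = 0.0
        with pytest.raises(ParameterError):
            vsn_normalize(AbundanceTable(data=data, design=tab.design,
                                         stage="raw"))


class TestImputeMixed:
    def test_no_missing_is_identity(self):
        norm = vsn_normalize(small_table(seed=8))
        imp = impute_mixed(norm)
        pd.testing.assert_frame_equal(imp.data, norm.data)
        assert imp.stage == "imputed"

    def test_condition_wise_absence_is_mnar(self):
        norm = vsn_normalize(small_table(n_proteins=150, n_replicates=3,
                                         seed=9))
        data = norm.data.copy()
        cols = norm.samples_of("polysome", "HRN")
        data.loc[data.index[0], cols] = np.nan
        imp = impute_mixed(
            AbundanceTable(data=data, design=norm.design, stage="normalized")
        )
        assert imp.imputation_class.iloc[0] == "MNAR"
        scale_min = np.nanmin(data.to_numpy())
        np.testing.assert_allclose(
            imp.data.loc[imp.data.index[0], cols], scale_min
        )

    def test_scattered_missing_is_mar_knn(self):
        norm = vsn_normalize(small_table(n_proteins=150, n_replicates=3,
                                         seed=10))
        data = norm.data.copy()
        data.iloc[5, 2] = np.nan  # one gap, others in its condition observed
        imp = impute_mixed(
            AbundanceTable(data=data, design=norm.design, stage="normalized")
        )
        assert imp.imputation_class.iloc[5] == "MAR"
        # knn fill should land near the protein's own observed level
        row_mean = np.nanmean(data.iloc[5].to_numpy())
        assert imp.data.iloc[5, 2] == pytest.approx(row_mean, abs=2.0)

    def test_mar_knn_beats_global_constant_imputation(self):
        norm = vsn_normalize(
            small_table(n_proteins=400, n_replicates=3, seed=11)
        )
        rng = np.random.default_rng(0)
        data = norm.data.copy()
        mask = rng.random(data.shape) < 0.10
        # never mask a full condition (keeps everything MAR)
        mask[:, :2] = False
        truth = data.to_numpy().copy()
        data = data.mask(pd.DataFrame(mask, index=data.index,
                                      columns=data.columns))
        imp = impute_mixed(
            AbundanceTable(data=data, design=norm.design, stage="normalized")
        )
        knn_rmse = np.sqrt(np.mean(
            (imp.data.to_numpy()[mask] - truth[mask]) ** 2
        ))
        const = np.nanmean(data.to_numpy())
        const_rmse = np.sqrt(np.mean((const - truth[mask]) ** 2))
        assert knn_rmse < const_rmse

    def test_all_missing_protein_dropped_with_warning(self):
        norm = vsn_normalize(small_table(n_proteins=120, seed=12))
        data = norm.data.copy()
        data.iloc[3, :] = np.nan
        with pytest.warns(RuntimeWarning, match="missing in every"):
            imp = impute_mixed(
                AbundanceTable(data=data, design=norm.design,
                               stage="normalized")
            )
        assert data.index[3] not in imp.data.index
        assert imp.data.shape[0] == 119

    def test_wrong_stage(self):
        with pytest.raises(ParameterError):
            impute_mixed(small_table(seed=13))


def toy_imputed_table(values: np.ndarray, n_replicates=3):
    """AbundanceTable at the imputed stage from a (proteins x 4*reps) array."""
    names, rows = [], []
    for frac in ("monosome", "polysome"):
        for trt in ("CHX", "HRN"):
            for rep in range(1, n_replicates + 1):
                names.append(f"{frac}_{trt}_{rep}")
                rows.append({"sample": names[-1], "fraction": frac,
                             "treatment": trt, "replicate": rep})
    data = pd.DataFrame(values,
                        index=[f"P{i}" for i in range(values.shape[0])],
                        columns=names)
    design = pd.DataFrame(rows).set_index("sample")
    return AbundanceTable(data=data, design=design, stage="imputed")


class TestModeratedTest:
    CONTRAST = (("polysome", "CHX"), ("monosome", "CHX"))

    def test_identical_groups(self):
        rng = np.random.default_rng(1)
        vals = np.tile(rng.normal(20, 2, (30, 1)), (1, 12))
        diff = moderated_test(toy_imputed_table(vals), self.CONTRAST)
        assert np.allclose(diff.table["log2FC"], 0)
        assert np.allclose(diff.table["t"], 0)
        assert np.allclose(diff.table["p"], 1)

    def test_prior_df_zero_equals_classic_t(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(20, 1, (40, 12))
        tab = toy_imputed_table(vals)
        diff = moderated_test(tab, self.CONTRAST, prior_df=0)
        a = tab.data[tab.samples_of("polysome", "CHX")].to_numpy()
        b = tab.data[tab.samples_of("monosome", "CHX")].to_numpy()
        t_classic, p_classic = stats.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(diff.table["t"], t_classic, atol=1e-10)
        np.testing.assert_allclose(diff.table["p"], p_classic, atol=1e-10)

    def test_prior_df_infinite_pools_variance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(20, 1, (40, 12))
        diff = moderated_test(toy_imputed_table(vals), self.CONTRAST,
                              prior_df=np.inf)
        # all proteins share one squeezed variance -> |t| proportional to |fc|
        tab = diff.table
        ratio = (tab["t"] / tab["log2FC"]).to_numpy()
        assert np.allclose(ratio, ratio[0])

    def test_moderation_interpolates_between_limits(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(20, 1, (60, 12))
        tab = toy_imputed_table(vals)
        t0 = moderated_test(tab, self.CONTRAST, prior_df=0).table["t"]
        t4 = moderated_test(tab, self.CONTRAST, prior_df=4).table["t"]
        tinf = moderated_test(tab, self.CONTRAST, prior_df=np.inf).table["t"]
        # per protein, the moderated t lies between the two limits
        lo = np.minimum(t0, tinf)
        hi = np.maximum(t0, tinf)
        assert ((t4 >= lo - 1e-9) & (t4 <= hi + 1e-9)).mean() > 0.95

    def test_small_group_rejected(self):
        rng = np.random.default_rng(5)
        tab = toy_imputed_table(rng.normal(20, 1, (30, 8)), n_replicates=2)
        tab.data = tab.data.drop(columns=["polysome_CHX_2"])
        with pytest.raises(DesignError):
            moderated_test(tab, self.CONTRAST)


class TestPAdjust:
    @pytest.mark.parametrize("seed", range(20))
    def test_bh_matches_bruteforce_stepup(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, rng.integers(5, 200))
        adj = p_adjust(p, "bh")
        # brute-force BH step-up
        m = p.size
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(ranked[::-1])[::-1]
        brute = np.empty(m)
        brute[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(adj, brute, atol=0)

    def test_qvalue_never_exceeds_bh_and_keeps_floor(self):
        rng = np.random.default_rng(0)
        p = np.concatenate([rng.uniform(0, 0.01, 50), rng.uniform(0, 1, 500)])
        bh = p_adjust(p, "bh")
        q = p_adjust(p, "qvalue")
        assert np.all(q <= bh + 1e-12)
        assert np.all(q >= p - 1e-12)

    def test_unknown_method(self):
        with pytest.raises(ParameterError):
            p_adjust(np.array([0.5]), "bonferroni-ish")


class TestRejectionsAndClasses:
    def _diff(self, rows):
        tab = pd.DataFrame(rows, columns=["log2FC", "t", "p", "adj_p"])
        tab["significant"] = pd.NA
        tab.index = [f"P{i}" for i in range(len(rows))]
        return DiffResult(table=tab, contrast="toy")

    def test_threshold_rule(self):
        diff = self._diff([
            (1.0, 5.0, 1e-4, 0.04),   # significant
            (0.3, 5.0, 1e-4, 0.04),   # fails lfc = log2(1.5) ~ 0.585
            (1.0, 1.0, 0.2, 0.30),    # fails alpha
        ])
        out = apply_rejections(diff)
        assert list(out.table["significant"]) == [True, False, False]

    def test_sweep_matches_bruteforce_filter(self):
        rng = np.random.default_rng(8)
        n = 400
        rows = np.column_stack([
            rng.normal(0, 1.5, n), rng.normal(0, 3, n),
            rng.uniform(0, 1, n), rng.uniform(0, 1, n),
        ])
        rows[:, 3] = np.maximum(rows[:, 2], rows[:, 3])  # adj_p >= p
        diff = self._diff(list(map(tuple, rows)))
        for alpha, lfc in [(0.05, 0.585), (0.2, 0.0), (0.01, 1.0)]:
            out = apply_rejections(diff, alpha=alpha, lfc=lfc)
            brute = {
                idx for idx, r in out.table.iterrows()
                if r["adj_p"] < alpha and abs(r["log2FC"]) > lfc
            }
            assert set(out.table.index[out.table["significant"]]) == brute

    def test_classification_rules(self):
        c1 = apply_rejections(self._diff([
            (2.0, 9, 1e-6, 1e-5),    # P0 polysome-enriched
            (2.0, 9, 1e-6, 1e-5),    # P1 polysome-enriched
            (-2.0, -9, 1e-6, 1e-5),  # P2 monosome-enriched
            (0.1, 0.5, 0.6, 0.8),    # P3 null
        ]))
        c2 = apply_rejections(self._diff([
            (-2.0, -9, 1e-6, 1e-5),  # P0 shifts out of polysomes
            (1.5, 8, 1e-6, 1e-5),    # P1 elevated after runoff
            (0.0, 0.0, 1.0, 1.0),    # P2
            (0.0, 0.0, 1.0, 1.0),    # P3
        ]))
        shifts = classify_fraction_shifts({
            CONTRAST_POLY_VS_MONO_CHX: c1, CONTRAST_HRN_VS_CHX_POLY: c2,
        })
        assert shifts.chx_polysome_enriched == {"P0", "P1"}
        assert shifts.shifted_to_monosome == {"P0"}
        assert shifts.hrn_polysome_elevated == {"P1"}

    def test_empty_significance_gives_empty_sets(self):
        c = apply_rejections(self._diff([(0.1, 0.2, 0.9, 0.95)] * 5))
        shifts = classify_fraction_shifts({
            CONTRAST_POLY_VS_MONO_CHX: c, CONTRAST_HRN_VS_CHX_POLY: c,
        })
        assert shifts.sizes() == {
            "chx_polysome_enriched": 0, "shifted_to_monosome": 0,
            "hrn_polysome_elevated": 0,
        }

    def test_missing_contrast(self):
        c = apply_rejections(self._diff([(0.1, 0.2, 0.9, 0.95)]))
        with pytest.raises(DesignError):
            classify_fraction_shifts({CONTRAST_POLY_VS_MONO_CHX: c})

    def test_subset_invariant_enforced(self):
        with pytest.raises(ParameterError):
            ShiftClasses(frozenset({"a"}), frozenset({"a", "b"}), frozenset())


class TestPipeline:
    def test_planted_shift_recovery(self):
        planted = pd.DataFrame(
            {"poly_enrichment": [2.2] * 10, "hrn_poly": [-2.0] * 10},
            index=range(10),
        )
        recovered = 0
        for seed in range(10):
            tab = simulate_proteomics(
                n_proteins=600, planted_shifts=planted, mar_rate=0.03,
                seed=seed,
            )
            res = run_shift_pipeline(tab)
            ids = {f"P{i:05d}" for i in range(10)}
            recovered += len(res["shifts"].shifted_to_monosome & ids)
        assert recovered / 100 >= 0.9

    def test_deterministic_end_to_end(self):
        tab = simulate_proteomics(n_proteins=300, mar_rate=0.05, seed=3)
        r1 = run_shift_pipeline(tab)
        tab2 = simulate_proteomics(n_proteins=300, mar_rate=0.05, seed=3)
        r2 = run_shift_pipeline(tab2)
        k = CONTRAST_POLY_VS_MONO_CHX
        pd.testing.assert_frame_equal(r1["diffs"][k].table,
                                      r2["diffs"][k].table)

    def test_qvalue_mode_runs_and_is_no_stricter_than_bh(self):
        planted = pd.DataFrame({"poly_enrichment": [2.5] * 5}, index=range(5))
        tab = simulate_proteomics(n_proteins=400, planted_shifts=planted,
                                  seed=9)
        bh = run_shift_pipeline(tab, adjust="bh")
        tab2 = simulate_proteomics(n_proteins=400, planted_shifts=planted,
                                   seed=9)
        qv = run_shift_pipeline(tab2, adjust="qvalue")
        assert bh["shifts"].chx_polysome_enriched <= \
            qv["shifts"].chx_polysome_enriched
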