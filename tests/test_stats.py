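import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import vasculonet as v
from vasculonet.stats import (anova_tukey, module_trait_correlation,
                              log2_enrichment, select_classifier_proteins,
                              normalize_reporter_channels, abeta_ratios,
                              TUKEY_FALLBACK_THRESHOLD, AB40_PEPTIDE,
                              AB42_PEPTIDE, EnrichmentRatios)
from vasculonet._tukey import studentized_range_sf


def _groups(n=10):
    cols = [f"S{i}" for i in range(3 * n)]
    g = pd.Series(np.repeat(["CTL", "AD", "PSP"], n), index=cols)
    return cols, g


class TestAnovaTukey:
    def test_overall_p_matches_f_oneway_oracle(self, rng):
        cols, g = _groups(8)
        X = pd.DataFrame(rng.normal(size=(20, 24)),
                         index=[f"P{i}|x" for i in range(20)], columns=cols)
        X.iloc[0, :8] += 2.0
        res = anova_tukey(X, g)
        for i in range(20):
            row = X.iloc[i]
            ref = sps.f_oneway(row[g == "CTL"], row[g == "AD"],
                               row[g == "PSP"]).pvalue
            assert res["anova_p"].iloc[i] == pytest.approx(ref, abs=1e-10)

    def test_pairwise_matches_scipy_studentized_range(self, rng):
        cols, g = _groups(10)
        X = pd.DataFrame(rng.normal(size=(5, 30)),
                         index=[f"P{i}|x" for i in range(5)], columns=cols)
        res = anova_tukey(X, g)
        for i in range(5):
            row = X.iloc[i].to_numpy()
            a, b = row[10:20], row[:10]           # AD, CTL
            groups = [row[:10], row[10:20], row[20:]]
            mse = np.mean([np.var(x, ddof=1) for x in groups])
            q = abs(a.mean() - b.mean()) / np.sqrt(mse / 10)
            ref = sps.studentized_range.sf(q, 3, 27)
            assert res["p_AD_vs_CTL"].iloc[i] == pytest.approx(ref, rel=1e-5)

    def test_degenerate_zero_variance_reported_skipped(self):
        cols, g = _groups(5)
        X = pd.DataFrame(np.full((1, 15), 3.0), index=["P0|x"], columns=cols)
        res = anova_tukey(X, g)
        assert bool(res["skipped"].iloc[0])
        assert np.isnan(res["anova_p"].iloc[0])

    def test_underfilled_group_skipped(self, rng):
        cols, g = _groups(5)
        X = pd.DataFrame(rng.normal(size=(1, 15)), index=["P0|x"], columns=cols)
        X.iloc[0, :4] = np.nan     # CTL has a single observation
        res = anova_tukey(X, g)
        assert bool(res["skipped"].iloc[0])

    def test_fallback_applies_triple_bonferroni_of_welch(self, rng):
        cols, g = _groups(10)
        row = np.concatenate([rng.normal(0, 0.1, 10),
                              rng.normal(10, 0.1, 10),
                              rng.normal(0, 0.1, 10)])
        X = pd.DataFrame(row[None, :], index=["P0|x"], columns=cols)
        res = anova_tukey(X, g)
        assert bool(res["fallback_AD_vs_CTL"].iloc[0])
        welch = sps.ttest_ind(row[10:20], row[:10], equal_var=False).pvalue
        assert res["p_AD_vs_CTL"].iloc[0] == pytest.approx(
            min(1.0, 3 * welch), rel=1e-9)
        # the CTL/PSP pair is null and must not fall back
        assert not bool(res["fallback_PSP_vs_CTL"].iloc[0])

    def test_fallback_only_below_threshold(self, rng):
        cols, g = _groups(10)
        X = pd.DataFrame(rng.normal(size=(50, 30)),
                         index=[f"P{i}|x" for i in range(50)], columns=cols)
        res = anova_tukey(X, g)
        for pair in ("AD_vs_CTL", "PSP_vs_CTL", "AD_vs_PSP"):
            fb = res[f"fallback_{pair}"]
            assert not fb.any()     # null data never crosses 10^-8.5


class TestTukeyQuadrature:
    def test_matches_scipy_over_grid(self):
        q = np.array([0.5, 1.5, 2.5, 3.5, 4.5, 6.0])
        for df in (10, 27, 57):
            ours = studentized_range_sf(q, 3, df)
            ref = sps.studentized_range.sf(q, 3, df)
            assert np.allclose(ours, ref, rtol=1e-6)


class TestModuleTraitCorrelation:
    def test_trait_equal_to_eigenprotein(self, rng):
        e = rng.normal(size=20)
        eig = pd.DataFrame([e], index=["M1"], columns=[f"S{i}" for i in range(20)])
        traits = pd.DataFrame({"age": e, "diagnosis": ["CTL"] * 20},
                              index=eig.columns)
        out = module_trait_correlation(eig, traits, trait_columns=["age"])
        row = out.set_index("trait").loc["age"]
        assert row["bicor"] == pytest.approx(1.0, abs=1e-9)
        assert row["p"] < 1e-12

    def test_null_p_values_uniform(self, rng):
        n = 62
        ps = []
        for _ in range(300):
            e = pd.DataFrame([rng.normal(size=n)], index=["M1"],
                             columns=[f"S{i}" for i in range(n)])
            tr = pd.DataFrame({"x": rng.normal(size=n)}, index=e.columns)
            out = module_trait_correlation(e, tr, trait_columns=["x"])
            ps.append(out["p"].iloc[0])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_binary_coding_swap_changes_only_sign(self, rng):
        n = 30
        e = pd.DataFrame([rng.normal(size=n)], index=["M1"],
                         columns=[f"S{i}" for i in range(n)])
        x = rng.integers(0, 2, n).astype(float)
        t1 = pd.DataFrame({"b": x}, index=e.columns)
        t2 = pd.DataFrame({"b": 1 - x}, index=e.columns)
        r1 = module_trait_correlation(e, t1, ["b"])
        r2 = module_trait_correlation(e, t2, ["b"])
        assert r1["bicor"].iloc[0] == pytest.approx(-r2["bicor"].iloc[0])
        assert r1["p"].iloc[0] == pytest.approx(r2["p"].iloc[0])

    def test_constant_trait_recorded_as_missing(self, rng):
        e = pd.DataFrame([rng.normal(size=10)], index=["M1"],
                         columns=[f"S{i}" for i in range(10)])
        tr = pd.DataFrame({"c": np.ones(10)}, index=e.columns)
        out = module_trait_correlation(e, tr, ["c"])
        assert np.isnan(out["bicor"].iloc[0])


class TestLog2Enrichment:
    def test_equal_fractions_give_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 6)),
                         index=[f"P{i}|x" for i in range(10)],
                         columns=[f"S{i}" for i in range(6)])
        enr = log2_enrichment(X, X.copy())
        assert np.allclose(enr.per_protein, 0.0)

    def test_planted_two_log2_shift(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 8)),
                         index=[f"P{i}|x" for i in range(5)],
                         columns=[f"S{i}" for i in range(8)])
        Y = X.copy()
        X.loc["P0|x"] += 2.0
        enr = log2_enrichment(X, Y)
        assert enr.per_protein["P0|x"] == pytest.approx(2.0)

    def test_planted_cohort_enrichment_recovered(self, small_cohort):
        c = small_cohort
        bio = list(c.traits.index)
        enr = log2_enrichment(c.vascular[bio], c.bulk[bio])
        truth = c.truth.vascular_enrichment
        shared = enr.per_protein.index
        resid = enr.per_protein - truth.reindex(shared)
        se = resid.std() / np.sqrt(len(resid))
        assert abs(resid.mean()) < 3 * se + 0.02
        assert set(enr.unique_to_vascular) == set(c.truth.unique_vascular)
        assert set(enr.unique_to_bulk) == set(c.truth.unique_bulk)

    def test_no_paired_samples_is_error(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 2)), columns=["A", "B"],
                         index=[f"P{i}|x" for i in range(3)])
        Y = pd.DataFrame(rng.normal(size=(3, 2)), columns=["C", "D"],
                         index=X.index)
        with pytest.raises(ValueError, match="paired"):
            log2_enrichment(X, Y)


class TestClassifierSelection:
    def _diff(self, pvals):
        idx = [f"P{i}|x" for i in range(len(pvals))]
        df = pd.DataFrame(index=idx)
        for pair in ("AD_vs_CTL", "PSP_vs_CTL", "AD_vs_PSP"):
            df[f"p_{pair}"] = [p[pair] for p in pvals]
        return df

    def test_three_fold_with_significance_selected(self):
        diff = self._diff([{"AD_vs_CTL": 0.01, "PSP_vs_CTL": 0.01,
                            "AD_vs_PSP": 0.01}])
        enr = EnrichmentRatios(
            per_protein=pd.Series([np.log2(3.0)], index=diff.index),
            unique_to_vascular=[], unique_to_bulk=[])
        assert select_classifier_proteins(diff, enr) == list(diff.index)

    def test_under_threshold_excluded_regardless_of_p(self):
        diff = self._diff([{"AD_vs_CTL": 1e-6, "PSP_vs_CTL": 1e-6,
                            "AD_vs_PSP": 1e-6}])
        enr = EnrichmentRatios(
            per_protein=pd.Series([np.log2(2.9)], index=diff.index),
            unique_to_vascular=[], unique_to_bulk=[])
        assert select_classifier_proteins(diff, enr) == []

    def test_matches_exhaustive_filter_oracle(self):
        specs = [
            (np.log2(4), False, 0.01, 0.01, 0.01),   # in
            (np.log2(2), True, 0.01, 0.01, 0.01),    # unique -> in
            (np.log2(4), False, 0.06, 0.01, 0.01),   # one p too big
            (np.log2(2), False, 0.01, 0.01, 0.01),   # not enriched
            (np.nan, True, 0.04, 0.04, 0.04),        # unique, sig -> in
            (np.log2(8), False, 0.01, 0.049, 0.051), # boundary p fails
        ]
        idx = [f"P{i}|x" for i in range(len(specs))]
        diff = pd.DataFrame({
            "p_AD_vs_CTL": [s[2] for s in specs],
            "p_PSP_vs_CTL": [s[3] for s in specs],
            "p_AD_vs_PSP": [s[4] for s in specs]}, index=idx)
        enr = EnrichmentRatios(
            per_protein=pd.Series([s[0] for s in specs], index=idx),
            unique_to_vascular=[idx[i] for i, s in enumerate(specs) if s[1]],
            unique_to_bulk=[])
        oracle = [idx[i] for i, s in enumerate(specs)
                  if ((s[1] or (np.isfinite(s[0]) and s[0] >= np.log2(3)))
                      and all(p < 0.05 for p in s[2:]))]
        assert select_classifier_proteins(diff, enr) == oracle


class TestReporterNormalization:
    def test_two_channel_factors(self):
        X = pd.DataFrame({"A": [60.0, 40.0], "B": [120.0, 80.0]},
                         index=["p1", "p2"])
        out = normalize_reporter_channels(X)
        assert np.allclose(out["A"], [120.0, 80.0])   # factor 2.0
        assert np.allclose(out["B"], [120.0, 80.0])   # factor 1.0

    def test_column_sums_equal_after_scaling(self, rng):
        X = pd.DataFrame(rng.uniform(1, 100, size=(30, 8)))
        out = normalize_reporter_channels(X)
        sums = out.sum()
        assert np.allclose(sums, X.sum().max())

    def test_single_channel_unchanged(self, rng):
        X = pd.DataFrame(rng.uniform(1, 10, size=(5, 1)), columns=["A"])
        pd.testing.assert_frame_equal(normalize_reporter_channels(X), X)

    def test_zero_sum_channel_named(self):
        X = pd.DataFrame({"A": [1.0, 2.0], "BAD": [0.0, 0.0]})
        with pytest.raises(ValueError, match="BAD"):
            normalize_reporter_channels(X)


class TestAbetaRatios:
    def _mats(self):
        cols = ["S1", "S2"]
        vasc = pd.DataFrame(
            [[3.0, 4.0], [1.0, 2.0], [5.0, 5.0]],
            index=[AB40_PEPTIDE, AB42_PEPTIDE, "OTHERPEP"], columns=cols)
        bulk = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0], [5.0, 5.0]],
            index=[AB40_PEPTIDE, AB42_PEPTIDE, "OTHERPEP"], columns=cols)
        return vasc, bulk

    def test_log2_ratio_from_linear_intensities(self):
        cols = ["S1"]
        vasc = pd.DataFrame([[8.0], [2.0]], index=[AB40_PEPTIDE, AB42_PEPTIDE],
                            columns=cols)
        bulk = pd.DataFrame([[2.0], [2.0]], index=[AB40_PEPTIDE, AB42_PEPTIDE],
                            columns=cols)
        res = abeta_ratios(vasc, bulk, log2_input=False)
        assert res.ab40_over_ab42.loc["vascular", "S1"] == pytest.approx(2.0)
        assert res.vascular_over_bulk.loc[AB40_PEPTIDE, "S1"] == pytest.approx(2.0)

    def test_log2_scale_differences(self):
        vasc, bulk = self._mats()
        res = abeta_ratios(vasc, bulk)
        assert res.ab40_over_ab42.loc["vascular", "S1"] == pytest.approx(2.0)
        assert res.vascular_over_bulk.loc[AB40_PEPTIDE, "S1"] == pytest.approx(2.0)
        assert res.vascular_over_bulk.loc[AB42_PEPTIDE, "S1"] == pytest.approx(-2.0)

    def test_missing_peptide_row_cites_sequence(self):
        vasc, bulk = self._mats()
        with pytest.raises(ValueError, match=AB40_PEPTIDE):
            abeta_ratios(vasc.drop(index=AB40_PEPTIDE), bulk)

    def test_generated_peptides_show_planted_enrichment(self):
        from vasculonet.synthetic import generate_abeta_peptides
        mats = generate_abeta_peptides(seed=3)
        res = abeta_ratios(mats["vascular"], mats["bulk"], log2_input=False)
        assert res.vascular_over_bulk.loc[AB40_PEPTIDE].mean() > 2.0
        assert res.vascular_over_bulk.loc[AB42_PEPTIDE].mean() < -2.0
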