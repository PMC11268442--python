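"""Beta computation, QC filters, beta-mixture EM, and BMIQ normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from methylgrowth import (BetaMatrix, IntensityMatrix, annotation_filters,
                          background_filter, bmiq_normalize, compute_beta,
                          fit_beta_mixture, intensities_to_beta,
                          preprocess_pipeline, sample_outlier_screen)


def _intensity_fixture(meth, unmeth, probes=None, samples=None):
    meth = np.atleast_2d(np.asarray(meth, dtype=float))
    unmeth = np.atleast_2d(np.asarray(unmeth, dtype=float))
    probes = probes or [f"cg{i}" for i in range(meth.shape[0])]
    samples = samples or [f"S{j}" for j in range(meth.shape[1])]
    return IntensityMatrix(pd.DataFrame(meth, index=probes, columns=samples),
                           pd.DataFrame(unmeth, index=probes, columns=samples))


class TestComputeBeta:
    @pytest.mark.parametrize("m,u,expected", [
        (0.0, 0.0, 0.0),
        (900.0, 0.0, 0.9),
        (100.0, 100.0, 100.0 / 300.0),
        (50.0, 350.0, 0.1),
    ])
    def test_printed_formula(self, m, u, expected):
        assert compute_beta(m, u) == pytest.approx(expected, abs=1e-15)

    def test_negative_input_names_probe_and_sample(self):
        m = pd.DataFrame([[10.0, -1.0]], index=["cg1"], columns=["A", "B"])
        u = pd.DataFrame([[10.0, 5.0]], index=["cg1"], columns=["A", "B"])
        with pytest.raises(ValueError, match=r"cg1.*B"):
            compute_beta(m, u)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_bounds_and_zero_iff_m_zero(self, m, u):
        b = compute_beta(m, u)
        assert 0 <= b < 1
        assert (b == 0) == (m == 0)

    @given(st.floats(0, 1e5), st.floats(1, 1e5), st.floats(1e-3, 1e4))
    def test_strictly_increasing_in_m(self, m, u, dm):
        assert compute_beta(m + dm, u) > compute_beta(m, u)


class TestBackgroundFilter:
    def test_all_samples_low_removed(self):
        intens = _intensity_fixture([[5, 5, 5], [5000, 6, 7]],
                                    [[5, 5, 5], [8, 9, 10]])
        mask = background_filter(intens, background_threshold=50)
        assert mask.tolist() == [True, False]

    def test_boundary_equal_is_retained(self):
        intens = _intensity_fixture([[50.0]], [[50.0]])
        assert not background_filter(intens, background_threshold=50).iloc[0]

    def test_threshold_must_be_positive(self):
        intens = _intensity_fixture([[5.0]], [[5.0]])
        with pytest.raises(ValueError):
            background_filter(intens, background_threshold=0)


class TestAnnotationFilters:
    def _betas(self, n=20):
        rng = np.random.default_rng(0)
        beta = pd.DataFrame(rng.random((n, 3)),
                            index=[f"cg{i}" for i in range(n)],
                            columns=list("ABC"))
        ann = pd.DataFrame({"chrom": "chr1", "pos": np.arange(n) + 1,
                            "design_type": "II",
                            "snp_flag": False, "sex_chrom_flag": False},
                           index=beta.index)
        return BetaMatrix(beta, annotation=ann)

    def test_no_flags_is_identity(self):
        bm = self._betas()
        out = annotation_filters(bm)
        pd.testing.assert_frame_equal(out.beta, bm.beta)

    def test_union_count_of_flags(self):
        bm = self._betas()
        ann = bm.annotation.copy()
        ann.iloc[:10, ann.columns.get_loc("snp_flag")] = True
        ann.iloc[8:13, ann.columns.get_loc("sex_chrom_flag")] = True
        out = annotation_filters(bm, ann)  # 10 snp, 5 sex, 2 overlap -> 13
        assert len(out.beta) == 20 - 13
        assert out.qc_log[-1]["probes_removed"] == 13

    def test_all_flagged_is_error(self):
        bm = self._betas()
        ann = bm.annotation.assign(snp_flag=True)
        with pytest.raises(ValueError, match="empty matrix"):
            annotation_filters(bm, ann)

    def test_missing_probe_lists_offenders(self):
        bm = self._betas()
        with pytest.raises(KeyError, match="cg0"):
            annotation_filters(bm, bm.annotation.iloc[5:])

    def test_filter_order_insensitive(self, small_cohort):
        intens = small_cohort.intensities
        ann = small_cohort.probe_annotation
        bg = background_filter(intens, 50.0)
        # background then annotation
        keep1 = intens.probes[~bg.values]
        bm1 = annotation_filters(
            intensities_to_beta(intens.subset(probes=keep1),
                                ann.loc[keep1]))
        # annotation then background
        bm2 = annotation_filters(intensities_to_beta(intens, ann))
        keep2 = bm2.probes[~bg.loc[bm2.probes].values]
        assert set(bm1.probes) == set(keep2)


class TestSampleOutlierScreen:
    def test_identical_samples_none_removed(self):
        intens = _intensity_fixture(np.full((10, 4), 2000.0),
                                    np.full((10, 4), 2000.0))
        assert not sample_outlier_screen(intens, 10.0).any()

    def test_scaled_down_sample_removed(self, small_cohort):
        m = small_cohort.intensities.methylated.copy()
        u = small_cohort.intensities.unmethylated.copy()
        m.iloc[:, 0] /= 100
        u.iloc[:, 0] /= 100
        mask = sample_outlier_screen(IntensityMatrix(m, u), 10.0)
        assert mask.iloc[0] and mask.iloc[1:].sum() == 0

    def test_vacuous_threshold(self, small_cohort):
        assert not sample_outlier_screen(small_cohort.intensities,
                                         -np.inf).any()

    def test_all_removed_is_error(self):
        intens = _intensity_fixture(np.full((10, 3), 2.0),
                                    np.full((10, 3), 2.0))
        with pytest.raises(ValueError, match="all samples"):
            sample_outlier_screen(intens, 10.0)


class TestBetaMixture:
    def test_simulate_and_refit_recovers_parameters(self):
        # weights (0.5, 0.1, 0.4), component means (0.1, 0.5, 0.9)
        rng = np.random.default_rng(21)
        x = np.concatenate([rng.beta(2, 18, 5000), rng.beta(5, 5, 1000),
                            rng.beta(18, 2, 4000)])
        fit = fit_beta_mixture(x)
        np.testing.assert_allclose(fit.weights, [0.5, 0.1, 0.4], atol=0.05)
        np.testing.assert_allclose(fit.means, [0.1, 0.5, 0.9], atol=0.03)

    def test_single_component_dominates(self):
        rng = np.random.default_rng(3)
        fit = fit_beta_mixture(rng.beta(2, 20, 4000))
        assert fit.weights.max() > 0.9

    def test_loglik_nondecreasing(self, small_cohort):
        x = small_cohort.betas.values[:, 0]
        fit = fit_beta_mixture(x)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-7 *
                      (1 + np.abs(fit.loglik_trace[:-1])))

    def test_invariants(self):
        rng = np.random.default_rng(4)
        fit = fit_beta_mixture(rng.beta(2, 5, 2000))
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(fit.means) > 0)
        assert np.all(fit.a > 0) and np.all(fit.b > 0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="50"):
            fit_beta_mixture(np.linspace(0.1, 0.9, 30))


class TestBmiq:
    @pytest.fixture(scope="class")
    def normalized(self, small_cohort):
        betas = preprocess_pipeline(small_cohort.intensities,
                                    small_cohort.probe_annotation, bmiq=False)
        return betas, bmiq_normalize(betas, seed=0)

    def test_rank_preserving_within_infii(self, normalized):
        pre, post = normalized
        is_ii = (pre.annotation["design_type"] == "II").values
        for s in pre.samples:
            rho = stats.spearmanr(pre.beta[s].values[is_ii],
                                  post.beta[s].values[is_ii]).statistic
            assert rho == pytest.approx(1.0, abs=1e-12)

    def test_ks_distance_strictly_decreases_every_sample(self, normalized):
        pre, post = normalized
        is_ii = (pre.annotation["design_type"] == "II").values
        for s in pre.samples:
            ks_pre = stats.ks_2samp(pre.beta[s].values[is_ii],
                                    pre.beta[s].values[~is_ii]).statistic
            ks_post = stats.ks_2samp(post.beta[s].values[is_ii],
                                     post.beta[s].values[~is_ii]).statistic
            assert ks_post < ks_pre

    def test_infi_values_bit_identical(self, normalized):
        pre, post = normalized
        is_i = (pre.annotation["design_type"] == "I").values
        np.testing.assert_array_equal(pre.beta.values[is_i],
                                      post.beta.values[is_i])

    def test_values_stay_in_unit_interval(self, normalized):
        _, post = normalized
        assert post.beta.values.min() >= 0 and post.beta.values.max() <= 1

    def test_identity_when_designs_share_distribution(self):
        rng = np.random.default_rng(5)
        n = 6000
        vals = np.concatenate([rng.beta(2, 15, n // 2), rng.beta(15, 2, n // 2)])
        rng.shuffle(vals)
        beta = pd.DataFrame({"S0": vals}, index=[f"cg{i}" for i in range(n)])
        ann = pd.DataFrame({"chrom": "chr1", "pos": np.arange(n) + 1,
                            "design_type": np.where(np.arange(n) % 2, "II", "I"),
                            "snp_flag": False, "sex_chrom_flag": False},
                           index=beta.index)
        bm = BetaMatrix(beta, annotation=ann)
        out = bmiq_normalize(bm, seed=0)
        is_ii = (ann["design_type"] == "II").values
        change = np.abs(out.beta.values[is_ii, 0] - beta.values[is_ii, 0])
        assert change.mean() < 0.02

    def test_requires_both_designs(self):
        beta = pd.DataFrame({"S0": np.linspace(0.05, 0.95, 100)},
                            index=[f"cg{i}" for i in range(100)])
        ann = pd.DataFrame({"chrom": "1", "pos": np.arange(100) + 1,
                            "design_type": "II", "snp_flag": False,
                            "sex_chrom_flag": False}, index=beta.index)
        with pytest.raises(ValueError, match="both"):
            bmiq_normalize(BetaMatrix(beta, annotation=ann))


class TestQcBookkeeping:
    def test_qc_log_counts_reconcile(self, small_cohort):
        betas = preprocess_pipeline(small_cohort.intensities,
                                    small_cohort.probe_annotation, bmiq=False)
        for entry in betas.qc_log:
            assert (entry["probes_in"] - entry["probes_removed"]
                    == entry["probes_out"])
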