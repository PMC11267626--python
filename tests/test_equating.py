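"""Equating tests: score distributions, the four equating methods and the
crosswalk application contract."""

import numpy as np
import pytest

from harmonex.equating import (
    apply_equating,
    crosswalk_table,
    equipercentile_equate,
    kernel_equate_single_group,
    linear_equate,
    mean_equate,
    score_distribution,
)


@pytest.fixture
def toy_src():
    # pmf (0.5, 0.3, 0.2) on {0, 1, 2}
    return score_distribution([0, 0, 0, 0, 0, 1, 1, 1, 2, 2], (0, 2))


@pytest.fixture
def toy_tgt_uniform():
    return score_distribution([0, 1, 2, 3, 4], (0, 4))


class TestScoreDistribution:
    def test_counting(self):
        d = score_distribution([0, 0, 1, 2], (0, 2))
        assert d.probs == pytest.approx([0.5, 0.25, 0.25])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            score_distribution([], (0, 2))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_distribution([0, 3], (0, 2))

    def test_full_support_with_zero_frequencies(self, cohort_scale_dataset):
        d = score_distribution(cohort_scale_dataset.target_sums, (0, 22))
        assert d.support.tolist() == list(range(23))
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestMeanLinear:
    def test_mean_shift(self):
        src = score_distribution([1, 2, 3], (0, 5))
        tgt = score_distribution([4, 5, 6], (0, 10))
        e = mean_equate(src, tgt)
        assert e(3) == pytest.approx(6.0)
        # unit slope
        assert e(4) - e(3) == pytest.approx(1.0)

    def test_identity_for_identical_distributions(self):
        d = score_distribution([0, 1, 1, 2], (0, 3))
        for fn in (mean_equate(d, d), linear_equate(d, d)):
            x = np.array([0.0, 1.0, 2.5, 3.0])
            np.testing.assert_allclose(fn(x), x, atol=1e-12)

    def test_linear_closed_form(self):
        # e(x) = (sd_t/sd_s)(x - mu_s) + mu_t with mu_s=3, sd_s=2, mu_t=6, sd_t=4
        src = score_distribution([1, 3, 5], (0, 6), ddof=0)
        tgt = score_distribution([2, 5, 6, 7, 10], (0, 12), ddof=0)
        assert src.mean == 3 and tgt.mean == 6
        e = linear_equate(src, tgt)
        slope = tgt.sd / src.sd
        assert e(5) == pytest.approx(slope * 2 + 6, abs=1e-10)

    def test_linear_moment_matching(self, cohort_scale_dataset):
        ds = cohort_scale_dataset
        src = score_distribution(ds.source_sums, (0, 10))
        tgt = score_distribution(ds.target_sums, (0, 22))
        e = linear_equate(src, tgt)
        z = e(ds.source_sums.astype(float))
        assert z.mean() == pytest.approx(tgt.mean, abs=1e-10)
        assert z.std(ddof=1) == pytest.approx(tgt.sd, abs=1e-10)

    def test_linear_symmetry_composes_to_identity(self, cohort_scale_dataset):
        ds = cohort_scale_dataset
        src = score_distribution(ds.source_sums, (0, 10))
        tgt = score_distribution(ds.target_sums, (0, 22))
        fwd, back = linear_equate(src, tgt), linear_equate(tgt, src)
        x = np.linspace(0, 10, 21)
        np.testing.assert_allclose(back(fwd(x)), x, atol=1e-10)

    def test_degenerate_source_rejected(self):
        flat = score_distribution([2, 2, 2], (0, 4))
        tgt = score_distribution([0, 1, 2], (0, 4))
        with pytest.raises(ValueError):
            linear_equate(flat, tgt)

    def test_equal_sds_reduce_linear_to_mean(self):
        src = score_distribution([0, 1, 2], (0, 4))
        tgt = score_distribution([2, 3, 4], (0, 6))
        lin, mn = linear_equate(src, tgt), mean_equate(src, tgt)
        x = np.linspace(0, 4, 9)
        np.testing.assert_allclose(lin(x), mn(x), atol=1e-12)


class TestEquipercentile:
    def test_self_equating_is_identity(self, toy_src):
        e = equipercentile_equate(toy_src, toy_src)
        for x in (0, 1, 2):
            assert e(x) == pytest.approx(x, abs=1e-12)

    def test_hand_computed_inversion(self, toy_src, toy_tgt_uniform):
        # PR_src(1) = 100*(0.5 + 0.3/2) = 65; in the uniform target
        # y* = 3 (F=0.8), e = 2.5 + (0.65-0.6)/0.2 = 2.75
        e = equipercentile_equate(toy_src, toy_tgt_uniform)
        assert e(1) == pytest.approx(2.75, abs=1e-12)

    def test_monotone_on_support(self, cohort_scale_dataset):
        ds = cohort_scale_dataset
        src = score_distribution(ds.source_sums, (0, 10))
        tgt = score_distribution(ds.target_sums, (0, 22))
        vals = equipercentile_equate(src, tgt)(np.arange(11).astype(float))
        assert np.all(np.diff(vals) >= 0)

    def test_matches_brute_force_on_toy(self, toy_src, toy_tgt_uniform):
        # independent brute-force percentile-rank inversion
        e = equipercentile_equate(toy_src, toy_tgt_uniform)
        F_s = np.concatenate([[0.0], np.cumsum(toy_src.probs)])
        F_t = np.concatenate([[0.0], np.cumsum(toy_tgt_uniform.probs)])
        for x in toy_src.support:
            p = F_s[x] + 0.5 * toy_src.probs[x]
            ystar = int(np.argmax(F_t[1:] >= p))
            expect = ystar - 0.5 + (p - F_t[ystar]) / toy_tgt_uniform.probs[ystar]
            assert e(int(x)) == pytest.approx(expect, abs=1e-12)

    def test_zero_frequency_run_maps_to_midpoint(self):
        src = score_distribution([0, 1], (0, 1))
        # target mass only at 0 and 4: scores 1..3 form a zero-frequency run
        tgt = score_distribution([0, 4], (0, 4))
        e = equipercentile_equate(src, tgt)
        # PR_src(0)=0.25 lands inside target score 0's mass
        assert 0 - 0.5 <= e(0) <= 0.5
        # p = 0.5 falls exactly on the CDF plateau across the run {1, 2, 3}
        assert e(0.5) == pytest.approx(2.0)


class TestKernel:
    def test_self_equating_identity(self, cohort_scale_dataset):
        x = cohort_scale_dataset.source_sums
        e = kernel_equate_single_group(x, x, (0, 10), (0, 10))
        xs = np.arange(11).astype(float)
        assert np.max(np.abs(e(xs) - xs)) < 1e-6

    def test_symmetric_pmf_cdf_half_at_center(self):
        from harmonex.equating import _kernel_cdf_factory

        d = score_distribution([0, 1, 1, 2], (0, 2))
        for h in (0.2, 0.7, 2.0):
            cdf, _ = _kernel_cdf_factory(d, h)
            assert cdf(1.0)[0] == pytest.approx(0.5, abs=1e-12)

    def test_small_bandwidth_matches_equipercentile_self_equating(self, toy_src):
        # percentile ranks align exactly in self-equating, where the
        # small-h kernel map and the percentile-rank map coincide
        rng = np.random.default_rng(0)
        x = rng.choice([0, 1, 2], size=200, p=[0.5, 0.3, 0.2])
        ep = equipercentile_equate(
            score_distribution(x, (0, 2)), score_distribution(x, (0, 2))
        )
        ker = kernel_equate_single_group(x, x, (0, 2), (0, 2), bandwidth=0.001)
        for v in (0, 1, 2):
            assert ker(v) == pytest.approx(ep(v), abs=0.01)

    def test_bandwidth_recorded_and_positive(self, cohort_scale_dataset):
        ds = cohort_scale_dataset
        e = kernel_equate_single_group(ds.source_sums, ds.target_sums, (0, 10), (0, 22))
        assert e.metadata["bandwidth_source"] > 0
        assert e.metadata["bandwidth_target"] > 0

    def test_strictly_increasing(self, cohort_scale_dataset):
        ds = cohort_scale_dataset
        e = kernel_equate_single_group(ds.source_sums, ds.target_sums, (0, 10), (0, 22))
        vals = e(np.linspace(0, 10, 41))
        assert np.all(np.diff(vals) > 0)

    def test_unpaired_or_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            kernel_equate_single_group(np.zeros(60), np.zeros(59), (0, 10), (0, 22))
        with pytest.raises(ValueError):
            kernel_equate_single_group(np.zeros(10), np.zeros(10), (0, 10), (0, 22))

    def test_presmoothing_options_run(self, cohort_scale_dataset):
        ds = cohort_scale_dataset
        sub = slice(0, 400)
        for kw in (dict(presmoothing_degree=3), dict(bivariate_presmoothing=True)):
            e = kernel_equate_single_group(
                ds.source_sums[sub], ds.target_sums[sub], (0, 10), (0, 22), **kw
            )
            vals = e(np.arange(11).astype(float))
            assert np.all(np.diff(vals) > 0)


class TestApplyEquating:
    def test_identity_passthrough(self):
        d = score_distribution(list(range(11)), (0, 10))
        e = mean_equate(d, d)
        np.testing.assert_allclose(apply_equating(e, [0, 5, 10]), [0, 5, 10])

    def test_clamped_to_target_range(self):
        src = score_distribution([0, 5, 10], (0, 10), ddof=0)
        tgt = score_distribution([0, 11, 22], (0, 22), ddof=0)
        e = linear_equate(src, tgt)
        assert e(10) == pytest.approx(22 + (e(10) - 22))  # raw value may exceed
        out = apply_equating(e, [10, 12])
        assert np.all(out <= 22)

    def test_mean_shift_values(self):
        src = score_distribution([0, 1, 2], (0, 10))
        tgt = score_distribution([3, 4, 5], (0, 22))
        e = mean_equate(src, tgt)
        np.testing.assert_allclose(apply_equating(e, [0, 1, 2]), [3, 4, 5])

    def test_out_of_range_extrapolates_with_boundary_slope(self, caplog):
        src = score_distribution([0, 1, 2, 3, 4], (0, 4))
        tgt = score_distribution([0, 2, 4, 6, 8], (0, 8))
        e = linear_equate(src, tgt)
        with caplog.at_level("WARNING"):
            out = apply_equating(e, [-1.0], clamp=False)
        assert out[0] == pytest.approx(-2.0, abs=1e-6)
        assert "outside source range" in caplog.text

    def test_crosswalk_table_columns(self, cohort_scale_dataset):
        ds = cohort_scale_dataset
        e = kernel_equate_single_group(ds.source_sums, ds.target_sums, (0, 10), (0, 22))
        table = crosswalk_table(e)
        assert list(table["source_score"]) == list(range(11))
        assert {"harmonized_target_score", "method", "bandwidth"} <= set(table.columns)
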