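"""Translocation dynamics: ratio invariances, peak timing, reporter fold,
segmentation, and rank correlations."""

import numpy as np
import pytest

from smstoich.nfkb import (
    correlate_dynamics,
    nc_ratio,
    reporter_fold_increase,
    segment_cell,
    series_from_stack,
    summarize_cell,
    time_to_first_peak,
)
from smstoich.simulate import CellTimeSeries, NfkbCellParams, \
    simulate_nfkb_cohort, simulate_nfkb_series


def make_series(nuc, cyt=None, red=None, dt=3.0, cell_id="c"):
    nuc = np.asarray(nuc, dtype=float)
    cyt = np.ones_like(nuc) * 100.0 if cyt is None else np.asarray(cyt, float)
    red = np.ones_like(nuc) * 50.0 if red is None else np.asarray(red, float)
    t = np.arange(nuc.size) * dt
    return CellTimeSeries(cell_id, t, nuc, cyt, red)


class TestNcRatio:
    def test_equal_channels_give_unity(self):
        s = make_series(np.full(20, 100.0))
        assert np.allclose(nc_ratio(s), 1.0)

    def test_double_nuclear_gives_two(self):
        s = make_series(np.full(20, 200.0))
        assert np.allclose(nc_ratio(s), 2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        nuc = rng.uniform(50, 300, 40)
        cyt = rng.uniform(50, 300, 40)
        a = nc_ratio(make_series(nuc, cyt))
        b = nc_ratio(make_series(7.3 * nuc, 7.3 * cyt))
        assert np.allclose(a, b)

    def test_invalid_points_become_gaps(self):
        s = make_series(np.full(10, 100.0))
        s.valid[3] = False
        r = nc_ratio(s)
        assert np.isnan(r[3]) and np.isfinite(r).sum() == 9

    def test_all_invalid_rejected(self):
        s = make_series(np.full(10, 100.0))
        s.valid[:] = False
        with pytest.raises(ValueError):
            nc_ratio(s)


class TestTimeToFirstPeak:
    def test_noiseless_peak_at_nearest_grid_sample(self):
        p = NfkbCellParams(t_peak_min=20.0, noise_sd=0.0)
        s = simulate_nfkb_series(p, 300.0, seed=0)
        responded, t_peak, mag = time_to_first_peak(s.t_min, nc_ratio(s))
        assert responded
        assert t_peak == 21.0  # 3-min grid starting at 0
        assert mag == pytest.approx(p.peak_ratio, rel=0.05)

    def test_flat_series_not_responded(self):
        responded, t, m = time_to_first_peak(np.arange(20) * 3.0, np.ones(20))
        assert not responded and t is None and m is None

    def test_monotone_series_not_responded(self):
        responded, _, _ = time_to_first_peak(np.arange(30) * 3.0,
                                             np.linspace(1, 3, 30))
        assert not responded

    def test_invariant_to_channel_rescaling(self):
        p = NfkbCellParams(t_peak_min=45.0, noise_sd=0.02)
        s = simulate_nfkb_series(p, 300.0, seed=5)
        r = nc_ratio(s)
        _, t1, _ = time_to_first_peak(s.t_min, r)
        _, t2, _ = time_to_first_peak(s.t_min, r)  # ratio already scale-free
        s2 = CellTimeSeries("c", s.t_min, 3.0 * s.nuclear_green,
                            3.0 * s.cytoplasm_green, s.red_reporter)
        _, t3, _ = time_to_first_peak(s2.t_min, nc_ratio(s2))
        assert t1 == t2 == t3

    def test_recovery_median_error_within_one_interval(self):
        series, truth = simulate_nfkb_cohort(200, seed=3, noise_sd=0.05,
                                             fold_link=None)
        errs = []
        for s, (_, row) in zip(series, truth.iterrows()):
            responded, t_peak, _ = time_to_first_peak(s.t_min, nc_ratio(s))
            if responded:
                errs.append(abs(t_peak - row.t_peak_min))
        assert len(errs) >= 190
        assert np.median(errs) <= 3.0

    def test_slope_of_estimated_vs_true_peak_time(self):
        # pooled across 20 seeds, regression slope in [0.9, 1.1]
        est, tru = [], []
        for seed in range(20):
            series, truth = simulate_nfkb_cohort(20, seed=seed, noise_sd=0.1,
                                                 fold_link=None)
            for s, (_, row) in zip(series, truth.iterrows()):
                responded, t_peak, _ = time_to_first_peak(s.t_min, nc_ratio(s))
                if responded:
                    est.append(t_peak)
                    tru.append(row.t_peak_min)
        slope = np.polyfit(tru, est, 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_needs_five_valid_points(self):
        with pytest.raises(ValueError):
            time_to_first_peak(np.arange(4) * 3.0, np.ones(4))


class TestReporterFold:
    def test_constant_channel_fold_one(self):
        s = make_series(np.full(30, 100.0), red=np.full(30, 40.0))
        assert reporter_fold_increase(s) == pytest.approx(1.0)

    def test_doubled_channel_fold_two(self):
        red = np.concatenate([np.full(15, 40.0), np.full(15, 80.0)])
        s = make_series(np.full(30, 100.0), red=red)
        assert reporter_fold_increase(s) == pytest.approx(2.0)

    def test_generator_fold_recovered_within_ten_percent(self):
        p = NfkbCellParams(reporter_fold=4.0, noise_sd=0.05)
        s = simulate_nfkb_series(p, 900.0, seed=2)
        assert reporter_fold_increase(s) == pytest.approx(4.0, rel=0.10)

    def test_nonpositive_baseline_rejected(self):
        s = make_series(np.full(30, 100.0), red=np.zeros(30))
        with pytest.raises(ValueError):
            reporter_fold_increase(s)


class TestSegmentation:
    def test_provided_masks_returned_verbatim(self):
        nuc = np.zeros((16, 16), bool); nuc[6:10, 6:10] = True
        cyt = np.zeros((16, 16), bool); cyt[2:14, 2:14] = True; cyt &= ~nuc
        out = segment_cell(np.zeros((16, 16)), provided_masks=(nuc, cyt))
        assert out.valid
        assert np.array_equal(out.nucleus_mask, nuc)
        assert np.array_equal(out.cytoplasm_mask, cyt)

    def test_blank_image_invalid(self):
        out = segment_cell(np.zeros((32, 32)))
        assert not out.valid

    def test_rendered_cell_jaccard_at_least_090(self):
        p = NfkbCellParams(t_peak_min=30.0, peak_ratio=2.5, noise_sd=0.0)
        s, stack, nuc, cyt = simulate_nfkb_series(p, 60.0, seed=0,
                                                  emit_images=True,
                                                  image_size=96)
        frame = stack[10, 0]  # near the translocation peak: nucleus bright
        out = segment_cell(frame)
        assert out.valid
        for est, true in ((out.nucleus_mask, nuc), (out.cytoplasm_mask, cyt)):
            jac = (est & true).sum() / (est | true).sum()
            assert jac >= 0.90

    def test_series_from_stack_matches_generator(self):
        p = NfkbCellParams(t_peak_min=30.0, noise_sd=0.0)
        s, stack, nuc, cyt = simulate_nfkb_series(p, 120.0, seed=0,
                                                  emit_images=True)
        s2 = series_from_stack(stack, nuc, cyt)
        ratio = nc_ratio(s2)
        expect = nc_ratio(s)
        assert np.allclose(ratio, expect, rtol=1e-5)


class TestCorrelations:
    def summaries(self, t_peaks, folds):
        out = []
        for i, (t, f) in enumerate(zip(t_peaks, folds)):
            s = summarize_cell  # noqa: F841 (constructed directly below)
            from smstoich.nfkb import TranslocationSummary
            out.append(TranslocationSummary(f"c{i}", True, t, 2.0, f))
        return out

    def test_perfect_monotone_decreasing_rho_minus_one(self):
        t = np.linspace(10, 100, 12)
        out = correlate_dynamics(self.summaries(t, 1.0 / t), "time_vs_fold")
        assert out["rho"] == pytest.approx(-1.0)
        assert not out["underpowered"]

    def test_independent_summaries_small_rho(self):
        # |rho| < 0.3 at n = 100 in >= 95% of seeds
        rng = np.random.default_rng(0)
        small = 0
        for _ in range(60):
            t = rng.uniform(10, 100, 100)
            f = rng.uniform(1, 6, 100)
            out = correlate_dynamics(self.summaries(t, f), "time_vs_fold")
            small += abs(out["rho"]) < 0.3
        assert small / 60 >= 0.95

    def test_constructed_cohort_significantly_negative(self):
        series, _ = simulate_nfkb_cohort(50, seed=7, noise_sd=0.05,
                                         fold_link="inverse")
        summaries = [summarize_cell(s) for s in series]
        out = correlate_dynamics(summaries, "time_vs_fold")
        assert out["rho"] < -0.5
        assert out["p_value"] < 0.001

    def test_underpowered_flag_below_five_cells(self):
        out = correlate_dynamics(self.summaries([10, 20, 30], [3, 2, 1]),
                                 "time_vs_fold")
        assert out["underpowered"]
        assert out["rho"] is not None
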