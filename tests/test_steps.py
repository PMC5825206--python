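"""Step counting: filter behaviour, exactness of the change-point fit
against an exhaustive oracle, Monte-Carlo recovery, and the quality-control
classification rules."""

import itertools
import math

import numpy as np
import pytest

from smstoich.simulate import simulate_trace
from smstoich.steps import (
    QCThresholds,
    StepFitResult,
    _dp_candidates,
    _selection_score,
    apply_qc,
    chung_kennedy_filter,
    fit_steps,
    fit_traces,
    population_fractions,
)


# ---------------------------------------------------------------------------
# exhaustive change-point oracle


def oracle_rss_per_k(y, k_max, min_seg):
    """Brute-force minimum RSS for every step count by enumerating all
    admissible change-point sets."""
    y = np.asarray(y, dtype=float)
    n = y.size
    c1 = np.concatenate(([0.0], np.cumsum(y)))
    c2 = np.concatenate(([0.0], np.cumsum(y * y)))

    def seg(a, b):
        s = c1[b] - c1[a]
        return (c2[b] - c2[a]) - s * s / (b - a)

    out_rss, out_cp = [], []
    for k in range(k_max + 1):
        best, best_cp = math.inf, None
        for cps in itertools.combinations(range(min_seg, n - min_seg + 1), k):
            if any(b - a < min_seg for a, b in zip(cps[:-1], cps[1:])):
                continue
            bounds = (0, *cps, n)
            rss = sum(seg(a, b) for a, b in zip(bounds[:-1], bounds[1:]))
            if rss < best - 1e-12:
                best, best_cp = rss, list(cps)
        out_rss.append(best)
        out_cp.append(best_cp)
    return np.array(out_rss), out_cp


def random_step_trace(rng, n=48, k=None, min_seg=3):
    """Noiseless piecewise-constant trace with distinct levels."""
    if k is None:
        k = int(rng.integers(0, 5))
    while True:
        cps = sorted(rng.choice(np.arange(min_seg, n - min_seg + 1),
                                size=k, replace=False))
        if all(b - a >= min_seg for a, b in zip(cps[:-1], cps[1:])):
            break
    levels = rng.permutation(np.arange(k + 1) * 120.0 + 50.0)
    y = np.empty(n)
    for lv, a, b in zip(levels, (0, *cps), (*cps, n)):
        y[a:b] = lv
    return y, list(map(int, cps))


class TestChungKennedy:
    def test_constant_trace_unchanged(self):
        y = np.full(50, 77.0)
        assert np.array_equal(chung_kennedy_filter(y, 8), y)

    def test_noiseless_step_preserved_exactly(self):
        y = np.where(np.arange(80) < 37, 200.0, 60.0)
        out = chung_kennedy_filter(y, 8, 2.0)
        assert np.allclose(out, y, atol=1e-9)

    def test_edge_sharper_than_boxcar(self):
        y = np.where(np.arange(80) < 40, 100.0, 0.0)
        ck = chung_kennedy_filter(y, 8, 2.0)
        box = np.convolve(y, np.ones(17) / 17, mode="same")
        mid = lambda v: ((v > 5) & (v < 95)).sum()
        assert mid(ck) < mid(box)
        assert mid(ck) == 0

    def test_variance_reduction_on_white_noise(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0.0, 3.0, 10_000)
        out = chung_kennedy_filter(y, 8, 2.0)
        assert out.var() < y.var()
        assert out.var() < 0.5 * y.var()

    def test_window_preconditions(self):
        with pytest.raises(ValueError):
            chung_kennedy_filter(np.zeros(50), window=1)
        with pytest.raises(ValueError):
            chung_kennedy_filter(np.zeros(10), window=8)


class TestFitSteps:
    def test_noiseless_single_step_exact(self):
        y = np.where(np.arange(100) < 50, 100.0, 0.0)
        fit = fit_steps(y)
        assert fit.n_steps == 1
        assert fit.step_frames == [50]
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.level_means == pytest.approx([100.0, 0.0])

    def test_flat_trace_zero_steps(self):
        rng = np.random.default_rng(1)
        fit = fit_steps(rng.normal(50.0, 2.0, 120))
        assert fit.n_steps == 0

    def test_dp_matches_exhaustive_rss_on_noisy_traces(self):
        # the DP is exact: per-step-count RSS equals brute-force enumeration
        rng = np.random.default_rng(7)
        for _ in range(8):
            y = rng.normal(0, 1, 30) + np.where(np.arange(30) < 14, 5.0, 0.0)
            rss_dp, _ = _dp_candidates(y[None, :], 3, 3)
            rss_bf, _ = oracle_rss_per_k(y, 3, 3)
            assert np.allclose(rss_dp[0], rss_bf, rtol=1e-9)

    @pytest.mark.parametrize("k", [0, 1, 2, 3, 4])
    def test_noiseless_recovery_matches_oracle_selection(self, k):
        # noiseless step fits are exact in count and location for up to 4
        # steps, and agree with the exhaustive oracle under the same
        # selection rule
        rng = np.random.default_rng(100 + k)
        for _ in range(5):
            y, true_cps = random_step_trace(rng, n=48, k=k)
            fit = fit_steps(y, k_max=5, prune_sd_multiplier=None)
            assert fit.n_steps == k
            assert fit.step_frames == true_cps
            rss_bf, cp_bf = oracle_rss_per_k(y, 5, 3)
            score = _selection_score(rss_bf, y.size, 3.0, float(np.ptp(y) or 1.0))
            assert int(np.argmin(score)) == k
            if k:
                assert cp_bf[k] == true_cps

    def test_rss_nonincreasing_in_step_count(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 60) + np.where(np.arange(60) < 25, 8.0, 0.0)
        rss, _ = _dp_candidates(y[None, :], 5, 3)
        finite = rss[0][np.isfinite(rss[0])]
        assert (np.diff(finite) <= 1e-9).all()

    def test_two_fluorophore_recovery_at_snr5(self):
        # >=90% of two-fluorophore traces fit with exactly 2 steps and
        # step-frame error <= 2 frames (two-stage fit, as in the pipeline)
        rng = np.random.default_rng(42)
        I, sd = 20000.0, 2926.0  # window-sum noise at single-fluorophore SNR 5
        raws, bleaches = [], []
        for _ in range(400):
            v, b = simulate_trace(2, I, 0.01, sd, 400, seed=rng)
            raws.append(v)
            bleaches.append(sorted(int(x) for x in b))
        R = np.vstack(raws)
        F = np.vstack([chung_kennedy_filter(v, 12, 2.0) for v in raws])
        fits = fit_traces(F, R, r2_span="balanced")
        resolvable = 0
        good = 0
        for fit, b in zip(fits, bleaches):
            if b[1] - b[0] < 3 or b[1] > 395:  # unresolvable or truncated
                continue
            resolvable += 1
            if fit.n_steps == 2 and max(abs(f - t) for f, t
                                        in zip(fit.step_frames, b)) <= 2:
                good += 1
        assert resolvable > 300
        assert good / resolvable >= 0.90


class TestApplyQC:
    def fit(self, **kw):
        base = dict(spot_id=0, n_steps=2, step_frames=[40, 80],
                    level_means=[200.0, 100.0, 0.0], r_squared=0.99,
                    residual_sd=5.0)
        base.update(kw)
        return StepFitResult(**base)

    def test_clean_two_step_accepted_as_dimer(self):
        out = apply_qc(self.fit())
        assert out.classification == "dimer"

    def test_single_step_is_monomer(self):
        out = apply_qc(self.fit(n_steps=1, step_frames=[40],
                                level_means=[100.0, 0.0]))
        assert out.classification == "monomer"

    def test_r_squared_below_threshold_rejected(self):
        out = apply_qc(self.fit(r_squared=0.90))
        assert out.classification == "rejected"

    def test_post_bleach_jump_rejected_by_displacement_rule(self):
        rng = np.random.default_rng(0)
        pos = np.tile([5.0, 5.0], (120, 1)) + rng.normal(0, 0.05, (120, 2))
        pos[40:] += 10.0  # spot "jumps" at the step
        fit = self.fit(n_steps=1, step_frames=[40], level_means=[100.0, 0.0])
        out = apply_qc(fit, pos)
        assert out.displacement_ok is False
        assert out.classification == "rejected"

    def test_immobile_spot_passes_displacement_rule(self):
        rng = np.random.default_rng(1)
        pos = np.tile([5.0, 5.0], (120, 1)) + rng.normal(0, 0.05, (120, 2))
        out = apply_qc(self.fit(), pos)
        assert out.displacement_ok is True

    def test_upward_step_rejected(self):
        out = apply_qc(self.fit(level_means=[100.0, 150.0, 0.0]))
        assert out.classification == "rejected"

    def test_incomplete_bleaching_rejected(self):
        out = apply_qc(self.fit(n_steps=1, step_frames=[40],
                                level_means=[200.0, 100.0]))
        assert out.classification == "rejected"

    def test_three_or_more_steps_is_multimer(self):
        out = apply_qc(self.fit(n_steps=3, step_frames=[20, 40, 60],
                                level_means=[300.0, 200.0, 100.0, 0.0]))
        assert out.classification == "multimer"

    def test_rejection_monotone_in_r2_threshold(self):
        rng = np.random.default_rng(5)
        fits = [self.fit(r_squared=float(r)) for r in rng.uniform(0.8, 1.0, 30)]
        accepted = []
        for r2_min in (0.85, 0.90, 0.95, 0.99):
            qc = QCThresholds(r2_min=r2_min)
            accepted.append({f.spot_id for i, f in enumerate(fits)
                             if apply_qc(self.fit(spot_id=i, r_squared=f.r_squared),
                                         qc=qc).classification != "rejected"})
        for a, b in zip(accepted[:-1], accepted[1:]):
            assert b <= a


class TestPopulationFractions:
    def mk(self, cls, cell=None):
        return StepFitResult(spot_id=0, n_steps=1, step_frames=[5],
                             level_means=[1.0, 0.0], r_squared=1.0,
                             residual_sd=0.0, classification=cls, cell_id=cell)

    def test_known_composition_exact(self):
        fits = [self.mk("monomer")] * 78 + [self.mk("dimer")] * 22
        out = population_fractions(fits)
        assert out["monomer_fraction"] == pytest.approx(0.78)
        assert out["dimer_fraction"] == pytest.approx(0.22)
        assert out["n_accepted"] == 100

    def test_all_monomers(self):
        out = population_fractions([self.mk("monomer")] * 10)
        assert out["monomer_fraction"] == 1.0
        assert out["dimer_fraction"] == 0.0

    def test_zero_accepted_flagged(self):
        out = population_fractions([self.mk("rejected")] * 5)
        assert out["dimer_fraction"] is None
        assert "flag" in out

    def test_sem_across_cells_when_labelled(self):
        fits = ([self.mk("monomer", "a")] * 8 + [self.mk("dimer", "a")] * 2
                + [self.mk("monomer", "b")] * 7 + [self.mk("dimer", "b")] * 3
                + [self.mk("monomer", "c")] * 9 + [self.mk("dimer", "c")] * 1)
        out = population_fractions(fits)
        per_cell = np.array([0.2, 0.3, 0.1])
        assert out["sem"] == pytest.approx(per_cell.std(ddof=1) / np.sqrt(3))

    def test_multimers_counted_separately(self):
        fits = [self.mk("monomer")] * 3 + [self.mk("dimer")] * 1 + \
            [self.mk("multimer")] * 2
        out = population_fractions(fits)
        assert out["n_accepted"] == 4
        assert out["n_multimer"] == 2
        assert out["dimer_fraction"] == pytest.approx(0.25)
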