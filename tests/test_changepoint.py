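"""Contiguous piecewise-linear fitting, learning-plateau detection and
minimum-test-time analysis."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from digibench.changepoint import (detect_learning_end, fit_piecewise,
                                   minimum_test_time, speed_change)
from digibench.scoring import sitting_scores
from digibench.simulate import (LearningCurveParams, generate_answer_stream,
                                generate_longitudinal,
                                generate_stream_cohort)


def brute_force_fit(x, y, k, min_seg=3):
    """Independent oracle: enumerate every admissible breakpoint
    placement on the candidate grid (interval midpoints and interior
    observations) and solve each by least squares on the linear-spline
    basis."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    cand = np.unique(np.concatenate([(x[:-1] + x[1:]) / 2, x[1:-1]]))
    best = (np.inf, None)
    for combo in combinations(cand, k):
        counts = np.searchsorted(x, combo, side="right")
        sizes = np.diff([0, *counts, n])
        if np.any(sizes < min_seg):
            continue
        A = np.column_stack([np.ones(n), x]
                            + [np.maximum(x - b, 0) for b in combo])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(np.sum((y - A @ beta) ** 2))
        if sse < best[0] - 1e-12:
            best = (sse, combo)
    return best


def piecewise_truth(x, breaks, slopes, intercept):
    y = np.full_like(x, float(intercept))
    y += slopes[0] * x
    for b, (s0, s1) in zip(breaks, zip(slopes, slopes[1:])):
        y += (s1 - s0) * np.maximum(x - b, 0)
    return y


class TestFitPiecewise:
    def test_exact_two_segment_recovery(self):
        x = np.arange(1, 21, dtype=float)
        y = np.where(x <= 8, 3 * x, 24.0)
        fit = fit_piecewise(x, y, 1)
        assert fit.breakpoints[0] == pytest.approx(8.0, abs=1e-6)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)
        assert fit.segments[0][0] == pytest.approx(3.0)
        assert fit.segments[1][0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_breakpoints_is_ols(self, rng):
        x = np.arange(10, dtype=float)
        y = 2 * x + 1 + rng.normal(0, 1, 10)
        fit = fit_piecewise(x, y, 0)
        slope, intercept = np.polyfit(x, y, 1)
        assert fit.segments[0] == pytest.approx((slope, intercept))
        assert fit.n_segments == 1 and fit.breakpoints == ()

    @pytest.mark.parametrize("k", [1, 2])
    def test_matches_exhaustive_oracle(self, rng, k):
        for _ in range(20):
            n = int(rng.integers(3 * (k + 1), 26))
            x = np.sort(rng.uniform(0, 10, n))
            x += np.arange(n) * 1e-6  # strictly increasing
            y = rng.normal(0, 1, n) + rng.uniform(-2, 2) * x
            fit = fit_piecewise(x, y, k, refine=False)
            sse_oracle, _ = brute_force_fit(x, y, k)
            assert fit.sse == pytest.approx(sse_oracle, rel=1e-9, abs=1e-9)

    def test_continuity_at_breakpoints(self, rng):
        for _ in range(10):
            x = np.arange(1, 26, dtype=float)
            y = piecewise_truth(x, [8, 17], [2.0, -1.0, 0.5], 5.0)
            y = y + rng.normal(0, 2, x.size)
            fit = fit_piecewise(x, y, 2)
            for b, (left, right) in zip(fit.breakpoints,
                                        zip(fit.segments, fit.segments[1:])):
                vl = left[1] + left[0] * b
                vr = right[1] + right[0] * b
                assert abs(vl - vr) < 1e-9

    def test_sse_monotone_in_breakpoints(self, rng):
        x = np.arange(1, 26, dtype=float)
        y = rng.normal(0, 3, x.size) + 0.5 * x
        sses = [fit_piecewise(x, y, k).sse for k in (0, 1, 2)]
        assert sses[1] <= sses[0] + 1e-9
        assert sses[2] <= sses[1] + 1e-9

    def test_too_few_points_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError):
            fit_piecewise(x, x, 1)

    def test_non_monotone_x_rejected(self):
        with pytest.raises(ValueError):
            fit_piecewise(np.array([1.0, 1.0, 2, 3, 4, 5, 6, 7, 8]),
                          np.zeros(9), 1)


class TestDetectLearningEnd:
    def test_noise_free_plateau_recovered_exactly(self):
        x = np.arange(1, 26, dtype=float)
        y = 40 - 3.0 * np.maximum(0, 8 - x)
        res = detect_learning_end(x, y)
        assert res.identified and res.sitting == 8

    def test_strictly_increasing_line_not_identified(self):
        x = np.arange(1, 26, dtype=float)
        res = detect_learning_end(x, 20 + 1.0 * x)
        assert not res.identified

    def test_min_sittings_enforced(self):
        x = np.arange(1, 11, dtype=float)
        with pytest.raises(ValueError):
            detect_learning_end(x, x)

    def test_noise_free_generator_recovery(self):
        """With zero session noise the sitting means are exactly the
        piecewise curve (trial contrast cancels in the mean), so the
        break is recovered exactly for every plateauing subject."""
        p = LearningCurveParams(session_noise_sd=0.0, trial_noise_sd=0.0,
                                trial2_advantage=0.0, learning_slope=3.0,
                                plateau_between_sd=0.0, seed=3)
        trials = generate_longitudinal(p)
        never = trials.attrs["never_plateau"]
        scores = sitting_scores(trials, "mean")
        for sid, grp in scores.groupby("subject_id"):
            res = detect_learning_end(grp["sitting"], grp["score_90s"])
            if never[sid]:
                assert not res.identified
            else:
                assert res.identified and res.sitting == p.break_sitting

    def test_all_never_plateau_reported_not_identified(self):
        p = LearningCurveParams(prop_never_plateau=1.0,
                                session_noise_sd=0.0, trial_noise_sd=0.0,
                                trial2_advantage=0.0, seed=5)
        trials = generate_longitudinal(p)
        scores = sitting_scores(trials, "mean")
        for _, grp in scores.groupby("subject_id"):
            res = detect_learning_end(grp["sitting"], grp["score_90s"])
            assert not res.identified

    def test_detection_rate_at_default_noise(self):
        """At the calibrated study conditions the plateau is found in a
        mean of at least 12.5 of 16 subjects (the clinical analysis
        found 14/16)."""
        identified = []
        for seed in range(20):
            trials = generate_longitudinal(LearningCurveParams(seed=seed))
            scores = sitting_scores(trials, "mean")
            n = sum(
                detect_learning_end(g["sitting"], g["score_90s"]).identified
                for _, g in scores.groupby("subject_id"))
            identified.append(n)
        assert np.mean(identified) >= 12.5


class TestMinimumTestTime:
    def test_exact_three_segment_curve_recovered(self):
        cutoffs = np.arange(5.0, 95.0, 5.0)
        rho = piecewise_truth(cutoffs, [40, 70], [0.012, 0.003, 0.0], 0.1)
        fit = fit_piecewise(cutoffs, rho, 2)
        assert fit.breakpoints[0] == pytest.approx(40, abs=0.5)
        assert fit.breakpoints[1] == pytest.approx(70, abs=0.5)
        assert fit.sse == pytest.approx(0.0, abs=1e-10)

    def test_grid_and_plateau_on_synthetic_cohort(self):
        st = generate_stream_cohort(n_subjects=40, seed=9)
        res = minimum_test_time(st)
        assert len(res.curve) == 18
        assert list(res.curve["cutoff_s"]) == list(np.arange(5.0, 95.0, 5.0))
        late = res.curve[res.curve["cutoff_s"] >= 60]["rho"]
        assert late.mean() == pytest.approx(0.9, abs=0.07)
        # reliability grows from short to long cutoffs
        assert res.curve["rho"].iloc[-3:].mean() > \
            res.curve["rho"].iloc[:3].mean()

    def test_requires_event_streams(self, longitudinal_default):
        with pytest.raises(ValueError, match="event stream"):
            minimum_test_time(longitudinal_default)


class TestSpeedChange:
    def test_uniform_stream_has_zero_difference(self):
        # 1 answer/s aligns exactly with both the 75-s and 90-s cutoffs
        ev = generate_answer_stream(1.0, 90, deterministic=True)
        trials = pd.DataFrame({
            "subject_id": ["a"], "trial": [1],
            "event_times": [tuple(ev)],
        })
        res = speed_change(trials)
        assert res.mean_diff == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_end_spurt_gives_positive_difference(self):
        st = generate_stream_cohort(n_subjects=60, seed=4,
                                    end_spurt_factor=1.2)
        flat = generate_stream_cohort(n_subjects=60, seed=4,
                                      end_spurt_factor=1.0)
        assert speed_change(st).mean_diff > speed_change(flat).mean_diff
        assert speed_change(st).mean_diff > 0
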