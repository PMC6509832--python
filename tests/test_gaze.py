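import math

import numpy as np
import pandas as pd
import pytest

from emotrace.aoi import AoI
from emotrace.config import ScreenGeometry
from emotrace.gaze import (
    delta_scores,
    detect_fixations,
    trial_indexes,
)

SCREEN = ScreenGeometry(1000, 1000)


def stream(points, hz=10.0, valid=None, t0=0.0):
    n = len(points)
    return pd.DataFrame(
        {
            "t_s": t0 + np.arange(n) / hz,
            "x_px": [p[0] for p in points],
            "y_px": [p[1] for p in points],
            "valid": valid if valid is not None else [1] * n,
        }
    )


class TestDetectFixations:
    def test_steady_gaze_single_fixation(self):
        samples = stream([(300, 300)] * 4)  # 300 ms span at 10 Hz
        fixations = detect_fixations(samples, 60, 0.1)
        assert len(fixations) == 1
        assert fixations[0].centroid_px == (300.0, 300.0)
        assert fixations[0].duration_s == pytest.approx(0.3)

    def test_alternating_far_points_no_fixation(self):
        samples = stream([(0, 0), (900, 900)] * 10)
        assert detect_fixations(samples, 60, 0.1) == []

    def test_empty_stream(self):
        assert detect_fixations(stream([]), 60, 0.1) == []

    def test_invalid_samples_break_runs(self):
        pts = [(100, 100)] * 9
        valid = [1, 1, 1, 1, 0, 1, 1, 1, 1]
        fixations = detect_fixations(stream(pts, valid=valid), 60, 0.1)
        assert len(fixations) == 2

    def _oracle(self, t, x, y, disp, mind):
        """Independent greedy I-DT: recompute window dispersion from
        scratch at every step (no incremental state)."""
        out = []
        i, n = 0, len(t)
        while i < n:
            j = i
            while j < n and t[j] - t[i] < mind:
                j += 1
            if j >= n:
                break

            def dispersion(a, b):
                return (max(x[a : b + 1]) - min(x[a : b + 1])) + (
                    max(y[a : b + 1]) - min(y[a : b + 1])
                )

            if dispersion(i, j) > disp:
                i += 1
                continue
            while j + 1 < n and dispersion(i, j + 1) <= disp:
                j += 1
            out.append((i, j))
            i = j + 1
        return out

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle_on_jittered_clusters(self, seed):
        rng = np.random.default_rng(seed)
        pts = []
        for cx, cy in [(200, 200), (700, 600), (250, 210)]:
            k = rng.integers(3, 10)
            pts += [
                (cx + rng.normal(0, 15), cy + rng.normal(0, 15)) for _ in range(k)
            ]
        samples = stream(pts)
        got = detect_fixations(samples, 60, 0.1)
        t = samples["t_s"].to_numpy()
        x = samples["x_px"].to_numpy()
        y = samples["y_px"].to_numpy()
        expected = self._oracle(t, x, y, 60, 0.1)
        assert len(got) == len(expected)
        for fix, (i, j) in zip(got, expected):
            assert fix.start_s == pytest.approx(t[i])
            assert fix.end_s == pytest.approx(t[j])
            assert fix.centroid_px[0] == pytest.approx(np.mean(x[i : j + 1]))


AOI_A = AoI("A", "stim", "experimental", ((0, 0, 100, 100),))
AOI_B = AoI("B", "stim", "experimental", ((900, 900, 1000, 1000),))


def scripted_trial():
    """10-sample trial visiting both AoIs; every value hand-computable."""
    pts = (
        [(500, 500)]
        + [(50, 50)] * 3
        + [(950, 950)] * 3
        + [(500, 500), (10, 900), (990, 10)]
    )
    return stream(pts)


class TestTrialIndexes:
    def test_all_samples_inside_single_aoi(self):
        samples = stream([(50, 60)] * 6)
        fixations = detect_fixations(samples, 60, 0.1)
        idx = trial_indexes(fixations, samples, [AOI_A], SCREEN, 0.0)
        assert idx.raw_prop_gaze == 1.0
        assert idx.prop_gaze == pytest.approx(1.0 / 0.01)

    def test_area_correction_contract(self):
        half = AoI("H", "stim", "experimental", ((0, 0, 1000, 500),))
        pts = [(500, 250)] * 2 + [(500, 800)] * 3  # 2 of 5 inside
        samples = stream(pts)
        idx = trial_indexes([], samples, [half], SCREEN, 0.0)
        assert idx.raw_prop_gaze == pytest.approx(0.4)
        assert idx.prop_gaze == pytest.approx(0.8)

    def test_scripted_two_aoi_trial_matches_hand_computation(self):
        samples = scripted_trial()
        fixations = detect_fixations(samples, 60, 0.1)
        assert len(fixations) == 2
        idx = trial_indexes(fixations, samples, [AOI_A, AOI_B], SCREEN, 0.0)
        # per-sample tabulation: 3 samples in A, 3 in B, 10 valid
        assert idx.raw_prop_gaze == pytest.approx(0.6)
        # one 0.2 s fixation in each AoI; mean over AoIs
        assert idx.raw_mean_time == pytest.approx(0.2)
        # per-AoI first-fixation start times 0.1 (A) and 0.4 (B), summed
        assert idx.raw_time_1st_fix == pytest.approx(0.5)
        # per-AoI first-fixation durations 0.2 + 0.2, summed
        assert idx.raw_fix1_duration == pytest.approx(0.4)
        # corrections: family area fraction 0.02; distance from the first
        # gaze sample (500,500) to AoI A's nearest corner (100,100)
        assert idx.prop_gaze == pytest.approx(0.6 / 0.02)
        assert idx.mean_time == pytest.approx(0.2 / 0.02)
        assert idx.fix1_duration == pytest.approx(0.4 / 0.02)
        dist = math.hypot(400, 400)
        assert idx.time_1st_fix == pytest.approx(0.5 / dist)

    def test_prop_gaze_fixation_mode(self):
        samples = scripted_trial()
        fixations = detect_fixations(samples, 60, 0.1)
        idx = trial_indexes(
            fixations, samples, [AOI_A], SCREEN, 0.0, prop_gaze_mode="fixations"
        )
        assert idx.raw_prop_gaze == pytest.approx(0.5)  # 1 of 2 fixations

    def test_no_fixation_in_aoi_yields_missing_not_zero(self):
        samples = stream([(500, 500)] * 5)
        fixations = detect_fixations(samples, 60, 0.1)
        idx = trial_indexes(fixations, samples, [AOI_A], SCREEN, 0.0)
        assert math.isnan(idx.raw_time_1st_fix)
        assert math.isnan(idx.time_1st_fix)
        assert math.isnan(idx.raw_fix1_duration)
        assert idx.raw_mean_time == 0.0

    def test_partition_prop_gaze_sums_to_one(self):
        rng = np.random.default_rng(3)
        pts = list(zip(rng.uniform(0, 999, 50), rng.uniform(0, 999, 50)))
        samples = stream(pts)
        parts = [
            AoI("q1", "stim", "experimental", ((0, 0, 500, 500),)),
            AoI("q2", "stim", "experimental", ((500, 0, 1000, 500),)),
            AoI("q3", "stim", "experimental", ((0, 500, 500, 1000),)),
            AoI("q4", "stim", "experimental", ((500, 500, 1000, 1000),)),
        ]
        total = sum(
            trial_indexes([], samples, [p], SCREEN, 0.0).raw_prop_gaze
            for p in parts
        )
        assert total == pytest.approx(1.0)

    def test_time_1st_fix_non_increasing_for_nested_aoi(self):
        samples = scripted_trial()
        fixations = detect_fixations(samples, 60, 0.1)
        small = AoI("s", "stim", "experimental", ((0, 0, 100, 100),))
        large = AoI("l", "stim", "experimental", ((0, 0, 1000, 1000),))
        t_small = trial_indexes(fixations, samples, [small], SCREEN, 0.0)
        t_large = trial_indexes(fixations, samples, [large], SCREEN, 0.0)
        assert t_large.raw_time_1st_fix <= t_small.raw_time_1st_fix

    def test_onset_relative_timing(self):
        samples = stream([(500, 500)] * 2 + [(50, 50)] * 4, t0=100.0)
        fixations = detect_fixations(samples, 60, 0.1)
        idx = trial_indexes(fixations, samples, [AOI_A], SCREEN, 100.0)
        assert idx.raw_time_1st_fix == pytest.approx(0.2)


class TestDeltaScores:
    def _sets(self):
        samples = scripted_trial()
        fixations = detect_fixations(samples, 60, 0.1)
        pilot_aoi = AoI("p", "stim", "pilot", ((0, 0, 200, 200), (900, 900, 1000, 1000)))
        exp = trial_indexes(fixations, samples, [AOI_A, AOI_B], SCREEN, 0.0)
        pil = trial_indexes(fixations, samples, [pilot_aoi], SCREEN, 0.0)
        return pil, exp

    def test_identical_sets_zero_deltas(self):
        _, exp = self._sets()
        exp_as_pilot = type(exp)(
            **{**exp.__dict__, "aoi_kind": "pilot"}
        )
        deltas = delta_scores(exp_as_pilot, exp)
        assert deltas.prop_gaze == 0.0
        assert deltas.mean_time == 0.0

    def test_sign_convention(self):
        pil, exp = self._sets()
        deltas = delta_scores(pil, exp)
        assert deltas.prop_gaze == pytest.approx(pil.prop_gaze - exp.prop_gaze)
        # scripted gaze sits inside the experimental regions, so the
        # area-corrected pilot values are smaller: negative deltas mean a
        # focus on the detailed socio-emotional content
        assert deltas.prop_gaze < 0

    def test_kind_mismatch_rejected(self):
        pil, exp = self._sets()
        with pytest.raises(ValueError):
            delta_scores(exp, pil)

    def test_missing_propagates(self):
        samples = stream([(500, 500)] * 5)
        fixations = detect_fixations(samples, 60, 0.1)
        pilot_aoi = AoI("p", "stim", "pilot", ((0, 0, 200, 200),))
        exp = trial_indexes(fixations, samples, [AOI_A], SCREEN, 0.0)
        pil = trial_indexes(fixations, samples, [pilot_aoi], SCREEN, 0.0)
        assert math.isnan(delta_scores(pil, exp).time_1st_fix)
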