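import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scgbeat as sb
from scgbeat import (
    PeakTrain,
    compute_hr,
    compute_prf,
    evaluate_episode,
    grid_to_frame,
    interval_difference,
    match_peaks,
    run_grid,
    trim_peaks,
)
from scgbeat.detect import register_detector, get_detector
from scgbeat.synth import DEFAULT_CHANNEL, generate_record, rest_preset

FS = 1000.0


def match_bruteforce(r: PeakTrain, j: PeakTrain):
    """Literal enumeration of every (interval, peak) containment."""
    tp = fp = fn = 0
    for a, b in zip(r.indices[:-1], r.indices[1:]):
        contained = [p for p in j.indices if a <= p < b]
        if contained:
            tp += 1
            fp += len(contained) - 1
        else:
            fn += 1
    return tp, fp, fn


class TestTrim:
    def test_trimming_rule(self):
        r = PeakTrain([1000, 2000, 3000], FS)
        j = PeakTrain([500, 1500, 2500, 3500], FS)
        assert trim_peaks(j, r).indices.tolist() == [1500, 2500]

    def test_all_before_first_reference(self):
        r = PeakTrain([1000, 2000], FS)
        j = PeakTrain([100, 200], FS)
        assert len(trim_peaks(j, r)) == 0

    def test_idempotent(self):
        r = PeakTrain([1000, 2000, 3000], FS)
        j = PeakTrain([500, 1500, 2999, 3001], FS)
        once = trim_peaks(j, r)
        twice = trim_peaks(once, r)
        assert np.array_equal(once.indices, twice.indices)

    def test_requires_two_reference_peaks(self):
        with pytest.raises(ValueError, match="2 peaks"):
            trim_peaks(PeakTrain([5], FS), PeakTrain([3], FS))


class TestMatch:
    def test_one_peak_per_interval(self):
        r = PeakTrain([1000, 2000, 3000], FS)
        m = match_peaks(r, PeakTrain([1400, 2500], FS))
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)

    def test_second_peak_in_interval_is_fp(self):
        r = PeakTrain([1000, 2000, 3000], FS)
        m = match_peaks(r, PeakTrain([1200, 1600, 2500], FS))
        assert (m.tp, m.fp, m.fn) == (2, 1, 0)
        assert m.assignments == ((1200, 1600), (2500,))

    def test_untrimmed_train_rejected(self):
        r = PeakTrain([1000, 2000], FS)
        with pytest.raises(ValueError, match="trimmed"):
            match_peaks(r, PeakTrain([500, 1500], FS))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            nr = int(rng.integers(2, 50))
            r_idx = np.cumsum(rng.integers(200, 1500, size=nr))
            r = PeakTrain(r_idx, FS)
            nj = int(rng.integers(0, 50))
            lo, hi = r_idx[0], r_idx[-1]
            j_idx = np.unique(rng.integers(lo, hi, size=nj)) if nj else np.empty(0, int)
            j = PeakTrain(j_idx, FS)
            m = match_peaks(r, j)
            assert (m.tp, m.fp, m.fn) == match_bruteforce(r, j)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        r_gaps=st.lists(st.integers(200, 2000), min_size=2, max_size=30),
        j_rel=st.lists(st.floats(0.0, 1.0 - 1e-9), min_size=0, max_size=40),
    )
    def test_count_identities_always_hold(self, r_gaps, j_rel):
        r_idx = np.cumsum(r_gaps)
        r = PeakTrain(r_idx, FS)
        span = r_idx[-1] - r_idx[0]
        j_idx = np.unique((r_idx[0] + np.asarray(j_rel) * span).astype(int))
        j_idx = j_idx[j_idx < r_idx[-1]]
        m = match_peaks(r, PeakTrain(j_idx, FS))
        assert m.tp + m.fn == len(r) - 1
        assert m.tp + m.fp == len(j_idx)
        assert m.tp <= len(r) - 1

    def test_global_shift_invariance(self):
        r = PeakTrain([1000, 2000, 3000, 4000], FS)
        j = PeakTrain([1100, 2100, 3900], FS)
        m0 = match_peaks(r, j)
        shift = 12_345
        m1 = match_peaks(
            PeakTrain(r.indices + shift, FS), PeakTrain(j.indices + shift, FS)
        )
        assert (m0.tp, m0.fp, m0.fn) == (m1.tp, m1.fp, m1.fn)

    def test_drop_last_reference_variant(self):
        r = PeakTrain([1000, 2000, 3000], FS)
        j = PeakTrain([1500, 2500], FS)
        m = match_peaks(r, j, drop_last_reference=True)
        assert m.tp + m.fn == 1  # one interval left


class TestScores:
    def test_formula(self):
        m = match_peaks(PeakTrain([0, 1000, 2000], FS), PeakTrain([100, 400, 1500], FS))
        s = compute_prf(m)
        assert s.precision == pytest.approx(66.7, abs=0.05)
        assert s.recall == 100.0
        assert s.f1 == pytest.approx(0.8)

    def test_no_detections_recall_zero(self):
        r = PeakTrain(np.arange(6) * 1000, FS)
        with pytest.warns(UserWarning, match="precision undefined"):
            s = compute_prf(match_peaks(r, PeakTrain(np.empty(0, int), FS)))
        assert s.recall == 0.0
        assert s.f1 == 0.0
        assert s.precision_undefined

    def test_perfect_detection_scores(self):
        # 9 matched beats -> precision 100%, recall 100%, F1 1.00
        r = PeakTrain(np.arange(10) * 1000, FS)
        j = PeakTrain(np.arange(9) * 1000 + 400, FS)
        s = compute_prf(match_peaks(r, j))
        assert s.precision == 100.0
        assert s.recall == 100.0
        assert s.f1 == 1.0


class TestHeartRate:
    @pytest.mark.parametrize("period_ms,expected", [(1000, 60.0), (500, 120.0)])
    def test_periodic(self, period_ms, expected):
        p = PeakTrain(np.arange(10) * period_ms, FS)
        assert compute_hr(p) == pytest.approx(expected)

    def test_mean_interval_formula(self):
        p = PeakTrain(np.cumsum([0, 800, 900, 1000]), FS)
        assert compute_hr(p) == pytest.approx(60.0 / 0.9, abs=0.01)

    def test_needs_two_peaks(self):
        with pytest.raises(ValueError):
            compute_hr(PeakTrain([5], FS))

    def test_concatenation_of_identical_periodic_episodes(self):
        one = PeakTrain(np.arange(50) * 900, FS)
        both = PeakTrain(np.arange(100) * 900, FS)
        assert compute_hr(one) == pytest.approx(compute_hr(both))


class TestEvaluateEpisode:
    def test_clean_synthetic_is_perfect(self):
        rec, truth = generate_record(rest_preset(seed=11, noise_sd=0.0))
        m = evaluate_episode(
            rec.ecg, rec.scg[DEFAULT_CHANNEL], "hamilton2002", "nabian2018",
            r_peaks=truth.r_train(),
        )
        assert m.f1 == 1.0
        assert m.hr_diff < 0.5

    def test_self_agreement_when_scg_is_ecg(self):
        rec, _ = generate_record(rest_preset(seed=12, noise_sd=0.0))
        m = evaluate_episode(rec.ecg, rec.ecg, "neurokit", "neurokit")
        assert m.f1 == 1.0

    def test_count_identity_on_noise_channel(self):
        rec, truth = generate_record(rest_preset(seed=13))
        rng = np.random.default_rng(0)
        noise = rec.scg[DEFAULT_CHANNEL].with_samples(
            rng.standard_normal(rec.n_samples)
        )
        m = evaluate_episode(rec.ecg, noise, "hamilton2002", "nabian2018",
                             r_peaks=truth.r_train())
        assert m.tp + m.fn == len(truth.r_train()) - 1


class TestIntervalDifference:
    def test_constant_latency_cancels(self):
        r = PeakTrain(np.cumsum([1000, 900, 950, 1000, 870]), FS)
        j = PeakTrain(r.indices + 120, FS)
        stats = interval_difference(r, j)
        assert stats["mean_abs_diff_ms"] == pytest.approx(0.0)

    def test_alternating_jitter(self):
        r = PeakTrain(np.arange(10) * 1000, FS)
        jit = np.tile([10, -10], 5)[:10]
        j = PeakTrain(np.arange(10) * 1000 + 200 + jit, FS)
        stats = interval_difference(r, j)
        assert stats["mean_abs_diff_ms"] == pytest.approx(20.0)

    def test_unpaired_intervals_reported(self):
        r = PeakTrain(np.arange(10) * 1000, FS)
        j = PeakTrain(np.arange(8) * 1000 + 300, FS)
        stats = interval_difference(r, j)
        assert stats["n_dropped"] == 2

    def test_monte_carlo_small_jitter(self):
        diffs = []
        for seed in range(20):
            rec, truth = generate_record(rest_preset(seed=seed, noise_sd=0.0))
            j = get_detector("nabian2018")(
                sb.apply_pipeline(rec.scg[DEFAULT_CHANNEL], "hamilton2002")
            )
            jt = trim_peaks(j, truth.r_train())
            diffs.append(interval_difference(truth.r_train(), jt)["mean_abs_diff_ms"])
        assert 1.5 <= float(np.mean(diffs)) <= 4.5


@pytest.fixture(scope="module")
def long_record():
    return generate_record(rest_preset(seed=21, duration_s=200.0))[0]


class TestGrid:
    def test_factorial_counting(self, long_record):
        rows = run_grid([long_record, long_record], ["hamilton2002", "raw"],
                        ["nabian2018", "neurokit"], episodes_per_record=5,
                        episode_s=30.0, seed=1, channel=DEFAULT_CHANNEL)
        assert len(rows) == 4
        assert all(len(r.episode_metrics) == 10 for r in rows)

    def test_seed_determinism(self, long_record):
        kw = dict(episodes_per_record=3, episode_s=30.0, seed=5,
                  channel=DEFAULT_CHANNEL)
        a = grid_to_frame(run_grid([long_record], ["hamilton2002"], ["nabian2018"], **kw))
        b = grid_to_frame(run_grid([long_record], ["hamilton2002"], ["nabian2018"], **kw))
        assert a.equals(b)

    def test_degraded_detector_ranks_below_original(self, long_record):
        def degraded(sig):
            train = get_detector("nabian2018")(sig)
            return PeakTrain(np.delete(train.indices, np.arange(0, len(train), 10)),
                             train.fs)

        register_detector("nabian_degraded", degraded, overwrite=True)
        rows = run_grid([long_record], ["hamilton2002"],
                        ["nabian2018", "nabian_degraded"], episodes_per_record=5,
                        episode_s=30.0, seed=2, channel=DEFAULT_CHANNEL)
        order = [r.detector for r in rows]
        assert order.index("nabian2018") < order.index("nabian_degraded")
        assert rows[0].hr_diff_mean <= rows[-1].hr_diff_mean

    def test_aggregates_recomputable_from_episodes(self, long_record):
        rows = run_grid([long_record], ["hamilton2002"], ["nabian2018"],
                        episodes_per_record=4, episode_s=30.0, seed=3,
                        channel=DEFAULT_CHANNEL)
        row = rows[0]
        vals = [m.hr_diff for m in row.episode_metrics if m is not None]
        assert row.hr_diff_mean == pytest.approx(float(np.mean(vals)))

    def test_failing_detector_is_flagged_not_fatal(self, long_record):
        def broken(sig):
            raise ValueError("always fails")

        register_detector("always_fails", broken, overwrite=True)
        rows = run_grid([long_record], ["raw"], ["always_fails"],
                        episodes_per_record=2, episode_s=30.0, seed=4,
                        channel=DEFAULT_CHANNEL)
        assert rows[0].all_failed
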