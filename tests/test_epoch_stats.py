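import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pupilcf import (
    EpochSamples,
    TaskComparison,
    analyze_recording,
    compare_task,
    evaluate_subject,
    rank_test,
    segment,
)
from pupilcf.epoch_stats import RANK_SUM, SIGNED_RANK, _symmetric_trim
from pupilcf.errors import ValidationError
from pupilcf.recording import Epoch, PupilRecording, PupilSample, build_schedule
from pupilcf.synthetic import SimulationParams, simulate_recording

from .oracles import rank_sum_exact_p, signed_rank_exact_p


def _epoch(kind="task", index=1, start=0.0, end=30.0):
    return Epoch(kind, index, start, end)


def _es(diameters, kind="task", index=1):
    return EpochSamples(epoch=_epoch(kind, index), diameters=np.asarray(diameters))


class TestSegment:
    def test_full_recording_fills_all_epochs(self, responder_recording, moderate_schedule):
        parts = segment(responder_recording, moderate_schedule)
        assert len(parts) == 11
        for es in parts:
            # 30 s at 30 Hz, minus the occasional blink dropout
            assert 850 <= es.n <= 900
        assert sum(es.n for es in parts) == responder_recording.n_valid

    def test_boundary_sample_goes_to_later_epoch(self, moderate_schedule):
        rec = PupilRecording(
            subject_id="b",
            samples=(PupilSample(29.9, 4.0), PupilSample(30.0, 5.0)),
        )
        with pytest.warns(UserWarning, match="ends at"):
            parts = segment(rec, moderate_schedule)
        assert parts[0].n == 1 and parts[0].diameters[0] == 4.0
        assert parts[1].n == 1 and parts[1].diameters[0] == 5.0

    def test_all_invalid_recording_yields_empty_epochs(self, moderate_schedule):
        samples = tuple(
            PupilSample(t, float("nan"), valid=False) for t in np.arange(0, 330, 1.0)
        )
        parts = segment(
            PupilRecording(subject_id="inv", samples=samples), moderate_schedule
        )
        assert len(parts) == 11
        assert all(es.n == 0 for es in parts)


class TestRankTestExamples:
    def test_rank_sum_one_sided_enumeration_value(self):
        # {4,5,6} vs {1,2,3}: only 1 of C(6,3)=20 assignments is as extreme
        res = rank_test([4, 5, 6], [1, 2, 3], method=RANK_SUM, alternative="greater")
        assert res.pvalue == pytest.approx(1 / 20)

    def test_signed_rank_all_positive_pairs(self):
        # 5 positive differences: 1 of 2^5=32 sign patterns is as extreme
        x = [5.1, 5.2, 5.3, 5.4, 5.5]
        y = [4.1, 4.25, 4.15, 4.35, 4.42]  # distinct difference magnitudes
        res = rank_test(x, y, method=SIGNED_RANK, alternative="greater")
        assert res.pvalue == pytest.approx(1 / 32)

    @pytest.mark.parametrize("method", [RANK_SUM, SIGNED_RANK])
    def test_identical_samples_give_p_one(self, method, rng):
        x = rng.normal(4.5, 0.2, 30)
        res = rank_test(x, x, method=method, alternative="two_sided")
        assert res.pvalue == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_differences_flagged_degenerate(self):
        res = rank_test([4.0, 4.0], [4.0, 4.0], method=SIGNED_RANK)
        assert res.degenerate and res.pvalue == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            rank_test([], [1.0])

    def test_symmetric_trim_removes_front_then_back(self):
        v = np.arange(10.0)
        assert list(_symmetric_trim(v, 7)) == [1, 2, 3, 4, 5, 6, 7]
        assert list(_symmetric_trim(v, 10)) == list(v)


class TestRankTestOracleEquivalence:
    """The exact branches must equal brute-force null-distribution enumeration."""

    @given(st.data())
    def test_rank_sum_matches_enumeration(self, data):
        n1 = data.draw(st.integers(1, 6))
        n2 = data.draw(st.integers(1, 6))
        vals = data.draw(
            st.lists(st.integers(-50, 50), min_size=n1 + n2, max_size=n1 + n2, unique=True)
        )
        alt = data.draw(st.sampled_from(["two_sided", "greater"]))
        x, y = np.array(vals[:n1], float), np.array(vals[n1:], float)
        res = rank_test(x, y, method=RANK_SUM, alternative=alt)
        assert res.pvalue == pytest.approx(rank_sum_exact_p(x, y, alt))

    @given(st.data())
    def test_signed_rank_matches_enumeration(self, data):
        n = data.draw(st.integers(1, 10))
        mags = data.draw(
            st.lists(st.integers(1, 60), min_size=n, max_size=n, unique=True)
        )
        signs = data.draw(st.lists(st.sampled_from([-1, 1]), min_size=n, max_size=n))
        alt = data.draw(st.sampled_from(["two_sided", "greater"]))
        d = np.array(mags, float) * np.array(signs)
        x = 4.0 + d
        y = np.full(n, 4.0)
        res = rank_test(x, y, method=SIGNED_RANK, alternative=alt)
        assert res.pvalue == pytest.approx(signed_rank_exact_p(d, alt))


class TestMonotonicity:
    def test_shifting_task_up_never_hurts(self, rng):
        task = rng.normal(4.6, 0.1, 40)
        rest = rng.normal(4.6, 0.1, 80)
        prev_p = None
        for c in [0.0, 0.05, 0.1, 0.3]:
            res = rank_test(task + c, rest, method=RANK_SUM, alternative="greater")
            if prev_p is not None:
                assert res.pvalue <= prev_p + 1e-12
            prev_p = res.pvalue


class TestCompareTask:
    def test_clear_separation_is_significant(self, rng):
        task = _es(rng.normal(5.1, 0.05, 900))
        rb = _es(rng.normal(4.6, 0.05, 900), kind="rest")
        ra = _es(rng.normal(4.6, 0.05, 900), kind="rest", index=2)
        c = compare_task(task, rb, ra)
        assert c.dilated and c.significant_dilation
        assert c.p_adj < 1e-4
        assert c.median_task_mm == pytest.approx(5.1, abs=0.02)
        assert c.n_rest == 1800

    def test_constant_trace_not_dilated(self):
        const = [4.0] * 50
        c = compare_task(_es(const), _es(const, "rest"), _es(const, "rest", 2))
        assert not c.dilated and not c.significant_dilation

    def test_threshold_logic_dilated_but_not_significant(self, rng):
        # small shift, tiny n: direction right but p above alpha
        task = _es([4.62, 4.63, 4.61])
        rb = _es([4.60, 4.59], "rest")
        ra = _es([4.61, 4.58], "rest", 2)
        c = compare_task(task, rb, ra)
        assert c.dilated and c.p_adj > 0.01 and not c.significant_dilation

    def test_both_mode_takes_worse_p(self, rng):
        task = _es(rng.normal(5.0, 0.05, 100))
        rb = _es(rng.normal(4.5, 0.05, 100), "rest")
        ra = _es(rng.normal(4.95, 0.05, 100), "rest", 2)
        pooled = compare_task(task, rb, ra, rest_pooling="pooled")
        both = compare_task(task, rb, ra, rest_pooling="both")
        assert both.p_raw >= pooled.p_raw

    def test_empty_epoch_identified(self):
        with pytest.raises(ValidationError, match="rest_after"):
            compare_task(_es([4.0, 4.1]), _es([4.0, 4.1], "rest"), _es([], "rest", 2))

    def test_invariant_significant_implies_dilated(self):
        with pytest.raises(ValidationError):
            TaskComparison(
                task_index=1, n_task=10, n_rest=20,
                median_task_mm=4.0, median_rest_mm=4.5,
                statistic=0.0, p_raw=0.001, p_adj=0.005,
                dilated=False, significant_dilation=True,
            )


def _comparison(sig, idx=1):
    return TaskComparison(
        task_index=idx, n_task=900, n_rest=1800,
        median_task_mm=5.0 if sig else 4.5, median_rest_mm=4.5,
        statistic=1.0, p_raw=0.0001 if sig else 0.5,
        p_adj=0.0005 if sig else 1.0,
        dilated=sig, significant_dilation=sig,
    )


class TestEvaluateSubject:
    @pytest.mark.parametrize(
        "flags, expected",
        [
            ([1, 1, 1, 1, 0], True),
            ([1, 1, 1, 0, 0], False),
            ([0, 0, 0, 0, 0], False),
            ([1, 1, 1, 1, 1], True),
        ],
    )
    def test_four_of_five_rule(self, flags, expected):
        comps = [_comparison(bool(f), i + 1) for i, f in enumerate(flags)]
        res = evaluate_subject(comps, subject_id="s")
        assert res.command_following is expected
        assert res.n_significant == sum(flags)

    def test_permutation_invariant(self):
        comps = [_comparison(bool(f), i + 1) for i, f in enumerate([1, 1, 0, 1, 1])]
        outcomes = {
            evaluate_subject(list(p)).command_following
            for p in itertools.permutations(comps)
        }
        assert outcomes == {True}

    def test_configurable_k(self):
        comps = [_comparison(bool(f), i + 1) for i, f in enumerate([1, 1, 1, 1, 0])]
        assert evaluate_subject(comps, k=4).command_following
        assert not evaluate_subject(comps, k=5).command_following

    def test_requires_exactly_five(self):
        with pytest.raises(ValidationError):
            evaluate_subject([_comparison(True)] * 4)


class TestAnalyzeRecording:
    def test_responder_detected_end_to_end(self, responder_recording, moderate_schedule):
        res = analyze_recording(responder_recording, moderate_schedule)
        assert res.n_significant == 5
        assert res.command_following
        assert all(c.significant_dilation for c in res.comparisons)

    def test_signed_rank_method_also_detects_responder(
        self, responder_recording, moderate_schedule
    ):
        res = analyze_recording(
            responder_recording, moderate_schedule, method=SIGNED_RANK
        )
        assert res.command_following
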