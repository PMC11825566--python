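"""Filtering, quantiles, delta-curve decomposition and CAF analyses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import conflictdelta as cd
from conflictdelta.core_design import Congruency, ResponseFocus, TrialRecord
from conflictdelta.delta_analysis import (
    EIGHT_BIN_GRID,
    TEN_BIN_GRID,
    caf_curves,
    condition_summaries,
    filter_trials,
    group_delta_curve,
    participant_delta_curve,
    rt_quantiles,
    vincentize,
)


def _make_records(pid, rts_by_cond, correct_by_cond=None, focus=ResponseFocus.BALANCED):
    """Hand-built trial records for one participant and focus."""
    records = []
    idx = 0
    for cond, rts in rts_by_cond.items():
        flags = correct_by_cond.get(cond) if correct_by_cond else [True] * len(rts)
        for rt, ok in zip(rts, flags):
            records.append(
                TrialRecord(
                    participant_id=pid,
                    task="flanker",
                    focus=focus,
                    congruency=cond,
                    block_index=0,
                    trial_index=idx,
                    rt=rt,
                    correct=ok,
                    deadline=2500.0,
                    exceeded_deadline=False,
                    flagged_fast=rt is not None and rt < 150,
                )
            )
            idx += 1
    return records


SAMPLE = {c: [300.0 + 10 * i for i in range(20)] for c in Congruency}


class TestFiltering:
    def test_clean_log_keeps_everyone(self):
        aset = filter_trials(_make_records("P1", SAMPLE))
        assert len(aset.rt_trials) == len(aset.all_trials) == 60
        assert aset.exclusion_log == []

    def test_low_accuracy_participant_removed(self):
        bad = _make_records(
            "bad",
            SAMPLE,
            {c: [i % 10 < 7 for i in range(20)] for c in Congruency},  # 70% correct
        )
        good = _make_records("good", SAMPLE)
        aset = filter_trials(bad + good)
        assert aset.participants == ["good"]
        assert any("percent correct" in line for line in aset.exclusion_log)

    def test_fast_flagged_participant_removed(self):
        fast = {c: [100.0 + i for i in range(20)] for c in Congruency}  # all < 150 ms
        aset = filter_trials(_make_records("fast", fast) + _make_records("good", SAMPLE))
        assert aset.participants == ["good"]
        assert any("flagged" in line for line in aset.exclusion_log)

    def test_error_trials_excluded_from_rt_kept_in_all(self):
        correct = {c: [True] * 15 + [False] * 5 for c in Congruency}
        aset = filter_trials(_make_records("P1", SAMPLE, correct))
        assert len(aset.all_trials) == 60
        assert len(aset.rt_trials) == 45
        assert aset.rt_trials["correct"].all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            filter_trials([])


class TestQuantiles:
    def test_single_value_repeats(self):
        assert np.allclose(rt_quantiles([412.0], TEN_BIN_GRID), 412.0)

    def test_median_of_one_to_nine(self):
        assert rt_quantiles(range(1, 10), [0.5])[0] == pytest.approx(5.0)

    def test_output_nondecreasing(self):
        q = rt_quantiles(np.random.default_rng(1).normal(400, 50, 100), TEN_BIN_GRID)
        assert np.all(np.diff(q) >= 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rt_quantiles([], [0.5])
        with pytest.raises(ValueError):
            rt_quantiles([1.0], [0.0, 0.5])

    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(1.0, 2000.0), min_size=1, max_size=40),
        probs=st.lists(
            st.floats(0.01, 0.99), min_size=1, max_size=8, unique=True
        ).map(sorted),
    )
    def test_matches_sort_and_interpolate_oracle(self, values, probs):
        # independent oracle: place the k-th of n sorted values at
        # probability (k-1)/(n-1) and interpolate linearly, clamping ends
        srt = np.sort(np.asarray(values))
        n = len(srt)
        expected = []
        for p in probs:
            if n == 1:
                expected.append(srt[0])
                continue
            pos = p * (n - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, n - 1)
            frac = pos - lo
            expected.append(srt[lo] * (1 - frac) + srt[hi] * frac)
        assert np.allclose(rt_quantiles(values, probs), expected, rtol=1e-12, atol=1e-9)


class TestDeltaCurves:
    def test_identical_conditions_give_zero_deltas(self):
        aset = filter_trials(_make_records("P1", SAMPLE))
        curve = participant_delta_curve(aset, "P1", ResponseFocus.BALANCED)
        assert np.allclose(curve.d_fac, 0) and np.allclose(curve.d_inh, 0)

    def test_additivity_identity_exact(self):
        rng = np.random.default_rng(8)
        rts = {c: list(rng.lognormal(6, 0.3, 30)) for c in Congruency}
        aset = filter_trials(_make_records("P1", rts))
        curve = participant_delta_curve(aset, "P1", "balanced", EIGHT_BIN_GRID)
        assert np.allclose(curve.d_cong, curve.d_fac + curve.d_inh, atol=1e-9)

    def test_missing_condition_raises(self):
        partial = {Congruency.CONGRUENT: SAMPLE[Congruency.CONGRUENT],
                   Congruency.NEUTRAL: SAMPLE[Congruency.NEUTRAL],
                   Congruency.INCONGRUENT: []}
        aset = filter_trials(_make_records("P1", partial))
        with pytest.raises(ValueError, match="incongruent"):
            participant_delta_curve(aset, "P1", "balanced")

    def test_vincentize_single_curve_unchanged(self):
        aset = filter_trials(_make_records("P1", SAMPLE))
        c = participant_delta_curve(aset, "P1", "balanced")
        v = vincentize([c])
        assert np.allclose(v.d_fac, c.d_fac) and v.n_participants == 1

    def test_vincentize_two_curves_midpoint_preserves_additivity(self):
        rng = np.random.default_rng(3)
        curves = []
        for pid in ("P1", "P2"):
            rts = {c: list(rng.lognormal(6, 0.25, 25)) for c in Congruency}
            aset = filter_trials(_make_records(pid, rts))
            curves.append(participant_delta_curve(aset, pid, "balanced"))
        v = vincentize(curves)
        assert np.allclose(v.d_fac, (curves[0].d_fac + curves[1].d_fac) / 2)
        assert np.allclose(v.d_cong, v.d_fac + v.d_inh, atol=1e-9)
        assert v.n_participants == 2

    def test_vincentize_rejects_mismatched_grids(self):
        aset = filter_trials(_make_records("P1", SAMPLE))
        a = participant_delta_curve(aset, "P1", "balanced", TEN_BIN_GRID)
        b = participant_delta_curve(aset, "P1", "balanced", EIGHT_BIN_GRID)
        with pytest.raises(ValueError):
            vincentize([a, b])

    def test_synthetic_flanker_cohort_inhibition_rises(self, small_analysis_set):
        curve = group_delta_curve(small_analysis_set, ResponseFocus.ACCURACY)
        assert curve.d_inh[-1] > curve.d_inh[0]
        assert np.mean(np.diff(curve.d_inh) > 0) >= 0.6


class TestCAF:
    def test_all_correct_gives_zero_error_rates(self):
        aset = filter_trials(_make_records("P1", SAMPLE))
        caf = caf_curves(aset, "P1", "balanced")
        assert np.allclose(caf.pe_congruent, 0)
        assert np.allclose(caf.d_inh_pe, 0)

    def test_five_bin_centers(self):
        aset = filter_trials(_make_records("P1", SAMPLE))
        caf = caf_curves(aset, "P1", "balanced", n_bins=5)
        assert np.allclose(caf.bin_centers, [0.1, 0.3, 0.5, 0.7, 0.9])

    def test_weighted_bin_error_recovers_overall_error(self):
        rng = np.random.default_rng(5)
        rts = {c: list(rng.lognormal(6, 0.3, 37)) for c in Congruency}
        correct = {c: list(rng.random(37) > 0.2) for c in Congruency}
        aset = filter_trials(_make_records("P1", rts, correct))
        caf = caf_curves(aset, "P1", "balanced", n_bins=5)
        counts = [len(b) for b in np.array_split(np.arange(37), 5)]
        for cond, pe in (
            (Congruency.CONGRUENT, caf.pe_congruent),
            (Congruency.NEUTRAL, caf.pe_neutral),
            (Congruency.INCONGRUENT, caf.pe_incongruent),
        ):
            overall = 1.0 - np.mean(correct[cond])
            assert np.average(pe, weights=counts) == pytest.approx(overall, abs=1e-12)

    def test_insufficient_trials_raise(self):
        tiny = {c: [300.0, 310.0] for c in Congruency}
        aset = filter_trials(_make_records("P1", tiny))
        with pytest.raises(ValueError, match="bins"):
            caf_curves(aset, "P1", "balanced", n_bins=5)


class TestSummaries:
    def test_single_participant_identical_rts_zero_se(self):
        rts = {c: [400.0] * 10 for c in Congruency}
        aset = filter_trials(_make_records("P1", rts))
        _, group = condition_summaries(aset)
        assert (group["se_rt"] == 0).all()
        assert group["percent_correct"].between(0, 100).all()

    def test_accuracy_focus_more_accurate_than_speed(self, small_analysis_set):
        _, group = condition_summaries(small_analysis_set)
        acc = group.groupby("focus", observed=True)["percent_correct"].mean()
        assert acc["accuracy"] > acc["speed"]
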