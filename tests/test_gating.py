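import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgmoco import gating
from dgmoco.errors import GatingError
from dgmoco.gating import (
    REJECTED,
    BinAssignment,
    CardiacAssignment,
    CycleSet,
    GatingThresholds,
    RespiratoryAssignment,
    assign_cardiac_bins,
    assign_respiratory_bins,
    combine_dual,
    compute_thresholds,
    data_fractions,
    detect_cycles,
    gate_study,
)
from dgmoco.phantom import (
    RespiratoryTrace,
    TriggerList,
    generate_cardiac_triggers,
    generate_respiratory_trace,
)

END_EXPIRATORY_CLOSED_FORM = 100.0 * np.arccos(0.6) / np.pi  # 29.517 %


def _cycleset(maxima, minima, valid=None):
    n = len(maxima)
    valid = np.ones(n, bool) if valid is None else np.asarray(valid)
    idx = np.arange(n + 1) * 10
    return CycleSet(start_idx=idx[:-1], end_idx=idx[1:],
                    start_time=idx[:-1].astype(float),
                    end_time=idx[1:].astype(float),
                    max_amplitude=np.asarray(maxima, float),
                    min_amplitude=np.asarray(minima, float), valid=valid)


class TestDetectCycles:
    def test_noiseless_sinusoid_all_valid(self, sinusoid_trace):
        cycles = detect_cycles(sinusoid_trace)
        assert cycles.n_cycles == 25
        assert cycles.n_valid == 25

    def test_corrupted_cycles_flagged_exactly(self):
        trace = generate_respiratory_trace(duration=505, period=5,
                                           period_jitter=0.03,
                                           amplitude_jitter=0.05,
                                           invalid_cycle_rate=0.14, seed=42)
        cycles = detect_cycles(trace)
        assert cycles.n_cycles == trace.invalid_cycles.size
        assert np.array_equal(~cycles.valid, trace.invalid_cycles)

    def test_monotone_ramp_errors(self):
        trace = RespiratoryTrace(time=np.linspace(0, 10, 200),
                                 amplitude=np.linspace(0, 5, 200))
        with pytest.raises(GatingError):
            detect_cycles(trace)

    def test_flat_trace_errors(self):
        trace = RespiratoryTrace(time=np.linspace(0, 10, 200),
                                 amplitude=np.ones(200))
        with pytest.raises(GatingError):
            detect_cycles(trace)


class TestComputeThresholds:
    def test_degenerate_all_equal(self):
        thr = compute_thresholds(_cycleset([10, 10, 10], [0, 0, 0]))
        assert thr.a_max == 10.0
        assert thr.a_min == 0.0
        assert np.allclose(thr.edges, [0, 2, 4, 6, 8, 10])

    def test_sample_sd_convention(self):
        # maxima {8,10,12}: mean 10, sample SD 2 -> a_max 12; minima mean 1
        thr = compute_thresholds(_cycleset([8, 10, 12], [0, 1, 2]))
        assert thr.a_max == pytest.approx(12.0)
        assert thr.a_min == pytest.approx(1.0)

    def test_single_valid_cycle_errors(self):
        with pytest.raises(GatingError):
            compute_thresholds(_cycleset([10, 10], [0, 0], valid=[True, False]))

    def test_invalid_cycles_excluded(self):
        thr = compute_thresholds(
            _cycleset([8, 10, 12, 99], [0, 1, 2, -50],
                      valid=[True, True, True, False]))
        assert thr.a_max == pytest.approx(12.0)
        assert thr.a_min == pytest.approx(1.0)


class TestAssignRespiratoryBins:
    def test_boundaries(self):
        t = np.arange(6, dtype=float)
        amp = np.array([0.0, 1.9, 2.0, 9.9, 10.0, 10.1])
        trace = RespiratoryTrace(time=t, amplitude=amp)
        cycles = CycleSet(start_idx=np.array([0]), end_idx=np.array([6]),
                          start_time=np.array([0.0]), end_time=np.array([5.0]),
                          max_amplitude=np.array([10.1]),
                          min_amplitude=np.array([0.0]),
                          valid=np.array([True]))
        thr = GatingThresholds(a_max=10.0, a_min=0.0)
        labels = assign_respiratory_bins(trace, cycles, thr).labels
        assert labels[0] == 5      # exactly a_min -> bin 5
        assert labels[1] == 5      # below first edge
        assert labels[2] == 4      # closed-below edge
        assert labels[3] == 1
        assert labels[4] == 1      # exactly a_max stays in top bin
        assert labels[5] == REJECTED  # above maximum threshold

    def test_below_minimum_clipped_into_bin5(self):
        t = np.arange(3, dtype=float)
        trace = RespiratoryTrace(time=t, amplitude=np.array([-5.0, 0.5, 3.0]))
        cycles = CycleSet(start_idx=np.array([0]), end_idx=np.array([3]),
                          start_time=np.array([0.0]), end_time=np.array([2.0]),
                          max_amplitude=np.array([3.0]),
                          min_amplitude=np.array([-5.0]),
                          valid=np.array([True]))
        thr = GatingThresholds(a_max=10.0, a_min=1.0)
        labels = assign_respiratory_bins(trace, cycles, thr).labels
        assert labels[0] == 5 and labels[1] == 5

    def test_sinusoid_end_expiratory_fraction(self, sinusoid_trace):
        cycles = detect_cycles(sinusoid_trace)
        thr = compute_thresholds(cycles)
        labels = assign_respiratory_bins(sinusoid_trace, cycles, thr).labels
        frac = 100.0 * np.mean(labels == 5)
        assert frac == pytest.approx(END_EXPIRATORY_CLOSED_FORM, abs=0.5)

    def test_invalid_cycle_samples_rejected(self):
        trace = generate_respiratory_trace(duration=200, period=5,
                                           invalid_cycle_rate=0.3, seed=7)
        cycles = detect_cycles(trace)
        thr = compute_thresholds(cycles)
        labels = assign_respiratory_bins(trace, cycles, thr).labels
        for s, e, ok in zip(cycles.start_idx, cycles.end_idx, cycles.valid):
            if not ok:
                assert np.all(labels[s:e] == REJECTED)


class TestAssignCardiacBins:
    def test_printed_division(self, constant_triggers):
        # tau = 300 ms -> c3; tau = 550 ms -> c5 (closed below); times are
        # measured from the first trigger (t = 0) to keep tau exact
        times = np.array([0.3, 0.55, 0.0, 0.049, 0.05, 0.119, 0.12,
                          0.419, 0.42, 0.549])
        labels = assign_cardiac_bins(times, constant_triggers).labels
        assert list(labels) == [3, 5, 1, 1, 2, 2, 3, 3, 4, 4]

    def test_constant_rr_diastolic_fraction(self, sinusoid_trace,
                                            constant_triggers):
        labels = assign_cardiac_bins(sinusoid_trace.time,
                                     constant_triggers).labels
        frac = np.mean(labels == 5)
        assert frac == pytest.approx(0.45, abs=0.01)

    def test_rejections(self):
        triggers = TriggerList(r_peak_times=np.array([1.0, 2.0, 3.0]))
        # before first, at/after last, and tau >= 1500 ms on a long gap
        long_gap = TriggerList(r_peak_times=np.array([0.0, 2.0]))
        labels = assign_cardiac_bins(np.array([0.5, 3.0, 3.5]), triggers).labels
        assert list(labels) == [REJECTED, REJECTED, REJECTED]
        labels2 = assign_cardiac_bins(np.array([1.49, 1.51]), long_gap).labels
        assert labels2[0] == 5 and labels2[1] == REJECTED

    def test_empty_triggers_error(self):
        with pytest.raises(GatingError):
            assign_cardiac_bins(np.array([1.0]),
                                TriggerList(r_peak_times=np.array([])))


class TestCombineDual:
    def test_anchor_bins(self):
        t = np.arange(3, dtype=float)
        resp = RespiratoryAssignment(time=t, labels=np.array([5, 1, 1]))
        card = CardiacAssignment(time=t, labels=np.array([5, 5, 1]))
        dual = combine_dual(resp, card).dual
        assert list(dual) == [25, 21, 1]

    def test_rejected_propagates(self):
        t = np.arange(2, dtype=float)
        resp = RespiratoryAssignment(time=t, labels=np.array([REJECTED, 3]))
        card = CardiacAssignment(time=t, labels=np.array([2, REJECTED]))
        assert list(combine_dual(resp, card).dual) == [REJECTED, REJECTED]

    def test_misaligned_time_bases_error(self):
        resp = RespiratoryAssignment(time=np.array([0.0, 1.0]),
                                     labels=np.array([1, 1]))
        card = CardiacAssignment(time=np.array([0.0, 1.5]),
                                 labels=np.array([1, 1]))
        with pytest.raises(GatingError):
            combine_dual(resp, card)

    def test_dual_bin_invariants(self):
        rng = np.random.default_rng(0)
        t = np.arange(500, dtype=float)
        r = rng.integers(1, 6, 500)
        c = rng.integers(1, 6, 500)
        dual = combine_dual(RespiratoryAssignment(t, r),
                            CardiacAssignment(t, c)).dual
        assert np.all((dual >= 1) & (dual <= 25))
        assert np.array_equal(dual == 25, (c == 5) & (r == 5))
        assert np.array_equal((dual >= 21) & (dual <= 25), c == 5)


class TestDataFractions:
    def test_uniform_labels(self):
        t = np.arange(25.0)
        dual = np.arange(1, 26)
        asg = BinAssignment(time=t, resp=np.ones(25, int),
                            cardiac=np.ones(25, int), dual=dual)
        rep = data_fractions(asg)
        assert all(v == pytest.approx(1 / 25) for v in rep.bin_fractions.values())
        assert rep.rejected_fraction == 0.0

    def test_moco_minus_dg_close_to_discussion_value(self, sinusoid_trace):
        # 35% diastolic design: constant RR with (RR - 550 ms)/RR = 0.35
        triggers = generate_cardiac_triggers(duration=125,
                                             mean_hr=60 * 0.65 / 0.55,
                                             sd_hr=0)
        _, rep, _ = gate_study(sinusoid_trace, triggers)
        extra = 100 * (rep.moco_fraction - rep.dg_fraction)
        # closed form 0.35 * (1 - 0.295) = 24.7 percentage points
        assert extra == pytest.approx(24.7, abs=1.0)

    def test_moco_superset_of_dg(self):
        rng = np.random.default_rng(3)
        t = np.arange(1000.0)
        dual = rng.choice(np.concatenate([[REJECTED], np.arange(1, 26)]), 1000)
        asg = BinAssignment(time=t, resp=np.zeros(1000, int),
                            cardiac=np.zeros(1000, int), dual=dual)
        rep = data_fractions(asg)
        assert rep.moco_fraction >= rep.dg_fraction
        assert sum(rep.bin_fractions.values()) + rep.rejected_fraction \
            == pytest.approx(1.0, abs=1e-12)

    def test_json_round_trip(self, tmp_path, sinusoid_trace, constant_triggers):
        _, rep, _ = gate_study(sinusoid_trace, constant_triggers)
        path = tmp_path / "fractions.json"
        rep.to_json(path)
        back = gating.DataFractionReport.from_json(path)
        assert back.bin_fractions == rep.bin_fractions
        assert back.moco_fraction == rep.moco_fraction


class TestProperties:
    @given(scale=st.floats(0.1, 10.0), offset=st.floats(-5.0, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_labels_invariant_under_affine_amplitude_rescale(self, scale, offset):
        trace = generate_respiratory_trace(duration=60, period=5,
                                           period_jitter=0.05,
                                           amplitude_jitter=0.1, seed=21)
        scaled = RespiratoryTrace(time=trace.time,
                                  amplitude=scale * trace.amplitude + offset)
        lab = []
        for tr in (trace, scaled):
            cycles = detect_cycles(tr)
            thr = compute_thresholds(cycles)
            lab.append(assign_respiratory_bins(tr, cycles, thr).labels)
        assert np.array_equal(lab[0], lab[1])

    def test_brute_force_labeler_matches_vectorized(self):
        trace = generate_respiratory_trace(duration=90, period=4.5,
                                           period_jitter=0.06,
                                           amplitude_jitter=0.12,
                                           invalid_cycle_rate=0.1, seed=33)
        cycles = detect_cycles(trace)
        thr = compute_thresholds(cycles)
        fast = assign_respiratory_bins(trace, cycles, thr).labels

        # independent per-sample oracle: direct interval tests
        # (bins closed below: bin 5 = [a_min, e1), ..., bin 1 = [e4, a_max])
        edges = thr.edges
        slow = np.full(trace.time.size, REJECTED)
        for i, a in enumerate(trace.amplitude):
            in_valid = any(s <= i < e for s, e, ok in
                           zip(cycles.start_idx, cycles.end_idx, cycles.valid)
                           if ok)
            if not in_valid or a > thr.a_max:
                continue
            if a >= edges[4]:
                slow[i] = 1
            elif a >= edges[3]:
                slow[i] = 2
            elif a >= edges[2]:
                slow[i] = 3
            elif a >= edges[1]:
                slow[i] = 4
            else:
                slow[i] = 5
        assert np.array_equal(fast, slow)

    def test_independent_signals_factorize_bin25(self):
        trace = generate_respiratory_trace(duration=600, period=5.3,
                                           period_jitter=0.05, seed=8)
        triggers = generate_cardiac_triggers(duration=600, mean_hr=63,
                                             sd_hr=6, seed=9)
        asg, rep, _ = gate_study(trace, triggers)
        p_c5 = np.mean(asg.cardiac == 5)
        p_r5 = np.mean(asg.resp == 5)
        assert rep.bin_fractions[25] == pytest.approx(p_c5 * p_r5, abs=0.02)
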