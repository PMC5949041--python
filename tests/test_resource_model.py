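"""Cost-model formulas at their printed special cases, plus feasibility logic."""

import numpy as np
import pytest

from q15pipe import resource_model as rm


class TestCycleFormulas:
    def test_hardware_layer(self):
        mean, worst = rm.cycles_hardware(1)
        assert worst == 97
        assert rm.cycles_hardware(10)[0] == pytest.approx(88.0)
        assert rm.cycles_hardware(10**9)[0] == pytest.approx(87.0, abs=1e-6)

    def test_goertzel_worst_case(self):
        assert rm.cycles_goertzel(0) == (1786.0, 1786.0)
        assert rm.cycles_goertzel(None)[0] == 965.0

    def test_timing(self):
        assert rm.cycles_timing(0, 10)[0] == pytest.approx(8.7)
        assert rm.cycles_timing(0, 1)[1] == 42.0
        assert rm.cycles_timing(3, 10)[0] == pytest.approx(4.3 * 3 + 8.7)
        assert rm.cycles_timing(2, 1)[1] == 42.0 + 43 * 2

    def test_polyphase_vs_filter_structural_offset(self):
        # at D=1 the decimator costs 103.5 + 0.1 p cycles more than the filter
        for p in (0, 10, 100, 254):
            diff = rm.cycles_polyphase(p, 1) - rm.cycles_filter(p, 0)
            assert diff == pytest.approx(103.5 + 0.1 * p)

    @pytest.mark.parametrize(
        "fn,args",
        [
            (rm.cycles_hardware, (0,)),
            (rm.cycles_filter, (-1, 0)),
            (rm.cycles_polyphase, (1, 0)),
            (rm.cycles_block, (-1,)),
            (rm.cycles_timing, (0, 0)),
        ],
    )
    def test_domain_errors(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)


class TestMemoryFormulas:
    def test_printed_values(self):
        assert rm.dm_hardware(1, 1) == 30
        assert rm.dm_goertzel() == 62
        assert rm.dm_block(50) == 112
        assert rm.dm_timing(0) == 7
        assert rm.dm_filter(495, 0, include_coeffs=True) == 2008

    def test_coefficient_storage_is_separate(self):
        assert rm.dm_filter(4, 0) == 20 + 2 * 6
        assert rm.dm_filter(4, 0, include_coeffs=True) == 20 + 4 * 6
        assert rm.dm_polyphase(49, 5) == 10 + 100 + 4 * 10
        assert rm.dm_polyphase(49, 5, include_coeffs=True) == 10 + 100 + 40 + 100


class TestFeasibility:
    def test_cycles_available(self):
        assert rm.cycles_available(250.0) == pytest.approx(63_903.0)
        assert rm.cycles_available_block(10_000.0, 256) == pytest.approx(384_768.0)
        assert rm.cycles_available(16_000_000.0) < 0

    def test_max_filter_length_1hz_is_497(self):
        assert rm.max_filter_length(1.0, 1) == 497

    def test_max_filter_length_250hz_memory_bound(self):
        # at 250 Hz the cycle budget is generous; the DM bound from 1 Hz holds
        length, binding = rm.max_filter_length_detail(250.0, 1)
        assert length == rm.max_filter_length(1.0, 1) == 497
        assert binding == "memory"

    def test_infeasible_regime_returns_zero(self):
        # faster than the clock can serve even a 1-coefficient filter
        assert rm.max_filter_length(23_000.0, 1) == 0

    def test_goertzel_count_bounds(self):
        assert rm.PlatformModel().free_dm() // rm.dm_goertzel() == 32
        assert rm.max_goertzel_count(100.0) == 32  # memory-bound at low rates
        assert rm.max_goertzel_count(9_000.0) == 1
        assert rm.max_goertzel_count(15_000.0) == 1
        assert rm.max_goertzel_count(16_000.0) == 0

    def test_largest_whole_khz_with_one_goertzel_is_15(self):
        rates = [f * 1000.0 for f in range(1, 25)]
        feasible = [f for f in rates if rm.max_goertzel_count(f) >= 1]
        assert max(feasible) == 15_000.0

    def test_fft_256_at_10khz_feasible(self):
        report = rm.fft_feasible(10_000.0, 256)
        assert report.feasible
        assert report.dm_bytes == 1334 + 512  # data size + double-buffer queue

    def test_fft_16_boundary_rounds_to_21_khz(self):
        boundary = rm.fft_max_rate(16)
        assert round(boundary / 1000) == 21
        assert rm.fft_feasible(boundary - 1, 16).feasible
        assert not rm.fft_feasible(22_000.0, 16).feasible

    def test_fft_unsupported_size(self):
        with pytest.raises(ValueError):
            rm.fft_feasible(1000.0, 48)


class TestMonotonicity:
    def test_max_filter_length_nonincreasing_in_fs(self):
        fs = np.geomspace(1, 20_000, 40)
        lengths = [rm.max_filter_length(f, 1) for f in fs]
        assert all(a >= b for a, b in zip(lengths, lengths[1:]))

    def test_goertzel_count_monotone(self):
        fs = np.geomspace(100, 20_000, 30)
        counts = [rm.max_goertzel_count(f) for f in fs]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        # non-decreasing in N (longer windows amortize the emission cost)
        for f in (5_000.0, 9_000.0):
            by_n = [rm.max_goertzel_count(f, n) for n in (1, 10, 100, None)]
            assert all(a <= b for a, b in zip(by_n, by_n[1:]))

    def test_cycles_available_strictly_decreasing(self):
        fs = np.linspace(100, 10_000, 20)
        cava = [rm.cycles_available(f) for f in fs]
        assert all(a > b for a, b in zip(cava, cava[1:]))

    def test_single_binding_crossover_filter_curve(self):
        # memory-bound at low rates, cycle-bound at high rates, one switch
        fs = np.geomspace(1, 22_000, 200)
        bindings = [rm.max_filter_length_detail(f, 1)[1] for f in fs]
        bindings = [b for b in bindings if b != "none"]
        switches = sum(a != b for a, b in zip(bindings, bindings[1:]))
        assert bindings[0] == "memory" and bindings[-1] == "cycles"
        assert switches == 1

    def test_polyphase_curve_feasible_and_monotone(self):
        fs = np.geomspace(10, 20_000, 50)
        lengths = [rm.max_filter_length(f, 8) for f in fs]
        assert all(a >= b for a, b in zip(lengths, lengths[1:]))
        assert lengths[0] > 0
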