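"""Fixed-point DSP kernels against exact and brute-force oracles."""

from fractions import Fraction

import numpy as np
import pytest

from q15pipe.dsp import (
    FilterSpec,
    Goertzel,
    PolyphaseDecimator,
    PolyphaseSpec,
    Q15Filter,
    SlidingWindow,
    WindowOverflowError,
    WindowStateError,
    sliding_energies,
)
from q15pipe.fixedpoint import FixedPointOverflowError, Q15_ONE, rounded_div

SC1_B = [2048, 6628, 9458, 6628, 2048]
SC2_B = [2731, -21845, 0, 21845, -2731]


def exact_fir_oracle(b, a0, x):
    """FIR recurrence in exact rational arithmetic, half-even rounded output."""
    out = []
    hist = [0] * len(b)
    for v in x:
        hist = [int(v)] + hist[:-1]
        acc = sum(bk * xk for bk, xk in zip(b, hist))
        out.append(rounded_div(acc, a0))
    return out


class TestFilter:
    def test_unity_filter_is_identity(self, rng):
        f = Q15Filter(FilterSpec(b=[26810], a=[26810]))
        x = rng.integers(-1024, 1024, size=200)
        assert [f.assess(int(v)) for v in x] == list(x)

    def test_sc1_constant_input_steady_state(self):
        # sum(b) == a0 == 26810: DC gain exactly 1
        f = Q15Filter(FilterSpec(SC1_B, [26810]))
        outs = [f.assess(1000) for _ in range(20)]
        assert outs[-1] == 1000
        assert all(o == 1000 for o in outs[4:])  # after the 5-tap transient

    def test_sc2_constant_input_rejected(self):
        # sum(b) == 0: DC gain exactly 0
        f = Q15Filter(FilterSpec(SC2_B, [32767]))
        outs = [f.assess(777) for _ in range(20)]
        assert all(o == 0 for o in outs[4:])

    def test_fir_matches_exact_rational_oracle(self, rng):
        x = rng.integers(0, 1024, size=300)
        f = Q15Filter(FilterSpec(SC1_B, [26810]))
        got = [f.assess(int(v)) for v in x]
        expected = exact_fir_oracle(SC1_B, 26810, x)
        assert got == expected  # rounding only at the output: deviation 0 <= 1 LSB

    def test_iir_recurrence_first_order(self):
        # y[n] = (b0 x[n] - a1 y[n-1]) / a0 with per-step half-even rounding
        spec = FilterSpec(b=[16384], a=[16384, -8192])
        y, ys = 0, []
        for x in [1000, 0, 0, 0, 0]:
            y = rounded_div(16384 * x + 8192 * y, 16384)
            ys.append(y)
        f = Q15Filter(spec)
        assert [f.assess(x) for x in [1000, 0, 0, 0, 0]] == ys
        assert ys == [1000, 500, 250, 125, 62]  # decaying exponential, half-even

    def test_block_path_bit_identical_to_scalar(self, rng):
        x = rng.integers(0, 1024, size=777)
        fa, fb = Q15Filter(FilterSpec(SC1_B, [26810])), Q15Filter(FilterSpec(SC1_B, [26810]))
        ys = [fa.assess(int(v)) for v in x]
        yb = np.concatenate(
            [fb.assess_block(x[:100]), fb.assess_block(x[100:101]), fb.assess_block(x[101:])]
        )
        assert ys == list(yb)

    def test_reset_and_view(self):
        spec = FilterSpec(SC1_B, [26810])
        f = Q15Filter(spec)
        f.assess(7)
        assert f.view(0) == 7  # newest input slot after first assess
        f.reset()
        assert all(f.view(k) == 0 for k in range(spec.length))
        with pytest.raises(IndexError):
            f.view(spec.length)

    def test_accumulator_overflow_flagged(self):
        f = Q15Filter(FilterSpec(b=[32767] * 100, a=[32767]))
        with pytest.raises(FixedPointOverflowError):
            for _ in range(100):
                f.assess(32767)

    @pytest.mark.parametrize(
        "b,a", [([], [1]), ([1], []), ([1], [0]), ([1] * 256, [1]), ([1], [1] * 256)]
    )
    def test_spec_validation(self, b, a):
        with pytest.raises(ValueError):
            FilterSpec(b, a)


class TestPolyphase:
    def test_d1_equals_plain_fir(self, rng):
        h = list(rng.integers(-5000, 5000, size=9))
        x = rng.integers(-512, 512, size=100)
        dec = PolyphaseDecimator(PolyphaseSpec(h, 1))
        got = [dec.assess(int(v)) for v in x]
        expected = exact_fir_oracle(h, Q15_ONE, x)
        assert got == expected

    def test_single_tap_halfband_example(self):
        dec = PolyphaseDecimator(PolyphaseSpec([32767], 2))
        outs = [dec.assess(x) for x in [1000, 2000, 3000, 4000]]
        # emits on input indices 0 and 2: rounded_div(32767*x, 32768)
        assert outs == [1000, None, 3000, None]

    def test_output_rate(self, rng):
        dec = PolyphaseDecimator(PolyphaseSpec([100, 200, 300], 5))
        outs = [dec.assess(int(v)) for v in rng.integers(0, 1024, 100)]
        assert sum(o is not None for o in outs) == 20

    @pytest.mark.parametrize("d", [1, 2, 3, 5, 8])
    def test_equivalent_to_fullrate_filter_then_decimate(self, d, rng):
        h = list(rng.integers(-8000, 8000, size=11))
        x = rng.integers(-512, 512, size=123)
        dec = PolyphaseDecimator(PolyphaseSpec(h, d))
        emitted = [o for o in (dec.assess(int(v)) for v in x) if o is not None]
        full = exact_fir_oracle(h, Q15_ONE, x)
        assert emitted == full[::d]

    def test_block_path_bit_identical_to_scalar(self, rng):
        h = list(rng.integers(-8000, 8000, size=14))
        x = rng.integers(-512, 512, size=260)
        da, db = PolyphaseDecimator(PolyphaseSpec(h, 3)), PolyphaseDecimator(PolyphaseSpec(h, 3))
        scalar = [o for o in (da.assess(int(v)) for v in x) if o is not None]
        block = np.concatenate([db.assess_block(x[:50]), db.assess_block(x[50:])])
        assert scalar == list(block)


class TestGoertzel:
    @staticmethod
    def dft_oracle(x, w0):
        n = np.arange(len(x))
        return abs(np.sum(np.asarray(x) * np.exp(-1j * w0 * n))) ** 2

    def test_zero_input_zero_power(self):
        g = Goertzel(0.7, 16)
        powers = [g.power(0.0) for _ in range(16)]
        assert powers[-1] == 0.0

    def test_matched_tone_beats_mismatched(self):
        n = 64
        w0 = 2 * np.pi * 8 / n
        t = np.arange(n)
        matched = np.cos(w0 * t)
        mismatched = np.cos(2 * w0 * t)
        def run(x):
            g = Goertzel(np.cos(w0), n)
            return [g.power(v) for v in x][-1]
        assert run(matched) > run(mismatched)
        assert run(matched) == pytest.approx(self.dft_oracle(matched, w0), rel=1e-9)

    @pytest.mark.parametrize("n", [1, 2, 7, 16, 33, 64])
    def test_float_mode_matches_dft_oracle(self, n, rng):
        x = rng.normal(size=n)
        for w0 in (0.3, 2 * np.pi * max(1, n // 4) / n, 3.0):
            g = Goertzel(np.cos(w0), n)
            p = [g.power(v) for v in x][-1]
            ref = self.dft_oracle(x, w0)
            assert p == pytest.approx(ref, rel=1e-6, abs=1e-9)

    def test_state_resets_between_emissions(self, rng):
        n = 16
        x = rng.normal(size=n)
        g = Goertzel(0.5, n)
        p1 = [g.power(v) for v in x][-1]
        p2 = [g.power(v) for v in x][-1]
        assert p1 == p2  # identical data after reset gives identical power

    def test_q15_coefficient_mode_close_to_float(self, rng):
        n = 32
        w0 = 2 * np.pi * 4 / n
        x = list(rng.integers(-512, 512, size=n))
        gq = Goertzel(np.cos(w0), n, mode="q15")
        pq = [gq.power(v) for v in x][-1]
        ref = self.dft_oracle(x, w0)
        assert pq == pytest.approx(ref, rel=0.05)

    @pytest.mark.parametrize("bad", [dict(cos_w0=1.5, n=4), dict(cos_w0=0.5, n=0)])
    def test_validation(self, bad):
        with pytest.raises(ValueError):
            Goertzel(**bad)


class TestSlidingWindow:
    def test_fill_advance_cycle(self):
        w = SlidingWindow(10, 4)
        for i in range(10):
            w.add(i)
        assert w.ready
        with pytest.raises(WindowOverflowError):
            w.add(99)
        w.advance()
        assert not w.ready
        for i in range(4):
            w.add(10 + i)
        assert w.ready
        assert [w.access(i) for i in range(10)] == list(range(4, 14))

    def test_nonoverlapping_blocks(self):
        w = SlidingWindow(64, 64)
        for i in range(64):
            w.add(1)
        assert w.ready and w.energy() == 64
        w.advance()
        assert w.fill == 0

    def test_access_before_ready_and_bounds(self):
        w = SlidingWindow(10, 4)
        with pytest.raises(WindowStateError):
            w.access(0)
        for i in range(10):
            w.add(i)
        with pytest.raises(IndexError):
            w.access(10)
        with pytest.raises(WindowStateError):
            SlidingWindow(4, 2).energy()

    def test_energy_matches_brute_force(self, rng):
        x = rng.integers(-1024, 1024, size=50)
        w = SlidingWindow(50, 50)
        for v in x:
            w.add(int(v))
        assert w.energy() == int(np.sum(x.astype(np.int64) ** 2))

    def test_energy_examples(self):
        w = SlidingWindow(10, 10)
        for _ in range(10):
            w.add(1)
        assert w.energy() == 10

    def test_vectorized_energies_match_window_object(self, rng):
        x = rng.integers(-512, 512, size=500)
        L, H = 50, 25
        w = SlidingWindow(L, H)
        scalar = []
        for v in x:
            w.add(int(v))
            if w.ready:
                scalar.append(w.energy())
                w.advance()
        assert scalar == list(sliding_energies(x, L, H))

    @pytest.mark.parametrize("L,H", [(0, 1), (10, 0), (10, 11)])
    def test_validation(self, L, H):
        with pytest.raises(ValueError):
            SlidingWindow(L, H)
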