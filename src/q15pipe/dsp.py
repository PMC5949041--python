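"""Fixed-point DSP kernels: rational filter, polyphase decimator, Goertzel, windows.

These are the signal-processing primitives of the simulated pipeline, with
the exact integer semantics of the 16-bit Q15 target:

* :class:`Q15Filter` — the rational (IIR/FIR) difference equation

  .. math::

     y[n] = \\Bigl(-\\sum_{k=1}^{q} a[k]\\,y[n-k]
             + \\sum_{k=0}^{p} b[k]\\,x[n-k]\\Bigr) / a[0]

  with 32-bit accumulation and banker's rounding of the quotient, holding
  current and past inputs/outputs in one ``p+q+2``-word circular buffer.

* :class:`PolyphaseDecimator` — a ``p+1``-tap FIR evaluated only on every
  D-th input (``y[n] = sum_k x[nD-k] h[k]``), emitting at rate ``Fs/D``.

* :class:`Goertzel` — the second-order recurrence
  ``s[n] = x[n] + 2 cos(w0) s[n-1] - s[n-2]`` run for N data samples plus
  one zero-input step, whose terminal states give the squared magnitude of
  the single DFT bin at ``w0``.

* :class:`SlidingWindow` — length-L circular segmentation buffer with hop H
  and a block-energy reduction.

Each stateful class offers a scalar ``assess``/``power``/``add`` method (the
per-sample semantics of the embedded target) and, where it matters for long
simulations, a bit-exact vectorized ``assess_block``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fixedpoint import (
    I16_MAX,
    I16_MIN,
    I32_MAX,
    I32_MIN,
    Q15_ONE,
    Accum32,
    FixedPointOverflowError,
    rounded_div,
    rounded_div_array,
    to_q15,
)

__all__ = [
    "FilterSpec",
    "Q15Filter",
    "PolyphaseSpec",
    "PolyphaseDecimator",
    "Goertzel",
    "SlidingWindow",
    "WindowOverflowError",
    "WindowStateError",
    "sliding_energies",
]

_MAX_COEFFS = 255  # byte-indexed coefficient tables on the target


def _check_i16_coeffs(name: str, coeffs: Sequence[int]) -> tuple[int, ...]:
    out = tuple(int(c) for c in coeffs)
    for c in out:
        if not I16_MIN <= c <= I16_MAX:
            raise ValueError(f"{name} coefficient {c} outside 16-bit signed range")
    return out


@dataclass(frozen=True)
class FilterSpec:
    """Coefficients of the rational filter, as raw Q15 integers.

    ``b[0..p]`` is the causal part, ``a[0..q]`` the anti-causal part;
    ``a[0]`` is the output normalizer and must be non-zero.  Each part is
    limited to 255 coefficients (byte-size indexing on the target).
    """

    b: tuple[int, ...]
    a: tuple[int, ...]

    def __init__(self, b: Sequence[int], a: Sequence[int]) -> None:
        object.__setattr__(self, "b", _check_i16_coeffs("b", b))
        object.__setattr__(self, "a", _check_i16_coeffs("a", a))
        if not self.b or not self.a:
            raise ValueError("filter needs at least one b and one a coefficient")
        if self.a[0] == 0:
            raise ValueError("a[0] must be non-zero")
        if len(self.b) > _MAX_COEFFS or len(self.a) > _MAX_COEFFS:
            raise ValueError(f"at most {_MAX_COEFFS} coefficients per part")

    @property
    def p(self) -> int:
        return len(self.b) - 1

    @property
    def q(self) -> int:
        return len(self.a) - 1

    @property
    def length(self) -> int:
        """History buffer length in words: current + past inputs and outputs."""
        return self.p + self.q + 2

    @classmethod
    def from_float(cls, b: Sequence[float], a: Sequence[float]) -> "FilterSpec":
        """Quantize real coefficients to Q15 (nearest, saturating)."""
        return cls([to_q15(c) for c in b], [to_q15(c) for c in a])


class Q15Filter:
    """Stateful fixed-point evaluation of a :class:`FilterSpec`.

    The history lives in a single ``p+q+2``-word buffer — input region first
    (slots ``0..p``), then output region (slots ``p+1..p+q+1``) — written
    with modulo addressing, matching the embedded memory layout so that
    :meth:`view` exposes the same words a debugger would see.
    """

    def __init__(self, spec: FilterSpec) -> None:
        self.spec = spec
        self._nx = spec.p + 1
        self._ny = spec.q + 1
        self._buf = [0] * spec.length
        self._xi = 0  # slot of most recent input, within [0, p]
        self._yi = 0  # slot of most recent output, within [0, q] of output region
        self._primed = False

    def reset(self) -> None:
        """Empty the whole buffer and re-initialize the pointers."""
        self._buf = [0] * self.spec.length
        self._xi = 0
        self._yi = 0
        self._primed = False

    def view(self, index: int) -> int:
        """Raw content of buffer word ``index`` (0-based), without mutation."""
        if not 0 <= index < self.spec.length:
            raise IndexError(
                f"view index {index} outside [0, {self.spec.length - 1}]"
            )
        return self._buf[index]

    def assess(self, x: int) -> int:
        """Consume one input sample and return the filter output.

        The sum of products is accumulated in a checked 32-bit register and
        divided by ``a[0]`` with round-half-to-even; the quotient saturates
        at the 16-bit rails with a warning.
        """
        b, a = self.spec.b, self.spec.a
        if self._primed:
            self._xi = (self._xi + 1) % self._nx
        self._buf[self._xi] = int(x)
        acc = Accum32()
        for k in range(self._nx):
            acc.add(b[k] * self._buf[(self._xi - k) % self._nx])
        for k in range(1, self._ny):
            acc.sub(a[k] * self._buf[self._nx + (self._yi - k + 1) % self._ny])
        y = rounded_div(acc.value, a[0])
        if self._primed:
            self._yi = (self._yi + 1) % self._ny
        self._buf[self._nx + self._yi] = y
        self._primed = True
        return y

    def assess_block(self, x: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`assess` over a 1-D int array, bit-exact.

        FIR specs (``q == 0``) run through an int64 convolution with a
        final-accumulator overflow check; IIR specs fall back to the scalar
        recursion (per-step rounding cannot be vectorized).  Streaming is
        supported: state carries over between consecutive calls.
        """
        x = np.asarray(x, dtype=np.int64)
        if x.ndim != 1:
            raise ValueError("assess_block expects a 1-D array")
        if x.size == 0:
            return np.empty(0, dtype=np.int64)
        if self.spec.q > 0:
            return np.fromiter(
                (self.assess(int(v)) for v in x), dtype=np.int64, count=x.size
            )
        p = self.spec.p
        hist = np.array(
            [self._buf[(self._xi - k) % self._nx] for k in range(p - 1, -1, -1)]
            if self._primed
            else [0] * p,
            dtype=np.int64,
        )
        ext = np.concatenate([hist, x]) if p else x
        acc = np.convolve(ext, np.asarray(self.spec.b, dtype=np.int64))
        acc = acc[p : p + x.size]
        if acc.size and (acc.max() > I32_MAX or acc.min() < I32_MIN):
            raise FixedPointOverflowError("32-bit accumulator overflow in block")
        y = rounded_div_array(acc, self.spec.a[0])
        # refresh scalar-path state so the two paths interleave bit-exactly
        tail = np.concatenate([hist, x])[-self._nx :]  # oldest..newest
        self._xi = 0
        for k in range(self._nx):
            self._buf[(self._xi - k) % self._nx] = (
                int(tail[-1 - k]) if k < tail.size else 0
            )
        self._yi = 0
        self._buf[self._nx] = int(y[-1])
        self._primed = True
        return y


@dataclass(frozen=True)
class PolyphaseSpec:
    """FIR taps ``h[0..p]`` (raw Q15) and decimation factor ``D >= 1``."""

    h: tuple[int, ...]
    D: int

    def __init__(self, h: Sequence[int], D: int) -> None:
        object.__setattr__(self, "h", _check_i16_coeffs("h", h))
        object.__setattr__(self, "D", int(D))
        if not self.h:
            raise ValueError("at least one tap required")
        if len(self.h) > _MAX_COEFFS:
            raise ValueError(f"at most {_MAX_COEFFS} taps")
        if self.D < 1:
            raise ValueError("decimation factor must be >= 1")

    @property
    def p(self) -> int:
        return len(self.h) - 1


class PolyphaseDecimator:
    """Decimating FIR: consumes every input, emits on every D-th.

    Output ``y[n] = rounded_div(sum_k x[nD-k] h[k], 2**15)`` — the taps are
    Q15, so unity gain corresponds to ``sum h = 2**15``.  Outputs are
    aligned so that ``y[n]`` is the full-rate FIR output at input index
    ``n*D`` (0-based): the decimator keeps every D-th full-rate output
    starting from the first.
    """

    def __init__(self, spec: PolyphaseSpec) -> None:
        self.spec = spec
        self._hist = [0] * len(spec.h)  # newest first
        self._n = 0

    def reset(self) -> None:
        self._hist = [0] * len(self.spec.h)
        self._n = 0

    def assess(self, x: int) -> Optional[int]:
        """Consume one input; return an output on emitting inputs, else None."""
        self._hist.insert(0, int(x))
        self._hist.pop()
        emit = self._n % self.spec.D == 0
        self._n += 1
        if not emit:
            return None
        acc = Accum32()
        for h_k, x_k in zip(self.spec.h, self._hist):
            acc.add(h_k * x_k)
        return rounded_div(acc.value, Q15_ONE)

    def assess_block(self, x: np.ndarray) -> np.ndarray:
        """Vectorized, bit-exact, streaming-safe block version of assess."""
        x = np.asarray(x, dtype=np.int64)
        if x.size == 0:
            return np.empty(0, dtype=np.int64)
        p, D = self.spec.p, self.spec.D
        hist = np.array(self._hist[:p][::-1], dtype=np.int64)  # oldest..newest
        ext = np.concatenate([hist, x]) if p else x
        acc = np.convolve(ext, np.asarray(self.spec.h, dtype=np.int64))
        acc = acc[p : p + x.size]
        if acc.size and (acc.max() > I32_MAX or acc.min() < I32_MIN):
            raise FixedPointOverflowError("32-bit accumulator overflow in block")
        # emitting input indices: global n ≡ 0 (mod D)
        first = (-self._n) % D
        out = rounded_div_array(acc[first::D], Q15_ONE)
        self._n += x.size
        tail = np.concatenate([hist, x])[-len(self.spec.h) :]
        self._hist = [int(v) for v in tail[::-1]] + [0] * (
            len(self.spec.h) - tail.size
        )
        return out


class Goertzel:
    """Single-bin spectral power via the Goertzel recurrence.

    Runs ``s[n] = x[n] + 2 cos(w0) s[n-1] - s[n-2]`` over ``N`` data
    samples, then one extra step with zero input, and reports

    ``P = s1**2 + s2**2 - 2 cos(w0) s1 s2``

    from the two terminal states — exactly the squared magnitude of the
    DFT sum ``|sum_n x[n] exp(-j w0 n)|**2`` for any ``w0`` (not only bin
    centres), in double precision.

    Parameters
    ----------
    cos_w0 : float
        Tuning value ``cos(w0)`` for the target frequency.
    n : int
        Number of data samples per power estimate (``N >= 1``).
    mode : {"float", "q15"}
        ``"float"`` (default) runs the recurrence in double precision.
        ``"q15"`` quantizes ``cos(w0)`` to Q15 and keeps the state in a
        checked 32-bit integer register: the product ``cos_q15 * s`` is
        scaled back by ``2**15`` with banker's rounding and doubled in the
        accumulator (the factor 2 cannot live inside a Q15 coefficient).
    """

    def __init__(self, cos_w0: float, n: int, mode: str = "float") -> None:
        if not -1.0 <= cos_w0 <= 1.0:
            raise ValueError("cos_w0 must lie in [-1, 1]")
        if n < 1:
            raise ValueError("iteration count N must be >= 1")
        if mode not in ("float", "q15"):
            raise ValueError(f"unknown mode {mode!r}")
        self.cos_w0 = float(cos_w0)
        self.n = int(n)
        self.mode = mode
        self._c_q15 = to_q15(cos_w0)
        self._s1: float | int = 0
        self._s2: float | int = 0
        self.iter = 0

    def reset(self) -> None:
        self._s1 = self._s2 = 0
        self.iter = 0

    def _step(self, x) -> None:
        if self.mode == "float":
            s = x + 2.0 * self.cos_w0 * self._s1 - self._s2
        else:
            t = rounded_div(self._c_q15 * int(self._s1), Q15_ONE)
            s = int(x) + 2 * t - int(self._s2)
            if not I32_MIN <= s <= I32_MAX:
                raise FixedPointOverflowError(f"Goertzel state overflow: {s}")
        self._s2, self._s1 = self._s1, s

    def power(self, x) -> Optional[float]:
        """Feed one sample; after the N-th, emit the bin power and reset."""
        self._step(x)
        self.iter += 1
        if self.iter < self.n:
            return None
        self._step(0)  # terminal zero-input iteration
        if self.mode == "float":
            p = (
                self._s1 * self._s1
                + self._s2 * self._s2
                - 2.0 * self.cos_w0 * self._s1 * self._s2
            )
        else:
            t = rounded_div(self._c_q15 * int(self._s1), Q15_ONE)
            p = int(self._s1) ** 2 + int(self._s2) ** 2 - 2 * t * int(self._s2)
        self.reset()
        return p

    def power_block(self, x: np.ndarray) -> list:
        """Feed an array of samples, returning the powers emitted."""
        out = []
        for v in np.asarray(x).ravel():
            p = self.power(v)
            if p is not None:
                out.append(p)
        return out


class WindowOverflowError(RuntimeError):
    """``add`` was called on a full window that has not been advanced."""


class WindowStateError(RuntimeError):
    """The window is not ready for the requested access."""


class SlidingWindow:
    """Length-L circular segmentation buffer with hop H (1 <= H <= L).

    ``add`` appends a sample (raising :class:`WindowOverflowError` when the
    window is already full), ``ready`` flags a full window, ``access(i)``
    returns the i-th oldest sample of a ready window, ``advance`` discards
    the oldest H samples, and ``energy`` reduces a ready window to
    ``sum(x**2)`` in a checked 32-bit accumulator.
    """

    def __init__(self, L: int, H: int) -> None:
        if L < 1:
            raise ValueError("window length L must be >= 1")
        if not 1 <= H <= L:
            raise ValueError("hop size H must satisfy 1 <= H <= L")
        self.L = int(L)
        self.H = int(H)
        self._buf = [0] * self.L
        self._start = 0  # index of oldest sample
        self.fill = 0

    def reset(self) -> None:
        self._buf = [0] * self.L
        self._start = 0
        self.fill = 0

    @property
    def ready(self) -> bool:
        return self.fill == self.L

    def add(self, x: int) -> None:
        if self.ready:
            raise WindowOverflowError("window full; advance before adding")
        self._buf[(self._start + self.fill) % self.L] = int(x)
        self.fill += 1

    def access(self, i: int) -> int:
        if not self.ready:
            raise WindowStateError("window not ready")
        if not 0 <= i < self.L:
            raise IndexError(f"access index {i} outside [0, {self.L - 1}]")
        return self._buf[(self._start + i) % self.L]

    def advance(self) -> None:
        """Drop the oldest H samples, keeping the newest L-H in order."""
        drop = min(self.H, self.fill)
        self._start = (self._start + drop) % self.L
        self.fill -= drop

    def energy(self) -> int:
        """Sum of squares of the ready window, 32-bit accumulation."""
        if not self.ready:
            raise WindowStateError("window not ready")
        acc = Accum32()
        for i in range(self.L):
            v = self._buf[(self._start + i) % self.L]
            acc.add(v * v)
        return acc.value


def sliding_energies(x: np.ndarray, L: int, H: int) -> np.ndarray:
    """Vectorized stream of window energies: one per filled window.

    Equivalent to driving a :class:`SlidingWindow` with ``x`` and collecting
    ``energy()`` at every ready instant, i.e. over windows starting at
    ``0, H, 2H, ...`` while a full L samples remain.
    """
    x = np.asarray(x, dtype=np.int64)
    if x.size < L:
        return np.empty(0, dtype=np.int64)
    sq = x * x
    csum = np.concatenate([[0], np.cumsum(sq)])
    starts = np.arange(0, x.size - L + 1, H)
    e = csum[starts + L] - csum[starts]
    if e.size and e.max() > I32_MAX:
        raise FixedPointOverflowError("32-bit energy accumulator overflow")
    return e
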