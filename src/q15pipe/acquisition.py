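"""Virtual hardware layer: multiplexed ADC sampling into per-channel queues.

A hardware timer triggers one analog-to-digital conversion every
``Tint = 1 / (Fs * Nch)`` seconds, rotating round-robin over the ``Nch``
channels so each channel is sampled at exactly ``Fs`` with uniform spacing.
Each conversion quantizes the channel voltage to a 10-bit code and pushes
it onto that channel's bounded FIFO queue for the DSP layer to drain.

Queue overflow (a consumer that cannot keep up) drops the incoming sample
— reject-newest, which keeps the queued data contiguous — and increments a
per-channel overflow counter, the raw material of the simulator's
mean-time-between-failures bookkeeping.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionConfig",
    "ChannelQueue",
    "SignalSource",
    "quantize",
    "quantize_array",
    "acquisition_tick",
]

#: the target's SAR ADC keeps full 10-bit resolution only up to this rate
MAX_FULL_RES_RATE = 15_000.0


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sampling configuration of the virtual hardware layer.

    Parameters
    ----------
    fs : float
        Per-channel sampling rate in Hz.
    nch : int
        Number of multiplexed analog channels (1..8).
    lq : int
        Depth of each channel's FIFO queue, in samples.
    adc_bits : int
        ADC resolution (default 10).
    vref : float
        Full-scale voltage; codes span ``[0, 2**adc_bits - 1]`` over
        ``[0, vref)``.
    """

    fs: float
    nch: int = 1
    lq: int = 8
    adc_bits: int = 10
    vref: float = 1.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 1 <= self.nch <= 8:
            raise ValueError("nch must be in 1..8")
        if self.lq < 1:
            raise ValueError("queue depth lq must be >= 1")
        if self.adc_bits < 1:
            raise ValueError("adc_bits must be >= 1")
        if self.vref <= 0:
            raise ValueError("vref must be positive")
        if self.adc_bits == 10 and self.fs > MAX_FULL_RES_RATE:
            warnings.warn(
                f"fs={self.fs} Hz exceeds the {MAX_FULL_RES_RATE:.0f} Hz limit "
                "of full 10-bit resolution on the modelled ADC",
                UserWarning,
                stacklevel=2,
            )

    @property
    def tint(self) -> float:
        """Inter-conversion interval of the multiplexed ADC, seconds."""
        return 1.0 / (self.fs * self.nch)

    @property
    def code_max(self) -> int:
        return (1 << self.adc_bits) - 1


def quantize(v: float, cfg: AcquisitionConfig) -> int:
    """ADC transfer: ``floor(2**bits * v / vref)`` clamped to the code range."""
    code = math.floor((1 << cfg.adc_bits) * v / cfg.vref)
    return min(max(code, 0), cfg.code_max)


def quantize_array(v: np.ndarray, cfg: AcquisitionConfig) -> np.ndarray:
    """Vectorized :func:`quantize` returning int64 codes."""
    code = np.floor((1 << cfg.adc_bits) * np.asarray(v, dtype=float) / cfg.vref)
    return np.clip(code, 0, cfg.code_max).astype(np.int64)


class ChannelQueue:
    """Bounded FIFO of ADC codes with push/pop/overflow accounting.

    The conservation invariant ``pushed == popped + len(queue) + overflowed``
    holds at all times; overflow applies the reject-newest policy.
    """

    def __init__(self, capacity: int) -> None:
        if capacity < 1:
            raise ValueError("queue capacity must be >= 1")
        self.capacity = int(capacity)
        self._q: deque[int] = deque()
        self.pushed = 0
        self.popped = 0
        self.overflow_count = 0

    def __len__(self) -> int:
        return len(self._q)

    def push(self, code: int) -> bool:
        """Append a code; on a full queue drop it and count the overflow."""
        if len(self._q) >= self.capacity:
            self.overflow_count += 1
            return False
        self._q.append(code)
        self.pushed += 1
        return True

    def pop(self) -> int:
        if not self._q:
            raise IndexError("pop from empty channel queue")
        self.popped += 1
        return self._q.popleft()

    def conserved(self) -> bool:
        return self.pushed == self.popped + len(self._q)


class SignalSource:
    """Multichannel voltage source defined over ``[0, duration]`` seconds.

    Built either from per-channel callables ``t -> volts``, from arrays on a
    regular grid, or from a CSV file with header ``time,ch0[,ch1,...]``.
    """

    def __init__(
        self,
        channels: Sequence[Callable[[float], float]],
        duration: float,
    ) -> None:
        if duration < 0:
            raise ValueError("duration must be non-negative")
        self.channels = list(channels)
        self.duration = float(duration)

    @property
    def nch(self) -> int:
        return len(self.channels)

    def sample(self, channel: int, t: float) -> float:
        return float(self.channels[channel](t))

    @classmethod
    def from_arrays(
        cls, data: np.ndarray, fs: float, duration: Optional[float] = None
    ) -> "SignalSource":
        """Wrap a ``(nch, nsamples)`` or 1-D array sampled at ``fs`` Hz.

        Ticks fall exactly on the grid in practice; lookup is by nearest
        index, clamped at the ends.
        """
        arr = np.atleast_2d(np.asarray(data, dtype=float))
        n = arr.shape[1]
        if duration is None:
            duration = n / fs

        def make(ch: int) -> Callable[[float], float]:
            col = arr[ch]

            def f(t: float) -> float:
                i = int(round(t * fs))
                return float(col[min(max(i, 0), n - 1)])

            return f

        return cls([make(c) for c in range(arr.shape[0])], duration)

    @classmethod
    def from_csv(
        cls,
        path,
        cfg: AcquisitionConfig,
        input_kind: str = "volts",
    ) -> "SignalSource":
        """Load ``time,ch0[,ch1,...]`` CSV on a strictly increasing regular grid.

        ``input_kind="volts"`` keeps the float voltages (quantized later at
        acquisition time); ``input_kind="codes"`` expects integer ADC codes
        and maps them back to the mid-rise voltage grid so that requantizing
        reproduces the codes exactly.
        """
        if input_kind not in ("volts", "codes"):
            raise ValueError("input_kind must be 'volts' or 'codes'")
        df = pd.read_csv(path)
        if df.shape[1] < 2 or df.columns[0] != "time":
            raise ValueError("CSV must have header time,ch0[,ch1,...]")
        t = df["time"].to_numpy(dtype=float)
        if t.size < 2:
            raise ValueError("CSV must contain at least two rows")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time column must be strictly increasing and regular")
        fs_file = 1.0 / dt[0]
        vals = df.iloc[:, 1:].to_numpy(dtype=float).T
        if input_kind == "codes":
            codes = np.round(vals).astype(np.int64)
            if np.any(codes < 0) or np.any(codes > cfg.code_max):
                raise ValueError("ADC codes outside the configured range")
            # mid-step voltage of each code bin, so floor-quantization round-trips
            vals = (codes + 0.5) * cfg.vref / (1 << cfg.adc_bits)
        return cls.from_arrays(vals, fs_file, duration=t[-1] - t[0] + dt[0])


def acquisition_tick(
    source: SignalSource,
    cfg: AcquisitionConfig,
    queues: Sequence[ChannelQueue],
    k: int,
) -> tuple[int, int, bool]:
    """Perform conversion number ``k`` (at time ``k * Tint``).

    Samples channel ``k mod Nch``, quantizes, pushes to its queue and
    advances the multiplexer.  Returns ``(channel, code, accepted)``.
    """
    ch = k % cfg.nch
    t = k * cfg.tint
    code = quantize(source.sample(ch, t), cfg)
    accepted = queues[ch].push(code)
    return ch, code, accepted
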