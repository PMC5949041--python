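"""Cycle-count and memory cost models, and real-time feasibility analysis.

Each DSP component of the embedded library was profiled on a 16 MHz
AVR-class board (ATmega328-family, 2 KiB data memory, 32 KiB program
memory); the resulting regression formulas — clock cycles per invocation
and bytes of data/program memory as functions of the component parameters
— are embedded here as data.  On top of them sit the feasibility analyses:
the cycle budget per sample,

    C_ava = Fclk / Fs - Cmax_hardware,

(or ``N`` times that for block algorithms fed by an N-deep queue), and the
data-memory budget left after the acquisition layer and a small reserve.
These answer the design questions a practitioner actually has: how long a
filter fits at a given sampling rate, how many simultaneous Goertzel
detectors are possible, and up to what rate an N-bin FFT remains real-time.

All formula constants are measurements shipped as data; they are exact
inputs, not things this package estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "PlatformModel",
    "CostReport",
    "FFT_TABLE",
    "cycles_hardware",
    "cycles_filter",
    "cycles_polyphase",
    "cycles_goertzel",
    "cycles_block",
    "cycles_timing",
    "dm_hardware",
    "dm_filter",
    "dm_polyphase",
    "dm_goertzel",
    "dm_block",
    "dm_timing",
    "cycles_available",
    "cycles_available_block",
    "max_filter_length",
    "max_filter_length_detail",
    "max_goertzel_count",
    "fft_feasible",
    "fft_max_rate",
]

#: measured FFT library costs: N -> (program bytes, data bytes, exec cycles)
FFT_TABLE = {
    16: (3368, 254, 10_793),
    32: (3468, 326, 22_860),
    64: (3684, 470, 49_560),
    128: (4116, 758, 107_338),
    256: (5004, 1334, 232_554),
}

#: worst-case hardware-layer cycles (queue pointer wrap every push, lq=1)
CMAX_HARDWARE = 97


@dataclass(frozen=True)
class PlatformModel:
    """The modelled micro-controller target.

    Defaults describe the profiled board: 16 MHz clock, 2048 B data memory,
    32768 B program memory, with 10 B of data memory withheld for stack and
    globals (calibrated so the 1 Hz maximum filter length is exact).
    """

    fclk: float = 16_000_000.0
    dm_total: int = 2048
    pm_total: int = 32_768
    reserve: int = 10

    def __post_init__(self) -> None:
        if min(self.fclk, self.dm_total, self.pm_total) <= 0 or self.reserve < 0:
            raise ValueError("platform parameters must be positive")

    def free_dm(self, nch: int = 1, lq: int = 1) -> int:
        """Data memory left for DSP components after acquisition + reserve."""
        return self.dm_total - dm_hardware(nch, lq) - self.reserve


@dataclass(frozen=True)
class CostReport:
    """Per-component cost summary with the feasibility verdict."""

    component: str
    mean_cycles: float
    max_cycles: float
    dm_bytes: int
    pm_bytes: int
    feasible: bool
    binding: str  # "cycles" | "memory" | "none"

    def __post_init__(self) -> None:
        if not (self.max_cycles >= self.mean_cycles >= 0):
            raise ValueError("require max_cycles >= mean_cycles >= 0")
        if self.dm_bytes < 0 or self.pm_bytes < 0:
            raise ValueError("memory sizes must be non-negative")


# ---------------------------------------------------------------- cycles


def cycles_hardware(lq: int) -> tuple[float, int]:
    """(mean, worst-case) cycles of one acquisition interrupt at queue depth lq.

    mean = 10/lq + 87; the worst case, 97, occurs at lq=1 when the queue
    pointer wraps on every push.
    """
    if lq < 1:
        raise ValueError("queue depth lq must be >= 1")
    return 10.0 / lq + 87.0, CMAX_HARDWARE


def cycles_filter(p: int, q: int) -> float:
    """Cycles per filter output: 669 + 83.5 (p + q); mean ≈ worst case."""
    if p < 0 or q < 0:
        raise ValueError("p and q must be non-negative")
    return 669.0 + 83.5 * (p + q)


def cycles_polyphase(p: int, D: int) -> float:
    """Cycles per decimated output: 772.5 + 83.6 p / D."""
    if p < 0:
        raise ValueError("p must be non-negative")
    if D < 1:
        raise ValueError("decimation factor must be >= 1")
    return 772.5 + 83.6 * p / D


def cycles_goertzel(n: Optional[int]) -> tuple[float, float]:
    """(mean, worst-case) cycles per Goertzel iteration.

    mean = 965 + 821/(N+1); the worst case is the N=0 evaluation, 1786.
    ``n=None`` gives the asymptotic per-sample cost (965 cycles).
    """
    if n is None:
        mean = 965.0
    else:
        if n < 0:
            raise ValueError("N must be non-negative")
        mean = 965.0 + 821.0 / (n + 1)
    return mean, 1786.0


def cycles_block(L: int) -> float:
    """Cycles of the block-energy reduction: 653 + 51 L."""
    if L < 0:
        raise ValueError("L must be non-negative")
    return 653.0 + 51.0 * L


def cycles_timing(nt: int, t0r: int) -> tuple[float, float]:
    """(mean, worst-case) cycles of the 1 ms timing interrupt.

    mean = 5 + (43 Nt + 37)/T0r  (8.7 at Nt=0, T0r=10);
    worst case = 42 + 43 Nt  (every tick updates the list, T0r=1).
    """
    if nt < 0:
        raise ValueError("Nt must be non-negative")
    if t0r < 1:
        raise ValueError("T0r must be >= 1")
    mean = 5.0 + (43.0 * nt + 37.0) / t0r
    return mean, 42.0 + 43.0 * nt


# ---------------------------------------------------------------- memory


def dm_hardware(nch: int, lq: int) -> int:
    """Acquisition-layer data memory: 4 + (24 + 2 lq) Nch bytes."""
    if nch < 1 or lq < 1:
        raise ValueError("nch and lq must be >= 1")
    return 4 + (24 + 2 * lq) * nch


def dm_filter(p: int, q: int, include_coeffs: bool = False) -> int:
    """Filter data memory: 20 + 2 (p+q+2) bytes, plus 2 bytes per coefficient.

    The coefficient table itself lives outside the class but must be
    budgeted; ``include_coeffs`` adds ``2 * (p+q+2)`` for it.
    """
    if p < 0 or q < 0:
        raise ValueError("p and q must be non-negative")
    size = 20 + 2 * (p + q + 2)
    if include_coeffs:
        size += 2 * (p + q + 2)
    return size


def dm_polyphase(p: int, D: int, include_coeffs: bool = False) -> int:
    """Polyphase data memory: 10 + 20 D + 4 ceil((p+1)/D), plus taps."""
    if p < 0:
        raise ValueError("p must be non-negative")
    if D < 1:
        raise ValueError("decimation factor must be >= 1")
    size = 10 + 20 * D + 4 * math.ceil((p + 1) / D)
    if include_coeffs:
        size += 2 * (p + 1)
    return size


def dm_goertzel() -> int:
    """Goertzel data memory is constant: 62 bytes per detector."""
    return 62


def dm_block(L: int) -> int:
    """Segmentation window data memory: 12 + 2 L bytes."""
    if L < 0:
        raise ValueError("L must be non-negative")
    return 12 + 2 * L


def dm_timing(nt: int) -> int:
    """Timing subsystem data memory: 7 + 6 Nt bytes."""
    if nt < 0:
        raise ValueError("Nt must be non-negative")
    return 7 + 6 * nt


# ------------------------------------------------------------ feasibility


def cycles_available(fs: float, platform: PlatformModel = PlatformModel()) -> float:
    """Per-sample cycle budget: Fclk/Fs minus the worst-case acquisition cost."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    return platform.fclk / fs - CMAX_HARDWARE


def cycles_available_block(
    fs: float, n: int, platform: PlatformModel = PlatformModel()
) -> float:
    """Cycle budget for a block algorithm fed by an N-deep queue: N·(Fclk/Fs − Cmax)."""
    if n < 1:
        raise ValueError("N must be >= 1")
    return n * cycles_available(fs, platform)


def max_filter_length_detail(
    fs: float,
    D: int = 1,
    platform: PlatformModel = PlatformModel(),
    nch: int = 1,
    lq: int = 1,
) -> tuple[int, str]:
    """Largest feasible filter length and which constraint binds.

    Length counts total coefficients: ``p+q+2`` for the plain filter
    (evaluated with ``q=0``, used when ``D == 1``) and ``p+1`` taps for the
    polyphase decimator (``D > 1``).  A length is feasible when the
    component's data memory *including its coefficient table* fits the free
    DM budget and its per-output cycles fit :func:`cycles_available`.
    Returns ``(0, "none")`` when nothing fits.
    """
    cava = cycles_available(fs, platform)
    budget = platform.free_dm(nch, lq)
    if D == 1:
        # memory: 20 + 4(p+2) <= budget ; cycles: 669 + 83.5 p <= cava
        p_mem = (budget - 20) // 4 - 2
        p_cyc = math.floor((cava - 669.0) / 83.5) if cava >= 669.0 else -1
        if p_mem < 0 or p_cyc < 0:
            return 0, "none"
        p = min(p_mem, p_cyc)
        return p + 2, ("memory" if p_mem <= p_cyc else "cycles")
    # feasibility is monotone in p (both costs increase), so walk upward
    def ok(p: int) -> tuple[bool, bool]:
        return (
            dm_polyphase(p, D, include_coeffs=True) <= budget,
            cycles_polyphase(p, D) <= cava,
        )

    mem_ok, cyc_ok = ok(0)
    if not (mem_ok and cyc_ok):
        return 0, "none"
    p = 0
    while True:
        mem_ok, cyc_ok = ok(p + 1)
        if mem_ok and cyc_ok:
            p += 1
            continue
        return p + 1, ("memory" if not mem_ok else "cycles")


def max_filter_length(
    fs: float,
    D: int = 1,
    platform: PlatformModel = PlatformModel(),
    nch: int = 1,
    lq: int = 1,
) -> int:
    """Largest feasible filter length (see :func:`max_filter_length_detail`)."""
    return max_filter_length_detail(fs, D, platform, nch, lq)[0]


def max_goertzel_count(
    fs: float,
    n: Optional[int] = None,
    platform: PlatformModel = PlatformModel(),
    nch: int = 1,
    lq: int = 1,
) -> int:
    """How many Goertzel detectors can run simultaneously at ``fs``.

    The count is the smaller of the memory bound (62 B each out of the free
    DM budget) and the cycle bound (mean per-sample cost out of the
    per-sample budget).  ``n=None`` uses the asymptotic 965-cycle cost.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    mem_bound = platform.free_dm(nch, lq) // dm_goertzel()
    cava = cycles_available(fs, platform)
    if cava <= 0:
        return 0
    cyc_bound = int(cava // cycles_goertzel(n)[0])
    return max(0, min(mem_bound, cyc_bound))


def fft_feasible(
    fs: float,
    n: int,
    platform: PlatformModel = PlatformModel(),
    nch: int = 1,
) -> CostReport:
    """Real-time feasibility of the external N-bin FFT at sampling rate ``fs``.

    Cycle test: the measured execution cycles must fit the block budget
    ``N (Fclk/Fs - Cmax_hardware)`` (the acquisition queue, lq=N, buys the
    transform N sample periods).  Memory test: the library's data size plus
    a 2N-byte double-buffer queue must fit the free DM budget.
    """
    if n not in FFT_TABLE:
        raise ValueError(f"unsupported FFT size {n}; choose from {sorted(FFT_TABLE)}")
    pm, dm, exec_cycles = FFT_TABLE[n]
    budget = cycles_available_block(fs, n, platform)
    dm_needed = dm + 2 * n
    cyc_ok = budget >= exec_cycles
    mem_ok = dm_needed <= platform.free_dm(nch, 1)
    if cyc_ok and mem_ok:
        binding = "none"
    else:
        binding = "cycles" if not cyc_ok else "memory"
    return CostReport(
        component=f"fft{n}",
        mean_cycles=float(exec_cycles),
        max_cycles=float(exec_cycles),
        dm_bytes=dm_needed,
        pm_bytes=pm,
        feasible=cyc_ok and mem_ok,
        binding=binding,
    )


def fft_max_rate(n: int, platform: PlatformModel = PlatformModel()) -> float:
    """Highest sampling rate (Hz) at which the N-bin FFT stays real-time.

    Solves ``N (Fclk/Fs - Cmax_hardware) >= exec_cycles`` for Fs.
    """
    if n not in FFT_TABLE:
        raise ValueError(f"unsupported FFT size {n}")
    exec_cycles = FFT_TABLE[n][2]
    return platform.fclk / (exec_cycles / n + CMAX_HARDWARE)
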