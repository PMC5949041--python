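"""Deterministic discrete-event executive for the layered acquisition pipeline.

Reproduces the embedded control flow: two synchronous processes — the
fixed-rate acquisition tick and the 1 ms timing tick — interleaved with an
asynchronous task manager that runs the DSP stages whenever their input
queues hold data.  Simulated time advances over the merged event
timestamps; at each instant events fire in a fixed priority (acquisition
tick, then timer tick, then one full task-manager round in declared stage
order, each stage draining its input queue), so identical configurations
and seeds yield bit-identical outputs.

Stages are linear chains per channel (one producer, one consumer per
queue); queue overflow is logged and counted but never aborts the run, and
the :class:`EventLog` carries the push/pop/overflow accounting behind the
sample-count (MTBF) integrity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np

from .acquisition import (
    AcquisitionConfig,
    ChannelQueue,
    SignalSource,
    acquisition_tick,
)
from .dsp import (
    FilterSpec,
    Goertzel,
    PolyphaseDecimator,
    PolyphaseSpec,
    Q15Filter,
    SlidingWindow,
)
from .timing import TimerSystem

__all__ = [
    "Stage",
    "FilterStage",
    "PolyphaseStage",
    "GoertzelStage",
    "BlockEnergyStage",
    "FFTStage",
    "PipelineConfig",
    "EventLog",
    "PipelineResult",
    "run_pipeline",
    "expected_sample_count",
    "stage_factory_from_dict",
]

_NS = 1_000_000_000


class Stage:
    """A task-manager stage: consumes one value, emits zero or more."""

    name = "stage"

    def process(self, value):  # pragma: no cover - interface
        raise NotImplementedError


class FilterStage(Stage):
    """Rational Q15 filter stage (one output per input)."""

    def __init__(self, spec: FilterSpec, name: str = "filter") -> None:
        self.name = name
        self._f = Q15Filter(spec)

    def process(self, value):
        return [self._f.assess(value)]


class PolyphaseStage(Stage):
    """Decimating FIR stage (one output per D inputs)."""

    def __init__(self, spec: PolyphaseSpec, name: str = "polyphase") -> None:
        self.name = name
        self._d = PolyphaseDecimator(spec)

    def process(self, value):
        y = self._d.assess(value)
        return [] if y is None else [y]


class GoertzelStage(Stage):
    """Single-bin power detector stage (one output per N inputs)."""

    def __init__(
        self, cos_w0: float, n: int, mode: str = "float", name: str = "goertzel"
    ) -> None:
        self.name = name
        self._g = Goertzel(cos_w0, n, mode=mode)

    def process(self, value):
        p = self._g.power(value)
        return [] if p is None else [p]


class BlockEnergyStage(Stage):
    """Sliding-window energy stage: one energy per filled window."""

    def __init__(self, L: int, H: int, name: str = "block_energy") -> None:
        self.name = name
        self._w = SlidingWindow(L, H)

    def process(self, value):
        self._w.add(value)
        if not self._w.ready:
            return []
        e = self._w.energy()
        self._w.advance()
        return [e]


class FFTStage(Stage):
    """Non-overlapping N-sample blocks handed to a host FFT.

    Stands in for the external fixed-point FFT library: the simulator
    delegates the transform itself to ``numpy.fft.rfft`` and emits the
    magnitude-squared spectrum of each block as an ndarray.
    """

    def __init__(self, n: int, name: str = "fft") -> None:
        self.name = name
        self._w = SlidingWindow(n, n)
        self.n = n

    def process(self, value):
        self._w.add(value)
        if not self._w.ready:
            return []
        block = np.array([self._w.access(i) for i in range(self.n)], dtype=float)
        self._w.advance()
        return [np.abs(np.fft.rfft(block)) ** 2]


@dataclass
class PipelineConfig:
    """A linear per-channel stage chain over an acquisition front end.

    ``chains[ch]`` is a list of zero-argument stage factories for channel
    ``ch`` (factories, so every run starts from fresh state and repeated
    runs are bit-identical).  ``queue_capacity`` sizes every inter-stage
    queue; ``drain_full`` selects whether a stage empties its whole input
    queue per task round (the embedded task-manager behaviour) or services
    one sample per round (for stress-testing queue sizing).
    """

    acquisition: AcquisitionConfig
    chains: Sequence[Sequence[Callable[[], Stage]]]
    duration: float
    queue_capacity: int = 64
    drain_full: bool = True
    seed: int = 0
    timer_system: Optional[TimerSystem] = None

    def __post_init__(self) -> None:
        if len(self.chains) != self.acquisition.nch:
            raise ValueError("need one stage chain per channel")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.queue_capacity < 1:
            raise ValueError("queue capacity must be >= 1")


@dataclass
class EventLog:
    """Push/pop/overflow accounting per queue plus stage invocation counts."""

    queues: dict = field(default_factory=dict)  # name -> dict of counters
    stage_invocations: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record_queue(self, name: str, q: ChannelQueue) -> None:
        self.queues[name] = {
            "pushed": q.pushed,
            "popped": q.popped,
            "residual": len(q),
            "overflow": q.overflow_count,
        }

    @property
    def total_overflow(self) -> int:
        return sum(v["overflow"] for v in self.queues.values())

    def conserved(self) -> bool:
        return all(
            v["pushed"] == v["popped"] + v["residual"] for v in self.queues.values()
        )


@dataclass
class PipelineResult:
    """Final-stage output streams per channel, with the event log."""

    outputs: List[list]
    log: EventLog


def run_pipeline(config: PipelineConfig, source: SignalSource) -> PipelineResult:
    """Run the executive over ``config.duration`` simulated seconds.

    Acquisition conversions happen at integer multiples of ``Tint``
    (nanosecond-quantized timestamps), timer ticks every millisecond; after
    the synchronous events of each instant, one task-manager round runs the
    stage chains in declared order.  Stages with empty queues are skipped,
    never blocked on.
    """
    acq = config.acquisition
    if source.nch != acq.nch:
        raise ValueError("source channel count does not match acquisition config")
    timers = config.timer_system or TimerSystem()

    hw_queues = [ChannelQueue(acq.lq) for _ in range(acq.nch)]
    chains = [[make() for make in chain] for chain in config.chains]
    # stage input queues: stage 0 reads the hardware queue directly
    stage_queues: List[List[ChannelQueue]] = [
        [ChannelQueue(config.queue_capacity) for _ in chain[1:]] for chain in chains
    ]
    outputs: List[list] = [[] for _ in range(acq.nch)]

    n_conv = math.floor(config.duration * acq.fs * acq.nch + 0.5**30)
    tint_ns = _NS / (acq.fs * acq.nch)
    n_ms = math.floor(config.duration * 1000)

    def run_task_round() -> None:
        for ch, chain in enumerate(chains):
            for si, stage in enumerate(chain):
                in_q = hw_queues[ch] if si == 0 else stage_queues[ch][si - 1]
                while len(in_q):
                    value = in_q.pop()
                    invocations[(ch, si)] = invocations.get((ch, si), 0) + 1
                    for out in stage.process(value):
                        if si + 1 < len(chain):
                            stage_queues[ch][si].push(out)
                        else:
                            outputs[ch].append(out)
                    if not config.drain_full:
                        break

    invocations: dict = {}
    k = 0  # next conversion index
    m = 1  # next ms tick
    while k < n_conv or m <= n_ms:
        t_acq = round(k * tint_ns) if k < n_conv else None
        t_ms = m * 1_000_000 if m <= n_ms else None
        t_now = min(t for t in (t_acq, t_ms) if t is not None)
        if t_acq == t_now:
            acquisition_tick(source, acq, hw_queues, k)
            k += 1
        if t_ms == t_now:
            timers.tick()
            m += 1
        run_task_round()

    log = EventLog()
    for ch in range(acq.nch):
        log.record_queue(f"hw/ch{ch}", hw_queues[ch])
        for si, q in enumerate(stage_queues[ch]):
            log.record_queue(f"ch{ch}/stage{si}->{si + 1}", q)
    for (ch, si), count in sorted(invocations.items()):
        log.stage_invocations[f"ch{ch}/{chains[ch][si].name}"] = count
    return PipelineResult(outputs=outputs, log=log)


def expected_sample_count(
    cfg: AcquisitionConfig, duration: float, D: int = 1
) -> int:
    """Reference per-channel output count: floor(floor(Fs·duration) / D).

    The bookkeeping target of the MTBF check: with no losses, every channel
    must deliver exactly this many decimated samples.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if D < 1:
        raise ValueError("decimation factor must be >= 1")
    return math.floor(cfg.fs * duration + 0.5**30) // D


def stage_factory_from_dict(d: dict) -> Callable[[], Stage]:
    """Build a stage factory from a JSON-style dict (``{"type": ...}``).

    Supported types: ``filter`` (keys b, a), ``polyphase`` (h, D),
    ``goertzel`` (cos_w0, N, optional mode), ``block_energy`` (L, H),
    ``fft`` (N).  Coefficients are raw Q15 integers.
    """
    kind = d.get("type")
    if kind == "filter":
        spec = FilterSpec(d["b"], d["a"])
        return lambda: FilterStage(spec)
    if kind == "polyphase":
        spec = PolyphaseSpec(d["h"], d["D"])
        return lambda: PolyphaseStage(spec)
    if kind == "goertzel":
        return lambda: GoertzelStage(
            d["cos_w0"], d["N"], mode=d.get("mode", "float")
        )
    if kind == "block_energy":
        return lambda: BlockEnergyStage(d["L"], d["H"])
    if kind == "fft":
        return lambda: FFTStage(d["N"])
    raise ValueError(f"unknown stage type {kind!r}")
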