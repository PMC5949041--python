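"""Non-blocking delays: software countdown timers driven by a 1 ms tick.

A hardware timer interrupt fires every millisecond; every ``T0r`` ticks
(default 10, i.e. a 10 ms resolution) the interrupt walks the list of
installed timers and decrements each non-zero one.  Application code never
waits: it installs a timer, polls ``expired`` and ``retrigger``s it, so the
data pipeline keeps flowing.  A timer loaded with count ``k`` therefore
expires exactly ``k * T0r`` ms after (re)trigger — in simulation the drift
is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

__all__ = ["SoftTimer", "TimerSystem", "TimerInstallError"]


class TimerInstallError(RuntimeError):
    """Installing an already-installed timer, or uninstalling a foreign one."""


@dataclass
class SoftTimer:
    """Countdown timer in units of the system resolution ``T0r`` ms.

    ``timeout`` is the remaining count, ``timeout_initial`` the reload value
    used by :meth:`retrigger`.  Expiry is level-signalled: ``expired`` stays
    true until the timer is retriggered.
    """

    timeout_initial: int
    timeout: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.timeout_initial < 0:
            raise ValueError("timeout_initial must be non-negative")
        if self.timeout < 0:
            self.timeout = self.timeout_initial

    @property
    def expired(self) -> bool:
        return self.timeout == 0

    def retrigger(self) -> None:
        self.timeout = self.timeout_initial

    def decrease(self) -> None:
        if self.timeout > 0:
            self.timeout -= 1


class TimerSystem:
    """The 1 ms tick source and the ordered list of installed timers."""

    def __init__(self, t0r: int = 10) -> None:
        if t0r < 1:
            raise ValueError("resolution T0r must be >= 1 ms")
        self.t0r = int(t0r)
        self.installed: List[SoftTimer] = []
        self.tick_count = 0  # ms elapsed

    @property
    def nt(self) -> int:
        return len(self.installed)

    def install(self, timer: SoftTimer) -> None:
        if any(t is timer for t in self.installed):
            raise TimerInstallError("timer already installed")
        self.installed.append(timer)

    def uninstall(self, timer: SoftTimer) -> None:
        for i, t in enumerate(self.installed):
            if t is timer:
                del self.installed[i]
                return
        raise TimerInstallError("timer not installed")

    def tick(self) -> None:
        """Advance 1 ms; on every T0r-th tick decrement all installed timers."""
        self.tick_count += 1
        if self.tick_count % self.t0r == 0:
            for t in self.installed:  # installation order, for determinism
                t.decrease()
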