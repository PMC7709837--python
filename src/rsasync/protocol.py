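"""Paced deep-breathing protocol and its synchronized sampling windows.

The guided breathing pattern is 6 breaths/min: 3 s inhale, 3 s hold,
3 s exhale, 1 s pause, for a 10 s cycle.  Heart rate is sampled in two
1-second windows locked to the cycle: 2.5-3.5 s (end of inspiration) and
7.5-8.5 s (mid expiration), giving one window every 5 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class BreathingProtocol:
    """Timing of the paced-breathing cycle and its HR sampling windows.

    All durations in seconds.  ``origin`` is the recording time at which
    cycle phase zero (start of the first inhale) occurs.  Windows are
    half-open ``[start, end)`` in cycle time.
    """

    inhale: float = 3.0
    hold: float = 3.0
    exhale: float = 3.0
    pause: float = 1.0
    insp_window: tuple[float, float] = (2.5, 3.5)
    exp_window: tuple[float, float] = (7.5, 8.5)
    origin: float = 0.0

    def __post_init__(self) -> None:
        for name in ("inhale", "hold", "exhale", "pause"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for win, name in ((self.insp_window, "insp_window"),
                          (self.exp_window, "exp_window")):
            lo, hi = win
            if not (0.0 <= lo < hi <= self.cycle):
                raise ValueError(f"{name} {win} not within [0, {self.cycle})")
        if self.insp_window[1] > self.exp_window[0]:
            raise ValueError("inspiration and expiration windows overlap")

    @property
    def cycle(self) -> float:
        """Full cycle length: inhale + hold + exhale + pause."""
        return self.inhale + self.hold + self.exhale + self.pause

    @property
    def breaths_per_minute(self) -> float:
        return 60.0 / self.cycle

    @property
    def update_spacing(self) -> float:
        """Spacing between consecutive window centres (insp -> exp)."""
        insp_mid = 0.5 * (self.insp_window[0] + self.insp_window[1])
        exp_mid = 0.5 * (self.exp_window[0] + self.exp_window[1])
        return exp_mid - insp_mid

    def cycle_start(self, k: int) -> float:
        """Recording time at which cycle ``k`` begins."""
        return self.origin + k * self.cycle

    def insp_window_abs(self, k: int) -> tuple[float, float]:
        """Inspiration window of cycle ``k`` in recording time."""
        t0 = self.cycle_start(k)
        return (t0 + self.insp_window[0], t0 + self.insp_window[1])

    def exp_window_abs(self, k: int) -> tuple[float, float]:
        """Expiration window of cycle ``k`` in recording time."""
        t0 = self.cycle_start(k)
        return (t0 + self.exp_window[0], t0 + self.exp_window[1])

    def n_cycles(self, duration: float) -> int:
        """Number of complete cycles inside a recording of ``duration`` s."""
        if duration <= self.origin:
            return 0
        return int((duration - self.origin) // self.cycle)


DEFAULT_PROTOCOL = BreathingProtocol()
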