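"""Real-time breathing-compliance feedback: threshold test and balloon score.

Every 5 s (each time a protocol sampling window closes) the engine forms the
rolling ratio of the most recent inspiration-window HR to the most recent
expiration-window HR, classifies it against the HR-I:E_sync threshold (1.1,
boundary inclusive), and advances the game's exponential altitude score.
The growth factor is calibrated so 24 consecutive compliant updates — 120 s
of continuous compliance — carry the balloon from 1 m to exactly
1,000,000 m.  Altitude is accumulated in the exponent (compliant-update
count), so the endpoint is exact and drift-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .beat_detect import Tachogram
from .protocol import BreathingProtocol, DEFAULT_PROTOCOL
from .rsa_metrics import window_hr

__all__ = [
    "FeedbackConfig",
    "FeedbackState",
    "classify_update",
    "growth_factor",
    "step",
    "run_session",
]


@dataclass(frozen=True)
class FeedbackConfig:
    """Compliance threshold and altitude-score schedule."""

    threshold: float = 1.1
    update_interval: float = 5.0
    altitude_start: float = 1.0
    altitude_target: float = 1_000_000.0
    target_time: float = 120.0
    noncompliance_policy: str = "hold"  # "hold" | "decay"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.update_interval <= 0 or self.target_time <= 0:
            raise ValueError("intervals must be positive")
        if self.altitude_start <= 0 or self.altitude_target <= self.altitude_start:
            raise ValueError("need 0 < altitude_start < altitude_target")
        if self.noncompliance_policy not in ("hold", "decay"):
            raise ValueError(
                f"unknown noncompliance_policy {self.noncompliance_policy!r}")

    @property
    def updates_to_target(self) -> float:
        return self.target_time / self.update_interval


def growth_factor(cfg: FeedbackConfig) -> float:
    """Per-update altitude multiplier G = (target/start)^(interval/target_time)."""
    return (cfg.altitude_target / cfg.altitude_start) ** (1.0 / cfg.updates_to_target)


def _altitude(cfg: FeedbackConfig, exponent_steps: float) -> float:
    # exact at the endpoint: 24 steps -> exponent 1 -> altitude_target
    return cfg.altitude_start * (
        cfg.altitude_target / cfg.altitude_start
    ) ** (exponent_steps / cfg.updates_to_target)


@dataclass(frozen=True)
class FeedbackState:
    """Session state: time, altitude, and the full update trace."""

    t: float = 0.0
    altitude: float = 1.0
    last_ratio: float | None = None
    compliant_updates: int = 0
    exponent_steps: int = 0  # net steps under the decay policy
    trace: tuple = ()

    @classmethod
    def initial(cls, cfg: FeedbackConfig) -> "FeedbackState":
        return cls(t=0.0, altitude=cfg.altitude_start)


def classify_update(ratio: float, cfg: FeedbackConfig) -> bool:
    """Compliant iff the rolling HR-I:E_sync ratio >= threshold (inclusive)."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return ratio >= cfg.threshold


def step(state: FeedbackState, compliant: bool, cfg: FeedbackConfig,
         ratio: float | None = None, t: float | None = None) -> FeedbackState:
    """Advance one 5-s update: grow the altitude on compliance, else hold/decay."""
    if compliant:
        exp_steps = state.exponent_steps + 1
        n_comp = state.compliant_updates + 1
    else:
        n_comp = state.compliant_updates
        if cfg.noncompliance_policy == "decay":
            exp_steps = max(state.exponent_steps - 1, 0)
        else:
            exp_steps = state.exponent_steps
    alt = _altitude(cfg, exp_steps)
    t = state.t + cfg.update_interval if t is None else t
    return replace(
        state, t=t, altitude=alt, last_ratio=ratio,
        compliant_updates=n_comp, exponent_steps=exp_steps,
        trace=state.trace + ((t, ratio, compliant, alt),))


def run_session(tach: Tachogram,
                protocol: BreathingProtocol = DEFAULT_PROTOCOL,
                cfg: FeedbackConfig = FeedbackConfig(),
                duration: float | None = None) -> FeedbackState:
    """Replay a tachogram through the real-time feedback loop.

    Updates fire at each sampling-window close (origin + 3.5 s, 8.5 s,
    13.5 s, ... — one every 5 s).  The rolling ratio pairs the most recent
    valid inspiration-window HR with the most recent valid expiration-window
    HR; updates before both exist emit no decision and leave the altitude
    unchanged.
    """
    end = duration if duration is not None else tach.span[1]
    if protocol.n_cycles(end) < 1:
        raise ValueError("tachogram must cover at least one full cycle")

    # every sampling window that closes within the session is an update,
    # including a trailing inspiration window of a partially covered cycle
    events: list[tuple[float, str, tuple[float, float]]] = []
    k = 0
    while True:
        added = False
        for kind, win in (("insp", protocol.insp_window_abs(k)),
                          ("exp", protocol.exp_window_abs(k))):
            if win[1] <= end + 1e-9:
                events.append((win[1], kind, win))
                added = True
        if not added:
            break
        k += 1
    events.sort(key=lambda e: e[0])

    state = FeedbackState.initial(cfg)
    last: dict[str, float] = {}
    for t_close, kind, win in events:
        est = window_hr(tach, *win)
        if est.valid:
            last[kind] = est.hr
        if "insp" in last and "exp" in last:
            ratio = last["insp"] / last["exp"]
            state = step(state, classify_update(ratio, cfg), cfg,
                         ratio=ratio, t=t_close)
        else:
            state = replace(
                state, t=t_close,
                trace=state.trace + ((t_close, None, None, state.altitude),))
    return state
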