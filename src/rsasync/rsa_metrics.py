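"""Protocol-synchronized windowed heart rates, RSA_sync and HR-I:E_sync.

Heart rate is sampled in two 1-second windows locked to the 10-s breathing
cycle (2.5-3.5 s for inspiration, 7.5-8.5 s for expiration).  Per cycle,

    RSA_sync   = HR_inspiration - HR_expiration        (bpm)
    HR-I:E_sync = HR_inspiration / HR_expiration       (dimensionless)

and the participant-level value is the average over valid cycles.  Window
heart rate is the time-weighted mean of the beat-to-beat IHR step function
over the window, using only physiologically in-range inter-beat intervals;
a window is invalid when those intervals cover less than half of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beat_detect import Tachogram
from .protocol import BreathingProtocol, DEFAULT_PROTOCOL

__all__ = [
    "WindowEstimate",
    "CycleRSA",
    "ParticipantSummary",
    "InsufficientCyclesError",
    "MIN_VALID_CYCLES",
    "window_hr",
    "cycle_metrics",
    "analyze_tachogram",
    "participant_summary",
]

MIN_VALID_CYCLES = 4
_MIN_COVERAGE = 0.5


class InsufficientCyclesError(ValueError):
    """Raised when too few valid cycles exist for a participant summary."""

    def __init__(self, n_valid: int, n_total: int, required: int):
        self.n_valid, self.n_total, self.required = n_valid, n_total, required
        super().__init__(
            f"only {n_valid} of {n_total} cycles valid; need {required}")


@dataclass(frozen=True)
class WindowEstimate:
    """Time-weighted mean HR over one window, or the reason it is invalid."""

    hr: float | None
    coverage: float
    valid: bool
    reason: str = ""


@dataclass(frozen=True)
class CycleRSA:
    """Windowed heart rates and synchronized RSA measures of one cycle."""

    cycle_index: int
    hr_insp: float | None
    hr_exp: float | None
    rsa_sync: float | None
    ratio: float | None
    valid: bool
    reason: str = ""


@dataclass(frozen=True)
class ParticipantSummary:
    """Per-participant averages over valid cycles, by recording mode."""

    participant_id: str
    mode: str
    n_valid_cycles: int
    mean_ratio: float
    mean_rsa_sync: float
    mean_hr_insp: float
    mean_hr_exp: float
    age_years: int | None = None


def window_hr(tach: Tachogram, t_start: float, t_end: float) -> WindowEstimate:
    """Time-weighted mean of the IHR step function over [t_start, t_end).

    Only in-range inter-beat intervals contribute; the window is invalid if
    they cover less than 50% of its length.
    """
    if t_end <= t_start:
        raise ValueError("window must satisfy t_end > t_start")
    width = t_end - t_start
    lo = np.maximum(tach.beat_times[:-1], t_start)
    hi = np.minimum(tach.beat_times[1:], t_end)
    overlap = np.clip(hi - lo, 0.0, None) * tach.in_range
    covered = float(overlap.sum())
    coverage = covered / width
    if covered == 0.0:
        return WindowEstimate(None, 0.0, False, "no coverage")
    if coverage < _MIN_COVERAGE:
        return WindowEstimate(None, coverage, False,
                              f"coverage {coverage:.0%} below 50%")
    hr = float(np.dot(overlap, tach.ihr) / covered)
    return WindowEstimate(hr, coverage, True)


def cycle_metrics(tach: Tachogram,
                  protocol: BreathingProtocol,
                  k: int,
                  duration: float | None = None) -> CycleRSA:
    """Windowed HRs and RSA measures for breathing cycle ``k``.

    ``duration`` (recording length) bounds the cycle when known; a cycle
    extending past it raises.  Invalid windows mark the cycle invalid with
    the offending reason rather than raising.
    """
    if k < 0:
        raise ValueError("cycle index must be non-negative")
    if duration is not None and protocol.cycle_start(k + 1) > duration + 1e-9:
        raise ValueError(f"cycle {k} extends past the {duration} s recording")

    insp = window_hr(tach, *protocol.insp_window_abs(k))
    exp = window_hr(tach, *protocol.exp_window_abs(k))
    if not (insp.valid and exp.valid):
        reasons = "; ".join(
            f"{name} window: {w.reason}"
            for name, w in (("insp", insp), ("exp", exp)) if not w.valid)
        return CycleRSA(k, insp.hr, exp.hr, None, None, False, reasons)
    return CycleRSA(
        cycle_index=k, hr_insp=insp.hr, hr_exp=exp.hr,
        rsa_sync=insp.hr - exp.hr, ratio=insp.hr / exp.hr, valid=True)


def analyze_tachogram(tach: Tachogram,
                      protocol: BreathingProtocol = DEFAULT_PROTOCOL,
                      duration: float | None = None,
                      discard_first: bool = False) -> list[CycleRSA]:
    """Per-cycle metrics for every complete cycle slot in the recording.

    The slot count comes from ``duration`` when given (a 60-s recording has
    6 slots, a 120-s one 12, origin 0), otherwise from the tachogram span.
    ``discard_first`` drops cycle 0 (protocol transition warm-up).
    """
    end = duration if duration is not None else tach.span[1]
    n = protocol.n_cycles(end)
    cycles = [cycle_metrics(tach, protocol, k, duration) for k in range(n)]
    return cycles[1:] if discard_first else cycles


def participant_summary(cycles: list[CycleRSA],
                        participant_id: str = "",
                        mode: str = "",
                        age_years: int | None = None,
                        min_cycles: int = MIN_VALID_CYCLES,
                        ratio_of_means: bool = False) -> ParticipantSummary:
    """Average the per-cycle measures into one participant-level row.

    Default: mean of per-cycle ratios.  ``ratio_of_means`` instead divides
    the session-mean inspiration HR by the session-mean expiration HR.
    """
    valid = [c for c in cycles if c.valid]
    if len(valid) < min_cycles:
        raise InsufficientCyclesError(len(valid), len(cycles), min_cycles)
    hr_i = float(np.mean([c.hr_insp for c in valid]))
    hr_e = float(np.mean([c.hr_exp for c in valid]))
    if ratio_of_means:
        mean_ratio = hr_i / hr_e
    else:
        mean_ratio = float(np.mean([c.ratio for c in valid]))
    return ParticipantSummary(
        participant_id=participant_id, mode=mode,
        n_valid_cycles=len(valid),
        mean_ratio=mean_ratio,
        mean_rsa_sync=float(np.mean([c.rsa_sync for c in valid])),
        mean_hr_insp=hr_i, mean_hr_exp=hr_e, age_years=age_years)
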