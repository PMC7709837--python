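"""Beat detection from raw PPG and the beat-to-beat heart-rate tachogram.

The detector band-limits the waveform to 0.5-4 Hz with a fourth-order
Butterworth band-pass and places candidate beats at negative-going zero
crossings of the first-difference signal (local maxima of the filtered
waveform), refined by linear interpolation.  Candidates falling within a
refractory period keep only the larger-amplitude peak, and low-amplitude
ripple maxima are rejected against a robust fraction of the typical peak
height.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synth_ppg import PPGRecording

__all__ = [
    "FilterSpec",
    "BeatSeries",
    "Tachogram",
    "InsufficientBeatsError",
    "bandpass",
    "estimate_latency",
    "detect_beats",
    "build_tachogram",
    "detect_from_recording",
    "match_beats",
]

# Physiological inter-beat-interval bounds: 0.25 s refractory (240 bpm
# ceiling) and 2 s gap flag (30 bpm floor); out-of-range intervals are
# excluded from windowed HR estimates downstream.
DEFAULT_REFRACTORY = 0.25
MAX_IBI = 2.0

# Reject candidate maxima below this fraction of the robust peak height
# (75th percentile of positive-maximum amplitudes); suppresses noise ripple
# between pulses without tracking a full adaptive threshold.
_AMP_GATE_FRACTION = 0.3


class InsufficientBeatsError(ValueError):
    """Raised when fewer than two beats are available for a tachogram."""


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification: 0.5-4 Hz, total order 4 by default.

    ``order`` is the total filter order of the band-pass (Butterworth, two
    poles per band edge at the default 4).  ``zero_phase`` applies the
    filter forward-backward, which doubles the effective attenuation order
    and removes group delay; the causal mode is a single forward pass for
    streaming use, whose constant passband latency can be estimated with
    :func:`estimate_latency` and subtracted before window lookup.
    """

    low: float = 0.5
    high: float = 4.0
    order: int = 4
    phase_mode: str = "zero_phase"  # "zero_phase" | "causal"

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError("need 0 < low < high")
        if self.order < 2 or self.order % 2:
            raise ValueError("order must be an even integer >= 2")
        if self.phase_mode not in ("zero_phase", "causal"):
            raise ValueError(f"unknown phase_mode {self.phase_mode!r}")

    def validate_against(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band edge {self.high} Hz is not below the Nyquist "
                f"frequency {fs / 2} Hz")

    def sos(self, fs: float) -> np.ndarray:
        self.validate_against(fs)
        return sps.butter(self.order // 2, [self.low, self.high],
                          btype="bandpass", fs=fs, output="sos")


@dataclass(frozen=True)
class BeatSeries:
    """Detected beat times in seconds, strictly increasing."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def bandpass(rec: PPGRecording | np.ndarray,
             spec: FilterSpec = FilterSpec(),
             fs: float | None = None) -> np.ndarray:
    """Band-limit a PPG signal to the FilterSpec passband.

    Accepts a :class:`PPGRecording` or a bare array plus ``fs``.  Output
    length equals input length in both phase modes.
    """
    if isinstance(rec, PPGRecording):
        x, fs = rec.samples, rec.fs
    else:
        x = np.asarray(rec, dtype=float)
        if fs is None:
            raise ValueError("fs is required with a bare array")
    sos = spec.sos(fs)
    # settling span: ~3 periods of the low edge
    if x.size <= 3 * fs / spec.low / 4:
        raise ValueError("signal too short for the filter settling span")
    if spec.phase_mode == "zero_phase":
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def estimate_latency(spec: FilterSpec, fs: float) -> float:
    """Constant latency (s) of the causal filter at the band centre.

    Group delay evaluated at the geometric mean of the band edges; subtract
    this from detected beat times before protocol window lookup when running
    the causal/streaming mode.
    """
    f0 = np.sqrt(spec.low * spec.high)
    b, a = sps.sos2tf(spec.sos(fs))
    w, gd = sps.group_delay((b, a), w=[2 * np.pi * f0 / fs])
    return float(gd[0] / fs)


def detect_beats(filtered: np.ndarray,
                 fs: float,
                 refractory: float = DEFAULT_REFRACTORY) -> BeatSeries:
    """Detect beats at negative-going zero crossings of the difference signal.

    The first-order difference d[n] = x[n] - x[n-1] changes sign from
    positive to negative at local maxima of the filtered waveform; the
    crossing time is refined by linear interpolation between the bracketing
    samples.  Flat tops take the earliest sample of the flat region.
    Candidates closer than ``refractory`` keep the larger peak; maxima below
    a robust amplitude gate are dropped.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    x = np.asarray(filtered, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return BeatSeries(times=np.empty(0))

    d = np.diff(x)
    # negative-going crossing: d[i] > 0 and the next nonzero diff is < 0;
    # exact zeros (flat tops) resolve to the earliest sample of the flat.
    cand = np.where((d[:-1] > 0) & (d[1:] <= 0))[0]
    times_l: list[float] = []
    amps_l: list[float] = []
    for i in cand:
        k = i + 1
        while k < d.size and d[k] == 0:
            k += 1
        if k >= d.size or d[k] >= 0:
            continue  # rise ran into the signal end or resumed rising
        if k == i + 1:
            # interpolate the crossing of d between samples i and i+1
            frac = d[i] / (d[i] - d[k])
            times_l.append((i + 0.5 + frac) / fs)
        else:
            times_l.append((i + 1) / fs)  # earliest sample of the flat top
        amps_l.append(x[i + 1])
    if not times_l:
        return BeatSeries(times=np.empty(0))
    times = np.asarray(times_l)
    amps = np.asarray(amps_l)

    # robust amplitude gate against noise-ripple maxima
    pos = amps[amps > 0]
    if pos.size:
        gate = _AMP_GATE_FRACTION * np.percentile(pos, 75)
        keep = amps >= gate
        times, amps = times[keep], amps[keep]

    # refractory suppression keeping the larger-amplitude peak
    kept_t: list[float] = []
    kept_a: list[float] = []
    for tt, aa in zip(times, amps):
        if kept_t and tt - kept_t[-1] < refractory:
            if aa > kept_a[-1]:
                kept_t[-1], kept_a[-1] = tt, aa
        else:
            kept_t.append(tt)
            kept_a.append(aa)
    return BeatSeries(times=np.asarray(kept_t))


@dataclass(frozen=True)
class Tachogram:
    """Beat-to-beat heart rate as a right-open step function in time.

    ``ihr[k] = 60 / ibi[k]`` holds on the interval
    ``[beat_times[k], beat_times[k+1])``.  Intervals outside the
    physiological bounds (refractory .. 2 s gap) are flagged and excluded
    from windowed estimates.
    """

    beat_times: np.ndarray
    ibi: np.ndarray = field(init=False)
    ihr: np.ndarray = field(init=False)
    in_range: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        if bt.size < 2:
            raise InsufficientBeatsError(
                f"tachogram needs at least 2 beats, got {bt.size}")
        if not np.all(np.diff(bt) > 0):
            raise ValueError("beat times must be strictly increasing")
        object.__setattr__(self, "beat_times", bt)
        ibi = np.diff(bt)
        object.__setattr__(self, "ibi", ibi)
        object.__setattr__(self, "ihr", 60.0 / ibi)
        object.__setattr__(
            self, "in_range", (ibi >= DEFAULT_REFRACTORY) & (ibi <= MAX_IBI))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.beat_times[0]), float(self.beat_times[-1])

    def ihr_at(self, t: np.ndarray | float) -> np.ndarray:
        """IHR of the interval containing ``t``; NaN outside [first, last)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.beat_times, t, side="right") - 1
        out = np.full(t.shape, np.nan)
        ok = (idx >= 0) & (idx < self.ihr.size)
        out[ok] = self.ihr[idx[ok]]
        return out


def build_tachogram(beats: BeatSeries | np.ndarray) -> Tachogram:
    """Build the IBI/IHR tachogram from a detected beat series."""
    times = beats.times if isinstance(beats, BeatSeries) else np.asarray(beats)
    return Tachogram(beat_times=times)


def detect_from_recording(rec: PPGRecording,
                          spec: FilterSpec = FilterSpec(),
                          refractory: float = DEFAULT_REFRACTORY) -> BeatSeries:
    """Convenience: band-pass a recording and detect its beats."""
    return detect_beats(bandpass(rec, spec), rec.fs, refractory)


def match_beats(true_times: np.ndarray, detected: np.ndarray,
                tol: float = 0.03) -> dict:
    """Match detected beats to ground truth within ``tol`` seconds.

    Greedy one-to-one nearest matching; returns hit rate, spurious rate and
    the matched absolute timing errors.
    """
    true_times = np.asarray(true_times, dtype=float)
    det = np.asarray(detected, dtype=float)
    used = np.zeros(det.size, dtype=bool)
    errors = []
    hits = 0
    for tt in true_times:
        if det.size == 0:
            break
        j = int(np.argmin(np.abs(det - tt) + np.where(used, np.inf, 0.0)))
        err = abs(det[j] - tt)
        if not used[j] and err <= tol:
            used[j] = True
            hits += 1
            errors.append(err)
    n_true = true_times.size
    spurious = int(det.size - used.sum())
    return {
        "n_true": int(n_true),
        "n_detected": int(det.size),
        "hit_rate": hits / n_true if n_true else float("nan"),
        "spurious_rate": spurious / det.size if det.size else 0.0,
        "errors": np.asarray(errors),
    }
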