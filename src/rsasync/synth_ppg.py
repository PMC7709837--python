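"""Synthetic participants and PPG recordings with known ground truth.

Emulates the study conditions: children aged 5-17 recorded for 1 minute of
spontaneous breathing and 2 minutes of paced deep breathing at 6 breaths/min.
Each participant has a baseline heart rate drawn from age-group-specific
distributions, a respiratory sinus arrhythmia (RSA) amplitude derived from a
target inspiration/expiration heart-rate ratio, and an instantaneous heart
rate (IHR) that is realized into beat times by an integrate-and-fire model
and rendered into a PPG waveform (pulse train + baseline wander + noise).

Ground truth (beat times, per-cycle window heart rates, participant-level
ratio) is attached to every recording so the detection and metric pipeline
can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .protocol import BreathingProtocol, DEFAULT_PROTOCOL

__all__ = [
    "ParticipantProfile",
    "NoiseConfig",
    "GeneratorConfig",
    "GroundTruth",
    "PPGRecording",
    "AGE_GROUPS",
    "draw_profile",
    "instantaneous_hr",
    "generate_beats",
    "render_ppg",
    "ground_truth_for",
    "simulate_cohort",
    "simulate_paired_cohort",
]

# Age groups used throughout the analysis (inclusive year ranges).
AGE_GROUPS: dict[str, tuple[int, int]] = {
    "5-7": (5, 7),
    "8-10": (8, 10),
    "11-13": (11, 13),
    "14-17": (14, 17),
}

# Cohort allocation across the four age groups for n=80.
_GROUP_WEIGHTS = {"5-7": 18, "8-10": 20, "11-13": 21, "14-17": 21}

# Group baseline-HR centres: midpoint of the spontaneous-mode inspiration-
# and expiration-window median heart rates observed per age group.
_BASELINE_HR_MEAN = {"5-7": 81.6, "8-10": 79.75, "11-13": 89.55, "14-17": 85.35}

# Fixed rendering constants: the pulse peak sits exactly at the beat time
# (documented pulse offset = 0.0 s); a smaller dicrotic lobe trails it.
PULSE_OFFSET = 0.0
_SYSTOLIC_SIGMA = 0.06   # s
_DICROTIC_DELAY = 0.25   # s
_DICROTIC_AMP = 0.3      # relative to systolic lobe
_DICROTIC_SIGMA = 0.09   # s
_ARTIFACT_SIGMA = 0.04   # s, transient spike width


@dataclass(frozen=True)
class NoiseConfig:
    """Additive disturbances for the rendered PPG (arbitrary units).

    ``wander_amp``/``wander_freq`` describe sinusoidal baseline wander
    (respiratory/venous), ``white_sigma`` the sensor noise floor, and
    ``artifact_rate`` the expected count of transient motion spikes per
    minute.
    """

    wander_amp: float = 0.3
    wander_freq: float = 0.2
    white_sigma: float = 0.05
    artifact_rate: float = 2.0

    def __post_init__(self) -> None:
        for name in ("wander_amp", "wander_freq", "white_sigma", "artifact_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(wander_amp=0.0, white_sigma=0.0, artifact_rate=0.0)


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent parameters of one simulated participant.

    ``rsa_amp`` is half the peak-to-trough heart-rate modulation in bpm.
    ``resp_period`` and ``phase_offset`` describe the participant's own
    breathing rhythm and matter only in spontaneous mode (paced mode is
    phase-locked to the protocol).  ``resp_jitter`` is the multiplicative
    per-breath period jitter fraction.
    """

    id: str
    age_years: int
    baseline_hr: float
    rsa_amp: float
    resp_mode: str  # "paced" | "spontaneous"
    resp_period: float = 4.0
    phase_offset: float = 0.0
    resp_jitter: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 5 <= self.age_years <= 17:
            raise ValueError("age_years must be in 5-17")
        if not 50.0 <= self.baseline_hr <= 140.0:
            raise ValueError("baseline_hr must be within [50, 140] bpm")
        if self.rsa_amp < 0:
            raise ValueError("rsa_amp must be non-negative")
        if self.baseline_hr - self.rsa_amp <= 30.0:
            raise ValueError("baseline_hr - rsa_amp must exceed 30 bpm")
        if self.resp_mode not in ("paced", "spontaneous"):
            raise ValueError(f"unknown resp_mode {self.resp_mode!r}")
        if self.resp_mode == "spontaneous" and not 2.5 <= self.resp_period <= 6.0:
            raise ValueError("spontaneous resp_period must be in [2.5, 6.0] s")


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generator settings.

    The paced-mode target-ratio distribution is a Beta(a, b) scaled onto
    ``ratio_support``; its defaults put the median near 1.26 with support
    [1.01, 1.60].  Spontaneous mode attenuates the RSA amplitude by
    ``spont_attenuation`` and breathes at the participant's own period,
    uniform over ``resp_period_range`` with random phase.
    """

    fs: float = 100.0
    baseline_hr_mean: dict[str, float] = field(
        default_factory=lambda: dict(_BASELINE_HR_MEAN))
    baseline_hr_sd: float = 9.0
    baseline_hr_bounds: tuple[float, float] = (55.0, 130.0)
    ratio_beta_a: float = 2.0
    ratio_beta_b: float = 2.6
    ratio_support: tuple[float, float] = (1.01, 1.60)
    spont_attenuation: float = 0.5
    resp_period_range: tuple[float, float] = (2.5, 5.0)
    resp_jitter: float = 0.10
    spont_duration: float = 60.0
    paced_duration: float = 120.0
    group_weights: dict[str, int] = field(
        default_factory=lambda: dict(_GROUP_WEIGHTS))
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    # fraction of hold at whose end g has decayed to this plateau level
    plateau_level: float = 0.5

    def __post_init__(self) -> None:
        if self.fs < 25.0:
            raise ValueError("fs must be at least 25 Hz")
        lo, hi = self.ratio_support
        if not 1.0 <= lo < hi:
            raise ValueError("ratio_support must satisfy 1 <= lo < hi")
        if self.ratio_beta_a <= 0 or self.ratio_beta_b <= 0:
            raise ValueError("Beta parameters must be positive")
        if not 0.0 <= self.spont_attenuation <= 1.0:
            raise ValueError("spont_attenuation must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Oracle values attached to a simulated recording."""

    beat_times: np.ndarray
    true_cycle_metrics: list[tuple[float, float]]  # (hr_insp, hr_exp) per cycle
    true_participant_ratio: float

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        if bt.size > 1 and not np.all(np.diff(bt) > 0):
            raise ValueError("beat_times must be strictly increasing")
        if self.true_participant_ratio <= 0:
            raise ValueError("true_participant_ratio must be positive")


@dataclass
class PPGRecording:
    """Raw sampled PPG waveform with acquisition metadata."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


# ---------------------------------------------------------------------------
# RSA modulation waveform

def _modulation_params(protocol: BreathingProtocol, plateau: float) -> tuple[float, float]:
    """Solve for the cycle-start level s0 making g exactly zero-mean.

    g is piecewise raised-cosine: s0 -> +1 over the inhale, +1 -> plateau
    over the hold, plateau -> -1 reaching the trough at the expiration
    window centre, then -1 -> s0 over the remainder of the cycle.  Each
    raised-cosine segment has mean (a+b)/2, so the zero-mean condition is
    linear in s0.
    """
    ti, th = protocol.inhale, protocol.hold
    cycle = protocol.cycle
    t_min = 0.5 * (protocol.exp_window[0] + protocol.exp_window[1])
    d_desc = t_min - ti - th          # descent span
    d_rise = cycle - t_min            # recovery span
    if d_desc <= 0 or d_rise <= 0:
        raise ValueError("expiration-window centre must lie after the hold "
                         "and before the cycle end")
    # 0 = ti*(s0+1)/2 + th*(1+p)/2 + d_desc*(p-1)/2 + d_rise*(-1+s0)/2
    s0 = -(ti + th * (1 + plateau) + d_desc * (plateau - 1)
           - d_rise) / (ti + d_rise)
    if s0 < -1.0 - 1e-12:
        raise ValueError("modulation start level below -1; adjust plateau")
    return max(s0, -1.0), t_min


def _raised_cosine(u: np.ndarray, a: float, b: float, span: float) -> np.ndarray:
    return a + (b - a) * 0.5 * (1.0 - np.cos(np.pi * u / span))


def modulation_waveform(u: np.ndarray | float,
                        protocol: BreathingProtocol = DEFAULT_PROTOCOL,
                        plateau: float = 0.5) -> np.ndarray:
    """Zero-mean, unit-peak RSA modulation g evaluated at cycle time ``u``.

    g(+1) at the end of the inhale, g(-1) at the expiration-window centre
    (mid expiration); exactly zero mean over one cycle by construction.
    """
    u = np.asarray(u, dtype=float) % protocol.cycle
    s0, t_min = _modulation_params(protocol, plateau)
    ti, th = protocol.inhale, protocol.hold
    cycle = protocol.cycle
    g = np.empty_like(u)

    m = u < ti
    g[m] = _raised_cosine(u[m], s0, 1.0, ti)
    m = (u >= ti) & (u < ti + th)
    g[m] = _raised_cosine(u[m] - ti, 1.0, plateau, th)
    m = (u >= ti + th) & (u < t_min)
    g[m] = _raised_cosine(u[m] - ti - th, plateau, -1.0, t_min - ti - th)
    m = u >= t_min
    g[m] = _raised_cosine(u[m] - t_min, -1.0, s0, cycle - t_min)
    return g


def _breath_boundaries(profile: ParticipantProfile, t_max: float) -> np.ndarray:
    """Start times of successive spontaneous breaths covering [0, t_max].

    Periods are the participant's resp_period with multiplicative per-breath
    jitter, drawn deterministically from the profile seed; the first breath
    starts at -phase_offset so phase is random relative to the recording.
    """
    rng = np.random.default_rng(np.random.SeedSequence([profile.seed, 0x5EED]))
    bounds = [-profile.phase_offset]
    while bounds[-1] <= t_max:
        jitter = 1.0 + profile.resp_jitter * rng.uniform(-1.0, 1.0)
        bounds.append(bounds[-1] + profile.resp_period * jitter)
    return np.asarray(bounds)


def instantaneous_hr(profile: ParticipantProfile,
                     protocol: BreathingProtocol,
                     t: np.ndarray | float) -> np.ndarray:
    """Instantaneous heart rate (bpm) at time(s) ``t`` seconds.

    IHR(t) = baseline_hr + rsa_amp * g(phase(t)).  In paced mode the phase
    is locked to the protocol grid; in spontaneous mode it advances through
    the participant's own jittered breath cycle, rescaled onto the canonical
    cycle shape.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if profile.rsa_amp == 0.0:
        return np.full_like(t, profile.baseline_hr)

    if profile.resp_mode == "paced":
        u = (t - protocol.origin - profile.phase_offset) % protocol.cycle
    else:
        bounds = _breath_boundaries(profile, float(t.max()))
        idx = np.searchsorted(bounds, t, side="right") - 1
        frac = (t - bounds[idx]) / (bounds[idx + 1] - bounds[idx])
        u = frac * protocol.cycle
    return profile.baseline_hr + profile.rsa_amp * modulation_waveform(u, protocol)


# ---------------------------------------------------------------------------
# Beat generation and waveform rendering

def generate_beats(profile: ParticipantProfile,
                   protocol: BreathingProtocol,
                   duration: float,
                   grid_dt: float = 1e-3) -> np.ndarray:
    """Integrate-and-fire realization of the instantaneous heart rate.

    A beat is emitted whenever the running integral of IHR/60 crosses an
    integer; crossing times are found by inverse interpolation of the
    cumulative integral on a fine grid.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.arange(0.0, duration + grid_dt, grid_dt)
    rate = instantaneous_hr(profile, protocol, t) / 60.0
    cum = np.concatenate([[0.0], cumulative_trapezoid(rate, t)])
    n_beats = int(math.floor(cum[-1]))
    if n_beats < 1:
        return np.empty(0)
    beats = np.interp(np.arange(1, n_beats + 1, dtype=float), cum, t)
    return beats[beats <= duration]


def _add_pulses(signal: np.ndarray, t: np.ndarray, beat_times: np.ndarray,
                fs: float) -> None:
    half = 0.6  # s, support of one pulse
    n = signal.size
    for tb in beat_times:
        i0 = max(0, int((tb - half) * fs))
        i1 = min(n, int((tb + half + _DICROTIC_DELAY) * fs) + 1)
        tt = t[i0:i1]
        signal[i0:i1] += (
            np.exp(-0.5 * ((tt - tb - PULSE_OFFSET) / _SYSTOLIC_SIGMA) ** 2)
            + _DICROTIC_AMP
            * np.exp(-0.5 * ((tt - tb - PULSE_OFFSET - _DICROTIC_DELAY)
                             / _DICROTIC_SIGMA) ** 2)
        )


def render_ppg(beat_times: np.ndarray,
               fs: float,
               noise: NoiseConfig,
               duration: float,
               rng: np.random.Generator | None = None,
               meta: dict | None = None) -> PPGRecording:
    """Render beat times into a sampled PPG waveform.

    Each beat contributes a fixed asymmetric pulse (unit systolic lobe plus
    a 0.3-amplitude dicrotic lobe delayed 0.25 s) whose systolic peak falls
    exactly at the beat time.  Sinusoidal baseline wander, white noise and
    optional transient artifacts are added on top.
    """
    if fs < 25.0:
        raise ValueError("fs must be at least 25 Hz")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and (beat_times.min() < 0 or beat_times.max() > duration):
        raise ValueError("beat_times must lie within [0, duration]")

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sig = np.zeros(n)
    _add_pulses(sig, t, beat_times, fs)

    if noise.wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi) if rng is not None else 0.0
        sig += noise.wander_amp * np.sin(2 * np.pi * noise.wander_freq * t + phase)
    if noise.white_sigma > 0:
        if rng is None:
            raise ValueError("white noise requested but no rng supplied")
        sig += rng.normal(0.0, noise.white_sigma, n)
    if noise.artifact_rate > 0:
        if rng is None:
            raise ValueError("artifacts requested but no rng supplied")
        k = rng.poisson(noise.artifact_rate * duration / 60.0)
        for _ in range(k):
            tc = rng.uniform(0, duration)
            amp = rng.uniform(2.0, 4.0) * rng.choice([-1.0, 1.0])
            sig += amp * np.exp(-0.5 * ((t - tc) / _ARTIFACT_SIGMA) ** 2)

    return PPGRecording(samples=sig, fs=fs, meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# Profile and cohort drawing

def _age_group_of(age: int) -> str:
    for name, (lo, hi) in AGE_GROUPS.items():
        if lo <= age <= hi:
            return name
    raise ValueError(f"age {age} outside the study range 5-17")


def draw_ratio(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    """Draw a paced-mode target inspiration/expiration HR ratio."""
    lo, hi = cfg.ratio_support
    return lo + (hi - lo) * rng.beta(cfg.ratio_beta_a, cfg.ratio_beta_b)


def draw_profile(rng: np.random.Generator,
                 age_group: str,
                 mode: str,
                 cfg: GeneratorConfig | None = None,
                 pid: str = "P000",
                 seed: int = 0) -> ParticipantProfile:
    """Draw one participant profile for the given age group and mode.

    The RSA amplitude follows from the drawn target ratio r through
    ``rsa_amp = baseline_hr * (r - 1) / (r + 1)`` (so that the ratio of the
    modulation extremes (b + a)/(b - a) equals r).  Draw order is fixed —
    age, baseline, ratio, then mode-specific parameters — so the same rng
    state yields the same latent participant in either mode (paired design).
    """
    cfg = cfg or GeneratorConfig()
    if age_group not in AGE_GROUPS:
        raise ValueError(f"unknown age_group {age_group!r}; "
                         f"expected one of {sorted(AGE_GROUPS)}")
    if mode not in ("paced", "spontaneous"):
        raise ValueError(f"unknown mode {mode!r}")

    lo_age, hi_age = AGE_GROUPS[age_group]
    age = int(rng.integers(lo_age, hi_age + 1))
    lo_hr, hi_hr = cfg.baseline_hr_bounds
    baseline = float(np.clip(
        rng.normal(cfg.baseline_hr_mean[age_group], cfg.baseline_hr_sd),
        lo_hr, hi_hr))
    ratio = draw_ratio(rng, cfg)
    rsa_amp = baseline * (ratio - 1.0) / (ratio + 1.0)

    resp_period, phase_offset = 4.0, 0.0
    if mode == "spontaneous":
        rsa_amp *= cfg.spont_attenuation
        resp_period = float(rng.uniform(*cfg.resp_period_range))
        phase_offset = float(rng.uniform(0.0, resp_period))

    return ParticipantProfile(
        id=pid, age_years=age, baseline_hr=baseline, rsa_amp=rsa_amp,
        resp_mode=mode, resp_period=resp_period, phase_offset=phase_offset,
        resp_jitter=cfg.resp_jitter, seed=seed)


def ground_truth_for(profile: ParticipantProfile,
                     protocol: BreathingProtocol,
                     beat_times: np.ndarray,
                     duration: float) -> GroundTruth:
    """Oracle window heart rates from the exact (noise-free) beat times.

    The true per-cycle (hr_insp, hr_exp) are the time-weighted means of the
    IHR step function built from the exact integrate-and-fire beat times —
    i.e. what the windowed measure is defined to produce given perfect beat
    detection.  Recovery error against this truth therefore isolates
    rendering, filtering and detection errors.  (The windowed measure itself
    deliberately underestimates the continuous RSA modulation; that bias is
    a property of the measure, not of the pipeline.)
    """
    from .rsa_metrics import window_hr  # local import: avoid module cycle
    from .beat_detect import Tachogram

    beat_times = np.asarray(beat_times, dtype=float)
    metrics: list[tuple[float, float]] = []
    if beat_times.size >= 2:
        tach = Tachogram(beat_times=beat_times)
        for k in range(protocol.n_cycles(duration)):
            insp = window_hr(tach, *protocol.insp_window_abs(k))
            exp = window_hr(tach, *protocol.exp_window_abs(k))
            if insp.valid and exp.valid:
                metrics.append((insp.hr, exp.hr))
    if metrics:
        ratio = float(np.mean([i / e for i, e in metrics]))
    else:
        ratio = 1.0
    return GroundTruth(beat_times=beat_times,
                       true_cycle_metrics=metrics,
                       true_participant_ratio=ratio)


def allocate_groups(n: int, weights: dict[str, int]) -> dict[str, int]:
    """Allocate n participants across age groups by largest remainder."""
    if n < 0:
        raise ValueError("n must be non-negative")
    total = sum(weights.values())
    quotas = {g: n * w / total for g, w in weights.items()}
    counts = {g: int(math.floor(q)) for g, q in quotas.items()}
    short = n - sum(counts.values())
    order = sorted(weights, key=lambda g: quotas[g] - counts[g], reverse=True)
    for g in order[:short]:
        counts[g] += 1
    return counts


def simulate_participant(profile: ParticipantProfile,
                         protocol: BreathingProtocol,
                         duration: float,
                         cfg: GeneratorConfig,
                         noise_rng: np.random.Generator | None,
                         noise: NoiseConfig | None = None
                         ) -> tuple[PPGRecording, GroundTruth]:
    """Generate one recording + ground truth for an existing profile."""
    noise = cfg.noise if noise is None else noise
    beats = generate_beats(profile, protocol, duration)
    meta = {
        "id": profile.id, "mode": profile.resp_mode,
        "age_years": profile.age_years, "fs_hz": cfg.fs,
        "protocol_origin": protocol.origin, "seed": profile.seed,
    }
    rec = render_ppg(beats, cfg.fs, noise, duration, rng=noise_rng, meta=meta)
    truth = ground_truth_for(profile, protocol, beats, duration)
    return rec, truth


def _participant_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(n)]


def simulate_cohort(n: int,
                    mode: str,
                    seed: int,
                    cfg: GeneratorConfig | None = None,
                    protocol: BreathingProtocol = DEFAULT_PROTOCOL,
                    ) -> list[tuple[PPGRecording, GroundTruth]]:
    """Simulate a cohort of ``n`` participants in one breathing mode.

    Participants are allocated across the four age groups near-equally
    (18/20/21/21 when n=80); spontaneous recordings last 60 s and paced
    recordings 120 s by default.  Fully deterministic given (n, mode, seed,
    cfg): the same seed yields the same latent participants in either mode.
    """
    cfg = cfg or GeneratorConfig()
    if n < 0:
        raise ValueError("n must be non-negative")
    counts = allocate_groups(n, cfg.group_weights)
    duration = cfg.spont_duration if mode == "spontaneous" else cfg.paced_duration
    seeds = _participant_seeds(seed, n)

    out: list[tuple[PPGRecording, GroundTruth]] = []
    i = 0
    for group in AGE_GROUPS:
        for _ in range(counts[group]):
            pseed = seeds[i]
            prof_rng = np.random.default_rng(
                np.random.SeedSequence([pseed, 1]))
            noise_rng = np.random.default_rng(
                np.random.SeedSequence([pseed, 2 if mode == "paced" else 3]))
            profile = draw_profile(prof_rng, group, mode, cfg,
                                   pid=f"P{i:03d}", seed=pseed)
            out.append(simulate_participant(profile, protocol, duration,
                                            cfg, noise_rng))
            i += 1
    return out


def simulate_paired_cohort(n: int, seed: int,
                           cfg: GeneratorConfig | None = None,
                           protocol: BreathingProtocol = DEFAULT_PROTOCOL):
    """Simulate the paired design: each participant in both modes.

    Returns (spontaneous, paced) lists aligned by participant; the latent
    baseline heart rate and target ratio are identical within a pair.
    """
    spont = simulate_cohort(n, "spontaneous", seed, cfg, protocol)
    paced = simulate_cohort(n, "paced", seed, cfg, protocol)
    return spont, paced
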