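"""File formats: PPG recordings (CSV + JSON sidecar), beats, ground truth,
cycle tables, summaries, and the run configuration.

Conventions: times in seconds from recording start, half-open windows,
UTF-8, decimal point, fixed decimal places for deterministic bytes, stable
JSON key order.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .beat_detect import FilterSpec
from .feedback import FeedbackConfig
from .protocol import BreathingProtocol
from .rsa_metrics import CycleRSA, ParticipantSummary
from .synth_ppg import GeneratorConfig, GroundTruth, NoiseConfig, PPGRecording

__all__ = [
    "RunConfig",
    "read_recording",
    "write_recording",
    "read_beats",
    "write_beats",
    "read_truth",
    "write_truth",
    "write_cycles",
    "append_summary",
    "read_summaries",
]

_META_KEYS = ("id", "mode", "age_years", "fs_hz", "protocol_origin", "seed")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Full effective configuration of a pipeline run."""

    seed: int = 7
    fs: float = 100.0
    filter: FilterSpec = dataclasses.field(default_factory=FilterSpec)
    protocol: BreathingProtocol = dataclasses.field(
        default_factory=BreathingProtocol)
    feedback: FeedbackConfig = dataclasses.field(default_factory=FeedbackConfig)
    generator: GeneratorConfig = dataclasses.field(
        default_factory=GeneratorConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def dumps(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(klass, data):
            if data is None:
                return klass()
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(data) - names
            if unknown:
                raise ValueError(
                    f"unknown {klass.__name__} keys: {sorted(unknown)}")
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name not in data:
                    continue
                v = data[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                if f.name == "noise" and isinstance(v, dict):
                    v = NoiseConfig(**v)
                kwargs[f.name] = v
            return klass(**kwargs)

        top = {"seed", "fs", "filter", "protocol", "feedback", "generator"}
        unknown = set(raw) - top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            seed=int(raw.get("seed", 7)),
            fs=float(raw.get("fs", 100.0)),
            filter=build(FilterSpec, raw.get("filter")),
            protocol=build(BreathingProtocol, raw.get("protocol")),
            feedback=build(FeedbackConfig, raw.get("feedback")),
            generator=build(GeneratorConfig, raw.get("generator")),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _paths(base: str | Path) -> tuple[Path, Path]:
    base = Path(base)
    stem = base.name
    for suffix in (".ppg.csv", ".meta.json"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    root = base.parent / stem
    return root.with_name(stem + ".ppg.csv"), root.with_name(stem + ".meta.json")


def write_recording(rec: PPGRecording, base: str | Path,
                    overwrite: bool = False) -> tuple[Path, Path]:
    """Write ``<id>.ppg.csv`` (time_s, ppg) and ``<id>.meta.json``.

    Fixed formatting (6 decimals) so repeated writes are byte-identical;
    refuses to clobber existing files unless ``overwrite``.
    """
    csv_path, meta_path = _paths(base)
    if not overwrite:
        for p in (csv_path, meta_path):
            if p.exists():
                raise FileExistsError(f"{p} exists; pass overwrite=True")
    t = rec.t0 + np.arange(rec.samples.size) / rec.fs
    lines = ["time_s,ppg"]
    lines += [f"{tt:.6f},{vv:.6f}" for tt, vv in zip(t, rec.samples)]
    csv_path.write_text("\n".join(lines) + "\n")
    meta = {"fs_hz": rec.fs, "t0": rec.t0}
    meta.update({k: rec.meta[k] for k in _META_KEYS if k in rec.meta})
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return csv_path, meta_path


def read_recording(base: str | Path) -> PPGRecording:
    """Read a ``.ppg.csv`` + ``.meta.json`` pair back into a recording.

    Validates monotone, uniform sampling and that the CSV spacing matches
    the metadata sampling rate within 1%.
    """
    csv_path, meta_path = _paths(base)
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
    if not csv_path.exists():
        raise FileNotFoundError(f"missing samples file {csv_path}")
    meta = json.loads(meta_path.read_text())
    df = pd.read_csv(csv_path)
    if list(df.columns) != ["time_s", "ppg"]:
        raise ValueError(f"{csv_path}: expected header 'time_s,ppg'")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if t.size > 1 and np.any(dt <= 0):
        raise ValueError(f"{csv_path}: non-monotonic time")
    fs = float(meta["fs_hz"])
    if t.size > 1:
        spacing = float(np.median(dt))
        jitter = np.abs(dt - spacing).max()
        if jitter > 0.1 * spacing:
            raise ValueError(f"{csv_path}: non-uniform sampling "
                             f"(max jitter {jitter:.3g} s)")
        fs_csv = 1.0 / spacing
        if abs(fs_csv - fs) / fs > 0.01:
            raise ValueError(
                f"{csv_path}: sample spacing implies {fs_csv:.3g} Hz but "
                f"metadata says {fs:.3g} Hz")
    extra = {k: meta[k] for k in _META_KEYS if k in meta}
    return PPGRecording(samples=df["ppg"].to_numpy(), fs=fs,
                        t0=float(meta.get("t0", t[0] if t.size else 0.0)),
                        meta=extra)


def write_beats(times: np.ndarray, path: str | Path,
                overwrite: bool = False) -> Path:
    """Write detected beats, one time per row, seconds, 6 decimals."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    lines = ["beat_time_s"] + [f"{t:.6f}" for t in np.asarray(times)]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_beats(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)["beat_time_s"].to_numpy()


def write_truth(truth: GroundTruth, path: str | Path,
                overwrite: bool = False) -> Path:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    doc = {
        "beat_times": [round(float(t), 6) for t in truth.beat_times],
        "true_cycle_metrics": [
            {"hr_insp": round(i, 6), "hr_exp": round(e, 6)}
            for i, e in truth.true_cycle_metrics],
        "true_participant_ratio": round(truth.true_participant_ratio, 6),
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def read_truth(path: str | Path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    return GroundTruth(
        beat_times=np.asarray(doc["beat_times"], dtype=float),
        true_cycle_metrics=[(m["hr_insp"], m["hr_exp"])
                            for m in doc["true_cycle_metrics"]],
        true_participant_ratio=float(doc["true_participant_ratio"]))


def write_cycles(cycles: list[CycleRSA], path: str | Path) -> Path:
    df = pd.DataFrame([dataclasses.asdict(c) for c in cycles])
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def append_summary(summary: ParticipantSummary, path: str | Path) -> Path:
    path = Path(path)
    row = pd.DataFrame([dataclasses.asdict(summary)])
    header = not path.exists()
    row.to_csv(path, mode="a", header=header, index=False,
               float_format="%.6f")
    return path


def read_summaries(path: str | Path) -> list[ParticipantSummary]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(ParticipantSummary(
            participant_id=str(r["participant_id"]), mode=str(r["mode"]),
            n_valid_cycles=int(r["n_valid_cycles"]),
            mean_ratio=float(r["mean_ratio"]),
            mean_rsa_sync=float(r["mean_rsa_sync"]),
            mean_hr_insp=float(r["mean_hr_insp"]),
            mean_hr_exp=float(r["mean_hr_exp"]),
            age_years=int(r["age_years"]) if not pd.isna(r["age_years"]) else None))
    return out
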