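"""Synthetic SisFall-format IMU recordings for pipeline testing.

The generator writes plain-text recordings in the SisFall dialect (nine
integer ADC-count columns at 200 Hz) with class-dependent structure:

* standing — quasi-static 1 g gravity with small sway;
* walking / jogging — periodic gait oscillation (jogging has higher
  frequency and amplitude);
* sitting — one smooth postural transition with a moderate bump and a
  partial gravity reorientation;
* falls — exactly one high-amplitude impact transient whose axis and sign
  encode direction (forward +x, backward -x, lateral +y), whose peak
  amplitude encodes severity (hard > soft), followed by a lying-down
  gravity reorientation; soft falls get a smaller pre-impact "support" bump.

The signal model is additive and piecewise-deterministic — gravity +
class component + Gaussian floor noise — then quantised to sensor counts by
inverting the linear unit conversion. It exercises the pipeline's logic;
it makes no claim to biomechanical realism.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sisfall_io import (
    ACTIVITY_LABELS,
    TRIALS_PER_CODE,
    LabelScheme,
    RawRecording,
    RecordingMeta,
    SensorConfig,
    format_sisfall_file,
    map_label,
)

__all__ = ["SyntheticConfig", "simulate_recording", "simulate_dataset"]

#: direction -> (acceleration axis, sign) for the impact transient
_FALL_AXIS = {"F": (0, +1.0), "B": (0, -1.0), "L": (1, +1.0)}


@dataclass(frozen=True)
class SyntheticConfig:
    fs: float = 200.0
    short_duration_s: float = 12.0   # falls and transient/short ADL protocols
    long_duration_s: float = 100.0   # continuous walking/jogging (D01-D04)
    gravity_axis: int = 2
    noise_floor_sd: float = 0.02     # g

    gait_freq_walk_hz: float = 1.8
    gait_amp_walk_g: float = 0.35
    gait_freq_jog_hz: float = 2.6
    gait_amp_jog_g: float = 0.9
    sit_bump_g: float = 1.2
    quiescent_amp_g: float = 0.02

    impact_hard_g: float = 6.0
    impact_soft_g: float = 3.0
    support_bump_g: float = 1.5
    gyro_gait_walk_dps: float = 40.0
    gyro_gait_jog_dps: float = 100.0
    gyro_impact_hard_dps: float = 250.0
    gyro_impact_soft_dps: float = 120.0

    subjects: int = 2
    trials_per_code: dict = field(default_factory=lambda: dict(TRIALS_PER_CODE))
    window_len: int = 600            # impacts are kept >= L/2 from both ends
    seed: int = 0
    sensor: SensorConfig = SensorConfig()

    def __post_init__(self) -> None:
        max_adl = 1.0 + max(self.gait_amp_jog_g, self.sit_bump_g, self.quiescent_amp_g)
        if not self.impact_hard_g > self.impact_soft_g > max_adl:
            raise ValueError(
                "need impact_hard_g > impact_soft_g > max ADL SMV amplitude "
                f"({self.impact_hard_g} > {self.impact_soft_g} > {max_adl} fails)"
            )
        for dur in (self.short_duration_s, self.long_duration_s):
            if dur * self.fs < self.window_len:
                raise ValueError("every recording must hold at least one window")


def _gauss_pulse(t: np.ndarray, center: int, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _sigmoid(t: np.ndarray, center: int, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - center) / width))


def _quantize(values: np.ndarray, lsb: float, bits: int) -> np.ndarray:
    counts = np.rint(values / lsb)
    lo, hi = -(2 ** (bits - 1)), 2 ** (bits - 1) - 1
    return np.clip(counts, lo, hi).astype(np.int64)


def _recording_rng(cfg: SyntheticConfig, code: str, subject: str, trial: int):
    sub_num = int("".join(ch for ch in subject if ch.isdigit()) or 0)
    key = [cfg.seed, ord(code[0]), int(code[1:]), sub_num, trial]
    return np.random.default_rng(key)


def _class_signal(
    code: str, T: int, cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int]:
    """Noise-free 6-channel physical signal and the impact index (-1 if none)."""
    t = np.arange(T, dtype=np.float64)
    acc = np.zeros((T, 3))
    gyr = np.zeros((T, 3))
    acc[:, cfg.gravity_axis] = 1.0
    label = ACTIVITY_LABELS[code]
    fs = cfg.fs
    impact = -1
    L2 = cfg.window_len // 2

    if label in ("W", "J"):
        walk = label == "W"
        freq = (cfg.gait_freq_walk_hz if walk else cfg.gait_freq_jog_hz) * rng.uniform(0.9, 1.1)
        amp = (cfg.gait_amp_walk_g if walk else cfg.gait_amp_jog_g) * rng.uniform(0.85, 1.15)
        gamp = (cfg.gyro_gait_walk_dps if walk else cfg.gyro_gait_jog_dps) * rng.uniform(0.85, 1.15)
        phase = rng.uniform(0, 2 * np.pi)
        osc = np.sin(2 * np.pi * freq * t / fs + phase)
        acc[:, cfg.gravity_axis] += amp * osc
        acc[:, 0] += 0.3 * amp * np.sin(2 * np.pi * freq * t / fs + phase + np.pi / 3)
        gyr[:, 1] += gamp * osc
        gyr[:, 0] += 0.4 * gamp * np.sin(np.pi * freq * t / fs + phase)
    elif label == "S":
        center = int(rng.integers(L2, T - L2))
        trans = _sigmoid(t, center, 0.4 * fs)
        # gravity partially reorients from vertical to the sagittal axis
        acc[:, cfg.gravity_axis] = np.cos(trans * np.pi / 4)
        acc[:, 0] = np.sin(trans * np.pi / 4)
        bump = cfg.sit_bump_g * rng.uniform(0.8, 1.0)
        acc[:, cfg.gravity_axis] += bump * _gauss_pulse(t, center, 0.08 * fs)
        gyr[:, 1] += 80.0 * _gauss_pulse(t, center, 0.2 * fs)
    elif label == "SB":
        sway = cfg.quiescent_amp_g * np.sin(2 * np.pi * 0.3 * t / fs + rng.uniform(0, 2 * np.pi))
        acc[:, 0] += sway
        gyr[:, 2] += 5.0 * sway / max(cfg.quiescent_amp_g, 1e-9)
    else:  # fall classes
        direction, severity = label[0], label[1]  # e.g. "FHF" -> ("F", "H")
        axis, sign = _FALL_AXIS[direction]
        hard = severity == "H"
        peak = (cfg.impact_hard_g if hard else cfg.impact_soft_g) * rng.uniform(0.9, 1.1)
        gpeak = (cfg.gyro_impact_hard_dps if hard else cfg.gyro_impact_soft_dps)
        impact = int(rng.integers(L2, T - L2))
        # mild pre-impact activity (standing or slow walking)
        pre = 0.15 * np.sin(2 * np.pi * 1.5 * t / fs + rng.uniform(0, 2 * np.pi))
        acc[:, cfg.gravity_axis] += pre * (t < impact)
        # impact transient on the direction-coded axis
        acc[:, axis] += sign * peak * _gauss_pulse(t, impact, 0.05 * fs)
        gyr[:, 1 - axis] += gpeak * _gauss_pulse(t, impact, 0.1 * fs)
        if not hard:  # support bump ~0.5 s before a dampened fall
            bump_at = impact - int(0.5 * fs)
            acc[:, axis] += sign * cfg.support_bump_g * _gauss_pulse(t, bump_at, 0.06 * fs)
            gyr[:, 1 - axis] += 0.4 * gpeak * _gauss_pulse(t, bump_at, 0.1 * fs)
        # lying down after the impact: gravity moves to the impact axis
        lie = _sigmoid(t, impact + int(0.5 * fs), 0.3 * fs)
        acc[:, cfg.gravity_axis] *= (1.0 - 0.9 * lie)
        acc[:, axis] += sign * 0.9 * lie
    return acc, gyr, impact


def simulate_recording(
    code: str,
    subject: str,
    trial: int,
    cfg: SyntheticConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RawRecording, int]:
    """One synthetic recording plus the injected impact index (-1 for ADLs).

    Deterministic for a fixed ``(code, subject, trial, cfg.seed)``: when
    ``rng`` is not supplied it is derived from exactly those values.
    """
    cfg = cfg or SyntheticConfig()
    if code not in ACTIVITY_LABELS:
        raise ValueError(f"unknown activity code {code!r}")
    if rng is None:
        rng = _recording_rng(cfg, code, subject, trial)
    long = code in {"D01", "D02", "D03", "D04"}
    T = int((cfg.long_duration_s if long else cfg.short_duration_s) * cfg.fs)
    acc, gyr, impact = _class_signal(code, T, cfg, rng)
    if cfg.noise_floor_sd > 0:
        acc += rng.normal(0.0, cfg.noise_floor_sd, acc.shape)
        gyr += rng.normal(0.0, cfg.noise_floor_sd * 50.0, gyr.shape)
    sensor = cfg.sensor
    acc_counts = _quantize(acc, sensor.acc_lsb_g, sensor.acc_resolution_bits)
    gyr_counts = _quantize(gyr, sensor.gyro_lsb_dps, sensor.gyro_resolution_bits)
    # second accelerometer: same motion seen through the first sensor's ADC
    rows = np.concatenate([acc_counts, gyr_counts, acc_counts], axis=1)
    meta = RecordingMeta(activity_code=code, subject_id=subject, trial=trial,
                         sampling_rate_hz=cfg.fs)
    return RawRecording(meta=meta, rows=rows), impact


def simulate_dataset(out_dir: str | Path, cfg: SyntheticConfig | None = None) -> Path:
    """Write a directory-per-subject tree of recordings plus a manifest.

    The manifest CSV lists every file with its activity code, ten-class
    label, and injected impact index (-1 for ADLs). Returns the manifest
    path.
    """
    cfg = cfg or SyntheticConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scheme = LabelScheme()
    manifest_rows = []
    for s in range(1, cfg.subjects + 1):
        subject = f"SA{s:02d}"
        subj_dir = out_dir / subject
        subj_dir.mkdir(exist_ok=True)
        for code in sorted(cfg.trials_per_code):
            for trial in range(1, cfg.trials_per_code[code] + 1):
                rec, impact = simulate_recording(code, subject, trial, cfg)
                fname = f"{code}_{subject}_R{trial:02d}.txt"
                (subj_dir / fname).write_text(format_sisfall_file(rec))
                manifest_rows.append(
                    [f"{subject}/{fname}", code, map_label(code, scheme), impact]
                )
    manifest = out_dir / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "code", "label", "impact_index"])
        writer.writerows(manifest_rows)
    return manifest
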