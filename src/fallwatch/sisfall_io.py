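"""Reading and labelling of SisFall-format waist-IMU recordings.

A recording is a plain-text file with one sample per line and nine
comma-separated integer columns: the first accelerometer's x/y/z, the
gyroscope's x/y/z, and the second accelerometer's x/y/z, sampled at 200 Hz.
File names follow ``<code>_<subject>_R<trial>.txt`` (e.g. ``F07_SA05_R03.txt``)
where the activity code is a letter ``D`` (activity of daily living) or ``F``
(fall) followed by two digits.

Raw sensor values are ADC counts; :func:`convert_units` maps them to physical
units (g for acceleration, deg/s for angular rate) via the linear full-scale
relation ``value = counts * 2*range / 2**resolution``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RecordingMeta",
    "RawRecording",
    "SensorConfig",
    "ImuSignal",
    "LabelVariant",
    "LabelScheme",
    "EXCLUDED",
    "ACTIVITY_LABELS",
    "TRIALS_PER_CODE",
    "FALL_LABELS",
    "ADL_LABELS",
    "parse_filename",
    "parse_sisfall_file",
    "format_sisfall_file",
    "convert_units",
    "map_label",
    "load_recording",
    "iter_recordings",
]

_CODE_RE = re.compile(r"^[DF]\d{2}$")
_FNAME_RE = re.compile(r"^([DF]\d{2})_([A-Za-z]+\d+)_R(\d+)\.txt$")

#: Activity code -> output class label. Codes absent from this mapping
#: (D14, D17, D18, D19, ...) are excluded from the classification problem.
ACTIVITY_LABELS: dict[str, str] = {
    "D01": "W", "D02": "W", "D03": "J", "D04": "J",
    "D05": "W", "D06": "W",
    "D07": "S", "D08": "S", "D09": "S", "D10": "S",
    "D11": "S", "D12": "S", "D13": "S",
    "D15": "SB", "D16": "SB",
    "F01": "FHF", "F02": "BHF", "F03": "LHF",
    "F04": "FHF", "F05": "FHF",
    "F06": "FSF", "F07": "LSF", "F08": "FSF", "F09": "LSF",
    "F10": "FSF", "F11": "BSF", "F12": "LSF",
    "F13": "FSF", "F14": "BSF", "F15": "LSF",
}

#: Protocol trial counts per activity code (long walking/jogging recordings
#: D01-D04 have a single trial; everything else has five).
TRIALS_PER_CODE: dict[str, int] = {
    code: (1 if code in {"D01", "D02", "D03", "D04"} else 5)
    for code in ACTIVITY_LABELS
}

FALL_LABELS: tuple[str, ...] = ("FHF", "BHF", "LHF", "FSF", "BSF", "LSF")
ADL_LABELS: tuple[str, ...] = ("W", "J", "S", "SB")

#: Sentinel returned by :func:`map_label` for codes outside the label scheme.
EXCLUDED = "excluded"


@dataclass(frozen=True)
class RecordingMeta:
    """Identity of one recording: activity code, subject, trial, sample rate."""

    activity_code: str
    subject_id: str
    trial: int
    sampling_rate_hz: float = 200.0

    def __post_init__(self) -> None:
        if not _CODE_RE.match(self.activity_code):
            raise ValueError(f"bad activity code {self.activity_code!r}")
        if self.trial < 1:
            raise ValueError(f"trial must be positive, got {self.trial}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")

    @property
    def recording_id(self) -> str:
        return f"{self.activity_code}_{self.subject_id}_R{self.trial:02d}"


@dataclass(frozen=True)
class RawRecording:
    """Integer sensor rows straight from a SisFall file.

    ``rows`` is a T x 9 int array: acc1 x/y/z, gyro x/y/z, acc2 x/y/z.
    """

    meta: RecordingMeta
    rows: np.ndarray

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows)
        if rows.ndim != 2 or rows.shape[1] != 9:
            raise ValueError(f"rows must be T x 9, got shape {rows.shape}")
        if rows.shape[0] < 1:
            raise ValueError("recording must contain at least one row")
        object.__setattr__(self, "rows", rows)


class AccelerometerChoice(str, Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"


@dataclass(frozen=True)
class SensorConfig:
    """Which accelerometer to use and the ADC full-scale constants.

    Defaults correspond to a +/-16 g, 13-bit accelerometer (the wide-range
    sensor of the SisFall unit) and a +/-2000 deg/s, 16-bit gyroscope.
    """

    accelerometer_choice: AccelerometerChoice = AccelerometerChoice.PRIMARY
    acc_range_g: float = 16.0
    acc_resolution_bits: int = 13
    gyro_range_dps: float = 2000.0
    gyro_resolution_bits: int = 16

    def __post_init__(self) -> None:
        if self.acc_range_g <= 0 or self.gyro_range_dps <= 0:
            raise ValueError("sensor ranges must be positive")
        for bits in (self.acc_resolution_bits, self.gyro_resolution_bits):
            if not 8 <= bits <= 32:
                raise ValueError(f"resolution bits must be in [8, 32], got {bits}")

    @property
    def acc_lsb_g(self) -> float:
        """Acceleration represented by one ADC count, in g."""
        return 2.0 * self.acc_range_g / 2 ** self.acc_resolution_bits

    @property
    def gyro_lsb_dps(self) -> float:
        """Angular rate represented by one ADC count, in deg/s."""
        return 2.0 * self.gyro_range_dps / 2 ** self.gyro_resolution_bits


@dataclass(frozen=True)
class ImuSignal:
    """Six-channel physical-unit time series: [Ax, Ay, Az, Gx, Gy, Gz].

    Acceleration channels are in g, angular-rate channels in deg/s.
    """

    meta: RecordingMeta
    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 2 or samples.shape[1] != 6:
            raise ValueError(f"samples must be T x 6, got shape {samples.shape}")
        object.__setattr__(self, "samples", samples)

    @property
    def acceleration(self) -> np.ndarray:
        return self.samples[:, :3]

    @property
    def gyro(self) -> np.ndarray:
        return self.samples[:, 3:]

    def __len__(self) -> int:
        return self.samples.shape[0]


class LabelVariant(str, Enum):
    TEN_CLASS = "TEN_CLASS"
    FALL_VS_ADL = "FALL_VS_ADL"


@dataclass(frozen=True)
class LabelScheme:
    """Mapping of activity codes to output classes.

    ``TEN_CLASS`` keeps the four daily-living activities (W, J, S, SB)
    separate; ``FALL_VS_ADL`` pools them into a single ``ADL`` class while
    the six direction/severity fall classes are unchanged.
    """

    variant: LabelVariant = LabelVariant.TEN_CLASS
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mapping:
            mapping = dict(ACTIVITY_LABELS)
            if self.variant is LabelVariant.FALL_VS_ADL:
                mapping = {
                    code: ("ADL" if lab in ADL_LABELS else lab)
                    for code, lab in mapping.items()
                }
            object.__setattr__(self, "mapping", mapping)

    @property
    def class_set(self) -> tuple[str, ...]:
        if self.variant is LabelVariant.TEN_CLASS:
            return ADL_LABELS + FALL_LABELS
        return ("ADL",) + FALL_LABELS


def map_label(code: str, scheme: LabelScheme) -> str:
    """Class label for an activity code, or :data:`EXCLUDED` if unlisted.

    Total over syntactically valid codes; never raises for an unknown code
    so a whole dataset directory can be swept.
    """
    if not _CODE_RE.match(code):
        raise ValueError(f"bad activity code {code!r}")
    label = scheme.mapping.get(code)
    if label is None:
        logger.info("activity code %s is not part of the label scheme; excluded", code)
        return EXCLUDED
    return label


def parse_filename(name: str) -> RecordingMeta:
    """Extract metadata from a ``<code>_<subject>_R<NN>.txt`` file name."""
    m = _FNAME_RE.match(Path(name).name)
    if m is None:
        raise ValueError(f"file name {name!r} does not follow <code>_<subject>_R<NN>.txt")
    code, subject, trial = m.groups()
    return RecordingMeta(activity_code=code, subject_id=subject, trial=int(trial))


def parse_sisfall_file(text: str, meta: RecordingMeta) -> RawRecording:
    """Parse raw file content into a :class:`RawRecording`.

    Lines hold nine comma-separated integers; surrounding whitespace, blank
    lines, and one trailing ``;`` per line are tolerated.
    """
    if not text.strip():
        raise ValueError(f"{meta.recording_id}: empty recording file")
    rows: list[list[int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.endswith(";"):
            line = line[:-1]
        tokens = [tok.strip() for tok in line.split(",")]
        if len(tokens) != 9:
            raise ValueError(
                f"{meta.recording_id}: line {lineno}: expected 9 columns, got {len(tokens)}"
            )
        try:
            rows.append([int(tok) for tok in tokens])
        except ValueError as exc:
            raise ValueError(f"{meta.recording_id}: line {lineno}: non-integer token") from exc
    return RawRecording(meta=meta, rows=np.asarray(rows, dtype=np.int64))


def format_sisfall_file(rec: RawRecording) -> str:
    """Serialize a recording back to the SisFall text dialect (round-trips)."""
    lines = [",".join(str(v) for v in row) + ";" for row in rec.rows]
    return "\n".join(lines) + "\n"


def convert_units(rec: RawRecording, cfg: SensorConfig | None = None) -> ImuSignal:
    """Convert ADC counts to physical units and select one accelerometer.

    Output channel order is fixed: [Ax, Ay, Az, Gx, Gy, Gz] with
    acceleration in g and angular rate in deg/s.
    """
    cfg = cfg or SensorConfig()
    rows = rec.rows.astype(np.float64)
    if cfg.accelerometer_choice is AccelerometerChoice.PRIMARY:
        acc = rows[:, 0:3]
    else:
        acc = rows[:, 6:9]
    gyro = rows[:, 3:6]
    samples = np.concatenate([acc * cfg.acc_lsb_g, gyro * cfg.gyro_lsb_dps], axis=1)
    return ImuSignal(meta=rec.meta, samples=samples)


def load_recording(path: str | Path, cfg: SensorConfig | None = None) -> ImuSignal:
    """Read one SisFall file from disk and convert it to physical units."""
    path = Path(path)
    meta = parse_filename(path.name)
    raw = parse_sisfall_file(path.read_text(), meta)
    return convert_units(raw, cfg)


def iter_recordings(
    root: str | Path, cfg: SensorConfig | None = None
) -> Iterable[ImuSignal]:
    """Yield converted recordings from a directory tree, sorted by file name.

    Files whose names do not follow the convention are skipped with a log
    message; parse errors are re-raised.
    """
    root = Path(root)
    for path in sorted(root.rglob("*.txt")):
        try:
            meta = parse_filename(path.name)
        except ValueError:
            logger.info("skipping non-recording file %s", path.name)
            continue
        raw = parse_sisfall_file(path.read_text(), meta)
        yield convert_units(raw, cfg)
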