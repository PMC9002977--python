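"""Fixed-duration window extraction around the acceleration-magnitude peak.

Every recording is reduced to one or more 3 s segments of the 6-channel IMU
signal. For transient activities (falls, sit-downs, ...) the segment is
centred on the sample with the largest signal magnitude vector
``SMV = sqrt(Ax^2 + Ay^2 + Az^2)`` — for a fall this is the impact. The long
continuous walking/jogging recordings (codes D01-D04) are instead cut into
consecutive non-overlapping windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sisfall_io import EXCLUDED, ImuSignal, LabelScheme, map_label

logger = logging.getLogger(__name__)

__all__ = [
    "WindowingConfig",
    "Window",
    "smv",
    "smv_series",
    "peak_index",
    "extract_peak_window",
    "extract_sliding_windows",
    "window_recording",
]

#: Augmentation provenance tags a window can carry.
WINDOW_TAGS = ("original", "noise", "scale", "resample")


@dataclass(frozen=True)
class WindowingConfig:
    duration_s: float = 3.0
    fs: float = 200.0
    sliding_codes: frozenset[str] = frozenset({"D01", "D02", "D03", "D04"})

    def __post_init__(self) -> None:
        n = self.duration_s * self.fs
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(f"duration_s * fs must be a positive integer, got {n}")

    @property
    def window_len(self) -> int:
        """Window length L in samples (600 at the 3 s / 200 Hz defaults)."""
        return int(round(self.duration_s * self.fs))


@dataclass(frozen=True)
class Window:
    """One labelled L x 6 segment with provenance.

    ``source`` is ``(recording_id, start, end)`` with a 0-based inclusive
    start and exclusive end index into the source recording.
    """

    samples: np.ndarray
    label: str
    source: tuple[str, int, int]
    augmentation_tag: str = "original"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 2 or samples.shape[1] != 6:
            raise ValueError(f"window must be L x 6, got {samples.shape}")
        _, start, end = self.source
        if end - start != samples.shape[0]:
            raise ValueError("source span length must equal sample count")
        if self.augmentation_tag not in WINDOW_TAGS:
            raise ValueError(f"unknown augmentation tag {self.augmentation_tag!r}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.shape[0]


def smv(ax: float, ay: float, az: float) -> float:
    """Signal magnitude vector of one acceleration sample (root sum of squares)."""
    return float(np.sqrt(ax * ax + ay * ay + az * az))


def smv_series(signal: ImuSignal) -> np.ndarray:
    """Per-sample SMV over the three acceleration channels."""
    return np.sqrt(np.sum(signal.acceleration ** 2, axis=1))


def peak_index(signal: ImuSignal) -> int:
    """0-based index of the SMV maximum; ties go to the earliest sample."""
    if len(signal) < 1:
        raise ValueError("cannot locate peak of an empty signal")
    return int(np.argmax(smv_series(signal)))


def extract_peak_window(
    signal: ImuSignal, cfg: WindowingConfig, label: str
) -> Window:
    """Extract the L-sample window centred on the SMV peak.

    The nominal span is ``[p - L//2, p + L//2)`` for peak index p; when that
    span crosses a recording boundary it is shifted minimally so that exactly
    L real samples are returned (no padding is fabricated).
    """
    L = cfg.window_len
    T = len(signal)
    if T < L:
        raise ValueError(
            f"{signal.meta.recording_id}: recording has {T} samples, "
            f"shorter than the window length {L}"
        )
    p = peak_index(signal)
    start = min(max(p - L // 2, 0), T - L)
    return Window(
        samples=signal.samples[start : start + L],
        label=label,
        source=(signal.meta.recording_id, start, start + L),
    )


def extract_sliding_windows(
    signal: ImuSignal, cfg: WindowingConfig, label: str
) -> list[Window]:
    """Cut a recording into consecutive non-overlapping L-sample windows.

    The trailing remainder shorter than L is discarded; the list is empty
    for recordings shorter than one window.
    """
    L = cfg.window_len
    n = len(signal) // L
    rid = signal.meta.recording_id
    return [
        Window(
            samples=signal.samples[i * L : (i + 1) * L],
            label=label,
            source=(rid, i * L, (i + 1) * L),
        )
        for i in range(n)
    ]


def window_recording(
    signal: ImuSignal,
    scheme: LabelScheme,
    cfg: WindowingConfig | None = None,
) -> list[Window]:
    """Window one recording according to its activity code.

    Codes in ``cfg.sliding_codes`` (long walking/jogging protocols) use the
    non-overlapping sliding scheme; every other labelled code yields a single
    peak-centred window. Codes outside the label scheme yield an empty list.
    """
    cfg = cfg or WindowingConfig()
    code = signal.meta.activity_code
    label = map_label(code, scheme)
    if label == EXCLUDED:
        logger.info("%s: excluded code %s, no windows", signal.meta.recording_id, code)
        return []
    if code in cfg.sliding_codes:
        return extract_sliding_windows(signal, cfg, label)
    return [extract_peak_window(signal, cfg, label)]
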