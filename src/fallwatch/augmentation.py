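"""Training-set augmentation for under-represented classes.

Each original window from a minority class (standing plus the six fall
classes) spawns exactly three variants: additive white Gaussian noise
(sensor-noise emulation), a single uniform amplitude scale in [0.8, 1.2]
(sensor fixation / physique variation), and up-then-down resampling by a
factor of 10 with linear interpolation (sampling inconsistency emulation).
Augmentation is meant for the training split only; validation and test
windows are never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .windowing import Window

__all__ = [
    "AugmentationConfig",
    "add_noise",
    "scale_window",
    "resample_window",
    "augment_minority",
]

DEFAULT_MINORITY = frozenset({"SB", "FHF", "FSF", "BHF", "BSF", "LHF", "LSF"})


@dataclass(frozen=True)
class AugmentationConfig:
    noise_sd: float = 0.01
    scale_low: float = 0.8
    scale_high: float = 1.2
    resample_factor: int = 10
    minority_classes: frozenset[str] = DEFAULT_MINORITY
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.scale_low <= self.scale_high:
            raise ValueError("need 0 < scale_low <= scale_high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.resample_factor < 2:
            raise ValueError("resample_factor must be >= 2")


def add_noise(w: Window, sd: float, rng: np.random.Generator) -> Window:
    """Add iid zero-mean Gaussian noise of standard deviation ``sd``."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    noisy = w.samples + rng.normal(0.0, sd, size=w.samples.shape) if sd > 0 else w.samples.copy()
    return replace(w, samples=noisy, augmentation_tag="noise")


def scale_window(w: Window, lo: float, hi: float, rng: np.random.Generator) -> Window:
    """Multiply the whole window by one scalar drawn from Uniform(lo, hi).

    A single factor for all channels and samples preserves the inter-axis
    geometry of the movement.
    """
    if not 0 < lo <= hi:
        raise ValueError("need 0 < lo <= hi")
    u = float(rng.uniform(lo, hi))
    return replace(w, samples=w.samples * u, augmentation_tag="scale")


def resample_window(w: Window, factor: int) -> Window:
    """Upsample by ``factor`` via linear interpolation, then decimate back.

    Deterministic; exact on affine signals. The decimation is a stride over
    the interpolated grid, so the output keeps exactly L samples.
    """
    if factor < 2:
        raise ValueError("factor must be >= 2")
    L = len(w)
    x = np.arange(L, dtype=np.float64)
    up = np.arange(L * factor, dtype=np.float64) / factor
    resampled = np.empty_like(w.samples)
    for c in range(w.samples.shape[1]):
        dense = np.interp(up, x, w.samples[:, c])
        resampled[:, c] = dense[::factor]
    return replace(w, samples=resampled, augmentation_tag="resample")


def augment_minority(
    windows: list[Window], cfg: AugmentationConfig | None = None
) -> list[Window]:
    """Return all originals plus three variants per minority-class window.

    Output order is deterministic: each original is followed immediately by
    its noise, scale, and resample variants. Fully reproducible from
    ``cfg.seed``; the resample variant involves no randomness at all, so
    changing the seed alters only the noise and scale variants.
    """
    cfg = cfg or AugmentationConfig()
    rng = np.random.default_rng(cfg.seed)
    out: list[Window] = []
    for w in windows:
        out.append(w)
        if w.label in cfg.minority_classes:
            out.append(add_noise(w, cfg.noise_sd, rng))
            out.append(scale_window(w, cfg.scale_low, cfg.scale_high, rng))
            out.append(resample_window(w, cfg.resample_factor))
    return out
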