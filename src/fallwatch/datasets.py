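"""Windowed-dataset container: one ``.npz`` file per preprocessed dataset.

Columnar little-endian NumPy arrays: ``samples`` (N x L x 6 float32),
``labels``, ``rec_ids``, ``starts``/``ends`` (provenance spans), and
``tags`` (augmentation provenance). Runtime artefact only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .windowing import Window

__all__ = ["save_windows", "load_windows"]


def save_windows(path: str | Path, windows: list[Window]) -> None:
    if not windows:
        raise ValueError("refusing to save an empty window set")
    np.savez_compressed(
        path,
        samples=np.stack([w.samples for w in windows]).astype(np.float32),
        labels=np.array([w.label for w in windows]),
        rec_ids=np.array([w.source[0] for w in windows]),
        starts=np.array([w.source[1] for w in windows], dtype=np.int64),
        ends=np.array([w.source[2] for w in windows], dtype=np.int64),
        tags=np.array([w.augmentation_tag for w in windows]),
    )


def load_windows(path: str | Path) -> list[Window]:
    with np.load(path, allow_pickle=False) as data:
        return [
            Window(
                samples=data["samples"][i].astype(np.float64),
                label=str(data["labels"][i]),
                source=(str(data["rec_ids"][i]), int(data["starts"][i]), int(data["ends"][i])),
                augmentation_tag=str(data["tags"][i]),
            )
            for i in range(len(data["labels"]))
        ]
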