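"""Shared fixtures: tiny hand-built windows and a small synthetic dataset."""

from __future__ import annotations

import numpy as np
import pytest

from fallwatch.sisfall_io import ImuSignal, RecordingMeta
from fallwatch.windowing import Window


def make_signal(samples: np.ndarray, code: str = "F01", subject: str = "SA01",
                trial: int = 1) -> ImuSignal:
    meta = RecordingMeta(activity_code=code, subject_id=subject, trial=trial)
    return ImuSignal(meta=meta, samples=np.asarray(samples, dtype=np.float64))


def make_window(samples: np.ndarray, label: str = "FHF", rid: str = "F01_SA01_R01",
                start: int = 0) -> Window:
    samples = np.asarray(samples, dtype=np.float64)
    return Window(samples=samples, label=label,
                  source=(rid, start, start + samples.shape[0]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def zero_window() -> Window:
    return make_window(np.zeros((600, 6)))


@pytest.fixture(scope="session")
def synthetic_tree(tmp_path_factory):
    """A small on-disk synthetic dataset: 1 subject, reduced trial counts."""
    from fallwatch.synthetic import SyntheticConfig, simulate_dataset

    root = tmp_path_factory.mktemp("sisfall_synth")
    trials = {code: 1 for code in
              ["D01", "D03", "D05", "D07", "D15", "F01", "F02", "F03",
               "F06", "F07", "F11"]}
    cfg = SyntheticConfig(subjects=1, trials_per_code=trials, seed=7)
    manifest = simulate_dataset(root, cfg)
    return root, manifest, cfg
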