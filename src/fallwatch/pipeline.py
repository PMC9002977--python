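"""High-level orchestration: directory -> windows -> trained pipeline -> report.

These functions are what the CLI wraps; they are equally usable from
Python for scripted experiments.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

from .augmentation import augment_minority
from .config import RunConfig
from .metrics import EvalReport, evaluate
from .model import (
    FallPipeline,
    build_cnn,
    extract_features,
    stratified_split,
    train_cnn,
    tune_and_train_xgb,
    windows_to_arrays,
)
from .sisfall_io import iter_recordings
from .windowing import Window, window_recording

logger = logging.getLogger(__name__)

__all__ = ["preprocess_directory", "train_pipeline", "evaluate_pipeline"]


def preprocess_directory(data_dir: str | Path, cfg: RunConfig) -> list[Window]:
    """Read, convert, label, and window every recording under ``data_dir``.

    Unreadable files are reported and skipped so one bad recording does not
    abort a dataset sweep; excluded activity codes contribute no windows.
    """
    data_dir = Path(data_dir)
    if not data_dir.is_dir():
        raise FileNotFoundError(f"{data_dir} is not a directory")
    windows: list[Window] = []
    n_files = 0
    for signal in iter_recordings(data_dir, cfg.sensor):
        n_files += 1
        try:
            windows.extend(window_recording(signal, cfg.scheme, cfg.windowing))
        except ValueError as exc:
            logger.error("skipping %s: %s", signal.meta.recording_id, exc)
    if n_files == 0:
        raise FileNotFoundError(f"no SisFall-format recordings under {data_dir}")
    counts = Counter(w.label for w in windows)
    logger.info("windows per class: %s", dict(sorted(counts.items())))
    return windows


def train_pipeline(
    windows: list[Window], cfg: RunConfig
) -> tuple[FallPipeline, dict]:
    """Split, augment the training split, train CNN, fit the XGB head.

    Returns the fitted pipeline and a summary dict (split sizes, epoch-wise
    validation UAR history, chosen XGB parameters).
    """
    class_order = cfg.scheme.class_set
    train_w, val_w, test_w = stratified_split(windows, cfg.split)
    train_aug = augment_minority(train_w, cfg.augmentation)
    logger.info(
        "split sizes: train=%d (augmented %d) val=%d test=%d",
        len(train_w), len(train_aug), len(val_w), len(test_w),
    )
    L = cfg.windowing.window_len
    model = build_cnn(cfg.cnn, L, n_channels=6, n_classes=len(class_order),
                      seed=cfg.cnn_init_seed)
    model, history = train_cnn(model, train_aug, val_w, cfg.train, class_order)
    for epoch, v in enumerate(history, start=1):
        logger.info("epoch %3d validation UAR %.4f", epoch, v)
    feats_tr = extract_features(model, train_aug)
    feats_val = extract_features(model, val_w)
    _, y_tr = windows_to_arrays(train_aug, class_order)
    _, y_val = windows_to_arrays(val_w, class_order)
    xgb, params = tune_and_train_xgb(feats_tr, y_tr, feats_val, y_val,
                                     cfg.xgb_search, seed=cfg.xgb_seed)
    logger.info("chosen XGB parameters: %s", params)
    pipe = FallPipeline(cnn=model, xgb=xgb, class_order=class_order,
                        cnn_cfg=cfg.cnn, xgb_params=params,
                        scheme_variant=cfg.label_variant.value)
    summary = {
        "split_sizes": {"train": len(train_w), "train_augmented": len(train_aug),
                        "validation": len(val_w), "test": len(test_w)},
        "val_uar_history": history,
        "best_val_uar": max(history),
        "xgb_params": params,
    }
    return pipe, summary


def evaluate_pipeline(
    pipe: FallPipeline, windows: list[Window], cfg: RunConfig
) -> EvalReport:
    """Recompute the deterministic split and score the held-out test set."""
    if pipe.scheme_variant != cfg.label_variant.value:
        raise ValueError(
            f"label-scheme mismatch: model was trained with {pipe.scheme_variant}, "
            f"dataset is configured as {cfg.label_variant.value}"
        )
    _, _, test_w = stratified_split(windows, cfg.split)
    y_true = [w.label for w in test_w]
    y_pred = pipe.predict(test_w)
    return evaluate(y_true, y_pred, pipe.class_order)
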