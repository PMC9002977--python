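"""CNN feature extractor with a gradient-boosted-tree classification head.

Training proceeds in two stages. First a small 1D CNN (four conv layers of
64 length-3 filters, batch norm, ReLU, average pooling after the first
three conv layers) with a temporary fully connected softmax head is trained
by plain SGD to maximise validation UAR, with early stopping. The softmax
head is then discarded: every window is passed through the frozen conv
stack, the final feature maps are flattened, and an XGBoost classifier is
grid-searched (selection again by validation UAR) and fitted on those
features. Inference = conv stack forward pass + tree ensemble.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
from xgboost import XGBClassifier

# scikit-learn >= 1.6 dropped ClassifierMixin._estimator_type, which the
# xgboost sklearn wrapper still reads when (de)serialising models; restore it.
if not hasattr(XGBClassifier, "_estimator_type"):
    XGBClassifier._estimator_type = "classifier"

from . import nn
from .windowing import Window

__all__ = [
    "CnnConfig",
    "TrainConfig",
    "SplitSpec",
    "XgbSearchSpace",
    "CnnClassifier",
    "FallPipeline",
    "stratified_split",
    "build_cnn",
    "feature_dim",
    "train_cnn",
    "extract_features",
    "tune_and_train_xgb",
    "windows_to_arrays",
]


@dataclass(frozen=True)
class CnnConfig:
    n_conv: int = 4
    filters_per_layer: int = 64
    kernel_len: int = 3
    pool_len: int = 2

    def __post_init__(self) -> None:
        if self.n_conv < 1 or self.filters_per_layer < 1:
            raise ValueError("n_conv and filters_per_layer must be positive")
        if self.kernel_len < 1 or self.pool_len < 1:
            raise ValueError("kernel_len and pool_len must be positive")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01
    batch_size: int = 20
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass(frozen=True)
class SplitSpec:
    train: float = 0.70
    validation: float = 0.15
    test: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.train, self.validation, self.test)
        if min(fr) <= 0 or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")


@dataclass(frozen=True)
class XgbSearchSpace:
    n_estimators: tuple[int, ...] = (100, 300, 500)
    max_depth: tuple[int, ...] = (3, 6, 9)
    learning_rate: tuple[float, ...] = (0.05, 0.1, 0.3)

    def __post_init__(self) -> None:
        if not (self.n_estimators and self.max_depth and self.learning_rate):
            raise ValueError("all search grids must be non-empty")

    def grid(self):
        """Candidates ordered so the tie-break (fewer trees, then shallower
        depth) falls out of a stable max over this iteration order."""
        return product(self.n_estimators, self.max_depth, self.learning_rate)


def stratified_split(
    windows: list[Window], spec: SplitSpec | None = None
) -> tuple[list[Window], list[Window], list[Window]]:
    """Per-class random partition into train/validation/test.

    Each class is shuffled and allocated independently: floor of the train
    and validation fractions, remainder to test, then validation/test are
    topped up from train if rounding left them empty. Deterministic given
    ``spec.seed``; every class must have at least 3 windows.
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    by_class: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_class.setdefault(w.label, []).append(i)
    train_idx, val_idx, test_idx = [], [], []
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        if len(idx) < 3:
            raise ValueError(f"class {label!r} has only {len(idx)} windows; need >= 3")
        rng.shuffle(idx)
        n = len(idx)
        n_tr = int(spec.train * n)
        n_val = int(spec.validation * n)
        n_te = n - n_tr - n_val
        if n_val == 0:
            n_val, n_tr = 1, n_tr - 1
        if n_te == 0:
            n_te, n_tr = 1, n_tr - 1
        train_idx.extend(idx[:n_tr])
        val_idx.extend(idx[n_tr:n_tr + n_val])
        test_idx.extend(idx[n_tr + n_val:])
    return (
        [windows[i] for i in sorted(train_idx)],
        [windows[i] for i in sorted(val_idx)],
        [windows[i] for i in sorted(test_idx)],
    )


def _layer_lengths(cfg: CnnConfig, input_len: int) -> list[int]:
    """Temporal length after each conv (and pool) stage; raises if any <= 0."""
    lengths = []
    L = input_len
    for i in range(cfg.n_conv):
        L = L - cfg.kernel_len + 1
        if L < 1:
            raise ValueError("input too short for the conv stack")
        lengths.append(L)
        if i < cfg.n_conv - 1:  # pooling after all conv layers but the last
            L = L // cfg.pool_len
            if L < 1:
                raise ValueError("input too short for the conv stack")
            lengths.append(L)
    return lengths


def feature_dim(cfg: CnnConfig, input_len: int) -> int:
    """Flattened conv-feature size — a pure function of config and L."""
    return _layer_lengths(cfg, input_len)[-1] * cfg.filters_per_layer


def _min_input_len(cfg: CnnConfig) -> int:
    L = 1
    while True:
        try:
            _layer_lengths(cfg, L)
            return L
        except ValueError:
            L += 1


class CnnClassifier:
    """Conv feature stack plus a temporary fully connected softmax head."""

    def __init__(self, features: nn.Sequential, head: nn.Linear,
                 input_len: int, n_channels: int, n_classes: int) -> None:
        self.features = features
        self.head = head
        self.input_len = input_len
        self.n_channels = n_channels
        self.n_classes = n_classes

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.features.forward(x, train), train)

    def backward(self, dlogits: np.ndarray) -> None:
        self.features.backward(self.head.backward(dlogits))

    def sgd_step(self, lr: float) -> None:
        self.features.sgd_step(lr)
        for p, g in zip(self.head.params, self.head.grads):
            p -= lr * g

    def get_state(self) -> list[np.ndarray]:
        return self.features.get_state() + [p.copy() for p in self.head.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        n_head = len(self.head.params)
        self.features.set_state(state[:-n_head])
        for p, s in zip(self.head.params, state[-n_head:]):
            p[...] = s


def build_cnn(
    cfg: CnnConfig, input_len: int, n_channels: int = 6, n_classes: int = 10,
    seed: int = 0,
) -> CnnClassifier:
    """Assemble [Conv-BN-ReLU-AvgPool] x (n-1) -> Conv-BN-ReLU -> Flatten -> FC.

    Convolutions are valid (no padding), stride 1; pooling kernel equals its
    stride. Raises a configuration error, stating the minimum input length,
    when the stack cannot fit.
    """
    try:
        fdim = feature_dim(cfg, input_len)
    except ValueError:
        raise ValueError(
            f"input length {input_len} too short for the conv stack; "
            f"minimum is {_min_input_len(cfg)}"
        ) from None
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_in = n_channels
    for i in range(cfg.n_conv):
        layers.append(nn.Conv1d(c_in, cfg.filters_per_layer, cfg.kernel_len, rng))
        layers.append(nn.BatchNorm1d(cfg.filters_per_layer))
        layers.append(nn.ReLU())
        if i < cfg.n_conv - 1:
            layers.append(nn.AvgPool1d(cfg.pool_len))
        c_in = cfg.filters_per_layer
    layers.append(nn.Flatten())
    head = nn.Linear(fdim, n_classes, rng)
    return CnnClassifier(nn.Sequential(layers), head, input_len, n_channels, n_classes)


def windows_to_arrays(
    windows: list[Window], class_order: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into an (N, 6, L) float32 tensor and int label vector."""
    index = {c: i for i, c in enumerate(class_order)}
    x = np.stack([w.samples.T for w in windows]).astype(np.float32) if windows else \
        np.empty((0, 6, 0), dtype=np.float32)
    y = np.array([index[w.label] for w in windows], dtype=np.int64)
    return x, y


def _batched_logits(model: CnnClassifier, x: np.ndarray, batch: int = 256) -> np.ndarray:
    outs = [model.forward(x[i:i + batch], train=False) for i in range(0, len(x), batch)]
    return np.concatenate(outs) if outs else np.empty((0, model.n_classes))


def _int_uar(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean recall over the classes present in y_true, on a 0-1 scale."""
    recalls = []
    for c in np.unique(y_true):
        mask = y_true == c
        recalls.append(float((y_pred[mask] == c).mean()))
    return float(np.mean(recalls))


def train_cnn(
    model: CnnClassifier,
    train: list[Window],
    val: list[Window],
    cfg: TrainConfig,
    class_order: tuple[str, ...],
) -> tuple[CnnClassifier, list[float]]:
    """SGD training with epoch-wise validation-UAR early stopping.

    Returns the model restored to the parameter state with the highest
    validation UAR, plus the per-epoch validation-UAR history. Training
    stops once ``cfg.patience`` epochs pass without improvement (patience 0
    therefore trains exactly one epoch) or at ``cfg.max_epochs``.
    """
    if not train or not val:
        raise ValueError("train and validation splits must be non-empty")
    x_tr, y_tr = windows_to_arrays(train, class_order)
    x_val, y_val = windows_to_arrays(val, class_order)
    rng = np.random.default_rng(cfg.seed)
    best_uar, best_epoch, best_state = -1.0, 0, model.get_state()
    history: list[float] = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            if len(sel) < 2:
                continue  # batch norm needs more than one sample
            logits = model.forward(x_tr[sel], train=True)
            _, dlogits = nn.cross_entropy_grad(logits, y_tr[sel])
            model.backward(dlogits.astype(np.float32))
            model.sgd_step(cfg.learning_rate)
        val_uar = _int_uar(y_val, _batched_logits(model, x_val).argmax(axis=1))
        history.append(val_uar)
        if val_uar > best_uar:
            best_uar, best_epoch, best_state = val_uar, epoch, model.get_state()
        if epoch - best_epoch >= cfg.patience:
            break
    model.set_state(best_state)
    return model, history


def extract_features(model: CnnClassifier, windows: list[Window] | np.ndarray) -> np.ndarray:
    """Flattened conv features, one row per window, in input order.

    Inference mode: batch norm uses its learned running statistics, so the
    output is deterministic and unchanged by removing the softmax head.
    """
    if isinstance(windows, np.ndarray):
        x = windows.astype(np.float32)
    else:
        x = (np.stack([w.samples.T for w in windows]).astype(np.float32)
             if windows else np.empty((0, model.n_channels, model.input_len), np.float32))
    if x.shape[0] == 0:
        fdim = model.head.params[0].shape[1]
        return np.empty((0, fdim), dtype=np.float32)
    if x.shape[2] != model.input_len:
        raise ValueError(f"window length {x.shape[2]} != trained length {model.input_len}")
    outs = [model.features.forward(x[i:i + 256], train=False) for i in range(0, len(x), 256)]
    return np.concatenate(outs)


def tune_and_train_xgb(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    val_features: np.ndarray,
    val_labels: np.ndarray,
    space: XgbSearchSpace | None = None,
    seed: int = 0,
) -> tuple[XGBClassifier, dict]:
    """Exhaustive grid search over the XGB hyper-parameters.

    Each candidate is fitted on the training features and scored by
    validation UAR; ties break toward fewer trees, then shallower depth
    (the grid iteration order). The winning parameter set is refitted on
    the training features and returned.
    """
    if train_features.shape[1] != val_features.shape[1]:
        raise ValueError("train and validation feature dimensions differ")
    uniq = np.unique(train_labels)
    if len(uniq) < 2:
        raise ValueError("training labels are degenerate (single class)")
    # XGBoost wants contiguous 0..k-1 labels; encode and score in decoded space
    y_tr = np.searchsorted(uniq, train_labels)
    space = space or XgbSearchSpace()
    best = None
    for n_est, depth, lr in space.grid():
        clf = XGBClassifier(
            n_estimators=n_est, max_depth=depth, learning_rate=lr,
            tree_method="hist", random_state=seed, verbosity=0,
        )
        clf.fit(train_features, y_tr)
        score = _int_uar(val_labels, uniq[clf.predict(val_features)])
        if best is None or score > best[0]:
            best = (score, {"n_estimators": n_est, "max_depth": depth, "learning_rate": lr})
    params = best[1]
    final = XGBClassifier(tree_method="hist", random_state=seed, verbosity=0, **params)
    final.fit(train_features, y_tr)
    final.label_classes_ = uniq
    return final, params


@dataclass
class FallPipeline:
    """Frozen conv stack + fitted tree ensemble + label bookkeeping."""

    cnn: CnnClassifier
    xgb: XGBClassifier
    class_order: tuple[str, ...]
    cnn_cfg: CnnConfig
    xgb_params: dict = field(default_factory=dict)
    scheme_variant: str = "TEN_CLASS"

    def predict(self, windows: list[Window] | np.ndarray) -> list[str]:
        feats = extract_features(self.cnn, windows)
        if feats.shape[0] == 0:
            return []
        pred = self.xgb.predict(feats)
        label_classes = getattr(self.xgb, "label_classes_", None)
        if label_classes is not None:
            pred = np.asarray(label_classes)[pred]
        return [self.class_order[i] for i in pred]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        state = self.cnn.get_state()
        np.savez(directory / "cnn_state.npz", **{f"p{i}": a for i, a in enumerate(state)})
        self.xgb.save_model(str(directory / "xgb_model.json"))
        sidecar = {
            "class_order": list(self.class_order),
            "scheme_variant": self.scheme_variant,
            "cnn": {
                "n_conv": self.cnn_cfg.n_conv,
                "filters_per_layer": self.cnn_cfg.filters_per_layer,
                "kernel_len": self.cnn_cfg.kernel_len,
                "pool_len": self.cnn_cfg.pool_len,
                "input_len": self.cnn.input_len,
                "n_channels": self.cnn.n_channels,
                "n_classes": self.cnn.n_classes,
            },
            "xgb_params": self.xgb_params,
            "label_classes": [int(v) for v in getattr(self.xgb, "label_classes_",
                                                      range(len(self.class_order)))],
        }
        (directory / "pipeline.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "FallPipeline":
        directory = Path(directory)
        sidecar = json.loads((directory / "pipeline.json").read_text())
        c = sidecar["cnn"]
        cfg = CnnConfig(n_conv=c["n_conv"], filters_per_layer=c["filters_per_layer"],
                        kernel_len=c["kernel_len"], pool_len=c["pool_len"])
        cnn = build_cnn(cfg, c["input_len"], c["n_channels"], c["n_classes"])
        with np.load(directory / "cnn_state.npz") as data:
            cnn.set_state([data[f"p{i}"] for i in range(len(data.files))])
        xgb = XGBClassifier()
        xgb.load_model(str(directory / "xgb_model.json"))
        if "label_classes" in sidecar:
            xgb.label_classes_ = np.asarray(sidecar["label_classes"])
        return cls(cnn=cnn, xgb=xgb, class_order=tuple(sidecar["class_order"]),
                   cnn_cfg=cfg, xgb_params=sidecar.get("xgb_params", {}),
                   scheme_variant=sidecar.get("scheme_variant", "TEN_CLASS"))
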