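"""Residual convolutional severity classifiers and hybrid variants.

The volumetric classifier is a residual bottleneck network (the 50-layer
stage plan 3-4-6-3 by default, with shallower presets and a channel
``width_scale`` for desk-scale runs).  Three classification heads are
supported — softmax (2 logits), tanh and sigmoid (1 logit each) — plus a
``feature`` head: the classification layer replaced by a fully connected
layer of ``feature_dim`` units whose output feeds a kNN or SVM, forming the
hybrid variant.  The feature layer is randomly initialised and *not*
retrained; a best-of-``restarts`` protocol re-draws it.

The 2D variant of the same architecture backs the slice-range evaluation
protocol: one classifier per contiguous group of slices along a chosen
anatomical axis, scored subject-level by majority vote over the subject's
slices.

Training protocol: only scored high/low subjects may appear in the training
set (controls are strictly test-time inputs), and the train/test subject-id
sets must be disjoint.  Both rules are enforced, not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import nn
from .core import (
    BrainVolume,
    ProtocolError,
    SizingError,
    ValidationError,
)

__all__ = [
    "ModelConfig", "TrainSpec", "ClassifierResult", "SeverityNet",
    "build_classifier", "train_classifier", "to_feature_model",
    "hybrid_classify", "slice_range_evaluation", "classify_controls",
    "compare_heads", "make_split", "save_model", "load_model",
]

#: Residual stage plans (bottleneck blocks per stage).
DEPTH_PRESETS = {
    "resnet50": (3, 4, 6, 3),
    "resnet26": (2, 2, 2, 2),
    "tiny": (1, 1),
}

#: Base channel widths per stage at width_scale = 1.
BASE_WIDTHS = (16, 32, 64, 128)

HEADS = ("softmax", "tanh", "sigmoid", "feature")

#: Binary label order used everywhere: low = 0, high = 1.
LABELS = ("low", "high")

_AXIS_INDEX = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class ModelConfig:
    dimensionality: int = 3
    depth_preset: str = "resnet50"
    width_scale: float = 1.0
    head: str = "softmax"
    feature_dim: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimensionality not in (2, 3):
            raise ValidationError("dimensionality must be 2 or 3")
        if self.head not in HEADS:
            raise ValidationError(f"unknown head {self.head!r}")
        if self.width_scale <= 0:
            raise ValidationError("width_scale must be > 0")
        if (self.head == "feature") != (self.feature_dim is not None):
            raise ValidationError("feature_dim is required iff head == 'feature'")
        if self.depth_preset not in DEPTH_PRESETS:
            raise ValidationError(
                f"unknown depth_preset {self.depth_preset!r}; "
                f"options: {sorted(DEPTH_PRESETS)}"
            )

    @property
    def stage_plan(self):
        return DEPTH_PRESETS[self.depth_preset]


@dataclass
class TrainSpec:
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    train_ids: Sequence[str] = ()
    test_ids: Sequence[str] = ()
    seed: int = 0

    def validate(self, records) -> None:
        train, test = set(self.train_ids), set(self.test_ids)
        if train & test:
            raise ProtocolError(
                f"train/test id sets overlap: {sorted(train & test)}"
            )
        by_id = {r.subject_id: r for r in records}
        unknown = (train | test) - set(by_id)
        if unknown:
            raise ValidationError(f"ids not in the cohort: {sorted(unknown)}")
        for sid in train:
            if by_id[sid].group == "control":
                raise ProtocolError(
                    f"control subject {sid} in the training set; the network "
                    "is never trained on unscored controls"
                )
        for name, ids in (("training", train), ("test", test)):
            groups = {by_id[s].group for s in ids} - {"control"}
            if groups != {"high", "low"}:
                raise ProtocolError(
                    f"{name} set must contain both high and low subjects, got {sorted(groups)}"
                )


@dataclass
class ClassifierResult:
    predictions: dict  # subject_id -> "high" | "low"
    accuracy: float
    variant: str
    history: list = field(default_factory=list, repr=False)
    classifier: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValidationError("accuracy must be in [0, 1]")


def make_split(records, test_size: int, seed: int = 0):
    """Deterministic stratified split of the scored subjects.

    Returns (train_ids, test_ids); controls are never included.
    """
    rng = np.random.default_rng(seed)
    test, train = [], []
    for g in ("high", "low"):
        ids = [r.subject_id for r in records if r.group == g]
        ids = list(rng.permutation(ids))
        k = max(1, round(test_size * len(ids) /
                         sum(1 for r in records if r.group in ("high", "low"))))
        test += ids[:k]
        train += ids[k:]
    return sorted(train), sorted(test)


class SeverityNet:
    """A residual CNN handle: body + head, with input-gradient support."""

    def __init__(self, config: ModelConfig, in_channels: int = 1):
        self.config = config
        nd = config.dimensionality
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
        plan = config.stage_plan
        widths = [max(1, round(w * config.width_scale)) for w in BASE_WIDTHS[:len(plan)]]
        stem = nn.Conv(nd, in_channels, widths[0], k=3, stride=2, pad=1, rng=rng, bias=False)
        stem.skip_input_grad = True  # eval-mode backward (saliency) still returns dx
        layers = [stem, nn.BatchNorm(widths[0]), nn.ReLU(), nn.MaxPool(2)]
        cin = widths[0]
        for i, (n_blocks, w) in enumerate(zip(plan, widths)):
            for b in range(n_blocks):
                stride = 2 if (i > 0 and b == 0) else 1
                blk = nn.Bottleneck(nd, cin, w, stride=stride, rng=rng)
                layers.append(blk)
                cin = blk.cout
        layers.append(nn.GlobalAvgPool())
        self.body = nn.Sequential(layers)
        self.feature_width = cin
        n_out = {"softmax": 2, "tanh": 1, "sigmoid": 1}.get(config.head, config.feature_dim)
        self.head = nn.Linear(cin, n_out, rng=rng)
        #: total downsampling of the spatial grid (stem conv + pool + stages)
        self.downsampling = 4 * 2 ** max(0, len(plan) - 1)
        self.norm = (0.0, 1.0)  # set by train_classifier

    # -- plumbing ----------------------------------------------------------
    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params())

    def params(self):
        return self.body.params() + self.head.params()

    def check_grid(self, shape) -> None:
        if min(shape) < self.downsampling:
            raise SizingError(
                f"input grid {shape} is smaller than the network's total "
                f"downsampling factor {self.downsampling}"
            )

    def _prep(self, volumes) -> np.ndarray:
        arrs = [v.data if isinstance(v, BrainVolume) else np.asarray(v) for v in volumes]
        x = np.stack(arrs).astype(np.float32)[:, None]
        mu, sd = self.norm
        return (x - mu) / sd

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.check_grid(x.shape[2:])
        return self.head.forward(self.body.forward(x, train), train)

    def forward_volumes(self, volumes, train: bool = False, batch: int = 16) -> np.ndarray:
        x = self._prep(volumes)
        return np.concatenate([self.logits(x[i:i + batch], train)
                               for i in range(0, len(x), batch)])

    def predict_labels(self, volumes) -> list:
        z = self.forward_volumes(volumes)
        if self.config.head == "softmax":
            idx = z.argmax(axis=1)
        else:
            idx = (z[:, 0] > 0).astype(int)
        return [LABELS[i] for i in idx]

    def input_gradient(self, volume, target: Optional[int] = None) -> np.ndarray:
        """d(pre-activation score of ``target``)/d(input voxels).

        ``target`` indexes :data:`LABELS`; defaults to the predicted class.
        Gradients are taken with respect to the *raw* (un-normalised) input.
        """
        x = self._prep([volume])
        z = self.logits(x, train=False)
        if self.config.head == "feature":
            raise ValidationError("saliency requires a classification head")
        if self.config.head == "softmax":
            t = int(z.argmax(axis=1)[0]) if target is None else int(target)
            dz = np.zeros_like(z)
            dz[0, t] = 1.0
        else:
            t = int(z[0, 0] > 0) if target is None else int(target)
            dz = np.full_like(z, 1.0 if t == 1 else -1.0)
        g = self.body.backward(self.head.backward(dz))[0, 0]
        if not np.all(np.isfinite(g)):
            raise ValidationError("non-finite input gradients")
        return g / self.norm[1], t  # chain rule through input normalisation


def build_classifier(config: ModelConfig, in_channels: int = 1) -> SeverityNet:
    """Build a (deterministically initialised) residual classifier."""
    return SeverityNet(config, in_channels=in_channels)


def _labels_of(records, ids):
    by_id = {r.subject_id: r for r in records}
    return np.array([LABELS.index(by_id[s].group) for s in ids])


def train_classifier(model: SeverityNet, volumes, records, spec: TrainSpec):
    """Train on high/low subjects; report held-out test accuracy.

    ``volumes`` is aligned with ``records``.  Returns
    ``(model, ClassifierResult)``; the training history (per-epoch loss and
    training accuracy) is logged on the result.
    """
    spec.validate(records)
    vol_by_id = {r.subject_id: v for r, v in zip(records, volumes)}
    train_ids = list(spec.train_ids)
    test_ids = list(spec.test_ids)

    x_train = np.stack([vol_by_id[s].data for s in train_ids]).astype(np.float32)[:, None]
    mu, sd = float(x_train.mean()), float(x_train.std())
    model.norm = (mu, sd if sd > 0 else 1.0)
    x_train = (x_train - model.norm[0]) / model.norm[1]
    y_train = _labels_of(records, train_ids)
    model.check_grid(x_train.shape[2:])

    loss_fn = nn.LOSSES[model.config.head]
    opt = nn.Adam(model.params(), lr=spec.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 404]))
    history = []
    for epoch in range(spec.epochs):
        order = rng.permutation(len(train_ids))
        losses = []
        for i in range(0, len(order), spec.batch_size):
            idx = order[i:i + spec.batch_size]
            if len(idx) < 2:  # batch norm needs > 1 sample
                continue
            z = model.logits(x_train[idx], train=True)
            loss, dz = loss_fn(z, y_train[idx])
            opt.zero_grad()
            # weight gradients only; the returned input gradient is discarded
            model.body.backward(model.head.backward(dz))
            opt.step()
            losses.append(loss)
        z = model.forward_volumes([vol_by_id[s] for s in train_ids])
        pred = z.argmax(axis=1) if model.config.head == "softmax" else (z[:, 0] > 0).astype(int)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "train_accuracy": float((pred == y_train).mean())})

    preds = model.predict_labels([vol_by_id[s] for s in test_ids])
    y_test = _labels_of(records, test_ids)
    acc = float(np.mean([LABELS.index(p) for p in preds] == y_test))
    result = ClassifierResult(
        predictions=dict(zip(test_ids, preds)),
        accuracy=acc,
        variant=model.config.head,
        history=history,
    )
    return model, result


# ---------------------------------------------------------------------------
# hybrid variants

def to_feature_model(model: SeverityNet, feature_dim: int, seed: int = 0) -> SeverityNet:
    """Swap the classification layer for a random ``feature_dim``-unit FC.

    The backbone (and its input normalisation) is shared with the trained
    model; only the head is replaced, with freshly drawn random weights.
    """
    cfg = replace(model.config, head="feature", feature_dim=feature_dim, seed=seed)
    out = SeverityNet.__new__(SeverityNet)
    out.config = cfg
    out.body = model.body
    out.feature_width = model.feature_width
    out.downsampling = model.downsampling
    out.norm = model.norm
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    out.head = nn.Linear(model.feature_width, feature_dim, rng=rng)
    return out


class HybridClassifier:
    """Frozen feature extractor + kNN or SVM decision head."""

    def __init__(self, feature_model: SeverityNet, estimator):
        self.feature_model = feature_model
        self.estimator = estimator

    def predict_labels(self, volumes) -> list:
        f = self.feature_model.forward_volumes(volumes)
        return [LABELS[i] for i in self.estimator.predict(f)]


def hybrid_classify(feature_model: SeverityNet, volumes, records, spec: TrainSpec,
                    head: str = "knn", k: int = 5, restarts: int = 1,
                    svm_kernel: str = "linear") -> ClassifierResult:
    """Fit a kNN or SVM on extracted feature vectors and score the test set.

    kNN votes among the ``k`` nearest training vectors by Euclidean
    distance; the SVM fits a separating hyperplane on the training vectors.
    With ``restarts`` > 1 the random feature layer is re-drawn and the best
    test accuracy is reported (the per-restart accuracies are logged on the
    result history).
    """
    if feature_model.config.head != "feature":
        raise ValidationError("hybrid_classify requires a feature-head model")
    if head not in ("knn", "svm"):
        raise ValidationError(f"unknown hybrid head {head!r}")
    spec.validate(records)
    if head == "knn":
        if k > len(spec.train_ids):
            raise ValidationError(
                f"k={k} exceeds the training-set size {len(spec.train_ids)}"
            )
        if k % 2 == 0:
            raise ValidationError("k must be odd so the majority vote is defined")

    vol_by_id = {r.subject_id: v for r, v in zip(records, volumes)}
    y_train = _labels_of(records, spec.train_ids)
    y_test = _labels_of(records, spec.test_ids)
    train_vols = [vol_by_id[s] for s in spec.train_ids]
    test_vols = [vol_by_id[s] for s in spec.test_ids]

    attempts = []
    best = None
    for attempt in range(restarts):
        fm = to_feature_model(feature_model, feature_model.config.feature_dim,
                              seed=feature_model.config.seed + attempt) \
            if restarts > 1 else feature_model
        f_train = fm.forward_volumes(train_vols)
        f_test = fm.forward_volumes(test_vols)
        if head == "knn":
            est = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
        else:
            est = SVC(kernel=svm_kernel)
        est.fit(f_train, y_train)
        pred = est.predict(f_test)
        acc = float((pred == y_test).mean())
        attempts.append(acc)
        if best is None or acc > best[0]:
            best = (acc, pred, HybridClassifier(fm, est))
    acc, pred, clf = best
    return ClassifierResult(
        predictions={s: LABELS[i] for s, i in zip(spec.test_ids, pred)},
        accuracy=acc,
        variant=f"hybrid-{head}",
        history=[{"attempt": i, "accuracy": a} for i, a in enumerate(attempts)],
        classifier=clf,
    )


# ---------------------------------------------------------------------------
# slice-range protocol (2D)

def slice_range_evaluation(volumes, records, axis: str, spec: TrainSpec,
                           start: int = 24, stop: int = 103, group_size: int = 8,
                           model_config: Optional[ModelConfig] = None):
    """Train one 2D classifier per contiguous slice group along ``axis``.

    Every slice in a group is a training image labelled with its subject's
    severity group; train/test membership follows the subject-id split, so
    no subject's slices leak across it.  Accuracy per group is subject-level
    (majority vote over the subject's slices); the slice-level accuracy is
    logged alongside.
    """
    if axis not in _AXIS_INDEX:
        raise ValidationError(f"unknown axis {axis!r}")
    spec.validate(records)
    ax = _AXIS_INDEX[axis]
    n_slices = volumes[0].data.shape[ax]
    if n_slices < stop + 1:
        raise ValidationError(
            f"axis {axis} has {n_slices} slices, needs >= {stop + 1}"
        )
    if (stop - start + 1) % group_size:
        raise ValidationError("(stop - start + 1) must be divisible by group_size")
    base = model_config or ModelConfig(dimensionality=2, depth_preset="tiny",
                                       width_scale=0.25, seed=spec.seed)
    if base.dimensionality != 2:
        raise ValidationError("slice-range evaluation uses 2D classifiers")

    vol_by_id = {r.subject_id: v for r, v in zip(records, volumes)}
    by_id = {r.subject_id: r for r in records}
    results = []
    for g0 in range(start, stop + 1, group_size):
        sl = list(range(g0, g0 + group_size))

        def stack(ids):
            imgs, owner = [], []
            for s in ids:
                arr = np.take(vol_by_id[s].data, sl, axis=ax)
                arr = np.moveaxis(arr, ax, 0)  # (group_size, H, W)
                imgs.append(arr)
                owner += [s] * len(sl)
            return np.concatenate(imgs)[:, None].astype(np.float32), owner

        x_train, _ = stack(spec.train_ids)
        x_test, owner_test = stack(spec.test_ids)
        y_train = np.repeat(_labels_of(records, spec.train_ids), group_size)
        y_test_slice = np.repeat(_labels_of(records, spec.test_ids), group_size)

        model = SeverityNet(replace(base, seed=base.seed + g0), in_channels=1)
        mu, sd = float(x_train.mean()), float(x_train.std())
        model.norm = (mu, sd if sd > 0 else 1.0)
        xtr = (x_train - model.norm[0]) / model.norm[1]
        loss_fn = nn.LOSSES[model.config.head]
        opt = nn.Adam(model.params(), lr=spec.learning_rate)
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 606, g0]))
        for _ in range(spec.epochs):
            order = rng.permutation(len(xtr))
            for i in range(0, len(order), spec.batch_size):
                idx = order[i:i + spec.batch_size]
                if len(idx) < 2:
                    continue
                z = model.logits(xtr[idx], train=True)
                _, dz = loss_fn(z, y_train[idx])
                opt.zero_grad()
                model.body.backward(model.head.backward(dz))
                opt.step()

        z = model.forward_volumes(x_test[:, 0])
        pred_slice = z.argmax(axis=1) if model.config.head == "softmax" \
            else (z[:, 0] > 0).astype(int)
        slice_acc = float((pred_slice == y_test_slice).mean())
        subj_pred = {}
        for s in spec.test_ids:
            votes = pred_slice[[i for i, o in enumerate(owner_test) if o == s]]
            subj_pred[s] = int(votes.sum() * 2 > len(votes))
        subj_acc = float(np.mean([
            subj_pred[s] == LABELS.index(by_id[s].group) for s in spec.test_ids
        ]))
        results.append({"axis": axis, "start": g0, "stop": g0 + group_size - 1,
                        "accuracy": subj_acc, "slice_accuracy": slice_acc})
    return results


def classify_controls(model, control_volumes) -> float:
    """Fraction of control volumes assigned to the low-severity class."""
    if len(control_volumes) == 0:
        raise ValidationError("empty control set")
    labels = model.predict_labels(control_volumes)
    return float(np.mean([lab == "low" for lab in labels]))


def compare_heads(volumes, records, spec: TrainSpec, base: Optional[ModelConfig] = None):
    """Train softmax/tanh/sigmoid heads under identical seeds; report all."""
    base = base or ModelConfig()
    out = {}
    for head in ("softmax", "tanh", "sigmoid"):
        cfg = replace(base, head=head, feature_dim=None)
        model = build_classifier(cfg)
        _, res = train_classifier(model, volumes, records, spec)
        out[head] = res
    return out


# ---------------------------------------------------------------------------
# checkpoints

def save_model(model: SeverityNet, path) -> None:
    """Serialise a model (config, normalisation, parameters) to ``.npz``."""
    import json as _json
    arrays = {f"p{i}": p for i, (p, _) in enumerate(model.params())}
    bn_state = {}
    i = 0
    for layer in _iter_layers(model):
        if isinstance(layer, nn.BatchNorm):
            bn_state[f"bn{i}_mean"] = layer.running_mean
            bn_state[f"bn{i}_var"] = layer.running_var
            i += 1
    np.savez_compressed(
        path,
        config=_json.dumps({**model.config.__dict__}),
        norm=np.array(model.norm, dtype=np.float64),
        **arrays, **bn_state,
    )


def load_model(path) -> SeverityNet:
    """Rebuild a model saved by :func:`save_model`."""
    import json as _json
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig(**_json.loads(str(data["config"])))
        model = SeverityNet(cfg)
        for i, (p, _) in enumerate(model.params()):
            p[...] = data[f"p{i}"]
        i = 0
        for layer in _iter_layers(model):
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = data[f"bn{i}_mean"]
                layer.running_var = data[f"bn{i}_var"]
                i += 1
        model.norm = tuple(data["norm"])
    return model


def _iter_layers(model: SeverityNet):
    stack = list(model.body.layers) + [model.head]
    while stack:
        layer = stack.pop(0)
        if isinstance(layer, nn.Bottleneck):
            stack = layer.main.layers \
                + (layer.skip.layers if layer.skip else []) + stack
        elif isinstance(layer, nn.Sequential):
            stack = layer.layers + stack
        else:
            yield layer
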