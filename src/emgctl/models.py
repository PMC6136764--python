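"""The two 9-class decoders: a CNN on raw windows, an RBF-SVM on features.

The CNN consumes raw filtered 8 x 192 windows.  Its 22 layers are an
input layer, five 3x3 convolution blocks (16, 32, 64, 64, 16 filters,
each convolution -> batch norm -> ReLU), 2x2/stride-2 max pooling after
the first three blocks (8x192 -> 4x96 -> 2x48 -> 1x24), a dense layer to
the 9 classes, a softmax layer and the argmax classification layer.
Training uses stochastic gradient descent with momentum (initial rate
0.001, minibatch 128, L2 1e-4), a random 90/10 train/validation split,
validation twice per epoch, at most 40 epochs, and early stopping after
5 validation checks without improvement.

The SVM consumes 40-dimensional feature vectors (5 features x 8
channels), z-scored with training-set statistics that are persisted
inside the model, and uses an RBF kernel with gamma = 1/40 and cost 1,
with one-vs-one multiclass voting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .features import extract_many
from .motions import MotionClass
from .preprocess import LabeledWindowSet

DEFAULT_INPUT_SHAPE = (8, 192)
N_CLASSES = 9


@dataclass(frozen=True)
class CnnSpec:
    """Architecture of the raw-EMG CNN."""

    conv_filters: tuple[int, ...] = (16, 32, 64, 64, 16)
    kernel: int = 3
    pool_after: tuple[int, ...] = (0, 1, 2)  # pooling follows blocks 1-3
    input_shape: tuple[int, int] = DEFAULT_INPUT_SHAPE
    n_classes: int = N_CLASSES

    def shape_trace(self) -> list[tuple[int, int]]:
        """Spatial (H, W) after each convolution block (post-pool)."""
        h, w = self.input_shape
        trace = []
        for i in range(len(self.conv_filters)):
            if i in self.pool_after:
                h, w = h // 2, w // 2
            trace.append((h, w))
        return trace

    @property
    def n_layers(self) -> int:
        """Layer count in the input/conv/bn/relu/pool/fc/softmax/class accounting."""
        nb = len(self.conv_filters)
        return 1 + 3 * nb + len(self.pool_after) + 3

    def build(self, rng: np.random.Generator) -> nn.Sequential:
        layers: list = []
        in_ch = 1
        h, w = self.input_shape
        for i, out_ch in enumerate(self.conv_filters):
            layers.append(nn.Conv2d(in_ch, out_ch, rng, k=self.kernel))
            layers.append(nn.BatchNorm2d(out_ch))
            layers.append(nn.ReLU())
            if i in self.pool_after:
                if h % 2 or w % 2:
                    raise ValueError(f"cannot 2x2-pool odd spatial size {h}x{w}")
                layers.append(nn.MaxPool2x2())
                h, w = h // 2, w // 2
            in_ch = out_ch
        layers.append(nn.Flatten())
        layers.append(nn.Dense(in_ch * h * w, self.n_classes, rng))
        return nn.Sequential(layers)


@dataclass(frozen=True)
class TrainSpec:
    """CNN optimization recipe."""

    lr: float = 1e-3
    momentum: float = 0.9
    batch_size: int = 128
    max_epochs: int = 40
    l2: float = 1e-4
    val_fraction: float = 0.10
    checks_per_epoch: int = 2
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if min(self.lr, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("training hyper-parameters must be positive")


def _encode_labels(labels) -> tuple[np.ndarray, list]:
    classes = sorted({MotionClass(c) if not isinstance(c, MotionClass) else c
                      for c in labels}, key=lambda c: c.value)
    lut = {c: i for i, c in enumerate(classes)}
    y = np.array([lut[MotionClass(c)] for c in labels], dtype=np.int64)
    return y, classes


class CnnClassifier:
    """Raw-window CNN decoder with the standard training recipe.

    Use :meth:`fit` on windows shaped (n, 8, 192); :meth:`predict` and
    :meth:`predict_with_scores` accept a single window or a stack.
    """

    kind = "cnn"

    def __init__(self, spec: CnnSpec | None = None, tspec: TrainSpec | None = None,
                 standardize: bool = False):
        self.spec = spec or CnnSpec()
        self.tspec = tspec or TrainSpec()
        self.standardize = standardize  # optional per-channel z-scoring
        self.net: nn.Sequential | None = None
        self.classes_: list[MotionClass] = []
        self.history: list[dict] = []
        self._norm: tuple[np.ndarray, np.ndarray] | None = None

    # -- training ----------------------------------------------------------

    def fit(self, windows: np.ndarray, labels) -> "CnnClassifier":
        X = np.asarray(windows, dtype=nn.F)
        if X.ndim != 3 or X.shape[1:] != self.spec.input_shape:
            raise ValueError(f"windows must be (n, {self.spec.input_shape[0]}, "
                             f"{self.spec.input_shape[1]}), got {X.shape}")
        y, self.classes_ = _encode_labels(labels)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes to train")
        if self.standardize:
            mu = X.mean(axis=(0, 2), keepdims=True)
            sd = X.std(axis=(0, 2), keepdims=True) + 1e-8
            self._norm = (mu, sd)
            X = (X - mu) / sd
        spec = self.spec if self.spec.n_classes == len(self.classes_) else \
            CnnSpec(conv_filters=self.spec.conv_filters, kernel=self.spec.kernel,
                    pool_after=self.spec.pool_after, input_shape=self.spec.input_shape,
                    n_classes=len(self.classes_))
        ts = self.tspec
        rng = np.random.default_rng(ts.seed)
        self.net = spec.build(rng)
        X = X[:, None]  # (n, 1, H, W)

        n = len(X)
        n_val = max(1, int(round(ts.val_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) == 0:
            raise ValueError("not enough data for the validation split")
        Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

        opt = nn.SGDM(lr=ts.lr, momentum=ts.momentum, l2=ts.l2)
        iters_per_epoch = max(1, int(np.ceil(len(Xtr) / ts.batch_size)))
        check_every = max(1, iters_per_epoch // ts.checks_per_epoch)
        best_loss, best_state, bad_checks = np.inf, None, 0
        self.history = []
        it = 0
        stop = False
        for epoch in range(ts.max_epochs):
            order = rng.permutation(len(Xtr))
            losses = []
            for b in range(iters_per_epoch):
                idx = order[b * ts.batch_size:(b + 1) * ts.batch_size]
                losses.append(self.net.train_step(Xtr[idx], ytr[idx], opt))
                it += 1
                if it % check_every == 0 or b == iters_per_epoch - 1:
                    vloss, vacc = self._evaluate(Xval, yval)
                    self.history.append({"iteration": it, "epoch": epoch,
                                         "train_loss": float(np.mean(losses)),
                                         "val_loss": vloss, "val_acc": vacc})
                    if vloss < best_loss - 1e-6:
                        best_loss, best_state, bad_checks = vloss, self.net.get_state(), 0
                    else:
                        bad_checks += 1
                        if bad_checks >= ts.patience:
                            stop = True
                            break
            if stop:
                break
        if best_state is not None:
            self.net.set_state(best_state)
        return self

    def _evaluate(self, X: np.ndarray, y: np.ndarray,
                  batch: int = 512) -> tuple[float, float]:
        losses, hits, n = [], 0, len(X)
        for s in range(0, n, batch):
            p = self.net.predict_proba(X[s:s + batch])
            yb = y[s:s + batch]
            losses.append(nn.cross_entropy(p, yb) * len(yb))
            hits += int((p.argmax(axis=1) == yb).sum())
        return float(np.sum(losses) / n), hits / n

    # -- inference ---------------------------------------------------------

    def _prep(self, windows: np.ndarray) -> np.ndarray:
        X = np.asarray(windows, dtype=nn.F)
        single = X.ndim == 2
        if single:
            X = X[None]
        if X.shape[1:] != self.spec.input_shape:
            raise ValueError(f"expected windows of shape {self.spec.input_shape}, "
                             f"got {X.shape[1:]}")
        if self._norm is not None:
            mu, sd = self._norm
            X = (X - mu) / sd
        return X[:, None]

    def predict_scores(self, windows: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, (n, n_classes); rows sum to 1."""
        if self.net is None:
            raise RuntimeError("model is not fitted")
        return self.net.predict_proba(self._prep(windows))

    def predict(self, windows: np.ndarray) -> np.ndarray:
        scores = self.predict_scores(windows)
        out = np.empty(len(scores), dtype=object)
        out[:] = [self.classes_[i] for i in scores.argmax(axis=1)]
        return out

    def predict_with_scores(self, window: np.ndarray) -> tuple[MotionClass, np.ndarray]:
        """Single-window (class, score-vector) interface used by the control loop."""
        scores = self.predict_scores(window)[0]
        return self.classes_[int(scores.argmax())], scores

    def accuracy(self, windows: np.ndarray, labels) -> float:
        pred = [c.value for c in self.predict(windows)]
        truth = [MotionClass(c).value for c in labels]
        return float(np.mean(np.array(pred) == np.array(truth)))

    # -- persistence ---------------------------------------------------------

    def save(self, prefix: str | Path) -> None:
        """Write <prefix>.npz (parameters) and <prefix>.json (manifest)."""
        if self.net is None:
            raise RuntimeError("model is not fitted")
        prefix = Path(prefix)
        state = self.net.get_state()
        if self._norm is not None:
            state["norm_mu"], state["norm_sd"] = self._norm
        np.savez(prefix.with_suffix(".npz"), **state)
        manifest = {
            "kind": self.kind,
            "classes": [c.value for c in self.classes_],
            "spec": asdict(self.spec),
            "tspec": asdict(self.tspec),
            "standardize": self.standardize,
            "history": self.history,
        }
        prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "CnnClassifier":
        prefix = Path(prefix)
        manifest = json.loads(prefix.with_suffix(".json").read_text())
        spec_d = manifest["spec"]
        spec = CnnSpec(conv_filters=tuple(spec_d["conv_filters"]),
                       kernel=spec_d["kernel"],
                       pool_after=tuple(spec_d["pool_after"]),
                       input_shape=tuple(spec_d["input_shape"]),
                       n_classes=spec_d["n_classes"])
        model = cls(spec=spec, tspec=TrainSpec(**manifest["tspec"]),
                    standardize=manifest["standardize"])
        model.classes_ = [MotionClass(c) for c in manifest["classes"]]
        model.history = manifest["history"]
        with np.load(prefix.with_suffix(".npz")) as data:
            state = {k: data[k] for k in data.files}
        if "norm_mu" in state:
            model._norm = (state.pop("norm_mu"), state.pop("norm_sd"))
        build_spec = spec if spec.n_classes == len(model.classes_) else \
            CnnSpec(conv_filters=spec.conv_filters, kernel=spec.kernel,
                    pool_after=spec.pool_after, input_shape=spec.input_shape,
                    n_classes=len(model.classes_))
        model.net = build_spec.build(np.random.default_rng(0))
        model.net.set_state(state)
        return model


class SvmClassifier:
    """RBF-SVM decoder on the 40-dimensional feature vectors.

    The z-scoring feature scaler is fitted on the training set and
    stored inside the model; gamma defaults to 1 / n_features (= 1/40).
    """

    kind = "svm"

    def __init__(self, c: float = 1.0, gamma: float | None = None,
                 dead_band: float = 0.0):
        self.c = c
        self.gamma = gamma  # None -> 1 / n_features at fit time
        self.dead_band = dead_band
        self.pipeline = None
        self.classes_: list[MotionClass] = []

    def fit(self, features: np.ndarray, labels) -> "SvmClassifier":
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        X = np.asarray(features, dtype=float)
        if X.ndim != 2:
            raise ValueError("features must be (n, n_features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain NaN or infinite values")
        y, self.classes_ = _encode_labels(labels)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes to train")
        gamma = self.gamma if self.gamma is not None else 1.0 / X.shape[1]
        self.pipeline = Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(C=self.c, kernel="rbf", gamma=gamma,
                        decision_function_shape="ovr")),
        ])
        self.pipeline.fit(X, y)
        return self

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        """One-vs-rest aggregated decision values (n, n_classes)."""
        if self.pipeline is None:
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain NaN or infinite values")
        scores = self.pipeline.decision_function(X)
        if scores.ndim == 1:  # binary
            scores = np.stack([-scores, scores], axis=1)
        return scores

    def predict(self, features: np.ndarray) -> np.ndarray:
        scores = self.predict_scores(features)
        out = np.empty(len(scores), dtype=object)
        out[:] = [self.classes_[i] for i in scores.argmax(axis=1)]
        return out

    def predict_with_scores(self, features: np.ndarray) -> tuple[MotionClass, np.ndarray]:
        scores = self.predict_scores(features)[0]
        return self.classes_[int(scores.argmax())], scores

    def accuracy(self, features: np.ndarray, labels) -> float:
        pred = [c.value for c in self.predict(features)]
        truth = [MotionClass(c).value for c in labels]
        return float(np.mean(np.array(pred) == np.array(truth)))

    def save(self, prefix: str | Path) -> None:
        import joblib

        if self.pipeline is None:
            raise RuntimeError("model is not fitted")
        prefix = Path(prefix)
        joblib.dump(self.pipeline, prefix.with_suffix(".joblib"))
        manifest = {
            "kind": self.kind,
            "classes": [c.value for c in self.classes_],
            "c": self.c,
            "gamma": self.gamma,
            "dead_band": self.dead_band,
        }
        prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "SvmClassifier":
        import joblib

        prefix = Path(prefix)
        manifest = json.loads(prefix.with_suffix(".json").read_text())
        model = cls(c=manifest["c"], gamma=manifest["gamma"],
                    dead_band=manifest["dead_band"])
        model.classes_ = [MotionClass(c) for c in manifest["classes"]]
        model.pipeline = joblib.load(prefix.with_suffix(".joblib"))
        return model


def load_model(prefix: str | Path):
    """Load either decoder kind from its <prefix>.json manifest."""
    manifest = json.loads(Path(prefix).with_suffix(".json").read_text())
    return CnnClassifier.load(prefix) if manifest["kind"] == "cnn" \
        else SvmClassifier.load(prefix)


def build_cnn(spec: CnnSpec | None = None, seed: int = 0) -> nn.Sequential:
    """An untrained network for the given architecture (for inspection/tests)."""
    spec = spec or CnnSpec()
    return spec.build(np.random.default_rng(seed))


def train_cnn(data: LabeledWindowSet, tspec: TrainSpec | None = None,
              spec: CnnSpec | None = None, standardize: bool = False) -> CnnClassifier:
    model = CnnClassifier(spec=spec, tspec=tspec, standardize=standardize)
    return model.fit(data.windows, data.labels)


def train_svm(data: LabeledWindowSet | None = None, *, features: np.ndarray | None = None,
              labels=None, c: float = 1.0, gamma: float | None = None,
              dead_band: float = 0.0) -> SvmClassifier:
    """Fit the SVM from a window set (features computed here) or raw features."""
    if data is not None:
        features = extract_many(data.windows, data.fs, dead_band)
        labels = data.labels
    if features is None or labels is None:
        raise ValueError("need a window set or features + labels")
    model = SvmClassifier(c=c, gamma=gamma, dead_band=dead_band)
    return model.fit(np.asarray(features), labels)


def balanced_indices(labels, seed: int = 0) -> np.ndarray:
    """Indices of a class-balanced subsample (equal count per class).

    Evaluation sets from the training protocol are mildly imbalanced
    (the rest trial contributes more windows than each active trial);
    balancing makes chance level exactly 1/n_classes.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(MotionClass(lab).value, []).append(i)
    m = min(len(v) for v in by_class.values())
    idx = np.concatenate([rng.choice(v, m, replace=False)
                          for _, v in sorted(by_class.items())])
    return np.sort(idx)


@dataclass
class CvResult:
    fold_accuracies: list[float]
    mean: float
    sem: float


def cross_validate(data: LabeledWindowSet, method: str = "svm", k_folds: int = 4,
                   seed: int = 0, tspec: TrainSpec | None = None,
                   dead_band: float = 0.0) -> CvResult:
    """Window-level k-fold cross-validated accuracy.

    Fold assignment is stratified and seeded, so two methods evaluated
    with the same ``seed`` and ``k_folds`` see identical splits (the
    paired-comparison contract).
    """
    from sklearn.model_selection import StratifiedKFold

    y, _ = _encode_labels(data.labels)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    labels_list = [MotionClass(c) for c in data.labels]
    if method == "svm":
        X = extract_many(data.windows, data.fs, dead_band)
    elif method == "cnn":
        X = data.windows
    else:
        raise ValueError(f"unknown method {method!r}")
    accs = []
    for tr, te in skf.split(X, y):
        tr_labels = [labels_list[i] for i in tr]
        te_labels = [labels_list[i] for i in te]
        if method == "svm":
            model = SvmClassifier(dead_band=dead_band).fit(X[tr], tr_labels)
        else:
            model = CnnClassifier(tspec=tspec).fit(X[tr], tr_labels)
        accs.append(model.accuracy(X[te], te_labels))
    accs_arr = np.asarray(accs)
    sem = float(accs_arr.std(ddof=1) / np.sqrt(k_folds)) if k_folds > 1 else 0.0
    return CvResult(fold_accuracies=[float(a) for a in accs], mean=float(accs_arr.mean()),
                    sem=sem)
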