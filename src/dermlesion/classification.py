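"""Modified-AlexNet feature extraction with a random-forest head.

The extractor is a fixed 12-layer stack — seven 3x3 same-padding
convolutions (a 32-filter pair, a 64-filter pair, a 128-filter triple),
three 2x2 stride-2 max-poolings, and two fully connected layers — applied
to grayscale lesion patches of side 16, 32 or 48.  For a 32x32x1 input the
feature maps are 16x16x32, 8x8x64 and 4x4x128 after the three poolings, and
the flatten layer emits a 2048-element vector.

Training attaches a temporary softmax head over the benign/malignant task
(Adam / RMSprop / SGD selectable; published settings: learning rate 1e-4,
batch size 50, 200 epochs, 80/20 stratified split).  After training the
head is discarded and a random forest is fitted on activations from a
configurable tap (flatten, fc1 or fc2); the forest supplies class
probabilities and reduces overfitting relative to the softmax head alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import joblib
import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from . import nn
from .hair_removal import to_grayscale
from .metrics import BENIGN, MALIGNANT
from .nn import Tensor, max_pool2x2

VALID_SIDES = (16, 32, 48)
CONV_FILTERS = ((32, 32), (64, 64), (128, 128, 128))  # three conv groups


def conv2d_plain(U: np.ndarray, V: np.ndarray, padding: str = "valid") -> np.ndarray:
    """2-D correlation of a single-channel grid U with a p x q filter V.

    This is the feature-map operation the convolutional layers apply,
    exposed standalone: Z(x, y) = sum_p sum_q U(y+q, x+p) V(p, q).
    """
    U = np.asarray(U, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    if U.ndim != 2 or V.ndim != 2:
        raise ValueError("conv2d_plain expects 2-D input and filter")
    x = Tensor(U[None, :, :, None])
    w = Tensor(V[:, :, None, None])
    out = nn.conv2d(x, w, padding=padding)
    return out.data[0, :, :, 0].astype(np.float64)


def relu(z):
    """Rectified linear unit f(z) = max(0, z): zero for z <= 0, identity above."""
    return np.maximum(0, np.asarray(z))


@dataclass
class AlexNetRFSpec:
    """Configuration of the extractor + forest hybrid."""

    input_side: int = 32
    fc1: int = 256
    fc2: int = 64
    feature_tap: str = "fc1"  # flatten | fc1 | fc2
    rf_trees: int = 100
    rf_max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.input_side not in VALID_SIDES:
            raise ValueError(f"input_side must be one of {VALID_SIDES}")
        if self.input_side % 8:
            raise ValueError("input_side must be divisible by 8")
        if self.feature_tap not in ("flatten", "fc1", "fc2"):
            raise ValueError("feature_tap must be flatten, fc1 or fc2")

    @property
    def flatten_length(self) -> int:
        side = self.input_side // 8
        return side * side * CONV_FILTERS[-1][-1]

    def tap_length(self) -> int:
        return {"flatten": self.flatten_length, "fc1": self.fc1,
                "fc2": self.fc2}[self.feature_tap]


class AlexNetExtractor(nn.Module):
    """The 12-layer stack (7 conv / 3 pool / 2 FC) plus a detachable softmax head."""

    def __init__(self, spec: AlexNetRFSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.convs = []
        cin = 1
        for group in CONV_FILTERS:
            block = []
            for cout in group:
                block.append(nn.Conv2D(cin, cout, k=3, padding="same", rng=rng))
                cin = cout
            self.convs.append(block)
        self.fc1 = nn.Dense(spec.flatten_length, spec.fc1, rng=rng)
        self.fc2 = nn.Dense(spec.fc1, spec.fc2, rng=rng)
        self.head = nn.Dense(spec.fc2, 2, rng=rng)

    def layer_census(self) -> dict[str, int]:
        n_conv = sum(len(b) for b in self.convs)
        return {"conv": n_conv, "pool": len(self.convs), "fc": 2}

    def forward_taps(self, x: Tensor) -> dict[str, Tensor]:
        """Forward pass returning every tap; records per-stage shapes."""
        shapes = {"input": x.shape[1:]}
        for gi, block in enumerate(self.convs, start=1):
            for conv in block:
                x = conv(x).relu()
            x = max_pool2x2(x)
            shapes[f"pool{gi}"] = x.shape[1:]
        n = x.shape[0]
        flat = x.reshape(n, -1)
        shapes["flatten"] = flat.shape[1:]
        h1 = self.fc1(flat).relu()
        h2 = self.fc2(h1).relu()
        self.shapes_ = shapes
        return {"flatten": flat, "fc1": h1, "fc2": h2}

    def __call__(self, x: Tensor) -> Tensor:
        """Logits of the temporary softmax head."""
        return self.head(self.forward_taps(x)["fc2"])

    def features(self, x: Tensor, tap: str | None = None) -> np.ndarray:
        tap = tap or self.spec.feature_tap
        return self.forward_taps(x)[tap].data.copy()

    def shape_ledger(self) -> dict[str, tuple[int, ...]]:
        """Shapes after each pooling stage and the flatten, by introspection."""
        side = self.spec.input_side
        self.eval()
        self.forward_taps(Tensor(np.zeros((1, side, side, 1), dtype=np.float32)))
        return dict(self.shapes_)


def build_extractor(spec: AlexNetRFSpec | None = None,
                    seed: int = 0) -> AlexNetExtractor:
    return AlexNetExtractor(spec or AlexNetRFSpec(), seed=seed)


def split_dataset(labels, train_fraction: float = 0.8, seed: int = 0,
                  stratify: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation index split, stratified by label.

    Train size is ceil(train_fraction * n) overall; per-class sizes round to
    the nearest integer.  Falls back (with a warning) to a plain shuffle
    when a class has fewer than 2 members.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(np.ceil(train_fraction * n))
    classes, counts = np.unique(labels, return_counts=True)
    if stratify and counts.min() < 2:
        warnings.warn("a class has fewer than 2 members; splitting without "
                      "stratification", RuntimeWarning, stacklevel=2)
        stratify = False
    if not stratify:
        perm = rng.permutation(n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    train_idx: list[np.ndarray] = []
    taken = 0
    for i, cls in enumerate(classes):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        if i == len(classes) - 1:
            k = n_train - taken
        else:
            k = int(round(train_fraction * len(idx)))
        k = min(max(k, 1), len(idx) - 1)
        train_idx.append(idx[:k])
        taken += k
    tr = np.sort(np.concatenate(train_idx))
    va = np.sort(np.setdiff1d(np.arange(n), tr))
    return tr, va


def fit_random_forest(features, labels, n_trees: int = 100,
                      max_depth: int | None = None,
                      seed: int = 0) -> RandomForestClassifier:
    """Seeded random forest over extracted feature vectors."""
    features = np.asarray(features)
    labels = np.asarray(labels)
    if len(features) < 2:
        raise ValueError("need at least 2 samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set contains a single class")
    rf = RandomForestClassifier(n_estimators=n_trees, max_depth=max_depth,
                                random_state=seed)
    rf.fit(features, labels)
    return rf


def _prepare_patches(X, side: int) -> np.ndarray:
    """Grayscale [0, 1] patches of shape (n, side, side, 1)."""
    out = np.empty((len(X), side, side, 1), dtype=np.float32)
    for i, img in enumerate(X):
        img = np.asarray(img)
        if img.ndim == 3:
            img = to_grayscale(img)
        arr = img.astype(np.float32)
        if arr.max() > 1.0:
            arr = arr / 255.0
        if arr.shape != (side, side):
            arr = resize(arr, (side, side), order=1, preserve_range=True,
                         anti_aliasing=False).astype(np.float32)
        out[i] = arr[:, :, None]
    return out


class AlexNetRFClassifier(BaseEstimator, ClassifierMixin):
    """Benign/malignant classifier: modified-AlexNet features + random forest.

    ``fit`` expects grayscale lesion patches (RGB images are converted and
    resized to ``input_side``) with labels in {benign, malignant}.  The
    extractor trains under a temporary softmax head on the stratified
    training split; the forest is then fitted on tapped activations.
    Validation accuracy of both heads is exposed via ``val_accuracy_`` and
    ``softmax_val_accuracy_``.
    """

    def __init__(self, input_side=32, fc1=256, fc2=64, feature_tap="fc1",
                 rf_trees=100, rf_max_depth=None, optimizer="adam",
                 learning_rate=1e-4, batch_size=50, epochs=200,
                 train_fraction=0.8, seed=0):
        self.input_side = input_side
        self.fc1 = fc1
        self.fc2 = fc2
        self.feature_tap = feature_tap
        self.rf_trees = rf_trees
        self.rf_max_depth = rf_max_depth
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.train_fraction = train_fraction
        self.seed = seed

    def _spec(self) -> AlexNetRFSpec:
        return AlexNetRFSpec(input_side=self.input_side, fc1=self.fc1,
                             fc2=self.fc2, feature_tap=self.feature_tap,
                             rf_trees=self.rf_trees,
                             rf_max_depth=self.rf_max_depth)

    def _encode_labels(self, y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "iub":
            return y.astype(int)
        mapping = {BENIGN: 0, MALIGNANT: 1}
        try:
            return np.array([mapping[v] for v in y])
        except KeyError as e:
            raise ValueError(f"unknown label {e.args[0]!r}") from None

    def fit(self, X, y) -> "AlexNetRFClassifier":
        spec = self._spec()
        codes = self._encode_labels(y)
        if len(np.unique(codes)) < 2:
            raise ValueError("both classes must be present for training")
        patches = _prepare_patches(X, spec.input_side)
        rng = np.random.default_rng(self.seed)
        tr, va = split_dataset(codes, self.train_fraction,
                               seed=int(rng.integers(2 ** 31 - 1)))
        model = AlexNetExtractor(spec, seed=int(rng.integers(2 ** 31 - 1)))
        opt = nn.make_optimizer(self.optimizer, model.parameters(),
                                lr=self.learning_rate)
        history = []
        for _epoch in range(self.epochs):
            model.train()
            order = rng.permutation(len(tr))
            losses = []
            for s in range(0, len(order), self.batch_size):
                bi = tr[order[s:s + self.batch_size]]
                logits = model(Tensor(patches[bi]))
                loss = nn.softmax_cross_entropy(logits, codes[bi])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)))
        model.eval()

        feats_tr = self._batched_features(model, patches[tr])
        rf = fit_random_forest(feats_tr, codes[tr], n_trees=spec.rf_trees,
                               max_depth=spec.rf_max_depth,
                               seed=int(rng.integers(2 ** 31 - 1)))

        self.model_ = model
        self.forest_ = rf
        self.spec_ = spec
        self.classes_ = np.array([BENIGN, MALIGNANT])
        self.history_ = history
        self.train_idx_, self.val_idx_ = tr, va
        if len(va):
            feats_va = self._batched_features(model, patches[va])
            rf_pred = rf.predict(feats_va)
            self.val_accuracy_ = float(np.mean(rf_pred == codes[va]))
            logits = self._batched_logits(model, patches[va])
            self.softmax_val_accuracy_ = float(
                np.mean(logits.argmax(axis=1) == codes[va]))
            counts = np.bincount(codes[va], minlength=2)
            self.majority_baseline_ = float(counts.max() / counts.sum())
        return self

    @staticmethod
    def _batched_features(model, patches, chunk: int = 64) -> np.ndarray:
        return np.concatenate([
            model.features(Tensor(patches[i:i + chunk]))
            for i in range(0, len(patches), chunk)
        ])

    @staticmethod
    def _batched_logits(model, patches, chunk: int = 64) -> np.ndarray:
        return np.concatenate([
            model(Tensor(patches[i:i + chunk])).data
            for i in range(0, len(patches), chunk)
        ])

    def extract_features(self, X) -> np.ndarray:
        self._check_fitted()
        patches = _prepare_patches(X, self.spec_.input_side)
        return self._batched_features(self.model_, patches)

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        probs = self.forest_.predict_proba(self.extract_features(X))
        # forest classes are the integer codes 0/1 in sorted order
        return probs

    def predict(self, X) -> np.ndarray:
        codes = self.predict_proba(X).argmax(axis=1)
        return self.classes_[codes]

    def classify(self, image) -> tuple[str, float]:
        """Label and winning-class probability for a single patch/image."""
        proba = self.predict_proba([image])[0]
        code = int(proba.argmax())
        return str(self.classes_[code]), float(proba[code])

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")

    # -- serialization -------------------------------------------------------

    def save(self, path) -> None:
        self._check_fitted()
        joblib.dump({
            "params": self.get_params(),
            "arrays": self.model_.state_arrays(),
            "forest": self.forest_,
            "classes": self.classes_,
        }, path)

    @classmethod
    def load(cls, path) -> "AlexNetRFClassifier":
        blob = joblib.load(path)
        est = cls(**blob["params"])
        est.spec_ = est._spec()
        model = AlexNetExtractor(est.spec_)
        model.load_state_arrays(blob["arrays"])
        model.eval()
        est.model_ = model
        est.forest_ = blob["forest"]
        est.classes_ = blob["classes"]
        return est


# HAM10000-style diagnosis codes -> binary task labels (configurable mapping)
DIAGNOSIS_MAP = {
    "mel": MALIGNANT, "bcc": MALIGNANT, "akiec": MALIGNANT,
    "nv": BENIGN, "bkl": BENIGN, "df": BENIGN, "vasc": BENIGN,
    BENIGN: BENIGN, MALIGNANT: MALIGNANT,
}


def map_diagnosis(code: str, mapping: dict[str, str] | None = None) -> str:
    """Map a raw diagnosis code to the benign/malignant binary task."""
    mapping = mapping or DIAGNOSIS_MAP
    try:
        return mapping[code]
    except KeyError:
        raise ValueError(f"unknown diagnosis code {code!r}") from None
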