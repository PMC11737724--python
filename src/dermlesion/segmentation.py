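"""ResUNet++ lesion segmentation.

The network is an encoder-decoder with a residual stem, three encoder
stages, an atrous-spatial-pyramid-pooling (ASPP) bridge, three decoder
stages and a second ASPP before a 1x1-conv sigmoid head.  Residual units
compute y = F(x) + x; squeeze-and-excitation blocks gate encoder channels;
attention gates reweight encoder skips before decoder fusion; downsampling
uses stride-2 convolutions and upsampling nearest-neighbour resize.

A dense convolutional block (layer i consumes concat(x_{i-1},
Conv(x_{i-1}, k)) through a BN+ReLU composite) is provided as an optional
encoder replacement behind ``use_dense_blocks``.

:class:`ResUNetSegmenter` wraps construction, seeded training with a
BCE + soft-Dice objective, and thresholded mask prediction in a
scikit-learn style estimator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator

from . import nn
from .metrics import dice as dice_score
from .nn import Tensor, concat, max_pool2x2, upsample_nearest2x  # noqa: F401


@dataclass
class NetworkSpec:
    """Declarative description of the segmentation network."""

    input_shape: tuple[int, int, int] = (64, 64, 3)
    filters: tuple[int, ...] = (32, 64, 128, 256)  # stem + 3 encoder stages
    aspp_rates: tuple[int, ...] = (1, 2, 4)
    se_reduction: int = 8
    use_se: bool = True
    use_attention: bool = True
    use_dense_blocks: bool = False
    dense_layers: int = 2
    dense_growth: int = 16

    def __post_init__(self) -> None:
        n_down = len(self.filters) - 1
        h, w, _ = self.input_shape
        if h % (2 ** n_down) or w % (2 ** n_down):
            raise ValueError(
                f"input {h}x{w} not divisible by 2^{n_down} downsampling levels")
        if list(self.filters) != sorted(set(self.filters)):
            raise ValueError("encoder filter counts must be strictly increasing")
        if not self.aspp_rates:
            raise ValueError("aspp_rates must be non-empty")


class ConvBNRelu(nn.Module):
    def __init__(self, cin, cout, rng, k=3, stride=1, dilation=1):
        self.conv = nn.Conv2D(cin, cout, k=k, stride=stride, dilation=dilation,
                              bias=False, rng=rng)
        self.bn = nn.BatchNorm(cout)

    def __call__(self, x):
        return self.bn(self.conv(x)).relu()


class ResidualBlock(nn.Module):
    """Pre-activation residual unit y = F(x) + x (projected when shapes differ)."""

    def __init__(self, cin, cout, rng, stride=1):
        self.bn1 = nn.BatchNorm(cin)
        self.conv1 = nn.Conv2D(cin, cout, k=3, stride=stride, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm(cout)
        self.conv2 = nn.Conv2D(cout, cout, k=3, bias=True, rng=rng)
        self.identity_shortcut = cin == cout and stride == 1
        if not self.identity_shortcut:
            self.proj = nn.Conv2D(cin, cout, k=1, stride=stride, bias=True, rng=rng)

    def transform(self, x):
        h = self.conv1(self.bn1(x).relu())
        return self.conv2(self.bn2(h).relu())

    def __call__(self, x):
        skip = x if self.identity_shortcut else self.proj(x)
        return self.transform(x) + skip

    def zero_transform_(self) -> None:
        """Zero the final transform conv so F(x) = 0 exactly."""
        self.conv2.weight.data[:] = 0.0
        self.conv2.bias.data[:] = 0.0


class DenseBlock(nn.Module):
    """Dense convolutional block: x_i = H(concat(x_{i-1}, Conv(x_{i-1}, k)))."""

    def __init__(self, cin, n_layers, growth, rng):
        if n_layers < 1:
            raise ValueError("dense block needs at least one layer")
        self.convs = []
        self.bns = []
        c = cin
        for _ in range(n_layers):
            self.convs.append(nn.Conv2D(c, growth, k=3, bias=False, rng=rng))
            c += growth
            self.bns.append(nn.BatchNorm(c))
        self.out_channels = c

    def __call__(self, x):
        for conv, bn in zip(self.convs, self.bns):
            x = bn(concat([x, conv(x)], axis=-1)).relu()
        return x


class SqueezeExcite(nn.Module):
    """Channel gating from globally pooled statistics; gates in (0, 1)."""

    def __init__(self, channels, rng, reduction=8):
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Dense(channels, hidden, rng=rng)
        self.fc2 = nn.Dense(hidden, channels, rng=rng)
        self.channels = channels

    def gates(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(1, 2))  # (N, C)
        return self.fc2(self.fc1(pooled).relu()).sigmoid()

    def __call__(self, x):
        n = x.shape[0]
        return x * self.gates(x).reshape(n, 1, 1, self.channels)


class ASPP(nn.Module):
    """Parallel dilated 3x3 convolutions fused by a 1x1 convolution."""

    def __init__(self, cin, cout, rates, rng):
        if not rates:
            raise ValueError("aspp_rates must be non-empty")
        self.branches = [
            nn.Conv2D(cin, cout, k=3, dilation=r, bias=False, rng=rng)
            for r in rates
        ]
        self.fuse = nn.Conv2D(cout * len(rates), cout, k=1, bias=True, rng=rng)
        self.bn = nn.BatchNorm(cout)

    def __call__(self, x):
        feats = [b(x) for b in self.branches]
        return self.bn(self.fuse(concat(feats, axis=-1))).relu()


class AttentionGate(nn.Module):
    """Additive attention over an encoder skip, gated by the decoder signal."""

    def __init__(self, skip_ch, gate_ch, rng, inter_ch=None):
        inter = inter_ch or max(skip_ch // 2, 1)
        self.theta = nn.Conv2D(skip_ch, inter, k=1, bias=False, rng=rng)
        self.phi = nn.Conv2D(gate_ch, inter, k=1, bias=True, rng=rng)
        self.psi = nn.Conv2D(inter, 1, k=1, bias=True, rng=rng)

    def coefficients(self, skip: Tensor, gate: Tensor) -> Tensor:
        return self.psi((self.theta(skip) + self.phi(gate)).relu()).sigmoid()

    def __call__(self, skip, gate):
        return skip * self.coefficients(skip, gate)


class _EncoderStage(nn.Module):
    def __init__(self, cin, cout, spec: NetworkSpec, rng):
        self.se = SqueezeExcite(cin, rng, spec.se_reduction) if spec.use_se else None
        if spec.use_dense_blocks:
            self.dense = DenseBlock(cin, spec.dense_layers, spec.dense_growth, rng)
            self.down = nn.Conv2D(self.dense.out_channels, cout, k=3, stride=2,
                                  bias=True, rng=rng)
            self.res = None
        else:
            self.dense = None
            self.res = ResidualBlock(cin, cout, rng, stride=2)

    def __call__(self, x):
        if self.se is not None:
            x = self.se(x)
        if self.res is not None:
            return self.res(x)
        return self.down(self.dense(x))


class _DecoderStage(nn.Module):
    def __init__(self, in_ch, skip_ch, cout, spec: NetworkSpec, rng):
        self.attn = (AttentionGate(skip_ch, in_ch, rng)
                     if spec.use_attention else None)
        self.res = ResidualBlock(in_ch + skip_ch, cout, rng, stride=1)

    def __call__(self, x, skip):
        up = upsample_nearest2x(x)
        if self.attn is not None:
            skip = self.attn(skip, up)
        return self.res(concat([up, skip], axis=-1))


class ResUNetPP(nn.Module):
    """Stem + 3 encoders + ASPP bridge + 3 decoders + ASPP + sigmoid head."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        f0, f1, f2, f3 = spec.filters
        cin = spec.input_shape[2]
        self.spec = spec
        self.stem = ResidualBlock(cin, f0, rng, stride=1)
        self.enc1 = _EncoderStage(f0, f1, spec, rng)
        self.enc2 = _EncoderStage(f1, f2, spec, rng)
        self.enc3 = _EncoderStage(f2, f3, spec, rng)
        self.bridge = ASPP(f3, f3, spec.aspp_rates, rng)
        self.dec1 = _DecoderStage(f3, f2, f2, spec, rng)
        self.dec2 = _DecoderStage(f2, f1, f1, spec, rng)
        self.dec3 = _DecoderStage(f1, f0, f0, spec, rng)
        self.aspp_out = ASPP(f0, f0, spec.aspp_rates, rng)
        self.head = nn.Conv2D(f0, 1, k=1, bias=True, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        s0 = self.stem(x)
        s1 = self.enc1(s0)
        s2 = self.enc2(s1)
        b = self.bridge(self.enc3(s2))
        d = self.dec1(b, s2)
        d = self.dec2(d, s1)
        d = self.dec3(d, s0)
        out = self.head(self.aspp_out(d)).sigmoid()
        self.shapes_ = {"input": x.shape[1:], "bottleneck": b.shape[1:],
                        "output": out.shape[1:]}
        return out


def build_resunetpp(spec: NetworkSpec | None = None, seed: int = 0) -> ResUNetPP:
    """Construct the segmentation network from a declarative spec."""
    return ResUNetPP(spec or NetworkSpec(), seed=seed)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)


def _prepare_images(X, shape: tuple[int, int, int]) -> np.ndarray:
    """Stack images as float32 in [0, 1], bilinearly resized to the spec shape."""
    H, W, C = shape
    out = np.empty((len(X), H, W, C), dtype=np.float32)
    for i, img in enumerate(X):
        img = np.asarray(img)
        arr = img.astype(np.float32) / 255.0
        if arr.ndim == 2:
            arr = arr[:, :, None].repeat(C, axis=2)
        if arr.shape[:2] != (H, W):
            arr = resize(arr, (H, W), order=1, preserve_range=True,
                         anti_aliasing=False).astype(np.float32)
        out[i] = arr
    return out


def _prepare_masks(y, shape: tuple[int, int]) -> np.ndarray:
    H, W = shape
    out = np.empty((len(y), H, W, 1), dtype=np.float32)
    for i, m in enumerate(y):
        m = np.asarray(m).astype(np.float32)
        if m.shape != (H, W):
            m = resize(m, (H, W), order=0, preserve_range=True)
        out[i] = (m > 0.5)[:, :, None]
    return out


class ResUNetSegmenter(BaseEstimator):
    """ResUNet++ lesion segmenter with a scikit-learn fit/predict surface.

    Defaults mirror the published training settings (Adam, learning rate
    1e-4, batch size 50, 200 epochs); desk-scale runs override them.
    Training is a pure function of ``seed``: weight init, the train/val
    split and batch order all derive from it, and the weights with the best
    validation Dice are retained.
    """

    def __init__(self, input_shape=(64, 64, 3), filters=(32, 64, 128, 256),
                 aspp_rates=(1, 2, 4), use_se=True, use_attention=True,
                 use_dense_blocks=False, optimizer="adam", learning_rate=1e-4,
                 batch_size=50, epochs=200, threshold=0.5,
                 validation_fraction=0.2, seed=0):
        self.input_shape = input_shape
        self.filters = filters
        self.aspp_rates = aspp_rates
        self.use_se = use_se
        self.use_attention = use_attention
        self.use_dense_blocks = use_dense_blocks
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.threshold = threshold
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _spec(self) -> NetworkSpec:
        return NetworkSpec(
            input_shape=tuple(self.input_shape), filters=tuple(self.filters),
            aspp_rates=tuple(self.aspp_rates), use_se=self.use_se,
            use_attention=self.use_attention,
            use_dense_blocks=self.use_dense_blocks,
        )

    def fit(self, X, y) -> "ResUNetSegmenter":
        if len(X) == 0:
            raise ValueError("empty dataset")
        if len(X) != len(y):
            raise ValueError("images and masks differ in length")
        spec = self._spec()
        rng = np.random.default_rng(self.seed)
        model = ResUNetPP(spec, seed=int(rng.integers(2 ** 31 - 1)))
        imgs = _prepare_images(X, spec.input_shape)
        masks = _prepare_masks(y, spec.input_shape[:2])

        n = len(imgs)
        n_val = max(int(round(n * self.validation_fraction)), 1) if n > 1 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) == 0:
            tr_idx = perm
        opt = nn.make_optimizer(self.optimizer, model.parameters(),
                                lr=self.learning_rate)
        history = TrainHistory()
        best = (-1.0, None)
        for _epoch in range(self.epochs):
            model.train()
            order = rng.permutation(len(tr_idx))
            losses = []
            for start in range(0, len(order), self.batch_size):
                bi = tr_idx[order[start:start + self.batch_size]]
                pred = model(Tensor(imgs[bi]))
                loss = nn.bce_dice_loss(pred, masks[bi])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history.train_loss.append(float(np.mean(losses)))
            vd = self._val_dice(model, imgs, masks, val_idx if n_val else tr_idx)
            history.val_dice.append(vd)
            if vd > best[0]:
                best = (vd, [a.copy() for a in model.state_arrays()])
        if best[1] is not None:
            model.load_state_arrays(best[1])
        model.eval()
        self.model_ = model
        self.spec_ = spec
        self.history_ = history
        self.best_val_dice_ = best[0]
        return self

    def _val_dice(self, model, imgs, masks, idx) -> float:
        model.eval()
        scores = []
        for start in range(0, len(idx), 16):
            bi = idx[start:start + 16]
            prob = model(Tensor(imgs[bi])).data[:, :, :, 0]
            for p, m in zip(prob, masks[bi][:, :, :, 0]):
                scores.append(dice_score(m > 0.5, p >= self.threshold))
        return float(np.mean(scores))

    # -- inference -----------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        imgs = _prepare_images(X, self.spec_.input_shape)
        self.model_.eval()
        chunks = [
            self.model_(Tensor(imgs[i:i + 16])).data[:, :, :, 0]
            for i in range(0, len(imgs), 16)
        ]
        return np.concatenate(chunks, axis=0)

    def predict(self, X, threshold: float | None = None) -> np.ndarray:
        thr = self.threshold if threshold is None else threshold
        return self.predict_proba(X) >= thr

    def predict_mask(self, image, threshold: float | None = None) -> np.ndarray:
        """Binary lesion mask for one image, resized back to its native frame."""
        mask = self.predict([image], threshold=threshold)[0]
        target = np.asarray(image).shape[:2]
        if mask.shape != target:
            mask = resize(mask.astype(float), target, order=0,
                          preserve_range=True) > 0.5
        return mask

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("segmenter is not fitted")

    # -- serialization -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        self._check_fitted()
        arrays = {f"arr_{i}": a for i, a in enumerate(self.model_.state_arrays())}
        meta = {"params": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in self.get_params().items()}}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ResUNetSegmenter":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
        params = meta["params"]
        for key in ("input_shape", "filters", "aspp_rates"):
            params[key] = tuple(params[key])
        est = cls(**params)
        est.spec_ = est._spec()
        model = ResUNetPP(est.spec_)
        model.load_state_arrays(arrays)
        model.eval()
        est.model_ = model
        est.history_ = TrainHistory()
        return est


def train_segmenter(images, masks, **kwargs) -> ResUNetSegmenter:
    """Functional wrapper: fit a :class:`ResUNetSegmenter` on image/mask pairs."""
    return ResUNetSegmenter(**kwargs).fit(images, masks)


def predict_mask(segmenter: ResUNetSegmenter, image,
                 threshold: float | None = None) -> np.ndarray:
    return segmenter.predict_mask(image, threshold=threshold)
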