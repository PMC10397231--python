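"""Vessel segmentation: a DenseBlock-Unet plus pixel-classification metrics.

The network is a U-shaped encoder/decoder.  The contraction path captures
context: at each level a DenseBlock (two 3x3 convolutions, each preceded by
batch normalization and a rectified linear unit, with dense cross-layer
concatenation so every layer sees all previous outputs of the block) is
followed by 2x2 max pooling.  The symmetric expanding path upsamples with
2x2 transposed convolutions and concatenates the encoder skip connection at
each level before another DenseBlock.  A final 1x1 convolution produces a
single-channel probability map.

A non-learned vesselness fallback segmenter (ridge filtering + hysteresis
thresholding) is provided behind the same probability-map interface so the
geometric pipeline can run without any training.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats
from skimage import filters as _skfilters

from fvs3d import _nn


@dataclass
class SegmenterConfig:
    depth: int = 2
    base_channels: int = 8
    denseblock_convs: int = 2        # fixed by the architecture
    learning_rate: float = 1e-3
    epochs: int = 60
    batch_size: int = 8
    seed: int = 0
    patch_size: int = 32
    patches_per_epoch: int = 32
    threshold: float = 0.5

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.denseblock_convs != 2:
            raise ValueError("the DenseBlock used here has exactly 2 convolutions")


@dataclass
class SegMetrics:
    tp: int
    fn: int
    tn: int
    fp: int
    acc: float
    se: float
    sp: float
    auc: float
    auc_defined: bool = True


class _DenseBlock:
    """Two 3x3 convs with BN+ReLU pre-activations and dense concatenation.

    out = concat(x, h1, h2) where h1 = conv1(relu(bn1(x))),
    h2 = conv2(relu(bn2(concat(x, h1)))).  Output channels: c_in + 2*growth.
    """

    def __init__(self, c_in: int, growth: int, rng):
        self.bn1 = _nn.BatchNorm(c_in)
        self.relu1 = _nn.ReLU()
        self.conv1 = _nn.Conv3x3(c_in, growth, rng)
        self.bn2 = _nn.BatchNorm(c_in + growth)
        self.relu2 = _nn.ReLU()
        self.conv2 = _nn.Conv3x3(c_in + growth, growth, rng)
        self.c_in = c_in
        self.c_out = c_in + 2 * growth

    def params(self):
        return (self.bn1.params() + self.conv1.params()
                + self.bn2.params() + self.conv2.params())

    def layers(self):
        return [self.bn1, self.conv1, self.bn2, self.conv2]

    def forward(self, x):
        h1 = self.conv1.forward(self.relu1.forward(self.bn1.forward(x)))
        cat1 = np.concatenate([x, h1], axis=1)
        h2 = self.conv2.forward(self.relu2.forward(self.bn2.forward(cat1)))
        return np.concatenate([x, h1, h2], axis=1)

    def backward(self, dout):
        ci = self.c_in
        g = (self.c_out - ci) // 2
        dx = dout[:, :ci].copy()
        dh1 = dout[:, ci:ci + g].copy()
        dh2 = dout[:, ci + g:].copy()
        dcat1 = self.bn2.backward(self.relu2.backward(self.conv2.backward(dh2)))
        dx += dcat1[:, :ci]
        dh1 += dcat1[:, ci:]
        dx += self.bn1.backward(self.relu1.backward(self.conv1.backward(dh1)))
        return dx


class DenseBlockUnet:
    """Encoder-decoder with DenseBlocks; see module docstring."""

    def __init__(self, config: SegmenterConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, b = config.depth, config.base_channels
        self.enc: list[_DenseBlock] = []
        self.pools: list[_nn.MaxPool2] = []
        c = 1
        enc_out = []
        for i in range(d):
            blk = _DenseBlock(c, b * (2 ** i), rng)
            self.enc.append(blk)
            self.pools.append(_nn.MaxPool2())
            enc_out.append(blk.c_out)
            c = blk.c_out
        self.bottleneck = _DenseBlock(c, b * (2 ** d), rng)
        c = self.bottleneck.c_out
        self.ups: list[_nn.ConvT2x2] = []
        self.dec: list[_DenseBlock] = []
        for i in reversed(range(d)):
            up = _nn.ConvT2x2(c, enc_out[i], rng)
            self.ups.append(up)
            blk = _DenseBlock(2 * enc_out[i], b * (2 ** i), rng)
            self.dec.append(blk)
            c = blk.c_out
        self.head = _nn.Conv1x1(c, 1, rng, zero_init=True)

    # -- plumbing ----------------------------------------------------------
    def params(self):
        ps = []
        for blk in self.enc:
            ps += blk.params()
        ps += self.bottleneck.params()
        for up, blk in zip(self.ups, self.dec):
            ps += up.params() + blk.params()
        ps += self.head.params()
        return ps

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    def set_training(self, training: bool):
        for blk in self.enc + [self.bottleneck] + self.dec:
            blk.bn1.training = training
            blk.bn2.training = training

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 1, H, W) with H, W divisible by 2**depth; returns logits."""
        d = self.config.depth
        if x.shape[2] % (2 ** d) or x.shape[3] % (2 ** d):
            raise ValueError(
                f"input size {x.shape[2:]} not divisible by 2**depth={2**d}")
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x)
        self._skip_channels = [s.shape[1] for s in skips]
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray):
        d = self.head.backward(dlogits)
        skip_grads = [None] * len(self.enc)
        for idx in reversed(range(len(self.dec))):
            blk = self.dec[idx]
            up = self.ups[idx]
            d = blk.backward(d)
            enc_level = len(self.enc) - 1 - idx
            ch = self._skip_channels[enc_level]
            skip_grads[enc_level] = d[:, :ch]
            d = up.backward(d[:, ch:])
        d = self.bottleneck.backward(d)
        for i in reversed(range(len(self.enc))):
            d = self.pools[i].backward(d)
            d = d + skip_grads[i]
            d = self.enc[i].backward(d)
        return d

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        self.set_training(False)
        out = self.forward(x)
        self.set_training(True)
        return out

    def save(self, path: str):
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str) -> "DenseBlockUnet":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def build_denseblock_unet(config: SegmenterConfig | None = None) -> DenseBlockUnet:
    return DenseBlockUnet(config or SegmenterConfig())


def _normalize(gray: np.ndarray) -> np.ndarray:
    g = np.asarray(gray, dtype=float)
    rng_ = g.max() - g.min()
    return (g - g.min()) / rng_ if rng_ > 0 else np.zeros_like(g)


def _sample_patches(images, masks, n, size, rng):
    xs, ys = [], []
    for _ in range(n):
        k = rng.integers(len(images))
        img, msk = images[k], masks[k]
        H, W = img.shape
        r = rng.integers(0, H - size + 1)
        c = rng.integers(0, W - size + 1)
        xs.append(img[r:r + size, c:c + size])
        ys.append(msk[r:r + size, c:c + size])
    return (np.asarray(xs)[:, None, :, :].astype(float),
            np.asarray(ys)[:, None, :, :].astype(float))


def train_segmenter(model: DenseBlockUnet, dataset, config: SegmenterConfig
                    ) -> tuple[DenseBlockUnet, list[float]]:
    """Adam + binary cross-entropy on random patches; deterministic per seed.

    ``dataset`` is a sequence of (grayscale, binary mask) pairs.  Returns the
    trained model and the per-epoch mean loss.  Aborts on NaN loss.
    """
    if not dataset:
        raise ValueError("need at least one training pair")
    images = [_normalize(img) for img, _ in dataset]
    masks = [np.asarray(m).astype(float) for _, m in dataset]
    rng = np.random.default_rng(config.seed + 1)
    losses: list[float] = []
    step = 0
    model.set_training(True)
    for _epoch in range(config.epochs):
        epoch_losses = []
        for _ in range(max(config.patches_per_epoch // config.batch_size, 1)):
            x, y = _sample_patches(images, masks, config.batch_size,
                                   config.patch_size, rng)
            logits = model.forward(x)
            loss, dlogits = _nn.bce_with_logits(logits, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf loss at step {step}; lr={config.learning_rate}")
            model.backward(dlogits)
            step += 1
            _nn.adam_step(model.params(), config.learning_rate, step)
            epoch_losses.append(loss)
        losses.append(float(np.mean(epoch_losses)))
    return model, losses


def predict_prob_map(model: DenseBlockUnet, gray: np.ndarray) -> np.ndarray:
    """Full-image inference: pad to a multiple of 2**depth, crop back."""
    g = _normalize(gray)
    d = 2 ** model.config.depth
    H, W = g.shape
    ph, pw = (-H) % d, (-W) % d
    gp = np.pad(g, ((0, ph), (0, pw)), mode="reflect")
    logits = model.predict_logits(gp[None, None, :, :])[0, 0]
    return 1.0 / (1.0 + np.exp(-logits[:H, :W]))


def vesselness_segmenter(gray: np.ndarray,
                         sigmas=(1.0, 2.0, 3.0, 4.0)) -> np.ndarray:
    """Non-learned fallback: ridge (Sato) vesselness of the inverted image,
    normalized to [0, 1] as a probability map."""
    g = _normalize(gray)
    v = _skfilters.sato(1.0 - g, sigmas=sigmas, black_ridges=False)
    return _normalize(v)


def hysteresis_mask(prob: np.ndarray, low: float = 0.1, high: float = 0.3
                    ) -> np.ndarray:
    """Binary mask by hysteresis thresholding of a probability map."""
    return _skfilters.apply_hysteresis_threshold(prob, low, high)


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Threshold-free AUC via the rank statistic; ties counted half."""
    scores = np.asarray(scores, float).ravel()
    truth = np.asarray(truth).ravel().astype(bool)
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: ground truth contains a single class")
    ranks = _stats.rankdata(scores)
    return float((ranks[truth].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_segmentation(prob_map: np.ndarray, truth_mask: np.ndarray,
                          threshold: float = 0.5) -> SegMetrics:
    """Pixel counts at the threshold plus threshold-free AUC.

    If the truth is single-class the AUC is flagged undefined (NaN) while the
    count-based metrics are still reported.
    """
    prob = np.asarray(prob_map, dtype=float)
    truth = np.asarray(truth_mask).astype(bool)
    if prob.shape != truth.shape:
        raise ValueError("probability map and truth mask shapes differ")
    pred = prob >= threshold
    tp = int((pred & truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    fp = int((pred & ~truth).sum())
    acc = (tp + tn) / truth.size
    se = tp / (tp + fn) if (tp + fn) else float("nan")
    sp = tn / (tn + fp) if (tn + fp) else float("nan")
    try:
        auc = roc_auc(prob, truth)
        defined = True
    except ValueError:
        auc, defined = float("nan"), False
    return SegMetrics(tp, fn, tn, fp, acc, se, sp, auc, defined)


def leave_one_out_segmentation(pairs, config: SegmenterConfig
                               ) -> list[SegMetrics]:
    """With N images, each image is scored by a model never shown that image."""
    out = []
    for i in range(len(pairs)):
        train = [p for j, p in enumerate(pairs) if j != i]
        model = build_denseblock_unet(config)
        model, _ = train_segmenter(model, train, config)
        prob = predict_prob_map(model, pairs[i][0])
        out.append(evaluate_segmentation(prob, pairs[i][1], config.threshold))
    return out
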