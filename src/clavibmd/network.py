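"""Multi-task (segmentation + regression) and single-task BMD networks.

The backbone is a depth-4 U-Net: each encoder stage is ``convs_per_stage``
repetitions of (3x3 conv -> BN -> ReLU) followed by 2x2 max-pooling; a
bottleneck block at 1/16 resolution produces the feature maps ``A^k`` that
feed both the regression branch (global average pooling + one linear unit)
and, in multi-task mode, a decoder of 2x2 nearest up-sampling + conv blocks
with channel-concatenated skip connections and a 1x1 conv + sigmoid
segmentation head.  The single-task comparison model is the encoder +
regression branch alone; with the same seed it starts from bitwise-identical
encoder and regression-branch weights as the multi-task model, so the two
differ only in the decoder and loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
from skimage.transform import resize

from . import nn

MULTI_TASK = "multi_task"
SINGLE_TASK = "single_task"


@dataclass
class NetworkSpec:
    """Architecture hyperparameters.

    ``base_filters`` doubles at each of the 4 encoder stages
    (f, 2f, 4f, 8f) with a 16f bottleneck — the standard U-Net schedule.
    ``input_size`` must be divisible by 2**depth so pooling halves exactly.
    """

    depth: int = 4
    base_filters: int = 8
    convs_per_stage: int = 2
    input_size: int = 64
    mode: str = MULTI_TASK
    seed: int = 0
    bn_after_relu: bool = False  # True -> conv->ReLU->BN ordering

    def validate(self) -> None:
        if self.depth != 4:
            raise ValueError("depth must be 4 (four down-sampling stages)")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.convs_per_stage < 1:
            raise ValueError("convs_per_stage must be >= 1")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by {2 ** self.depth}")
        if self.mode not in (MULTI_TASK, SINGLE_TASK):
            raise ValueError(f"unknown mode {self.mode!r}")


class _ConvBlock:
    """(conv -> BN -> ReLU) x n, or conv -> ReLU -> BN when flipped."""

    def __init__(self, c_in, c_out, n_convs, rng, dtype, bn_after_relu):
        self.layers: list[nn.Layer] = []
        for i in range(n_convs):
            conv = nn.Conv2d(c_in if i == 0 else c_out, c_out, 3, rng, dtype)
            bn = nn.BatchNorm2d(c_out, dtype=dtype)
            relu = nn.ReLU()
            if bn_after_relu:
                self.layers += [conv, relu, bn]
            else:
                self.layers += [conv, bn, relu]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class NetworkHandle:
    """A built network: forward/backward, feature access, checkpointing.

    ``forward`` returns ``(seg, bmd)`` with ``seg`` of shape (N, H, W) in
    (0,1) for multi-task mode (``None`` for single-task) and ``bmd`` of
    shape (N,) in g/cm².
    """

    def __init__(self, spec: NetworkSpec, dtype=np.float32):
        spec.validate()
        self.spec = spec
        self.dtype = dtype
        f = spec.base_filters
        n = spec.convs_per_stage
        # shared (encoder + regression branch) weights come from one seeded
        # stream, decoder/segmentation-head weights from a second, so multi-
        # and single-task models with equal seeds share initializations
        rng_shared = np.random.default_rng([spec.seed, 0])
        rng_dec = np.random.default_rng([spec.seed, 1])

        widths = [f, 2 * f, 4 * f, 8 * f]
        self.enc = []
        c_prev = 1
        for c in widths:
            self.enc.append(_ConvBlock(c_prev, c, n, rng_shared, dtype,
                                       spec.bn_after_relu))
            c_prev = c
        self.pools = [nn.MaxPool2() for _ in widths]
        self.bottleneck = _ConvBlock(8 * f, 16 * f, n, rng_shared, dtype,
                                     spec.bn_after_relu)
        self.gap = nn.GlobalAvgPool()
        self.reg_dense = nn.Dense(16 * f, 1, rng_shared, dtype)

        self.dec = []
        self.ups = []
        if spec.mode == MULTI_TASK:
            c_up = 16 * f
            for c_skip in reversed(widths):
                self.ups.append(nn.Upsample2())
                self.dec.append(_ConvBlock(c_up + c_skip, c_skip, n, rng_dec,
                                           dtype, spec.bn_after_relu))
                c_up = c_skip
            self.seg_conv = nn.Conv2d(f, 1, 1, rng_dec, dtype)
            self.seg_sigmoid = nn.Sigmoid()

        self._A = None  # bottleneck activations from the last forward

    # ---- parameter bookkeeping -------------------------------------------

    def params(self) -> list[nn.Param]:
        ps = []
        for blk in self.enc:
            ps += blk.params()
        ps += self.bottleneck.params() + self.reg_dense.params()
        for blk in self.dec:
            ps += blk.params()
        if self.spec.mode == MULTI_TASK:
            ps += self.seg_conv.params()
        return ps

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def _bn_layers(self):
        blocks = self.enc + [self.bottleneck] + self.dec
        return [l for blk in blocks for l in blk.layers
                if isinstance(l, nn.BatchNorm2d)]

    def state(self) -> list[np.ndarray]:
        arrs = [p.value.copy() for p in self.params()]
        for bn in self._bn_layers():
            arrs += [bn.running_mean.copy(), bn.running_var.copy()]
        return arrs

    def load_state(self, arrs: list[np.ndarray]) -> None:
        ps = self.params()
        for p, a in zip(ps, arrs[:len(ps)]):
            p.value[...] = a
        rest = arrs[len(ps):]
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean[...] = rest[2 * i]
            bn.running_var[...] = rest[2 * i + 1]

    # ---- forward / backward ----------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != self.spec.input_size \
                or x.shape[2] != self.spec.input_size:
            raise ValueError(
                f"expected (N, {self.spec.input_size}, {self.spec.input_size}) "
                f"images, got {x.shape}")
        return x[:, None]  # NCHW

    def forward(self, images: np.ndarray, train: bool = False):
        x = self._check_input(images)
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        a = self.bottleneck.forward(h, train)
        self._A = a
        bmd = self.reg_dense.forward(self.gap.forward(a, train), train)[:, 0]
        if self.spec.mode == SINGLE_TASK:
            return None, bmd
        d = a
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            d = up.forward(d, train)
            d = blk.forward(np.concatenate([skip, d], axis=1), train)
        self._skip_channels = [s.shape[1] for s in skips]
        seg = self.seg_sigmoid.forward(self.seg_conv.forward(d, train), train)
        return seg[:, 0], bmd

    def backward(self, dseg: np.ndarray | None, dbmd: np.ndarray) -> None:
        """Accumulate parameter gradients from output-side loss gradients.

        ``dseg``: dL/d(sigmoid output), shape (N, H, W) or None.
        ``dbmd``: dL/d(BMD_pred), shape (N,).
        """
        dskips = [None] * len(self.enc)
        da = self.gap.backward(
            self.reg_dense.backward(np.asarray(dbmd, self.dtype)[:, None]))
        if self.spec.mode == MULTI_TASK and dseg is not None:
            dd = self.seg_conv.backward(
                self.seg_sigmoid.backward(np.asarray(dseg, self.dtype)[:, None]))
            # decoder stages were built bottleneck-first, i.e. dec[i] sits at
            # encoder stage (depth-1-i); walk them in reverse of forward order
            for i in range(len(self.dec) - 1, -1, -1):
                stage = len(self.enc) - 1 - i
                dcat = self.dec[i].backward(dd)
                c_skip = self._skip_channels[stage]
                dskips[stage] = dcat[:, :c_skip]
                dd = self.ups[i].backward(dcat[:, c_skip:])
            da = da + dd
        dh = self.bottleneck.backward(da)
        for blk, pool, dskip in zip(self.enc[::-1], self.pools[::-1],
                                    dskips[::-1]):
            dh = pool.backward(dh)
            if dskip is not None:
                dh = dh + dskip
            dh = blk.backward(dh)

    # ---- Grad-CAM hooks ---------------------------------------------------

    def encoder_features(self, image: np.ndarray) -> np.ndarray:
        """Feature maps A^k of the final encoder (bottleneck) convolution.

        Returns (K, U, V) for a single image, where U = V = input_size/16.
        """
        x = self._check_input(image)
        if x.shape[0] != 1:
            raise ValueError("encoder_features takes a single image")
        h = x
        for blk, pool in zip(self.enc, self.pools):
            h = pool.forward(blk.forward(h, False), False)
        return self.bottleneck.forward(h, False)[0]

    def regression_from_features(self, A: np.ndarray) -> float:
        """BMD prediction as a function of bottleneck features (K,U,V)."""
        y = self.reg_dense.forward(self.gap.forward(A[None], False), False)
        return float(y[0, 0])

    def feature_gradients(self, A: np.ndarray) -> np.ndarray:
        """Exact d BMD_pred / d A^k, backpropagated through the branch."""
        self.regression_from_features(A)  # populate caches
        dy = np.ones((1, 1), dtype=self.dtype)
        dA = self.gap.backward(self.reg_dense.backward(dy))
        return dA[0]

    # ---- checkpoint I/O ---------------------------------------------------

    def save(self, path) -> None:
        """Weights as .npz with a JSON architecture sidecar."""
        arrs = {f"arr_{i}": a for i, a in enumerate(self.state())}
        np.savez(path, **arrs)
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump(asdict(self.spec), fh, indent=1)

    @classmethod
    def load(cls, path, dtype=np.float32) -> "NetworkHandle":
        with open(str(path) + ".json") as fh:
            spec = NetworkSpec(**json.load(fh))
        handle = cls(spec, dtype)
        with np.load(str(path) if str(path).endswith(".npz")
                     else str(path) + ".npz") as data:
            handle.load_state([data[f"arr_{i}"] for i in range(len(data.files))])
        return handle


def build_network(spec: NetworkSpec, dtype=np.float32) -> NetworkHandle:
    spec.validate()
    return NetworkHandle(spec, dtype)


def encoder_features(handle: NetworkHandle, image: np.ndarray) -> np.ndarray:
    return handle.encoder_features(image)


def preprocess_radiograph(raw_image: np.ndarray, target: int = 256) -> np.ndarray:
    """Aspect-preserving resize to ``target`` x ``target`` with zero padding,
    then 12-bit normalization (divide by 4095, clip to [0, 1]).

    The longer side is scaled to ``target``; the shorter side is centred
    between symmetric zero bands.
    """
    raw = np.asarray(raw_image, dtype=np.float64)
    if raw.size == 0 or raw.ndim != 2:
        raise ValueError("raw image must be a non-empty 2-D array")
    if raw.min() < 0:
        raise ValueError("raw image intensities must be nonnegative")
    h, w = raw.shape
    scale = target / max(h, w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    scaled = resize(raw, (nh, nw), order=1, anti_aliasing=(scale < 1),
                    preserve_range=True)
    out = np.zeros((target, target), dtype=np.float64)
    top = (target - nh) // 2
    left = (target - nw) // 2
    out[top:top + nh, left:left + nw] = scaled
    return np.clip(out / 4095.0, 0.0, 1.0)


def parameter_count(spec: NetworkSpec) -> int:
    """Trainable-parameter count of a built network (convenience)."""
    return build_network(spec).n_params()
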