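"""Encoder-decoder segmentation network with dual output heads.

The network follows a U-Net-like layout: three encoder blocks (16, 32, 64
channels) joined by factor-2 max pooling, a 64-channel bottleneck, and three
decoder blocks reached through index-based unpooling and skip concatenation.
Every block is three iterations of leaky ReLU -> batch normalization ->
same-padded convolution, in that order. Two 1x1 heads decode the final
feature map: a 3-class softmax for {background, ipsilateral hippocampus,
contralateral hippocampus} and a sigmoid for the brain mask (skull stripping).

Index-based unpooling scatters each value back to the position its encoder
max came from, so the tensor being unpooled must have the same channel count
as the encoder tensor that was pooled. With the 16/32/64 encoder plan this
fixes the decoder widths at 32/16/16: each decoder block's convolutions step
down to the width of the next (shallower) pooling stage.

The 2D variant uses 3x3 kernels on coronal slices (for anisotropic
multi-slice data; the slice axis is the lowest-resolution axis), the 3D
variant 3x3x3 kernels on whole volumes.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import nn
from .errors import ShapeError
from .grids import LabelMap, VolumeGrid
from .nn import BatchNorm, Conv, LeakyReLU, max_pool, max_unpool, pool_backward, unpool_backward

ENCODER_CHANNELS = (16, 32, 64)
BOTTLENECK_CHANNELS = 64
DECODER_CHANNELS = (32, 16, 16)


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters."""

    dim: int = 3  # 2 or 3
    kernel: int = 3
    channels: tuple[int, ...] = ENCODER_CHANNELS + (BOTTLENECK_CHANNELS,)
    convs_per_block: int = 3
    leaky_slope: float = 0.01
    n_region_classes: int = 3
    brain_head: bool = True
    init_seed: int = 0
    dtype: str = "float32"
    eval_stats: str = "input"  # see nn.BatchNorm: "input" or "running"

    def validate(self):
        if self.dim not in (2, 3):
            raise ShapeError("dim must be 2 or 3")
        if self.kernel % 2 != 1:
            raise ShapeError("kernel size must be odd")
        if len(self.channels) != 4:
            raise ShapeError("channel plan must list three encoder blocks plus bottleneck")


@dataclasses.dataclass
class Prediction:
    """Per-voxel class probabilities for both tasks, on the input grid."""

    region_probs: np.ndarray  # (3, X, Y, Z) summing to 1 over axis 0
    brain_prob: np.ndarray  # (X, Y, Z) in [0, 1]


class _Block:
    """convs_per_block iterations of LeakyReLU -> BatchNorm -> Conv."""

    def __init__(self, cin, cout, dim, k, n, slope, rng, name, dtype, eval_stats):
        self.layers = []
        cur = cin
        for i in range(n):
            self.layers.append(LeakyReLU(slope))
            self.layers.append(BatchNorm(cur, name=f"{name}.bn{i}", dtype=dtype,
                                         eval_stats=eval_stats))
            self.layers.append(Conv(cur, cout, dim, k, rng=rng, name=f"{name}.conv{i}",
                                    dtype=dtype, slope=slope))
            cur = cout

    @property
    def params(self):
        return [p for lay in self.layers for p in lay.params]

    def forward(self, x, training=False):
        for lay in self.layers:
            x = lay.forward(x, training)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class Network:
    """The full dual-head encoder-decoder; operates on (N, 1, *spatial) arrays."""

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(cfg.init_seed)
        d, k, n, slope = cfg.dim, cfg.kernel, cfg.convs_per_block, cfg.leaky_slope
        c1, c2, c3, cb = cfg.channels
        dec3, dec2, dec1 = DECODER_CHANNELS
        mk = lambda cin, cout, name: _Block(cin, cout, d, k, n, slope, rng, name,
                                            dtype, cfg.eval_stats)
        self.enc1 = mk(1, c1, "enc1")
        self.enc2 = mk(c1, c2, "enc2")
        self.enc3 = mk(c2, c3, "enc3")
        self.bottleneck = mk(c3, cb, "bottleneck")
        self.dec3 = mk(cb + c3, dec3, "dec3")
        self.dec2 = mk(dec3 + c2, dec2, "dec2")
        self.dec1 = mk(dec2 + c1, dec1, "dec1")
        self.region_head = Conv(dec1, cfg.n_region_classes, d, 1, rng=rng,
                                name="region_head", dtype=dtype, slope=slope)
        self.brain_head = (
            Conv(dec1, 1, d, 1, rng=rng, name="brain_head", dtype=dtype, slope=slope)
            if cfg.brain_head
            else None
        )
        self._cache = None

    # -- parameter plumbing ------------------------------------------------
    @property
    def blocks(self):
        out = [self.enc1, self.enc2, self.enc3, self.bottleneck, self.dec3, self.dec2,
               self.dec1, self.region_head]
        if self.brain_head is not None:
            out.append(self.brain_head)
        return out

    @property
    def params(self) -> list[nn.Param]:
        return [p for b in self.blocks for p in b.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def state_copy(self):
        """Deep copy of weights and batch-norm running statistics."""
        state = {p.name: p.value.copy() for p in self.params}
        for b in self.blocks:
            for lay in getattr(b, "layers", []):
                if isinstance(lay, BatchNorm):
                    state[lay.gamma.name + ".running"] = (
                        lay.running_mean.copy(),
                        lay.running_var.copy(),
                    )
        return state

    def load_state(self, state):
        for p in self.params:
            p.value[...] = state[p.name]
        for b in self.blocks:
            for lay in getattr(b, "layers", []):
                if isinstance(lay, BatchNorm):
                    rm, rv = state[lay.gamma.name + ".running"]
                    lay.running_mean[...] = rm
                    lay.running_var[...] = rv

    # -- forward / backward ------------------------------------------------
    def _check_shape(self, x):
        sp = x.shape[2:]
        bad = {i: (8 - s % 8) % 8 for i, s in enumerate(sp) if s % 8}
        if bad:
            raise ShapeError(
                f"spatial shape {sp} must be divisible by 8 (three pooling steps); "
                f"required padding per axis: {bad}"
            )

    def forward(self, x: np.ndarray, training: bool = False):
        """Return (region_logits, brain_logits) in channel-first layout
        (C_out, N, *spatial), for a batch of 1-channel inputs (N, 1, *spatial).
        """
        self._check_shape(x)
        d = self.cfg.dim
        xi = np.ascontiguousarray(np.moveaxis(x, 1, 0))
        e1 = self.enc1.forward(xi, training)
        p1, i1 = max_pool(e1, d)
        e2 = self.enc2.forward(p1, training)
        p2, i2 = max_pool(e2, d)
        e3 = self.enc3.forward(p2, training)
        p3, i3 = max_pool(e3, d)
        b = self.bottleneck.forward(p3, training)
        u3 = max_unpool(b, i3, d)
        d3 = self.dec3.forward(np.concatenate([u3, e3], axis=0), training)
        u2 = max_unpool(d3, i2, d)
        d2 = self.dec2.forward(np.concatenate([u2, e2], axis=0), training)
        u1 = max_unpool(d2, i1, d)
        d1 = self.dec1.forward(np.concatenate([u1, e1], axis=0), training)
        region = self.region_head.forward(d1, training)
        brain = self.brain_head.forward(d1, training) if self.brain_head else None
        if training:
            self._cache = (i1, i2, i3, e1.shape[0], e2.shape[0], e3.shape[0])
        return region, brain

    def backward(self, dregion: np.ndarray, dbrain: np.ndarray | None):
        """Backpropagate channel-first gradients (C, N, *spatial)."""
        i1, i2, i3, c1, c2, c3 = self._cache
        d = self.cfg.dim
        dd1 = self.region_head.backward(dregion)
        if self.brain_head is not None and dbrain is not None:
            dd1 = dd1 + self.brain_head.backward(dbrain)
        dcat1 = self.dec1.backward(dd1)
        du1, de1_skip = dcat1[:-c1], dcat1[-c1:]
        dd2 = unpool_backward(du1, i1, d)
        dcat2 = self.dec2.backward(dd2)
        du2, de2_skip = dcat2[:-c2], dcat2[-c2:]
        dd3 = unpool_backward(du2, i2, d)
        dcat3 = self.dec3.backward(dd3)
        du3, de3_skip = dcat3[:-c3], dcat3[-c3:]
        db = unpool_backward(du3, i3, d)
        dp3 = self.bottleneck.backward(db)
        de3 = pool_backward(dp3, i3, d) + de3_skip
        dp2 = self.enc3.backward(de3)
        de2 = pool_backward(dp2, i2, d) + de2_skip
        dp1 = self.enc2.backward(de2)
        de1 = pool_backward(dp1, i1, d) + de1_skip
        dx = self.enc1.backward(de1)
        self._cache = None
        return dx

    # -- volume-level interface -------------------------------------------
    def _to_batch(self, v: VolumeGrid) -> tuple[np.ndarray, int | None]:
        data = np.asarray(v.data, dtype=self.cfg.dtype)
        if self.cfg.dim == 3:
            return data[None, None], None
        ax = v.slice_axis()
        batch = np.moveaxis(data, ax, 0)[:, None]  # (n_slices, 1, H, W)
        return batch, ax

    def predict(self, v: VolumeGrid) -> Prediction:
        """Probability maps for one volume (eval mode, deterministic)."""
        x, ax = self._to_batch(v)
        region, brain = self.forward(x, training=False)
        rp = nn.softmax(region, axis=0)  # (3, N, *sp)
        bp = nn.sigmoid(brain[0]) if brain is not None else np.ones(x.shape[0:1] + x.shape[2:])
        if self.cfg.dim == 3:
            return Prediction(region_probs=rp[:, 0], brain_prob=bp[0])
        # reassemble slices: batch axis back to the slice axis
        rp = np.moveaxis(rp, 1, ax + 1)  # (3, X, Y, Z)
        bp = np.moveaxis(bp, 0, ax)
        return Prediction(region_probs=np.ascontiguousarray(rp), brain_prob=np.ascontiguousarray(bp))


def build_network(cfg: ModelConfig) -> Network:
    """Instantiate the architecture described by ``cfg``."""
    return Network(cfg)


def count_parameters(net: Network) -> int:
    """Number of trainable scalars (conv weights/biases, batch-norm affine)."""
    return int(sum(p.size for p in net.params))


def decode_prediction(pred: Prediction, spacing, affine=None) -> LabelMap:
    """Hard labels: per-voxel argmax of region probabilities (ties resolve to
    the lowest class index) and brain probability thresholded at 0.5."""
    labels = np.argmax(pred.region_probs, axis=0).astype(np.uint8)
    brain = pred.brain_prob > 0.5
    return LabelMap(labels=labels, brain=brain, spacing=spacing, affine=affine)


def predict_labels(net: Network, v: VolumeGrid) -> LabelMap:
    """Segment one volume. Expects standardized input (zero mean, unit
    variance); warns otherwise but proceeds."""
    mean = float(np.mean(v.data))
    var = float(np.var(v.data))
    if abs(mean) > 0.1 or not (0.5 <= var <= 2.0):
        warnings.warn(
            f"input does not look standardized (mean {mean:.3f}, var {var:.3f})",
            stacklevel=2,
        )
    return decode_prediction(net.predict(v), v.spacing, v.affine)
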