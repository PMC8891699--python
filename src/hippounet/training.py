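"""Single-network optimization: RAdam, online scaling augmentation, early stop.

Training follows the protocol the tool is built around: rectified Adam
(lr 0.001, beta1 0.9, beta2 0.999, no weight decay), batch size one (one
volume per update; for the 2D variant the volume's slices form the internal
batch), up to 250 epochs with early stopping once the mean validation loss
has not improved for 10 consecutive epochs, and online augmentation that,
with probability 0.5, rescales image and labels about the volume center by a
factor drawn uniformly from [0.95, 1.05] (image: linear interpolation;
labels: nearest neighbor; no rotations). Each volume is standardized to zero
mean and unit variance after augmentation, at load time. Weights are
restored from the epoch with the best validation loss.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateInputError
from .grids import LabelMap, VolumeGrid, standardize
from .network import Network
from .objective import loss_and_logit_grads


@dataclasses.dataclass
class TrainConfig:
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.0
    max_epochs: int = 250
    patience: int = 10
    augment_prob: float = 0.5
    scale_range: tuple[float, float] = (0.95, 1.05)
    weights_from: str = "truth"
    seed: int = 0

    def validate(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0 <= self.augment_prob <= 1:
            raise ValueError("augment_prob must lie in [0, 1]")
        lo, hi = self.scale_range
        if not lo <= 1.0 <= hi:
            raise ValueError("scale_range must contain 1")


@dataclasses.dataclass
class TrainHistory:
    epochs: pd.DataFrame  # columns: epoch, train_loss, val_loss
    best_epoch: int
    best_val_loss: float
    stop_reason: str

    def to_csv(self, path):
        self.epochs.to_csv(path, index=False)


class RAdam:
    """Rectified Adam (per-parameter moment rectification).

    Falls back to an unadapted momentum update while the variance estimate is
    intractable (rectification term rho_t <= 4), then switches to the
    variance-rectified adaptive step.
    """

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, beta1, beta2, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - beta2) - 1.0

    def step(self):
        self.t += 1
        t = self.t
        b1t, b2t = self.b1**t, self.b2**t
        rho = self.rho_inf - 2.0 * t * b2t / (1.0 - b2t)
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            if self.wd:
                g = g + self.wd * p.value
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            mhat = m / (1.0 - b1t)
            if rho > 4.0:
                vhat = np.sqrt(v / (1.0 - b2t))
                r = np.sqrt(
                    ((rho - 4.0) * (rho - 2.0) * self.rho_inf)
                    / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho)
                )
                update = r * mhat / (vhat + self.eps)
            else:
                update = mhat
            p.value -= (self.lr * update).astype(p.value.dtype)


def _rescale(arr: np.ndarray, alpha: float, order: int) -> np.ndarray:
    """Scale by alpha about the volume center, keeping the grid shape.

    Growth crops at the borders, shrinkage zero-pads: both fall out of the
    center-fixed affine map (out-of-range samples take the zero fill value).
    """
    center = (np.array(arr.shape) - 1) / 2.0
    # output voxel -> input voxel: in = (out - c) / alpha + c
    matrix = np.full(arr.ndim, 1.0 / alpha)
    offset = center * (1.0 - 1.0 / alpha)
    return ndimage.affine_transform(
        arr if order == 0 else arr.astype(np.float32),
        matrix, offset=offset, order=order, mode="constant", cval=0,
        output_shape=arr.shape,
    )


def augment(v: VolumeGrid, l: LabelMap, rng: np.random.Generator, cfg: TrainConfig):
    """Online scaling augmentation; with probability 1 - augment_prob the
    exact identity. Never rotates."""
    if rng.random() >= cfg.augment_prob:
        return v, l
    alpha = float(rng.uniform(*cfg.scale_range))
    data = _rescale(np.asarray(v.data), alpha, order=1)
    labels = _rescale(np.asarray(l.labels), alpha, order=0)
    brain = _rescale(l.brain.astype(np.uint8), alpha, order=0)
    return (
        VolumeGrid(data=data, spacing=v.spacing, affine=v.affine),
        LabelMap(labels=labels, brain=brain, spacing=l.spacing, affine=l.affine),
    )


def _batch_pair(net: Network, v: VolumeGrid, l: LabelMap):
    """Arrange (volume, labels) as network batches.

    Returns x (N, 1, *sp) plus channel-first truth: onehot (L, N, *sp) and
    brain (N, *sp)."""
    x, ax = net._to_batch(v)
    onehot = l.one_hot()  # (L, X, Y, Z)
    brain = l.brain.astype(np.float32)
    if net.cfg.dim == 3:
        return x, onehot[:, None], brain[None]
    # slices along ax become the batch axis (second axis of channel-first truth)
    y = np.moveaxis(onehot, ax + 1, 1)  # (L, N, H, W)
    b = np.moveaxis(brain, ax, 0)
    return x, np.ascontiguousarray(y), np.ascontiguousarray(b)


def _epoch_loss(net: Network, samples, cfg: TrainConfig) -> float:
    """Mean total loss over samples in eval mode."""
    total = 0.0
    for s in samples:
        v = standardize(s["volume"])
        x, y, b = _batch_pair(net, v, s["labels"])
        region, brain = net.forward(x, training=False)
        lb, _, _ = loss_and_logit_grads(region, brain, y, b, cfg.weights_from)
        total += lb.total
    return total / len(samples)


def train_single(net: Network, train_set, val_set, cfg: TrainConfig):
    """Optimize one network; returns (net-with-best-weights, TrainHistory).

    ``train_set`` / ``val_set`` are sequences of {"volume": VolumeGrid,
    "labels": LabelMap} records (extra keys ignored).
    """
    cfg.validate()
    if len(train_set) == 0:
        raise DegenerateInputError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = RAdam(net.params, lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2,
                weight_decay=cfg.weight_decay)
    rows = []
    best_val = np.inf
    best_epoch = -1
    best_state = None
    stop_reason = "max_epochs"
    from .objective import _class_weights

    def step(x, y, b, weights):
        net.zero_grad()
        region, brain = net.forward(x, training=True)
        lb, dz_r, dz_b = loss_and_logit_grads(region, brain, y, b, cfg.weights_from,
                                              weights=weights)
        if not np.isfinite(lb.total):
            raise RuntimeError(f"non-finite loss: {lb}")
        net.backward(dz_r.astype(region.dtype),
                     None if dz_b is None else dz_b.astype(region.dtype))
        opt.step()
        return lb.total

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_set))
        epoch_train = 0.0
        n_steps = 0
        for i in order:
            s = train_set[i]
            v, l = augment(s["volume"], s["labels"], rng, cfg)
            v = standardize(v)
            x, y, b = _batch_pair(net, v, l)
            if net.cfg.dim == 3:
                epoch_train += step(x, y, b, None)
                n_steps += 1
            else:
                # batch size one = one coronal slice per update; the class
                # weights of the parent volume are shared by its slices so
                # the slice losses approximate the volume-level objective
                w_vol = None
                if cfg.weights_from == "truth":
                    w_vol = _class_weights(np.asarray(y, dtype=np.float64))
                for j in rng.permutation(x.shape[0]):
                    epoch_train += step(
                        x[j : j + 1], np.ascontiguousarray(y[:, j : j + 1]),
                        b[j : j + 1], w_vol,
                    )
                    n_steps += 1
        epoch_train /= n_steps
        val_loss = _epoch_loss(net, val_set, cfg) if len(val_set) else epoch_train
        rows.append({"epoch": epoch, "train_loss": epoch_train, "val_loss": val_loss})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            best_state = net.state_copy()
        elif epoch - best_epoch >= cfg.patience:
            stop_reason = "early_stop"
            break
    if best_state is not None:
        net.load_state(best_state)
    history = TrainHistory(
        epochs=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
        stop_reason=stop_reason,
    )
    return net, history
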