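"""Composite training loss: generalized Dice (regions) + Dice term (brain).

The total loss is ``L = L_HC + L_Brain``.

``L_HC`` is the generalized Dice loss over the three region classes,

    L_HC = 1 - 2 * (sum_l w_l sum_n y_ln p_ln) / (sum_l w_l sum_n (y_ln + p_ln)),

with per-class weights ``w_l = (sum_n y_ln)^-2`` computed from the ground
truth, which up-weights the small hippocampus classes against the large
background class. (A variant computing the weights from the prediction,
``weights_from="prediction"``, is also provided; see the methods note.) An
epsilon stabilizes both the weight and loss denominators so absent classes
cannot produce infinities. L_HC lies in [0, 1]: 0 at perfect overlap, 1 at
zero overlap.

``L_Brain`` is the skull-stripping Dice term in its raw form,

    L_Brain = - sum_n y_n p_n / sum_n (y_n + p_n),

whose minimum is -0.5 at perfect overlap (no factor 2 applied; the constant
scaling does not move the optimum). Hence L in [-0.5, 1].
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DegenerateInputError

EPS = 1e-5


@dataclasses.dataclass
class LossBreakdown:
    total: float
    region: float
    brain: float
    class_weights: np.ndarray


def _class_weights(ref: np.ndarray, eps: float = EPS) -> np.ndarray:
    """w_l = (sum_n ref_ln)^-2, stabilized; ref is (L, ...).

    Classes entirely absent from the reference get weight zero rather than
    the near-infinite 1/eps^2: an absent class carries no overlap
    information, and a huge weight on its denominator term otherwise drowns
    the present classes (ruinous when training on 2D slices that contain no
    hippocampus). The softmax coupling still suppresses false positives of
    absent classes through the present ones.
    """
    sums = ref.reshape(ref.shape[0], -1).sum(axis=1)
    w = 1.0 / (sums + eps) ** 2
    w[sums == 0] = 0.0
    return w


def generalized_dice_loss(
    region_probs: np.ndarray,
    truth_onehot: np.ndarray,
    weights_from: str = "truth",
    return_grad: bool = False,
    weights: np.ndarray | None = None,
):
    """Generalized Dice loss with size-based class weights.

    Parameters
    ----------
    region_probs : (L, ...) per-class probabilities.
    truth_onehot : (L, ...) one-hot ground truth.
    weights_from : "truth" (default; follows the generalized-Dice reference)
        or "prediction" (the literal printed weight formula).
    return_grad : also return d(loss)/d(region_probs), treating the weights
        as constants.
    weights : fixed per-class weights overriding ``weights_from`` (used when
        slice-wise updates share the weights of their parent volume).
    """
    p = np.asarray(region_probs, dtype=np.float64)
    y = np.asarray(truth_onehot, dtype=np.float64)
    if p.shape != y.shape:
        raise DegenerateInputError(f"shape mismatch {p.shape} vs {y.shape}")
    if y.sum() == 0:
        raise DegenerateInputError("empty ground truth")
    if weights is not None:
        w = np.asarray(weights, dtype=np.float64)
    elif weights_from == "truth":
        w = _class_weights(y)
    elif weights_from == "prediction":
        w = _class_weights(p)
    else:
        raise ValueError(f"weights_from must be 'truth' or 'prediction', got {weights_from!r}")
    L = p.shape[0]
    pf = p.reshape(L, -1)
    yf = y.reshape(L, -1)
    num = float((w * (yf * pf).sum(axis=1)).sum())
    # the denominator is strictly positive whenever the truth is nonempty;
    # EPS only guards the all-weights-zero corner
    den = max(float((w * (yf + pf).sum(axis=1)).sum()), EPS)
    loss = 1.0 - 2.0 * num / den
    if not return_grad:
        return loss, w
    # d loss / d p_ln = -2 (w_l y_ln den - num w_l) / den^2
    grad = (-2.0 * (w[:, None] * yf * den - num * w[:, None]) / den**2).reshape(p.shape)
    return loss, w, grad


def brain_dice_loss(brain_prob: np.ndarray, brain_truth: np.ndarray, return_grad: bool = False):
    """Skull-stripping Dice term, minimum -0.5 at perfect overlap."""
    p = np.asarray(brain_prob, dtype=np.float64)
    y = np.asarray(brain_truth, dtype=np.float64)
    if p.shape != y.shape:
        raise DegenerateInputError(f"shape mismatch {p.shape} vs {y.shape}")
    if y.sum() == 0:
        raise DegenerateInputError("empty brain mask")
    num = float((y * p).sum())
    den = float((y + p).sum()) + EPS
    loss = -num / den
    if not return_grad:
        return loss
    grad = -(y * den - num) / den**2
    return loss, grad


def total_loss(pred, truth, weights_from: str = "truth") -> LossBreakdown:
    """L = L_HC + L_Brain for a Prediction-like object and a LabelMap."""
    region, w = generalized_dice_loss(pred.region_probs, truth.one_hot(), weights_from)
    brain = brain_dice_loss(pred.brain_prob, truth.brain.astype(np.float64))
    return LossBreakdown(total=region + brain, region=region, brain=brain, class_weights=w)


def loss_and_logit_grads(region_logits, brain_logits, truth_onehot, brain_truth,
                         weights_from: str = "truth", weights=None):
    """Loss breakdown plus gradients with respect to the two logit maps.

    Channel-first layouts: region_logits (L, N, *sp); brain_logits
    (1, N, *sp) or None; truth_onehot (L, N, *sp); brain_truth (N, *sp).
    """
    from . import nn

    p = nn.softmax(np.asarray(region_logits, dtype=np.float64), axis=0)
    y = np.asarray(truth_onehot, dtype=np.float64)
    region, w, dp = generalized_dice_loss(p, y, weights_from, return_grad=True,
                                          weights=weights)
    dz_region = p * (dp - (dp * p).sum(axis=0, keepdims=True))
    bt = np.asarray(brain_truth, dtype=np.float64)
    if brain_logits is not None and bt.sum() > 0:
        bp = nn.sigmoid(np.asarray(brain_logits[0], dtype=np.float64))
        brain, dbp = brain_dice_loss(bp, bt, return_grad=True)
        dz_brain = (dbp * bp * (1.0 - bp))[None]
    elif brain_logits is not None:
        # the Dice term is undefined on an empty mask (e.g. a brainless edge
        # slice during 2D training); it contributes nothing
        brain, dz_brain = 0.0, np.zeros_like(np.asarray(brain_logits, dtype=np.float64))
    else:
        brain, dz_brain = 0.0, None
    lb = LossBreakdown(total=region + brain, region=region, brain=brain, class_weights=w)
    return lb, dz_region, dz_brain
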