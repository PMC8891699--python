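"""Optimizer, augmentation, and the training loop contracts."""
import math

import numpy as np
import pytest

from hippounet.errors import DegenerateInputError
from hippounet.grids import LabelMap, VolumeGrid
from hippounet.network import ModelConfig, build_network
from hippounet.nn import Param
from hippounet.phantom import PhantomSpec, generate_phantom
from hippounet.training import RAdam, TrainConfig, augment, train_single


def radam_reference_trace(theta0, grad_fn, lr, b1, b2, eps, steps):
    """Scalar rectified-Adam recurrence, written out step by step."""
    rho_inf = 2.0 / (1.0 - b2) - 1.0
    m = v = 0.0
    theta = theta0
    trace = []
    for t in range(1, steps + 1):
        g = grad_fn(theta)
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mhat = m / (1 - b1**t)
        rho = rho_inf - 2.0 * t * b2**t / (1 - b2**t)
        if rho > 4.0:
            vhat = math.sqrt(v / (1 - b2**t))
            r = math.sqrt(
                ((rho - 4) * (rho - 2) * rho_inf) / ((rho_inf - 4) * (rho_inf - 2) * rho)
            )
            theta -= lr * r * mhat / (vhat + eps)
        else:
            theta -= lr * mhat
        trace.append(theta)
    return trace


class TestRAdam:
    def test_quadratic_bowl_matches_reference_trace(self):
        # minimize f(x) = 0.5 * (x - 3)^2 from x0 = 0
        p = Param("x", np.array([0.0]))
        opt = RAdam([p], lr=0.1)
        got = []
        for _ in range(25):
            p.grad[...] = p.value - 3.0
            opt.step()
            got.append(float(p.value[0]))
        ref = radam_reference_trace(0.0, lambda x: x - 3.0, 0.1, 0.9, 0.999, 1e-8, 25)
        np.testing.assert_allclose(got, ref, rtol=1e-10)

    def test_warmup_steps_are_unadapted(self):
        # while rho <= 4 (first 4 steps at beta2=0.999) the update is plain
        # bias-corrected momentum: first step moves by exactly lr * grad-direction
        p = Param("x", np.array([10.0]))
        opt = RAdam([p], lr=0.5)
        p.grad[...] = 2.0
        opt.step()
        assert p.value[0] == pytest.approx(10.0 - 0.5 * 2.0)

    def test_converges_on_quadratic(self):
        p = Param("x", np.array([0.0]))
        opt = RAdam([p], lr=0.1)
        for _ in range(300):
            p.grad[...] = p.value - 3.0
            opt.step()
        assert p.value[0] == pytest.approx(3.0, abs=1e-3)


def _toy_pair(seed=0, shape=(16, 16, 8)):
    vol, lab = generate_phantom(PhantomSpec(seed=seed))
    return vol, lab


class TestAugment:
    def _cfg(self, prob):
        return TrainConfig(augment_prob=prob)

    def test_no_augment_branch_is_identity(self, sham_phantom):
        vol, lab = sham_phantom
        v2, l2 = augment(vol, lab, np.random.default_rng(0), self._cfg(0.0))
        np.testing.assert_array_equal(v2.data, vol.data)
        np.testing.assert_array_equal(l2.labels, lab.labels)

    def test_unit_scale_is_identity_within_interpolation(self, sham_phantom):
        vol, lab = sham_phantom
        cfg = TrainConfig(augment_prob=1.0, scale_range=(1.0, 1.0))
        v2, l2 = augment(vol, lab, np.random.default_rng(0), cfg)
        np.testing.assert_allclose(v2.data, vol.data, atol=1e-4)
        np.testing.assert_array_equal(l2.labels, lab.labels)

    def test_grow_scales_mask_volume(self):
        # centered cube mask grows by ~alpha^3 voxels under alpha = 1.05
        data = np.zeros((40, 40, 40), dtype=np.float32)
        lab = np.zeros((40, 40, 40), dtype=np.uint8)
        lab[10:30, 10:30, 10:30] = 1
        vol = VolumeGrid(data=data, spacing=(0.2,) * 3)
        lmap = LabelMap(labels=lab, brain=lab > 0, spacing=(0.2,) * 3)
        cfg = TrainConfig(augment_prob=1.0, scale_range=(1.05, 1.05))
        _, l2 = augment(vol, lmap, np.random.default_rng(0), cfg)
        ratio = (l2.labels == 1).sum() / (lab == 1).sum()
        assert ratio == pytest.approx(1.05**3, rel=0.10)

    def test_shrink_keeps_shape_and_pads(self, sham_phantom):
        vol, lab = sham_phantom
        cfg = TrainConfig(augment_prob=1.0, scale_range=(0.95, 0.95))
        v2, l2 = augment(vol, lab, np.random.default_rng(0), cfg)
        assert v2.data.shape == vol.data.shape
        assert l2.labels.shape == lab.labels.shape


def _records(n, shape=(16, 16, 8), start_seed=0):
    out = []
    for i in range(n):
        spec = PhantomSpec(shape=shape, seed=start_seed + i)
        vol, lab = generate_phantom(spec)
        out.append({"animal": i, "volume": vol, "labels": lab})
    return out


class TestTrainSingle:
    def test_smoke_contract(self):
        data = _records(3)
        net = build_network(ModelConfig(dim=2, init_seed=0))
        cfg = TrainConfig(max_epochs=3, patience=10, seed=0)
        net, hist = train_single(net, data[:2], data[2:], cfg)
        assert len(hist.epochs) <= 3
        assert np.isfinite(hist.epochs["train_loss"]).all()
        assert np.isfinite(hist.epochs["val_loss"]).all()
        assert hist.best_epoch >= 1
        assert hist.stop_reason in ("max_epochs", "early_stop")

    def test_loss_decreases_on_repeated_sample(self):
        data = _records(1)
        net = build_network(ModelConfig(dim=2, init_seed=0))
        cfg = TrainConfig(max_epochs=8, patience=20, seed=0, augment_prob=0.0)
        net, hist = train_single(net, data, data, cfg)
        losses = hist.epochs["train_loss"].to_numpy()
        assert losses[-1] < losses[0]

    def test_reproducible_history(self):
        data = _records(2)
        cfg = TrainConfig(max_epochs=2, patience=10, seed=7)
        _, h1 = train_single(build_network(ModelConfig(dim=2, init_seed=1)),
                             data[:1], data[1:], cfg)
        _, h2 = train_single(build_network(ModelConfig(dim=2, init_seed=1)),
                             data[:1], data[1:], cfg)
        np.testing.assert_array_equal(h1.epochs.to_numpy(), h2.epochs.to_numpy())

    def test_early_stop_rule(self, monkeypatch):
        # constant validation loss with patience 1 stops after epoch 2
        import hippounet.training as tr

        data = _records(2)
        monkeypatch.setattr(tr, "_epoch_loss", lambda *a, **k: 0.5)
        net = build_network(ModelConfig(dim=2, init_seed=0))
        cfg = TrainConfig(max_epochs=50, patience=1, seed=0)
        net, hist = train_single(net, data[:1], data[1:], cfg)
        assert len(hist.epochs) == 2
        assert hist.stop_reason == "early_stop"
        assert len(hist.epochs) - hist.best_epoch <= cfg.patience

    def test_empty_train_set_rejected(self):
        net = build_network(ModelConfig(dim=2))
        with pytest.raises(DegenerateInputError):
            train_single(net, [], _records(1), TrainConfig())
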