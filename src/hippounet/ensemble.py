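"""Animal-level cross-validation, six-network ensembling, majority-vote label
fusion, and the registration-experiment planner.

The evaluation design is nested k-fold cross-validation *by animal*: the
outer split holds out test animals; the remaining animals are randomly
re-partitioned into k nested folds, and one network is trained per nested
fold (validating on it, training on the rest), yielding a k-member ensemble
whose per-voxel majority vote labels the outer test fold. Keeping every scan
of an animal inside a single fold prevents leakage across timepoints.

The registration planner enumerates the atlas-to-target pairs a
registration-based baseline would need: within each timepoint, every
annotated available target is paired with every annotated available atlas
outside the target's fold.
"""
from __future__ import annotations

import dataclasses
import json

import numpy as np

from .errors import ShapeError, SpecError
from .grids import LabelMap
from .network import ModelConfig, Network, build_network
from .training import TrainConfig, TrainHistory, train_single


@dataclasses.dataclass
class FoldPlan:
    outer: list[list[int]]  # animal ids per outer fold
    seed: int

    def to_json(self, path):
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2)


def make_folds(animal_ids, k: int, fold_size: int | None = None, seed: int = 0) -> list[list[int]]:
    """Random animal-level partition into k folds.

    With ``fold_size`` given, requires ``len(animal_ids) == k * fold_size``;
    with ``fold_size=None`` the partition is as even as possible (sizes
    differing by at most one), which nested splits need when the training
    pool is not divisible by k.
    """
    ids = list(animal_ids)
    if fold_size is not None and len(ids) != k * fold_size:
        raise SpecError(f"{len(ids)} animals cannot form {k} folds of {fold_size}")
    if len(ids) < k:
        raise SpecError(f"cannot split {len(ids)} animals into {k} folds")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    sizes = [len(ids) // k + (1 if i < len(ids) % k else 0) for i in range(k)]
    folds, start = [], 0
    for s in sizes:
        folds.append(sorted(perm[start : start + s]))
        start += s
    return folds


def fuse_majority(label_maps, probs=None) -> LabelMap:
    """Per-voxel modal label over candidate segmentations.

    Ties are broken by the mean class probability when per-map probabilities
    are supplied, otherwise by the lowest class index. The brain mask is
    fused the same way (per-voxel majority of the binary masks; exact ties
    count as brain, i.e. half the votes suffice, matching a 0.5 threshold on
    the vote fraction).
    """
    maps = list(label_maps)
    if not maps:
        raise SpecError("need at least one label map to fuse")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ShapeError("label maps disagree in shape")
    stack = np.stack([m.labels for m in maps])  # (M, X, Y, Z)
    n_classes = max(int(stack.max()) + 1, 3)
    counts = np.zeros((n_classes,) + shape, dtype=np.int32)
    for c in range(n_classes):
        counts[c] = (stack == c).sum(axis=0)
    if probs is not None:
        mean_probs = np.mean([np.asarray(p) for p in probs], axis=0)  # (L, X, Y, Z)
        if mean_probs.shape != counts.shape:
            raise ShapeError("probability maps disagree with label maps in shape")
        # probabilities are < 1 per class, so they only ever break exact count ties
        score = counts + np.clip(mean_probs, 0.0, 1.0) * (1.0 - 1e-9)
    else:
        score = counts
    fused = np.argmax(score, axis=0).astype(np.uint8)
    brain_votes = np.stack([m.brain for m in maps]).sum(axis=0)
    brain = brain_votes * 2 >= len(maps)
    first = maps[0]
    return LabelMap(labels=fused, brain=brain, spacing=first.spacing, affine=first.affine)


@dataclasses.dataclass
class Ensemble:
    members: list[Network]
    histories: list[TrainHistory]
    train_manifests: list[list[int]]  # animal ids each member trained on

    def predict_fused(self, volume, postprocess_fn=None) -> LabelMap:
        from .network import decode_prediction

        preds = [m.predict(volume) for m in self.members]
        maps = [decode_prediction(p, volume.spacing, volume.affine) for p in preds]
        fused = fuse_majority(maps, probs=[p.region_probs for p in preds])
        if postprocess_fn is not None:
            fused = postprocess_fn(fused)
        return fused


def train_ensemble(dataset, test_animals, model_cfg: ModelConfig, train_cfg: TrainConfig,
                   k: int = 6, seed: int = 0) -> Ensemble:
    """Train the k-member ensemble for one outer fold.

    ``dataset`` is a sequence of records {"animal": id, "volume": VolumeGrid,
    "labels": LabelMap, ...}; every record of a test animal is excluded from
    all training and validation sets.
    """
    test_animals = set(test_animals)
    pool = sorted({r["animal"] for r in dataset} - test_animals)
    if len(pool) < k:
        raise SpecError(f"training pool of {len(pool)} animals cannot form {k} nested folds")
    nested = make_folds(pool, k, fold_size=None, seed=seed)
    members, histories, manifests = [], [], []
    for i, val_animals in enumerate(nested):
        val_set = [r for r in dataset if r["animal"] in val_animals]
        train_animals = [a for a in pool if a not in val_animals]
        train_set = [r for r in dataset if r["animal"] in train_animals]
        cfg_i = dataclasses.replace(model_cfg, init_seed=int(np.random.default_rng([seed, i]).integers(0, 2**31 - 1)))
        net = build_network(cfg_i)
        tcfg_i = dataclasses.replace(train_cfg, seed=int(np.random.default_rng([seed, i, 1]).integers(0, 2**31 - 1)))
        net, hist = train_single(net, train_set, val_set, tcfg_i)
        members.append(net)
        histories.append(hist)
        manifests.append(train_animals)
    return Ensemble(members=members, histories=histories, train_manifests=manifests)


@dataclasses.dataclass
class CohortPlan:
    """Fold and annotation structure of a cohort, for the registration planner."""

    folds: list[list[int]]  # animal ids per fold
    timepoints: tuple[int, ...]
    missing: tuple[tuple[int, int], ...] = ()  # (animal, timepoint) without labels

    def validate(self):
        seen = [a for f in self.folds for a in f]
        if len(seen) != len(set(seen)):
            raise SpecError("an animal appears in more than one fold")
        for a, t in self.missing:
            if a not in seen:
                raise SpecError(f"missing entry names unknown animal {a}")
            if t not in self.timepoints:
                raise SpecError(f"missing entry names unknown timepoint {t}")


def plan_registrations(plan: CohortPlan):
    """Enumerate within-timepoint atlas-to-target registrations.

    For each timepoint, each annotated available target is paired with every
    annotated available atlas outside the target's entire fold. Returns
    (pairs, count) with pairs as (atlas_animal, target_animal, timepoint).
    """
    plan.validate()
    missing = set(plan.missing)
    fold_of = {a: i for i, f in enumerate(plan.folds) for a in f}
    animals = sorted(fold_of)
    pairs = []
    for t in plan.timepoints:
        present = [a for a in animals if (a, t) not in missing]
        for target in present:
            for atlas in present:
                if fold_of[atlas] != fold_of[target]:
                    pairs.append((atlas, target, t))
    return pairs, len(pairs)
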