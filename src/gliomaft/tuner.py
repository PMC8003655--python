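"""Training and selective-block fine-tuning.

Five freezing strategies control which named blocks stay learnable when
adapting a trained segmentation model to a new facility:

* ``fine_all``   - every block learnable
* ``down_only``  - encoder (down) blocks only
* ``up_only``    - decoder (up) blocks only
* ``down1_up1``  - one down block + one up block
* ``down2_up2``  - two down blocks + two up blocks (the recommended
  protocol: it recovers most of the lost accuracy from <= 20 target
  cases while updating far fewer parameters than full fine-tuning)

Because up blocks are *named* deepest-first ("1st up" is the deepest),
"up1"/"up2" in a strategy name is ambiguous. ``up_convention`` resolves
it: ``"shallow"`` (default) picks the shallowest up blocks — low-level
image differences between scanners live in shallow layers, so these are
the ones worth adapting — while ``"literal"`` picks the blocks literally
named "1st up"/"2nd up" (the deepest).

Defaults: base training uses RMSprop at lr 5e-4 with a best-validation-
Dice checkpoint; fine-tuning uses AdaGrad at lr 5e-3 for a fixed 20
epochs with no validation split. The training loss is soft Dice with
additive smoothing eps = 1.0, matching the evaluation metric.
"""
from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

from . import engine as eg
from .blocknet import BlockRegistry, SegNet3d, ordinal

__all__ = [
    "FreezeStrategy",
    "TrainSpec",
    "BASE_TRAIN_SPEC",
    "FINE_TUNE_SPEC",
    "STRATEGY_NAMES",
    "apply_freeze",
    "train_base",
    "fine_tune",
    "soft_dice_loss",
    "soft_dice_loss_grad",
    "sample_finetune_cases",
]

STRATEGY_NAMES = ("fine_all", "down_only", "up_only", "down1_up1", "down2_up2")

DICE_EPS = 1.0


@dataclass(frozen=True)
class FreezeStrategy:
    """A named selective-learnability strategy."""

    name: str
    up_convention: str = "shallow"

    def __post_init__(self):
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}; choose from {STRATEGY_NAMES}")
        if self.up_convention not in ("shallow", "literal"):
            raise ValueError("up_convention must be 'shallow' or 'literal'")

    def _up_names(self, depth: int, k: int) -> set[str]:
        if self.up_convention == "literal":
            idx = range(1, k + 1)
        else:  # shallowest k up blocks; the shallowest is named "<depth>th up"
            idx = range(depth, depth - k, -1)
        return {f"{ordinal(i)} up" for i in idx}

    def learnable_blocks(self, depth: int) -> set[str]:
        downs = {f"{ordinal(i)} down" for i in range(1, depth + 1)}
        ups = {f"{ordinal(i)} up" for i in range(1, depth + 1)}
        if self.name == "fine_all":
            return downs | ups
        if self.name == "down_only":
            return downs
        if self.name == "up_only":
            return ups
        k = 1 if self.name == "down1_up1" else 2
        if depth < k:
            raise ValueError(f"strategy {self.name} needs depth >= {k}")
        return {f"{ordinal(i)} down" for i in range(1, k + 1)} | self._up_names(depth, k)


@dataclass(frozen=True)
class TrainSpec:
    """Optimization protocol for one training run."""

    optimizer_name: str = "rmsprop"
    learning_rate: float = 5e-4
    epochs: int = 20
    batch_size: int = 1
    loss_name: str = "soft_dice"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss_name != "soft_dice":
            raise ValueError("only the soft_dice loss is implemented")


BASE_TRAIN_SPEC = TrainSpec(optimizer_name="rmsprop", learning_rate=5e-4, epochs=20)
FINE_TUNE_SPEC = TrainSpec(optimizer_name="adagrad", learning_rate=5e-3, epochs=20)


def soft_dice_loss(prob: np.ndarray, truth: np.ndarray) -> float:
    """1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps), eps = 1.0."""
    prob = np.asarray(prob)
    truth = np.asarray(truth)
    if prob.shape != truth.shape:
        raise ValueError(f"shape mismatch: {prob.shape} vs {truth.shape}")
    inter = float((prob * truth).sum(dtype=np.float64))
    denom = float(prob.sum(dtype=np.float64) + truth.sum(dtype=np.float64)) + DICE_EPS
    return 1.0 - (2.0 * inter + DICE_EPS) / denom


def soft_dice_loss_grad(prob: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """dLoss/dprob of :func:`soft_dice_loss` (same shape as ``prob``)."""
    prob = np.asarray(prob, dtype=np.float32)
    truth = np.asarray(truth, dtype=np.float32)
    inter = (prob * truth).sum(dtype=np.float64)
    denom = prob.sum(dtype=np.float64) + truth.sum(dtype=np.float64) + DICE_EPS
    num = 2.0 * inter + DICE_EPS
    grad = truth * np.float32(-2.0 / denom)
    grad += np.float32(num / denom**2)
    return grad


def apply_freeze(model: SegNet3d, registry: BlockRegistry, strategy: FreezeStrategy):
    """Set per-parameter trainability; returns (n_trainable, n_frozen)."""
    depth = model.config.depth
    learnable = strategy.learnable_blocks(depth)
    unknown = learnable - set(registry.blocks)
    if unknown:
        raise ValueError(f"strategy references blocks absent from the registry: {unknown}")
    learnable_params = set()
    for b in learnable:
        learnable_params.update(registry.param_names(b))
    n_train = n_frozen = 0
    for name, p in model.param_dict().items():
        p.trainable = name in learnable_params
        if p.trainable:
            n_train += p.size
        else:
            n_frozen += p.size
    return n_train, n_frozen


def _hard_dice(prob: np.ndarray, truth: np.ndarray, threshold: float = 0.5) -> float:
    pred = prob >= threshold
    t = truth > 0
    denom = pred.sum() + t.sum()
    if denom == 0:
        return float("nan")
    return 2.0 * float(np.logical_and(pred, t).sum()) / float(denom)


def _run_epochs(model, cases, val_cases, spec, keep_best, log):
    """Shared epoch loop. ``cases``/``val_cases``: lists of (x, y) float32/binary arrays."""
    ss = np.random.SeedSequence([int(spec.seed), 5821])
    order_rng, dropout_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    opt = eg.make_optimizer(spec.optimizer_name, model.params(), spec.learning_rate)
    history = []
    best = (-np.inf, None)
    for epoch in range(1, spec.epochs + 1):
        idx = order_rng.permutation(len(cases))
        losses = []
        for start in range(0, len(idx), spec.batch_size):
            opt.zero_grad()
            for i in idx[start:start + spec.batch_size]:
                x, y = cases[i]
                prob = model.forward_train(x, dropout_rng)
                losses.append(soft_dice_loss(prob, y))
                model.backward(soft_dice_loss_grad(prob, y))
            opt.step()
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_cases:
            vloss, vdice = [], []
            for x, y in val_cases:
                prob = model.forward(x)
                vloss.append(soft_dice_loss(prob, y))
                vdice.append(_hard_dice(prob, y))
            entry["val_loss"] = float(np.mean(vloss))
            entry["val_dice"] = float(np.nanmean(vdice))
            if keep_best and entry["val_dice"] > best[0]:
                best = (entry["val_dice"], model.state_dict())
        history.append(entry)
        if log is not None:
            log.write(json.dumps(entry) + "\n")
    if keep_best and best[1] is not None:
        model.load_state_dict(best[1])
    return history


def train_base(model: SegNet3d, train_cases, val_cases, spec: TrainSpec = BASE_TRAIN_SPEC,
               log=None):
    """Train all parameters from scratch; keeps the best-validation-Dice state.

    ``train_cases`` / ``val_cases``: lists of ``(x, y)`` pairs where ``x``
    is a float32 ``(4, *target_shape)`` array (already preprocessed) and
    ``y`` a binary mask of shape ``target_shape``. Returns the per-epoch
    loss/Dice history; reproducible given ``spec.seed``.
    """
    if not train_cases or not val_cases:
        raise ValueError("train and validation case lists must be nonempty")
    for p in model.params():
        p.trainable = True
    return _run_epochs(model, train_cases, val_cases, spec, keep_best=True, log=log)


def sample_finetune_cases(cases, max_cases: int, seed: int):
    """Seeded subsampler for the <= max_cases fine-tuning pool."""
    if len(cases) <= max_cases:
        return list(cases)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 211]))
    idx = rng.choice(len(cases), size=max_cases, replace=False)
    return [cases[i] for i in sorted(idx)]


def fine_tune(base_model: SegNet3d, registry: BlockRegistry, facility_cases,
              strategy: FreezeStrategy, spec: TrainSpec = FINE_TUNE_SPEC,
              max_cases: int = 20, log=None) -> SegNet3d:
    """Fine-tune a copy of ``base_model`` on one facility's cases.

    Only parameters in the strategy's learnable blocks may change;
    everything else remains bit-identical to the base model. At most
    ``max_cases`` cases are accepted (callers subsample explicitly with
    :func:`sample_finetune_cases`). No validation split: the epoch count
    is fixed by ``spec``.
    """
    if not facility_cases:
        raise ValueError("facility_cases must be nonempty")
    if len(facility_cases) > max_cases:
        raise ValueError(
            f"{len(facility_cases)} cases exceed max_cases={max_cases}; "
            "subsample explicitly (see sample_finetune_cases)"
        )
    model = base_model.copy()
    apply_freeze(model, model.registry, strategy)
    _run_epochs(model, facility_cases, [], spec, keep_best=False, log=log)
    return model
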