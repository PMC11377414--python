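"""Teacher–student semi-supervised training of the connected U-Net.

Two study pools drive the objective: Data A studies pair CT with acquired
PET (no masks) and supervise the pseudo-PET branch via MSE; Data B studies
pair CT with tumor masks (no PET) and supervise segmentation via focal+dice.
A teacher copy of the network, updated by exponential moving average of the
student, sees a randomly quarter-turned view of each Data B CT; disagreement
between the un-rotated teacher pseudo-PET and the student pseudo-PET is the
consistency term.  Only the student receives gradients.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from . import losses, nn
from .model import (ConnectedUNet, ModelConfig, load_checkpoint_weights,
                    save_checkpoint_weights)
from .nn import Tensor

__all__ = [
    "SampleA",
    "SampleB",
    "AugmentationSpec",
    "TrainerConfig",
    "TrainingState",
    "Checkpoint",
    "augment",
    "teacher_view",
    "rotate_back",
    "Trainer",
    "train",
    "predict",
    "ConnectedUNetSegmenter",
]


@dataclass
class SampleA:
    """A CT slice with its acquired-PET counterpart (no mask available)."""

    ct: np.ndarray
    pet: np.ndarray
    study_id: str = ""

    def __post_init__(self):
        if self.ct.shape != self.pet.shape:
            raise ValueError("ct and pet shapes differ")


@dataclass
class SampleB:
    """A CT slice with its binary tumor mask (no PET available)."""

    ct: np.ndarray
    mask: np.ndarray
    study_id: str = ""

    def __post_init__(self):
        if self.ct.shape != self.mask.shape:
            raise ValueError("ct and mask shapes differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


@dataclass
class AugmentationSpec:
    """Joint geometric augmentation: rotation, flipping, cropping."""

    rotation_degrees: tuple = (0, 90, 180, 270)
    flip_prob: float = 0.5
    crop_size: tuple | None = None
    seed: int = 0


def _rotate(grid: np.ndarray, angle: float, order: int) -> np.ndarray:
    if angle % 90 == 0:
        return np.rot90(grid, int(angle // 90) % 4).copy()
    return ndimage.rotate(grid, angle, reshape=False, order=order, mode="nearest")


def augment(sample, spec: AugmentationSpec, rng: np.random.Generator):
    """Apply one random draw of the spec jointly to every grid of the sample.

    Masks are resampled nearest-neighbor so they stay binary.
    """
    is_a = isinstance(sample, SampleA)
    grids = [sample.ct, sample.pet if is_a else sample.mask]
    orders = [1, 1] if is_a else [1, 0]

    angle = float(rng.choice(np.asarray(sorted(spec.rotation_degrees), dtype=float)))
    do_h = rng.random() < spec.flip_prob
    do_v = rng.random() < spec.flip_prob
    if spec.crop_size is not None:
        ch, cw = spec.crop_size
        h, w = grids[0].shape
        if ch > h or cw > w:
            raise ValueError(f"crop {spec.crop_size} larger than image {(h, w)}")
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))

    out = []
    for grid, order in zip(grids, orders):
        g = _rotate(grid, angle, order)
        if do_h:
            g = g[:, ::-1]
        if do_v:
            g = g[::-1, :]
        if spec.crop_size is not None:
            g = g[top:top + ch, left:left + cw]
        out.append(np.ascontiguousarray(g))
    if is_a:
        return SampleA(ct=out[0], pet=out[1], study_id=sample.study_id)
    return SampleB(ct=out[0], mask=np.rint(out[1]).astype(out[1].dtype),
                   study_id=sample.study_id)


def teacher_view(ct: np.ndarray, rng: np.random.Generator):
    """Random quarter-turn of a square CT slice plus the undo record."""
    h, w = ct.shape[-2:]
    if h != w:
        raise ValueError("teacher view requires square slices for quarter-turns")
    k = int(rng.integers(0, 4))
    return np.rot90(ct, k, axes=(-2, -1)).copy(), k


def rotate_back(grid: np.ndarray, record: int) -> np.ndarray:
    """Map a teacher output back to the student (un-rotated) frame."""
    return np.rot90(grid, -record, axes=(-2, -1)).copy()


@dataclass
class TrainerConfig:
    """All training hyperparameters, with the published values as defaults."""

    model: ModelConfig = field(default_factory=ModelConfig)
    epochs: int = 20
    batch_size_a: int = 8
    batch_size_b: int = 8
    lr_max: float = 1e-4
    lr_min: float = 1e-5
    focal_gamma: float = 2.0
    dice_smooth: float = 1e-6
    ramp_length: int = 80        # epochs over which the consistency weight ramps
    mask_threshold: float = 0.5
    use_pet_branch: bool = True      # ablation switch: drop H
    use_consistency: bool = True     # ablation switch: drop C
    augmentation: AugmentationSpec | None = None
    seed: int = 0


@dataclass
class TrainingState:
    """Mutable snapshot of the teacher–student loop."""

    student: ConnectedUNet
    teacher: ConnectedUNet
    step: int = 0
    epoch: int = 0
    alpha: float = 0.0
    w: float = losses.W_MAX

    @property
    def student_weights(self) -> dict:
        return {k: p.data for k, p in self.student.named_parameters().items()}

    @property
    def teacher_weights(self) -> dict:
        return {k: p.data for k, p in self.teacher.named_parameters().items()}


@dataclass
class Checkpoint:
    """Best-validation snapshot produced by `train`."""

    model_weights: dict
    teacher_weights: dict
    config: TrainerConfig
    validation_score: float
    epoch: int

    def save(self, path) -> None:
        meta = {"validation_score": self.validation_score, "epoch": self.epoch,
                "trainer": _trainer_cfg_dict(self.config)}
        save_checkpoint_weights(path, self.model_weights, self.teacher_weights,
                                self.config.model, meta)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        model_w, teacher_w, model_cfg, meta = load_checkpoint_weights(path)
        tmeta = meta.get("trainer", {})
        aug = tmeta.pop("augmentation", None)
        cfg = TrainerConfig(model=model_cfg,
                            **{k: v for k, v in tmeta.items() if k != "model"})
        if aug is not None:
            cfg.augmentation = AugmentationSpec(**{**aug,
                "rotation_degrees": tuple(aug["rotation_degrees"]),
                "crop_size": tuple(aug["crop_size"]) if aug["crop_size"] else None})
        return cls(model_weights=model_w, teacher_weights=teacher_w or model_w,
                   config=cfg, validation_score=meta.get("validation_score", 0.0),
                   epoch=meta.get("epoch", 0))

    def build_model(self) -> ConnectedUNet:
        model = ConnectedUNet(self.config.model, seed=self.config.seed)
        model.load_state_dict(self.model_weights)
        return model


def _trainer_cfg_dict(cfg: TrainerConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d.pop("model")
    return d


def _stack(grids: Sequence[np.ndarray]) -> np.ndarray:
    return np.stack([np.asarray(g, dtype=np.float32)[None] for g in grids])


class Trainer:
    """Runs the teacher–student loop and tracks the best validation DSC."""

    def __init__(self, config: TrainerConfig | None = None):
        self.config = config or TrainerConfig()
        cfg = self.config
        student = ConnectedUNet(cfg.model, seed=cfg.seed)
        teacher = ConnectedUNet(cfg.model, seed=cfg.seed)
        teacher.load_state_dict(student.state_dict())  # teacher starts as a copy
        self.state = TrainingState(student=student, teacher=teacher)
        self.optimizer = nn.Adam(student.parameters(), lr=cfg.lr_max)
        self.rng = np.random.default_rng(cfg.seed)
        self.history: list[dict] = []

    # -- one optimization step -------------------------------------------
    def train_step(self, batch_a: Sequence[SampleA],
                   batch_b: Sequence[SampleB]) -> losses.LossBreakdown:
        cfg, state = self.config, self.state
        if not batch_b:
            raise ValueError("batch_b must be non-empty (segmentation supervision)")
        state.w = losses.consistency_weight(state.epoch, cfg.ramp_length)
        state.alpha = losses.ema_schedule(state.step)
        w_eff = state.w if cfg.use_consistency else 0.0

        zero = Tensor(np.float32(0.0))
        # (i) PET supervision on Data A
        h_t = zero
        if batch_a and cfg.use_pet_branch:
            ct_a = Tensor(_stack([s.ct for s in batch_a]))
            pet_a = _stack([s.pet for s in batch_a])
            pet_pred, _ = state.student.unet1(ct_a)
            h_t = losses.pet_mse(pet_pred, pet_a)

        # (ii) segmentation supervision on Data B
        ct_b = Tensor(_stack([s.ct for s in batch_b]))
        mask_b = _stack([s.mask for s in batch_b])
        pet_sb, seg_logit = state.student.forward_tensors(ct_b)
        prob = nn.sigmoid(seg_logit)
        f_t = (losses.focal_loss(prob, mask_b, gamma=cfg.focal_gamma)
               + losses.dice_loss(prob, mask_b, smooth=cfg.dice_smooth))

        # (iii) consistency with the teacher on rotated Data B
        c_t = zero
        if cfg.use_consistency and cfg.use_pet_branch:
            views, records = zip(*(teacher_view(s.ct, self.rng) for s in batch_b))
            with nn.no_grad():
                pet_tb, _ = state.teacher.unet1(Tensor(_stack(views)))
            aligned = np.stack([rotate_back(m, r)
                                for m, r in zip(pet_tb.data[:, 0], records)])[:, None]
            c_t = losses.consistency_loss(pet_sb, aligned)

        # (iv) optimize the student on L = w*C + H + F
        total_t = w_eff * c_t + h_t + f_t
        breakdown = losses.total_loss(c_t.item(), h_t.item(), f_t.item(), w_eff)
        if not np.isfinite(breakdown.total):
            raise FloatingPointError(f"non-finite training loss: {breakdown}")
        self.optimizer.zero_grad()
        total_t.backward()
        self.optimizer.step()

        # (v) EMA teacher update
        losses.ema_update(state.teacher_weights, state.student_weights, state.alpha)
        state.step += 1
        return breakdown

    # -- epochs ----------------------------------------------------------
    def _batches(self, items: list, size: int, n_steps: int) -> list:
        if not items:
            return [[] for _ in range(n_steps)]
        order = self.rng.permutation(len(items))
        chunks = [[items[i] for i in order[k:k + size]]
                  for k in range(0, len(items), size)]
        return [chunks[i % len(chunks)] for i in range(n_steps)]

    def _maybe_augment(self, batch):
        spec = self.config.augmentation
        if spec is None:
            return batch
        return [augment(s, spec, self.rng) for s in batch]

    def fit(self, data_a: Sequence[SampleA], data_b: Sequence[SampleB],
            val_b: Sequence[SampleB]) -> Checkpoint:
        cfg = self.config
        if not data_b:
            raise ValueError("data_b must be non-empty")
        if not val_b:
            raise ValueError("validation set must be non-empty")
        best = (-1.0, 0, None, None)
        for epoch in range(cfg.epochs):
            self.state.epoch = epoch
            lr = nn.cosine_lr(epoch, cfg.epochs, cfg.lr_max, cfg.lr_min)
            self.optimizer.lr = lr
            n_steps = max(
                (len(data_a) + cfg.batch_size_a - 1) // cfg.batch_size_a if data_a else 0,
                (len(data_b) + cfg.batch_size_b - 1) // cfg.batch_size_b)
            batches_a = self._batches(list(data_a), cfg.batch_size_a, n_steps)
            batches_b = self._batches(list(data_b), cfg.batch_size_b, n_steps)
            for ba, bb in zip(batches_a, batches_b):
                bd = self.train_step(self._maybe_augment(ba), self._maybe_augment(bb))
                self.history.append({
                    "step": self.state.step, "epoch": epoch, "lr": lr,
                    "H": bd.pet_mse, "C": bd.consistency, "F": bd.seg,
                    "w": bd.w, "alpha": self.state.alpha, "total": bd.total})
            score = self.validate(val_b)
            self.history[-1]["val_dsc"] = score
            if score > best[0]:
                best = (score, epoch, self.state.student.state_dict(),
                        self.state.teacher.state_dict())
        return Checkpoint(model_weights=best[2], teacher_weights=best[3],
                          config=copy.deepcopy(cfg), validation_score=best[0],
                          epoch=best[1])

    def validate(self, val_b: Sequence[SampleB]) -> float:
        """Mean study-wise Dice: slices are pooled per study before scoring."""
        from .metrics import dice_coefficient

        cfg = self.config
        preds, by_study = [], {}
        with nn.no_grad():
            for k in range(0, len(val_b), cfg.batch_size_b):
                chunk = val_b[k:k + cfg.batch_size_b]
                out = self.state.student(_stack([s.ct for s in chunk]))
                preds += list(out.seg_prob[:, 0] > cfg.mask_threshold)
        for s, p in zip(val_b, preds):
            by_study.setdefault(s.study_id, []).append((p, s.mask.astype(bool)))
        scores = [dice_coefficient(np.stack([p for p, _ in pairs]),
                                   np.stack([m for _, m in pairs]))
                  for pairs in by_study.values()]
        return float(np.mean(scores))


def train(config: TrainerConfig, data_a, data_b, val_b) -> Checkpoint:
    """Run the full teacher–student loop; returns the best checkpoint."""
    return Trainer(config).fit(data_a, data_b, val_b)


def predict(checkpoint_or_model, volume, threshold: float = 0.5, batch: int = 8):
    """Slice-wise inference on a 3-D CT array or Volume.

    Returns (pseudo-PET volume, probability volume, binary mask volume) as
    numpy arrays on the input grid.
    """
    from .volume import Volume

    if isinstance(checkpoint_or_model, Checkpoint):
        model = checkpoint_or_model.build_model()
        threshold = checkpoint_or_model.config.mask_threshold
    else:
        model = checkpoint_or_model
    vox = volume.voxels if isinstance(volume, Volume) else np.asarray(volume)
    if vox.ndim != 3:
        raise ValueError("expected a (slices, rows, cols) CT array")
    pet = np.empty_like(vox, dtype=np.float32)
    prob = np.empty_like(vox, dtype=np.float32)
    with nn.no_grad():
        for k in range(0, vox.shape[0], batch):
            out = model(vox[k:k + batch, None].astype(np.float32))
            pet[k:k + batch] = out.pseudo_pet[:, 0]
            prob[k:k + batch] = out.seg_prob[:, 0]
    return pet, prob, (prob > threshold).astype(np.uint8)


class ConnectedUNetSegmenter(BaseEstimator):
    """Scikit-learn–style front end for the connected U-Net.

    ``fit`` accepts a mixed sequence of `SampleA` and `SampleB` slices (the
    supervision each sample carries determines which loss terms it feeds);
    ``predict`` maps a stack of CT slices to binary tumor masks.

    Parameters mirror `TrainerConfig`; fitted attributes carry the trained
    model (`model_`), its EMA teacher (`teacher_`), the best validation DSC
    (`best_score_`) and the per-step loss log (`history_`).
    """

    def __init__(self, base_width: int = 48, depth: int = 5, epochs: int = 20,
                 batch_size: int = 8, lr_max: float = 1e-4, lr_min: float = 1e-5,
                 focal_gamma: float = 2.0, ramp_length: int = 80,
                 mask_threshold: float = 0.5, use_pet_branch: bool = True,
                 use_consistency: bool = True, val_fraction: float = 0.2,
                 random_state: int = 0):
        self.base_width = base_width
        self.depth = depth
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_max = lr_max
        self.lr_min = lr_min
        self.focal_gamma = focal_gamma
        self.ramp_length = ramp_length
        self.mask_threshold = mask_threshold
        self.use_pet_branch = use_pet_branch
        self.use_consistency = use_consistency
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _trainer_config(self) -> TrainerConfig:
        return TrainerConfig(
            model=ModelConfig(base_width=self.base_width, depth=self.depth),
            epochs=self.epochs, batch_size_a=self.batch_size,
            batch_size_b=self.batch_size, lr_max=self.lr_max, lr_min=self.lr_min,
            focal_gamma=self.focal_gamma, ramp_length=self.ramp_length,
            mask_threshold=self.mask_threshold, use_pet_branch=self.use_pet_branch,
            use_consistency=self.use_consistency, seed=self.random_state)

    def fit(self, X, y=None, val_b: Sequence[SampleB] | None = None):
        data_a = [s for s in X if isinstance(s, SampleA)]
        data_b = [s for s in X if isinstance(s, SampleB)]
        if val_b is None:
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(data_b))
            n_val = max(1, int(round(self.val_fraction * len(data_b))))
            val_b = [data_b[i] for i in order[:n_val]]
            data_b = [data_b[i] for i in order[n_val:]]
        trainer = Trainer(self._trainer_config())
        ckpt = trainer.fit(data_a, data_b, val_b)
        self.checkpoint_ = ckpt
        self.model_ = ckpt.build_model()
        self.teacher_ = ConnectedUNet(ckpt.config.model, seed=self.random_state)
        self.teacher_.load_state_dict(ckpt.teacher_weights)
        self.best_score_ = ckpt.validation_score
        self.best_epoch_ = ckpt.epoch
        self.history_ = trainer.history
        self.n_parameters_ = self.model_.num_parameters()
        return self

    def predict_proba(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        _, prob, _ = predict(self.model_, np.asarray(X), self.mask_threshold)
        return prob

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) > self.mask_threshold).astype(np.uint8)

    def predict_pet(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        pet, _, _ = predict(self.model_, np.asarray(X), self.mask_threshold)
        return pet

    def score(self, X, y) -> float:
        """Mean Dice coefficient over slices."""
        from .metrics import dice_coefficient

        pred = self.predict(X)
        return float(np.mean([dice_coefficient(p, m) for p, m in zip(pred, y)]))
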