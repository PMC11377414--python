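"""Loss terms and scalar schedules of the teacher–student objective.

The training loss is L = w*C + H + F, where H is the mean-squared error
between true and pseudo-PET on PET-paired studies, F = focal + dice on
mask-labeled studies, and C is the consistency (MSE) between the student's
pseudo-PET and the teacher's pseudo-PET computed from a rotated view of the
same CT.  The teacher is an exponential moving average of the student with
decay alpha = min(1 - 1/(step+1), 0.99); the consistency weight ramps as
w = 0.1 * exp(-5 * (1 - T)^2) with T = clamp(1 - step/80, 0, 1).

Every function accepts either plain numpy arrays (returning a float) or
`conunet.nn.Tensor`s (returning a Tensor on the gradient tape).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "LossBreakdown",
    "pet_mse",
    "consistency_loss",
    "dice_loss",
    "focal_loss",
    "ema_schedule",
    "consistency_weight",
    "total_loss",
    "ema_update",
]

ALPHA_CAP = 0.99
W_MAX = 0.1
RAMP_LENGTH = 80


@dataclass(frozen=True)
class LossBreakdown:
    """Unweighted components plus the combined total of one training step."""

    consistency: float  # C
    pet_mse: float      # H
    seg: float          # F = focal + dice
    w: float
    total: float


def _check_shapes(a, b):
    sa = a.shape if hasattr(a, "shape") else np.shape(a)
    sb = b.shape if hasattr(b, "shape") else np.shape(b)
    if sa != sb:
        raise ValueError(f"shape mismatch: {sa} vs {sb}")


def _wrap(x):
    """(tensor, was_tensor) for dual numpy/Tensor entry points."""
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def pet_mse(pred, target):
    """Mean squared difference between pseudo-PET and acquired PET."""
    _check_shapes(pred, target)
    p, tp = _wrap(pred)
    t, tt = _wrap(target)
    out = ((p - t) ** 2.0).mean()
    return out if (tp or tt) else out.item()


def consistency_loss(student_pet, teacher_pet):
    """MSE between student and (un-rotated) teacher pseudo-PET maps."""
    return pet_mse(student_pet, teacher_pet)


def _validate_mask(mask_data: np.ndarray) -> None:
    if not np.isin(mask_data, (0, 1)).all():
        raise ValueError("mask must be binary (values in {0, 1})")


def dice_loss(prob, mask, smooth: float = 1e-6):
    """1 - (2*sum(p*m) + s) / (sum(p) + sum(m) + s), soft Dice overlap loss."""
    _check_shapes(prob, mask)
    p, tp = _wrap(prob)
    m, _ = _wrap(mask)
    _validate_mask(m.data)
    m = m.detach()
    inter = (p * m).sum()
    out = 1.0 - (2.0 * inter + smooth) / (p.sum() + m.sum() + smooth)
    return out if tp else out.item()


def focal_loss(prob, mask, gamma: float = 2.0, eps: float = 1e-7):
    """Mean of -(1 - p_t)^gamma * log(p_t); gamma 0 is binary cross-entropy."""
    _check_shapes(prob, mask)
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    p, tp = _wrap(prob)
    m, _ = _wrap(mask)
    _validate_mask(m.data)
    m = m.detach()
    pc = p.clip(eps, 1.0 - eps)
    pt = pc * m + (1.0 - pc) * (1.0 - m)
    out = -(((1.0 - pt) ** gamma) * pt.log()).mean()
    return out if tp else out.item()


def ema_schedule(step: int) -> float:
    """Teacher EMA decay: min(1 - 1/(step+1), 0.99)."""
    if step < 0:
        raise ValueError("step must be non-negative")
    return min(1.0 - 1.0 / (step + 1), ALPHA_CAP)


def consistency_weight(step: int, ramp_length: int = RAMP_LENGTH) -> float:
    """Ramp w = 0.1 * exp(-5 * (1 - T)^2), T = clamp(1 - step/ramp, 0, 1)."""
    t = min(max(1.0 - step / ramp_length, 0.0), 1.0)
    return W_MAX * math.exp(-5.0 * (1.0 - t) ** 2)


def total_loss(c: float, h: float, f: float, w: float) -> LossBreakdown:
    """Combine the components into L = w*C + H + F."""
    parts = (c, h, f, w)
    if not all(math.isfinite(v) for v in parts):
        raise ValueError(f"non-finite loss component: C={c}, H={h}, F={f}, w={w}")
    return LossBreakdown(consistency=c, pet_mse=h, seg=f, w=w, total=w * c + h + f)


def ema_update(teacher: dict, student: dict, alpha: float) -> dict:
    """theta'_t = alpha * theta'_{t-1} + (1 - alpha) * theta_t, per array.

    Operates on weight collections (name -> numpy array); arrays are updated
    in place so the same dict can track a live model, and the dict is also
    returned.  The student is never modified.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if set(teacher) != set(student):
        raise ValueError("teacher/student weight collections have different structure")
    a = np.float32(alpha)
    one_minus = np.float32(1.0 - alpha)
    for k, tv in teacher.items():
        sv = student[k]
        if tv.shape != sv.shape:
            raise ValueError(f"shape mismatch for weight {k}")
        tv *= a
        tv += one_minus * sv
    return teacher
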