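"""Synthetic chest-phantom studies for training and testing the pipeline.

Each study is a CT/PET/mask triple with the statistical structure the method
assumes: a bright body disc containing two dark elliptical lung fields, one
bright ellipsoidal tumor inside a lung field (coherent across slices), an
optional bright distractor blob in the opposite lung (never part of the
mask, there to create the false positives the area detector removes), and a
PET channel that is a blurred tumor-centered hot spot over a low background.
All intensities are normalized to [0, 1].
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .trainer import SampleA, SampleB
from .volume import Volume

__all__ = ["PhantomSpec", "PhantomStudy", "generate_phantom", "make_ab_split",
           "extract_slices"]


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters of one synthetic study.

    Defaults target a 64x64, 48-slice study whose tumor spans enough slices
    to exercise the 21-slice window logic of the area detector.
    """

    image_size: tuple = (64, 64)
    n_slices: int = 48
    tumor_radius_range: tuple = (4.0, 9.0)   # in-plane radius, pixels
    tumor_axial_factor: float = 1.5          # axial semi-axis = factor * radius
    tumor_intensity: float = 0.75            # contrast above the lung field
    distractor_intensity: float = 0.45       # distractor contrast (sub-tumor)
    pet_contrast: float = 5.0                # hot-spot multiple of background
    pet_blur_sigma: float = 2.0              # pixels
    noise_sigma: float = 0.03
    distractor_prob: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if min(self.tumor_radius_range) < 2:
            raise ValueError("tumor radii must be >= 2 px")
        if not 0.0 <= self.distractor_prob <= 1.0:
            raise ValueError("distractor_prob must lie in [0, 1]")


@dataclass
class PhantomStudy:
    ct: Volume
    pet: Volume
    mask: Volume
    spec: PhantomSpec
    tumor_center: tuple  # (slice, row, col)
    tumor_radius: float
    study_id: str = ""
    distractor_center: tuple | None = None  # (slice, row, col) when present


_BODY_LEVEL = 0.45
_LUNG_LEVEL = 0.12
_PET_BACKGROUND = 0.05


def _ellipse_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator | None = None,
                     study_id: str = "") -> PhantomStudy:
    """Draw one study; identical (spec, rng state) gives identical output."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    h, w = spec.image_size
    nz = spec.n_slices

    body = _ellipse_mask((h, w), (h / 2 - 0.5, w / 2 - 0.5), (h * 0.48, w * 0.48))
    lung_ax = (h * 0.30, w * 0.18)
    lung_centers = [(h / 2 - 0.5, w * 0.28), (h / 2 - 0.5, w * 0.72)]
    lungs = [_ellipse_mask((h, w), c, lung_ax) for c in lung_centers]

    radius = float(rng.uniform(*spec.tumor_radius_range))
    rz = spec.tumor_axial_factor * radius
    if radius >= min(lung_ax):
        raise ValueError(f"tumor radius {radius:.1f} exceeds the lung field")
    tumor_side = int(rng.integers(0, 2))
    lc = lung_centers[tumor_side]
    # keep the whole tumor inside its lung field
    cy = float(lc[0] + rng.uniform(-1, 1) * (lung_ax[0] - radius) * 0.5)
    cx = float(lc[1] + rng.uniform(-1, 1) * (lung_ax[1] - radius) * 0.5)
    cz = float(rng.uniform(rz + 1, nz - rz - 2)) if nz > 2 * rz + 3 else nz / 2

    tumor = _ellipse_mask((nz, h, w), (cz, cy, cx), (rz, radius, radius))

    ct2d = np.where(body, _BODY_LEVEL, 0.0)
    for lung in lungs:
        ct2d = np.where(lung, _LUNG_LEVEL, ct2d)
    ct = np.repeat(ct2d[None], nz, axis=0)
    ct[tumor] = _LUNG_LEVEL + spec.tumor_intensity

    # a distractor emulates a transient spurious detection: a smaller bright
    # blob in the opposite lung whose slice range is disjoint from the tumor's,
    # so the area detector's majority-cluster logic has something to remove
    distractor_center = None
    if rng.random() < spec.distractor_prob:
        dlc = lung_centers[1 - tumor_side]
        dr = float(rng.uniform(spec.tumor_radius_range[0],
                               max(spec.tumor_radius_range[0], radius)))
        drz = 0.75 * spec.tumor_axial_factor * dr
        lo_room = cz - rz - 2 * drz - 2          # space below the tumor run
        hi_room = (nz - 1) - (cz + rz) - 2 * drz - 2
        if max(lo_room, hi_room) > 0:
            if hi_room >= lo_room:
                dz = float(rng.uniform(cz + rz + drz + 2, nz - 1 - drz))
            else:
                dz = float(rng.uniform(drz, cz - rz - drz - 2))
            distractor = _ellipse_mask((nz, h, w), (dz, dlc[0], dlc[1]),
                                       (drz, dr, dr))
            ct[distractor] = _LUNG_LEVEL + spec.distractor_intensity  # not in mask
            distractor_center = (dz, float(dlc[0]), float(dlc[1]))

    pet = spec.pet_contrast * _PET_BACKGROUND * ndimage.gaussian_filter(
        tumor.astype(float), sigma=(0, spec.pet_blur_sigma, spec.pet_blur_sigma))
    pet += _PET_BACKGROUND * np.repeat(body[None], nz, axis=0)

    if spec.noise_sigma > 0:
        ct = ct + rng.normal(0.0, spec.noise_sigma, ct.shape)
        pet = pet + rng.normal(0.0, spec.noise_sigma * 0.5, pet.shape)
    ct = np.clip(ct, 0.0, 1.0).astype(np.float32)
    pet = np.clip(pet, 0.0, 1.0).astype(np.float32)
    mask = tumor.astype(np.uint8)

    spacing = (1.0, 1.0, 1.0)
    return PhantomStudy(
        ct=Volume(voxels=ct, spacing=spacing, modality="CT"),
        pet=Volume(voxels=pet, spacing=spacing, modality="PET"),
        mask=Volume(voxels=mask, spacing=spacing, modality="mask"),
        spec=copy.deepcopy(spec), tumor_center=(cz, cy, cx),
        tumor_radius=radius, study_id=study_id,
        distractor_center=distractor_center)


@dataclass
class StudySplit:
    """Study-level A/B/val/test partition with the supervision each keeps."""

    data_a: list   # studies exposing (ct, pet) only
    data_b: list   # studies exposing (ct, mask) only
    val: list
    test: list


@dataclass
class StudyA:
    ct: Volume
    pet: Volume
    study_id: str


@dataclass
class StudyB:
    ct: Volume
    mask: Volume
    study_id: str


def make_ab_split(studies: list[PhantomStudy], fractions=(0.8, 0.1, 0.1),
                  rng: np.random.Generator | None = None,
                  ab_ratio: float = 0.5) -> StudySplit:
    """Partition studies into train/val/test, then split training into
    PET-paired Data A and mask-labeled Data B (disjoint supervision).
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    n = len(studies)
    n_val = int(round(n * fractions[1]))
    n_test = int(round(n * fractions[2]))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"{n} studies are too few for a non-empty split")
    order = rng.permutation(n)
    train = [studies[i] for i in order[:n_train]]
    val = [studies[i] for i in order[n_train:n_train + n_val]]
    test = [studies[i] for i in order[n_train + n_val:]]
    n_a = int(round(len(train) * ab_ratio))
    data_a = [StudyA(ct=s.ct, pet=s.pet, study_id=s.study_id) for s in train[:n_a]]
    data_b = [StudyB(ct=s.ct, mask=s.mask, study_id=s.study_id) for s in train[n_a:]]
    to_b = lambda s: StudyB(ct=s.ct, mask=s.mask, study_id=s.study_id)
    return StudySplit(data_a=data_a, data_b=data_b,
                      val=[to_b(s) for s in val], test=[to_b(s) for s in test])


def extract_slices(studies, max_slices: int | None = None,
                   rng: np.random.Generator | None = None,
                   tumor_margin: int = 4):
    """Flatten studies into 2-D training samples.

    For mask-labeled studies only slices within `tumor_margin` of the tumor
    run are kept (plus the run itself); for PET-paired studies, slices whose
    PET exceeds background analogously.  `max_slices` subsamples the pool.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    samples = []
    for s in studies:
        if hasattr(s, "mask"):
            key = s.mask.voxels.reshape(s.mask.voxels.shape[0], -1).max(axis=1) > 0
        else:
            pools = s.pet.voxels.reshape(s.pet.voxels.shape[0], -1).max(axis=1)
            key = pools > 2.0 * _PET_BACKGROUND
        idx = np.nonzero(key)[0]
        if len(idx) == 0:
            continue
        lo = max(0, idx.min() - tumor_margin)
        hi = min(s.ct.voxels.shape[0] - 1, idx.max() + tumor_margin)
        for k in range(lo, hi + 1):
            if hasattr(s, "mask"):
                samples.append(SampleB(ct=s.ct.voxels[k], mask=s.mask.voxels[k],
                                       study_id=s.study_id))
            else:
                samples.append(SampleA(ct=s.ct.voxels[k], pet=s.pet.voxels[k],
                                       study_id=s.study_id))
    if max_slices is not None and len(samples) > max_slices:
        keep = rng.choice(len(samples), size=max_slices, replace=False)
        samples = [samples[i] for i in sorted(keep)]
    return samples
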