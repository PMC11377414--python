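"""Clustering-based tumor-area detection and re-prediction.

Refinement runs in three stages on a predicted slice sequence:

1. *Rotation expansion*: every CT slice is followed by its 90/180/270-degree
   rotations, quadrupling the sequence; the model predicts a tumor
   segmentation image (TSI) for each entry, and each prediction is mapped
   back to the original frame.
2. *Quadruple clustering*: around the middle slice of the longest
   tumor-positive run, up to 21 TSIs are selected; on each, the two mutually
   farthest tumor pixels form a quadruple (x_l, y_l, x_r, y_r); 2-means
   clustering of the quadruples separates the dominant tumor location from
   stray detections.
3. *Non-critical-area filtering*: the majority cluster's column means give
   two points whose bounding box, padded by lambda pixels (default 50) and
   clipped to the image, becomes a rectangular mask U; every CT slice is
   multiplied by U and re-predicted, and the refined masks are restricted
   to U.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

__all__ = [
    "SliceSequence",
    "Quadruple",
    "ClusterResult",
    "RegionMask",
    "expand_with_rotations",
    "unrotate_sequence",
    "select_tsi_window",
    "farthest_pair",
    "cluster_quadruples",
    "build_region_mask",
    "refine",
    "NoTumorDetectedError",
    "TumorAreaRefiner",
]

DEFAULT_LAMBDA = 50


class NoTumorDetectedError(RuntimeError):
    """Raised when no slice of the prediction contains tumor pixels."""


@dataclass
class SliceSequence:
    """Ordered 2-D slices with per-entry provenance (source index, rotation)."""

    slices: list
    provenance: list  # (source_index, rotation_degrees)

    def __len__(self) -> int:
        return len(self.slices)

    @classmethod
    def from_volume(cls, voxels) -> "SliceSequence":
        slices = [np.asarray(s) for s in voxels]
        return cls(slices=slices, provenance=[(i, 0) for i in range(len(slices))])


@dataclass(frozen=True)
class Quadruple:
    """The two mutually farthest tumor pixels of one slice (x = col, y = row)."""

    x_l: int
    y_l: int
    x_r: int
    y_r: int
    distance: float
    source_slice: int = -1

    def as_vector(self) -> np.ndarray:
        return np.array([self.x_l, self.y_l, self.x_r, self.y_r], dtype=float)


@dataclass
class ClusterResult:
    centers: np.ndarray    # (2, 4)
    assignment: np.ndarray  # label per quadruple
    sizes: tuple


@dataclass
class RegionMask:
    mask: np.ndarray  # binary, 1 exactly on one clipped axis-aligned rectangle
    p0: tuple         # (x, y) mean of left endpoints of the majority cluster
    p0_prime: tuple   # (x, y) mean of right endpoints
    lam: int


def expand_with_rotations(ct: "SliceSequence | list | np.ndarray") -> SliceSequence:
    """Insert the 90/180/270-degree rotations after each slice (x4 length)."""
    if not isinstance(ct, SliceSequence):
        ct = SliceSequence.from_volume(ct)
    slices, prov = [], []
    for idx, (s, (src, rot)) in enumerate(zip(ct.slices, ct.provenance)):
        s = np.asarray(s)
        if s.shape[0] != s.shape[1]:
            raise ValueError(f"slice {idx} is not square: {s.shape}")
        if rot != 0:
            raise ValueError("sequence is already rotation-expanded")
        for angle in (0, 90, 180, 270):
            slices.append(np.rot90(s, angle // 90).copy())
            prov.append((src, angle))
    return SliceSequence(slices=slices, provenance=prov)


def unrotate_sequence(seq: SliceSequence) -> SliceSequence:
    """Map every entry back to its source frame (inverse quarter-turns)."""
    slices = [np.rot90(np.asarray(s), -(rot // 90)).copy()
              for s, (_, rot) in zip(seq.slices, seq.provenance)]
    return SliceSequence(slices=slices,
                         provenance=[(src, 0) for src, _ in seq.provenance])


def _positive_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def select_tsi_window(tsi_masks, half_width: int = 10) -> list[int]:
    """Indices of up to 2*half_width+1 slices centered on the tumor run.

    The middle slice of the longest contiguous tumor-positive run anchors the
    window; the window is clipped to that run, so 21 slices are returned
    whenever the run is long enough.
    """
    slices = tsi_masks.slices if isinstance(tsi_masks, SliceSequence) else tsi_masks
    flags = np.array([np.any(np.asarray(s) > 0) for s in slices])
    if not flags.any():
        raise NoTumorDetectedError("no tumor-positive slice in the sequence")
    runs = _positive_runs(flags)
    start, end = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    middle = (start + end) // 2
    lo = max(start, middle - half_width)
    hi = min(end, middle + half_width)
    return list(range(lo, hi + 1))


def _brute_force_diameter(pts: np.ndarray) -> tuple[int, int, int]:
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = (diff.astype(np.int64) ** 2).sum(axis=-1)
    best = int(d2.max())
    ii, jj = np.nonzero(d2 == best)
    return best, ii, jj


def farthest_pair(tsi_mask: np.ndarray, source_slice: int = -1) -> Quadruple:
    """The positive-pixel pair with maximal Euclidean separation.

    Uses the convex hull (the diameter is attained at hull vertices) with an
    exact integer-distance brute force as fallback for degenerate point sets;
    ties break to the lexicographically smallest (x_l, y_l, x_r, y_r).
    """
    mask = np.asarray(tsi_mask) > 0
    ys, xs = np.nonzero(mask)
    if len(xs) < 2:
        raise ValueError("farthest_pair requires at least 2 positive pixels")
    pts = np.column_stack([xs, ys]).astype(np.int64)
    cand = pts
    if len(pts) > 16:
        try:
            cand = pts[ConvexHull(pts.astype(float)).vertices]
        except QhullError:  # collinear or otherwise degenerate set
            cand = pts
    best, ii, jj = _brute_force_diameter(cand)
    pairs = []
    for i, j in zip(ii, jj):
        a = (int(cand[i, 0]), int(cand[i, 1]))
        b = (int(cand[j, 0]), int(cand[j, 1]))
        pairs.append((a, b) if a <= b else (b, a))
    (xl, yl), (xr, yr) = min(pairs)
    return Quadruple(x_l=xl, y_l=yl, x_r=xr, y_r=yr,
                     distance=math.sqrt(best), source_slice=source_slice)


def cluster_quadruples(quads: list[Quadruple], seed: int = 0) -> ClusterResult:
    """2-means over the quadruple 4-vectors (10 restarts, fixed seed).

    With fewer than 2 quadruples a single-cluster result is returned (both
    centers coincide) so downstream masking still works.
    """
    if not quads:
        raise ValueError("no quadruples to cluster")
    X = np.stack([q.as_vector() for q in quads])
    if len(quads) < 2 or np.allclose(X, X[0]):
        center = X.mean(axis=0)
        return ClusterResult(centers=np.stack([center, center]),
                             assignment=np.zeros(len(quads), dtype=int),
                             sizes=(len(quads), 0))
    km = KMeans(n_clusters=2, n_init=10, max_iter=300, random_state=seed)
    labels = km.fit_predict(X)
    sizes = (int((labels == 0).sum()), int((labels == 1).sum()))
    return ClusterResult(centers=km.cluster_centers_, assignment=labels, sizes=sizes)


def _majority_label(cluster: ClusterResult, X: np.ndarray | None = None) -> int:
    s0, s1 = cluster.sizes
    if s0 != s1:
        return 0 if s0 > s1 else 1
    if X is not None:  # tie: prefer the tighter cluster, then the lower label
        var = [((X[cluster.assignment == l] - cluster.centers[l]) ** 2).sum()
               for l in (0, 1)]
        if not math.isclose(var[0], var[1]):
            return int(np.argmin(var))
    return 0


def build_region_mask(cluster: ClusterResult, lam: int, image_shape,
                      quads: list[Quadruple] | None = None) -> RegionMask:
    """Rectangle around the majority cluster's mean endpoints, padded by lam."""
    X = np.stack([q.as_vector() for q in quads]) if quads else None
    label = _majority_label(cluster, X)
    members = cluster.assignment == label
    if not members.any():
        raise ValueError("majority cluster is empty")
    if X is None:
        mean = cluster.centers[label]
    else:
        mean = X[members].mean(axis=0)
    x0, y0, x1, y1 = mean
    h, w = image_shape
    col_lo = max(0, int(round(min(x0, x1) - lam)))
    col_hi = min(w - 1, int(round(max(x0, x1) + lam)))
    row_lo = max(0, int(round(min(y0, y1) - lam)))
    row_hi = min(h - 1, int(round(max(y0, y1) + lam)))
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[row_lo:row_hi + 1, col_lo:col_hi + 1] = 1
    return RegionMask(mask=mask, p0=(float(x0), float(y0)),
                      p0_prime=(float(x1), float(y1)), lam=lam)


def refine(checkpoint_or_model, ct_volume, lam: int = DEFAULT_LAMBDA,
           seed: int = 0, threshold: float = 0.5, debug_dir=None) -> np.ndarray:
    """Full three-stage refinement; returns the refined binary mask volume.

    Raises `NoTumorDetectedError` when the first pass finds no tumor pixels
    anywhere in the rotation-expanded sequence.
    """
    from .trainer import Checkpoint, predict
    from .volume import Volume

    if isinstance(checkpoint_or_model, Checkpoint):
        model = checkpoint_or_model.build_model()
        threshold = checkpoint_or_model.config.mask_threshold
    else:
        model = checkpoint_or_model
    vox = ct_volume.voxels if isinstance(ct_volume, Volume) else np.asarray(ct_volume)

    expanded = expand_with_rotations(vox)
    _, _, tsi = predict(model, np.stack(expanded.slices), threshold)
    tsi_seq = unrotate_sequence(
        SliceSequence(slices=list(tsi), provenance=expanded.provenance))

    window = select_tsi_window(tsi_seq)
    quads = [farthest_pair(tsi_seq.slices[i], source_slice=i)
             for i in window if (np.asarray(tsi_seq.slices[i]) > 0).sum() >= 2]
    if not quads:
        raise NoTumorDetectedError("no slice in the window has >= 2 tumor pixels")
    cluster = cluster_quadruples(quads, seed=seed)
    region = build_region_mask(cluster, lam, vox.shape[1:], quads=quads)

    masked_ct = vox * region.mask[None]
    _, _, refined = predict(model, masked_ct, threshold)
    refined = (refined * region.mask[None]).astype(np.uint8)

    if debug_dir is not None:
        _dump_debug(Path(debug_dir), quads, cluster, region, window)
    return refined


def _dump_debug(debug_dir: Path, quads, cluster, region, window) -> None:
    import pandas as pd

    debug_dir.mkdir(parents=True, exist_ok=True)
    rows = [{"source_slice": q.source_slice, "x_l": q.x_l, "y_l": q.y_l,
             "x_r": q.x_r, "y_r": q.y_r, "distance": q.distance,
             "cluster": int(l)} for q, l in zip(quads, cluster.assignment)]
    pd.DataFrame(rows).to_csv(debug_dir / "quadruples.csv", index=False)
    np.savetxt(debug_dir / "region_mask.txt", region.mask, fmt="%d")
    (debug_dir / "window.txt").write_text(" ".join(map(str, window)))


class TumorAreaRefiner(BaseEstimator):
    """Estimator wrapper: refines the masks a fitted segmenter predicts.

    ``fit`` stores the segmentation model (a `ConnectedUNetSegmenter`, a
    `Checkpoint`, or a raw model); ``predict`` maps a CT volume to refined
    binary masks via the three-stage detection pipeline.
    """

    def __init__(self, lam: int = DEFAULT_LAMBDA, threshold: float = 0.5,
                 random_state: int = 0):
        self.lam = lam
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, segmenter, y=None):
        from .trainer import ConnectedUNetSegmenter

        if isinstance(segmenter, ConnectedUNetSegmenter):
            self.model_ = segmenter.model_
        elif hasattr(segmenter, "build_model"):
            self.model_ = segmenter.build_model()
        else:
            self.model_ = segmenter
        return self

    def predict(self, ct_volume) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        return refine(self.model_, ct_volume, lam=self.lam,
                      seed=self.random_state, threshold=self.threshold)
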