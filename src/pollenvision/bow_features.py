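"""Bag-of-visual-words features for pollen images.

Local interest points are detected and described on the grayscale image
with a scale- and rotation-tolerant gradient-based detector (SIFT); a
visual vocabulary is built by k-means over the descriptors pooled from the
training images only, and each image is then encoded as a histogram of
nearest-centroid assignments — the classic hard-assignment BOW pipeline.

The detector is pluggable: any callable with the ``detect_describe``
contract (keypoints + fixed-length descriptors) can stand in; the detector
tag is persisted with the vocabulary for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.feature import SIFT
from sklearn.cluster import KMeans

from .dataset_io import FeatureTable, SegmentedPollenImage, ValidationError

__all__ = [
    "DescriptorSet",
    "VisualVocabulary",
    "BOWHistogram",
    "detect_describe",
    "build_vocabulary",
    "encode_bow",
    "bow_feature_table",
    "phase1_vocab_sizes",
    "phase2_vocab_sizes",
    "tune_vocabulary_size",
    "save_vocabulary",
    "load_vocabulary",
]

DEFAULT_DETECTOR_TAG = "sift-skimage"

# vocabulary-size sweep bounds: exponential phase from 2 up to this cap
VOCAB_SIZE_CAP = 4392

# pooled-descriptor cap for k-means; subsampled deterministically per seed
MAX_POOLED_DESCRIPTORS = 150_000


@dataclass
class DescriptorSet:
    """Interest points and their descriptors for one image."""

    keypoints: np.ndarray  # (n, 3): row, col, scale
    descriptors: np.ndarray  # (n, descriptor_dim)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float).reshape(-1, 3)
        self.descriptors = np.asarray(self.descriptors, dtype=float)
        if self.descriptors.ndim != 2:
            self.descriptors = self.descriptors.reshape(len(self.keypoints), -1)
        if len(self.keypoints) != len(self.descriptors):
            raise ValidationError("one descriptor row per keypoint required")

    @property
    def n_keypoints(self) -> int:
        return len(self.keypoints)


@dataclass
class VisualVocabulary:
    """k-means centroids over local descriptors — the visual words."""

    centroids: np.ndarray  # (vocab_size, descriptor_dim)
    seed: int
    detector_tag: str = DEFAULT_DETECTOR_TAG

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or len(self.centroids) < 1:
            raise ValidationError("centroids must be a non-empty 2-D matrix")
        if not np.isfinite(self.centroids).all():
            raise ValidationError("centroid entries must be finite")

    @property
    def vocab_size(self) -> int:
        return self.centroids.shape[0]

    @property
    def descriptor_dim(self) -> int:
        return self.centroids.shape[1]


@dataclass
class BOWHistogram:
    counts: np.ndarray  # (vocab_size,) nonnegative ints
    n_keypoints: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.sum() != self.n_keypoints:
            raise ValidationError("histogram mass must equal keypoint count")


def _to_gray(image: SegmentedPollenImage) -> np.ndarray:
    return rgb2gray(image.pixels.astype(float) / 255.0)


def detect_describe(image: SegmentedPollenImage) -> DescriptorSet:
    """Detect and describe interest points on the grayscale image.

    Color is discarded; only keypoints inside the foreground mask (allowing
    a margin of the point's own scale) are retained, since the background of
    a segmented image is featureless by construction.  Deterministic for a
    fixed input; zero keypoints is a valid outcome.
    """
    gray = _to_gray(image)
    det = SIFT()
    try:
        det.detect_and_extract(gray)
    except RuntimeError:  # featureless image: no keypoints found
        return DescriptorSet(
            keypoints=np.empty((0, 3)), descriptors=np.empty((0, 128)),
            source_id=image.source_id,
        )
    kp = det.keypoints.astype(float)
    scales = det.sigmas.astype(float)  # per-keypoint blur scale in pixels
    desc = det.descriptors.astype(float)
    # distance (px) from each pixel to the nearest foreground pixel
    dist_to_fg = ndimage.distance_transform_edt(~image.mask)
    rr = np.clip(kp[:, 0].round().astype(int), 0, gray.shape[0] - 1)
    cc = np.clip(kp[:, 1].round().astype(int), 0, gray.shape[1] - 1)
    keep = dist_to_fg[rr, cc] <= np.maximum(scales, 1.0)
    if not keep.any():
        return DescriptorSet(
            keypoints=np.empty((0, 3)),
            descriptors=np.empty((0, desc.shape[1])),
            source_id=image.source_id,
        )
    return DescriptorSet(
        keypoints=np.column_stack([kp[keep, 0], kp[keep, 1], scales[keep]]),
        descriptors=desc[keep],
        source_id=image.source_id,
    )


def pool_descriptors(descriptor_sets: list[DescriptorSet]) -> np.ndarray:
    mats = [d.descriptors for d in descriptor_sets if d.n_keypoints > 0]
    if not mats:
        return np.empty((0, 128))
    return np.vstack(mats)


def build_vocabulary(
    descriptor_sets: list[DescriptorSet],
    vocab_size: int,
    seed: int,
    detector_tag: str = DEFAULT_DETECTOR_TAG,
) -> VisualVocabulary:
    """Cluster pooled training descriptors into ``vocab_size`` visual words.

    Single seeded k-means run (k-means++ init, iteration cap 300, relative
    tolerance 1e-4, Euclidean distance).  Descriptors must come from
    training images only; encoding never updates the centroids.
    """
    pooled = pool_descriptors(descriptor_sets)
    if len(pooled) < vocab_size:
        raise ValidationError(
            f"{len(pooled)} pooled descriptors < vocab_size {vocab_size}"
        )
    if len(pooled) > MAX_POOLED_DESCRIPTORS:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pooled), MAX_POOLED_DESCRIPTORS, replace=False)
        pooled = pooled[np.sort(idx)]
    km = KMeans(
        n_clusters=vocab_size, init="k-means++", n_init=1,
        max_iter=300, tol=1e-4, random_state=seed,
    )
    km.fit(pooled)
    return VisualVocabulary(
        centroids=km.cluster_centers_, seed=seed, detector_tag=detector_tag
    )


def encode_bow(descriptors: DescriptorSet, vocab: VisualVocabulary) -> BOWHistogram:
    """Hard-assign each descriptor to its nearest visual word.

    Euclidean distance; ties break to the lowest centroid index.
    """
    if descriptors.n_keypoints == 0:
        return BOWHistogram(
            counts=np.zeros(vocab.vocab_size, dtype=np.int64), n_keypoints=0
        )
    if descriptors.descriptors.shape[1] != vocab.descriptor_dim:
        raise ValidationError(
            f"descriptor dim {descriptors.descriptors.shape[1]} does not match "
            f"vocabulary dim {vocab.descriptor_dim}"
        )
    x = descriptors.descriptors
    c = vocab.centroids
    d2 = (x**2).sum(1)[:, None] - 2.0 * x @ c.T + (c**2).sum(1)[None, :]
    assign = np.argmin(d2, axis=1)  # argmin returns first (lowest) index on ties
    counts = np.bincount(assign, minlength=vocab.vocab_size)
    return BOWHistogram(counts=counts, n_keypoints=descriptors.n_keypoints)


def bow_feature_table(
    descriptor_sets: list[DescriptorSet],
    vocab: VisualVocabulary,
    labels: list[str],
    sample_ids: list[str] | None = None,
    normalize: bool = False,
) -> FeatureTable:
    """Encode a batch of images into a labeled BOW feature table."""
    rows = []
    for ds in descriptor_sets:
        h = encode_bow(ds, vocab).counts.astype(float)
        if normalize and h.sum() > 0:
            h = h / h.sum()
        rows.append(h)
    if sample_ids is None:
        sample_ids = [
            ds.source_id or f"sample_{i}" for i, ds in enumerate(descriptor_sets)
        ]
    return FeatureTable(
        values=np.vstack(rows),
        column_names=[f"word_{i}" for i in range(vocab.vocab_size)],
        labels=list(labels),
        sample_ids=list(sample_ids),
    )


# ---------------------------------------------------------------------------
# Vocabulary-size tuning: exponential sweep then arithmetic refinement

def phase1_vocab_sizes(cap: int = VOCAB_SIZE_CAP) -> list[int]:
    """Exponentially growing candidate sizes: 2, 4, 8, ... up to ``cap``."""
    sizes = []
    v = 2
    while v <= cap:
        sizes.append(v)
        v *= 2
    return sizes


def phase2_vocab_sizes(best: int, cap: int = VOCAB_SIZE_CAP) -> list[int]:
    """Arithmetic grid around a phase-1 optimum.

    Step = best / 8, spanning two phase-1 intervals on either side
    (best/4 .. 4*best), capped; this reaches refinement values like 768
    that lie off the pure power-of-two grid.
    """
    step = max(1, best // 8)
    lo = max(2, best // 4)
    hi = min(4 * best, cap)
    sizes = list(range(lo, hi + 1, step))
    return sorted(set(sizes))


def tune_vocabulary_size(
    evaluator,
    seed: int = 0,
    cap: int = VOCAB_SIZE_CAP,
) -> tuple[int, list[tuple[int, float]]]:
    """Two-phase vocabulary-size search.

    ``evaluator(size) -> score`` (typically cross-validated CCR).  Phase 1
    sweeps exponentially spaced sizes from 2 to ``cap``; phase 2 evaluates
    an arithmetic grid around the phase-1 optimum.  Returns the best size
    over both phases (ties break to the smallest size) and the full
    (size, score) trace.
    """
    trace: dict[int, float] = {}
    for v in phase1_vocab_sizes(cap):
        trace[v] = float(evaluator(v))
    best1 = min(sorted(trace), key=lambda v: (-trace[v], v))
    for v in phase2_vocab_sizes(best1, cap):
        if v not in trace:
            trace[v] = float(evaluator(v))
    best = min(sorted(trace), key=lambda v: (-trace[v], v))
    return best, sorted(trace.items())


# ---------------------------------------------------------------------------
# Vocabulary persistence (delimited text with a provenance header comment)

def save_vocabulary(vocab: VisualVocabulary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# vocab_size={vocab.vocab_size} seed={vocab.seed} "
            f"detector={vocab.detector_tag}\n"
        )
        for row in vocab.centroids:
            fh.write(",".join("%.12g" % v for v in row) + "\n")


def load_vocabulary(path: str | Path) -> VisualVocabulary:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(
            kv.split("=", 1) for kv in header.lstrip("# ").split() if "=" in kv
        )
        centroids = np.loadtxt(fh, delimiter=",", ndmin=2)
    return VisualVocabulary(
        centroids=centroids,
        seed=int(meta.get("seed", 0)),
        detector_tag=meta.get("detector", DEFAULT_DETECTOR_TAG),
    )
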